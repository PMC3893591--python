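"""Cross-species subgroup projection: NMF metagenes plus an SVM.

Four subgroup metagenes are extracted from a reference (human) expression
study by non-negative matrix factorisation, X ~ W H with W, H >= 0.  The
loadings W are then carried across species through an ortholog map, and
each target (mouse) sample's metagene scores are obtained by non-negative
least squares against the fixed, ortholog-restricted W.  A linear SVM
trained on the reference scores finally assigns each projected sample a
subgroup label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import SVC

from .metagene import ExpressionStudy

__all__ = [
    "NmfModel",
    "OrthologMap",
    "fit_nmf",
    "project_metagenes",
    "classify_projected",
    "SvmClassification",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NmfModel:
    """A fitted non-negative factorisation of a reference study."""

    W: pd.DataFrame            # genes x k, nonnegative loadings
    H: pd.DataFrame            # k x samples, rows scaled to unit maximum
    k: int
    residual: float            # relative Frobenius residual of the best restart
    residual_trajectory: np.ndarray   # per-iteration residuals (best restart)
    seed: int
    shift: pd.Series           # per-gene min subtracted before fitting
    h_row_max: np.ndarray = field(default=None)  # fit-time H row maxima (scaling constants)


@dataclass
class OrthologMap:
    """Unique (reference gene, target gene) pairs linking two studies."""

    pairs: pd.DataFrame  # columns: reference, target

    def __post_init__(self) -> None:
        self.pairs = self.pairs[["reference", "target"]].drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def read_tsv(cls, path) -> "OrthologMap":
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            names=["reference", "target"], dtype=str)
        return cls(frame)

    def collapsed_unique(self, reference_matrix: pd.DataFrame) -> pd.DataFrame:
        """Resolve many-to-many pairs to a one-to-one mapping.

        Candidate pairs are ranked by the training variance of their
        reference gene (most informative first) and greedily accepted while
        both sides are still unused — a deterministic rule that needs no
        cross-study samples.
        """
        variances = reference_matrix.var(axis=1, ddof=1)
        frame = self.pairs[self.pairs["reference"].isin(reference_matrix.index)].copy()
        frame["_var"] = frame["reference"].map(variances)
        frame = frame.sort_values(["_var", "reference", "target"],
                                  ascending=[False, True, True], kind="stable")
        used_ref, used_tgt, keep = set(), set(), []
        for row in frame.itertuples(index=False):
            if row.reference in used_ref or row.target in used_tgt:
                continue
            used_ref.add(row.reference)
            used_tgt.add(row.target)
            keep.append((row.reference, row.target))
        return pd.DataFrame(keep, columns=["reference", "target"])


def shift_nonnegative(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene minimum subtraction so every entry is >= 0."""
    shift = matrix.min(axis=1)
    return matrix.sub(shift, axis=0), shift


def _mu_nmf(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
            tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimising the squared Frobenius error."""
    n, m = X.shape
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS
    norm_x = np.linalg.norm(X)
    residuals = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        res = np.linalg.norm(X - W @ H) / (norm_x + _EPS)
        residuals.append(res)
        if prev - res < tol * max(prev, _EPS):
            break
        prev = res
    return W, H, np.asarray(residuals)


def fit_nmf(study: ExpressionStudy, k: int = 4, seed: int = 0,
            max_iter: int = 2000, tol: float = 1e-6,
            n_restarts: int = 10) -> NmfModel:
    """Fit k nonnegative metagenes to a reference study.

    The matrix is first shifted nonnegative by per-gene min subtraction.
    Multiplicative updates run until the relative residual change drops
    below ``tol`` or ``max_iter`` iterations; ``n_restarts`` seeded restarts
    keep the best residual.  H rows are scaled to unit maximum.
    """
    matrix = study.gene_matrix()
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite entries")
    if k < 1 or k > min(matrix.shape):
        raise ValueError(f"k must be in [1, {min(matrix.shape)}]")
    shifted, shift = shift_nonnegative(matrix)
    X = shifted.to_numpy(dtype=float)
    master = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(int(master.integers(2**31)))
        W, H, traj = _mu_nmf(X, k, rng, max_iter, tol)
        if best is None or traj[-1] < best[2][-1]:
            best = (W, H, traj)
    W, H, traj = best
    row_max = H.max(axis=1)
    row_max[row_max == 0] = 1.0
    H_scaled = H / row_max[:, None]
    factors = [f"metagene_{i + 1}" for i in range(k)]
    return NmfModel(
        W=pd.DataFrame(W, index=matrix.index, columns=factors),
        H=pd.DataFrame(H_scaled, index=factors, columns=matrix.columns),
        k=k, residual=float(traj[-1]), residual_trajectory=traj,
        seed=seed, shift=shift, h_row_max=row_max)


def project_metagenes(model: NmfModel, target: ExpressionStudy,
                      orthologs: OrthologMap, min_pairs: int = 50,
                      shift_target: bool = True) -> pd.DataFrame:
    """Score target samples against the fixed reference loadings.

    W is restricted to the ortholog rows; each target sample's scores are
    the nonnegative least-squares solution of ``W_orth s ~ x``.  Rows of the
    score matrix are scaled by the fit-time constants.

    ``shift_target`` applies the reference-style per-gene min subtraction to
    put raw log2 data on the factorisation scale.  Beware that in a
    *homogeneous* target cohort the per-gene minimum carries most of the
    shared signal, so min subtraction can strip it; data already on the
    factorisation scale (e.g. simulated from the loadings) should be
    projected with ``shift_target=False``.
    """
    target_matrix = target.gene_matrix()
    pairs = orthologs.collapsed_unique(model.W)
    pairs = pairs[pairs["target"].isin(target_matrix.index)]
    if len(pairs) < min_pairs:
        raise ValueError(
            f"only {len(pairs)} usable ortholog pairs (need >= {min_pairs})")
    W_orth = model.W.loc[pairs["reference"]].to_numpy(dtype=float)
    tgt = target_matrix.loc[pairs["target"]]
    if shift_target:
        shifted, _ = shift_nonnegative(tgt)
    else:
        if (tgt.to_numpy() < 0).any():
            raise ValueError("target matrix has negative entries; "
                             "use shift_target=True for raw log2 data")
        shifted = tgt
    X = shifted.to_numpy(dtype=float)
    scores = np.empty((model.k, X.shape[1]))
    for j in range(X.shape[1]):
        scores[:, j], _ = nnls(W_orth, X[:, j])
    # reuse the fit-time scaling so factor rows stay commensurate with H
    scores = scores / model.h_row_max[:, None]
    return pd.DataFrame(scores, index=model.H.index, columns=target_matrix.columns)


@dataclass
class SvmClassification:
    predictions: pd.Series
    margins: pd.DataFrame
    training_accuracy: float
    classes: list[str] = field(default_factory=list)


def classify_projected(train_scores: pd.DataFrame, train_labels: pd.Series,
                       test_scores: pd.DataFrame, C: float = 1.0) -> SvmClassification:
    """Linear one-vs-rest SVM on metagene scores.

    ``train_scores`` and ``test_scores`` are k x samples frames with matching
    factor rows.  Training accuracy is reported alongside the predictions
    and per-class decision margins.
    """
    labels = train_labels.reindex(train_scores.columns)
    classes = sorted(labels.dropna().unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes in training labels")
    for cls in classes:
        n = int((labels == cls).sum())
        if n < 3:
            logger.warning("class %s has only %d training samples", cls, n)
    svm = SVC(kernel="linear", C=C, decision_function_shape="ovr")
    X_train = train_scores.T.to_numpy(dtype=float)
    svm.fit(X_train, labels.to_numpy())
    train_acc = float(svm.score(X_train, labels.to_numpy()))
    X_test = test_scores.loc[train_scores.index].T.to_numpy(dtype=float)
    preds = pd.Series(svm.predict(X_test), index=test_scores.columns)
    decision = svm.decision_function(X_test)
    if decision.ndim == 1:  # binary: one column per convention
        decision = np.column_stack([-decision, decision])
    margins = pd.DataFrame(decision, index=test_scores.columns, columns=list(svm.classes_))
    return SvmClassification(predictions=preds, margins=margins,
                             training_accuracy=train_acc,
                             classes=[str(c) for c in svm.classes_])
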