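"""Differential expression, qPCR relative quantification and preranked GSEA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metagene import ExpressionStudy

__all__ = [
    "DeResult",
    "QpcrResult",
    "GseaResult",
    "differential_expression",
    "ddct_relative_expression",
    "preranked_gsea",
]

logger = logging.getLogger(__name__)


@dataclass
class DeResult:
    gene: str
    log_fold_change: float   # mean log2 difference, group A minus group B
    fold_change: float       # 2 ** log_fold_change
    t: float
    df: int
    p: float
    flagged: bool = False    # zero variance in both groups


@dataclass
class QpcrResult:
    sample: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    relative_quantity: float  # 2 ** -ddCt; calibrator == 1 by construction


@dataclass
class GseaResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    set_size: int
    n_perm: int
    seed: int


def differential_expression(study: ExpressionStudy, group_a, group_b,
                            adjust: bool = False) -> list[DeResult]:
    """Pooled-variance two-sample t-test per gene, sorted by |fold change|.

    The pooled (Student) form is used so df = nA + nB - 2 for every gene.
    Genes with zero variance in both groups get p = 1 and are flagged.
    ``adjust=True`` adds Benjamini-Hochberg correction of the p column.
    """
    matrix = study.gene_matrix()
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    df = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    denom = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    degenerate = denom == 0
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df))
    t = np.where(degenerate, 0.0, t)
    if degenerate.any():
        logger.warning("%d genes with zero variance in both groups; p set to 1",
                       int(degenerate.sum()))
    if adjust:
        p = multipletests(p, method="fdr_bh")[1]
    logfc = mean_a - mean_b
    results = [
        DeResult(gene=str(g), log_fold_change=float(lfc), fold_change=float(2.0 ** lfc),
                 t=float(ti), df=df, p=float(pi), flagged=bool(fl))
        for g, lfc, ti, pi, fl in zip(matrix.index, logfc, t, p, degenerate)
    ]
    results.sort(key=lambda r: abs(r.log_fold_change), reverse=True)
    return results


def ddct_relative_expression(ct_target: pd.Series, ct_reference: pd.Series,
                             calibrator: str, target_name: str = "target") -> list[QpcrResult]:
    """Relative qPCR quantification by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - dCt_calibrator;
    relative quantity = 2^-ddCt (so the calibrator sample is exactly 1).
    Samples missing either Ct are skipped with a warning.
    """
    if calibrator not in ct_target.index or pd.isna(ct_target.get(calibrator)) \
            or pd.isna(ct_reference.get(calibrator)):
        raise ValueError(f"calibrator sample {calibrator!r} has no complete Ct values")
    delta = ct_target - ct_reference.reindex(ct_target.index)
    calib_delta = float(delta[calibrator])
    results = []
    for sample, d_ct in delta.items():
        if pd.isna(d_ct):
            logger.warning("sample %s missing a Ct value; skipped", sample)
            continue
        ddct = float(d_ct) - calib_delta
        results.append(QpcrResult(sample=str(sample), target=target_name,
                                  delta_ct=float(d_ct), delta_delta_ct=ddct,
                                  relative_quantity=float(2.0 ** -ddct)))
    return results


def _running_es(order: np.ndarray, scores: np.ndarray, in_set: np.ndarray,
                weight: float) -> float:
    """Enrichment score: signed maximum deviation of the running sum.

    ``order`` indexes genes from best to worst rank; hits step up in
    proportion to |score|^weight, misses step down by 1/(N - set size).
    """
    hits = in_set[order]
    n = len(order)
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranked list")
    weights = np.abs(scores[order]) ** weight
    weights = np.where(hits, weights, 0.0)
    total = weights.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal steps
        weights = hits.astype(float)
        total = float(n_hits)
    running = np.cumsum(weights / total - (~hits) / (n - n_hits))
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranked: pd.Series, gene_sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> list[GseaResult]:
    """Preranked gene-set enrichment with a gene-label permutation null.

    ``ranked`` maps gene to a finite real ranking score (e.g. signed log2
    fold change); genes are ordered from highest to lowest.  For each set the
    running-sum enrichment score (ES) is computed, and nominal p / NES come
    from random same-size gene sets, normalised sign-separately: NES =
    ES / mean(null ES of the same sign), p = add-one tail fraction among
    same-sign null values.
    """
    scores = ranked.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    if ranked.index.duplicated().any():
        raise ValueError("ranked gene list contains duplicate genes")
    order = np.lexsort((ranked.index.to_numpy(), -scores))
    genes = ranked.index.to_numpy()
    rng = np.random.default_rng(seed)
    results = []
    for name, members in gene_sets.items():
        in_set = np.isin(genes, list(members))
        n_hits = int(in_set.sum())
        if n_hits < 2:
            logger.warning("gene set %s intersects the ranked list in %d genes; skipped",
                           name, n_hits)
            continue
        if n_hits == len(genes):
            raise ValueError(f"gene set {name} covers the entire ranked list")
        es = _running_es(order, scores, in_set, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_set = np.zeros(len(genes), dtype=bool)
            perm_set[rng.choice(len(genes), size=n_hits, replace=False)] = True
            null[b] = _running_es(order, scores, perm_set, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.sign(es) * np.inf
        else:
            p = (np.count_nonzero(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.mean(np.abs(same_sign))
        results.append(GseaResult(gene_set=str(name), es=es, nes=float(nes),
                                  p_value=float(p), set_size=n_hits,
                                  n_perm=n_perm, seed=seed))
    results.sort(key=lambda r: (r.p_value, -abs(r.nes)))
    return results
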