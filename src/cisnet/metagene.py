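"""Signed network metagene and its clinical association battery.

The metagene condenses the expression of a gene set into one score per
sample.  Each gene first receives an orientation: the sign of the summed
Spearman correlation with the other set members, so genes moving against
the majority contribute with a flipped sign and the score reflects the
unified action of the set.  The per-sample score is the mean of the signed
row-standardised (z-scored) log2 expression values.

Association tests: one-way ANOVA across molecular subgroups, a
label-permutation bootstrap of the Welch t for metastasis, and a
median-split two-group log-rank test for survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "SUBGROUPS",
    "ExpressionStudy",
    "CisGeneSign",
    "MetageneResult",
    "determine_signs",
    "metagene_score",
    "subgroup_anova",
    "bootstrap_t_test",
    "median_split_logrank",
    "LogrankResult",
]

logger = logging.getLogger(__name__)

#: the four molecular subgroups of medulloblastoma
SUBGROUPS = ("WNT", "SHH", "Group3", "Group4")


@dataclass
class ExpressionStudy:
    """A log2 expression matrix with per-sample clinical annotations.

    ``expression`` is probes-or-genes x samples.  ``annotations`` is indexed
    by sample id; recognised columns: ``subgroup``, ``metastasis`` (yes/no/
    unknown), ``time_months``, ``event`` (1 = death, 0 = censored).
    ``probe_to_gene`` maps probe ids to gene symbols when the matrix is at
    probe level.
    """

    expression: pd.DataFrame
    annotations: pd.DataFrame
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.annotations.index):
            if set(self.expression.columns) != set(self.annotations.index):
                raise ValueError("expression columns and annotation index disagree")
            self.annotations = self.annotations.loc[self.expression.columns]
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def gene_matrix(self) -> pd.DataFrame:
        """Collapse probes to genes, keeping per gene the probe with the
        highest mean expression across samples."""
        if self.probe_to_gene is None:
            return self.expression
        means = self.expression.mean(axis=1)
        frame = self.expression.copy()
        frame["_gene"] = self.probe_to_gene.reindex(frame.index)
        frame["_mean"] = means
        frame = frame.dropna(subset=["_gene"])
        best = (frame.sort_values("_mean", ascending=False, kind="stable")
                .drop_duplicates("_gene", keep="first"))
        return best.set_index("_gene").drop(columns=["_mean"]).rename_axis(None)


@dataclass
class CisGeneSign:
    """Orientation (+1/-1) per gene with the correlation evidence behind it."""

    signs: dict[str, int]
    evidence: dict[str, float]
    missing: list[str] = field(default_factory=list)

    def __getitem__(self, gene: str) -> int:
        return self.signs[gene]


@dataclass
class MetageneResult:
    """Per-sample signed network activity score."""

    scores: pd.Series
    genes_used: list[str]
    signs_used: dict[str, int]
    genes_skipped: list[str] = field(default_factory=list)


def determine_signs(study: ExpressionStudy, cis_genes) -> CisGeneSign:
    """Orient each gene by the sign of its summed Spearman correlation with
    the other set members.

    A zero sum defaults to +1 with a warning; genes absent from the matrix
    are excluded and reported.
    """
    matrix = study.gene_matrix()
    present = [g for g in cis_genes if g in matrix.index]
    missing = sorted(set(cis_genes) - set(present))
    if missing:
        logger.info("genes absent from expression matrix, excluded: %s",
                    ", ".join(missing))
    if len(present) < 2:
        raise ValueError("need at least 2 CIS genes present in the matrix")
    sub = matrix.loc[present].T  # samples x genes
    corr = sub.corr(method="spearman").to_numpy()
    np.fill_diagonal(corr, 0.0)
    sums = corr.sum(axis=1)
    signs, evidence = {}, {}
    for gene, total in zip(present, sums):
        if total == 0:
            logger.warning("gene %s: correlation sum is exactly 0; defaulting to +1", gene)
        signs[gene] = 1 if total >= 0 else -1
        evidence[gene] = float(total)
    return CisGeneSign(signs=signs, evidence=evidence, missing=missing)


def metagene_score(study: ExpressionStudy, genes, signs: CisGeneSign) -> MetageneResult:
    """Mean of signed z-scored expression over the gene set, per sample."""
    matrix = study.gene_matrix()
    usable, skipped = [], []
    for gene in genes:
        if gene not in matrix.index or gene not in signs.signs:
            skipped.append(gene)
            continue
        if matrix.loc[gene].std(ddof=1) == 0:
            logger.warning("gene %s has zero variance; skipped", gene)
            skipped.append(gene)
            continue
        usable.append(gene)
    if not usable:
        raise ValueError("no usable genes for metagene scoring")
    sub = matrix.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    sign_vec = pd.Series({g: signs.signs[g] for g in usable})
    scores = z.mul(sign_vec, axis=0).mean(axis=0)
    return MetageneResult(scores=scores, genes_used=usable,
                          signs_used={g: signs.signs[g] for g in usable},
                          genes_skipped=skipped)


def _clean_groups(values: pd.Series, labels: pd.Series, drop={"unknown", ""}):
    mask = labels.notna() & ~labels.astype(str).isin(drop)
    return values[mask], labels[mask]


def subgroup_anova(scores: pd.Series, subgroups: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of metagene scores across subgroups.

    Samples with unknown subgroup are excluded; singleton groups are dropped
    with a warning.
    """
    values, labels = _clean_groups(scores, subgroups.reindex(scores.index))
    groups = []
    for name, grp in values.groupby(labels):
        if len(grp) < 2:
            logger.warning("subgroup %s has n=%d; excluded from ANOVA", name, len(grp))
            continue
        groups.append(grp.to_numpy())
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups with n >= 2")
    f_stat, p = stats.f_oneway(*groups)
    return float(f_stat), float(p)


def bootstrap_t_test(scores: pd.Series, labels: pd.Series, n_boot: int = 10_000,
                     seed: int = 0) -> tuple[float, float]:
    """Welch t with a label-permutation null.

    The reported t is the classical Welch statistic on the observed data;
    the two-sided p is the add-one tail fraction of |t| under ``n_boot``
    random relabelings.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    values, lab = _clean_groups(scores, labels.reindex(scores.index))
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes}")
    a = values[lab == classes[0]].to_numpy()
    b = values[lab == classes[1]].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("each class needs n >= 2")
    t_obs = stats.ttest_ind(a, b, equal_var=False).statistic
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        perm = rng.permutation(pooled)
        t_null = stats.ttest_ind(perm[:len(a)], perm[len(a):], equal_var=False).statistic
        if abs(t_null) >= abs(t_obs):
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return float(t_obs), float(p)


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    n_high: int
    n_low: int
    threshold: float


def median_split_logrank(values: pd.Series, time: pd.Series, event: pd.Series) -> LogrankResult:
    """Two-group log-rank (Mantel-Cox) test after a median split.

    Samples at or above the median of ``values`` form the high group.  The
    statistic is the standard observed-minus-expected summation over distinct
    event times; p from chi-squared with 1 df.
    """
    common = values.index.intersection(time.index)
    values, time, event = values[common], time[common], event[common]
    mask = values.notna() & time.notna() & event.notna()
    values, time, event = values[mask], time[mask], event[mask]
    if event.sum() < 1:
        raise ValueError("need at least one event")
    threshold = float(values.median())
    high = values >= threshold
    if high.all() or (~high).all():
        raise ValueError("median split produced a single group (constant values?)")
    result = logrank_test(time[high], time[~high], event[high], event[~high])
    return LogrankResult(chi2=float(result.test_statistic), p_value=float(result.p_value),
                         n_high=int(high.sum()), n_low=int((~high).sum()),
                         threshold=threshold)
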