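"""Published reference tables bundled with the package.

The CIS catalogue is the published table of common insertion sites called
by Gaussian kernel convolution in a whole-body Sleeping Beauty screen on
Ptch+/- mice: 20 CISs in medulloblastomas (17 carrying gene symbols, 3
named by coordinate) and 5 in cerebellum controls, with the per-CIS sample
count (N), insert count (I), width in kb, GKC p-value, and inferred mode of
action.  ``mc_support`` marks loci independently recovered by the
Monte-Carlo comparison caller.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_cis_catalog",
    "catalog_pvalues",
    "count_named_genes",
    "BIALLELIC_CONTINGENCY",
]

#: Biallelic-hit contingency counts from an independent tissue-specific
#: screen: of 17 biallelically-hit genes, 6 fall among the 90 genes of the
#: CIS co-expression network versus 11 among the 5823 genes outside it.
BIALLELIC_CONTINGENCY = {
    "hits_in": 6,
    "total_in": 90,
    "hits_out": 11,
    "total_out": 5823,
}


def load_cis_catalog(cohort: str | None = None) -> pd.DataFrame:
    """The bundled CIS catalogue as a DataFrame.

    ``cohort`` filters to ``"medulloblastoma"`` or ``"cerebellum_control"``;
    p-values stay as printed (censored entries like ``"<1E-14"`` are kept as
    strings — :func:`cisnet.cis.median_cis_pvalue` knows how to parse them).
    """
    path = resources.files("cisnet.data") / "mb_cis_catalog.tsv"
    with resources.as_file(path) as fname:
        frame = pd.read_csv(fname, sep="\t", dtype={"gkc_p": str, "chromosome": str})
    if cohort is not None:
        frame = frame[frame["cohort"] == cohort].reset_index(drop=True)
    return frame


def catalog_pvalues(cohort: str = "medulloblastoma") -> list[str]:
    """The printed GKC p-value column for one cohort (as strings)."""
    return list(load_cis_catalog(cohort)["gkc_p"])


def count_named_genes(cohort: str = "medulloblastoma") -> int:
    """Number of catalogue CISs assigned a gene symbol (vs coordinate names)."""
    frame = load_cis_catalog(cohort)
    return int((~frame["gene"].str.startswith("CIS")).sum())
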