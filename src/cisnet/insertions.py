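"""Transposon insertion datasets: BED I/O and contamination filters.

A Sleeping Beauty screen yields, per tumour, the genomic TA dinucleotides
into which the transposon re-inserted.  Two artefact classes are removed
before hotspot statistics:

* **Same-Site Inserts (SSI)** — the identical dinucleotide occupied in two
  or more *different* samples.  Independent re-insertion into the same TA
  site is vanishingly unlikely, so these are treated as cross-sample
  contamination and *all* copies are dropped.
* **Same-Tumour Inserts (STI)** — several inserts from one sample inside a
  single called common insertion site.  Local hopping inflates the insert
  count without adding independent evidence; each sample keeps one insert
  per CIS footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeDefinition

__all__ = [
    "SITE_COLUMNS",
    "InsertionDataset",
    "FilterReport",
    "read_insertion_bed",
    "write_insertion_bed",
    "remove_same_site_inserts",
    "collapse_same_tumour_inserts",
]

logger = logging.getLogger(__name__)

#: canonical column order of :attr:`InsertionDataset.sites`
SITE_COLUMNS = ["sample_id", "chromosome", "position", "strand", "read_count"]


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": pd.Series(dtype=str),
        "chromosome": pd.Series(dtype=str),
        "position": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "read_count": pd.Series(dtype=float),
    })


@dataclass
class InsertionDataset:
    """Mapped insertion sites for a cohort of samples.

    ``sites`` columns: sample_id, chromosome, position (1-based first base of
    the TA dinucleotide), strand ('+', '-' or '.'), read_count (may be NaN).
    """

    sites: pd.DataFrame
    genome: GenomeDefinition
    cohort: str = ""

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            self.sites = _empty_sites()
            return
        self.sites = self.sites[SITE_COLUMNS].reset_index(drop=True)
        bad_chroms = set(self.sites["chromosome"]) - set(self.genome.lengths)
        if bad_chroms:
            raise ValueError(
                "insertion sites on chromosomes absent from the genome definition: "
                + ", ".join(sorted(bad_chroms))
            )
        lengths = self.sites["chromosome"].map(self.genome.lengths)
        pos = self.sites["position"]
        if (pos < 1).any() or (pos > lengths).any():
            raise ValueError("insertion positions outside chromosome bounds")
        if (self.sites["sample_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty sample_id")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return self.sites["sample_id"].nunique()

    def positions_on(self, chromosome: str) -> np.ndarray:
        """Sorted insertion positions on one chromosome."""
        mask = self.sites["chromosome"] == chromosome
        return np.sort(self.sites.loc[mask, "position"].to_numpy())

    def subset(self, mask) -> "InsertionDataset":
        return InsertionDataset(self.sites[mask].reset_index(drop=True),
                                self.genome, self.cohort)


@dataclass
class FilterReport:
    """Accounting of a filtering pass.

    The conservation identity ``input = retained + ssi_removed + sti_removed``
    holds on the post-collapse input count; within-sample duplicates merged at
    one dinucleotide are tallied separately in ``duplicates_collapsed``.
    """

    input: int
    retained: int
    ssi_removed: int = 0
    sti_removed: int = 0
    duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        if self.input != self.retained + self.ssi_removed + self.sti_removed:
            raise ValueError("filter report does not conserve insert counts")


def read_insertion_bed(path, genome: GenomeDefinition, cohort: str = "") -> InsertionDataset:
    """Read a 6-column insertion BED file.

    BED convention: 0-based half-open start/end, name = sample id,
    score = read count.  In memory, position = start + 1 (1-based).
    Malformed rows are reported with their line numbers.
    """
    rows = []
    bad_lines = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom, start = fields[0], int(fields[1])
                sample = fields[3] if len(fields) > 3 else "sample"
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else np.nan
                strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            except (IndexError, ValueError):
                bad_lines.append(lineno)
                continue
            rows.append((sample, chrom, start + 1, strand, score))
    if bad_lines:
        logger.warning("%s: skipped %d malformed rows (lines %s)",
                       path, len(bad_lines), ", ".join(map(str, bad_lines[:20])))
    if not rows:
        logger.warning("%s: no insertion records found", path)
        return InsertionDataset(_empty_sites(), genome, cohort)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return InsertionDataset(sites, genome, cohort)


def write_insertion_bed(ds: InsertionDataset, path) -> None:
    """Write a dataset as 6-column BED (inverse of :func:`read_insertion_bed`)."""
    with open(path, "w") as handle:
        for row in ds.sites.itertuples(index=False):
            score = "0" if pd.isna(row.read_count) else f"{row.read_count:g}"
            strand = row.strand if row.strand in {"+", "-"} else "."
            handle.write(f"{row.chromosome}\t{row.position - 1}\t{row.position + 1}\t"
                         f"{row.sample_id}\t{score}\t{strand}\n")


def remove_same_site_inserts(ds: InsertionDataset) -> tuple[InsertionDataset, FilterReport]:
    """Drop every insert at a dinucleotide shared by two or more samples.

    Within-sample duplicates at one dinucleotide are first collapsed to a
    single site (keeping the maximum read count); they are accounted as
    ``duplicates_collapsed``, not as SSIs.
    """
    sites = ds.sites
    if len(sites) == 0:
        return ds, FilterReport(0, 0)
    collapsed = (
        sites.sort_values("read_count", ascending=False, kind="stable")
        .drop_duplicates(["sample_id", "chromosome", "position"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    n_dupes = len(sites) - len(collapsed)
    n_samples_at_site = collapsed.groupby(["chromosome", "position"])["sample_id"].transform("nunique")
    shared = n_samples_at_site >= 2
    n_ssi = int(shared.sum())
    if n_ssi:
        removed = collapsed[shared]
        for (chrom, pos), grp in removed.groupby(["chromosome", "position"]):
            logger.info("SSI removal: %s:%d shared by samples %s — all %d copies dropped",
                        chrom, pos, sorted(grp["sample_id"].unique()), len(grp))
    kept = collapsed[~shared].reset_index(drop=True)
    report = FilterReport(input=len(collapsed), retained=len(kept),
                          ssi_removed=n_ssi, duplicates_collapsed=n_dupes)
    return InsertionDataset(kept, ds.genome, ds.cohort), report


def collapse_same_tumour_inserts(ds: InsertionDataset, peaks) -> tuple[InsertionDataset, FilterReport]:
    """Keep one insert per sample inside each CIS footprint.

    ``peaks`` is a list of called CIS peaks carrying ``chromosome``,
    ``start``, ``end`` and ``raw_p``.  Where footprints overlap, each site is
    attributed to the peak with the smaller raw p-value before collapsing.
    Within one footprint a sample retains its highest-read-count insert
    (leftmost on ties).  Sites outside every footprint pass through untouched.
    """
    sites = ds.sites
    if len(sites) == 0 or not peaks:
        return ds, FilterReport(len(sites), len(sites))
    ordered = sorted(peaks, key=lambda p: (p.raw_p, p.chromosome, p.start))
    assignment = np.full(len(sites), -1, dtype=int)
    chrom = sites["chromosome"].to_numpy()
    pos = sites["position"].to_numpy()
    for idx, peak in enumerate(ordered):
        inside = (assignment == -1) & (chrom == peak.chromosome) & \
                 (pos >= peak.start) & (pos <= peak.end)
        assignment[inside] = idx
    work = sites.assign(_peak=assignment,
                        _rc=sites["read_count"].fillna(-np.inf))
    outside = work[work["_peak"] == -1]
    inside = work[work["_peak"] >= 0]
    kept_inside = (
        inside.sort_values(["_rc", "position"], ascending=[False, True], kind="stable")
        .drop_duplicates(["_peak", "sample_id"], keep="first")
    )
    n_sti = len(inside) - len(kept_inside)
    kept = (
        pd.concat([outside, kept_inside])
        .sort_index()
        .drop(columns=["_peak", "_rc"])
        .reset_index(drop=True)
    )
    report = FilterReport(input=len(sites), retained=len(kept), sti_removed=n_sti)
    return InsertionDataset(kept, ds.genome, ds.cohort), report
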