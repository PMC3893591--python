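"""Recovery and calibration suites run on the synthetic study conditions.

These routines define the package's standard validation experiments — a
spike-in power run for the GKC caller, null-calibration sweeps for the
permutation tests, a planted-sign recovery run for the metagene, and the
full synthetic cross-species projection.  Both the test suite and the
reproduction script execute them; every routine is fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import crossspecies, exprstats
from . import metagene as mg
from . import network as net
from . import simulate as sim
from .cis import gkc_cis_scan
from .genome import GenomeDefinition
from .insertions import remove_same_site_inserts
from .metagene import median_split_logrank

__all__ = [
    "TOY_GENOME",
    "spikein_recovery",
    "cluster_test_calibration",
    "gsea_calibration",
    "logrank_type1_rate",
    "sign_recovery",
    "cross_species_recovery",
]

#: three-chromosome toy genome used by the spike-in suite
TOY_GENOME = GenomeDefinition({"chr1": 20_000_000, "chr2": 15_000_000,
                               "chr3": 10_000_000})

#: planted CIS loci: 10 spikes, each 5 samples x 2 inserts in a 10 kb window
TOY_SPIKE_CENTERS = {
    "chr1": (3_000_000, 8_000_000, 13_000_000, 18_000_000),
    "chr2": (3_000_000, 8_000_000, 13_000_000),
    "chr3": (2_500_000, 5_500_000, 8_500_000),
}


@dataclass
class SpikeinResult:
    n_spikes: int
    n_recovered: int
    n_called: int
    n_false: int

    @property
    def fdp(self) -> float:
        """Realised false-discovery proportion among called peaks."""
        return self.n_false / self.n_called if self.n_called else 0.0


def spikein_recovery(seed: int = 11, n_samples: int = 20,
                     background_per_sample: float = 10.0,
                     scales=(15_000, 30_000, 60_000), n_perm: int = 500,
                     alpha: float = 0.05) -> SpikeinResult:
    """Plant 10 CISs on the toy genome and score caller recovery and FDP.

    A spike counts as recovered when a called footprint covers its center;
    a called peak is false when its summit lies beyond width + scale of
    every planted center.
    """
    spikes = [sim.CisSpikeSpec(chrom, center, 10_000, 5, 2)
              for chrom, centers in TOY_SPIKE_CENTERS.items() for center in centers]
    ds, _ = sim.simulate_insertions(TOY_GENOME, n_samples, background_per_sample,
                                    spikes, seed=seed)
    ds, _ = remove_same_site_inserts(ds)
    peaks = gkc_cis_scan(ds, scales=scales, n_perm=n_perm, alpha=alpha, seed=seed + 1)
    recovered = sum(
        any(p.chromosome == s.chromosome and p.start <= s.center <= p.end for p in peaks)
        for s in spikes)
    false = sum(
        not any(p.chromosome == s.chromosome and
                abs(p.position - s.center) <= s.width + p.scale for s in spikes)
        for p in peaks)
    return SpikeinResult(n_spikes=len(spikes), n_recovered=int(recovered),
                         n_called=len(peaks), n_false=int(false))


def _calibration_graph(seed: int, n_nodes: int = 500, degree: int = 2) -> nx.Graph:
    """A connected sparse random graph for null calibration.

    The default (a uniform random recursive tree) has a broad shortest-path
    distribution, so the mean-nearest-member statistic takes many values and
    the tie-conservative permutation p stays close to uniform under the null.
    """
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    names = [f"g{i}" for i in range(n_nodes)]
    graph.add_nodes_from(names)
    for i in range(1, n_nodes):
        graph.add_edge(names[i], names[int(rng.integers(0, i))])
    for _ in range(n_nodes * (degree - 2) // 2):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        graph.add_edge(names[a], names[b])
    return graph


def cluster_test_calibration(seed: int = 0, n_replicates: int = 200,
                             n_perm: int = 199, set_size: int = 7) -> tuple[np.ndarray, float]:
    """Null p-values of the cluster test when the gene set itself is random.

    Returns the p-values and the Kolmogorov-Smirnov p against U(0, 1); under
    a calibrated test the KS test should not reject.
    """
    graph = _calibration_graph(seed)
    _, _, dist = net._distance_matrix(graph)   # computed once for all replicates
    n_nodes = dist.shape[0]
    rng = np.random.default_rng(seed + 1)
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        members = rng.choice(n_nodes, size=set_size, replace=False)
        _, _, pvals[rep] = net._cluster_test_from_matrix(
            dist, members, n_perm, np.random.default_rng(int(rng.integers(2**31))))
    ks_p = stats.kstest(pvals, "uniform").pvalue
    return pvals, float(ks_p)


def gsea_calibration(seed: int = 0, n_replicates: int = 200, n_genes: int = 400,
                     set_size: int = 25, n_perm: int = 99) -> tuple[np.ndarray, float]:
    """Null nominal p-values of preranked GSEA for random gene sets."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        ranked = pd.Series(rng.normal(size=n_genes), index=genes)
        members = set(rng.choice(genes, size=set_size, replace=False))
        res = exprstats.preranked_gsea(ranked, {"random": members}, weight=1.0,
                                       n_perm=n_perm, seed=int(rng.integers(2**31)))
        pvals[rep] = res[0].p_value
    ks_p = stats.kstest(pvals, "uniform").pvalue
    return pvals, float(ks_p)


def logrank_type1_rate(seed: int = 0, n_studies: int = 500, n_samples: int = 60,
                       alpha: float = 0.05) -> float:
    """Type-I error of the median-split log-rank test under a null coupling.

    Survival is exponential and independent of the split variable, censored
    administratively at 15 months; the rejection rate at ``alpha`` should sit
    near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    index = [f"S{i}" for i in range(n_samples)]
    for _ in range(n_studies):
        values = pd.Series(rng.normal(size=n_samples), index=index)
        raw = rng.exponential(10.0, size=n_samples)
        event = pd.Series((raw <= 15.0).astype(int), index=index)
        time = pd.Series(np.minimum(raw, 15.0), index=index)
        res = median_split_logrank(values, time, event)
        rejections += res.p_value < alpha
    return rejections / n_studies


def sign_recovery(seed: int = 42, n_genes: int = 300, n_samples: int = 200,
                  metagene_effect: float = 2.0, noise_sd: float = 1.0) -> float:
    """Fraction of planted orientations recovered by the sign rule."""
    study, _, truth = sim.simulate_expression(
        n_genes, n_samples, metagene_effect=metagene_effect, noise_sd=noise_sd,
        seed=seed)
    signs = mg.determine_signs(study, list(truth.planted_signs))
    agree = np.mean([signs.signs[g] == s for g, s in truth.planted_signs.items()])
    return float(agree)


@dataclass
class CrossSpeciesResult:
    training_accuracy: float
    n_target: int
    n_predicted_shh: int
    shh_factor: str


def cross_species_recovery(seed: int = 7, n_genes: int = 300,
                           n_reference: int = 108, n_target: int = 30,
                           k: int = 4, n_restarts: int = 5) -> CrossSpeciesResult:
    """Full synthetic reference-to-target projection with SVM classification.

    A 4-subgroup reference study is factorised; target samples are generated
    from the factor tracking the SHH subgroup and should project and
    classify as SHH.
    """
    study, _, _ = sim.simulate_expression(n_genes, n_reference, seed=seed)
    model = crossspecies.fit_nmf(study, k=k, seed=seed + 1, n_restarts=n_restarts)
    shh_mask = (study.annotations["subgroup"] == "SHH").to_numpy()
    shh_profile = model.H.loc[:, shh_mask].mean(axis=1)
    factor = shh_profile.idxmax()
    template = shh_profile * model.h_row_max  # back to raw H scale
    target, ortho_frame = sim.simulate_cross_species(study, model.W, template,
                                                     n_target, seed=seed + 2)
    orthologs = crossspecies.OrthologMap(ortho_frame)
    # the simulated target is already on the factorisation scale
    projected = crossspecies.project_metagenes(model, target, orthologs,
                                               shift_target=False)
    clf = crossspecies.classify_projected(model.H, study.annotations["subgroup"],
                                          projected)
    return CrossSpeciesResult(
        training_accuracy=clf.training_accuracy,
        n_target=n_target,
        n_predicted_shh=int((clf.predictions == "SHH").sum()),
        shh_factor=str(factor))
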