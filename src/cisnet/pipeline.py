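"""End-to-end orchestration: simulate -> CIS call -> network test ->
metagene -> cross-species projection -> DE/GSEA.

A run is driven by a :class:`RunConfig` (loadable from TOML).  Every
stochastic stage must carry an explicit seed — validation fails before any
stage runs otherwise.  Each invocation writes into a fresh run directory:
per-stage TSV outputs, a structured log of conventions applied, and a
manifest recording seeds and output digests so reruns can be checked for
bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cis, crossspecies, exprstats
from . import metagene as mg
from . import network as net
from . import simulate as sim
from .genome import GenomeDefinition

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_STOCHASTIC_STAGES = ("simulate", "cis_call", "network_test", "metagene", "cross_species", "gsea")


@dataclass
class RunConfig:
    """All tunables of one pipeline run."""

    out_dir: str = "runs"
    stages: list[str] = field(default_factory=lambda: list(_STOCHASTIC_STAGES))
    seeds: dict[str, int] = field(default_factory=dict)
    # simulate
    genome: dict[str, int] = field(default_factory=lambda: {
        "chr1": 20_000_000, "chr2": 15_000_000, "chr3": 10_000_000})
    n_tumours: int = 20
    background_per_sample: float = 10.0
    n_spikes: int = 6
    spike_width: int = 10_000
    spike_n_samples: int = 5
    spike_inserts_per_sample: int = 2
    n_genes: int = 400
    n_expression_samples: int = 120
    metagene_effect: float = 2.0
    noise_sd: float = 1.0
    # cis_call
    scales: list[int] = field(default_factory=lambda: [15_000, 30_000, 60_000])
    n_perm_cis: int = 500
    alpha: float = 0.05
    # network_test
    n_perm_network: int = 2000
    # metagene
    n_boot: int = 2000
    # cross_species
    nmf_k: int = 4
    nmf_restarts: int = 5
    n_target_samples: int = 30
    # gsea
    gsea_weight: float = 1.0
    n_perm_gsea: int = 500

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STOCHASTIC_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        missing = [s for s in self.stages if s not in self.seeds]
        if missing:
            raise ValueError(f"stochastic stages without an explicit seed: {missing}")


def load_config(path) -> RunConfig:
    with open(path, "rb") as handle:
        raw = tomllib.load(handle)
    return RunConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fresh_run_dir(base: Path) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    n = 1
    while (base / f"run{n:03d}").exists():
        n += 1
    out = base / f"run{n:03d}"
    out.mkdir()
    return out


def _spike_positions(genome: GenomeDefinition, n_spikes: int, width: int,
                     n_samples: int, ips: int, seed: int) -> list[sim.CisSpikeSpec]:
    """Evenly spaced, well-separated spike loci across the genome."""
    rng_chroms = sorted(genome.chromosomes)
    spikes = []
    i = 0
    while len(spikes) < n_spikes:
        chrom = rng_chroms[i % len(rng_chroms)]
        slot = i // len(rng_chroms)
        length = genome.length_of(chrom)
        center = int(length * (0.2 + 0.3 * slot))
        if center + width > length:
            i += 1
            continue
        spikes.append(sim.CisSpikeSpec(chromosome=chrom, center=center, width=width,
                                       n_samples=n_samples, inserts_per_sample=ips))
        i += 1
    return spikes


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory.  A stage failure raises with the stage name;
    outputs of completed stages are retained.
    """
    config.validate()
    run_dir = _fresh_run_dir(Path(config.out_dir))
    log_path = run_dir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cisnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": {}}
    state: dict = {}
    try:
        for stage in _STOCHASTIC_STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                _STAGE_FUNCS[stage](config, state, run_dir)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for path in sorted(run_dir.glob("*.tsv")):
            manifest["outputs"][path.name] = _digest(path)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


def _stage_simulate(config: RunConfig, state: dict, run_dir: Path) -> None:
    seed = config.seeds["simulate"]
    genome = GenomeDefinition(dict(config.genome))
    spikes = _spike_positions(genome, config.n_spikes, config.spike_width,
                              config.spike_n_samples, config.spike_inserts_per_sample, seed)
    ds, truth = sim.simulate_insertions(genome, config.n_tumours,
                                        config.background_per_sample, spikes, seed=seed)
    study, graph, expr_truth = sim.simulate_expression(
        config.n_genes, config.n_expression_samples,
        metagene_effect=config.metagene_effect, noise_sd=config.noise_sd,
        seed=seed + 1)
    from .insertions import write_insertion_bed
    write_insertion_bed(ds, run_dir / "insertions.bed")
    sim.write_truth_tsv(truth, run_dir / "insertion_truth.tsv")
    study.expression.to_csv(run_dir / "expression.tsv", sep="\t")
    study.annotations.to_csv(run_dir / "annotations.tsv", sep="\t")
    net.write_network_edges(graph, run_dir / "network_edges.tsv")
    state.update(dataset=ds, insertion_truth=truth, study=study,
                 graph=graph, expr_truth=expr_truth)


def _stage_cis_call(config: RunConfig, state: dict, run_dir: Path) -> None:
    from .insertions import remove_same_site_inserts
    ds, report = remove_same_site_inserts(state["dataset"])
    peaks = cis.gkc_cis_scan(ds, scales=config.scales, n_perm=config.n_perm_cis,
                             alpha=config.alpha, seed=config.seeds["cis_call"])
    state["peaks"] = peaks
    frame = cis.peaks_to_frame(peaks)
    frame.to_csv(run_dir / "cis_table.tsv", sep="\t", index=False)
    logger.info("SSI filter: %s; called %d CIS peaks", report, len(peaks))


def _stage_network_test(config: RunConfig, state: dict, run_dir: Path) -> None:
    truth = state["expr_truth"]
    cis_genes = list(truth.planted_signs)
    result = net.permutation_cluster_test(state["graph"], cis_genes,
                                          n_perm=config.n_perm_network,
                                          seed=config.seeds["network_test"])
    pd.DataFrame([{"observed_mean_distance": result.observed,
                   "p_value": result.p_value, "n_perm": result.n_perm,
                   "genes": ",".join(result.genes_used)}]
                 ).to_csv(run_dir / "network_cluster_test.tsv", sep="\t", index=False)
    state["cluster_test"] = result


def _stage_metagene(config: RunConfig, state: dict, run_dir: Path) -> None:
    study = state["study"]
    genes = list(state["expr_truth"].planted_signs)
    signs = mg.determine_signs(study, genes)
    result = mg.metagene_score(study, genes, signs)
    ann = study.annotations
    f_stat, p_anova = mg.subgroup_anova(result.scores, ann["subgroup"])
    t_stat, p_boot = mg.bootstrap_t_test(result.scores, ann["metastasis"],
                                         n_boot=config.n_boot,
                                         seed=config.seeds["metagene"])
    lr = mg.median_split_logrank(result.scores, ann["time_months"], ann["event"])
    result.scores.rename("metagene_score").to_csv(run_dir / "metagene_scores.tsv", sep="\t")
    pd.DataFrame([
        {"test": "subgroup_anova", "statistic": f_stat, "p_value": p_anova},
        {"test": "metastasis_bootstrap_t", "statistic": t_stat, "p_value": p_boot},
        {"test": "median_split_logrank", "statistic": lr.chi2, "p_value": lr.p_value},
    ]).to_csv(run_dir / "metagene_stats.tsv", sep="\t", index=False)
    state.update(metagene=result, signs=signs)


def _stage_cross_species(config: RunConfig, state: dict, run_dir: Path) -> None:
    seed = config.seeds["cross_species"]
    study = state["study"]
    model = crossspecies.fit_nmf(study, k=config.nmf_k, seed=seed,
                                 n_restarts=config.nmf_restarts)
    # which factor tracks SHH? the one whose scores are highest in SHH samples
    shh = study.annotations["subgroup"] == "SHH"
    shh_profile = model.H.loc[:, shh.to_numpy()].mean(axis=1)
    factor = shh_profile.idxmax()
    target, ortho_frame = sim.simulate_cross_species(
        study, model.W, shh_profile * model.h_row_max,
        n_target_samples=config.n_target_samples, seed=seed + 1)
    orthologs = crossspecies.OrthologMap(ortho_frame)
    projected = crossspecies.project_metagenes(model, target, orthologs,
                                               shift_target=False)
    labels = study.annotations["subgroup"]
    clf = crossspecies.classify_projected(model.H, labels, projected)
    projected.to_csv(run_dir / "projected_scores.tsv", sep="\t")
    clf.predictions.rename("predicted_subgroup").to_csv(
        run_dir / "projected_labels.tsv", sep="\t")
    logger.info("NMF residual %.4f; training accuracy %.3f; SHH factor %s",
                model.residual, clf.training_accuracy, factor)
    state.update(nmf=model, projection=projected, classification=clf, shh_factor=factor)


def _stage_gsea(config: RunConfig, state: dict, run_dir: Path) -> None:
    study = state["study"]
    truth = state["expr_truth"]
    scores = state["metagene"].scores
    # rank genes by correlation with the metagene score
    matrix = study.gene_matrix()
    centred = matrix.sub(matrix.mean(axis=1), axis=0)
    score_c = scores - scores.mean()
    denom = centred.std(axis=1, ddof=0) * score_c.std(ddof=0)
    ranking = (centred @ score_c) / (len(scores) * denom.replace(0, pd.NA))
    ranking = ranking.dropna().astype(float)
    gene_sets = {"planted_network": set(truth.planted_signs)}
    results = exprstats.preranked_gsea(ranking, gene_sets,
                                       weight=config.gsea_weight,
                                       n_perm=config.n_perm_gsea,
                                       seed=config.seeds["gsea"])
    pd.DataFrame([dataclasses.asdict(r) for r in results]
                 ).to_csv(run_dir / "gsea_results.tsv", sep="\t", index=False)
    state["gsea"] = results


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cis_call": _stage_cis_call,
    "network_test": _stage_network_test,
    "metagene": _stage_metagene,
    "cross_species": _stage_cross_species,
    "gsea": _stage_gsea,
}
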