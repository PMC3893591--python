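"""Gaussian kernel convolution CIS calling against analytic and brute-force
oracles, plus the Monte-Carlo comparison caller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisnet.cis import (CisPeak, assign_genes, correct_per_chromosome,
                        gkc_cis_scan, infer_moa, kernel_density,
                        median_cis_pvalue, montecarlo_cis, null_peak_height)
from cisnet.genome import GeneModel, GenomeDefinition
from cisnet.simulate import CisSpikeSpec, simulate_insertions

from conftest import make_dataset


class TestKernelDensity:
    def test_single_insert_analytic_values(self, toy_genome):
        # grid step 1000 with scale 10 kb; x0 = 200_001 lies on the grid
        x0 = 200_001
        ds = make_dataset(toy_genome, [("A", "chr1", x0, "+", 1.0)])
        prof = kernel_density(ds, "chr1", scale=10_000, grid_step=1000)
        at = {p: d for p, d in zip(prof.positions, prof.density)}
        assert at[x0] == pytest.approx(1.0, abs=1e-12)
        assert at[x0 + 10_000] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_two_coincident_inserts_additive(self, toy_genome):
        x0 = 200_001
        ds = make_dataset(toy_genome, [("A", "chr1", x0, "+", 1.0),
                                       ("B", "chr1", x0, "-", 1.0)])
        prof = kernel_density(ds, "chr1", scale=10_000, grid_step=1000)
        assert prof.density.max() == pytest.approx(2.0, abs=1e-12)

    def test_empty_chromosome_flat_zero(self, toy_genome):
        ds = make_dataset(toy_genome, [("A", "chr1", 5, "+", 1.0)])
        prof = kernel_density(ds, "chr2", scale=10_000)
        assert np.all(prof.density == 0)

    def test_matches_brute_force_double_loop(self, toy_genome, rng):
        """Windowed evaluation equals the exact double sum to 1e-9 of the
        profile maximum."""
        genome = GenomeDefinition({"c": 500_000})
        positions = np.sort(rng.integers(1, 500_001, size=200))
        ds = make_dataset(genome, [("A", "c", int(p), "+", 1.0) for p in positions])
        scale, step = 5000, 1000
        prof = kernel_density(ds, "c", scale=scale, grid_step=step)
        brute = np.zeros_like(prof.density)
        for i, x in enumerate(prof.positions):
            for xi in positions:
                brute[i] += np.exp(-((x - xi) ** 2) / (2.0 * scale ** 2))
        np.testing.assert_allclose(prof.density, brute, rtol=1e-9,
                                   atol=1e-9 * brute.max())

    def test_grid_step_validation(self, toy_genome):
        ds = make_dataset(toy_genome, [("A", "chr1", 5, "+", 1.0)])
        with pytest.raises(ValueError):
            kernel_density(ds, "chr1", scale=1000, grid_step=500)


class TestNullPeakHeight:
    def test_reproducible_under_seed(self):
        a = null_peak_height(30, 1_000_000, 10_000, 200, seed=5)
        b = null_peak_height(30, 1_000_000, 10_000, 200, seed=5)
        np.testing.assert_array_equal(a, b)
        c = null_peak_height(30, 1_000_000, 10_000, 200, seed=6)
        assert not np.array_equal(a, c)

    def test_zero_inserts_degenerate_at_zero(self):
        null = null_peak_height(0, 1_000_000, 10_000, 200, seed=0)
        assert np.all(null == 0)

    def test_add_one_estimator_floor(self):
        """An observed height above all 999 null maxima gets p = 1/1000,
        and a zero observation gets p = 1."""
        null = null_peak_height(10, 1_000_000, 10_000, 999, seed=1)
        p_floor = (np.count_nonzero(null >= null.max() + 1) + 1) / (999 + 1)
        assert p_floor == pytest.approx(1 / 1000)
        p_zero = (np.count_nonzero(null >= 0) + 1) / (999 + 1)
        assert p_zero == 1.0


class TestCorrectPerChromosome:
    def _peak(self, chrom, pos, raw_p):
        return CisPeak(chromosome=chrom, position=pos, start=pos - 10, end=pos + 10,
                       scale=30_000, raw_p=raw_p)

    def test_single_peak_identity(self):
        peaks = correct_per_chromosome([self._peak("chr1", 100, 0.01)])
        assert peaks[0].corrected_p == pytest.approx(0.01)

    def test_multiplies_by_candidate_count(self):
        peaks = [self._peak("chr1", 100 * i, 0.01) for i in range(1, 6)]
        corrected = correct_per_chromosome(peaks)
        assert all(p.corrected_p == pytest.approx(0.05) for p in corrected)

    def test_clamped_at_one(self):
        peaks = [self._peak("chr2", 100 * i, 0.5) for i in range(1, 5)]
        corrected = correct_per_chromosome(peaks)
        assert all(p.corrected_p == 1.0 for p in corrected)


class TestGkcScan:
    def test_single_spike_recovered(self):
        """One 5-sample spike on a 10 Mb chromosome over 20 background
        inserts yields exactly one significant peak at the spike."""
        genome = GenomeDefinition({"chr1": 10_000_000})
        spike = CisSpikeSpec("chr1", 5_000_000, 1000, 5, 2)
        ds, _ = simulate_insertions(genome, 5, 4.0, [spike], seed=7)
        peaks = gkc_cis_scan(ds, scales=[30_000], n_perm=500, seed=1)
        assert len(peaks) == 1
        peak = peaks[0]
        assert peak.start <= 5_000_000 <= peak.end
        assert peak.corrected_p < 0.05
        assert peak.n_samples <= peak.n_insertions

    def test_pvalue_ranges_and_ordering(self):
        genome = GenomeDefinition({"chr1": 10_000_000})
        spike = CisSpikeSpec("chr1", 2_000_000, 5000, 6, 2)
        ds, _ = simulate_insertions(genome, 10, 10.0, [spike], seed=3)
        peaks = gkc_cis_scan(ds, scales=[15_000, 30_000], n_perm=300, seed=2)
        for peak in peaks:
            assert 1 / 301 <= peak.raw_p <= 1.0
            assert peak.corrected_p >= peak.raw_p
        assert [p.corrected_p for p in peaks] == sorted(p.corrected_p for p in peaks)

    def test_empty_dataset_empty_list(self, toy_genome):
        ds, _ = simulate_insertions(toy_genome, 3, 0.0, seed=0)
        assert gkc_cis_scan(ds, scales=[30_000], n_perm=200, seed=0) == []


class TestMonteCarlo:
    def test_concentrated_inserts_hit_floor(self):
        """Ten inserts in one window on an otherwise empty 10 Mb chromosome
        reach the 1/1000 add-one floor with 999 simulations."""
        genome = GenomeDefinition({"chr1": 10_000_000})
        rows = [(f"S{i}", "chr1", 5_000_000 + 100 * i, "+", 1.0) for i in range(10)]
        ds = make_dataset(genome, rows)
        peaks = montecarlo_cis(ds, window=10_000, n_sims=999, seed=4)
        assert len(peaks) == 1
        assert peaks[0].raw_p == pytest.approx(1 / 1000)

    def test_empty_dataset(self, toy_genome):
        ds, _ = simulate_insertions(toy_genome, 3, 0.0, seed=0)
        assert montecarlo_cis(ds, window=10_000, n_sims=200, seed=0) == []

    def test_family_wise_p_brackets_poisson_tail(self, rng):
        """The simulated family-wise window p must lie between the analytic
        single-window Poisson tail and its union bound over windows."""
        length, window, k = 2_000_000, 20_000, 5
        n_background = 40
        rows = [("S1", "c", int(p), "+", 1.0)
                for p in rng.integers(1, length + 1, size=n_background)]
        rows += [("S2", "c", 1_000_000 + 100 * i, "+", 1.0) for i in range(k)]
        ds = make_dataset(GenomeDefinition({"c": length}), rows)
        peaks = montecarlo_cis(ds, window=window, n_sims=999, seed=8)
        target = [p for p in peaks if p.start <= 1_000_200 <= p.end]
        assert target, "the stacked window must be called"
        n_total = len(rows)
        lam = n_total * window / length
        obs_count = max(k, int(target[0].height))
        q = stats.poisson.sf(obs_count - 1, lam)
        n_windows = 2 * length / window
        assert q <= target[0].raw_p <= min(1.0, 2 * n_windows * q) + 2e-3

    def test_rank_agreement_with_gkc_on_spikes(self):
        """Both callers must agree on the ordering of clearly separated
        spike strengths (no strict rank inversions among the top loci)."""
        genome = GenomeDefinition({"chr1": 20_000_000})
        spikes = [CisSpikeSpec("chr1", 3_000_000, 5000, 10, 3),
                  CisSpikeSpec("chr1", 10_000_000, 5000, 6, 2),
                  CisSpikeSpec("chr1", 17_000_000, 5000, 3, 1)]
        ds, _ = simulate_insertions(genome, 12, 5.0, spikes, seed=21)
        gkc = gkc_cis_scan(ds, scales=[30_000], n_perm=400, seed=1)
        mc = montecarlo_cis(ds, window=30_000, n_sims=400, seed=2)

        def locus_of(peak):
            return min(spikes, key=lambda s: abs(peak.position - s.center)).center

        gkc_rank = {locus_of(p): i for i, p in enumerate(gkc[:3])}
        mc_rank = {locus_of(p): i for i, p in enumerate(mc[:3])}
        common = set(gkc_rank) & set(mc_rank)
        assert len(common) >= 2
        for a in common:
            for b in common:
                ga, gb = gkc_rank[a], gkc_rank[b]
                ma, mb = mc_rank[a], mc_rank[b]
                assert not (ga < gb and ma > mb)


GENES = [
    GeneModel("Alpha", "chr1", 100_000, 160_000, "+"),
    GeneModel("Beta", "chr1", 200_000, 260_000, "-"),
    GeneModel("Gamma", "chr2", 50_000, 90_000, "+"),
]


class TestGeneAssignment:
    def _peak(self, chrom, pos, start, end):
        return CisPeak(chromosome=chrom, position=pos, start=start, end=end,
                       scale=30_000, raw_p=0.01, corrected_p=0.01)

    def test_peak_inside_single_gene(self):
        peak = self._peak("chr1", 120_000, 110_000, 130_000)
        assign_genes([peak], GENES)
        assert peak.primary_gene == "Alpha" and peak.other_genes == []

    def test_intergenic_peak_coordinate_name(self):
        peak = self._peak("chr2", 4_000_000, 3_990_000, 4_010_000)
        assign_genes([peak], GENES)
        assert peak.primary_gene is None
        assert peak.name == "CIS2:4000000"

    def test_peak_spanning_two_genes_nearest_primary(self):
        peak = self._peak("chr1", 190_000, 150_000, 210_000)
        assign_genes([peak], GENES)
        assert peak.primary_gene == "Beta"
        assert peak.other_genes == ["Alpha"]


class TestInferMoa:
    def _gene(self):
        return GeneModel("G", "chr1", 100_000, 200_000, "+")

    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chromosome", "position",
                                           "strand", "read_count"])

    def test_same_strand_5prime_cluster_is_gain(self):
        sites = self._sites([("A", "chr1", 105_000, "+", 1.0),
                             ("B", "chr1", 108_000, "+", 1.0),
                             ("C", "chr1", 110_000, "+", 1.0)])
        peak = CisPeak("chr1", 107_000, 104_000, 111_000, 30_000)
        assert infer_moa(peak, sites, self._gene()) == "Gain"

    def test_mixed_strand_across_body_is_loss(self):
        sites = self._sites([("A", "chr1", 110_000, "+", 1.0),
                             ("B", "chr1", 150_000, "-", 1.0),
                             ("C", "chr1", 190_000, "+", 1.0),
                             ("D", "chr1", 170_000, "-", 1.0)])
        peak = CisPeak("chr1", 150_000, 105_000, 195_000, 30_000)
        assert infer_moa(peak, sites, self._gene()) == "Loss"

    def test_opposite_strand_5prime_pair_is_unknown(self):
        sites = self._sites([("A", "chr1", 105_000, "+", 1.0),
                             ("B", "chr1", 106_000, "-", 1.0)])
        peak = CisPeak("chr1", 105_500, 104_000, 107_000, 30_000)
        assert infer_moa(peak, sites, self._gene()) == "Unknown"

    def test_strandless_is_unknown(self):
        sites = self._sites([("A", "chr1", 150_000, ".", 1.0)])
        peak = CisPeak("chr1", 150_000, 140_000, 160_000, 30_000)
        assert infer_moa(peak, sites, self._gene()) == "Unknown"


class TestMedianPvalue:
    def test_single_peak(self):
        assert median_cis_pvalue([0.3]) == 0.3

    def test_even_count_central_mean(self):
        assert median_cis_pvalue([0.01, 0.03]) == pytest.approx(0.02)

    def test_censored_strings_parsed_as_bound(self):
        assert median_cis_pvalue(["<1E-3", 0.1, 0.2]) == pytest.approx(0.1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_cis_pvalue([])
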