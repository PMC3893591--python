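"""Signed metagene construction and its clinical association tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisnet.metagene import (ExpressionStudy, bootstrap_t_test, determine_signs,
                             median_split_logrank, metagene_score, subgroup_anova)


def make_study(matrix: pd.DataFrame, **ann_columns) -> ExpressionStudy:
    ann = pd.DataFrame(ann_columns, index=matrix.columns) if ann_columns else \
        pd.DataFrame(index=matrix.columns)
    return ExpressionStudy(matrix, ann)


class TestDetermineSigns:
    def test_concordant_gene_positive(self, rng):
        base = rng.normal(size=50)
        matrix = pd.DataFrame({f"S{i}": None for i in range(50)}, index=["a", "b", "c"])
        matrix.loc["a"] = base
        matrix.loc["b"] = base + rng.normal(0, 0.1, 50)
        matrix.loc["c"] = base + rng.normal(0, 0.1, 50)
        signs = determine_signs(make_study(matrix.astype(float)), ["a", "b", "c"])
        assert all(v == 1 for v in signs.signs.values())

    def test_exact_negation_flips_sign(self, rng):
        base = rng.normal(size=40)
        matrix = pd.DataFrame(
            {f"S{i}": [base[i],
                       base[i] + rng.normal(0, 0.05),
                       base[i] + rng.normal(0, 0.05),
                       -base[i]] for i in range(40)},
            index=["up", "up2", "up3", "down"]).astype(float)
        signs = determine_signs(make_study(matrix), ["up", "up2", "up3", "down"])
        assert signs.signs["down"] == -1
        assert signs.signs["up"] == 1 and signs.signs["up2"] == 1

    def test_absent_gene_reported(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"],
                              columns=[f"S{i}" for i in range(30)])
        signs = determine_signs(make_study(matrix), ["a", "b", "ghost"])
        assert signs.missing == ["ghost"]

    def test_probe_with_highest_mean_selected(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(3, 20)),
                              index=["p1", "p2", "p3"],
                              columns=[f"S{i}" for i in range(20)])
        matrix.loc["p2"] += 5.0  # highest mean probe for gene A
        study = ExpressionStudy(matrix, pd.DataFrame(index=matrix.columns),
                                probe_to_gene=pd.Series({"p1": "A", "p2": "A", "p3": "B"}))
        collapsed = study.gene_matrix()
        assert list(collapsed.index) == ["A", "B"]
        pd.testing.assert_series_equal(collapsed.loc["A"], matrix.loc["p2"],
                                       check_names=False)

    def test_planted_sign_recovery(self, planted_study):
        """At effect 2 and n=200 the sign rule recovers at least 95% of the
        planted orientations."""
        study, _, truth = planted_study
        signs = determine_signs(study, list(truth.planted_signs))
        agree = np.mean([signs.signs[g] == s for g, s in truth.planted_signs.items()])
        assert agree >= 0.95


class TestMetageneScore:
    def _signs(self, mapping):
        from cisnet.metagene import CisGeneSign
        return CisGeneSign(signs=mapping, evidence={g: 1.0 for g in mapping})

    def test_single_gene_score_is_zscore(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(1, 30)), index=["g"],
                              columns=[f"S{i}" for i in range(30)])
        res = metagene_score(make_study(matrix), ["g"], self._signs({"g": 1}))
        row = matrix.loc["g"]
        z = (row - row.mean()) / row.std(ddof=1)
        pd.testing.assert_series_equal(res.scores, z, check_names=False)

    def test_sign_negation_antisymmetry(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(4, 25)),
                              index=list("abcd"), columns=[f"S{i}" for i in range(25)])
        study = make_study(matrix)
        plus = metagene_score(study, list("abcd"), self._signs({g: 1 for g in "abcd"}))
        minus = metagene_score(study, list("abcd"), self._signs({g: -1 for g in "abcd"}))
        np.testing.assert_allclose(plus.scores, -minus.scores)

    def test_row_shift_invariance(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(3, 25)), index=list("abc"),
                              columns=[f"S{i}" for i in range(25)])
        shifted = matrix.copy()
        shifted.loc["b"] += 100.0
        signs = self._signs({g: 1 for g in "abc"})
        a = metagene_score(make_study(matrix), list("abc"), signs)
        b = metagene_score(make_study(shifted), list("abc"), signs)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_zero_variance_gene_skipped(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(2, 20)), index=["a", "flat"],
                              columns=[f"S{i}" for i in range(20)])
        matrix.loc["flat"] = 3.14
        res = metagene_score(make_study(matrix), ["a", "flat"],
                             self._signs({"a": 1, "flat": 1}))
        assert res.genes_used == ["a"] and "flat" in res.genes_skipped

    def test_no_usable_genes_raises(self):
        matrix = pd.DataFrame({"S1": [1.0], "S2": [1.0]}, index=["flat"])
        with pytest.raises(ValueError):
            metagene_score(make_study(matrix), ["flat"], self._signs({"flat": 1}))


class TestSubgroupAnova:
    def test_equal_groups_f_zero(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=scores.index)
        f_stat, _ = subgroup_anova(scores, groups)
        assert f_stat == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        scores = pd.Series(rng.normal(size=30), index=[f"S{i}" for i in range(30)])
        groups = pd.Series(["A"] * 14 + ["B"] * 16, index=scores.index)
        f_stat, p_f = subgroup_anova(scores, groups)
        t = stats.ttest_ind(scores[:14], scores[14:], equal_var=True)
        assert f_stat == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)

    def test_unknown_samples_excluded(self, rng):
        scores = pd.Series(rng.normal(size=10), index=[f"S{i}" for i in range(10)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["unknown"] * 2, index=scores.index)
        f_all, _ = subgroup_anova(scores, groups)
        f_sub, _ = subgroup_anova(scores[:8], groups[:8])
        assert f_all == pytest.approx(f_sub)

    def test_planted_subgroup_effect_detected(self, planted_study):
        study, _, truth = planted_study
        from cisnet.metagene import determine_signs
        signs = determine_signs(study, list(truth.planted_signs))
        scores = metagene_score_for(study, truth, signs)
        _, p = subgroup_anova(scores, study.annotations["subgroup"])
        assert p < 0.001


def metagene_score_for(study, truth, signs):
    from cisnet.metagene import metagene_score
    return metagene_score(study, list(truth.planted_signs), signs).scores


class TestBootstrapT:
    def test_reported_t_is_welch(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"S{i}" for i in range(40)])
        labels = pd.Series(["yes"] * 18 + ["no"] * 22, index=scores.index)
        t_obs, _ = bootstrap_t_test(scores, labels, n_boot=1000, seed=0)
        a = scores[labels == "no"]
        b = scores[labels == "yes"]
        welch = stats.ttest_ind(a, b, equal_var=False).statistic
        assert abs(t_obs) == pytest.approx(abs(welch), rel=1e-12)

    def test_null_case_large_p(self, rng):
        values = rng.normal(size=20)
        scores = pd.Series(np.concatenate([values, values]),
                           index=[f"S{i}" for i in range(40)])
        labels = pd.Series(["yes"] * 20 + ["no"] * 20, index=scores.index)
        _, p = bootstrap_t_test(scores, labels, n_boot=1000, seed=1)
        assert p >= 0.5

    def test_huge_separation_hits_floor(self, rng):
        scores = pd.Series(np.concatenate([rng.normal(0, 1, 30),
                                           rng.normal(10, 1, 30)]),
                           index=[f"S{i}" for i in range(60)])
        labels = pd.Series(["no"] * 30 + ["yes"] * 30, index=scores.index)
        _, p = bootstrap_t_test(scores, labels, n_boot=1000, seed=2)
        assert p == pytest.approx(1 / 1001)

    def test_single_class_raises(self, rng):
        scores = pd.Series(rng.normal(size=10), index=[f"S{i}" for i in range(10)])
        labels = pd.Series(["yes"] * 10, index=scores.index)
        with pytest.raises(ValueError):
            bootstrap_t_test(scores, labels, n_boot=1000, seed=0)


def logrank_oracle(time1, event1, time2, event2):
    """Independent O-E/V log-rank implementation by direct summation over
    distinct event times."""
    times = np.concatenate([time1, time2])
    events = np.concatenate([event1, event2])
    group = np.concatenate([np.zeros(len(time1)), np.ones(len(time2))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var


class TestMedianSplitLogrank:
    def _run(self, values, time, event):
        idx = [f"S{i}" for i in range(len(values))]
        return median_split_logrank(pd.Series(values, index=idx),
                                    pd.Series(time, index=idx),
                                    pd.Series(event, index=idx))

    def test_identical_event_patterns_chi2_zero(self):
        res = self._run([0, 0, 1, 1], [5.0, 8.0, 5.0, 8.0], [1, 0, 1, 0])
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_toy_data_matches_oracle(self):
        values = [1.0, 1.0, 0.0, 0.0]
        time = [1.0, 2.0, 3.0, 4.0]
        event = [0, 1, 1, 1]
        res = self._run(values, time, event)
        high = np.array(values) >= np.median(values)
        expected = logrank_oracle(np.array(time)[high], np.array(event)[high],
                                  np.array(time)[~high], np.array(event)[~high])
        assert res.chi2 == pytest.approx(expected, rel=1e-9)

    def test_exhaustive_small_datasets_match_oracle(self):
        """All two-group datasets on 4 samples with times in {1, 2} and all
        censoring patterns agree with the O-E/V oracle."""
        values = np.array([1.0, 1.0, 0.0, 0.0])  # fixed half/half split
        high = values >= np.median(values)
        checked = 0
        for times in itertools.product([1.0, 2.0], repeat=4):
            for events in itertools.product([0, 1], repeat=4):
                if sum(events) == 0:
                    continue
                t = np.array(times)
                e = np.array(events)
                expected = logrank_oracle(t[high], e[high], t[~high], e[~high])
                res = self._run(values, list(times), list(events))
                assert res.chi2 == pytest.approx(expected, rel=1e-8, abs=1e-10)
                checked += 1
        assert checked == 2 ** 4 * (2 ** 4 - 1)

    def test_constant_values_raise(self):
        with pytest.raises(ValueError):
            self._run([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [1, 1, 1, 1])

    def test_no_events_raise(self):
        with pytest.raises(ValueError):
            self._run([0, 0, 1, 1], [1, 2, 3, 4], [0, 0, 0, 0])


class TestGlobalSignFlip:
    def test_statistics_invariant_under_global_flip(self, planted_study):
        """Flipping every gene's sign negates scores but leaves F, |t| and
        chi-squared unchanged."""
        study, _, truth = planted_study
        from cisnet.metagene import CisGeneSign, metagene_score
        genes = list(truth.planted_signs)
        plus = CisGeneSign(signs=dict(truth.planted_signs),
                           evidence={g: 0.0 for g in genes})
        minus = CisGeneSign(signs={g: -s for g, s in truth.planted_signs.items()},
                            evidence={g: 0.0 for g in genes})
        ann = study.annotations
        s_plus = metagene_score(study, genes, plus).scores
        s_minus = metagene_score(study, genes, minus).scores
        f1, _ = subgroup_anova(s_plus, ann["subgroup"])
        f2, _ = subgroup_anova(s_minus, ann["subgroup"])
        assert f1 == pytest.approx(f2, rel=1e-10)
        lr1 = median_split_logrank(s_plus, ann["time_months"], ann["event"])
        lr2 = median_split_logrank(-s_plus, ann["time_months"], ann["event"])
        # the median split is mirror-symmetric up to tie handling at the median
        assert lr1.chi2 == pytest.approx(lr2.chi2, rel=1e-6)
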