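"""Stratification: ANOVA/Tukey lumping, ranking, means, benchmark map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from juriflux.biomass import (anova_oneway, build_benchmark_map,
                              compare_stratifications, elevation_class,
                              evaluate_strata, fit_stratum_means)


def brute_force_anova(groups):
    """Independent sum-of-squares oracle (explicit loops, no shortcuts)."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ssb = ssw = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for v in g:
            ssw += (v - m) ** 2
    k, n = len(groups), len(all_values)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return f, p


def _samples(groups):
    rows = []
    for label, values in groups.items():
        rows.extend({"stratum": label, "biomass": float(v)} for v in values)
    return pd.DataFrame(rows)


class TestAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        groups = [rng.normal(rng.uniform(50, 300), 20,
                             size=rng.integers(3, 25)).tolist()
                  for _ in range(k)]
        f, p = anova_oneway([np.array(g) for g in groups])
        f0, p0 = brute_force_anova(groups)
        assert f == pytest.approx(f0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 15, 30) for m in (50, 150, 300)]
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestEvaluateStrata:
    def test_identical_groups_are_lumped(self):
        values = [100.0, 110.0, 120.0, 130.0]
        res = evaluate_strata(_samples({"a": values, "b": values}))
        assert res.n_strata == 1
        assert res.assignment["a"] == res.assignment["b"]

    def test_well_separated_groups_all_retained(self):
        rng = np.random.default_rng(1)
        groups = {m: rng.normal(m, 10, 30) for m in (50, 150, 300)}
        res = evaluate_strata(_samples(groups))
        assert res.n_strata == 3
        f0, _ = brute_force_anova([list(v) for v in groups.values()])
        assert res.f_statistic == pytest.approx(f0, rel=1e-9)
        assert f0 > stats.f.isf(0.001, 2, 87)  # far beyond critical

    def test_lumping_is_a_coarsening(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(100 + 5 * i, 30, 12) for i in range(6)}
        res = evaluate_strata(_samples(groups))
        # every candidate maps to exactly one final stratum
        assert set(res.assignment) == set(groups)
        assert set(res.assignment.values()) == set(res.strata)
        assert res.n_strata <= len(groups)

    def test_retained_pairs_all_differ(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(60 + 25 * i, 18, 20) for i in range(5)}
        res = evaluate_strata(_samples(groups))
        if res.n_strata > 1:
            off_diag = res.tukey_p.to_numpy()[
                ~np.eye(res.n_strata, dtype=bool)]
            assert np.all(off_diag <= 0.05)

    def test_degenerate_identical_samples(self):
        res = evaluate_strata(_samples({"a": [5.0, 5.0], "b": [5.0, 5.0]}))
        assert res.degenerate
        assert res.n_strata == 1

    def test_default_jurisdiction_keeps_thirteen_classes(
            self, default_footprints):
        res = evaluate_strata(default_footprints, by="stratum")
        assert res.n_strata == 13

    def test_undersized_candidate_rejected(self):
        with pytest.raises(ValueError):
            evaluate_strata(_samples({"a": [1.0], "b": [1.0, 2.0]}))


class TestCompareStratifications:
    def test_true_labels_rank_first(self):
        rng = np.random.default_rng(4)
        truth = np.repeat([0, 1, 2], 40)
        biomass = np.array([50, 150, 300])[truth] + rng.normal(0, 15, 120)
        samples = pd.DataFrame({"biomass": biomass})
        ranked = compare_stratifications(
            samples, {"truth": truth, "random": rng.permutation(truth)})
        assert ranked.index[0] == "truth"

    def test_duplicate_stratifications_tie(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 20)
        samples = pd.DataFrame(
            {"biomass": labels * 100 + rng.normal(0, 10, 40)})
        ranked = compare_stratifications(samples, {"a": labels, "b": labels})
        assert ranked.loc["a", "F"] == pytest.approx(ranked.loc["b", "F"])

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1, 2], 15)
        samples = pd.DataFrame(
            {"biomass": labels * 80 + rng.normal(0, 10, 45)})
        relabeled = np.array([7, 3, 5])[labels]  # same partition, new ids
        ranked = compare_stratifications(samples,
                                         {"orig": labels, "renamed": relabeled})
        assert ranked.loc["orig", "F"] == pytest.approx(
            ranked.loc["renamed", "F"], rel=1e-12)

    def test_single_class_f_undefined(self):
        samples = pd.DataFrame({"biomass": [1.0, 2.0, 3.0]})
        ranked = compare_stratifications(samples, {"one": np.zeros(3, int)})
        assert np.isnan(ranked.loc["one", "F"])


class TestFitStratumMeans:
    def test_hand_arithmetic(self):
        recs = fit_stratum_means(_samples({"a": [100.0, 120.0]}))
        assert recs[0].mean == pytest.approx(110.0)
        assert recs[0].sem == pytest.approx(10.0 / np.sqrt(2))
        assert recs[0].n == 2

    def test_constant_stratum_has_zero_sem(self):
        recs = fit_stratum_means(_samples({"a": [80.0, 80.0, 80.0]}))
        assert recs[0].sem == 0.0

    def test_weighted_grand_mean_is_conserved(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.uniform(10, 300, rng.integers(2, 30))
                  for i in range(4)}
        recs = fit_stratum_means(_samples(groups))
        weighted = sum(r.mean * r.n for r in recs) / sum(r.n for r in recs)
        overall = np.concatenate(list(groups.values())).mean()
        assert weighted == pytest.approx(overall, rel=1e-12)


class TestBenchmarkMap:
    def test_uniform_landscape_gives_constant_raster(self):
        raster = np.ones((5, 5), dtype=int)
        out = build_benchmark_map(raster, {1: 150.0})
        assert np.all(out == 150.0)

    def test_nonforest_gets_nodata(self):
        raster = np.array([[0, 1], [1, 0]])
        out = build_benchmark_map(raster, {1: 99.0})
        assert np.isnan(out[0, 0]) and np.isnan(out[1, 1])
        assert out[0, 1] == 99.0

    def test_unmapped_stratum_id_listed_in_error(self):
        raster = np.array([[1, 2], [2, 3]])
        with pytest.raises(KeyError, match="3"):
            build_benchmark_map(raster, {1: 10.0, 2: 20.0})

    def test_lumping_changes_jurisdiction_stock(self, default_landscape,
                                                default_footprints):
        """Using one grand mean instead of strata shifts total mapped stock
        when high-biomass strata dominate; the stratified map conserves the
        footprint structure."""
        stratum = default_landscape.rasters["stratum"]
        recs = fit_stratum_means(default_footprints, by="stratum")
        stratified = build_benchmark_map(
            stratum, {r.stratum: r.mean for r in recs})
        grand = float(default_footprints["biomass"].mean())
        lumped = build_benchmark_map(
            stratum, {r.stratum: grand for r in recs})
        assert not np.isclose(np.nansum(stratified), np.nansum(lumped),
                              rtol=0.02)


class TestElevationClass:
    def test_edges_go_to_upper_class(self):
        assert elevation_class(100.0) == 1
        assert elevation_class(99.999) == 0
        assert list(elevation_class([0, 150, 300, 1000, 1500, 2000])) == \
            [0, 1, 2, 3, 4, 4]
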