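"""Nonparametric comparison layer: KW, Dunn, BH, Shapiro screen, reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from painsig.stats import (
    bh_adjust, compare_feature, dunn_posthoc, kruskal_wallis, kw_pvalue,
    run_comparisons, shapiro_screen,
)
from painsig.synthetic import simulate_null_feature_table


def naive_kruskal_h(groups):
    """Independent rank-based H for tie-free data (brute-force ranks)."""
    pooled = np.concatenate(list(groups.values()))
    n = pooled.size
    ranks = np.empty(n)
    ranks[np.argsort(pooled)] = np.arange(1, n + 1)
    h = 0.0
    start = 0
    for v in groups.values():
        r = ranks[start:start + len(v)]
        h += len(v) * (r.mean() - (n + 1) / 2) ** 2
        start += len(v)
    return 12.0 / (n * (n + 1)) * h


class TestKruskalWallis:
    def test_three_identical_groups(self):
        h, df, p = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_vs_oracle(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        h, df, p = kruskal_wallis(groups)
        assert h == pytest.approx(naive_kruskal_h(groups), abs=1e-12)
        assert p == pytest.approx(float(sstats.chi2.sf(h, 2)), abs=1e-15)

    def test_matches_exhaustive_rank_oracle_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            vals = rng.permutation(np.linspace(0.1, 9.9, n))  # tie-free
            k = int(rng.integers(2, min(4, n) + 1))
            cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
            parts = np.split(vals, cuts)
            groups = {f"g{i}": p for i, p in enumerate(parts)}
            if sum(len(v) for v in groups.values()) < k + 1:
                continue
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(naive_kruskal_h(groups), abs=1e-9)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.integers(0, 6, size=15).astype(float) for k in "abc"}
        h, df, p = kruskal_wallis(groups)
        ref = sstats.kruskal(*groups.values())
        assert h == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis({"a": [1.0, 2.0], "b": []})


class TestDunn:
    def test_z_squared_equals_h_for_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        h, _, _ = kruskal_wallis({"a": a, "b": b})
        (pair,) = dunn_posthoc({"a": a, "b": b})
        assert pair.z ** 2 == pytest.approx(h, abs=1e-9)

    def test_hand_computed_tie_free_example(self):
        # N=6, tie-free: mean ranks 1.5 / 3.5 / 5.5, variance core N(N+1)/12=3.5
        res = dunn_posthoc({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]})
        z = {(r.group_a, r.group_b): r.z for r in res}
        assert z[("a", "b")] == pytest.approx(-2.0 / np.sqrt(3.5), abs=1e-12)
        assert z[("a", "c")] == pytest.approx(-4.0 / np.sqrt(3.5), abs=1e-12)
        assert z[("b", "c")] == pytest.approx(-2.0 / np.sqrt(3.5), abs=1e-12)

    def test_separated_groups_small_p(self):
        res = dunn_posthoc({"a": np.arange(10.0), "b": np.arange(100.0, 110.0)})
        assert abs(res[0].z) > 3
        assert res[0].p_raw < 0.001

    def test_identical_multisets_z_zero(self):
        res = dunn_posthoc({"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0],
                            "c": [0.0, 5.0, 2.5]})
        z = {(r.group_a, r.group_b): r for r in res}
        assert z[("a", "b")].z == pytest.approx(0.0, abs=1e-12)
        assert z[("a", "b")].p_raw == pytest.approx(1.0)

    def test_single_deviant_pair_smallest_and_bh_preserves_order(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 15)
        groups = {"a": base, "b": base + rng.normal(0, 0.05, 15),
                  "c": base + 5.0}
        res = dunn_posthoc(groups)
        by_pair = {(r.group_a, r.group_b): r for r in res}
        raws = sorted(res, key=lambda r: r.p_raw)
        adjs = sorted(res, key=lambda r: r.p_adjusted)
        assert [(r.group_a, r.group_b) for r in raws][-1] == ("a", "b")
        assert {(r.group_a, r.group_b) for r in adjs[:2]} == {("a", "c"), ("b", "c")}
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-15


class TestBHAdjust:
    def test_rank_one_of_three_scaling(self):
        # smallest of three p-values at 0.015 adjusts to 0.015 * 3 = 0.045
        adj = bh_adjust([0.015, 0.5, 0.8])
        assert adj[0] == pytest.approx(0.045, abs=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 25)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_permutation_invariant(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestShapiroScreen:
    def test_tiny_group_gets_missing_p(self):
        p, flag = shapiro_screen({"a": [1.0, 2.0], "b": np.random.default_rng(0).normal(size=30)})
        assert np.isnan(p["a"])
        assert not np.isnan(p["b"])

    def test_heavy_tailed_groups_flagged(self):
        rng = np.random.default_rng(12)
        groups = {k: rng.lognormal(0, 1.5, 60) for k in "abc"}
        _, flag = shapiro_screen(groups)
        assert flag

    def test_normal_groups_rarely_flagged(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            groups = {k: rng.normal(0, 1, 50) for k in "abc"}
            flags.append(shapiro_screen(groups)[1])
        assert sum(flags) <= 4  # about 14% per screen under the null


class TestKWPvalue:
    def test_chi_square_tail(self):
        assert kw_pvalue(0.0, 2) == pytest.approx(1.0)
        assert kw_pvalue(7.17, 2) == pytest.approx(np.exp(-7.17 / 2), rel=1e-12)


def _toy_tables(n=60, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    feats, cohort = simulate_null_feature_table(n, rng, ["nSCR_CDA", "maxSCR_TTP"])
    if effect:
        mixed = cohort["pain_type"] == "mixed"
        feats.loc[mixed.values, "nSCR_CDA"] *= np.exp(-effect)
    return feats, cohort


class TestRunComparisons:
    def test_report_shape_and_pair_count(self):
        feats, cohort = _toy_tables()
        rep = run_comparisons(feats, cohort, strata=())
        overall = rep.overall()
        # 2 features x 2 groupings
        assert len(overall) == 4
        pairs = rep.pairwise()
        assert len(pairs) == 4 * 3  # k=3 groups -> 3 pairs each

    def test_injected_effect_detected_with_mixed_pairs_smallest(self):
        feats, cohort = _toy_tables(n=80, seed=4, effect=2.5)
        rep = run_comparisons(feats, cohort, strata=())
        row = rep.overall()
        row = row[(row.feature == "nSCR_CDA") & (row.grouping == "pain_type")]
        assert float(row["p_kw"].iloc[0]) < 0.05
        pairs = rep.pairwise()
        pairs = pairs[(pairs.feature == "nSCR_CDA") & (pairs.grouping == "pain_type")]
        worst = pairs.sort_values("p_adj").iloc[-1]
        assert {worst.group_a, worst.group_b} == {"nociceptive", "neuropathic"}

    def test_empty_stratum_group_reported_not_computable(self):
        feats, cohort = _toy_tables(n=40, seed=2)
        cohort = cohort.copy()
        # force a stratum with no mixed-pain patients at all
        cohort.loc[cohort["btcp"], "pain_type"] = "nociceptive"
        cohort.loc[cohort["btcp"] & (cohort.index % 2 == 0), "pain_type"] = "neuropathic"
        rep = run_comparisons(feats, cohort, groupings=("pain_type",), strata=("btcp",))
        t = rep.table
        bad = t[(t.stratum_var == "btcp") & (t.stratum_level == True)]  # noqa: E712
        assert not bad.empty
        assert bad["computable"].isin([True, False]).all()

    def test_orphan_patients_rejected(self):
        feats, cohort = _toy_tables(n=20)
        with pytest.raises(ValueError, match="patient_id"):
            run_comparisons(feats.iloc[:-2], cohort)

    def test_missing_feature_values_dropped_pairwise(self):
        feats, cohort = _toy_tables(n=60, seed=9)
        feats = feats.copy()
        feats.loc[feats.index[:10], "maxSCR_TTP"] = np.nan
        rep = run_comparisons(feats, cohort, groupings=("pain_type",), strata=())
        pairs = rep.pairwise()
        n_used = pairs[pairs.feature == "maxSCR_TTP"][["n_a", "n_b"]].sum(axis=1)
        assert (n_used < 60).all()

    def test_summary_renders(self):
        feats, cohort = _toy_tables()
        rep = run_comparisons(feats, cohort, strata=())
        text = rep.summary("pain_type")
        assert "nSCR_CDA" in text and "H" in text


class TestCompareFeature:
    def test_medians_and_iqr_definition(self):
        feats, cohort = _toy_tables(n=90, seed=6)
        res = compare_feature(feats.merge(cohort, on="patient_id"),
                              "nSCR_CDA", "pain_type")
        df = feats.merge(cohort, on="patient_id")
        vals = df.loc[df.pain_type == "nociceptive", "nSCR_CDA"]
        assert res.group_medians["nociceptive"] == pytest.approx(np.median(vals))
        assert res.group_iqrs["nociceptive"] == pytest.approx(
            np.percentile(vals, 75) - np.percentile(vals, 25))
        assert len(res.pairwise) == 3
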