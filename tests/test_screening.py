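"""Edge-wise group inference: t-tests, multiplicity, Cohen's D, screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connscreen.screening import (ConnectivityScreen, ScreenConfig,
                                  adjust_pvalues, cohens_d_matrix,
                                  edgewise_ttest, screen_edges)

from conftest import z_group, z_matrix


def pooled_t_oracle(a, b):
    """Hand-evaluated pooled-variance two-sample t."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((x - ma) ** 2 for x in a) / (na - 1)
    sb2 = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def bh_stepup_oracle(p):
    """Brute-force Benjamini–Hochberg adjusted values."""
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        k = order[rank_from_top - 1]
        running = min(running, p[k] * m / rank_from_top)
        adj[k] = running
    return adj


class TestEdgewiseTTest:
    def test_matches_pooled_formula_on_toy_edge(self):
        ga = z_group({(0, 1): [0.1, 0.2, 0.3]})
        gb = z_group({(0, 1): [0.4, 0.5, 0.6]})
        res = edgewise_ttest(ga, gb)
        assert res["t"].iloc[0] == pytest.approx(
            pooled_t_oracle([0.1, 0.2, 0.3], [0.4, 0.5, 0.6]), abs=1e-12)

    def test_identical_groups_are_null_everywhere(self):
        mats = z_group({(0, 1): [0.1, 0.5], (0, 2): [-0.2, 0.3],
                        (1, 2): [0.0, 0.1]}, n_rois=3)
        res = edgewise_ttest(mats, mats)
        assert np.allclose(res["t"], 0.0) and np.allclose(res["p"], 1.0)

    def test_31_rois_give_465_edges(self, rng):
        mats = [z_matrix({(i, j): rng.normal()
                          for i in range(31) for j in range(i + 1, 31)}, 31)
                for _ in range(4)]
        res = edgewise_ttest(mats[:2], mats[2:])
        assert len(res) == 31 * 30 // 2

    def test_degenerate_constant_edge_warns_and_sets_p_one(self):
        ga = z_group({(0, 1): [0.5, 0.5]})
        gb = z_group({(0, 1): [0.1, 0.1]})
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            res = edgewise_ttest(ga, gb)
        assert res["p"].iloc[0] == 1.0

    def test_single_animal_group_refused(self):
        ga = z_group({(0, 1): [0.1]})
        gb = z_group({(0, 1): [0.2, 0.3]})
        with pytest.raises(ValueError, match="at least 2"):
            edgewise_ttest(ga, gb)

    def test_label_swap_negates_t_and_keeps_p(self, rng):
        ga = z_group({(0, 1): rng.normal(size=5), (0, 2): rng.normal(size=5),
                      (1, 2): rng.normal(size=5)}, 3)
        gb = z_group({(0, 1): rng.normal(size=4), (0, 2): rng.normal(size=4),
                      (1, 2): rng.normal(size=4)}, 3)
        fwd, rev = edgewise_ttest(ga, gb), edgewise_ttest(gb, ga)
        assert np.allclose(fwd["t"], -rev["t"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_welch_variant_differs_under_unequal_variance(self, rng):
        ga = z_group({(0, 1): rng.normal(0, 1, size=6)})
        gb = z_group({(0, 1): rng.normal(0, 5, size=4)})
        s = edgewise_ttest(ga, gb, variant="student")["t"].iloc[0]
        w = edgewise_ttest(ga, gb, variant="welch")["t"].iloc[0]
        assert s != pytest.approx(w, abs=1e-6)


class TestAdjustPvalues:
    def test_single_unit_p_unchanged(self):
        assert adjust_pvalues([1.0], "bh_fdr") == pytest.approx([1.0])

    def test_bonferroni_scales_by_m(self):
        out = adjust_pvalues([0.01, 0.5, 0.2, 0.9, 0.3], "bonferroni")
        assert out[0] == pytest.approx(0.05, abs=1e-12)
        assert out[3] == 1.0  # capped

    def test_bh_matches_brute_force_stepup(self, rng):
        cases = [[0.01, 0.02, 0.03, 0.04],
                 list(rng.uniform(size=9)),
                 [0.5, 0.5, 0.01, 0.9]]
        for p in cases:
            assert adjust_pvalues(p, "bh_fdr") == pytest.approx(
                bh_stepup_oracle(p), abs=1e-12)

    def test_bh_worked_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr") == (
            pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12),
           st.data())
    def test_bh_monotone_in_each_raw_p(self, p, data):
        idx = data.draw(st.integers(0, len(p) - 1))
        bump = data.draw(st.floats(0, 1))
        p2 = list(p)
        p2[idx] = min(1.0, p2[idx] + bump)
        before = adjust_pvalues(p, "bh_fdr")
        after = adjust_pvalues(p2, "bh_fdr")
        assert np.all(after >= before - 1e-12)


class TestCohensD:
    def test_equal_means_give_zero(self):
        ga = z_group({(0, 1): [0.1, 0.3]})
        gb = z_group({(0, 1): [0.3, 0.1]})
        assert cohens_d_matrix(ga, gb).values[0, 1] == pytest.approx(0.0)

    def test_matches_pooled_formula(self):
        a, b = [0.1, 0.2, 0.3], [0.4, 0.5, 0.6]
        d = cohens_d_matrix(z_group({(0, 1): a}), z_group({(0, 1): b}))
        ma, mb = np.mean(a), np.mean(b)
        sp = math.sqrt((2 * np.var(a, ddof=1) + 2 * np.var(b, ddof=1)) / 4)
        assert d.values[0, 1] == pytest.approx((ma - mb) / sp, abs=1e-12)

    def test_zero_pooled_sd_masked_with_warning(self):
        ga = z_group({(0, 1): [1.0, 1.0]})
        gb = z_group({(0, 1): [0.0, 0.0]})
        with pytest.warns(RuntimeWarning, match="zero pooled SD"):
            d = cohens_d_matrix(ga, gb)
        assert np.isnan(d.values[0, 1])

    def test_label_swap_negates_d(self, rng):
        ga = z_group({(0, 1): rng.normal(size=5)})
        gb = z_group({(0, 1): rng.normal(size=5)})
        d1 = cohens_d_matrix(ga, gb).values[0, 1]
        d2 = cohens_d_matrix(gb, ga).values[0, 1]
        assert d1 == pytest.approx(-d2, abs=1e-12)


class TestScreen:
    def test_all_null_adjusted_p_gives_empty_sets(self, rng):
        ga = z_group({(0, 1): rng.normal(size=4), (0, 2): rng.normal(size=4),
                      (1, 2): rng.normal(size=4)}, 3)
        gb = z_group({(0, 1): rng.normal(size=4), (0, 2): rng.normal(size=4),
                      (1, 2): rng.normal(size=4)}, 3)
        res = edgewise_ttest(ga, gb)
        res["p_adj"] = 1.0
        res["d"] = 0.0
        sets = screen_edges(res)
        assert not sets.significance and not sets.effect

    def test_masked_d_excluded_from_effect_but_not_significance(self):
        import pandas as pd
        edges = pd.DataFrame({
            "roi_i": ["a"], "roi_j": ["b"], "t": [5.0], "p": [1e-5],
            "p_adj": [1e-4], "d": [np.nan]})
        sets = screen_edges(edges, ScreenConfig())
        assert sets.significance == [("a", "b")]
        assert sets.effect == []

    def test_model_results_roundtrip(self, rng):
        edge_vals = {(i, j): None for i in range(4) for j in range(i + 1, 4)}
        ga = z_group({e: rng.normal(0.5, 0.1, size=5) for e in edge_vals}, 4)
        gb = z_group({e: rng.normal(0.0, 0.1, size=5) for e in edge_vals}, 4)
        results = ConnectivityScreen(ga, gb).fit()
        assert len(results.edges) == 6
        assert (results.edges["p_adj"] >= results.edges["p"] - 1e-15).all()
        assert "Multi-parameter" in results.summary()
        chord = results.chord_edgelist("effect")
        assert len(chord) == len(results.sets.effect)
        assert set(chord["direction"]) <= {"enhanced", "reduced"}
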