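import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimsap.differentiation import (
    amova_phist,
    arcsine_transform,
    hierarchical_amova,
    jaccard_distances,
    locus_by_locus_amova,
    nmds,
    one_factor_anova,
    pairwise_group_anova,
    pairwise_sq_distances,
    panel_presence_response,
)


# ------------------------------------------------------------------ oracles


def naive_one_level(x, groups):
    """Brute-force AMOVA from the distance-matrix algebra (nested loops)."""
    d2 = pairwise_sq_distances(x)
    n = len(groups)
    levels = sorted(set(groups))
    ss_tot = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in levels:
        idx = [i for i in range(n) if groups[i] == g]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_tot - ss_w
    G = len(levels)
    msa, msw = ss_a / (G - 1), ss_w / (n - G)
    n0 = (n - sum(groups.count(g) ** 2 for g in levels) / n) / (G - 1)
    sa = (msa - msw) / n0
    phi = sa / (sa + msw)
    return ss_a, ss_w, sa, msw, phi


class TestOneFactorAnova:
    def test_identical_groups_f_zero(self):
        y = np.r_[np.arange(5.0), np.arange(5.0)]
        labels = np.repeat(["a", "b"], 5)
        res = one_factor_anova(y, labels)
        assert res.f == pytest.approx(0.0)

    def test_zero_within_variance(self):
        y = np.r_[np.zeros(4), np.full(4, 10.0)]
        res = one_factor_anova(y, np.repeat(["a", "b"], 4))
        assert np.isinf(res.f) and res.p == 0.0

    def test_matches_scipy(self, rng):
        y = rng.normal(size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        res = one_factor_anova(y, labels)
        f, p = stats.f_oneway(y[:4], y[4:8], y[8:])
        assert res.f == pytest.approx(f)
        assert res.p == pytest.approx(p)
        assert (res.df_between, res.df_within) == (2, 9)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            one_factor_anova([1, 2, 3], ["a", "a", "a"])


class TestPairwiseAnova:
    def test_identical_groups_adjusted_p_near_one(self, rng):
        base = rng.normal(size=6)
        y = np.r_[base, base, base]
        labels = np.repeat(["a", "b", "c"], 6)
        out = pairwise_group_anova(y, labels)
        assert (out["p_adjusted"] > 0.99).all()

    def test_adjusted_geq_raw(self, rng):
        y = rng.normal(size=20)
        labels = np.repeat(["a", "b", "c", "d"], 5)
        out = pairwise_group_anova(y, labels)
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()

    def test_planted_group_shift_detected(self, rng):
        y = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(8, 1, 30)]
        labels = np.repeat(["a", "b", "c"], 30)
        out = pairwise_group_anova(y, labels)
        sig = out[out["p_adjusted"] < 0.001]
        pairs = {frozenset((r.group1, r.group2)) for r in sig.itertuples()}
        assert pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_matches_pooled_t(self, rng):
        y = rng.normal(size=14)
        labels = np.repeat(["a", "b"], 7)
        out = pairwise_group_anova(y, labels)
        t, p = stats.ttest_ind(y[:7], y[7:], equal_var=True)
        assert out["t"].iloc[0] == pytest.approx(t)
        assert out["p"].iloc[0] == pytest.approx(p)

    def test_arcsine_transform(self):
        assert arcsine_transform([0, 25, 100]) == pytest.approx(
            [0, np.arcsin(0.5), np.pi / 2]
        )


class TestAmova:
    def test_matches_brute_force_oracle(self, rng):
        x = (rng.random((6, 9)) < 0.5).astype(float)
        groups = ["A", "A", "B", "B", "B", "B"]
        ss_a, ss_w, sa, sw, phi = naive_one_level(x, groups)
        res = amova_phist(x, np.array(groups), n_perm=199, seed=0)
        t = res.table.set_index("stratum")
        assert t.loc["Among groups", "SSD"] == pytest.approx(ss_a)
        assert t.loc["Within groups", "SSD"] == pytest.approx(ss_w)
        assert t.loc["Among groups", "sigma2"] == pytest.approx(sa)
        assert res.phi["phi_st"] == pytest.approx(phi)

    def test_additivity_and_msd(self, small_matrix, small_study):
        groups = small_study.metadata["group"].to_numpy()
        res = amova_phist(small_matrix, groups, n_perm=199, seed=1)
        t = res.table.set_index("stratum")
        assert t.loc["Among groups", "SSD"] + t.loc[
            "Within groups", "SSD"
        ] == pytest.approx(t.loc["Total", "SSD"])
        assert (t["MSD"] * t["df"]).iloc[0] == pytest.approx(t["SSD"].iloc[0])
        pct = t["variance_coefficient_pct"].iloc[:2].sum()
        assert pct == pytest.approx(100.0)

    def test_maximally_distinct_groups_phi_one(self):
        x = np.r_[np.zeros((4, 10)), np.ones((4, 10))]
        res = amova_phist(x, np.repeat(["a", "b"], 4), n_perm=199, seed=0)
        assert res.phi["phi_st"] == pytest.approx(1.0)
        assert res.p_values["phi_st"] < 0.05

    def test_identical_samples_flagged(self):
        x = np.ones((6, 5))
        res = amova_phist(x, np.repeat(["a", "b"], 3), n_perm=199, seed=0)
        assert res.undefined
        assert np.isnan(res.phi["phi_st"])

    def test_homogeneous_data_phi_near_zero(self, rng):
        x = (rng.random((40, 60)) < 0.5).astype(float)
        res = amova_phist(x, np.repeat(["a", "b"], 20), n_perm=199, seed=3)
        assert abs(res.phi["phi_st"]) < 0.05
        assert res.p_values["phi_st"] > 0.05

    def test_low_n_perm_warns(self, rng):
        x = (rng.random((6, 4)) < 0.5).astype(float)
        with pytest.warns(UserWarning):
            amova_phist(x, np.repeat(["a", "b"], 3), n_perm=9, seed=0)


class TestHierarchicalAmova:
    def test_matches_brute_force_oracle(self, rng):
        # naive nested decomposition written straight from the algebra
        x = (rng.random((6, 8)) < 0.5).astype(float)
        l1 = np.array(["A", "A", "B", "B", "B", "B"])
        l2 = np.array(["s", "s", "m", "m", "a", "a"])
        d2 = pairwise_sq_distances(x)
        n = 6

        def pair_sum(idx):
            return sum(d2[i, j] for i in idx for j in idx if i < j)

        subs = sorted(set(zip(l1, l2)))
        grps = sorted(set(l1))
        ss_tot = pair_sum(range(n)) / n
        ss_ws = sum(
            pair_sum([i for i in range(n) if (l1[i], l2[i]) == s])
            / sum(1 for i in range(n) if (l1[i], l2[i]) == s)
            for s in subs
        )
        t_g = sum(
            pair_sum([i for i in range(n) if l1[i] == g])
            / sum(1 for i in range(n) if l1[i] == g)
            for g in grps
        )
        res = hierarchical_amova(x, l1, l2, n_perm=49, seed=0)
        t = res.table.set_index("stratum")
        assert t.loc["level1", "SSD"] == pytest.approx(ss_tot - t_g)
        assert t.loc["level2 within level1", "SSD"] == pytest.approx(t_g - ss_ws)
        assert t.loc["Error", "SSD"] == pytest.approx(ss_ws)
        assert t.loc["Total", "SSD"] == pytest.approx(ss_tot)
        # 2 strata, 3 subpops (A/s, B/m, B/a), 6 samples -> dfs 1, 1, 3
        assert t["df"].iloc[:3].tolist() == [1, 1, 3]

    def test_msd_equals_ssd_over_df(self, small_matrix, small_study):
        meta = small_study.metadata
        res = hierarchical_amova(
            small_matrix,
            meta["ploidy"].to_numpy(),
            meta["reproduction_mode"].to_numpy(),
            n_perm=99,
            seed=0,
        )
        t = res.table[res.table["df"] > 0]
        assert np.allclose(t["MSD"] * t["df"], t["SSD"])


class TestLocusByLocus:
    def test_null_fraction_near_alpha(self, rng):
        x = (rng.random((60, 300)) < 0.5).astype(float)
        frac, table = locus_by_locus_amova(
            x, np.repeat(["a", "b"], 30), alpha=0.05, n_perm=199, seed=5
        )
        assert frac < 0.12  # type-I control (generous 2x margin)

    def test_planted_loci_detected(self, rng):
        n = 60
        x = (rng.random((n, 200)) < 0.5).astype(float)
        groups = np.repeat(["a", "b"], 30)
        for j in range(10):  # plant strong differentiation
            x[:30, j] = (rng.random(30) < 0.95).astype(float)
            x[30:, j] = (rng.random(30) < 0.05).astype(float)
        frac, table = locus_by_locus_amova(
            x, groups, alpha=0.05, n_perm=499, seed=6
        )
        assert table["significant"].iloc[:10].sum() >= 9

    def test_monomorphic_skipped_but_counted(self):
        x = np.c_[np.ones(8), np.r_[np.ones(4), np.zeros(4)]]
        frac, table = locus_by_locus_amova(
            x, np.repeat(["a", "b"], 4), n_perm=199, seed=0
        )
        assert table["monomorphic"].tolist() == [True, False]
        assert np.isnan(table["p"].iloc[0])
        assert len(table) == 2  # denominator includes monomorphic loci


class TestNmds:
    def test_duplicated_sample_coincident(self, rng):
        x = (rng.random((10, 30)) < 0.5).astype(int)
        x[1] = x[0]
        res = nmds(x, seed=0, n_restarts=4)
        c = res.coordinates.to_numpy()
        assert np.linalg.norm(c[0] - c[1]) < 1e-3 * np.abs(c).max()

    def test_separated_clusters_recovered(self, rng):
        a = np.c_[
            (rng.random((15, 15)) < 0.9), (rng.random((15, 15)) < 0.05)
        ].astype(int)
        b = np.c_[
            (rng.random((15, 15)) < 0.05), (rng.random((15, 15)) < 0.9)
        ].astype(int)
        x = np.r_[a, b]
        res = nmds(x, seed=0, n_restarts=8)
        from sklearn.metrics import silhouette_score

        labels = np.repeat([0, 1], 15)
        assert silhouette_score(res.coordinates.to_numpy(), labels) > 0.5

    def test_more_iterations_do_not_increase_stress(self, rng):
        x = (rng.random((20, 40)) < 0.5).astype(int)
        short = nmds(x, seed=3, n_restarts=1, max_iter=3)
        long = nmds(x, seed=3, n_restarts=1, max_iter=300)
        assert long.stress <= short.stress + 1e-9

    def test_jaccard_properties(self, rng):
        x = (rng.random((12, 25)) < 0.4).astype(int)
        d = jaccard_distances(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.max() <= 1.0 and d.min() >= 0.0
        for _ in range(50):
            i, j, k = rng.integers(0, 12, size=3)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nmds(np.ones((2, 4)))


class TestPanelResponse:
    def test_stacking(self, small_matrix):
        from epimsap.scoring import panel_types

        types = panel_types(small_matrix.columns)
        resp = panel_presence_response(small_matrix, types)
        assert len(resp) == 3 * small_matrix.shape[0]
        one = resp[(resp["panel"] == "n")]
        expected = np.asarray(small_matrix)[:, types == "n"].sum(axis=1)
        assert np.allclose(one["count"].to_numpy(), expected)
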