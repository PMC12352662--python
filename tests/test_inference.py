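"""Repeated-measures ANOVA, FDR, contrasts, correlations, spin tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcmanifold import inference as inf
from fcmanifold.design import EPOCHS, EPOCH_HAND, EPOCH_STAGE


def pingouin_rm_anova(y):
    """Independent two-way within-subject ANOVA oracle (pingouin)."""
    import pingouin as pg

    n = y.shape[0]
    rows = []
    for s in range(n):
        for j, ep in enumerate(EPOCHS):
            rows.append({"subject": s, "hand": EPOCH_HAND[ep],
                         "stage": EPOCH_STAGE[ep], "y": y[s, j]})
    df = pd.DataFrame(rows)
    res = pg.rm_anova(data=df, dv="y", within=["hand", "stage"],
                      subject="subject", detailed=True)
    out = {}
    for _, row in res.iterrows():
        out[row["Source"]] = (row["F"], row["p_unc"])
    return out


class TestRmAnova:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pingouin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((10, 6))
        res = inf.rm_anova_2way(y)
        oracle = pingouin_rm_anova(y)
        assert np.isclose(res["F_hand"][0], oracle["hand"][0], atol=1e-8)
        assert np.isclose(res["F_stage"][0], oracle["stage"][0], atol=1e-8)
        assert np.isclose(res["F_inter"][0], oracle["hand * stage"][0],
                          atol=1e-8)
        assert np.isclose(res["p_stage"][0], oracle["stage"][1], atol=1e-8)

    def test_df_structure_for_38_subjects(self):
        rng = np.random.default_rng(5)
        res = inf.rm_anova_2way(rng.standard_normal((38, 6)))
        assert res["df"]["stage"] == (2, 74)
        assert res["df"]["hand"] == (1, 37)
        assert res["df"]["interaction"] == (2, 74)

    def test_pure_subject_offsets_give_zero_f(self):
        rng = np.random.default_rng(6)
        y = np.repeat(rng.standard_normal((12, 1)), 6, axis=1)
        res = inf.rm_anova_2way(y)
        for eff in ("hand", "stage", "inter"):
            assert res[f"F_{eff}"][0] == 0.0
            assert res[f"p_{eff}"][0] == 1.0

    def test_agrees_with_permutation_p(self):
        # permutation of epoch labels within subject approximates the
        # parametric p under the null
        rng = np.random.default_rng(7)
        y = rng.standard_normal((12, 6))
        res = inf.rm_anova_2way(y)
        F_obs = res["F_stage"][0]
        count = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = np.array([rng.permutation(6) for _ in range(12)])
            yp = np.take_along_axis(y, perm, axis=1)
            count += inf.rm_anova_2way(yp)["F_stage"][0] >= F_obs
        p_perm = (1 + count) / (n_perm + 1)
        assert abs(p_perm - res["p_stage"][0]) < 0.12

    def test_missing_cell_rejected(self):
        y = np.random.default_rng(8).standard_normal((5, 6))
        y[2, 3] = np.nan
        with pytest.raises(ValueError):
            inf.rm_anova_2way(y)


class TestFdrBH:
    def test_hand_enumerated_step_up(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05 -> all rejected
        reject, adj = inf.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()

    def test_none_rejected(self):
        reject, _ = inf.fdr_bh(np.array([0.5, 0.6]), q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = inf.fdr_bh(np.array([0.03]), q=0.05)
        assert reject[0] and np.isclose(adj[0], 0.03)

    def test_empty_input(self):
        reject, adj = inf.fdr_bh(np.array([]))
        assert reject.size == 0 and adj.size == 0

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(9)
        p = rng.random(40) ** 2
        reject, adj = inf.fdr_bh(p, q=0.05)
        # brute-force BH: largest k with p_(k) <= k q / m
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * 0.05 / m:
                k_star = k
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        assert np.array_equal(reject, expected)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(10)
        p = rng.random(30)
        r1, _ = inf.fdr_bh(p, q=0.02)
        r2, _ = inf.fdr_bh(p, q=0.10)
        assert np.all(r2[r1])  # rejections grow with q


class TestPairedContrast:
    def test_equal_samples_give_zero_t(self):
        a = np.arange(5.0)
        t, p = inf.paired_contrast(a, a.copy())
        assert t == 0.0 and np.isnan(p)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        t1, _ = inf.paired_contrast(a, b)
        t2, _ = inf.paired_contrast(b, a)
        assert np.isclose(t1, -t2)

    @pytest.mark.parametrize("sided", ["two", "one-greater", "one-less"])
    def test_matches_formula_oracle(self, sided):
        rng = np.random.default_rng(12)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        t, p = inf.paired_contrast(a, b, sided=sided)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        assert np.isclose(t, t_ref, atol=1e-10)
        p_two = 2 * stats.t.sf(abs(t_ref), 19)
        if sided == "two":
            assert np.isclose(p, p_two, atol=1e-10)
        elif sided == "one-greater":
            assert np.isclose(p, stats.t.sf(t_ref, 19), atol=1e-10)
        else:
            assert np.isclose(p, stats.t.cdf(t_ref, 19), atol=1e-10)


class TestSeedContrast:
    def _covs(self, rng, n_sub=5, R=10, jitter=0.0):
        covs = {}
        for s in range(n_sub):
            base = np.eye(R) + 0.1
            for ep in EPOCHS:
                M = base + jitter * rng.standard_normal((R, R))
                covs[(s, ep)] = (M + M.T) / 2
        return covs

    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(13)
        covs = self._covs(rng)
        out = inf.seed_contrast(covs, 0, "EarlyVsBaseline", ["n"] * 10)
        t = out["t"]
        assert np.isnan(t[0])  # seed self-connection excluded
        assert np.allclose(t[1:], 0.0)

    def test_network_summary_of_zero_map_is_zero(self):
        rng = np.random.default_rng(14)
        covs = self._covs(rng)
        out = inf.seed_contrast(covs, 0, "LateVsEarly",
                                ["a"] * 5 + ["b"] * 5)
        assert all(np.isclose(v, 0.0) or np.isnan(v)
                   for v in out["network_mean_t"].values())

    def test_contra_vs_ipsi_sign_recovery(self, small_cohort,
                                          small_cohort_pipeline):
        # planted hand modulation: a sensorimotor seed's within-block
        # connectivity is higher in right-hand (contralateral) epochs
        _, _, extras = small_cohort_pipeline
        meta = small_cohort.metadata
        sm_idx = np.flatnonzero(meta["block_role"] == "sensorimotor")
        out = inf.seed_contrast(
            extras["centered"], int(sm_idx[0]), "ContraVsIpsi",
            meta["network"], seed_hemisphere="L",
        )
        others = [i for i in sm_idx if i != sm_idx[0]]
        assert np.nanmean(out["t"][others]) > 0

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            inf.seed_contrast({}, 0, "Bogus", [])


class TestEccBehaviorCorrelation:
    def test_region_copy_of_behavior_gives_r_one(self):
        rng = np.random.default_rng(15)
        b = rng.standard_normal(10)
        D = rng.standard_normal((10, 4))
        D[:, 2] = b
        out = inf.ecc_behavior_correlation(D, b)
        assert np.isclose(out["r"][2], 1.0)

    def test_constant_behavior_flagged_missing(self):
        D = np.random.default_rng(16).standard_normal((8, 3))
        out = inf.ecc_behavior_correlation(D, np.ones(8))
        assert np.all(np.isnan(out["r"]))

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(17)
        D = rng.standard_normal((12, 6))
        b = rng.standard_normal(12)
        out = inf.ecc_behavior_correlation(D, b)
        for j in range(6):
            r_ref = ((D[:, j] - D[:, j].mean()) @ (b - b.mean())
                     / (np.sqrt(np.sum((D[:, j] - D[:, j].mean())**2))
                        * np.sqrt(np.sum((b - b.mean())**2))))
            assert np.isclose(out["r"][j], r_ref, atol=1e-12)

    def test_pairwise_deletion_and_minimum_pairs(self):
        rng = np.random.default_rng(18)
        D = rng.standard_normal((6, 2))
        b = rng.standard_normal(6)
        b[:3] = np.nan  # only 3 complete pairs -> flagged missing
        out = inf.ecc_behavior_correlation(D, b)
        assert np.all(np.isnan(out["r"]))


class TestSpin:
    def _geometry(self, metadata):
        xyz = metadata[["x", "y", "z"]].to_numpy()
        return xyz, metadata["hemisphere"].to_numpy()

    def test_permutations_are_valid_and_hemisphere_respecting(self, metadata):
        xyz, hemi = self._geometry(metadata)
        perms = inf.spin_permutations(xyz, hemi, n_perm=10, seed=0)
        R = len(hemi)
        for perm in perms:
            assert sorted(perm) == list(range(R))
            assert all(hemi[perm[i]] == hemi[i] for i in range(R))

    def test_identity_rotation_reproduces_observed(self, metadata):
        # greedy assignment under zero rotation maps every region to itself,
        # so the null statistic equals the observed one
        xyz, hemi = self._geometry(metadata)
        from scipy.spatial.distance import cdist
        for h in ("L", "R"):
            idx = np.flatnonzero(hemi == h)
            D = cdist(xyz[idx], xyz[idx])
            assign = inf._greedy_assign(D)
            assert np.array_equal(assign, np.arange(len(idx)))

    def test_p_value_bounds_and_determinism(self, metadata):
        xyz, hemi = self._geometry(metadata)
        rng = np.random.default_rng(19)
        v = rng.standard_normal(len(hemi))
        target = rng.standard_normal(len(hemi))
        fn = lambda x: float(np.corrcoef(x, target)[0, 1])
        out1 = inf.spin_null(v, xyz, hemi, fn, n_perm=99, seed=3)
        out2 = inf.spin_null(v, xyz, hemi, fn, n_perm=99, seed=3)
        assert out1.p == out2.p
        assert 1 / 100 <= out1.p <= 1.0

    def test_spatially_smooth_map_beats_spin_null(self, metadata):
        # a statistic driven by true spatial alignment should be extreme
        # against rotated nulls
        xyz, hemi = self._geometry(metadata)
        v = xyz[:, 2]  # perfectly smooth map
        fn = lambda x: float(np.corrcoef(x, xyz[:, 2])[0, 1])
        out = inf.spin_null(v, xyz, hemi, fn, n_perm=199, seed=4)
        assert out.p < 0.05


class TestNetworkBehavior:
    def test_planted_network_association_detected(self, metadata):
        rng = np.random.default_rng(20)
        xyz = metadata[["x", "y", "z"]].to_numpy()
        hemi = metadata["hemisphere"].to_numpy()
        nets = metadata["network"].to_numpy()
        n_sub = 14
        behavior = rng.standard_normal(n_sub)
        D = rng.standard_normal((n_sub, len(nets)))
        target = (nets == "Visual") & (hemi == "L")
        D[:, target] += 3.0 * behavior[:, None]
        out = inf.network_ecc_behavior(D, behavior, nets, hemi, xyz,
                                       n_perm=200, seed=5)
        assert out["L:Visual"]["p_spin"] < 0.05
        assert abs(out["L:Visual"]["r"]) > 0.8

    def test_single_region_network_equals_region_r(self):
        rng = np.random.default_rng(21)
        n_sub, R = 10, 6
        xyz = rng.standard_normal((R, 3))
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        hemi = np.array(["L", "L", "L", "R", "R", "R"])
        nets = np.array(["a", "b", "b", "a", "b", "b"])
        D = rng.standard_normal((n_sub, R))
        b = rng.standard_normal(n_sub)
        out = inf.network_ecc_behavior(D, b, nets, hemi, xyz, n_perm=50,
                                       seed=6)
        r_ref = stats.pearsonr(D[:, 0], b)[0]
        assert np.isclose(out["L:a"]["r"], r_ref, atol=1e-12)
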