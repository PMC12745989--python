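"""RSA: RDM identities, information content, group statistics.

Welch's ANOVA and Games-Howell are checked against pingouin (independent
implementation) and against hand-evaluated textbook formulas.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vqmvpa as v

from conftest import tiny_design_config, tiny_sim_params


def make_index(categories, qualities):
    return pd.DataFrame(
        {
            "image_id": [f"img{k}" for k in range(len(categories))],
            "category": categories,
            "quality": qualities,
        }
    )


class TestComputeRdm:
    def test_identical_patterns_distance_zero(self):
        pats = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        rdm = v.compute_rdm(pats, make_index(["face", "face"], ["low", "low"]))
        np.testing.assert_allclose(rdm.matrix, 0, atol=1e-12)

    def test_negated_pattern_distance_two(self):
        pats = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        rdm = v.compute_rdm(pats, make_index(["face", "face"], ["low", "low"]))
        np.testing.assert_allclose(rdm.matrix[0, 1], 2.0, atol=1e-12)

    def test_hand_computed_pearson_distance(self):
        # r((1,2,3), (1,2,4)) = 3 / sqrt(2 * 14/3) = 0.981980...
        pats = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]])
        rdm = v.compute_rdm(pats, make_index(["face", "face"], ["low", "low"]))
        expected = 1 - 3 / np.sqrt(2 * 14 / 3)
        np.testing.assert_allclose(rdm.matrix[0, 1], expected, atol=1e-9)
        np.testing.assert_allclose(rdm.matrix[0, 1], 0.0180195, atol=1e-6)

    def test_constant_pattern_rejected(self):
        pats = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0]])
        with pytest.raises(ValueError, match="item 0"):
            v.compute_rdm(pats, make_index(["face", "face"], ["low", "low"]))

    def test_symmetry_zero_diag_bounds(self, rng):
        pats = rng.standard_normal((12, 30))
        rdm = v.compute_rdm(
            pats, make_index(["face"] * 12, ["low"] * 12)
        )
        assert (rdm.matrix >= 0).all() and (rdm.matrix <= 2).all()
        np.testing.assert_allclose(rdm.matrix, rdm.matrix.T)
        np.testing.assert_allclose(np.diag(rdm.matrix), 0)


class TestIdealRdms:
    def test_semantic_values(self):
        idx = make_index(["face", "face", "object", "scene"], ["low"] * 4)
        rdm = v.ideal_semantic_rdm(idx)
        assert rdm.matrix[0, 1] == 0.0
        assert rdm.matrix[0, 2] == 1.5  # r of two distinct one-hots is -1/2
        assert set(np.unique(rdm.matrix)) == {0.0, 1.5}

    def test_quality_values(self):
        idx = make_index(["face"] * 3, ["low", "neutral", "high"])
        rdm = v.ideal_quality_rdm(idx)
        assert rdm.matrix[0, 1] == 1.0  # low <-> neutral
        assert rdm.matrix[1, 2] == 1.0  # neutral <-> high
        np.testing.assert_allclose(rdm.matrix[0, 2], np.sqrt(2))  # low <-> high
        assert rdm.matrix[0, 0] == 0.0

    def test_neutral_equidistant(self):
        idx = make_index(["face"] * 6, ["low", "neutral", "high"] * 2)
        rdm = v.ideal_quality_rdm(idx)
        np.testing.assert_allclose(rdm.matrix[1, 0], rdm.matrix[1, 2])

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            v.ideal_semantic_rdm(make_index(["cat"], ["low"]))
        with pytest.raises(ValueError):
            v.ideal_quality_rdm(make_index(["face"], ["awful"]))


class TestInformationContent:
    def test_identity_gives_one(self):
        idx = make_index(["face", "object", "scene", "face"], ["low"] * 4)
        rdm = v.ideal_semantic_rdm(idx)
        assert v.information_content(rdm, rdm) == pytest.approx(1.0)

    def test_monotone_reversal_gives_minus_one(self):
        idx = make_index(["face", "object", "scene", "face"], ["low"] * 4)
        ideal = v.ideal_semantic_rdm(idx)
        reversed_rdm = v.RDM(matrix=2 - ideal.matrix
                             - np.diag(np.diag(2 - ideal.matrix)),
                             item_index=idx)
        assert v.information_content(reversed_rdm, ideal) == pytest.approx(-1.0)

    def test_constant_triangle_flagged(self):
        idx = make_index(["face", "face", "face"], ["low"] * 3)
        ideal = v.ideal_semantic_rdm(idx)  # all zeros off-diagonal
        other = v.RDM(matrix=np.array([[0, 1, 0.5], [1, 0, 0.2], [0.5, 0.2, 0]]),
                      item_index=idx)
        assert np.isnan(v.information_content(other, ideal))

    def test_reordering_invariance(self, rng):
        idx = make_index(["face", "object", "scene"] * 4, ["low"] * 12)
        pats = rng.standard_normal((12, 20))
        rdm = v.compute_rdm(pats, idx)
        ideal = v.ideal_semantic_rdm(idx)
        base = v.information_content(rdm, ideal)
        perm = rng.permutation(12)
        rdm_p = v.compute_rdm(pats[perm], idx.iloc[perm].reset_index(drop=True))
        ideal_p = v.ideal_semantic_rdm(idx.iloc[perm].reset_index(drop=True))
        assert v.information_content(rdm_p, ideal_p) == pytest.approx(
            base, abs=1e-12
        )

    def test_spearman_option(self, rng):
        idx = make_index(["face", "object", "scene"] * 2, ["low"] * 6)
        pats = rng.standard_normal((6, 10))
        rdm = v.compute_rdm(pats, idx)
        ideal = v.ideal_semantic_rdm(idx)
        r_s = v.information_content(rdm, ideal, method="spearman")
        a, b = rdm.upper_triangle(), ideal.upper_triangle()
        assert r_s == pytest.approx(stats.spearmanr(a, b).statistic)


class TestGroupAverageRdm:
    def test_single_participant_identity(self, rng):
        idx = make_index(["face", "object"], ["low"] * 2)
        rdm = v.compute_rdm(rng.standard_normal((2, 5)), idx)
        np.testing.assert_array_equal(
            v.group_average_rdm([rdm]).matrix, rdm.matrix
        )

    def test_complementary_pair_averages_constant(self):
        idx = make_index(["face", "object", "scene"], ["low"] * 3)
        a = np.array([[0, 0.5, 1.2], [0.5, 0, 0.8], [1.2, 0.8, 0]])
        rdm_a = v.RDM(matrix=a, item_index=idx)
        b = 2 - a
        np.fill_diagonal(b, 0)
        rdm_b = v.RDM(matrix=b, item_index=idx)
        avg = v.group_average_rdm([rdm_a, rdm_b])
        off = avg.upper_triangle()
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_mismatched_indices_rejected(self, rng):
        idx1 = make_index(["face", "object"], ["low"] * 2)
        idx2 = make_index(["face", "scene"], ["low"] * 2)
        idx2["image_id"] = ["imgX", "imgY"]
        r1 = v.compute_rdm(rng.standard_normal((2, 5)), idx1)
        r2 = v.compute_rdm(rng.standard_normal((2, 5)), idx2)
        with pytest.raises(ValueError):
            v.group_average_rdm([r1, r2])

    def test_group_averaging_suppresses_noise(self):
        """Group information content >= mean individual content in >= 90%
        of replicates (independent noise averages out)."""
        rng = np.random.default_rng(7)
        idx = make_index(["face", "object", "scene"] * 4, ["low"] * 12)
        ideal = v.ideal_semantic_rdm(idx)
        signal = ideal.matrix.copy()
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            rdms, indiv = [], []
            for _p in range(6):
                noise = rng.standard_normal(signal.shape)
                noise = 0.8 * (noise + noise.T) / 2
                m = np.clip(signal + noise, 0, 2)
                np.fill_diagonal(m, 0)
                rdm = v.RDM(matrix=m, item_index=idx)
                rdms.append(rdm)
                indiv.append(v.information_content(rdm, ideal))
            group = v.information_content(v.group_average_rdm(rdms), ideal)
            wins += group >= np.mean(indiv)
        assert wins / n_rep >= 0.9


def welch_anova_oracle(groups):
    """Textbook Welch formulas, evaluated independently."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    w = n / s2
    mw = np.sum(w * m) / np.sum(w)
    A = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    F = np.sum(w * (m - mw) ** 2) / (k - 1) / (1 + 2 * (k - 2) / (k**2 - 1) * A)
    df2 = (k**2 - 1) / (3 * A)
    p = stats.f.sf(F, k - 1, df2)
    return F, df2, p


class TestWelchAnova:
    def test_equal_groups_f_near_zero(self):
        g = [np.array([1.0, 2, 3, 4])] * 3
        res = v.welch_anova(g)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        groups = [np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]),
                  np.array([11.0, 12, 13, 14])]
        res = v.welch_anova(groups)
        F, df2, p = welch_anova_oracle(groups)
        assert res.f == pytest.approx(F, abs=1e-9)
        assert res.df2 == pytest.approx(df2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.5, 2, 10),
                               rng.normal(1, 0.5, 7)])
        labs = np.repeat(["a", "b", "c"], [8, 10, 7])
        df = pd.DataFrame({"y": vals, "g": labs})
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        groups = [vals[labs == g] for g in ["a", "b", "c"]]
        res = v.welch_anova(groups)
        assert res.f == pytest.approx(ref["F"].iloc[0], abs=1e-9)
        assert res.df2 == pytest.approx(ref["ddof2"].iloc[0], abs=1e-9)
        assert res.p == pytest.approx(ref["p_unc"].iloc[0], abs=1e-9)

    def test_type_one_error_calibrated_under_null(self):
        """Equal means, unequal variances, n = 14 per group: rejection rate
        at alpha = 0.05 stays within [0.035, 0.065] over 2,000 replicates."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = [rng.normal(0, sd, 14) for sd in (0.5, 1.0, 2.0)]
            rejections += v.welch_anova(groups).p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            v.welch_anova([np.array([1.0, 1.0]), np.array([1.0, 2.0]),
                           np.array([2.0, 3.0])])


class TestGamesHowell:
    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([rng.normal(0, 1, 9), rng.normal(1, 2, 12),
                               rng.normal(2, 0.5, 8)])
        labs = np.repeat(["a", "b", "c"], [9, 12, 8])
        df = pd.DataFrame({"y": vals, "g": labs})
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        groups = [vals[labs == g] for g in ["a", "b", "c"]]
        ours = v.games_howell(groups, labels=["a", "b", "c"])
        for _, row in ref.iterrows():
            mine = ours[(ours["A"] == row["A"]) & (ours["B"] == row["B"])]
            assert mine["df"].iloc[0] == pytest.approx(row["df"], abs=1e-9)
            assert mine["p"].iloc[0] == pytest.approx(row["pval"], abs=1e-9)

    def test_hand_formula_small_input(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([7.0, 9.0, 11.0])
        res = v.games_howell([a, b], labels=["a", "b"])
        se2 = np.var(a, ddof=1) / 3 + np.var(b, ddof=1) / 3
        t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
        df = se2**2 / ((np.var(a, ddof=1) / 3) ** 2 / 2
                       + (np.var(b, ddof=1) / 3) ** 2 / 2)
        p = stats.studentized_range.sf(abs(t) * np.sqrt(2), 2, df)
        assert res["t"].iloc[0] == pytest.approx(t, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-9)


class TestQualityGradedRecovery:
    def test_semantic_content_increases_with_quality_in_low_level_rois(self):
        """Parameter recovery: gains 0.2/0.5/0.9 in a low-level ROI ->
        estimated semantic information content strictly increasing with
        quality (mean over participants, majority of seeds)."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            design = v.generate_design(
                tiny_design_config(n_participants=3, seed=seed)
            )
            params = tiny_sim_params(
                seed=seed, roi_names=("calcarine", "fusiform")
            )
            ds = v.simulate_betas(design, params)
            reps = v.extract_representations(ds, k=10)
            table = v.information_content_table(reps)
            sub = table[(table["roi"] == "calcarine")
                        & (table["label_type"] == "semantic")]
            means = sub.groupby("quality")["r"].mean()
            hits += means["low"] < means["neutral"] < means["high"]
        assert hits >= n_seeds - 1
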