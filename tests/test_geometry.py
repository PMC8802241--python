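import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mismatchlab import (decompose, divergence, mismatch, pairwise_mismatch,
                         parent_deviation, parent_distances, population_mean)
from mismatchlab.geometry import cross_summary

from conftest import toy_cross_matrix
from oracles import chi_mean, grid_line_distance, half_normal_mean


class TestDivergence:
    def test_identical_vectors_give_zero(self):
        v = np.arange(15.0)
        assert divergence(v, v) == 0.0

    def test_unit_difference_in_every_trait(self):
        assert divergence(np.zeros(15), np.ones(15)) == pytest.approx(np.sqrt(15))

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=15), rng.normal(size=15)
            oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert divergence(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            divergence(np.zeros(3), np.zeros(4))


class TestMismatch:
    def test_perpendicular_offset_in_plane(self):
        assert mismatch(np.array([2.0, 3.0]), np.zeros(2),
                        np.array([4.0, 0.0])) == pytest.approx(3.0)

    def test_points_on_line_have_zero_mismatch(self):
        pm, pf = np.zeros(4), np.array([1.0, 2.0, 0.0, -1.0])
        for t in (0.0, 0.5, 1.0, 2.5, -1.0):  # parents, midparent, transgressive
            assert mismatch(pm + t * (pf - pm), pm, pf) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.integers(2, 16)
            pm, pf = rng.normal(size=p), rng.normal(size=p)
            f = rng.normal(scale=2.0, size=p)
            assert mismatch(f, pm, pf) == pytest.approx(
                grid_line_distance(f, pm, pf), abs=1e-6)

    def test_coincident_parents_fall_back_to_point_distance(self):
        pm = np.array([1.0, 1.0])
        with pytest.warns(UserWarning, match="coincide"):
            d = mismatch(np.array([4.0, 5.0]), pm, pm)
        assert d == pytest.approx(5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariances(self, seed):
        """Swap of parent labels, global translation, orthogonal rotation;
        linear scaling under uniform dilation."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 12))
        pm, pf, f = rng.normal(size=p), rng.normal(size=p), rng.normal(size=p)
        if np.linalg.norm(pf - pm) < 1e-6:
            return
        d = mismatch(f, pm, pf)
        assert mismatch(f, pf, pm) == pytest.approx(d, abs=1e-10)
        shift = rng.normal(size=p)
        assert mismatch(f + shift, pm + shift, pf + shift) == pytest.approx(d, abs=1e-8)
        Q = np.linalg.qr(rng.normal(size=(p, p)))[0]
        assert mismatch(f @ Q, pm @ Q, pf @ Q) == pytest.approx(d, abs=1e-8)
        assert mismatch(3.0 * f, 3.0 * pm, 3.0 * pf) == pytest.approx(3.0 * d, abs=1e-8)

    def test_zero_iff_on_line(self):
        rng = np.random.default_rng(4)
        pm, pf = rng.normal(size=6), rng.normal(size=6)
        on = pm + 0.37 * (pf - pm)
        assert mismatch(on, pm, pf) < 1e-10
        off = on + 1e-3 * np.eye(6)[0]
        assert mismatch(off, pm, pf) > 1e-5


class TestPopulationMean:
    def test_single_family_equals_family_mean(self):
        df = pd.DataFrame({"family_id": ["a"] * 3, "t": [1.0, 2.0, 3.0]})
        assert population_mean(df, ["t"])[0] == pytest.approx(2.0)

    def test_unbalanced_families_weighted_equally(self):
        # families of sizes 10 and 1 with means 0 and 1 -> 0.5, not 1/11
        df = pd.DataFrame({"family_id": ["big"] * 10 + ["small"],
                           "t": [0.0] * 10 + [1.0]})
        assert population_mean(df, ["t"])[0] == pytest.approx(0.5)

    def test_balanced_families_match_individual_mean(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"family_id": np.repeat(["a", "b", "c"], 7),
                           "t": rng.normal(size=21)})
        assert population_mean(df, ["t"])[0] == pytest.approx(df["t"].mean())

    def test_empty_population_errors(self):
        with pytest.raises(ValueError, match="empty"):
            population_mean(pd.DataFrame({"family_id": [], "t": []}), ["t"])


class TestDecompose:
    def test_all_hybrids_at_midparent(self):
        pm, pf = np.zeros(3), np.array([4.0, 0.0, 0.0])
        mid = (pm + pf) / 2
        m = toy_cross_matrix(pm, pf, np.tile(mid, (6, 1)))
        dec = decompose(m, "c1", "F1")
        assert dec.dominance_effect == pytest.approx(0.0, abs=1e-12)
        assert dec.variance_effect == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_perpendicular_offsets(self):
        # hybrid mean on the line, individuals at +/- delta perpendicular
        pm, pf = np.zeros(2), np.array([4.0, 0.0])
        delta = 0.7
        hybrids = np.array([[2.0, delta], [2.0, -delta]] * 5)
        m = toy_cross_matrix(pm, pf, hybrids)
        dec = decompose(m, "c1", "F1")
        assert dec.dominance_effect == pytest.approx(0.0, abs=1e-12)
        assert dec.variance_effect == pytest.approx(delta, abs=1e-12)

    def test_half_normal_variance_effect(self):
        # perpendicular N(0, s^2) noise in 2-D: E[variance effect] = s*sqrt(2/pi)
        rng = np.random.default_rng(6)
        s, n = 0.8, 20_000
        hybrids = np.column_stack([np.full(n, 2.0), rng.normal(0, s, n)])
        m = toy_cross_matrix(np.zeros(2), np.array([4.0, 0.0]), hybrids)
        dec = decompose(m, "c1", "F1", averaging="individual")
        mc_se = s * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(dec.variance_effect - half_normal_mean(s)) < 3 * mc_se + 2 * s / np.sqrt(n)

    def test_individual_averaging_is_exactly_additive(self, small_study):
        matrix, _ = small_study
        for cross in ("cross01", "cross02"):
            for gen in ("F1", "F2"):
                dec = decompose(matrix, cross, gen, averaging="individual")
                assert dec.mean_mismatch == pytest.approx(
                    dec.dominance_effect + dec.variance_effect, abs=1e-10)

    def test_jensen_variance_effect_nonnegative(self, default_study):
        matrix, _ = default_study
        for cross in [f"cross{i:02d}" for i in range(1, 13)]:
            for gen in ("F1", "F2"):
                for avg in ("family", "individual"):
                    assert decompose(matrix, cross, gen, averaging=avg).variance_effect >= 0


class TestParentDeviation:
    def test_zero_variance_parents(self):
        m = toy_cross_matrix(np.zeros(3), np.ones(3), np.ones((2, 3)) * 0.5)
        dev = parent_deviation(m, "c1")
        assert dev["PM"] == pytest.approx(0.0, abs=1e-12)
        assert dev["PF"] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_unit_variance_matches_chi(self):
        # p=15 isotropic unit parental noise: mean deviation ~ E[chi_14]
        rng = np.random.default_rng(7)
        p, n = 15, 8000
        traits = [f"t{i}" for i in range(p)]
        rows = []
        for gen, pop, center, cid in (("PM", "marine", np.zeros(p), ""),
                                      ("PF", "fw", np.r_[6.0, np.zeros(p - 1)], "c1")):
            X = center + rng.normal(size=(n, p))
            for k in range(n):
                rows.append({"individual_id": f"{gen}{k}", "population": pop,
                             "cross_id": cid, "generation": gen,
                             "family_id": f"{gen}f{k % 4}", **dict(zip(traits, X[k]))})
        rows.append({"individual_id": "h", "population": "fw", "cross_id": "c1",
                     "generation": "F1", "family_id": "hf",
                     **dict(zip(traits, np.zeros(p)))})
        from conftest import make_matrix
        m = make_matrix(rows, traits)
        dev = parent_deviation(m, "c1")
        mc_se = np.sqrt((p - 1 - chi_mean(p - 1) ** 2) / n)
        for gen in ("PM", "PF"):
            assert abs(dev[gen] - chi_mean(p - 1)) < 3 * mc_se + 0.02

    def test_invariant_to_swapping_parent_roles(self, small_study):
        matrix, _ = small_study
        dev = parent_deviation(matrix, "cross01")
        swapped = matrix.data.copy()
        gen = swapped["generation"].copy()
        # relabel: PF rows of cross01 become the "marine" side and vice versa
        pm_rows = (gen == "PM")
        pf_rows = (gen == "PF") & (swapped["cross_id"] == "cross01")
        swapped.loc[pm_rows, "generation"] = "PF"
        swapped.loc[pm_rows, "cross_id"] = "cross01"
        swapped.loc[pm_rows, "population"] = "fw01"
        swapped.loc[pf_rows, "generation"] = "PM"
        from mismatchlab import StandardizedMatrix
        sub = swapped[swapped["cross_id"] == "cross01"]
        m2 = StandardizedMatrix(sub.reset_index(drop=True), matrix.traits)
        dev2 = parent_deviation(m2, "cross01")
        assert dev2["PF"] == pytest.approx(dev["PM"], abs=1e-9)
        assert dev2["PM"] == pytest.approx(dev["PF"], abs=1e-9)


class TestPairwiseAndDistances:
    def test_two_trait_subspace_consistency(self):
        # when only two traits are nonzero, pairwise equals full mismatch
        rng = np.random.default_rng(8)
        pm = np.array([0.0, 0.0, 0.0, 0.0])
        pf = np.array([3.0, 1.0, 0.0, 0.0])
        hybrids = np.column_stack([rng.normal(size=(5, 2)), np.zeros((5, 2))])
        m = toy_cross_matrix(pm, pf, hybrids)
        pw = pairwise_mismatch(m, "c1", "t0", "t1", generation="F1")
        full = cross_summary(m, "c1").individual_mismatch
        np.testing.assert_allclose(pw["d_mm"], full["d_mm"], atol=1e-12)

    def test_off_line_hybrid_has_larger_pairwise_mismatch(self):
        pm, pf = np.zeros(2), np.array([4.0, 4.0])
        hybrids = np.array([[1.0, 1.05], [2.9, 3.0], [0.0, 3.0]])  # 2 near, 1 far
        m = toy_cross_matrix(pm, pf, hybrids)
        pw = pairwise_mismatch(m, "c1", "t0", "t1", generation="F1")
        assert pw["d_mm"].iloc[2] > 5 * pw["d_mm"].iloc[0]
        assert pw["d_mm"].iloc[2] > 5 * pw["d_mm"].iloc[1]

    def test_parent_distances_special_points(self):
        pm, pf = np.zeros(3), np.array([0.0, 6.0, 0.0])
        hybrids = np.array([pm, (pm + pf) / 2])
        m = toy_cross_matrix(pm, pf, hybrids)
        pd_ = parent_distances(m, "c1", "F1")
        np.testing.assert_allclose(pd_["dist_to_marine"], [0.0, 3.0], atol=1e-12)
        np.testing.assert_allclose(pd_["dist_to_freshwater"], [6.0, 3.0], atol=1e-12)

    def test_mismatch_bounded_by_parent_distances(self, small_study):
        matrix, _ = small_study
        for cross in ("cross01", "cross03"):
            for gen in ("F1", "F2"):
                cs = cross_summary(matrix, cross)
                dists = parent_distances(matrix, cross, gen)
                d_mm = cs.individual_mismatch.query("generation == @gen")["d_mm"]
                bound = np.minimum(dists["dist_to_marine"], dists["dist_to_freshwater"])
                assert (d_mm.to_numpy() <= bound.to_numpy() + 1e-10).all()


def test_decomposition_table_matches_per_cross_decompose(small_study):
    """The batched single-pass table agrees with the per-cross decompose
    path to machine precision."""
    from mismatchlab import decomposition_table
    matrix, _ = small_study
    dec = decomposition_table(matrix)
    for _, r in dec.iterrows():
        d = decompose(matrix, r["cross_id"], r["generation"], averaging="family")
        assert d.dominance_effect == pytest.approx(r["dominance_effect"], abs=1e-12)
        assert d.variance_effect == pytest.approx(r["variance_effect"], abs=1e-12)
        assert d.mean_mismatch == pytest.approx(r["mean_mismatch"], abs=1e-12)
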