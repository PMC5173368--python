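"""Neighbor graphs, Moran's I and join-count statistics against oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cavenet import (build_graph, default_bands, join_count_bb, morans_i,
                     scale_profile)


def brute_moran(W: np.ndarray, values: np.ndarray, active: np.ndarray) -> float:
    """O(n²) double-sum oracle for Moran's I over connected nodes."""
    Wa = W[np.ix_(active, active)]
    x = values[active]
    z = x - x.mean()
    n = active.sum()
    num = sum(Wa[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / Wa.sum()) * num / (z @ z)


def brute_bb(W: np.ndarray, x: np.ndarray, active: np.ndarray) -> float:
    Wa = W[np.ix_(active, active)]
    xa = x[active]
    return 0.5 * sum(Wa[i, j] * xa[i] * xa[j]
                     for i in range(active.sum()) for j in range(active.sum()))


class TestBuildGraph:
    def test_collinear_points_row_standardized(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        g = build_graph(coords, 12.0, style="W")
        W = g.weights.toarray()
        assert W[1, 0] == pytest.approx(0.5) and W[1, 2] == pytest.approx(0.5)
        assert W[0, 1] == pytest.approx(1.0) and W[2, 1] == pytest.approx(1.0)
        assert W[0, 2] == 0.0
        assert np.all(np.diag(W) == 0)

    def test_square_band_excludes_diagonal(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        g = build_graph(coords, 11.0, style="B")
        degrees = np.asarray(g.weights.sum(axis=1)).ravel()
        assert np.all(degrees == 2)  # sides only; diagonal is 14.1 m

    def test_style_c_sums_to_n(self, rng):
        coords = rng.uniform(0, 100, size=(50, 2))
        g = build_graph(coords, 40.0, style="C")
        assert g.n_islands == 0
        assert g.weights.sum() == pytest.approx(50.0)

    def test_symmetry_before_coding(self, rng):
        coords = rng.uniform(0, 100, size=(40, 2))
        g = build_graph(coords, 30.0, style="B")
        assert (g.weights != g.weights.T).nnz == 0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            build_graph(np.zeros((5, 2)), 10.0)

    def test_tiny_band_flags_all_islands(self, rng):
        coords = rng.uniform(0, 1000, size=(10, 2))
        g = build_graph(coords, 1e-6)
        assert g.all_islands

    def test_band_upper_bound_inclusive(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [50.0, 50.0]])
        g = build_graph(coords, 10.0, style="B")
        assert g.weights[0, 1] == 1.0


class TestMoran:
    def test_expected_value_is_minus_one_over_n_minus_1(self, rng):
        coords = rng.uniform(0, 100, size=(11, 2))
        g = build_graph(coords, 60.0)
        res = morans_i(g, rng.normal(size=11))
        assert res.expected == pytest.approx(-0.1)

    def test_checkerboard_perfect_dispersion(self):
        xx, yy = np.meshgrid(np.arange(4) * 10.0, np.arange(4) * 10.0)
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        values = (((xx + yy) // 10) % 2).ravel().astype(float)
        g = build_graph(coords, 11.0, style="W")
        res = morans_i(g, values)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("style", ["W", "B", "C"])
    def test_matches_brute_force(self, style, rng):
        coords = rng.uniform(0, 100, size=(20, 2))
        values = rng.normal(size=20)
        g = build_graph(coords, 35.0, style=style)
        res = morans_i(g, values)
        brute = brute_moran(g.weights.toarray(), values, ~g.islands)
        assert res.I == pytest.approx(brute, abs=1e-12)

    def test_constant_values_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(10, 2))
        g = build_graph(coords, 50.0)
        with pytest.raises(ValueError, match="constant"):
            morans_i(g, np.ones(10))

    def test_length_mismatch_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(10, 2))
        g = build_graph(coords, 50.0)
        with pytest.raises(ValueError, match="length"):
            morans_i(g, np.ones(9))

    def test_complete_graph_statistic_degenerates(self, rng):
        # at the maximal extent every pair is joined and I is pinned at E[I]
        coords = rng.uniform(0, 10, size=(15, 2))
        g = build_graph(coords, 100.0, style="W")
        res = morans_i(g, rng.normal(size=15))
        assert res.I == pytest.approx(res.expected, abs=1e-10)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(123)
        coords = rng.uniform(0, 100, size=(25, 2))
        values = rng.normal(size=25)
        g = build_graph(coords, 40.0)
        base = morans_i(g, values)
        scaled = morans_i(g, a * values + b)
        assert scaled.I == pytest.approx(base.I, rel=1e-9, abs=1e-12)
        assert scaled.variance == pytest.approx(base.variance, rel=1e-9)

    def test_regular_graph_styles_agree(self):
        # on a ring all degrees are equal, so B/W/C coded statistics coincide
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        coords = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        values = np.sin(3 * theta)
        gap = np.linalg.norm(coords[0] - coords[1])
        stats = [morans_i(build_graph(coords, gap * 1.01, style=s), values).I
                 for s in "WBC"]
        assert stats[0] == pytest.approx(stats[1], abs=1e-12)
        assert stats[0] == pytest.approx(stats[2], abs=1e-12)


class TestJoinCount:
    def test_all_present_w_style_bb_is_half_n(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        g = build_graph(coords, 60.0, style="W")
        assert g.n_islands == 0
        res = join_count_bb(g, np.ones(30, dtype=int))
        assert res.bb == pytest.approx(15.0)
        assert res.degenerate

    def test_all_absent_bb_is_zero(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        g = build_graph(coords, 60.0)
        res = join_count_bb(g, np.zeros(30, dtype=int))
        assert res.bb == 0.0
        assert res.degenerate

    def test_matches_brute_force(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        x = (rng.random(30) < 0.4).astype(int)
        g = build_graph(coords, 30.0, style="W")
        res = join_count_bb(g, x)
        assert res.bb == pytest.approx(
            brute_bb(g.weights.toarray(), x, ~g.islands), abs=1e-12)

    def test_moments_match_permutation(self, rng):
        """Analytic non-free-sampling mean/variance vs 20,000 relabelings."""
        coords = rng.uniform(0, 100, size=(30, 2))
        x = (rng.random(30) < 0.4).astype(int)
        g = build_graph(coords, 30.0, style="W")
        res = join_count_bb(g, x)
        W = g.weights.toarray()[np.ix_(~g.islands, ~g.islands)]
        xa = x[~g.islands].astype(float)
        perm = np.array([0.5 * (p := rng.permutation(xa)) @ W @ p
                         for _ in range(20000)])
        assert res.expected == pytest.approx(perm.mean(), abs=4 * perm.std() / 140)
        assert res.variance == pytest.approx(perm.var(), rel=0.08)

    def test_non_binary_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(10, 2))
        g = build_graph(coords, 60.0)
        with pytest.raises(ValueError, match="binary"):
            join_count_bb(g, np.arange(10))


class TestScaleProfile:
    def test_single_band_matches_direct_call(self, rng):
        coords = rng.uniform(0, 100, size=(40, 2))
        values = rng.normal(size=40)
        prof = scale_profile(coords, values, stat="moran", bands=[150.0])
        direct = morans_i(build_graph(coords, 150.0), values)
        assert len(prof.results) == 1
        assert prof.results[0].I == pytest.approx(direct.I)

    def test_default_bands_reach_max_extent(self, clustered_coords):
        from scipy.spatial.distance import pdist

        bands = default_bands(clustered_coords, 20)
        assert len(bands) == 20
        assert np.all(np.diff(bands) > 0)
        assert bands[-1] == pytest.approx(pdist(clustered_coords).max())

    def test_empty_band_list_rejected(self, clustered_coords, rng):
        with pytest.raises(ValueError, match="empty"):
            scale_profile(clustered_coords, rng.normal(size=len(clustered_coords)),
                          bands=[])

    def test_simulated_field_detected_then_decays(self, small_landscape):
        """Mirror of the published correlograms: positive autocorrelation at
        small scales, none at the maximal extent of the region."""
        coords = small_landscape[["x_m", "y_m"]].to_numpy(dtype=float)
        vals = small_landscape["richness"].to_numpy(dtype=float)
        prof = scale_profile(coords, vals, stat="moran", n_bands=20)
        frame = prof.to_frame()
        small_scale = frame.iloc[1]
        assert small_scale["estimate"] > small_scale["expected"]
        assert small_scale["p"] < 0.01
        assert frame.iloc[-1]["p"] > 0.05
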