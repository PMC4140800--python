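"""Trace processing, band matching and diversity/similarity measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import distance as ssd

import soilecol as se
from soilecol.fingerprint import Band, BandProfile, LaneTrace


def make_trace(values, lane_id="L"):
    return LaneTrace(np.asarray(values, dtype=float), lane_id=lane_id)


class TestBackground:
    def test_constant_trace_maps_to_zero(self):
        out = se.subtract_background(make_trace(np.full(200, 7.0)), ball_radius=20)
        assert np.allclose(out.intensities, 0.0)

    def test_narrow_peak_height_preserved(self):
        tr = se.simulate_lane_trace([(0.5, 100.0)], peak_width=0.005, n_points=400)
        out = se.subtract_background(make_trace(tr), ball_radius=50)
        assert abs(out.intensities.max() - tr.max()) / tr.max() < 0.05

    def test_output_nonnegative(self, rng):
        tr = np.abs(rng.normal(50, 20, size=300))
        out = se.subtract_background(make_trace(tr), ball_radius=30)
        assert out.intensities.min() >= 0

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            se.subtract_background(make_trace(np.zeros(100)), ball_radius=100)


class TestDetectBands:
    def test_relative_height_cutoff(self):
        # heights (100, 50, 1): the 1 is below 2% of 100 and must be dropped
        tr = se.simulate_lane_trace(
            [(0.2, 100.0), (0.5, 50.0), (0.8, 1.0)], peak_width=0.01, n_points=500
        )
        prof = se.detect_bands(make_trace(tr), min_slope=1.0, min_peak_fraction=0.02)
        assert len(prof.bands) == 2
        assert abs(prof.bands[0].position - 0.2) <= 1 / 499
        assert abs(prof.bands[1].position - 0.5) <= 1 / 499

    def test_all_zero_trace_no_bands(self):
        prof = se.detect_bands(make_trace(np.zeros(100)), min_slope=1.0)
        assert prof.bands == ()

    def test_two_equal_peaks_both_retained(self):
        tr = se.simulate_lane_trace(
            [(0.3, 80.0), (0.7, 80.0)], peak_width=0.01, n_points=1000
        )
        prof = se.detect_bands(make_trace(tr), min_slope=1.0, min_peak_fraction=0.02)
        assert len(prof.bands) == 2
        assert abs(prof.bands[0].position - 0.3) <= 1 / 999
        assert abs(prof.bands[1].position - 0.7) <= 1 / 999

    def test_min_slope_filters_gentle_ramps(self):
        # a very broad bump rises too slowly to clear a steep slope criterion
        tr = se.simulate_lane_trace([(0.5, 100.0)], peak_width=0.2, n_points=500)
        prof = se.detect_bands(make_trace(tr), min_slope=5.0)
        assert prof.bands == ()

    def test_area_positive_and_ordered(self):
        tr = se.simulate_lane_trace(
            [(0.25, 60.0), (0.75, 120.0)], peak_width=0.01, n_points=800
        )
        prof = se.detect_bands(make_trace(tr), min_slope=1.0)
        areas = [b.area for b in prof.bands]
        assert all(a > 0 for a in areas)
        assert areas[1] > areas[0]


def brute_force_classes(positions, tol):
    """Transitive closure of the within-tolerance relation (union-find)."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= tol:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(
        tuple(sorted(g)) for g in groups.values()
    )


class TestMatchBands:
    def test_identical_lanes_full_presence(self):
        prof = BandProfile(
            bands=(Band(0.2, 10.0), Band(0.5, 5.0)), lane_id="a"
        )
        prof2 = BandProfile(
            bands=(Band(0.2, 8.0), Band(0.5, 6.0)), lane_id="b"
        )
        m = se.match_bands([prof, prof2], position_tolerance=0.01)
        assert m.presence.shape == (2, 2)
        assert np.all(m.presence == 1)

    def test_close_positions_merge(self):
        a = BandProfile(bands=(Band(0.40, 1.0),), lane_id="a")
        b = BandProfile(bands=(Band(0.401, 1.0),), lane_id="b")
        m = se.match_bands([a, b], position_tolerance=0.01)
        assert m.presence.shape == (2, 1)

    def test_one_band_per_lane_per_class(self):
        # a lane with two bands inside one class keeps the nearer to centroid
        a = BandProfile(bands=(Band(0.400, 3.0), Band(0.406, 9.0)), lane_id="a")
        b = BandProfile(bands=(Band(0.401, 5.0),), lane_id="b")
        m = se.match_bands([a, b], position_tolerance=0.01)
        assert m.presence.sum(axis=1).tolist() == [1, 1]

    @pytest.mark.parametrize("trial", range(40))
    def test_agrees_with_union_find_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 13))
        tol = float(rng.uniform(0.005, 0.05))
        positions = np.sort(rng.uniform(0, 1, size=n))
        positions = positions[np.concatenate([[True], np.diff(positions) > 1e-6])]
        profiles = [
            BandProfile(bands=(Band(float(p), 1.0),), lane_id=f"l{i}")
            for i, p in enumerate(positions)
        ]
        m = se.match_bands(profiles, position_tolerance=tol)
        oracle = brute_force_classes(list(positions), tol)
        got = sorted(
            tuple(sorted(np.flatnonzero(m.presence[:, c])))
            for c in range(m.presence.shape[1])
        )
        assert got == oracle

    def test_relative_intensity_rows_sum_to_one(self):
        a = BandProfile(bands=(Band(0.1, 2.0), Band(0.6, 6.0)), lane_id="a")
        m = se.match_bands([a], position_tolerance=0.01)
        assert m.relative_intensity.sum(axis=1) == pytest.approx(1.0)


class TestDiversityIndices:
    def test_richness(self):
        assert se.richness(np.array([1, 0, 1, 1])) == 3
        assert se.richness(np.zeros(5)) == 0

    def test_shannon_values(self):
        assert se.shannon(np.array([1.0])) == 0.0
        assert se.shannon(np.full(4, 0.25)) == pytest.approx(math.log(4))
        assert se.shannon(np.array([0.5, 0.3, 0.2])) == pytest.approx(
            1.0296530140645737, rel=1e-12
        )

    def test_shannon_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            se.shannon(np.array([0.5, 0.6]))

    def test_simpson_values(self):
        assert se.simpson(np.array([1.0])) == 1.0
        assert se.simpson(np.array([0.5, 0.5])) == pytest.approx(0.5)
        assert se.simpson(np.array([0.5, 0.3, 0.2])) == pytest.approx(0.38)

    def test_evenness(self):
        assert se.evenness(math.log(5), 5) == pytest.approx(1.0)
        assert se.evenness(0.0, 1) == 1.0
        h = se.shannon(np.array([0.7, 0.3]))
        assert se.evenness(h, 2) == pytest.approx(h / math.log(2))
        with pytest.raises(ValueError):
            se.evenness(0.5, 0)

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=100)
    def test_index_bounds_and_scale_invariance(self, raw):
        x = np.asarray(raw)
        p = x / x.sum()
        r = len(p)
        h = se.shannon(p)
        d = se.simpson(p)
        assert -1e-9 <= h <= math.log(r) + 1e-9
        assert 1 / r - 1e-9 <= d <= 1 + 1e-9
        p2 = (x * 7.3) / (x * 7.3).sum()
        assert se.shannon(p2) == pytest.approx(h, abs=1e-9)

    def test_evening_abundances_moves_h_and_d_oppositely(self):
        skew = np.array([0.7, 0.2, 0.1])
        even = np.array([0.5, 0.3, 0.2])
        assert se.shannon(even) > se.shannon(skew)
        assert se.simpson(even) < se.simpson(skew)


class TestPairwiseMeasures:
    def test_dice_examples(self):
        assert se.dice_similarity(np.array([1, 1]), np.array([1, 1])) == 1.0
        assert se.dice_similarity(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert se.dice_similarity(
            np.array([1, 1, 1, 0]), np.array([0, 1, 1, 1])
        ) == pytest.approx(2 / 3)

    def test_jaccard_examples(self):
        assert se.jaccard_similarity(np.array([1, 1]), np.array([1, 1])) == 1.0
        assert se.jaccard_similarity(np.array([1, 0]), np.array([0, 1])) == 0.0
        assert se.jaccard_similarity(
            np.array([1, 1, 1, 0]), np.array([0, 1, 1, 1])
        ) == pytest.approx(0.5)

    def test_bray_curtis_examples(self):
        assert se.bray_curtis(np.array([2.0, 3.0]), np.array([2.0, 3.0])) == 0.0
        assert se.bray_curtis(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0
        assert se.bray_curtis(
            np.array([2.0, 3.0, 5.0]), np.array([1.0, 3.0, 4.0])
        ) == pytest.approx(1 / 9)
        with pytest.raises(ValueError):
            se.bray_curtis(np.zeros(3), np.zeros(3))

    def test_empty_rows_convention(self):
        assert se.dice_similarity(np.zeros(4), np.zeros(4)) == 1.0
        assert se.jaccard_similarity(np.zeros(4), np.zeros(4)) == 1.0

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_scipy(self, trial):
        rng = np.random.default_rng(2000 + trial)
        a = rng.integers(0, 2, size=12).astype(float)
        b = rng.integers(0, 2, size=12).astype(float)
        if a.sum() == 0 or b.sum() == 0:
            return
        assert se.dice_similarity(a, b) == pytest.approx(
            1 - ssd.dice(a.astype(bool), b.astype(bool))
        )
        assert se.jaccard_similarity(a, b) == pytest.approx(
            1 - ssd.jaccard(a.astype(bool), b.astype(bool))
        )
        x = rng.uniform(0, 5, size=12)
        y = rng.uniform(0, 5, size=12)
        assert se.bray_curtis(x, y) == pytest.approx(ssd.braycurtis(x, y))

    @given(
        st.lists(st.booleans(), min_size=1, max_size=15),
        st.lists(st.booleans(), min_size=1, max_size=15),
    )
    @settings(deadline=None, max_examples=100)
    def test_dice_jaccard_identity(self, la, lb):
        n = max(len(la), len(lb))
        a = np.array(la + [False] * (n - len(la)), dtype=float)
        b = np.array(lb + [False] * (n - len(lb)), dtype=float)
        dice = se.dice_similarity(a, b)
        jac = se.jaccard_similarity(a, b)
        assert dice == pytest.approx(2 * jac / (1 + jac), abs=1e-12)
        assert dice >= jac - 1e-12
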