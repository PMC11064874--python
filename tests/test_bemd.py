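"""BEMD: extrema detection vs brute force, envelope accuracy, sifting, completeness."""

import numpy as np
import pytest

from tfdenoise import (
    InsufficientExtremaError,
    SiftConfig,
    decompose,
    find_extrema,
    sift_once,
)
from tfdenoise.bemd import build_envelope


def brute_force_extrema(plane, connectivity):
    """All-neighbours scan; assumes no ties (continuous random values)."""
    rows, cols = plane.shape
    if connectivity == 8:
        offsets = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    maxima, minima = [], []
    for r in range(rows):
        for c in range(cols):
            nbrs = [
                plane[r + a, c + b]
                for a, b in offsets
                if 0 <= r + a < rows and 0 <= c + b < cols
            ]
            if all(plane[r, c] > v for v in nbrs):
                maxima.append((r, c, float(plane[r, c])))
            if all(plane[r, c] < v for v in nbrs):
                minima.append((r, c, float(plane[r, c])))
    return maxima, minima


def two_component_plane(n=64):
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    fast = np.sin(2 * np.pi * 6 * r / n) * np.sin(2 * np.pi * 6 * c / n)
    slow = 2.0 * np.exp(-(((r - n / 2) ** 2 + (c - n / 2) ** 2) / (2 * (n / 4) ** 2)))
    return fast, slow


class TestFindExtrema:
    def test_single_gaussian_bump(self):
        r, c = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
        plane = np.exp(-(((r - 5) ** 2 + (c - 5) ** 2)) / 8.0)
        maxima, minima = find_extrema(plane)
        assert [(m[0], m[1]) for m in maxima] == [(5, 5)]
        assert all(r_ in (0, 10) or c_ in (0, 10) for r_, c_, _ in minima)

    def test_constant_plane_has_no_extrema(self):
        maxima, minima = find_extrema(np.ones((8, 8)))
        assert maxima == [] and minima == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_on_random_plane(self, connectivity, rng):
        plane = rng.standard_normal((16, 16))
        got_max, got_min = find_extrema(plane, connectivity)
        exp_max, exp_min = brute_force_extrema(plane, connectivity)
        assert sorted(got_max) == sorted(exp_max)
        assert sorted(got_min) == sorted(exp_min)

    def test_plateau_reduces_to_centroid_pixel(self):
        plane = np.zeros((9, 9))
        plane[4:6, 4:6] = 1.0  # 2x2 plateau
        maxima, _ = find_extrema(plane)
        assert len(maxima) == 1
        assert maxima[0][:2] in [(4, 4), (4, 5), (5, 4), (5, 5)]


class TestBuildEnvelope:
    def test_reproduces_linear_surface(self, rng):
        shape = (15, 15)
        pts = [(0, 0), (0, 14), (14, 0), (14, 14)]
        pts += [tuple(p) for p in rng.integers(1, 14, size=(6, 2))]
        points = [(r, c, 2.0 * r + 3.0 * c + 1.0) for r, c in pts]
        surf = build_envelope(points, shape)
        rr, cc = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        assert np.abs(surf - (2.0 * rr + 3.0 * cc + 1.0)).max() < 1e-6

    def test_too_few_points(self):
        points = [(0, 0, 1.0), (3, 3, 2.0), (5, 1, 0.5)]
        with pytest.raises(InsufficientExtremaError):
            build_envelope(points, (8, 8))

    def test_collinear_points_are_degenerate(self):
        points = [(i, i, float(i)) for i in range(6)]
        with pytest.raises(InsufficientExtremaError):
            build_envelope(points, (8, 8))

    def test_quadratic_bowl_accuracy(self, rng):
        shape = (12, 12)
        bowl = lambda r, c: 0.05 * ((r - 5.5) ** 2 + (c - 5.5) ** 2)
        lattice = [(r, c) for r in (0, 2, 5, 8, 11) for c in (0, 2, 5, 8, 11)]
        pts = lattice + [tuple(p) for p in rng.integers(0, 12, size=(8, 2))]
        points = [(r, c, bowl(r, c)) for r, c in dict.fromkeys(pts)]
        surf = build_envelope(points, shape)
        rr, cc = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        truth = bowl(rr, cc)
        assert np.abs(surf - truth).max() < 0.05 * (truth.max() - truth.min())


class TestSiftOnce:
    def test_symmetric_checkerboard_is_fixed_point(self):
        # under 4-connectivity every +1 is a maximum and every -1 a minimum,
        # so the two envelopes are symmetric about zero
        r, c = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        plane = ((-1.0) ** (r + c)).astype(float)
        out = sift_once(plane, SiftConfig(extrema_connectivity=4))
        assert np.abs(out - plane).max() < 1e-6

    def test_removes_constant_offset_from_checkerboard(self):
        r, c = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        checker = ((-1.0) ** (r + c)).astype(float)
        out = sift_once(checker + 3.25, SiftConfig(extrema_connectivity=4))
        assert np.abs(out - checker).max() < 1e-6

    def test_monotone_ramp_has_no_extrema_to_sift(self):
        r, c = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        with pytest.raises(InsufficientExtremaError):
            sift_once((2.0 * r + c).astype(float))


class TestDecompose:
    def test_monotone_ramp_yields_empty_decomposition(self):
        r, c = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        plane = (2.0 * r + c).astype(float)
        out = decompose(plane)
        assert out.bimfs == ()
        assert np.array_equal(out.residue, plane)

    @pytest.mark.parametrize("method", ["spline", "orderstat"])
    def test_completeness_is_exact(self, method, rng):
        plane = rng.standard_normal((32, 32))
        out = decompose(plane, SiftConfig(envelope_method=method))
        assert np.abs(out.reconstruct() - plane).max() < 1e-10

    def test_two_component_separation(self):
        fast, slow = two_component_plane()
        out = decompose(fast + slow)
        assert len(out.bimfs) >= 1
        corr = np.corrcoef(out.bimfs[0].ravel(), fast.ravel())[0, 1]
        assert corr > 0.9
        rest = out.reconstruct() - out.bimfs[0]
        assert np.corrcoef(rest.ravel(), slow.ravel())[0, 1] > 0.9

    def test_scale_ordering_extrema_density(self):
        fast, slow = two_component_plane()
        out = decompose(fast + slow)
        densities = []
        for b in out.bimfs:
            maxima, minima = find_extrema(b)
            densities.append((len(maxima) + len(minima)) / b.size)
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(densities, densities[1:]))

    def test_deterministic(self, rng):
        plane = rng.standard_normal((24, 24))
        a = decompose(plane)
        b = decompose(plane)
        assert all(np.array_equal(x, y) for x, y in zip(a.bimfs, b.bimfs))
        assert np.array_equal(a.residue, b.residue)

    def test_sift_counts_respect_cap(self, rng):
        plane = rng.standard_normal((32, 32))
        config = SiftConfig(max_sift_iters=3)
        out = decompose(plane, config)
        assert out.n_sifts and all(1 <= s <= 3 for s in out.n_sifts)

    def test_max_bimfs_zero_disables_decomposition(self, rng):
        plane = rng.standard_normal((16, 16))
        out = decompose(plane, SiftConfig(max_bimfs=0))
        assert out.bimfs == () and np.array_equal(out.residue, plane)
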