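import numpy as np
import pytest

from halfscsa.conv_half import (
    DegeneratePointError,
    DifferenceHistogram,
    PhaseHistogram,
    convolve_difference,
    fold_to_intersection,
    ideal_reference,
    phase_angle,
    phase_histogram,
)


def brute_force_difference(f1, f2):
    """Independent oracle: explicit double loop over all phase-bin pairs."""
    n = len(f1)
    out = np.zeros(2 * n - 1)
    for e1 in range(n):
        for e2 in range(n):
            out[(e1 - e2) + n - 1] += f1[e1] * f2[e2]
    return out


def brute_force_fold(fu_counts):
    """Independent oracle: fold each signed bin through w = |u|, z = min(w, n-w)."""
    n = (len(fu_counts) + 1) // 2
    half = n // 2
    fz = np.zeros(half + 1)
    for k, c in enumerate(fu_counts):
        u = k - (n - 1)
        w = abs(u)
        z = w if w < half else n - w
        fz[z] += c
    out = fz[:half].copy()
    out[-1] += fz[half]
    return out


class TestPhaseAngle:
    @pytest.mark.parametrize(
        "p,expected", [((0, 1, 0), 90.0), ((-1, 0, 0), 180.0), ((0, -2, 0), 270.0)]
    )
    def test_examples(self, p, expected):
        got = phase_angle(p, (0, 0, 0), (0, 0, 1), (1, 0, 0))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_axis_must_be_in_plane(self):
        with pytest.raises(ValueError, match="perpendicular"):
            phase_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), (0, 0.2, 1))

    def test_degenerate_point(self):
        with pytest.raises(DegeneratePointError):
            phase_angle((0, 0, 5), (0, 0, 0), (0, 0, 1), (1, 0, 0))


class TestPhaseHistogram:
    def test_two_points(self):
        pts = [
            [np.cos(np.radians(10.5)), np.sin(np.radians(10.5)), 0],
            [np.cos(np.radians(190.5)), np.sin(np.radians(190.5)), 0],
        ]
        ph = phase_histogram(pts, (0, 0, 0), (0, 0, 1), (1, 0, 0))
        assert ph.counts[10] == 1 and ph.counts[190] == 1 and ph.total == 2

    def test_uniform_ring(self):
        ang = np.radians(np.arange(360) + 0.5)
        pts = np.c_[np.cos(ang), np.sin(ang), np.zeros(360)]
        ph = phase_histogram(pts, (0, 0, 0), (0, 0, 1), (1, 0, 0))
        np.testing.assert_array_equal(ph.counts, np.ones(360))

    def test_all_degenerate_errors(self):
        with pytest.raises(DegeneratePointError):
            phase_histogram([[0, 0, 1]], (0, 0, 0), (0, 0, 1), (1, 0, 0))


class TestConvolution:
    def test_single_spike_product(self):
        f1 = np.zeros(360)
        f1[340] = 2
        f2 = np.zeros(360)
        f2[0] = 3
        fu = convolve_difference(PhaseHistogram(f1), PhaseHistogram(f2))
        assert fu.at(340) == 6
        assert fu.total == 6

    def test_resolution_mismatch(self):
        with pytest.raises(ValueError, match="resolution"):
            convolve_difference(PhaseHistogram(np.ones(360)), PhaseHistogram(np.ones(180)))

    def test_matches_brute_force(self, rng):
        f1 = rng.integers(0, 5, size=24).astype(float)
        f2 = rng.integers(0, 5, size=24).astype(float)
        fu = convolve_difference(PhaseHistogram(f1), PhaseHistogram(f2))
        np.testing.assert_array_equal(fu.counts, brute_force_difference(f1, f2))

    def test_self_convolution_symmetry(self, rng):
        f = rng.integers(0, 7, size=360).astype(float)
        fu = convolve_difference(PhaseHistogram(f), PhaseHistogram(f))
        np.testing.assert_array_equal(fu.counts, fu.counts[::-1])


class TestFold:
    def test_absolute_value_rule(self):
        # only fu(+-200) populated: folds through w=200 to z=160
        fu = np.zeros(719)
        fu[359 + 200] = 5.0
        fu[359 - 200] = 2.0
        h = fold_to_intersection(DifferenceHistogram(fu))
        assert h.counts[160] == 7.0
        assert h.total == 7.0

    def test_wraparound_rule(self):
        # fw(42) and fw(318) both land in intersection bin 42
        fu = np.zeros(719)
        fu[359 + 42] = 3.0
        fu[359 + 318] = 4.0
        h = fold_to_intersection(DifferenceHistogram(fu))
        assert h.counts[42] == 7.0

    def test_matches_brute_force_fold(self, rng):
        fu_counts = rng.integers(0, 9, size=719).astype(float)
        h = fold_to_intersection(DifferenceHistogram(fu_counts))
        np.testing.assert_array_equal(h.counts, brute_force_fold(fu_counts))

    def test_chain_conservation(self, rng):
        f1 = rng.integers(0, 6, size=360).astype(float)
        f2 = rng.integers(0, 6, size=360).astype(float)
        fu = convolve_difference(PhaseHistogram(f1), PhaseHistogram(f2))
        h = fold_to_intersection(fu)
        assert h.total == fu.total == f1.sum() * f2.sum()


class TestIdealReferences:
    def test_leaf_uniform(self):
        h = ideal_reference("leaf")
        interior = h.counts[1:-1]
        assert np.allclose(interior, interior[0])
        # endpoint halving of the discrete fold: first bin carries half an
        # interior bin, last bin (merged with the 180-degree point) 1.5x
        assert h.counts[0] == pytest.approx(interior[0] / 2)
        assert h.counts[-1] == pytest.approx(1.5 * interior[0])
        assert 0.5 * np.abs(h.counts - 1.0 / 180).sum() < 0.01

    def test_stem_bimodal(self):
        h = ideal_reference("stem")
        assert set(np.nonzero(h.counts)[0]) == {0, 179}
        assert h.counts[0] == h.counts[179] == pytest.approx(0.5)

    def test_knot_peaks_at_pairwise_differences(self):
        # directions {0, 180, 70}: enumerate unordered direction pairs ->
        # differences {0 (self), 180, 70, 110}; equal weights give masses
        # 3/9 at 0 and 2/9 at each cross difference
        h = ideal_reference("knot", directions_deg=(0.0, 180.0, 70.0))
        nz = set(np.nonzero(h.counts)[0])
        assert nz == {0, 70, 110, 179}
        assert h.counts[0] == pytest.approx(3 / 9)
        for b in (70, 110, 179):
            assert h.counts[b] == pytest.approx(2 / 9)

    def test_knot_needs_three_directions(self):
        with pytest.raises(ValueError, match="3"):
            ideal_reference("knot", directions_deg=(0.0, 180.0))

    def test_normalized(self):
        for cls in ("leaf", "stem", "knot"):
            assert ideal_reference(cls).total == pytest.approx(1.0)
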