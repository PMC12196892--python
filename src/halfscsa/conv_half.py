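"""Convolution-based construction of ideal HALF profiles.

For zero-thickness geometry (organs idealized as planes and lines through
the interest point), every shell point has a well-defined phase angle
``eta`` in the supporting plane, and the intersection angle of a pair is a
folded difference of two independent phase angles:

    u = eta1 - eta2            (signed difference, -360 < u < 360)
    w = |u|                    (0 <= w < 360)
    z = w        if w < 180
        360 - w  if w >= 180   (intersection angle, 0 <= z <= 180)

The distribution of ``u`` is therefore the cross-correlation of the two
phase histograms, and the HALF follows by folding. This module implements
the chain at 1°-integer resolution and uses it to build the ideal class
references: a plane gives a uniform HALF, a line gives a bimodal HALF at
0°/180°, and a junction of k >= 3 branch directions gives one peak per
distinct pairwise direction difference.

The chain is exact only for zero-thickness geometry; real organs with
finite diameter progressively blur the line/junction peaks (see the
thickness sweep in :mod:`halfscsa.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classes import KNOT, LEAF, NAME_TO_CLASS, STEM
from .half_core import HalfHistogram

__all__ = [
    "PhaseHistogram",
    "DifferenceHistogram",
    "DegeneratePointError",
    "phase_angle",
    "phase_histogram",
    "convolve_difference",
    "fold_to_intersection",
    "ideal_reference",
]


class DegeneratePointError(ValueError):
    """Point projects to (numerically) zero length in the phase plane."""


@dataclass
class PhaseHistogram:
    """Counts over ``n_bins`` equal bins partitioning [0°, 360°)."""

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("counts must be a 1-d array of >= 2 bins")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class DifferenceHistogram:
    """Counts of the signed phase difference ``u`` in bin units.

    For phase histograms with ``n`` bins, ``u`` ranges over
    ``-(n-1) .. n-1``; ``counts[k]`` holds the frequency of
    ``u = k - (n - 1)``.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1 or len(self.counts) % 2 != 1:
            raise ValueError("counts must be a 1-d array of odd length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_phase_bins(self) -> int:
        return (len(self.counts) + 1) // 2

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def at(self, u: int) -> float:
        """Frequency of the signed difference ``u`` (in bin units)."""
        n = self.n_phase_bins
        if not (-(n - 1) <= u <= n - 1):
            return 0.0
        return float(self.counts[u + n - 1])


def phase_angle(p, origin, plane_normal, axis) -> float:
    """Phase angle in degrees [0, 360) of ``p`` about ``origin``.

    The angle of the projection of ``p - origin`` onto the plane with unit
    normal ``plane_normal``, measured counter-clockwise (about the normal)
    from the in-plane unit vector ``axis``.
    """
    n = np.asarray(plane_normal, dtype=np.float64)
    a = np.asarray(axis, dtype=np.float64)
    n = n / np.linalg.norm(n)
    a = a / np.linalg.norm(a)
    if abs(np.dot(n, a)) > 1e-9:
        raise ValueError("axis must be perpendicular to plane_normal")
    d = np.asarray(p, dtype=np.float64) - np.asarray(origin, dtype=np.float64)
    v = d - np.dot(d, n) * n
    if np.linalg.norm(v) <= 1e-12 * (1.0 + np.linalg.norm(d)):
        raise DegeneratePointError("point projects to zero length in the plane")
    b = np.cross(n, a)  # completes the right-handed in-plane basis
    eta = np.degrees(np.arctan2(np.dot(v, b), np.dot(v, a)))
    return float(eta % 360.0)


def phase_histogram(points, origin, plane_normal, axis, n_bins: int = 360) -> PhaseHistogram:
    """Histogram of :func:`phase_angle` over ``points``.

    Degenerate points (zero in-plane projection) are skipped and counted
    in ``n_skipped``; if every point is degenerate a
    :class:`DegeneratePointError` is raised.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.size == 0:
        raise DegeneratePointError("no points supplied")
    counts = np.zeros(n_bins)
    skipped = 0
    width = 360.0 / n_bins
    for p in points:
        try:
            eta = phase_angle(p, origin, plane_normal, axis)
        except DegeneratePointError:
            skipped += 1
            continue
        counts[min(int(eta / width), n_bins - 1)] += 1
    if counts.sum() == 0:
        raise DegeneratePointError("all points degenerate in the phase plane")
    return PhaseHistogram(counts, n_skipped=skipped)


def convolve_difference(f1: PhaseHistogram, f2: PhaseHistogram) -> DifferenceHistogram:
    """Distribution of the signed difference ``u = eta1 - eta2``.

    ``fu(u) = sum_eta1 f1(eta1) * f2(eta1 - u)`` over all ``eta1`` for which
    ``eta1 - u`` lies in [0, 360). Total mass is ``total(f1) * total(f2)``.
    """
    if f1.n_bins != f2.n_bins:
        raise ValueError(
            f"phase histograms have different resolutions: {f1.n_bins} vs {f2.n_bins}"
        )
    # correlate: out[k] = sum_m f1[m] * f2[m - (k - (n-1))]
    fu = np.correlate(f1.counts, f2.counts, mode="full")
    return DifferenceHistogram(fu)


def fold_to_intersection(fu: DifferenceHistogram) -> HalfHistogram:
    """Fold the signed difference distribution to intersection angles.

    First ``w = |u|``: ``fw(w) = fu(w) + fu(-w)`` for ``w > 0`` and
    ``fw(0) = fu(0)``; then ``z``: ``fz(z) = fw(z) + fw(360 - z)`` for
    ``0 < z < 180`` with ``fz(0) = fw(0)`` and ``fz(180) = fw(180)``
    (the piecewise map sends only ``w = 0`` to 0 and only ``w = 180`` to
    180). The endpoint ``z = 180`` is merged into the final half-open bin
    so the result shares the sampled-histogram binning over [0°, 180°].
    """
    n = fu.n_phase_bins
    if n % 2 != 0:
        raise ValueError("phase bin count must be even to fold at 180 degrees")
    half = n // 2
    center = n - 1
    fw = np.zeros(n)
    fw[0] = fu.counts[center]
    for w in range(1, n):
        fw[w] = fu.counts[center + w] + fu.counts[center - w]
    fz = np.zeros(half + 1)
    fz[0] = fw[0]
    fz[half] = fw[half]
    for z in range(1, half):
        fz[z] = fw[z] + fw[n - z]
    merged = fz[:half].copy()
    merged[half - 1] += fz[half]
    return HalfHistogram(merged)


def _self_half(phase_counts: np.ndarray) -> HalfHistogram:
    ph = PhaseHistogram(phase_counts)
    return fold_to_intersection(convolve_difference(ph, ph))


def ideal_reference(
    class_label,
    n_bins: int = 360,
    directions_deg=None,
    weights=None,
) -> HalfHistogram:
    """Ideal (zero-thickness) class HALF by phase self-convolution.

    Parameters
    ----------
    class_label
        ``"leaf"``, ``"stem"``, ``"knot"`` or the corresponding class code.
    n_bins
        Phase resolution (default 360 one-degree bins); the returned HALF
        has ``n_bins // 2`` bins over [0°, 180°].
    directions_deg
        Branch directions for the stem/knot phase support. Stem defaults
        to (0, 180); knot defaults to (0, 180, 70), the three in-plane
        directions of a vertical stem with a branch inclined 70° from the
        axis. A knot with fewer than 3 directions is rejected (that is a
        stem).
    weights
        Optional per-direction masses (default equal).

    Returns a HALF normalized to unit sum. The leaf reference is uniform
    (up to the discrete half-mass endpoints of the fold), the stem
    reference is bimodal at 0°/180°, and the knot reference has one peak
    per distinct pairwise difference of its directions.
    """
    if isinstance(class_label, str):
        code = NAME_TO_CLASS.get(class_label.lower())
        if code is None:
            raise ValueError(f"unknown class {class_label!r}")
    else:
        code = int(class_label)
    if n_bins % 2 != 0:
        raise ValueError("n_bins must be even")
    width = 360.0 / n_bins

    if code == LEAF:
        phase = np.ones(n_bins)
    elif code in (STEM, KNOT):
        if directions_deg is None:
            directions_deg = (0.0, 180.0) if code == STEM else (0.0, 180.0, 70.0)
        directions_deg = tuple(float(d) % 360.0 for d in directions_deg)
        if code == KNOT and len(directions_deg) < 3:
            raise ValueError("a knot needs >= 3 branch directions (2 is a stem)")
        if weights is None:
            weights = np.ones(len(directions_deg))
        weights = np.asarray(weights, dtype=np.float64)
        if len(weights) != len(directions_deg):
            raise ValueError("weights must match directions")
        phase = np.zeros(n_bins)
        for d, wt in zip(directions_deg, weights):
            phase[min(int(d / width), n_bins - 1)] += wt
    else:
        raise ValueError(f"no ideal reference for class code {code}")

    h = _self_half(phase)
    return HalfHistogram(h.counts / h.counts.sum())
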