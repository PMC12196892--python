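"""Histogram-intersection similarity, max-similarity classification, and
reference-HALF construction/optimization.

Similarity between two normalized histograms f, g is the intersection

    zeta = sum_i min(f_i, g_i)   in [0, 1],

and a query HALF is assigned to the class whose reference maximizes zeta.
Both operands are normalized to unit sum first, which makes the fixed
seed-quality threshold used downstream (zeta > 0.85) scale-free.

References come in two flavours:

* *initial* references, built from the zero-thickness convolution ideals
  (:func:`halfscsa.conv_half.ideal_reference`) and smoothed by a few
  degrees. Raw ideals for stem/knot have near-measure-zero support (the
  stem ideal occupies two bins out of 180) and real finite-diameter
  organs place almost no mass exactly there, so a small angular blur —
  about atan(stem radius / mean arm length) — is applied to make the
  ideals commensurate with measured HALFs.
* *optimum* references, detected from a measured HALF field: for each
  class the measured histogram maximizing the margin
  ``zeta(h, init_c) - max_{c' != c} zeta(h, init_c')`` is selected, then
  lightly smoothed to suppress pair-sampling noise. This adapts the
  references to the actual organ thicknesses and point density of the
  plant at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .classes import CLASS_NAMES, KNOT, LEAF, ORGAN_CLASSES, STEM, TIE_ORDER
from .conv_half import ideal_reference
from .half_core import HalfHistogram

__all__ = [
    "ReferenceSet",
    "normalize",
    "intersection",
    "classify",
    "initial_references",
    "optimize_references",
    "smooth_histogram",
]


def _counts(h) -> np.ndarray:
    if isinstance(h, HalfHistogram):
        return h.counts
    return np.asarray(h, dtype=np.float64)


def normalize(h) -> HalfHistogram:
    """Return ``h`` scaled to unit sum; a zero-total histogram is an error."""
    c = _counts(h)
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot normalize a zero-total histogram")
    return HalfHistogram(c / total)


def intersection(h, g) -> float:
    """Histogram intersection ``sum_i min(f_i, g_i)``.

    For normalized inputs the value lies in [0, 1] and equals 1 iff the
    histograms coincide.
    """
    f = _counts(h)
    g = _counts(g)
    if f.shape != g.shape:
        raise ValueError(f"bin-count mismatch: {f.shape} vs {g.shape}")
    return float(np.minimum(f, g).sum())


def smooth_histogram(h, sigma_deg: float, domain_deg: float = 180.0) -> HalfHistogram:
    """Gaussian angular smoothing with reflection at the domain endpoints.

    Reflection is the correct boundary for the folded intersection-angle
    domain [0°, 180°]: mass near 0° and 180° mirrors back rather than
    wrapping. The result is renormalized to the input total.
    """
    c = _counts(h)
    if sigma_deg <= 0:
        return HalfHistogram(c.copy())
    width = domain_deg / len(c)
    out = gaussian_filter1d(c, sigma_deg / width, mode="reflect")
    total = c.sum()
    if out.sum() > 0:
        out = out * (total / out.sum())
    return HalfHistogram(out)


@dataclass
class ReferenceSet:
    """One normalized reference HALF per class (leaf, stem, knot).

    ``provenance`` is ``"initial"`` (convolution-based) or ``"optimum"``
    (detected from a measured field). ``warnings`` lists classes for which
    optimization fell back to the initial reference.
    """

    leaf: np.ndarray
    stem: np.ndarray
    knot: np.ndarray
    provenance: str = "initial"
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.leaf = _counts(self.leaf)
        self.stem = _counts(self.stem)
        self.knot = _counts(self.knot)
        nb = {len(self.leaf), len(self.stem), len(self.knot)}
        if len(nb) != 1:
            raise ValueError("all references must share one bin count")
        for name, arr in self.items():
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} reference is not normalized")

    def items(self):
        return (("leaf", self.leaf), ("stem", self.stem), ("knot", self.knot))

    def __getitem__(self, class_code: int) -> np.ndarray:
        return {LEAF: self.leaf, STEM: self.stem, KNOT: self.knot}[class_code]

    @property
    def n_bins(self) -> int:
        return len(self.leaf)

    def to_frame(self) -> pd.DataFrame:
        """One row per bin, one column per class."""
        return pd.DataFrame({name: arr for name, arr in self.items()})

    def save_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, provenance: str = "initial") -> "ReferenceSet":
        df = pd.read_csv(path)
        return cls(
            leaf=df["leaf"].to_numpy(),
            stem=df["stem"].to_numpy(),
            knot=df["knot"].to_numpy(),
            provenance=provenance,
        )


def classify(h, refs: ReferenceSet):
    """Assign ``h`` to the class with maximal intersection similarity.

    Returns ``(class_code, zeta_best, zetas)`` where ``zetas`` maps every
    class code to its similarity. The query is normalized first, so the
    decision is invariant to positive rescaling. Exact ties resolve to
    the earlier class in the fixed order knot < stem < leaf.
    """
    q = normalize(h).counts
    zetas = {c: intersection(q, refs[c]) for c in ORGAN_CLASSES}
    best = None
    for c in TIE_ORDER:
        if best is None or zetas[c] > zetas[best]:
            best = c
    return best, zetas[best], zetas


def initial_references(
    n_bins: int = 180,
    knot_directions=(0.0, 180.0, 70.0),
    smooth_sigma_deg: float = 5.0,
) -> ReferenceSet:
    """Initial references from the convolution ideals, angularly smoothed.

    ``smooth_sigma_deg`` defaults to 5° ~ atan(1 mm / 11 mm): the angular
    dispersion a millimetre-scale organ radius induces over the default
    5-20 mm sampling shell. Set it to 0 for the raw ideals.
    """
    refs = {}
    for code, name in ((LEAF, "leaf"), (STEM, "stem"), (KNOT, "knot")):
        dirs = knot_directions if code == KNOT else None
        ideal = ideal_reference(code, n_bins=2 * n_bins, directions_deg=dirs)
        refs[name] = normalize(smooth_histogram(ideal, smooth_sigma_deg)).counts
    return ReferenceSet(provenance="initial", **refs)


def optimize_references(
    half_field,
    initial: ReferenceSet,
    smooth_sigma_deg: float = 2.0,
) -> ReferenceSet:
    """Detect optimum references from a measured HALF field.

    For each class c the measured histogram maximizing the margin
    ``zeta(h, initial_c) - max_{c' != c} zeta(h, initial_c')`` is selected
    and normalized. If no histogram has a positive margin for some class,
    that class falls back to its initial reference and is listed in
    ``warnings``. The selected histograms are smoothed by
    ``smooth_sigma_deg`` (default 2°) to suppress pair-sampling noise.
    """
    hists = [normalize(h).counts for h in half_field if h is not None and _counts(h).sum() > 0]
    if not hists:
        raise ValueError("half_field holds no usable histograms")
    zeta = np.array(
        [[intersection(q, initial[c]) for c in ORGAN_CLASSES] for q in hists]
    )
    out = {}
    warns = []
    for k, code in enumerate(ORGAN_CLASSES):
        others = [j for j in range(len(ORGAN_CLASSES)) if j != k]
        margins = zeta[:, k] - zeta[:, others].max(axis=1)
        best = int(np.argmax(margins))
        name = CLASS_NAMES[code]
        if margins[best] > 0:
            out[name] = normalize(smooth_histogram(hists[best], smooth_sigma_deg)).counts
        else:
            out[name] = initial[code].copy()
            warns.append(name)
    return ReferenceSet(provenance="optimum", warnings=tuple(warns), **out)
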