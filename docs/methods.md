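# Methods

## The descriptor

At an interest point `p0`, HALF (Histogram of Angles in Linked Features)
samples `N` point pairs `(p1, p2)` from the spherical shell
`r_min <= ||p - p0|| <= r_max` (both boundaries closed) and histograms the
intersection angle

    theta = arccos( d1·d2 ),   d_k = (p_k - p0)/||p_k - p0||,

over 180 one-degree bins covering [0°, 180°] (half-open bins, final bin
closed). Pairs are drawn uniformly with replacement over unordered
distinct index pairs — theta is symmetric in `p1, p2`, so ordered and
unordered sampling give the same distribution. Pairs with coincident
coordinates are skipped, not resampled, so the histogram total equals the
number of non-degenerate draws. The descriptor is invariant under rigid
motions (it depends only on pairwise angles) and covariant under joint
rescaling of coordinates and shell radii.

Shell radii default to 5 and 20 mm, matched to soybean-scale organs: the
inner radius suppresses the near field where measurement noise dominates
the direction of short difference vectors (coordinate noise of variance
sigma0² doubles in a difference vector), and the outer radius keeps the
shell mostly inside a single organ.

**Pairs per point.** `n_pairs` defaults to 10000. The choice is driven by
the intersection similarity used downstream: for a near-uniform (leaf-like)
angle distribution over 180 bins, two independent N-sample histograms
intersect at about `1 - 0.5·Σ E|f̂1_i - f̂2_i| ≈ 1 - 9.6/sqrt(N)`, i.e.
~0.83 at N = 2000 but ~0.92 at N = 10000. Since seed selection requires
similarity above 0.85, N must be large enough that sampling noise alone
cannot disqualify a true-class point; 10000 leaves ~0.07 of margin for
leaves (peaked stem/knot histograms have far less multinomial noise).

**Randomness.** One root seed; every interest point derives its own
stream from `(seed, point_index)`, so a batch over a cloud is
reproducible and independent of evaluation order.

## Convolution construction of ideal references

For zero-thickness geometry — organs idealized as planes and lines through
`p0` — every shell point has a phase angle `eta` in the supporting plane,
and the intersection angle of a pair is a folded difference of two
independent phase angles: `u = eta1 - eta2`, `w = |u|`, then `z = w` for
`w < 180` and `360 - w` otherwise. The distribution of `u` is the
cross-correlation of the two phase histograms; the HALF follows by the
two folds. The chain is implemented at 1° integer resolution, conserving
total mass (`Σfu = Σfw = Σfz = total(f1)·total(f2)`) bin-exactly.

Endpoint conventions follow the piecewise map literally: `z = 0` is
reachable only through `w = 0` and `z = 180` only through `w = 180`, so
those bins take single terms. The discrete fold of a uniform phase
histogram is therefore uniform on the interior with half-mass endpoints.
The `z = 180` value is merged into the final half-open bin `[179°, 180°]`
so the convolution chain and the sampled histogram share one binning;
this costs ~1/360 in total variation and is invisible at the 0.05
tolerance used for sampled-vs-ideal comparisons.

Class ideals by self-convolution of the class phase support:

* **leaf** — continuous uniform phase → uniform HALF;
* **stem** — two opposite directions (0°, 180°) → bimodal HALF with mass
  0.5 at each of the 0° and 180° bins;
* **knot** — k ≥ 3 branch directions → one peak per distinct pairwise
  direction difference. The default `(0°, 180°, 70°)` — a vertical stem
  with a branch inclined 70° from the axis — gives peaks at
  {0°, 70°, 110°, 180°} with masses {1/3, 2/9, 2/9, 2/9}.

The printed form of the phase-angle formula in the source literature is
typographically corrupted; the implementation uses the two-argument
arctangent of the in-plane components, which reproduces every stated
numeric consequence.

## Similarity, classification, and reference adaptation

Similarity is the histogram intersection `zeta = Σ_i min(f_i, g_i)` of
unit-normalized histograms, in [0, 1]; classification takes the class of
maximal zeta, with exact ties resolved to the rarest class first
(knot < stem < leaf). Normalizing both operands makes the fixed
seed-quality threshold (`zeta > 0.85`) scale-free.

**Initial references** are the convolution ideals smoothed by a 5°
Gaussian with reflection at 0°/180°. The raw stem ideal occupies two bins
out of 180; a real stem of diameter d spreads its peaks by roughly
`atan(d / arm length)` — ~5° for d = 2 mm over the 5–20 mm shell — so an
unsmoothed ideal would intersect a measured thick-stem HALF at nearly
zero (this is precisely the thickness degradation the sweep below
quantifies). 5° ≈ atan(1/11) is the dispersion of a 1 mm organ radius at
the 11 mm mean arm length; it is a fixed modeling constant, not fitted.

**Optimum references** are detected from the measured field: for each
class c, the measured histogram maximizing the margin
`zeta(h, init_c) - max_{c'≠c} zeta(h, init_c')` is selected (falling back
to the initial reference, with a warning, if no margin is positive), then
smoothed by 2° to suppress multinomial sampling noise. This adapts the
references to the actual organ thickness, noise, and density of the
plant at hand, which is what lets thick (≥1 mm) stems be recognized at
all.

## SCSA — sequential competitive segmentation

**Candidate seed points (CSPs).** Per class: points whose max-similarity
winner is that class with `zeta > 0.85`, thinned greedily in
descending-zeta order to pairwise spacing ≥ 24 mm within the class.

**Bubble growth (BSA).** A growth center labels every unlabeled point
within `r = 5 mm` with its class; among the newly labeled points,
farthest-first, up to four become next-level centers, skipping any
candidate already inside a sibling's bubble. Farthest-first placement
puts children at the bubble boundary; on dense clouds a nearest-first
child sits ~one point-spacing from its parent, its bubble swallows every
other candidate, and the frontier stalls — boundary children advance it
by about one bubble radius per level, so a cloud is covered in a number
of iterations proportional to its extent over r rather than to its
point count.

Classes alternate level-synchronously: each turn every class expands its
whole current frontier level, so all regions extend at the same
geometric speed regardless of frontier width (a thin stem run and a wide
leaf disk advance equally in millimetres per turn) and boundaries settle
midway between competing seeds. Labels are write-once throughout: no
point is ever relabeled, and points never reached stay unclassified —
which is how isolated outliers are rejected without any explicit outlier
test.

**Phytomer rounds.** Each round selects a connected quadruple — leaf,
upper stem, lower stem, knot — from the CSPs (connectivity = one
component of the r-radius proximity graph; the lower stem must sit below
the knot along the configured vertical axis, and the upper/lower stem
anchors are the nearest qualifying CSPs above/below it). The driving
leaf CSP must be unlabeled; stem and knot anchors prefer unlabeled CSPs
but remain reusable after labeling, since a labeled anchor still blocks
and competes spatially. A round with a live (unlabeled) knot stops when
the knot frontier is encircled or after `ceil((spacing/2)/r)` levels —
CSPs of a class are ≥ 24 mm apart, so territory farther than half that
spacing from a seed belongs to a later round's seed. Revisit rounds
(knot already segmented) run to leaf exhaustion: their boundaries are
already sealed and only interior fill remains. Rounds repeat while an
unlabeled leaf CSP and a quadruple exist, capped by the initial leaf CSP
count.

**Stem rounds.** Afterwards, each remaining stem CSP (best similarity
first, each used once) grows against the nearest connected knot CSP and
stops at stem-frontier exhaustion. These rounds may traverse their own
already-labeled class region without relabeling it, so a stem CSP buried
inside segmented territory can still carry growth to unlabeled runs at
the plant base or apex; other classes' regions remain impassable.

The whole pipeline is deterministic given the HALF field: every queue,
sort, and tie-break is totally ordered (distance, then index).

## Synthetic scenes and what they do (not) cover

`make_plane`, `make_cylinder` (surface points; diameter 0 = ideal line)
and `make_knot_junction` generate the primitive geometries;
`make_plant` assembles a vertical main stem with `n_phytomers` knots at
40 mm internode spacing (plus one internode of apex), each bearing a
25 mm petiole inclined 70° from the axis ending in a flat 30 mm-radius
leaf disk, with 137.5° phyllotaxy. Densities default to 1 point/mm² on
leaves and 15 points/mm on stems — a few thousand points per phytomer
with well-populated sampling shells. Dimensions are soybean-scale and
chosen so the 5–20 mm shell sees pure-class geometry inside organs and
mixed geometry only near knots.

Truth labels come from construction, with the knot class defined by the
same sphere rule used in evaluation: every point within five stem
diameters of a knot center is knot. The petiole is labeled leaf:
botanically the leaf comprises petiole plus blade, and the knot sphere
at the petiole base seals it off from every stem seed, so a stem-labeled
petiole would be unreachable by the algorithm's own construction.

Noise model: isotropic Gaussian coordinate noise (sigma0, default
0.1 mm) and uniform outliers in an inflated bounding box, rejected to
≥ 25 mm (= bubble radius + outer shell radius) from every plant point so
they can neither corrupt plant-point histograms nor be reached by
growth. Truth labels for outliers are "unclassified".

What the generator does **not** emulate: leaf curvature and venation
(the convolution theory assumes planes), self-occlusion and density
falloff of real photogrammetry, stipules, branching side stems, and
organ-size variation along the plant. Passing the synthetic suite
therefore demonstrates the internal consistency of descriptor, theory,
and growth dynamics at realistic scales and noise — not performance on
real reconstructions.

**Thickness sweep.** For each diameter d, a leaf slab of thickness d and
a stem cylinder of diameter d are built, the HALF is computed at their
exact central point (10⁵ pairs), and similarity against the unsmoothed
ideals is recorded. Stems lose similarity rapidly with thickness (their
ideal mass sits in two bins; ~0.02 at d = 2 mm) while leaves stay above
0.95 — the quantitative reason initial references are smoothed and then
adapted to measured data.

## Evaluation conventions

Point-wise per-class precision, recall, and F1. Unclassified predictions
count as false negatives for their true class but enter no precision
denominator (an unreached point weakens recall without polluting
precision). Points whose truth is "unclassified" (outliers) belong to no
organ class; labeling one is a false positive for the predicted class.
Degenerate precision (no predictions for a class) is reported as 0 with
a flag.

## Problem sizes

Defaults are sized for a laptop-class single core: the bundled suites
use plants of ~8–17k points (2–4 phytomers), 10⁴ pairs per point for
fields and 10⁵ pairs for single-point oracle comparisons. The full
synthetic recovery suite (10 plants) runs in about four minutes; the
unit test suite in under a minute.

## Known limitations

* Knot/stem boundaries land where frontiers meet, not exactly on the
  ground-truth sphere; knot F1 (~0.86 on the default suite) trails leaf
  and stem, mirroring the class's intrinsic boundary ambiguity.
* Stem runs farther than one seed spacing from every stem CSP can remain
  unclassified (stem-tip effect).
* The margin-based reference optimization assumes each class has at
  least one cleanly classified region; clouds missing a class fall back
  to initial references with a warning.
* The convolution construction applies to idealized thin geometry only;
  it is used for initial references and oracle tests, never as a
  substitute for measured HALFs.
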