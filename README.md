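# halfscsa

Label-free segmentation of 3D plant point clouds into **leaf**, **stem**,
and **knot** (stem-node) classes at phytomer level, for plant phenotyping
from laser scans, LiDAR, or photogrammetry.

Machine-learning segmenters need labeled training clouds, which are
expensive to produce for ongoing phenotyping databases. This package
implements an alternative that needs none: a local angular-histogram
shape descriptor (**HALF**, Histogram of Angles in Linked Features), a
convolution-based theory that predicts each organ class's ideal
histogram, and a competitive region-growing algorithm (**SCSA**,
Sequential Competitive Segmentation Algorithm) that turns per-point
descriptors into a phytomer-by-phytomer segmentation.

## The method in brief

At an interest point `p0`, sample `N` pairs `(p1, p2)` from the spherical
shell `r_min ≤ ‖p − p0‖ ≤ r_max` (defaults 5–20 mm) and histogram the
intersection angle

    θ = arccos( Δp̃1ᵀ Δp̃2 ),   Δp̃k = (pk − p0)/‖pk − p0‖,

over 180 one-degree bins on [0°, 180°]. Flat organs (leaves) give a
uniform histogram, linear organs (stems) a bimodal one at 0°/180°, and
branched junctions (knots) one peak per pairwise branch-direction
difference — e.g. branches at {0°, 180°, 70°} give peaks at
{0°, 70°, 110°, 180°}. For zero-thickness geometry these profiles follow
exactly from self-convolving the phase-angle histogram (`u = η1 − η2`,
folded through `w = |u|`, `z = min(w, 360 − w)`), which the package uses
to build initial class references.

Classification is by histogram intersection `ζ = Σᵢ min(fᵢ, gᵢ)` against
one normalized reference per class (max-ζ wins). SCSA then segments:
high-confidence, spatially thinned points become candidate seeds; each
round grows a connected leaf/upper-stem/lower-stem/knot seed quadruple by
bubble-based breadth-first expansion (radius 5 mm, four children per
center), classes alternating level-synchronously so regions extend at
equal speed and boundaries settle midway between seeds. Labels are
write-once; points no frontier reaches — isolated outliers — stay
unclassified.

## Worked example

```sh
# simulate a labeled 2-phytomer plant (~8.6k points) and keep the truth
half-scsa simulate plant.ply --seed 3 --n-phytomers 2 \
    --sigma0 0.1 --outlier-fraction 0.05 --truth truth.json

# segment it end to end (HALF field -> references -> SCSA)
half-scsa segment plant.ply segmented.ply --seed 3 --log rounds.jsonl

# compare against the generator's labels
half-scsa evaluate segmented.ply plant.ply
```

The `segment` step (about 20 s on one core) prints the per-class point
tallies it produced:

```
{"leaf": 6052, "stem": 1243, "knot": 911, "unclassified": 410}
```

and `evaluate` the per-class confusion and scores (percent):

```
class   tp  fp  fn  precision_pct  recall_pct  f_score_pct
 leaf 6052   0 138          100.0        97.8         98.9
 stem 1166  77   0           93.8       100.0         96.8
 knot  773 138  77           84.9        90.9         87.8
unclassified: 410 / 8616
```

98% of leaf, 100% of stem and 91% of knot points are recovered; the
residual confusion sits at the knot/stem boundary, where the ground
truth itself is defined by a sphere convention (every point within five
stem diameters of a knot center counts as knot). All 410 injected
outliers are among the unclassified points: growth never reaches
isolated debris. A thickness-degradation experiment
(`half-scsa sweep sweep.csv`) reproduces why references must be adapted:
an ideal-line stem scores ζ = 1.0 against its theoretical reference but
drops to ~0.02 at 2 mm diameter, while a leaf slab stays above 0.95.

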