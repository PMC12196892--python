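"""Sequential Competitive Segmentation Algorithm (SCSA).

Segmentation proceeds from *candidate seed points* (CSPs): points whose
HALF is both confidently classified (similarity above a threshold) and
spatially thinned within each class. Growth is *bubble-based* (BSA): a
growth center labels every unlabeled point within radius ``r`` with its
class, and among the newly labeled points — sorted by distance — up to
``max_children`` become new centers, skipping candidates already covered
by a sibling's bubble. Class frontiers alternate level-synchronously
("alternate width-priority search"): each turn, every class expands its
whole current frontier level, so regions extend by one bubble layer per
turn at uniform geometric speed and boundaries settle where frontiers
meet, roughly midway between competing seeds.

The full run has two phases:

* **phytomer rounds** — repeatedly select a connected quadruple of seeds
  (leaf, upper stem, lower stem, knot; the lower stem must sit below the
  knot), grow the three classes competitively, then demote any leaf/stem
  CSPs that were labeled back to normal points. Knot CSPs keep CSP status
  even when labeled so later rounds can still anchor knot competition.
  Rounds repeat while leaf CSPs remain and a quadruple exists.
* **stem rounds** — grow the best remaining stem CSP against a connected
  knot CSP (two classes), with the same CSP bookkeeping, while stem CSPs
  remain. This picks up internode tips not covered by any phytomer.

Labels are write-once: a point labeled in round k is never relabeled.
Points never reached by any frontier stay unclassified, which is how
isolated outliers are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .classes import CLASS_NAMES, KNOT, LEAF, ORGAN_CLASSES, STEM, UNCLASSIFIED
from .io_cloud import PointCloud
from .similarity import ReferenceSet, classify

__all__ = [
    "SegmentationParams",
    "SeedCandidate",
    "RoundLog",
    "SegmentationResult",
    "find_candidate_seeds",
    "bsa_grow",
    "select_phytomer_seeds",
    "run_scsa",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the competitive growth.

    bubble_radius : float
        Bubble radius r in mm (default 5): the label-propagation reach of
        one growth center and the hop length defining connectivity.
    sim_threshold : float
        Minimum similarity (zeta, on normalized histograms) for a point to
        qualify as a CSP (default 0.85).
    min_seed_spacing : float
        Minimum distance in mm between CSPs of the same class (default 24,
        about one soybean internode).
    max_children : int
        New centers promoted per expanded center (default 4).
    vertical_axis : str
        World axis treated as "up" for the phytomer height constraint.
    """

    bubble_radius: float = 5.0
    sim_threshold: float = 0.85
    min_seed_spacing: float = 24.0
    max_children: int = 4
    vertical_axis: str = "z"

    def __post_init__(self):
        if self.bubble_radius <= 0:
            raise ValueError("bubble_radius must be > 0")
        if not (0 < self.sim_threshold < 1):
            raise ValueError("sim_threshold must be in (0, 1)")
        if self.min_seed_spacing <= 0:
            raise ValueError("min_seed_spacing must be > 0")
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        if self.vertical_axis not in _AXIS_INDEX:
            raise ValueError("vertical_axis must be one of x, y, z")

    @property
    def up(self) -> int:
        return _AXIS_INDEX[self.vertical_axis]


@dataclass(frozen=True)
class SeedCandidate:
    index: int
    class_code: int
    zeta: float


@dataclass
class RoundLog:
    round_no: int
    phase: str  # "phytomer" | "stem"
    seeds: dict  # class name -> list of seed indices
    counts: dict  # class name -> points labeled this round (incl. seeds)
    centers: list = field(default_factory=list)  # (point index, class code)


@dataclass
class SegmentationResult:
    labels: np.ndarray
    rounds: list

    @property
    def n_unclassified(self) -> int:
        return int((self.labels == UNCLASSIFIED).sum())

    def counts(self) -> dict:
        return {
            CLASS_NAMES[c]: int((self.labels == c).sum())
            for c in (UNCLASSIFIED, LEAF, STEM, KNOT)
        }


def find_candidate_seeds(
    cloud: PointCloud,
    half_field,
    refs: ReferenceSet,
    params: SegmentationParams,
) -> dict:
    """Per-class CSP lists: confidently classified, spatially thinned.

    A point qualifies for class c when its max-similarity winner is c and
    ``zeta_c > sim_threshold``. Qualifiers are then thinned greedily in
    descending-zeta (index-ascending on ties) order so survivors within a
    class are pairwise at least ``min_seed_spacing`` apart.
    """
    per_class: dict[int, list[SeedCandidate]] = {c: [] for c in ORGAN_CLASSES}
    for idx, h in enumerate(half_field):
        if h is None:
            continue
        winner, zbest, _ = classify(h, refs)
        if zbest > params.sim_threshold:
            per_class[winner].append(SeedCandidate(idx, winner, zbest))
    out: dict[int, list[SeedCandidate]] = {}
    for c, cands in per_class.items():
        cands.sort(key=lambda s: (-s.zeta, s.index))
        kept: list[SeedCandidate] = []
        for cand in cands:
            p = cloud.coords[cand.index]
            if all(
                np.linalg.norm(p - cloud.coords[k.index]) >= params.min_seed_spacing
                for k in kept
            ):
                kept.append(cand)
        out[c] = kept
    return out


def bsa_grow(
    cloud: PointCloud,
    seeds,
    params: SegmentationParams,
    already_labeled: np.ndarray | None = None,
    tree: cKDTree | None = None,
    stop_classes=None,
    max_turns: int | None = None,
    traverse_own_class: bool = False,
):
    """Competitive bubble growth from ``seeds`` = [(point index, class), ...].

    Returns ``(labels, centers)`` where ``labels`` is the updated label
    array (the input mask is not modified) and ``centers`` lists every
    expanded growth center as ``(point index, class code)`` in expansion
    order. Labels are write-once; a seed already labeled with a different
    class is skipped.

    Growth is level-synchronous breadth-first ("alternate width-priority
    search"): per turn every class expands its whole current frontier
    level, so every class's region extends by about one bubble layer per
    turn regardless of frontier width, and boundaries settle midway
    between competing seeds. ``stop_classes`` optionally names classes
    whose frontier exhaustion ends the whole growth at that turn
    boundary, keeping the extension of the competitors uniform (none
    outlives the round's anchor classes). ``max_turns`` bounds the number
    of frontier levels (hence the reach, about ``max_turns * r`` beyond
    the seeds). By default growth runs until every frontier is empty.

    With ``traverse_own_class`` a frontier may also advance through
    points already labeled with its own class (without relabeling or
    recounting them), so a seed buried inside previously segmented
    territory can still carry growth to unlabeled runs at its region's
    rim; other classes' regions remain impassable.
    """
    n = len(cloud)
    labels = (
        np.zeros(n, dtype=np.int64)
        if already_labeled is None
        else np.asarray(already_labeled, dtype=np.int64).copy()
    )
    if tree is None:
        tree = cKDTree(cloud.coords)
    r = params.bubble_radius

    levels: dict[int, list[int]] = {}
    class_order: list[int] = []
    for idx, cls in seeds:
        if labels[idx] != UNCLASSIFIED and labels[idx] != cls:
            continue
        labels[idx] = cls
        if cls not in levels:
            levels[cls] = []
            class_order.append(cls)
        levels[cls].append(int(idx))

    if stop_classes is not None:
        stop_classes = {c for c in stop_classes if c in levels}
    centers: list[tuple[int, int]] = []
    coords = cloud.coords
    visited = {idx for lv in levels.values() for idx in lv}
    turns = 0
    while any(levels.values()):
        if stop_classes and any(not levels[c] for c in stop_classes):
            break
        if max_turns is not None and turns >= max_turns:
            break
        turns += 1
        for cls in class_order:
            next_level: list[int] = []
            for c in levels[cls]:
                centers.append((c, cls))
                neigh = tree.query_ball_point(coords[c], r)
                newly = [i for i in neigh if labels[i] == UNCLASSIFIED]
                labels[newly] = cls
                cands = list(newly)
                if traverse_own_class:
                    newly_set = set(newly)
                    cands.extend(
                        i for i in neigh
                        if labels[i] == cls and i not in visited and i not in newly_set
                    )
                if not cands:
                    continue
                d = np.linalg.norm(coords[cands] - coords[c], axis=1)
                # Children are taken farthest-first: on dense clouds a
                # near-center child's bubble would swallow every other
                # candidate and stall the frontier, whereas boundary
                # children advance it by about one bubble radius per level.
                order = np.lexsort((cands, -d))
                children: list[int] = []
                for k in order:
                    cand = cands[k]
                    if any(
                        np.linalg.norm(coords[cand] - coords[ch]) <= r
                        for ch in children
                    ):
                        continue  # already inside a sibling's bubble
                    children.append(cand)
                    if len(children) >= params.max_children:
                        break
                next_level.extend(children)
                visited.update(children)
            levels[cls] = next_level
    return labels, centers


def _proximity_components(cloud: PointCloud, r: float, tree: cKDTree | None = None):
    """Connected components of the r-radius proximity graph."""
    n = len(cloud)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if tree is None:
        tree = cKDTree(cloud.coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, comp = connected_components(adj, directed=False)
    return comp


def select_phytomer_seeds(
    cloud: PointCloud,
    csps: dict,
    params: SegmentationParams,
    labels: np.ndarray | None = None,
    components: np.ndarray | None = None,
    tree: cKDTree | None = None,
    allow_labeled_anchors: bool = False,
):
    """Pick a connected (leaf, upper-stem, lower-stem, knot) seed quadruple.

    Connectivity means all four lie in one component of the r-radius
    proximity graph (mutual reachability by hops of <= bubble_radius).
    The lower-stem seed must sit below the knot seed along the vertical
    axis; the upper-stem seed is the nearest qualifying stem CSP above
    it. The leaf seed is always unlabeled (it drives the round); the
    stem/knot anchors prefer unlabeled CSPs but, with
    ``allow_labeled_anchors``, fall back to already-labeled ones — those
    still bound the competition spatially when a round revisits a
    partially segmented phytomer. Returns the quadruple of
    :class:`SeedCandidate` or ``None`` when no quadruple exists.
    """
    if components is None:
        components = _proximity_components(cloud, params.bubble_radius, tree=tree)
    if labels is None:
        labels = np.zeros(len(cloud), dtype=np.int64)
    up = params.up

    def unlabeled(cands):
        return [s for s in cands if labels[s.index] == UNCLASSIFIED]

    def prefer_unlabeled(cands, key):
        free = unlabeled(cands)
        pool = free if free or not allow_labeled_anchors else cands
        return min(pool, key=key) if pool else None

    leaves = sorted(unlabeled(csps.get(LEAF, [])), key=lambda s: (-s.zeta, s.index))
    all_knots = csps.get(KNOT, [])
    all_stems = csps.get(STEM, [])
    for leaf in leaves:
        comp = components[leaf.index]
        lp = cloud.coords[leaf.index]
        cand_knots = [k for k in all_knots if components[k.index] == comp]
        free_knots = unlabeled(cand_knots)
        pool_knots = free_knots if free_knots or not allow_labeled_anchors else cand_knots
        pool_knots = sorted(
            pool_knots,
            key=lambda k: (np.linalg.norm(cloud.coords[k.index] - lp), k.index),
        )
        stems = [s for s in all_stems if components[s.index] == comp]
        for knot in pool_knots:
            kz = cloud.coords[knot.index][up]
            above = [s for s in stems if cloud.coords[s.index][up] > kz]
            below = [s for s in stems if cloud.coords[s.index][up] < kz]
            upper = prefer_unlabeled(
                above, key=lambda s: (cloud.coords[s.index][up], s.index)
            )
            lower = prefer_unlabeled(
                below, key=lambda s: (-cloud.coords[s.index][up], s.index)
            )
            if upper is None or lower is None:
                continue
            return leaf, upper, lower, knot
    return None


def run_scsa(
    cloud: PointCloud,
    half_field,
    refs: ReferenceSet,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Full two-phase SCSA segmentation.

    Deterministic given ``half_field``: every queue, sort and tie-break is
    ordered. Points never reached stay unclassified.
    """
    if params is None:
        params = SegmentationParams()
    n = len(cloud)
    labels = np.zeros(n, dtype=np.int64)
    rounds: list[RoundLog] = []
    if n == 0:
        return SegmentationResult(labels, rounds)

    tree = cKDTree(cloud.coords)
    components = _proximity_components(cloud, params.bubble_radius, tree=tree)
    csps = find_candidate_seeds(cloud, half_field, refs, params)

    def log_round(phase, seed_map, before, centers):
        counts = {
            CLASS_NAMES[c]: int(((labels == c) & (before != c)).sum())
            for c in ORGAN_CLASSES
        }
        rounds.append(
            RoundLog(
                round_no=len(rounds) + 1,
                phase=phase,
                seeds={CLASS_NAMES[c]: idxs for c, idxs in seed_map.items()},
                counts=counts,
                centers=centers,
            )
        )

    # Phytomer rounds: each is driven by one unlabeled leaf CSP; stem and
    # knot CSPs stay in the pool (Step 4 returns classified leaf/stem CSPs
    # to normal-point status only as round drivers — as anchors they remain
    # reusable, and knot CSPs persist explicitly).
    # Reach bound per phytomer round: CSPs of a class are at least
    # min_seed_spacing apart, so territory farther than half that spacing
    # from a seed lies closer to some later round's seed; growing past it
    # would trespass into a neighbouring phytomer before its own round.
    reach_turns = max(1, int(np.ceil(params.min_seed_spacing / 2 / params.bubble_radius)))
    round_cap = max(1, len(csps[LEAF]))  # safety net against livelock
    for _ in range(round_cap):
        quad = select_phytomer_seeds(
            cloud, csps, params, labels=labels, components=components,
            tree=tree, allow_labeled_anchors=True,
        )
        if quad is None:
            break
        leaf, upper, lower, knot = quad
        seeds = [
            (leaf.index, LEAF),
            (upper.index, STEM),
            (lower.index, STEM),
            (knot.index, KNOT),
        ]
        # A live knot anchors the round: growth ends once the knot frontier
        # is encircled or every frontier has reached half the seed
        # spacing, which seals the knot sphere against its stem
        # neighbours and keeps the round phytomer-local. When the knot
        # anchor is already segmented (a revisit round) the class
        # boundaries around the phytomer are settled, so the driving leaf
        # simply fills in its remaining interior, unbounded.
        if labels[knot.index] == UNCLASSIFIED:
            stop, cap = {KNOT}, reach_turns
        else:
            stop, cap = {LEAF}, None
        before = labels.copy()
        labels, centers = bsa_grow(
            cloud, seeds, params, already_labeled=labels, tree=tree,
            stop_classes=stop, max_turns=cap,
        )
        log_round(
            "phytomer",
            {LEAF: [leaf.index], STEM: [upper.index, lower.index], KNOT: [knot.index]},
            before,
            centers,
        )

    # Stem rounds: sweep remaining stem territory. Each round is driven by
    # the best not-yet-used stem CSP (unlabeled ones first; labeled ones
    # still expand into adjacent unlabeled runs) competing against the
    # nearest connected knot CSP, whose sealed region blocks trespass.
    used: set[int] = set()
    for _ in range(len(csps[STEM])):
        pool = [s for s in csps[STEM] if s.index not in used]
        if not pool:
            break
        free = [s for s in pool if labels[s.index] == UNCLASSIFIED]
        sp = max(free or pool, key=lambda s: (s.zeta, -s.index))
        used.add(sp.index)
        spp = cloud.coords[sp.index]
        knots = [k for k in csps[KNOT] if components[k.index] == components[sp.index]]
        knots.sort(key=lambda k: (np.linalg.norm(cloud.coords[k.index] - spp), k.index))
        seeds = [(sp.index, STEM)]
        seed_map = {STEM: [sp.index]}
        if knots:
            seeds.append((knots[0].index, KNOT))
            seed_map[KNOT] = [knots[0].index]
        before = labels.copy()
        labels, centers = bsa_grow(
            cloud, seeds, params, already_labeled=labels, tree=tree,
            stop_classes={STEM}, traverse_own_class=True,
        )
        log_round("stem", seed_map, before, centers)

    return SegmentationResult(labels, rounds)
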