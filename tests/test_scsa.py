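import numpy as np
import pytest

from halfscsa.classes import KNOT, LEAF, STEM, UNCLASSIFIED
from halfscsa.half_core import HalfHistogram
from halfscsa.io_cloud import PointCloud
from halfscsa.scsa import (
    SegmentationParams,
    bsa_grow,
    find_candidate_seeds,
    run_scsa,
    select_phytomer_seeds,
)
from halfscsa.similarity import ReferenceSet, initial_references


def spike(bin_, n_bins=180, mass=1.0):
    c = np.zeros(n_bins)
    c[bin_] = mass
    return c


@pytest.fixture(scope="module")
def toy_refs():
    """Orthogonal single-bin references: similarity is exact and legible."""
    return ReferenceSet(leaf=spike(90), stem=spike(0), knot=spike(45))


class TestFindCandidateSeeds:
    def test_spacing_thins_close_pairs(self, toy_refs):
        cloud = PointCloud([[0, 0, 0], [10, 0, 0], [40, 0, 0]])
        field = [HalfHistogram(spike(0))] * 3  # all perfect stems
        csps = find_candidate_seeds(cloud, field, toy_refs, SegmentationParams())
        kept = [s.index for s in csps[STEM]]
        assert kept == [0, 2]  # point 1 within 24 mm of point 0

    def test_perfect_leaf_selected(self, toy_refs):
        cloud = PointCloud([[0, 0, 0]])
        csps = find_candidate_seeds(cloud, [HalfHistogram(spike(90))], toy_refs,
                                    SegmentationParams())
        assert [s.index for s in csps[LEAF]] == [0]
        assert csps[LEAF][0].zeta == pytest.approx(1.0)

    def test_below_threshold_excluded(self, toy_refs):
        mixed = 0.6 * spike(0) + 0.4 * spike(90)  # zeta_stem = 0.6 < 0.85
        cloud = PointCloud([[0, 0, 0]])
        csps = find_candidate_seeds(cloud, [HalfHistogram(mixed)], toy_refs,
                                    SegmentationParams())
        assert csps[STEM] == [] and csps[LEAF] == []

    def test_plant_has_all_classes(self, small_plant):
        csps = find_candidate_seeds(
            small_plant["cloud"], small_plant["field"], small_plant["refs"],
            SegmentationParams(),
        )
        assert all(len(csps[c]) >= 1 for c in (LEAF, STEM, KNOT))


def line_cloud(n, spacing):
    return PointCloud(np.c_[np.arange(n) * spacing, np.zeros(n), np.zeros(n)])


class TestBsaGrow:
    def test_chain_propagation(self):
        cloud = line_cloud(7, 4.0)  # within one bubble hop of each other
        labels, _ = bsa_grow(cloud, [(0, LEAF)], SegmentationParams())
        assert (labels == LEAF).all()

    def test_gap_blocks_growth(self):
        cloud = PointCloud([[0, 0, 0], [6, 0, 0]])
        labels, _ = bsa_grow(cloud, [(0, LEAF)], SegmentationParams())
        assert labels.tolist() == [LEAF, UNCLASSIFIED]

    def test_competing_seeds_meet_near_midpoint(self):
        cloud = line_cloud(41, 1.0)  # 0..40 mm
        labels, _ = bsa_grow(cloud, [(0, LEAF), (40, STEM)], SegmentationParams())
        assert (labels != UNCLASSIFIED).all()
        boundary = np.max(np.where(labels == LEAF))  # rightmost leaf point
        assert abs(cloud.coords[boundary, 0] - 20.0) <= 5.0  # +- one bubble

    def test_write_once(self):
        cloud = line_cloud(10, 2.0)
        pre = np.zeros(10, dtype=np.int64)
        pre[:3] = KNOT
        labels, _ = bsa_grow(cloud, [(5, LEAF)], SegmentationParams(),
                             already_labeled=pre)
        assert (labels[:3] == KNOT).all()

    def test_seed_with_conflicting_label_skipped(self):
        cloud = line_cloud(5, 2.0)
        pre = np.full(5, STEM, dtype=np.int64)
        labels, centers = bsa_grow(cloud, [(0, LEAF)], SegmentationParams(),
                                   already_labeled=pre)
        assert (labels == STEM).all() and centers == []

    def test_spatial_soundness(self, rng):
        coords = rng.uniform(0, 40, size=(300, 3))
        cloud = PointCloud(coords)
        params = SegmentationParams()
        labels, centers = bsa_grow(cloud, [(0, LEAF), (299, STEM)], params)
        seed_idx = {0, 299}
        for cls in (LEAF, STEM):
            cls_centers = coords[[i for i, c in centers if c == cls]]
            for i in np.where(labels == cls)[0]:
                if i in seed_idx:
                    continue
                d = np.linalg.norm(cls_centers - coords[i], axis=1).min()
                assert d <= params.bubble_radius + 1e-9

    def test_max_turns_bounds_reach(self):
        cloud = line_cloud(41, 1.0)
        labels, _ = bsa_grow(cloud, [(0, LEAF)], SegmentationParams(), max_turns=2)
        reach = cloud.coords[labels == LEAF, 0].max()
        assert reach <= 2 * 5.0 + 1e-9


class TestSelectPhytomerSeeds:
    def make_csps(self, entries):
        from halfscsa.scsa import SeedCandidate

        out = {LEAF: [], STEM: [], KNOT: []}
        for idx, cls, z in entries:
            out[cls].append(SeedCandidate(idx, cls, z))
        return out

    def test_height_constraint_unsatisfiable(self):
        # both stem CSPs above the knot -> no quadruple
        cloud = PointCloud([[0, 0, 50], [0, 0, 30], [0, 0, 40], [0, 0, 45]])
        # dense chain for connectivity
        chain = np.c_[np.zeros(20), np.zeros(20), np.linspace(28, 52, 20)]
        cloud = PointCloud(np.vstack([cloud.coords, chain]))
        csps = self.make_csps(
            [(0, LEAF, 0.99), (3, STEM, 0.95), (2, STEM, 0.93), (1, KNOT, 0.9)]
        )
        # knot at z=30: stems at 40 and 45 are both above
        quad = select_phytomer_seeds(cloud, csps, SegmentationParams())
        assert quad is None

    def test_disconnected_leaf_excluded(self):
        cloud = PointCloud(
            [[0, 0, 50], [0, 0, 40], [0, 0, 45], [0, 0, 35], [500, 500, 500]]
        )
        chain = np.c_[np.zeros(10), np.zeros(10), np.linspace(33, 52, 10)]
        cloud = PointCloud(np.vstack([cloud.coords, chain]))
        csps = self.make_csps(
            [(4, LEAF, 0.99), (0, LEAF, 0.9), (2, STEM, 0.95), (3, STEM, 0.93),
             (1, KNOT, 0.9)]
        )
        quad = select_phytomer_seeds(cloud, csps, SegmentationParams())
        assert quad is not None
        assert quad[0].index == 0  # the far, disconnected leaf CSP is skipped

    def test_plant_quadruple_matches_construction(self, small_plant):
        cloud, truth = small_plant["cloud"], small_plant["truth"]
        params = SegmentationParams()
        csps = find_candidate_seeds(cloud, small_plant["field"],
                                    small_plant["refs"], params)
        quad = select_phytomer_seeds(cloud, csps, params)
        assert quad is not None
        leaf, upper, lower, knot = quad
        assert cloud.labels[leaf.index] == LEAF
        kz = cloud.coords[knot.index][2]
        assert cloud.coords[lower.index][2] < kz < cloud.coords[upper.index][2]
        # knot seed sits inside a true knot sphere
        d = np.linalg.norm(truth.knot_centers - cloud.coords[knot.index], axis=1)
        assert d.min() <= 10.0


class TestRunScsa:
    def test_recovers_plant_structure(self, small_plant):
        cloud, truth = small_plant["cloud"], small_plant["truth"]
        res = run_scsa(cloud, small_plant["field"], small_plant["refs"])
        from halfscsa.evaluation import score

        per = score(res.labels, cloud.labels)["per_class"]
        assert per["leaf"].f_score >= 0.9
        assert per["stem"].f_score >= 0.8
        assert per["knot"].f_score >= 0.6
        assert (res.labels[truth.outlier_mask] == UNCLASSIFIED).all()
        phases = [r.phase for r in res.rounds]
        assert phases.index("phytomer") == 0

    def test_deterministic(self, small_plant):
        a = run_scsa(small_plant["cloud"], small_plant["field"], small_plant["refs"])
        b = run_scsa(small_plant["cloud"], small_plant["field"], small_plant["refs"])
        np.testing.assert_array_equal(a.labels, b.labels)
        assert [r.counts for r in a.rounds] == [r.counts for r in b.rounds]

    def test_labels_write_once_across_rounds(self, small_plant):
        """Per-round labeled counts sum exactly to the final tallies: no
        point is ever relabeled by a later round."""
        res = run_scsa(small_plant["cloud"], small_plant["field"], small_plant["refs"])
        from halfscsa.classes import CLASS_NAMES

        for cls in (LEAF, STEM, KNOT):
            total = sum(r.counts[CLASS_NAMES[cls]] for r in res.rounds)
            assert total == int((res.labels == cls).sum())

    def test_stem_only_cloud_runs_stem_phase(self):
        from halfscsa.half_core import HalfParams, compute_half_field
        from halfscsa.synthetic import make_cylinder

        stem = make_cylinder(80.0, 2.0, 12.0, rng=np.random.default_rng(4))
        field = compute_half_field(stem, HalfParams(n_pairs=6000, rng_seed=4))
        from halfscsa.similarity import optimize_references

        refs = optimize_references(field, initial_references())
        res = run_scsa(stem, field, refs)
        phases = {r.phase for r in res.rounds}
        assert phases <= {"stem"}
        assert (res.labels == STEM).sum() > 0.5 * len(stem)

    def test_empty_cloud(self):
        res = run_scsa(PointCloud(np.empty((0, 3))), [], initial_references())
        assert len(res.labels) == 0 and res.rounds == []
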