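import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomatch.gating import (
    EmbeddingGuidedLabeler,
    Gate,
    GatingTree,
    GatingTreeClassifier,
    Labeling,
    PolygonGate,
    Rectangle,
    Threshold,
    TreeNode,
    UNIDENTIFIED,
    apply_gate,
    apply_tree,
    build_gating_tree,
    conventional_labeling,
    derive_embedding_labeling,
)
from cytomatch.matrix import CellMatrix
from cytomatch.datasets import sample_cohort


def _matrix(points):
    pts = np.asarray(points, dtype=float)
    return CellMatrix(pts, ["x", "y"], ["protein", "protein"])


def _ray_cast(poly, px, py, eps=1e-12):
    """Brute-force boundary-inclusive point-in-polygon oracle."""
    n = len(poly)
    # on-edge check
    for i in range(n):
        (x1, y1), (x2, y2) = poly[i], poly[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < eps:
            if min(x1, x2) - eps <= px <= max(x1, x2) + eps and \
               min(y1, y2) - eps <= py <= max(y1, y2) + eps:
                return True
    inside = False
    for i in range(n):
        (x1, y1), (x2, y2) = poly[i], poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


class TestGeometries:
    def test_unbounded_rectangle_is_identity(self):
        m = _matrix([(0, 0), (5, -3), (-100, 100)])
        g = Gate("all", "x", "y", Rectangle())
        parent = np.array([True, True, False])
        out = apply_gate(g, m, parent)
        np.testing.assert_array_equal(out, parent)

    def test_triangle_boundary_inclusive(self):
        """Triangle (0,0),(4,0),(0,4) vs points (1,1),(3,3),(0,2):
        members are (1,1) and the boundary point (0,2)."""
        m = _matrix([(1, 1), (3, 3), (0, 2)])
        g = Gate("tri", "x", "y", PolygonGate(((0, 0), (4, 0), (0, 4))))
        out = apply_gate(g, m, np.ones(3, dtype=bool))
        np.testing.assert_array_equal(out, [True, False, True])

    def test_threshold_closed_boundary(self):
        m = _matrix([(-1, 0), (0, 0), (1, 0)])
        g = Gate("pos", "x", "y", Threshold("x", 0.0, "positive"))
        out = apply_gate(g, m, np.ones(3, dtype=bool))
        np.testing.assert_array_equal(out, [False, True, True])

    def test_polygon_agrees_with_ray_casting_oracle(self, rng):
        verts = ((0, 0), (6, 1), (7, 5), (3, 7), (-1, 4))
        gate = Gate("p", "x", "y", PolygonGate(verts))
        pts = np.column_stack([rng.uniform(-2, 8, 300), rng.uniform(-2, 8, 300)])
        # include some exact vertices and edge midpoints
        extra = np.array(verts + ((3.0, 0.5), (5.0, 6.0)))
        pts = np.vstack([pts, extra])
        m = _matrix(pts)
        got = apply_gate(gate, m, np.ones(len(pts), dtype=bool))
        want = np.array([_ray_cast(verts, x, y) for x, y in pts])
        np.testing.assert_array_equal(got, want)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            PolygonGate(((0, 0), (1, 1)))
        with pytest.raises(ValueError):  # self-intersecting bow-tie
            PolygonGate(((0, 0), (2, 2), (2, 0), (0, 2)))

    def test_missing_channel(self):
        m = _matrix([(0, 0)])
        g = Gate("g", "CD3", "y", Threshold("x", 0, "positive"))
        with pytest.raises(KeyError):
            apply_gate(g, m, np.ones(1, dtype=bool))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.1, 4), st.floats(0.1, 4))
    def test_monotone_in_parent(self, x0, y0, w, h):
        """Shrinking the parent set never adds members to a child gate."""
        rng = np.random.default_rng(99)
        pts = rng.uniform(-6, 6, size=(80, 2))
        m = _matrix(pts)
        g = Gate("r", "x", "y", Rectangle(x0, x0 + w, y0, y0 + h))
        full = np.ones(80, dtype=bool)
        sub = rng.random(80) < 0.5
        out_full = apply_gate(g, m, full)
        out_sub = apply_gate(g, m, sub)
        assert not np.any(out_sub & ~out_full)
        assert not np.any(out_sub & ~sub)


class TestApplyTree:
    def _tree(self):
        nodes = [
            TreeNode("root", None, None),
            TreeNode("xpos", Gate("xpos", "x", "y", Threshold("x", 0, "positive")),
                     "root"),
            TreeNode("A", Gate("A", "y", "x", Threshold("x", 0, "positive")),
                     "xpos", terminal=True, level="lineage"),
            TreeNode("B", Gate("B", "y", "x", Threshold("x", 0, "negative")),
                     "xpos", terminal=True, level="lineage"),
        ]
        return GatingTree(nodes)

    def test_conjunction_semantics(self):
        m = _matrix([(1, 1), (1, -1), (-1, 1), (0, 0)])
        lab = apply_tree(self._tree(), m)
        # (1,-1) passes x>=0 but fails A's y>=0 -> lands in B;
        # (-1,1) fails the ancestor x>=0 gate entirely -> Unidentified
        assert list(lab.assignment) == ["A", "B", UNIDENTIFIED, "A"]

    def test_first_match_overlap_diagnostic(self):
        m = _matrix([(1, 0)])  # y == 0 satisfies both A and B (closed gates)
        lab = apply_tree(self._tree(), m)
        assert lab.assignment[0] == "A"
        assert lab.diagnostics["overlap_events"] == 1

    def test_empty_matrix(self):
        m = _matrix(np.zeros((0, 2)))
        lab = apply_tree(self._tree(), m)
        assert len(lab) == 0

    def test_lineage_labels_partition_events(self, mini_template, mini_cohort):
        lab = conventional_labeling(mini_template, mini_cohort.matrix)
        names = {p.name for p in mini_template.lineages} | {UNIDENTIFIED}
        assert set(lab.assignment) <= names
        assert len(lab) == mini_cohort.matrix.n_events

    def test_full_template_unidentified_below_one_percent(self, full_template):
        cohort = sample_cohort(full_template, 2, 4000, seed=17)
        for level in ("lineage", "subset"):
            lab = conventional_labeling(full_template, cohort.matrix, level=level)
            assert np.mean(lab.assignment == UNIDENTIFIED) < 0.01

    def test_lineage_recovery_on_discrete_cohort(self, mini_template, mini_cohort):
        lab = conventional_labeling(mini_template, mini_cohort.matrix)
        truth = mini_cohort.truth["lineage"].to_numpy()
        assert np.mean(lab.assignment == truth) > 0.999

    def test_classifier_wrapper(self, mini_template, mini_cohort):
        clf = GatingTreeClassifier(build_gating_tree(mini_template), level="lineage")
        clf.fit(mini_cohort.matrix)
        labels = clf.predict(mini_cohort.matrix)
        assert len(labels) == mini_cohort.matrix.n_events
        assert set(labels) <= set(clf.classes_)

    def test_tree_yaml_round_trip(self, tmp_path, mini_template, mini_cohort):
        tree = build_gating_tree(mini_template)
        p = tmp_path / "tree.yaml"
        tree.to_yaml(p)
        back = GatingTree.from_yaml(p)
        a = apply_tree(tree, mini_cohort.matrix)
        b = apply_tree(back, mini_cohort.matrix)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestEmbeddingGuidedLabeler:
    def _island_coords(self, truth, rng, spread=0.5, radius=30.0):
        """Synthetic embedding: one tight 2-D island per population."""
        pops = sorted(set(truth))
        angles = np.linspace(0, 2 * np.pi, len(pops), endpoint=False)
        centers = {
            p: radius * np.array([np.cos(a), np.sin(a)])
            for p, a in zip(pops, angles)
        }
        coords = np.array([centers[t] for t in truth])
        return coords + rng.normal(0, spread, coords.shape)

    def test_clusters_match_majority_truth(self, mini_template, mini_cohort, rng):
        """Every non-empty cluster is assigned its majority truth label."""
        truth = mini_cohort.truth["lineage"].to_numpy()
        coords = self._island_coords(truth, rng)
        lab = EmbeddingGuidedLabeler(mini_template, k=16, random_state=0)
        lab.fit(coords, mini_cohort.matrix)
        for c in range(16):
            rows = lab.cluster_labels_ == c
            if not rows.any() or lab.cluster_names_[c] == UNIDENTIFIED:
                continue
            majority = np.unique(truth[rows], return_counts=True)
            assert lab.cluster_names_[c] == majority[0][majority[1].argmax()]

    def test_two_populations_high_accuracy(self, mini_template, rng):
        cohort = sample_cohort(mini_template, 1, 2000, seed=8)
        truth = cohort.truth["lineage"].to_numpy()
        coords = self._island_coords(truth, rng)
        lab = derive_embedding_labeling(coords, cohort.matrix, mini_template,
                                        level="lineage", seed=1)
        assert np.mean(lab.assignment == truth) >= 0.99

    def test_seeded_determinism(self, mini_template, mini_cohort, rng):
        truth = mini_cohort.truth["lineage"].to_numpy()
        coords = self._island_coords(truth, rng)
        a = derive_embedding_labeling(coords, mini_cohort.matrix, mini_template, seed=5)
        b = derive_embedding_labeling(coords, mini_cohort.matrix, mini_template, seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_rotation_invariance(self, mini_template, mini_cohort, rng):
        """Cluster naming does not depend on embedding axis orientation."""
        truth = mini_cohort.truth["lineage"].to_numpy()
        coords = self._island_coords(truth, rng)
        theta = 2.2
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = derive_embedding_labeling(coords, mini_cohort.matrix, mini_template, seed=3)
        b = derive_embedding_labeling(coords @ R.T, mini_cohort.matrix,
                                      mini_template, seed=3)
        assert np.mean(a.assignment == b.assignment) > 0.999

    def test_k_below_population_count(self, mini_template, mini_cohort):
        with pytest.raises(ValueError):
            derive_embedding_labeling(
                np.zeros((3000, 2)), mini_cohort.matrix, mini_template, k=4
            )

    def test_most_specific_signature_wins(self, full_template, rng):
        """A naive-T cluster matches both the naive signature and the broader
        memory signature at distance 0; the more specific one is chosen."""
        cohort = sample_cohort(full_template, 1, 4000, seed=21)
        truth = cohort.truth["subset"].to_numpy()
        coords = self._island_coords(truth, rng)
        lab = derive_embedding_labeling(coords, cohort.matrix, full_template,
                                        level="subset", seed=2)
        naive = truth == "CD4 naive T"
        assert np.mean(lab.assignment[naive] == "CD4 naive T") > 0.95


def test_labeling_csv_round_trip(tmp_path, mini_template, mini_cohort):
    lab = conventional_labeling(mini_template, mini_cohort.matrix)
    p = tmp_path / "labels.csv"
    lab.to_csv(p)
    back = Labeling.from_csv(p)
    np.testing.assert_array_equal(back.assignment, lab.assignment)
    assert back.provenance == "conventional"
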