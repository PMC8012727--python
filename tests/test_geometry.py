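"""Unit and property tests for the arrow-alignment scoring pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctscore.geometry import (
    CentroidSet,
    CTSMatrix,
    DegenerateGeometryError,
    SkipLog,
    VelocityArrow,
    alignment_cosine,
    arrow_destination_score,
    compose_cts,
    distance_weights,
    log2_display,
    score_arrows,
    sum_by_transition,
)

from conftest import random_arrows, random_centroids


def dot_product_cosine(start, end, centroid, convention):
    """Independent oracle: cosine as a normalized dot product of direction vectors."""
    start, end, centroid = map(np.asarray, (start, end, centroid))
    if convention == "endpoint":
        u, v = start - end, centroid - end
    else:
        u, v = end - start, centroid - start
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestAlignmentCosine:
    @pytest.mark.parametrize(
        "convention, x, y, z, expected",
        [
            # arrow collinear with and pointing toward the centroid
            ("origin", (0, 0), (1, 0), (2, 0), 1.0),
            ("endpoint", (0, 0), (1, 0), (2, 0), -1.0),
            # perpendicular arrow: angle at the tip between Y->X and Y->Z
            ("endpoint", (0, 0), (0, 1), (2, 0), 1 / np.sqrt(5)),
            # arrow pointing directly away from the centroid
            ("endpoint", (0, 0), (-1, 0), (2, 0), 1.0),
            ("origin", (0, 0), (-1, 0), (2, 0), -1.0),
        ],
    )
    def test_analytic_anchors(self, convention, x, y, z, expected):
        assert alignment_cosine(x, y, z, convention) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("convention", ["endpoint", "origin"])
    def test_law_of_cosines_matches_dot_product_oracle(self, rng, convention):
        """1000+ random triangles: law-of-cosines result equals the normalized
        dot product of the corresponding direction vectors to 1e-9."""
        for _ in range(1200):
            x, y, z = rng.uniform(-50, 50, (3, 2))
            got = alignment_cosine(tuple(x), tuple(y), tuple(z), convention)
            want = dot_product_cosine(x, y, z, convention)
            assert got == pytest.approx(want, abs=1e-9)
            assert -1.0 <= got <= 1.0

    coord = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.tuples(coord, coord),
        y=st.tuples(coord, coord),
        z=st.tuples(coord, coord),
        convention=st.sampled_from(["endpoint", "origin"]),
    )
    def test_cosine_properties_hold_on_arbitrary_triangles(self, x, y, z, convention):
        """Whenever the active sides are non-degenerate the cosine is clamped
        to [-1, 1] and matches the dot-product oracle."""
        sides = [
            np.linalg.norm(np.subtract(a, b))
            for a, b in [(x, y), (y, z), (x, z)]
        ]
        # the law-of-cosines form loses all precision when one side is
        # vanishingly small relative to the others; exclude those triangles
        if min(sides) < 1e-6 * max(max(sides), 1.0):
            return
        got = alignment_cosine(x, y, z, convention)
        assert -1.0 <= got <= 1.0
        want = dot_product_cosine(x, y, z, convention)
        assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize(
        "convention, x, y, z",
        [
            ("endpoint", (0, 0), (0, 0), (1, 1)),  # zero-length arrow
            ("endpoint", (0, 0), (1, 1), (1, 1)),  # tip on centroid
            ("origin", (0, 0), (1, 1), (0, 0)),  # base on centroid
        ],
    )
    def test_degenerate_sides_raise(self, convention, x, y, z):
        with pytest.raises(DegenerateGeometryError):
            alignment_cosine(x, y, z, convention)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            alignment_cosine((0, 0), (1, 0), (2, 0), "sideways")


class TestDestinationScore:
    @pytest.mark.parametrize(
        "convention, x, y, z, expected",
        [
            ("endpoint", (0, 0), (1, 0), (2, 0), 1.0),   # (1-(-1)) * 1/2
            ("endpoint", (0, 0), (-1, 0), (2, 0), 0.0),  # points straight away
            ("origin", (0, 0), (1, 0), (2, 0), 1.0),     # (1+1) * 1/2
            ("origin", (0, 0), (-1, 0), (2, 0), 0.0),
        ],
    )
    def test_examples(self, convention, x, y, z, expected):
        _, s = arrow_destination_score(x, y, z, convention)
        assert s == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("convention", ["endpoint", "origin"])
    def test_score_is_non_negative_and_alignment_monotone(self, rng, convention):
        """S >= 0 everywhere, and rotating an arrow toward the centroid
        direction strictly increases S."""
        for _ in range(300):
            x = rng.uniform(-10, 10, 2)
            # keep the arrow shorter than the centroid distance: an arrow
            # overshooting the centroid legitimately scores ~0 at angle 0
            z = x + rng.uniform(2.5, 5) * np.array([1.0, 0.0])
            length = rng.uniform(0.1, 2.0)
            angles = [0.0, 0.5, 1.5, np.pi - 0.2]
            scores = []
            for a in angles:
                y = x + length * np.array([np.cos(a), np.sin(a)])
                _, s = arrow_destination_score(tuple(x), tuple(y), tuple(z), convention)
                assert s >= 0
                scores.append(s)
            assert scores == sorted(scores, reverse=True)

    def test_score_scales_with_arrow_length_and_centroid_distance(self):
        _, s1 = arrow_destination_score((0, 0), (1, 0), (4, 0))
        _, s2 = arrow_destination_score((0, 0), (2, 0), (4, 0))
        _, s3 = arrow_destination_score((0, 0), (1, 0), (8, 0))
        assert s2 > s1 > s3


class TestScoreArrows:
    def test_self_transition_excluded(self):
        arrows = [VelocityArrow("v", (0, 0), (1, 0), "A")]
        cents = CentroidSet("v", {"A": (0, 1), "B": (2, 0), "C": (0, -2)})
        scores = score_arrows(arrows, cents)
        assert len(scores) == 2
        assert {s.destination for s in scores} == {"B", "C"}

    def test_empty_arrow_set(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0)})
        assert score_arrows([], cents) == []

    def test_matches_pairwise_manual_computation(self, rng):
        arrows = random_arrows(rng, 2, ["A", "B"])
        cents = random_centroids(rng, ["A", "B"])
        scores = score_arrows(arrows, cents)
        for ps in scores:
            arrow = arrows[ps.arrow_index]
            cos, s = arrow_destination_score(
                arrow.start, arrow.end, cents[ps.destination]
            )
            assert ps.score == pytest.approx(s)
            assert ps.cos_theta == pytest.approx(cos)

    def test_unknown_start_cluster_raises(self):
        arrows = [VelocityArrow("v", (0, 0), (1, 0), "Z")]
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0)})
        with pytest.raises(KeyError, match="Z"):
            score_arrows(arrows, cents)

    def test_degenerate_pairs_counted_not_fatal(self):
        # zero-length arrow: every pair skipped
        arrows = [VelocityArrow("v", (0, 0), (0, 0), "A")]
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0), "C": (2, 0)})
        log = SkipLog()
        scores = score_arrows(arrows, cents, skip_log=log)
        assert scores == []
        assert log.degenerate_pairs == 2
        assert log.by_view == {"v": 2}


class TestSumByTransition:
    def test_additivity_example(self):
        arrows = [
            VelocityArrow("v", (0, 0), (1, 0), "A"),
            VelocityArrow("v", (0, 1), (1, 1), "A"),
        ]
        cents = CentroidSet("v", {"A": (-4, 0), "B": (4, 0.5)})
        scores = score_arrows(arrows, cents)
        order = ["A", "B"]
        raw = sum_by_transition(scores, arrows, order)
        assert raw[0, 1] == pytest.approx(sum(s.score for s in scores))
        assert raw[1, 0] == 0.0
        assert np.diag(raw).sum() == 0.0

    def test_empty_scores_give_zero_matrix(self):
        raw = sum_by_transition([], [], ["A", "B", "C"])
        assert raw.shape == (3, 3)
        assert not raw.any()

    def test_matches_brute_force_double_loop(self, rng):
        clusters = ["A", "B", "C", "D"]
        arrows = random_arrows(rng, 25, clusters)
        cents = random_centroids(rng, clusters)
        scores = score_arrows(arrows, cents)
        raw = sum_by_transition(scores, arrows, clusters)
        # oracle: direct double loop over arrows and destinations
        want = np.zeros((4, 4))
        for i, arrow in enumerate(arrows):
            for j, dest in enumerate(clusters):
                if dest == arrow.start_cluster:
                    continue
                _, s = arrow_destination_score(arrow.start, arrow.end, cents[dest])
                want[clusters.index(arrow.start_cluster), j] += s
        np.testing.assert_allclose(raw, want, rtol=1e-12)

    def test_doubling_arrows_doubles_totals(self, rng):
        clusters = ["A", "B"]
        arrows = random_arrows(rng, 10, clusters)
        cents = random_centroids(rng, clusters)
        raw1 = sum_by_transition(score_arrows(arrows, cents), arrows, clusters)
        doubled = arrows + arrows
        raw2 = sum_by_transition(score_arrows(doubled, cents), doubled, clusters)
        np.testing.assert_allclose(raw2, 2 * raw1, rtol=1e-12)


class TestDistanceWeights:
    def test_collinear_three_clusters(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0), "C": (3, 0)})
        table = distance_weights(cents)
        assert table.weight("B", "A") == 1.0
        assert table.weight("C", "A") == 0.0

    def test_two_clusters_degenerate_all_weights_one(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (5, 5)})
        table = distance_weights(cents)
        assert table.weight("A", "B") == 1.0
        assert table.weight("B", "A") == 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="transitions"):
            distance_weights(CentroidSet("v", {"A": (0, 0)}))

    def test_matches_pairwise_distance_oracle(self, rng):
        clusters = list("ABCDE")
        cents = random_centroids(rng, clusters)
        table = distance_weights(cents)
        pts = {c: np.asarray(cents[c]) for c in clusters}
        for dest in clusters:
            z = {
                src: np.linalg.norm(pts[src] - pts[dest])
                for src in clusters
                if src != dest
            }
            zmin, zmax = min(z.values()), max(z.values())
            for src, zv in z.items():
                want = 1.0 - (zv - zmin) / (zmax - zmin)
                assert table.weight(src, dest) == pytest.approx(want)
                assert table.distance(src, dest) == pytest.approx(zv)
            ws = [table.weight(src, dest) for src in z]
            assert max(ws) == 1.0 and min(ws) == 0.0
            assert all(0.0 <= w <= 1.0 for w in ws)


class TestComposeAndDisplay:
    def test_elementwise_product(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0), "C": (3, 0)})
        weights = distance_weights(cents)
        raw = np.array([[0, 0.75, 0.5], [1.0, 0, 0.25], [2.0, 0.5, 0]])
        cts = compose_cts(raw, weights, ["A", "B", "C"])
        wmat = weights.weight_matrix(["A", "B", "C"])
        np.testing.assert_allclose(cts.cts, wmat * raw)
        np.testing.assert_allclose(cts.raw, raw)
        assert np.diag(cts.cts).sum() == 0.0

    def test_zero_raw_gives_zero_cts(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0)})
        cts = compose_cts(np.zeros((2, 2)), distance_weights(cents), ["A", "B"])
        assert not cts.cts.any()

    def test_shape_mismatch_rejected(self):
        cents = CentroidSet("v", {"A": (0, 0), "B": (1, 0)})
        with pytest.raises(ValueError, match="shape"):
            compose_cts(np.zeros((3, 3)), distance_weights(cents), ["A", "B"])

    def test_log2_display_values_and_masking(self):
        mat = np.array([[0.0, 8.0], [1.0, 0.0]])
        disp = log2_display(mat)
        assert disp[0, 1] == 3.0
        assert disp[1, 0] == 0.0
        assert np.isnan(disp[0, 0]) and np.isnan(disp[1, 1])

    def test_log2_display_preserves_order_of_positive_entries(self, rng):
        mat = rng.uniform(0.01, 100, (4, 4))
        np.fill_diagonal(mat, 0.0)
        disp = log2_display(mat)
        off = ~np.eye(4, dtype=bool)
        assert (np.argsort(mat[off]) == np.argsort(disp[off])).all()


def _pipeline_cts(arrows, cents, order):
    scores = score_arrows(arrows, cents)
    raw = sum_by_transition(scores, arrows, order)
    return compose_cts(raw, distance_weights(cents), order)


class TestSimilarityInvariance:
    def test_cts_invariant_under_rigid_motion_and_scaling(self, rng):
        """Rotating, translating and uniformly scaling arrows and centroids
        together leaves the CTS matrix unchanged to 1e-6 relative."""
        clusters = list("ABCD")
        arrows = random_arrows(rng, 30, clusters)
        cents = random_centroids(rng, clusters)
        base = _pipeline_cts(arrows, cents, clusters)
        for _ in range(50):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.1, 10)
            shift = rng.uniform(-100, 100, 2)
            tf = lambda p: tuple(scale * rot @ np.asarray(p) + shift)
            arrows_t = [
                VelocityArrow(a.view_id, tf(a.start), tf(a.end), a.start_cluster, a.n_cells)
                for a in arrows
            ]
            cents_t = CentroidSet(
                cents.view_id, {c: tf(cents[c]) for c in clusters}
            )
            got = _pipeline_cts(arrows_t, cents_t, clusters)
            np.testing.assert_allclose(got.cts, base.cts, rtol=1e-6, atol=1e-12)

    def test_cts_invariant_under_arrow_permutation(self, rng):
        clusters = ["A", "B", "C"]
        arrows = random_arrows(rng, 20, clusters)
        cents = random_centroids(rng, clusters)
        base = _pipeline_cts(arrows, cents, clusters)
        perm = list(rng.permutation(len(arrows)))
        shuffled = [arrows[i] for i in perm]
        got = _pipeline_cts(shuffled, cents, clusters)
        np.testing.assert_allclose(got.cts, base.cts, rtol=1e-12)


class TestCTSMatrixType:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            CTSMatrix(["A", "B"], np.array([[0, -1], [0, 0]]), np.zeros((2, 2)))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            CTSMatrix(["A", "B"], np.eye(2), np.zeros((2, 2)))

    def test_addition_requires_matching_labels(self):
        a = CTSMatrix(["A", "B"], np.zeros((2, 2)), np.zeros((2, 2)))
        b = CTSMatrix(["A", "C"], np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            a + b
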