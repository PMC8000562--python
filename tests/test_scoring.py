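"""Barycenters, confidence ellipses, acceptance classification, comparisons."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from acceptmap.scoring import (
    DIMENSION_PAIRS,
    ConfidenceEllipse,
    barycenter,
    classify,
    confidence_ellipse,
    ellipse_quantile,
    score_coordinates,
    score_set,
    scores_differ,
)
from acceptmap.simulate import generate_medicine


def isotropic_coords(n, rng, scale=1.0, center=(0.0, 0.0, 0.0)):
    return rng.normal(size=(n, 3)) * scale + np.asarray(center)


class TestBarycenter:
    def test_single_point(self):
        assert np.allclose(barycenter(np.array([[1.0, 2.0, 3.0]])), [1, 2, 3])

    def test_symmetric_points_cancel(self):
        x = np.array([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5]])
        assert np.allclose(barycenter(x), 0.0)

    def test_matches_summation_oracle(self, rng):
        coords = isotropic_coords(58, rng)
        manual = np.array([sum(coords[:, d]) / 58 for d in range(3)])
        assert np.allclose(barycenter(coords), manual, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            barycenter(np.empty((0, 3)))


class TestConfidenceEllipse:
    def test_area_shrinks_like_one_over_n(self, rng):
        """With the sample covariance held fixed, area scales as q(n)/n."""
        coords = isotropic_coords(100, rng)
        big = np.vstack([coords] * 4)  # same covariance (up to ddof), 4x n
        e1 = confidence_ellipse(coords, (0, 1))
        e4 = confidence_ellipse(big, (0, 1))
        S1 = np.cov(coords[:, :2], rowvar=False, ddof=1)
        S4 = np.cov(big[:, :2], rowvar=False, ddof=1)
        expected_ratio = (
            (ellipse_quantile(400) / ellipse_quantile(100))
            * np.sqrt(np.linalg.det(S4) / np.linalg.det(S1))
            / 4.0
        )
        assert e4.area / e1.area == pytest.approx(expected_ratio, abs=1e-9)
        assert e4.area / e1.area == pytest.approx(0.25, rel=0.05)

    def test_isotropic_closed_form(self):
        """Exact isotropic unit covariance: semi-axes are sqrt(q/n)."""
        n = 100
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.sqrt(2.0) * np.stack(
            [np.cos(theta), np.sin(theta), np.cos(2 * theta)], axis=1
        )
        pts[:, :2] *= np.sqrt((n - 1) / n)  # unbiased covariance exactly I
        e = confidence_ellipse(pts, (0, 1), level=0.90)
        q = 2.0 * 99 / 98 * f_dist.ppf(0.90, 2, 98)
        lengths = np.sqrt(np.linalg.eigvalsh(e.shape) * e.radius2)
        assert np.allclose(lengths, np.sqrt(q / n), atol=1e-9)

    def test_boundary_points_sit_on_boundary(self, rng):
        e = confidence_ellipse(isotropic_coords(50, rng), (1, 2))
        b = e.boundary(64)
        assert np.allclose(e.mahalanobis2(b), e.radius2, atol=1e-9)

    def test_degenerate_covariance_rejected(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="singular|degenerate"):
            confidence_ellipse(coords, (0, 1))


class FakeFramework:
    """Planar zone rule: green iff dim1 < boundary (mimics two centroids)."""

    def __init__(self, boundary=1.0):
        self.boundary = boundary

    def assign_zone(self, pts):
        pts = np.atleast_2d(pts)
        return np.where(pts[:, 0] < self.boundary, "green", "red")


class TestClassify:
    def test_small_ellipse_deep_in_green(self, rng):
        coords = isotropic_coords(200, rng, scale=0.05, center=(-2, 0, 0))
        score = score_coordinates(coords, framework=FakeFramework())
        assert score.zone == "green" and score.accepted

    def test_barycenter_in_red_rejected_regardless(self, rng):
        coords = isotropic_coords(200, rng, scale=0.01, center=(2, 0, 0))
        score = score_coordinates(coords, framework=FakeFramework())
        assert score.zone == "red" and not score.accepted

    def test_ellipse_straddling_boundary_rejected(self, rng):
        """Green barycenter but the dim-1 ellipses cross into red."""
        fw = FakeFramework(boundary=1.0)
        coords = isotropic_coords(40, rng, scale=2.0, center=(0.5, 0, 0))
        score = score_coordinates(coords, framework=fw)
        assert score.zone == "green"
        # dense boundary oracle agrees with the 360-point default
        dense = classify(score, fw, boundary_points=10_000)
        assert classify(score, fw) == dense == False  # noqa: E712

    def test_monotone_under_shrinkage(self, rng):
        """Shrinking an accepted score's ellipses never flips it."""
        fw = FakeFramework()
        coords = isotropic_coords(100, rng, scale=0.5, center=(-1, 0, 0))
        score = score_coordinates(coords, framework=fw)
        assert score.accepted
        for factor in (0.5, 0.1, 0.01):
            shrunk = score_coordinates(coords, framework=fw)
            shrunk.ellipses = {
                p: e.scaled(factor) for p, e in score.ellipses.items()
            }
            assert classify(shrunk, fw)

    def test_unreliable_below_30_warns_but_classifies(self, rng):
        coords = isotropic_coords(20, rng, center=(-2, 0, 0))
        with pytest.warns(UserWarning, match="unreliable"):
            score = score_coordinates(coords, framework=FakeFramework())
        assert not score.reliable
        assert score.accepted is not None


def tiny_ellipse(cx, cy, r=0.1):
    return ConfidenceEllipse(
        center=np.array([cx, cy]), shape=np.eye(2) * r**2, radius2=1.0
    )


def make_score(ellipses, center3=(0, 0, 0)):
    from acceptmap.scoring import AcceptabilityScore

    return AcceptabilityScore(
        n=50, barycenter=np.asarray(center3, float), ellipses=ellipses
    )


class TestScoresDiffer:
    def test_self_comparison_not_different(self, rng):
        coords = isotropic_coords(60, rng)
        s = score_coordinates(coords)
        assert not scores_differ(s, s)

    def test_far_separated_tiny_ellipses_differ(self):
        a = make_score({p: tiny_ellipse(0, 0) for p in DIMENSION_PAIRS})
        b = make_score({p: tiny_ellipse(10, 10) for p in DIMENSION_PAIRS}, (10, 10, 10))
        assert scores_differ(a, b)

    def test_overlap_in_one_pair_means_not_different(self):
        a = make_score({p: tiny_ellipse(0, 0) for p in DIMENSION_PAIRS})
        ells = {p: tiny_ellipse(10, 10) for p in DIMENSION_PAIRS}
        ells[(1, 2)] = tiny_ellipse(0.05, 0.0)  # overlaps a's in this pane
        b = make_score(ells)
        assert not scores_differ(a, b)

    def test_tangent_ellipses_touch(self):
        """Externally tangent circles share one point -> not different."""
        a = {p: tiny_ellipse(0.0, 0.0, r=1.0) for p in DIMENSION_PAIRS}
        b = {p: tiny_ellipse(2.0, 0.0, r=1.0) for p in DIMENSION_PAIRS}
        sa, sb = make_score(a), make_score(b, (2, 0, 0))
        assert not scores_differ(sa, sb)
        # dense boundary-sampling oracle agrees
        assert not scores_differ(sa, sb, n_boundary=20_000)

    def test_contained_ellipse_not_different(self):
        a = {p: tiny_ellipse(0.0, 0.0, r=5.0) for p in DIMENSION_PAIRS}
        b = {p: tiny_ellipse(0.5, 0.0, r=0.2) for p in DIMENSION_PAIRS}
        assert not scores_differ(make_score(a), make_score(b))


class TestScoreSet:
    def test_null_filter_equals_no_filter(self, framework):
        med = generate_medicine(n_patients=40, seed=3)
        s_all = score_set(med, framework)
        s_true = score_set(med, framework, where=lambda df: np.ones(len(df), bool))
        assert np.allclose(s_all.barycenter, s_true.barycenter)
        assert s_all.n == s_true.n

    def test_subgroup_barycenters_average_to_total(self, framework):
        med = generate_medicine(n_patients=40, seed=3)
        total = score_set(med, framework)
        parts = [
            score_set(med, framework, where={"timepoint": t}) for t in (1, 2, 3)
        ]
        weighted = sum(p.n * p.barycenter for p in parts) / sum(p.n for p in parts)
        assert np.allclose(weighted, total.barycenter, atol=1e-9)

    def test_row_order_invariance(self, framework):
        med = generate_medicine(n_patients=40, seed=5)
        shuffled = med.copy()
        perm = np.random.default_rng(0).permutation(len(med))
        shuffled.evaluations = med.evaluations.iloc[perm].reset_index(drop=True)
        shuffled.latent_profile = None
        a = score_set(med, framework)
        b = score_set(shuffled, framework)
        assert np.allclose(a.barycenter, b.barycenter, atol=1e-12)
        for p in DIMENSION_PAIRS:
            assert np.allclose(a.ellipses[p].shape, b.ellipses[p].shape, atol=1e-12)

    def test_empty_filter_rejected(self, framework):
        med = generate_medicine(n_patients=10, seed=6)
        with pytest.raises(ValueError, match="selects no evaluation"):
            score_set(med, framework, where={"timepoint": 99})

    def test_positive_medicine_accepted_end_to_end(self, framework):
        med = generate_medicine(n_patients=58, timepoints=(1, 2, 3), seed=12)
        score = score_set(med, framework)
        assert score.n == 174
        assert score.zone == "green"
        assert score.accepted
        assert score.reliable
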