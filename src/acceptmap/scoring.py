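"""Acceptability scoring: barycenters, confidence ellipses, classification.

A medicine (or a subgroup of its evaluations) is positioned on the
reference map at the *barycenter* — the unweighted mean — of its
evaluations' supplementary coordinates.  Uncertainty is shown per
dimension pair (1-2, 1-3, 2-3) as the 90% confidence ellipse of the mean,

    {x : (x - m)^T (S/n)^{-1} (x - m) <= q},

with m the barycenter restricted to the pair and S the unbiased 2x2
sample covariance.  Because S is estimated from the same n evaluations,
the squared radius q defaults to the Hotelling-T^2 quantile
2(n-1)/(n-2) * F_{2,n-2}(level), which delivers the nominal coverage in
finite samples; the asymptotic chi-square(2 df) quantile is available as
``method="chi2"`` but undercovers at study-sized n.  The ellipse area
shrinks as 1/n, so homogeneous, well-replicated medicines get tight
ellipses.

The medicine is classified as *accepted* when the barycenter and the
entire boundary of each of the three ellipses (third coordinate held at
the barycenter) lie in the green zone of the map.  Two scores differ
significantly when their ellipses are disjoint in every dimension pair.
A score based on fewer than 30 patients is flagged unreliable (computed
anyway, with a warning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, f as f_dist

from .mca import build_indicator
from .schema import EvaluationSet

__all__ = [
    "AcceptabilityScore",
    "ConfidenceEllipse",
    "barycenter",
    "classify",
    "confidence_ellipse",
    "score_set",
    "scores_differ",
]

DIMENSION_PAIRS = ((0, 1), (0, 2), (1, 2))
RELIABLE_N = 30


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Ellipse {x : (x-center)^T shape^{-1} (x-center) <= radius2}."""

    center: np.ndarray  # (2,)
    shape: np.ndarray  # (2, 2) SPD, covariance of the mean
    radius2: float

    def __post_init__(self):
        eigvals = np.linalg.eigvalsh(self.shape)
        if eigvals.min() <= 0:
            raise ValueError("degenerate ellipse: shape matrix is singular")

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        sol = np.linalg.solve(self.shape, pts.T)
        return np.einsum("ij,ji->i", pts, sol)

    def contains(self, points: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        """Inclusive membership; tangent points count as contained."""
        inside = self.mahalanobis2(points) <= self.radius2 * (1.0 + rtol)
        return inside if np.asarray(points).ndim > 1 else bool(inside[0])

    def boundary(self, n_points: int = 360) -> np.ndarray:
        """Uniformly-in-angle sample of the ellipse boundary."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        L = np.linalg.cholesky(self.shape)
        return self.center + np.sqrt(self.radius2) * circle @ L.T

    @property
    def area(self) -> float:
        return np.pi * self.radius2 * float(np.sqrt(np.linalg.det(self.shape)))

    def scaled(self, factor: float) -> "ConfidenceEllipse":
        """Ellipse with semi-axes multiplied by ``factor`` (same center)."""
        return ConfidenceEllipse(self.center, self.shape, self.radius2 * factor**2)


@dataclass
class AcceptabilityScore:
    n: int
    barycenter: np.ndarray  # (3,)
    ellipses: dict[tuple[int, int], ConfidenceEllipse]
    level: float = 0.90
    zone: str | None = None
    accepted: bool | None = None
    label: str = ""
    filters: dict = field(default_factory=dict)

    @property
    def reliable(self) -> bool:
        return self.n >= RELIABLE_N

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "barycenter": self.barycenter.tolist(),
            "level": self.level,
            "zone": self.zone,
            "accepted": self.accepted,
            "reliable": self.reliable,
            "filters": {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in self.filters.items()
            },
            "ellipses": {
                f"{i + 1}-{j + 1}": {
                    "center": e.center.tolist(),
                    "shape": e.shape.tolist(),
                    "radius2": e.radius2,
                }
                for (i, j), e in self.ellipses.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def barycenter(coords: np.ndarray) -> np.ndarray:
    """Unweighted mean map position of a set of evaluations."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot compute the barycenter of an empty set")
    return coords.mean(axis=0)


def ellipse_quantile(n: int, level: float = 0.90, method: str = "hotelling") -> float:
    """Squared radius of the barycenter ellipse for a sample of size n."""
    if method == "hotelling":
        return float(2.0 * (n - 1) / (n - 2) * f_dist.ppf(level, 2, n - 2))
    if method == "chi2":
        return float(chi2.ppf(level, df=2))
    raise ValueError(f"unknown ellipse method {method!r}")


def confidence_ellipse(
    coords: np.ndarray,
    pair: tuple[int, int],
    level: float = 0.90,
    method: str = "hotelling",
) -> ConfidenceEllipse:
    """Confidence ellipse of the barycenter in one dimension pair."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if n < 3:
        raise ValueError(f"need at least 3 evaluations for an ellipse, got {n}")
    sub = coords[:, list(pair)]
    m = sub.mean(axis=0)
    S = np.cov(sub, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S) < 2 or np.linalg.det(S) <= 0:
        raise ValueError("degenerate ellipse: sample covariance is singular")
    return ConfidenceEllipse(
        center=m, shape=S / n, radius2=ellipse_quantile(n, level, method)
    )


def classify(
    score: AcceptabilityScore, framework, boundary_points: int = 360
) -> bool:
    """Accepted iff barycenter and all ellipse boundaries lie in green.

    Each 2D ellipse is tested in its own map pane, with the third
    coordinate held at the barycenter's value.
    """
    zones = framework.assign_zone(score.barycenter[None, :])
    if zones[0] != "green":
        return False
    for pair, ellipse in score.ellipses.items():
        pts2d = ellipse.boundary(boundary_points)
        pts3d = np.tile(score.barycenter, (len(pts2d), 1))
        pts3d[:, pair[0]] = pts2d[:, 0]
        pts3d[:, pair[1]] = pts2d[:, 1]
        if np.any(framework.assign_zone(pts3d) != "green"):
            return False
    return True


def _ellipses_overlap(
    a: ConfidenceEllipse, b: ConfidenceEllipse, n_boundary: int = 720
) -> bool:
    """Numeric overlap test: containment of centers or boundary crossing."""
    if a.contains(b.center[None, :])[0] or b.contains(a.center[None, :])[0]:
        return True
    if np.any(b.contains(a.boundary(n_boundary))):
        return True
    return bool(np.any(a.contains(b.boundary(n_boundary))))


def scores_differ(
    a: AcceptabilityScore, b: AcceptabilityScore, n_boundary: int = 720
) -> bool:
    """Two scores differ iff their ellipses are disjoint in EVERY pair."""
    for pair in DIMENSION_PAIRS:
        if _ellipses_overlap(a.ellipses[pair], b.ellipses[pair], n_boundary):
            return False
    return True


def score_coordinates(
    coords: np.ndarray,
    framework=None,
    level: float = 0.90,
    boundary_points: int = 360,
    label: str = "",
    filters: dict | None = None,
    method: str = "hotelling",
) -> AcceptabilityScore:
    """Score a set of already-projected 3D coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m = barycenter(coords)
    ellipses = {
        pair: confidence_ellipse(coords, pair, level, method) for pair in DIMENSION_PAIRS
    }
    score = AcceptabilityScore(
        n=len(coords),
        barycenter=m,
        ellipses=ellipses,
        level=level,
        label=label,
        filters=filters or {},
    )
    if not score.reliable:
        warnings.warn(
            f"acceptability score based on n={score.n} < {RELIABLE_N} evaluations "
            "is flagged unreliable",
            stacklevel=2,
        )
    if framework is not None:
        score.zone = str(framework.assign_zone(m[None, :])[0])
        score.accepted = classify(score, framework, boundary_points)
    return score


def _resolve_filter(evalset: EvaluationSet, where) -> np.ndarray:
    if where is None:
        return np.ones(len(evalset), dtype=bool)
    joined = evalset.with_age_groups()
    if callable(where):
        mask = np.asarray(where(joined), dtype=bool)
    else:
        mask = np.ones(len(joined), dtype=bool)
        for key, value in where.items():
            if key not in joined.columns:
                raise KeyError(f"unknown filter field {key!r}")
            mask &= (joined[key] == value).to_numpy()
    if not mask.any():
        raise ValueError(f"filter {where!r} selects no evaluation")
    return mask


def score_set(
    evalset: EvaluationSet,
    framework,
    where=None,
    level: float = 0.90,
    boundary_points: int = 360,
    label: str = "",
) -> AcceptabilityScore:
    """Impute (if needed), project as supplementary, and score a set.

    ``where`` is either a callable predicate on the evaluations joined
    with metadata (plus a derived ``age_group`` column), or a dict of
    equality filters, e.g. ``{"timepoint": 1}`` or
    ``{"age_group": "3-5"}``.
    """
    mask = _resolve_filter(evalset, where)
    subset = evalset.subset(mask)
    if subset.n_missing_cells:
        from .impute import impute  # local import avoids a cycle

        fuzzy = impute(subset).fuzzy_indicator
    else:
        fuzzy = build_indicator(subset)
    coords = framework.project(fuzzy)
    filt = {} if where is None or callable(where) else dict(where)
    return score_coordinates(
        coords,
        framework=framework,
        level=level,
        boundary_points=boundary_points,
        label=label,
        filters=filt,
    )
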