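"""Background ("ground") motion between frame pairs from point correspondences.

A nadir view of a flat ground plane relates consecutive frames by a plane
projective transform (homography).  This module provides the three stages the
pipeline needs: mutual nearest-neighbour descriptor matching under the angular
distance, least-squares homography fitting (normalized direct linear
transform), and RANSAC robust estimation with refit on the consensus set.
Keypoint detection and descriptor computation are external: any detector
producing (x, y, descriptor-vector) records can feed :func:`mutual_match`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .camera import InvalidInputError

__all__ = [
    "EstimationError",
    "SingularConfigurationError",
    "Correspondence",
    "Homography",
    "RansacParams",
    "mutual_match",
    "fit_homography",
    "ransac_homography",
    "background_shift",
]

logger = logging.getLogger("walkspeed")


class EstimationError(RuntimeError):
    """Robust estimation failed to produce a usable model."""


class SingularConfigurationError(EstimationError):
    """The correspondence configuration is degenerate (e.g. collinear points)."""


@dataclass(frozen=True)
class Correspondence:
    """A matched pixel pair between an earlier frame (a) and a later frame (b)."""

    point_a: tuple[float, float]
    point_b: tuple[float, float]
    score: float | None = None

    def __post_init__(self) -> None:
        for p in (self.point_a, self.point_b):
            if not np.all(np.isfinite(p)):
                raise InvalidInputError(f"non-finite correspondence point {p}")


@dataclass(frozen=True)
class Homography:
    """3×3 map from earlier-frame pixels to later-frame pixels.

    The matrix is normalized so its bottom-right entry is 1.  ``inlier_mask``
    and ``n_inliers`` are populated by :func:`ransac_homography`;
    ``consensus_ok`` is False when the inlier count fell short of the
    configured consensus size (a warning, not an error).
    """

    matrix: np.ndarray
    inlier_mask: np.ndarray | None = None
    n_inliers: int | None = None
    consensus_ok: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidInputError(f"homography matrix must be 3x3, got {m.shape}")
        if abs(m[2, 2]) < 1e-300:
            raise SingularConfigurationError("homography has zero bottom-right entry")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map pixel points (shape (2,) or (n, 2)) through the homography."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([p, np.ones((p.shape[0], 1))]) @ self.matrix.T
        w = hom[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise EstimationError("point maps to infinity under the homography")
        out = hom[:, :2] / w[:, None]
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, earlier: "Homography") -> "Homography":
        """Return the map ``self ∘ earlier`` (apply ``earlier`` first)."""
        return Homography(self.matrix @ earlier.matrix)


@dataclass(frozen=True)
class RansacParams:
    """RANSAC configuration.

    ``residual_threshold`` is the squared symmetric transfer error in px²
    (the default 7e3 corresponds to roughly 59 px one-way); ``min_fit_points``
    is a precondition on the input set size, while each iteration samples a
    4-point minimal set.  ``min_consensus`` flags — without failing — models
    whose support is smaller than expected for a textured ground scene.
    ``confidence`` enables standard adaptive early termination; set it to 1.0
    to always run ``max_iterations``.
    """

    min_fit_points: int = 50
    max_iterations: int = 5000
    residual_threshold: float = 7e3
    min_consensus: int = 300
    seed: int = 0
    confidence: float = 0.999

    def __post_init__(self) -> None:
        if self.min_fit_points < 4:
            raise InvalidInputError("min_fit_points must be >= 4")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if not self.residual_threshold > 0:
            raise InvalidInputError("residual_threshold must be positive")
        if not 0.0 < self.confidence <= 1.0:
            raise InvalidInputError("confidence must be in (0, 1]")


# ---------------------------------------------------------------------------
# Mutual nearest-neighbour matching under the angular distance
# ---------------------------------------------------------------------------

def _angular_distance_matrix(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Pairwise angle (radians) between descriptor vectors of two sets."""
    na = np.linalg.norm(da, axis=1, keepdims=True)
    nb = np.linalg.norm(db, axis=1, keepdims=True)
    cos = (da / na) @ (db / nb).T
    return np.arccos(np.clip(cos, -1.0, 1.0))


def mutual_match(
    descriptors_a: np.ndarray,
    descriptors_b: np.ndarray,
    keypoints_a: np.ndarray,
    keypoints_b: np.ndarray,
) -> list[Correspondence]:
    """Bidirectional nearest-neighbour matching.

    A pair (i, j) is kept only when j is i's nearest neighbour among set b
    *and* i is j's nearest neighbour among set a, under the angular distance
    (angle between descriptor vectors).  Zero-norm descriptors are skipped
    with a warning.  The returned ``score`` is the match angle in radians.
    """
    da = np.asarray(descriptors_a, dtype=float)
    db = np.asarray(descriptors_b, dtype=float)
    ka = np.asarray(keypoints_a, dtype=float)
    kb = np.asarray(keypoints_b, dtype=float)
    if da.size == 0 or db.size == 0:
        return []
    if da.shape[1] != db.shape[1]:
        raise InvalidInputError("descriptor sets have different dimensions")

    valid_a = np.linalg.norm(da, axis=1) > 0
    valid_b = np.linalg.norm(db, axis=1) > 0
    if not valid_a.all() or not valid_b.all():
        warnings.warn("zero-norm descriptors skipped in mutual_match", stacklevel=2)
    idx_a = np.flatnonzero(valid_a)
    idx_b = np.flatnonzero(valid_b)
    if idx_a.size == 0 or idx_b.size == 0:
        return []

    dist = _angular_distance_matrix(da[idx_a], db[idx_b])
    best_b = np.argmin(dist, axis=1)  # for each a, its NN in b
    best_a = np.argmin(dist, axis=0)  # for each b, its NN in a
    mutual = best_a[best_b] == np.arange(idx_a.size)

    matches = []
    for i in np.flatnonzero(mutual):
        j = best_b[i]
        matches.append(
            Correspondence(
                point_a=tuple(ka[idx_a[i]]),
                point_b=tuple(kb[idx_b[j]]),
                score=float(dist[i, j]),
            )
        )
    return matches


# ---------------------------------------------------------------------------
# Homography fitting (normalized direct linear transform)
# ---------------------------------------------------------------------------

def _as_arrays(correspondences) -> tuple[np.ndarray, np.ndarray]:
    pa = np.array([c.point_a for c in correspondences], dtype=float)
    pb = np.array([c.point_b for c in correspondences], dtype=float)
    return pa, pb


def _normalise(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalisation: zero centroid, mean distance √2."""
    centroid = points.mean(axis=0)
    d = np.linalg.norm(points - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 1e-12 else 1.0
    t = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]])
    ones = np.ones((points.shape[0], 1))
    return (np.hstack([points, ones]) @ t.T)[:, :2], t


def _dlt(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    n = pa.shape[0]
    a = np.zeros((2 * n, 9))
    x, y = pa[:, 0], pa[:, 1]
    u, v = pb[:, 0], pb[:, 1]
    a[0::2, 0] = -x
    a[0::2, 1] = -y
    a[0::2, 2] = -1
    a[0::2, 6] = u * x
    a[0::2, 7] = u * y
    a[0::2, 8] = u
    a[1::2, 3] = -x
    a[1::2, 4] = -y
    a[1::2, 5] = -1
    a[1::2, 6] = v * x
    a[1::2, 7] = v * y
    a[1::2, 8] = v
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-9 * max(s[0], 1.0):
        raise SingularConfigurationError("degenerate correspondence configuration")
    return vt[-1].reshape(3, 3)


def fit_homography(correspondences) -> Homography:
    """Least-squares homography through ≥4 correspondences (normalized DLT).

    Exact (to numerical precision) when the correspondences are noise-free and
    consistent with a projective map; raises
    :class:`SingularConfigurationError` for degenerate configurations such as
    three collinear points on either side.
    """
    if len(correspondences) < 4:
        raise InvalidInputError("at least 4 correspondences are required")
    pa, pb = _as_arrays(correspondences)
    na, ta = _normalise(pa)
    nb, tb = _normalise(pb)
    h_norm = _dlt(na, nb)
    h = np.linalg.inv(tb) @ h_norm @ ta
    if abs(h[2, 2]) < 1e-12 * np.abs(h).max():
        raise SingularConfigurationError("fit produced a singular homography")
    return Homography(h)


def symmetric_transfer_error(h: Homography, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Squared symmetric transfer error per correspondence, in px²."""
    fwd = h.apply(pa)
    bwd = Homography(np.linalg.inv(h.matrix)).apply(pb)
    return ((fwd - pb) ** 2).sum(axis=1) + ((bwd - pa) ** 2).sum(axis=1)


# ---------------------------------------------------------------------------
# RANSAC
# ---------------------------------------------------------------------------

def ransac_homography(correspondences, params: RansacParams | None = None) -> Homography:
    """Robust homography via RANSAC with 4-point minimal samples.

    Iteratively fits homographies to random minimal samples, scores them by
    the squared symmetric transfer error, keeps the largest consensus set and
    refits on it by least squares.  Deterministic given ``params.seed``.  When
    the final inlier count is below ``params.min_consensus`` the model is
    returned with ``consensus_ok=False`` and a log warning.
    """
    params = params or RansacParams()
    n = len(correspondences)
    if n < params.min_fit_points:
        raise InvalidInputError(
            f"need at least {params.min_fit_points} correspondences, got {n}"
        )
    pa, pb = _as_arrays(correspondences)
    rng = np.random.Generator(np.random.PCG64(params.seed))

    best_mask: np.ndarray | None = None
    best_count = 0
    best_err = np.inf
    max_iter = params.max_iterations
    it = 0
    while it < max_iter:
        it += 1
        sample = rng.choice(n, size=4, replace=False)
        try:
            cand = fit_homography([correspondences[i] for i in sample])
            err = symmetric_transfer_error(cand, pa, pb)
        except (SingularConfigurationError, EstimationError):
            continue
        mask = err <= params.residual_threshold
        count = int(mask.sum())
        mean_err = float(err[mask].mean()) if count else np.inf
        if count > best_count or (count == best_count and mean_err < best_err):
            best_mask, best_count, best_err = mask, count, mean_err
            if params.confidence < 1.0 and count >= 4:
                # adaptive stopping: enough iterations that a pure-inlier
                # 4-point sample was drawn with the requested confidence
                w = count / n
                denom = np.log1p(-min(w**4, 1 - 1e-12))
                needed = int(np.ceil(np.log(1 - params.confidence) / denom))
                max_iter = min(params.max_iterations, max(needed, it))

    if best_mask is None or best_count < 4:
        raise EstimationError("RANSAC found no model with at least 4 inliers")

    refit = fit_homography([c for c, m in zip(correspondences, best_mask) if m])
    err = symmetric_transfer_error(refit, pa, pb)
    mask = err <= params.residual_threshold
    # keep the refit's (possibly larger) support unless it lost inliers
    if int(mask.sum()) < best_count:
        mask = best_mask
    count = int(mask.sum())
    ok = count >= params.min_consensus
    if not ok:
        logger.warning(
            "homography consensus below threshold: %d inliers < %d",
            count,
            params.min_consensus,
        )
    return Homography(refit.matrix, inlier_mask=mask, n_inliers=count, consensus_ok=ok)


def background_shift(h: Homography, point) -> np.ndarray:
    """Local image-plane ground motion at ``point``: ``h(point) − point``.

    This is the vector-valued panning distance of the ground evaluated at a
    pedestrian's image location.
    """
    p = np.asarray(point, dtype=float)
    return h.apply(p) - p
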