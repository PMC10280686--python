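"""Walking-speed estimation from tracks and background homographies.

The measurement chain per stride of ``n`` frames:

1. ground-referenced image displacement ``S2 = X2 − H(X1)`` where ``H`` is the
   background homography between the two frames (the vector form of
   "ground panning minus image motion");
2. raw pixel speed ``vm' = ‖S2‖ · fps / n`` and metric speed
   ``vm = (L/M) · vm'`` via the ground sampling distance;
3. relief-displacement correction: a head at height ``h`` seen from altitude
   ``H`` is displaced radially outward by ``δ = r·h/H`` (``r`` the signed
   image distance from the centre along the flight axis), so the spurious
   speed contribution is ``vc = (r2−r1)·h·fps·L·cosθ / (n·H·M)`` with ``θ``
   the angle between the flight axis and the walking direction; the corrected
   speed is ``vm − vc``, clamped at zero.

The relief term is projected onto the walking direction: when the pedestrian's
ground-referenced image motion points against the flight axis (drone
overtaking, or walking towards the drone), the roles of ``r1``/``r2`` swap so
the correction keeps the sign of the bias it removes.  With this projection
the correction is exact for straight-line motion in an ideal central
projection, whichever direction the drone flies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .camera import CameraModel, FlightState, GroundFootprint, InvalidInputError
from .ground_motion import Homography

__all__ = [
    "TrackPoint",
    "Track",
    "PedestrianModel",
    "SpeedEstimate",
    "TrackSummary",
    "relative_displacement",
    "raw_speed_px",
    "to_mps",
    "image_point_displacement",
    "heading_angle",
    "speed_correction",
    "corrected_track_speed",
    "stride_homography",
]

logger = logging.getLogger("walkspeed")


@dataclass(frozen=True)
class TrackPoint:
    """One pedestrian observation: frame, identity and bounding box.

    ``bbox`` is (x, y, width, height) in pixels.  By default ``x, y`` is the
    box's top-left corner (MOT convention) and the pedestrian's image position
    is the box centre; pass an explicit ``center`` to override (e.g. for
    trackers that emit centre coordinates).
    """

    frame_index: int
    track_id: int
    bbox: tuple[float, float, float, float]
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InvalidInputError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise InvalidInputError(f"bbox width/height must be positive, got {self.bbox}")
        if self.center is None:
            x, y, w, h = self.bbox
            object.__setattr__(self, "center", (x + w / 2.0, y + h / 2.0))


@dataclass(frozen=True)
class Track:
    """Ordered per-frame observations of one identity."""

    track_id: int
    points: tuple[TrackPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        frames = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise InvalidInputError(f"track {self.track_id}: frame indices must strictly increase")
        if any(p.track_id != self.track_id for p in self.points):
            raise InvalidInputError(f"track {self.track_id}: mixed track ids")

    def __len__(self) -> int:
        return len(self.points)

    def by_frame(self) -> dict[int, TrackPoint]:
        return {p.frame_index: p for p in self.points}


@dataclass(frozen=True)
class PedestrianModel:
    """Assumed pedestrian height used by the relief correction (metres)."""

    height_m: float = 1.7

    def __post_init__(self) -> None:
        if self.height_m < 0:
            raise InvalidInputError(f"height_m must be >= 0, got {self.height_m}")


@dataclass(frozen=True)
class SpeedEstimate:
    """Raw and corrected speed over one stride, with the correction terms."""

    track_id: int
    frame_start: int
    frame_interval: int
    displacement_px: tuple[float, float]
    raw_speed_px_s: float
    raw_speed_m_s: float
    r1: float
    r2: float
    delta1: float
    delta2: float
    theta_deg: float
    correction_m_s: float
    corrected_speed_m_s: float
    clamped: bool = False
    degenerate_heading: bool = False


@dataclass(frozen=True)
class TrackSummary:
    """Per-track aggregate: the median of per-stride corrected speeds."""

    track_id: int
    n_strides: int
    median_corrected_m_s: float
    median_raw_m_s: float
    any_clamped: bool


def relative_displacement(p1: TrackPoint, p2: TrackPoint, h: Homography) -> np.ndarray:
    """Pedestrian image motion with the background motion removed (``S2``).

    Returns ``p2.center − h(p1.center)``; ``h`` must map p1's frame to p2's
    frame.  Reduces to the scalar ground-panning-minus-image-distance form for
    collinear motion while staying sign-correct in general.
    """
    if p1.track_id != p2.track_id:
        raise InvalidInputError(f"mismatched track ids {p1.track_id} != {p2.track_id}")
    x1 = np.asarray(p1.center, dtype=float)
    x2 = np.asarray(p2.center, dtype=float)
    return x2 - h.apply(x1)


def raw_speed_px(displacement, n: int, fps: float) -> float:
    """Pixel speed ``‖S2‖ / n · fps`` over a stride of ``n`` frames."""
    if n < 1:
        raise InvalidInputError(f"stride n must be >= 1, got {n}")
    return float(np.linalg.norm(np.asarray(displacement, dtype=float))) / n * fps


def to_mps(speed_px: float, footprint: GroundFootprint) -> float:
    """Convert a pixel speed to metres per second via the scale ``L / M``."""
    return footprint.metres_per_pixel * speed_px


def image_point_displacement(r: float, ped: PedestrianModel, flight: FlightState) -> float:
    """Relief displacement ``δ = r·h/H`` of a head image point, in pixels.

    ``r`` is the signed image distance from the projection point to the image
    centre along the flight axis (positive on the flight-direction side); the
    displacement keeps the sign of ``r`` (radially outward).
    """
    if ped.height_m >= flight.altitude_m:
        raise InvalidInputError("pedestrian height must be below the flight altitude")
    return r * ped.height_m / flight.altitude_m


def heading_angle(point, camera: CameraModel, axis=None) -> float:
    """Angle (degrees, in [0, 90]) between the flight axis and ``point``'s
    direction from the image centre: ``θ = arctan(|lateral| / |axial|)``.

    Computed with a two-argument arctangent so a point level with the centre
    yields 90°.  A point exactly at the centre is degenerate and returns 0
    (logged).  The same formula applied to a displacement vector (via a point
    offset from the centre by that vector) gives the walking-direction angle.
    """
    from .camera import FlightAxis

    axis = FlightAxis(axis) if axis is not None else FlightAxis.UP
    delta = np.asarray(point, dtype=float) - np.asarray(camera.centre)
    axial = float(delta @ np.asarray(axis.forward))
    lateral = float(delta @ np.asarray(axis.lateral))
    if axial == 0.0 and lateral == 0.0:
        logger.debug("heading_angle: point at image centre, returning 0")
        return 0.0
    return math.degrees(math.atan2(abs(lateral), abs(axial)))


def speed_correction(
    r1: float,
    r2: float,
    ped: PedestrianModel,
    n: int,
    camera: CameraModel,
    flight: FlightState,
    footprint: GroundFootprint,
    theta_deg: float,
) -> float:
    """Relief-displacement speed correction (m/s).

    ``vc = (r2 − r1) · h · fps · L · cos θ / (n · H · M)`` — the rate of change
    of the head's relief displacement, converted to metres and projected onto
    the walking direction.
    """
    if n < 1:
        raise InvalidInputError(f"stride n must be >= 1, got {n}")
    if ped.height_m >= flight.altitude_m:
        raise InvalidInputError("pedestrian height must be below the flight altitude")
    return (
        (r2 - r1)
        * ped.height_m
        * camera.fps
        * footprint.length_m
        * math.cos(math.radians(theta_deg))
        / n
        / flight.altitude_m
        / camera.image_width_px
    )


def stride_homography(
    homographies: Mapping[tuple[int, int], Homography], f1: int, f2: int
) -> Homography:
    """Background homography from frame ``f1`` to ``f2``.

    Uses a direct entry when present, otherwise composes consecutive
    frame-pair homographies ``(f1, f1+1), …, (f2−1, f2)``.  Raises
    ``KeyError`` when a pair in the chain is missing.
    """
    if (f1, f2) in homographies:
        return homographies[(f1, f2)]
    h = None
    for f in range(f1, f2):
        step = homographies[(f, f + 1)]
        h = step if h is None else step.compose(h)
    if h is None:
        raise KeyError((f1, f2))
    return h


def corrected_track_speed(
    track: Track,
    homographies: Mapping[tuple[int, int], Homography],
    *,
    camera: CameraModel,
    flight: FlightState,
    footprint: GroundFootprint,
    ped: PedestrianModel,
    stride_n: int | None = None,
) -> tuple[list[SpeedEstimate], TrackSummary | None]:
    """Per-stride raw and corrected speeds for one track, plus the summary.

    Strides span ``stride_n`` frames (default one second, ``n = fps``)
    starting at the track's first frame.  Strides whose endpoints or
    background homographies are missing are skipped and logged.  Tracks
    shorter than one stride yield an empty list and no summary.
    """
    n = int(stride_n) if stride_n is not None else int(round(camera.fps))
    if n < 1:
        raise InvalidInputError(f"stride n must be >= 1, got {n}")
    by_frame = track.by_frame()
    frames = [p.frame_index for p in track.points]
    if not frames or frames[-1] - frames[0] < n:
        logger.warning("track %d shorter than one stride of %d frames", track.track_id, n)
        return [], None

    axis = flight.flight_axis
    forward = np.asarray(axis.forward)
    lateral = np.asarray(axis.lateral)
    centre = np.asarray(camera.centre)
    h_over_h = ped.height_m / flight.altitude_m

    estimates: list[SpeedEstimate] = []
    for f_start in range(frames[0], frames[-1] - n + 1, n):
        f_end = f_start + n
        p1 = by_frame.get(f_start)
        p2 = by_frame.get(f_end)
        if p1 is None or p2 is None:
            logger.debug("track %d: missing endpoint for stride %d-%d", track.track_id, f_start, f_end)
            continue
        try:
            h = stride_homography(homographies, f_start, f_end)
        except KeyError:
            logger.warning("track %d: missing homography for %d-%d, stride skipped", track.track_id, f_start, f_end)
            continue

        s2 = relative_displacement(p1, p2, h)
        vpx = raw_speed_px(s2, n, camera.fps)
        vm = to_mps(vpx, footprint)

        x1 = np.asarray(p1.center) - centre
        x2 = np.asarray(p2.center) - centre
        r1 = float(x1 @ forward)
        r2 = float(x2 @ forward)
        s_axial = float(s2 @ forward)
        s_lat = float(s2 @ lateral)
        degenerate = s_axial == 0.0 and s_lat == 0.0
        theta = 0.0 if degenerate else math.degrees(math.atan2(abs(s_lat), abs(s_axial)))
        # project the relief term onto the walking direction
        ra, rb = (r2, r1) if s_axial < 0 else (r1, r2)
        vc = speed_correction(ra, rb, ped, n, camera, flight, footprint, theta)
        corrected = vm - vc
        clamped = corrected < 0
        estimates.append(
            SpeedEstimate(
                track_id=track.track_id,
                frame_start=f_start,
                frame_interval=n,
                displacement_px=(float(s2[0]), float(s2[1])),
                raw_speed_px_s=vpx,
                raw_speed_m_s=vm,
                r1=r1,
                r2=r2,
                delta1=r1 * h_over_h,
                delta2=r2 * h_over_h,
                theta_deg=theta,
                correction_m_s=vc,
                corrected_speed_m_s=max(corrected, 0.0),
                clamped=clamped,
                degenerate_heading=degenerate,
            )
        )

    if not estimates:
        return [], None
    summary = TrackSummary(
        track_id=track.track_id,
        n_strides=len(estimates),
        median_corrected_m_s=float(np.median([e.corrected_speed_m_s for e in estimates])),
        median_raw_m_s=float(np.median([e.raw_speed_m_s for e in estimates])),
        any_clamped=any(e.clamped for e in estimates),
    )
    return estimates, summary
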