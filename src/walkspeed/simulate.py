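"""Synthetic ground-truth scenes: pedestrians + moving nadir camera + features.

The simulator builds an ideal central-projection world on a flat ground
plane: pedestrians of known height walk in straight lines at constant speed
while the camera translates overhead at a configurable (optionally swaying)
speed.  It emits exactly the artefacts the pipeline consumes — a six-column
track file of head bounding boxes, per-consecutive-frame ground-feature
correspondences with Gaussian pixel noise and a gross-outlier fraction, and a
ground-truth table — so `simulate → estimate → evaluate` closes the loop
without any footage.

Projection geometry: a world point at elevation ``z`` and horizontal offset
``Δ`` from the nadir appears at ``centre + Δ·k·H/(H−z)`` pixels, with
``k = M/L`` the ground-plane pixel scale.  A head at height ``h`` above a
ground point imaged at radial distance ``r_ground`` is therefore displaced
outward by exactly ``r_head·h/H`` — the same identity the speed correction
inverts, which is what makes the simulator a fair oracle for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camera import CameraModel, FlightAxis, FlightState, InvalidInputError, ground_footprint
from .speed import Track, TrackPoint

__all__ = [
    "PedestrianSpec",
    "SceneConfig",
    "WorldPoint",
    "SyntheticDataset",
    "project",
    "simulate_scene",
    "random_pedestrians",
    "error_summary",
    "ErrorSummary",
    "load_scene_config",
]

#: ground half-width (m) of the simulated street, lateral to the flight line
DEFAULT_STREET_HALF_WIDTH_M = 7.5
#: shoulder width (m) used to size the synthetic head bounding boxes
BBOX_WIDTH_M = 0.5


@dataclass(frozen=True)
class PedestrianSpec:
    """One simulated pedestrian.

    ``direction_deg`` is the walking direction in the ground plane relative
    to the flight direction (0 = with the camera, 180 = against it);
    ``start_u``/``start_v`` are metres along/lateral to the flight line,
    relative to the camera's initial nadir point.
    """

    height_m: float = 1.7
    speed_m_s: float = 1.0
    direction_deg: float = 0.0
    start_u: float = 0.0
    start_v: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_m_s < 0:
            raise InvalidInputError("pedestrian speed must be >= 0")
        if self.height_m < 0:
            raise InvalidInputError("pedestrian height must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Scene description: camera, flight profile, pedestrians, noise.

    ``drone_speed_m_s`` is either a constant or a list of ``(duration_s,
    speed)`` segments (piecewise-constant profile).  ``lateral_jitter_m`` is
    the amplitude of a slow sinusoidal sway emulating wind drift.  Noise
    defaults mirror the study conditions: 1 px Gaussian error on head and
    feature positions and a 20% gross-outlier fraction among the feature
    matches.
    """

    camera: CameraModel = field(default_factory=CameraModel)
    altitude_m: float = 40.0
    flight_axis: FlightAxis = FlightAxis.UP
    drone_speed_m_s: float | tuple = 3.0
    lateral_jitter_m: float = 0.0
    jitter_period_s: float = 5.0
    duration_s: float = 10.0
    pedestrians: tuple[PedestrianSpec, ...] = ()
    feature_count: int = 500
    pixel_noise_sigma: float = 1.0
    outlier_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "flight_axis", FlightAxis(self.flight_axis))
        object.__setattr__(self, "pedestrians", tuple(self.pedestrians))
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise InvalidInputError("outlier_fraction must be in [0, 1)")
        if self.pixel_noise_sigma < 0:
            raise InvalidInputError("pixel_noise_sigma must be >= 0")
        for p in self.pedestrians:
            if p.height_m >= self.altitude_m:
                raise InvalidInputError("pedestrian height must be below the altitude")

    @property
    def flight(self) -> FlightState:
        return FlightState(altitude_m=self.altitude_m, flight_axis=self.flight_axis)

    def speed_segments(self) -> list[tuple[float, float]]:
        if isinstance(self.drone_speed_m_s, (int, float)):
            return [(self.duration_s, float(self.drone_speed_m_s))]
        return [(float(d), float(s)) for d, s in self.drone_speed_m_s]


@dataclass(frozen=True)
class WorldPoint:
    """A point in the ground-plane world frame (metres along/lateral, elevation)."""

    u: float
    v: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if self.elevation < 0:
            raise InvalidInputError("elevation must be >= 0")

    def radial_distance(self, nadir_u: float, nadir_v: float) -> float:
        """Ground radial distance R from the nadir point, metres."""
        return math.hypot(self.u - nadir_u, self.v - nadir_v)

    def ground_differential(self, nadir_u: float, nadir_v: float, altitude_m: float) -> float:
        """Relief ground differential ``Δh = R·h/(H−h)``, metres."""
        if self.elevation >= altitude_m:
            raise InvalidInputError("elevation must be below the altitude")
        r = self.radial_distance(nadir_u, nadir_v)
        return r * self.elevation / (altitude_m - self.elevation)


def project(
    world: WorldPoint,
    drone_position: tuple[float, float],
    camera: CameraModel,
    altitude_m: float,
    flight_axis: FlightAxis = FlightAxis.UP,
) -> tuple[np.ndarray, bool]:
    """Central projection of a world point onto the image.

    Returns ``(pixel, in_view)``.  A ground point at the nadir maps to the
    image centre; an elevated point is displaced radially outward by the
    ``H/(H−z)`` magnification.  Raises for points at or above the camera
    plane.
    """
    if world.elevation >= altitude_m:
        raise InvalidInputError("point at or above the camera plane cannot be projected")
    foot = ground_footprint(camera, FlightState(altitude_m=altitude_m, flight_axis=flight_axis))
    k = 1.0 / foot.metres_per_pixel
    mag = altitude_m / (altitude_m - world.elevation)
    du = world.u - drone_position[0]
    dv = world.v - drone_position[1]
    fwd = np.asarray(flight_axis.forward)
    lat = np.asarray(flight_axis.lateral)
    pixel = np.asarray(camera.centre) + fwd * (du * k * mag) + lat * (dv * k * mag)
    in_view = bool(
        0.0 <= pixel[0] <= camera.image_width_px - 1
        and 0.0 <= pixel[1] <= camera.image_height_px - 1
    )
    return pixel, in_view


@dataclass
class SyntheticDataset:
    """Everything one simulated scene produces.

    ``correspondences`` maps consecutive frame pairs to (N, 4) arrays of
    ``(xa, ya, xb, yb)`` pixel pairs; ``true_shifts`` holds the exact
    camera-induced ground translation (px) per pair for oracle checks.
    """

    config: SceneConfig
    tracks: list[Track]
    correspondences: dict[tuple[int, int], np.ndarray]
    truth: pd.DataFrame
    manifest: dict
    true_shifts: np.ndarray

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write tracks/matches/truth/manifest as plain text, deterministically."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tracks": outdir / "tracks.txt",
            "matches": outdir / "matches.csv",
            "truth": outdir / "truth.csv",
            "manifest": outdir / "manifest.yaml",
        }
        with open(paths["tracks"], "w") as fh:
            for track in self.tracks:
                for p in track.points:
                    x, y, w, h = p.bbox
                    fh.write(f"{p.frame_index} {p.track_id} {x:.3f} {y:.3f} {w:.3f} {h:.3f}\n")
        with open(paths["matches"], "w") as fh:
            fh.write("frame_a,frame_b,xa,ya,xb,yb\n")
            for (fa, fb), arr in sorted(self.correspondences.items()):
                for xa, ya, xb, yb in arr:
                    fh.write(f"{fa},{fb},{xa:.4f},{ya:.4f},{xb:.4f},{yb:.4f}\n")
        self.truth.to_csv(paths["truth"], index=False, float_format="%.6g", lineterminator="\n")
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        return paths


def _walking_state(speed: float) -> str:
    if speed < 0.05:
        return "standing"
    return "slow" if speed <= 1.0 else "fast"


def simulate_scene(config: SceneConfig) -> SyntheticDataset:
    """Render a scene into tracks, feature correspondences and ground truth.

    Fully deterministic for a given config + seed: the same seed regenerates
    byte-identical files.  Pedestrians leaving the view frustum have their
    tracks truncated, noted in the manifest.
    """
    cam = config.camera
    fps = cam.fps
    n_frames = int(round(config.duration_s * fps)) + 1
    foot = ground_footprint(cam, config.flight)
    k = 1.0 / foot.metres_per_pixel
    fwd = np.asarray(config.flight_axis.forward)
    lat = np.asarray(config.flight_axis.lateral)
    centre = np.asarray(cam.centre)
    h_alt = config.altitude_m

    root = np.random.SeedSequence(config.seed)
    ss_jitter, ss_tracks, ss_features = root.spawn(3)
    rng_tracks = np.random.Generator(np.random.PCG64(ss_tracks))
    rng_features = np.random.Generator(np.random.PCG64(ss_features))
    rng_jitter = np.random.Generator(np.random.PCG64(ss_jitter))

    # drone nadir trajectory (u along flight, v lateral)
    dt = 1.0 / fps
    t_edges = np.cumsum([d for d, _ in config.speed_segments()])
    seg_speeds = [s for _, s in config.speed_segments()]
    times = np.arange(n_frames) * dt
    seg_idx = np.minimum(np.searchsorted(t_edges, times, side="right"), len(seg_speeds) - 1)
    speeds = np.asarray(seg_speeds)[seg_idx]
    drone_u = np.concatenate([[0.0], np.cumsum(speeds[:-1] * dt)])
    phase = rng_jitter.uniform(0.0, 2 * math.pi)
    if config.lateral_jitter_m > 0:
        drone_v = config.lateral_jitter_m * np.sin(2 * math.pi * times / config.jitter_period_s + phase)
    else:
        drone_v = np.zeros(n_frames)

    # extents of the ground footprint along/lateral to the flight axis (m)
    ext_fwd_px = abs(fwd[0]) * cam.image_width_px + abs(fwd[1]) * cam.image_height_px
    ext_lat_px = abs(lat[0]) * cam.image_width_px + abs(lat[1]) * cam.image_height_px
    ext_fwd_m = ext_fwd_px / k
    ext_lat_m = ext_lat_px / k

    # pedestrian tracks
    tracks: list[Track] = []
    truth_rows = []
    truncated: list[int] = []
    for pid, ped in enumerate(config.pedestrians, start=1):
        mag = h_alt / (h_alt - ped.height_m)
        box_px = BBOX_WIDTH_M * k * mag
        ang = math.radians(ped.direction_deg)
        du_dir, dv_dir = math.cos(ang), math.sin(ang)
        noise = (
            rng_tracks.normal(0.0, config.pixel_noise_sigma, size=(n_frames, 2))
            if config.pixel_noise_sigma > 0
            else np.zeros((n_frames, 2))
        )
        points = []
        for t in range(n_frames):
            u = ped.start_u + ped.speed_m_s * du_dir * times[t]
            v = ped.start_v + ped.speed_m_s * dv_dir * times[t]
            pix = centre + fwd * ((u - drone_u[t]) * k * mag) + lat * ((v - drone_v[t]) * k * mag)
            pix = pix + noise[t]
            if not (0 <= pix[0] <= cam.image_width_px - 1 and 0 <= pix[1] <= cam.image_height_px - 1):
                continue
            points.append(
                TrackPoint(
                    frame_index=t,
                    track_id=pid,
                    bbox=(pix[0] - box_px / 2, pix[1] - box_px / 2, box_px, box_px),
                )
            )
        if points:
            tracks.append(Track(track_id=pid, points=points))
            if len(points) < n_frames:
                truncated.append(pid)
        truth_rows.append(
            {
                "track_id": pid,
                "true_speed_m_s": ped.speed_m_s,
                "height_m": ped.height_m,
                "direction_deg": ped.direction_deg,
                "start_u_m": ped.start_u,
                "start_v_m": ped.start_v,
                "state": _walking_state(ped.speed_m_s),
                "visible": bool(points),
            }
        )

    # ground-feature correspondences per consecutive frame pair
    correspondences: dict[tuple[int, int], np.ndarray] = {}
    true_shifts = np.zeros((n_frames - 1, 2))
    n_out = int(round(config.outlier_fraction * config.feature_count))
    margin = 2.0 / k  # keep clean features a couple of pixels inside the frame
    for t in range(n_frames - 1):
        u_lo = max(drone_u[t], drone_u[t + 1]) - ext_fwd_m / 2 + margin
        u_hi = min(drone_u[t], drone_u[t + 1]) + ext_fwd_m / 2 - margin
        v_lo = max(drone_v[t], drone_v[t + 1]) - ext_lat_m / 2 + margin
        v_hi = min(drone_v[t], drone_v[t + 1]) + ext_lat_m / 2 - margin
        pu = rng_features.uniform(u_lo, u_hi, size=config.feature_count)
        pv = rng_features.uniform(v_lo, v_hi, size=config.feature_count)
        pa = centre + np.outer((pu - drone_u[t]) * k, fwd) + np.outer((pv - drone_v[t]) * k, lat)
        pb = centre + np.outer((pu - drone_u[t + 1]) * k, fwd) + np.outer((pv - drone_v[t + 1]) * k, lat)
        if config.pixel_noise_sigma > 0:
            pa = pa + rng_features.normal(0, config.pixel_noise_sigma, pa.shape)
            pb = pb + rng_features.normal(0, config.pixel_noise_sigma, pb.shape)
        if n_out:
            idx = rng_features.choice(config.feature_count, size=n_out, replace=False)
            pa[idx, 0] = rng_features.uniform(0, cam.image_width_px - 1, n_out)
            pa[idx, 1] = rng_features.uniform(0, cam.image_height_px - 1, n_out)
            pb[idx, 0] = rng_features.uniform(0, cam.image_width_px - 1, n_out)
            pb[idx, 1] = rng_features.uniform(0, cam.image_height_px - 1, n_out)
        correspondences[(t, t + 1)] = np.hstack([pa, pb])
        shift = fwd * (-(drone_u[t + 1] - drone_u[t]) * k) + lat * (-(drone_v[t + 1] - drone_v[t]) * k)
        true_shifts[t] = shift

    manifest = {
        "seed": int(config.seed),
        "n_frames": int(n_frames),
        "fps": float(fps),
        "altitude_m": float(config.altitude_m),
        "flight_axis": config.flight_axis.value,
        "drone_speed_m_s": config.speed_segments(),
        "lateral_jitter_m": float(config.lateral_jitter_m),
        "pixel_noise_sigma": float(config.pixel_noise_sigma),
        "outlier_fraction": float(config.outlier_fraction),
        "feature_count": int(config.feature_count),
        "n_pedestrians": len(config.pedestrians),
        "truncated_track_ids": [int(i) for i in truncated],
    }
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        config=config,
        tracks=tracks,
        correspondences=correspondences,
        truth=truth,
        manifest=manifest,
        true_shifts=true_shifts,
    )


def random_pedestrians(
    n: int,
    seed: int | np.random.Generator,
    *,
    camera: CameraModel | None = None,
    altitude_m: float = 40.0,
    flight_axis: FlightAxis = FlightAxis.UP,
    height_range: tuple[float, float] = (1.5, 1.9),
    speed_range: tuple[float, float] = (0.0, 2.0),
    directions: tuple[float, ...] = (0.0, 180.0),
    street_half_width_m: float = DEFAULT_STREET_HALF_WIDTH_M,
) -> tuple[PedestrianSpec, ...]:
    """Draw a pedestrian population scattered inside the initial footprint.

    Heights and speeds are uniform over the given ranges; walking directions
    are drawn from ``directions`` (defaults: with or against the flight
    line, as on a street the camera flies along); start positions cover the
    central 80% of the along-flight ground extent and a street of the given
    half-width laterally.
    """
    cam = camera or CameraModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    flight_axis = FlightAxis(flight_axis)
    foot = ground_footprint(cam, FlightState(altitude_m=altitude_m, flight_axis=flight_axis))
    fwd = np.asarray(flight_axis.forward)
    ext_fwd_px = abs(fwd[0]) * cam.image_width_px + abs(fwd[1]) * cam.image_height_px
    ext_fwd_m = ext_fwd_px * foot.metres_per_pixel
    peds = []
    for _ in range(n):
        peds.append(
            PedestrianSpec(
                height_m=float(rng.uniform(*height_range)),
                speed_m_s=float(rng.uniform(*speed_range)),
                direction_deg=float(rng.choice(directions)),
                start_u=float(rng.uniform(-0.4, 0.4) * ext_fwd_m),
                start_v=float(rng.uniform(-street_half_width_m, street_half_width_m)),
            )
        )
    return tuple(peds)


# ---------------------------------------------------------------------------
# Error summary (structure of a before/after correction comparison table)
# ---------------------------------------------------------------------------

@dataclass
class ErrorSummary:
    """Mean signed errors per cell plus overall accuracy statistics."""

    cells: pd.DataFrame
    overall: dict

    def to_frame(self) -> pd.DataFrame:
        """Cells plus one trailing 'overall' row, for CSV export."""
        overall = dict(self.overall)
        for col in ("state", "drone_speed_m_s"):
            if col in self.cells.columns:
                overall[col] = "overall"
                break
        return pd.concat([self.cells, pd.DataFrame([overall])], ignore_index=True)


def error_summary(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.05, 0.1),
) -> ErrorSummary:
    """Compare estimated track speeds with ground truth.

    ``estimates`` needs columns ``track_id`` and ``corrected_speed_m_s``
    (optionally ``raw_speed_m_s`` for the before-correction column);
    ``truth`` needs ``track_id`` and ``true_speed_m_s`` plus any grouping
    columns (``drone_speed_m_s``, ``state``) present.  Errors are signed
    (estimate − truth); threshold fractions use strict ``|error| <
    threshold`` on the corrected estimates.
    """
    est = pd.DataFrame(estimates)
    tru = pd.DataFrame(truth)
    merged = est.merge(tru, on="track_id", how="inner")
    if merged.empty:
        raise InvalidInputError("no overlapping track ids between estimates and truth")
    merged["error_after"] = merged["corrected_speed_m_s"] - merged["true_speed_m_s"]
    has_raw = "raw_speed_m_s" in merged.columns
    if has_raw:
        merged["error_before"] = merged["raw_speed_m_s"] - merged["true_speed_m_s"]

    group_cols = [c for c in ("drone_speed_m_s", "state") if c in merged.columns]
    agg = {"error_after": "mean", "track_id": "count"}
    if has_raw:
        agg["error_before"] = "mean"
    if group_cols:
        cells = merged.groupby(group_cols, as_index=False).agg(agg)
    else:
        cells = merged.agg(agg).to_frame().T
    cells = cells.rename(
        columns={
            "error_after": "mean_error_after",
            "error_before": "mean_error_before",
            "track_id": "n",
        }
    )

    overall = {
        "n": int(len(merged)),
        "mean_error_after": float(merged["error_after"].mean()),
        "max_abs_error_after": float(merged["error_after"].abs().max()),
    }
    if has_raw:
        overall["mean_error_before"] = float(merged["error_before"].mean())
        overall["max_abs_error_before"] = float(merged["error_before"].abs().max())
    for thr in thresholds:
        key = f"frac_within_{thr:g}"
        overall[key] = float((merged["error_after"].abs() < thr).mean())
    return ErrorSummary(cells=cells, overall=overall)


def load_scene_config(path: str | Path) -> SceneConfig:
    """Build a :class:`SceneConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cam_keys = {"fov_deg", "image_width", "image_height", "fps"}
    cam_raw = {k: raw.pop(k) for k in list(raw) if k in cam_keys}
    camera = CameraModel(
        fov_deg=cam_raw.get("fov_deg", 84.0),
        image_width_px=cam_raw.get("image_width", 1920),
        image_height_px=cam_raw.get("image_height", 1080),
        fps=cam_raw.get("fps", 30.0),
    )
    peds = tuple(PedestrianSpec(**p) for p in raw.pop("pedestrians", []))
    n_random = raw.pop("random_pedestrians", None)
    cfg = SceneConfig(camera=camera, pedestrians=peds, **raw)
    if n_random:
        peds = random_pedestrians(
            int(n_random),
            cfg.seed,
            camera=camera,
            altitude_m=cfg.altitude_m,
            flight_axis=cfg.flight_axis,
        )
        cfg = SceneConfig(camera=camera, pedestrians=peds, **raw)
    return cfg
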