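"""Readers, writers, run configuration and the pipeline driver.

Track files are plain text with six whitespace- or comma-separated values per
line — frame index, track id, bounding-box x, y, width, height — the layout
multi-object trackers commonly emit.  Correspondences travel as CSV, either
four columns ``xa, ya, xb, yb`` for a single frame pair or six columns with
leading ``frame_a, frame_b`` for a whole sequence.  All writers use fixed
formats so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .camera import CameraModel, FlightAxis, FlightState, GroundFootprint, InvalidInputError, ground_footprint
from .ground_motion import Correspondence, Homography, RansacParams, ransac_homography
from .speed import (
    PedestrianModel,
    SpeedEstimate,
    Track,
    TrackPoint,
    TrackSummary,
    corrected_track_speed,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "read_tracks",
    "write_tracks",
    "read_correspondences",
    "write_correspondences",
    "write_speeds",
    "read_speeds",
    "write_summaries",
    "read_summaries",
    "fit_frame_homographies",
    "estimate_speeds",
]

logger = logging.getLogger("walkspeed")

SPEED_COLUMNS = [
    "track_id",
    "frame_start",
    "frame_interval",
    "displacement_px_x",
    "displacement_px_y",
    "raw_speed_px_s",
    "raw_speed_m_s",
    "r1",
    "r2",
    "delta1",
    "delta2",
    "theta_deg",
    "correction_m_s",
    "corrected_speed_m_s",
    "clamped",
    "degenerate_heading",
]

SUMMARY_COLUMNS = [
    "track_id",
    "n_strides",
    "median_corrected_m_s",
    "median_raw_m_s",
    "any_clamped",
]


class ParseError(ValueError):
    """A data file violates its documented layout."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one estimation run (camera, flight, pedestrian, RANSAC)."""

    camera: CameraModel = field(default_factory=CameraModel)
    flight: FlightState = field(default_factory=lambda: FlightState(altitude_m=40.0))
    pedestrian: PedestrianModel = field(default_factory=PedestrianModel)
    ransac: RansacParams = field(default_factory=RansacParams)
    frame_interval: int | None = None  # stride n; default = one second of frames
    bbox_origin: str = "corner"  # "corner" (MOT) or "center"
    seed: int = 0
    verbosity: str = "WARNING"

    def __post_init__(self) -> None:
        if self.bbox_origin not in ("corner", "center"):
            raise InvalidInputError(f"bbox_origin must be 'corner' or 'center', got {self.bbox_origin!r}")

    @property
    def stride_n(self) -> int:
        return self.frame_interval if self.frame_interval else int(round(self.camera.fps))

    @property
    def footprint(self) -> GroundFootprint:
        return ground_footprint(self.camera, self.flight)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Recognised keys: ``fov_deg, image_width, image_height, fps, altitude_m,
    pedestrian_height_m, frame_interval, flight_axis``, a nested ``ransac``
    mapping, ``bbox_origin``, ``seed`` and ``verbosity``; missing keys fall
    back to the defaults above.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    camera = CameraModel(
        fov_deg=raw.get("fov_deg", 84.0),
        image_width_px=raw.get("image_width", 1920),
        image_height_px=raw.get("image_height", 1080),
        fps=raw.get("fps", 30.0),
    )
    flight = FlightState(
        altitude_m=raw.get("altitude_m", 40.0),
        flight_axis=FlightAxis(raw.get("flight_axis", "up")),
    )
    ped = PedestrianModel(height_m=raw.get("pedestrian_height_m", 1.7))
    seed = int(raw.get("seed", 0))
    ransac_kwargs = dict(raw.get("ransac", {}))
    ransac_kwargs.setdefault("seed", seed)
    ransac = RansacParams(**ransac_kwargs)
    return RunConfig(
        camera=camera,
        flight=flight,
        pedestrian=ped,
        ransac=ransac,
        frame_interval=raw.get("frame_interval"),
        bbox_origin=raw.get("bbox_origin", "corner"),
        seed=seed,
        verbosity=raw.get("verbosity", "WARNING"),
    )


# ---------------------------------------------------------------------------
# Track files
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path, bbox_origin: str = "corner") -> list[Track]:
    """Parse a six-column track file into per-identity Tracks sorted by frame.

    Lines may be whitespace- or comma-separated.  A line with a field count
    other than six raises :class:`ParseError` naming the line number.
    """
    rows: dict[int, list[TrackPoint]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}: {line!r}")
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                x, y, w, h = (float(v) for v in parts[2:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparseable value ({exc})") from exc
            center = (x, y) if bbox_origin == "center" else None
            bbox = (x - w / 2, y - h / 2, w, h) if bbox_origin == "center" else (x, y, w, h)
            rows.setdefault(tid, []).append(
                TrackPoint(frame_index=frame, track_id=tid, bbox=bbox, center=center)
            )
    tracks = []
    for tid in sorted(rows):
        pts = sorted(rows[tid], key=lambda p: p.frame_index)
        tracks.append(Track(track_id=tid, points=pts))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for p in track.points:
                x, y, w, h = p.bbox
                fh.write(f"{p.frame_index} {p.track_id} {x:.3f} {y:.3f} {w:.3f} {h:.3f}\n")


# ---------------------------------------------------------------------------
# Correspondence files
# ---------------------------------------------------------------------------

def read_correspondences(path: str | Path):
    """Read matches CSV.

    Six columns (``frame_a, frame_b, xa, ya, xb, yb``) yield a dict mapping
    frame pairs to (N, 4) arrays; four columns (``xa, ya, xb, yb``) yield a
    single list of :class:`Correspondence`.
    """
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if set(("frame_a", "frame_b", "xa", "ya", "xb", "yb")).issubset(cols):
        out: dict[tuple[int, int], np.ndarray] = {}
        for (fa, fb), g in df.groupby(["frame_a", "frame_b"]):
            out[(int(fa), int(fb))] = g[["xa", "ya", "xb", "yb"]].to_numpy(dtype=float)
        return out
    if set(("xa", "ya", "xb", "yb")).issubset(cols):
        return [
            Correspondence(point_a=(r.xa, r.ya), point_b=(r.xb, r.yb))
            for r in df.itertuples()
        ]
    raise ParseError(f"{path}: expected columns (xa, ya, xb, yb) with optional (frame_a, frame_b)")


def write_correspondences(pairs: dict[tuple[int, int], np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame_a,frame_b,xa,ya,xb,yb\n")
        for (fa, fb), arr in sorted(pairs.items()):
            for xa, ya, xb, yb in arr:
                fh.write(f"{fa},{fb},{xa:.4f},{ya:.4f},{xb:.4f},{yb:.4f}\n")


# ---------------------------------------------------------------------------
# Speed outputs
# ---------------------------------------------------------------------------

def _estimates_frame(estimates: Sequence[SpeedEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        d = asdict(e)
        dx, dy = d.pop("displacement_px")
        d["displacement_px_x"] = dx
        d["displacement_px_y"] = dy
        rows.append(d)
    df = pd.DataFrame(rows, columns=SPEED_COLUMNS)
    return df


def write_speeds(estimates: Sequence[SpeedEstimate], path: str | Path) -> None:
    """Write per-stride estimates as CSV with a deterministic column order.

    Values round-trip through :func:`read_speeds` to 6 significant digits;
    identical inputs produce byte-identical files.
    """
    df = _estimates_frame(estimates)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def read_speeds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summaries(summaries: Sequence[TrackSummary], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in summaries], columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def fit_frame_homographies(
    correspondences: dict[tuple[int, int], np.ndarray],
    params: RansacParams,
) -> dict[tuple[int, int], Homography]:
    """Robustly fit one background homography per frame pair.

    Pairs whose estimation fails are dropped with a warning; downstream
    strides over a missing pair are skipped and logged.
    """
    out: dict[tuple[int, int], Homography] = {}
    for i, (pair, arr) in enumerate(sorted(correspondences.items())):
        corr = [Correspondence(point_a=(xa, ya), point_b=(xb, yb)) for xa, ya, xb, yb in arr]
        pair_params = replace(params, seed=params.seed + i)
        try:
            out[pair] = ransac_homography(corr, pair_params)
        except Exception as exc:  # noqa: BLE001 - per-pair isolation
            logger.warning("homography estimation failed for pair %s: %s", pair, exc)
    return out


def estimate_speeds(
    tracks: Sequence[Track],
    correspondences: dict[tuple[int, int], np.ndarray],
    config: RunConfig,
) -> tuple[list[SpeedEstimate], list[TrackSummary], dict[tuple[int, int], Homography]]:
    """Full pipeline: background homographies, then per-track speeds."""
    homographies = fit_frame_homographies(correspondences, config.ransac)
    low = sum(1 for h in homographies.values() if not h.consensus_ok)
    if low:
        logger.warning("%d/%d frame pairs below the consensus threshold", low, len(homographies))
    footprint = config.footprint
    estimates: list[SpeedEstimate] = []
    summaries: list[TrackSummary] = []
    for track in tracks:
        est, summary = corrected_track_speed(
            track,
            homographies,
            camera=config.camera,
            flight=config.flight,
            footprint=footprint,
            ped=config.pedestrian,
            stride_n=config.stride_n,
        )
        estimates.extend(est)
        if summary is not None:
            summaries.append(summary)
    return estimates, summaries, homographies
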