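"""Sensor and flight geometry: the pixel-to-metre conversion for a nadir camera.

A downward-looking camera at altitude ``H`` with diagonal field-of-view angle
``FOV`` images a ground rectangle whose diagonal is ``d = 2 H tan(FOV/2)``.
Splitting ``d`` by the image aspect ratio gives the footprint length ``L``
(long image side, ``M`` pixels) and width ``W``, and the ground sampling
distance ``L / M`` in metres per pixel.  All angles are degrees at the
configuration surface and radians internally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "InvalidInputError",
    "CameraModel",
    "FlightAxis",
    "FlightState",
    "GroundFootprint",
    "fov_diameter",
    "ground_footprint",
]


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


@dataclass(frozen=True)
class CameraModel:
    """Sensor parameters of the aerial camera.

    Parameters
    ----------
    fov_deg:
        Diagonal field-of-view angle in degrees; must lie in (0, 180).
    image_width_px, image_height_px:
        Decoded frame size in pixels (long side first for a landscape sensor).
    fps:
        Frame rate of the decoded video in frames per second.
    focal_length_mm:
        Lens focal length (35 mm equivalent).  Metadata only: the relief
        displacement identity eliminates it from every numeric formula.
    """

    fov_deg: float = 84.0
    image_width_px: int = 1920
    image_height_px: int = 1080
    fps: float = 30.0
    focal_length_mm: float | None = 24.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg < 180.0:
            raise InvalidInputError(f"fov_deg must be in (0, 180), got {self.fov_deg}")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise InvalidInputError("image dimensions must be positive integers")
        if int(self.image_width_px) != self.image_width_px or int(self.image_height_px) != self.image_height_px:
            raise InvalidInputError("image dimensions must be integers")
        if not self.fps > 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")

    @property
    def centre(self) -> tuple[float, float]:
        """Image centre (x0, y0), the nadir point for an exactly vertical view."""
        return (self.image_width_px / 2.0, self.image_height_px / 2.0)


class FlightAxis(str, enum.Enum):
    """Image axis the flight direction maps to, with sign.

    ``UP`` means the aircraft's forward direction corresponds to decreasing
    row index (scene content ahead of the aircraft appears above the image
    centre); analogously for the other three axis-aligned choices.
    """

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"

    @property
    def forward(self) -> tuple[float, float]:
        """Unit pixel vector (dx, dy) pointing along the flight direction."""
        return {
            FlightAxis.UP: (0.0, -1.0),
            FlightAxis.DOWN: (0.0, 1.0),
            FlightAxis.LEFT: (-1.0, 0.0),
            FlightAxis.RIGHT: (1.0, 0.0),
        }[self]

    @property
    def lateral(self) -> tuple[float, float]:
        """Unit pixel vector perpendicular to :attr:`forward` (right-hand)."""
        fx, fy = self.forward
        return (-fy, fx)


@dataclass(frozen=True)
class FlightState:
    """Flight geometry relative to the ground plane."""

    altitude_m: float
    flight_axis: FlightAxis = FlightAxis.UP

    def __post_init__(self) -> None:
        if not self.altitude_m > 0:
            raise InvalidInputError(f"altitude_m must be positive, got {self.altitude_m}")
        object.__setattr__(self, "flight_axis", FlightAxis(self.flight_axis))


@dataclass(frozen=True)
class GroundFootprint:
    """Ground rectangle imaged by the sensor, in metres."""

    diameter_m: float
    length_m: float
    width_m: float
    metres_per_pixel: float


def fov_diameter(camera: CameraModel, flight: FlightState) -> float:
    """Diameter of the ground footprint, ``d = 2 H tan(FOV / 2)`` in metres."""
    half_angle = math.radians(camera.fov_deg) / 2.0
    return 2.0 * flight.altitude_m * math.tan(half_angle)


def ground_footprint(camera: CameraModel, flight: FlightState) -> GroundFootprint:
    """Footprint sides from the diameter and the pixel aspect ratio.

    ``L = d·l/√(l²+w²)`` and ``W = d·w/√(l²+w²)`` where ``l:w`` is the pixel
    aspect ratio; the scale factor is ``L / M`` metres per pixel with ``M``
    the long-side pixel count.
    """
    d = fov_diameter(camera, flight)
    l = float(camera.image_width_px)
    w = float(camera.image_height_px)
    diag = math.hypot(l, w)
    length = d * l / diag
    width = d * w / diag
    return GroundFootprint(
        diameter_m=d,
        length_m=length,
        width_m=width,
        metres_per_pixel=length / camera.image_width_px,
    )
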