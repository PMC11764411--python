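"""Microscope/camera geometry utilities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import ConfigurationError

__all__ = ["SensorGeometry", "FieldOfView", "field_of_view", "DEFAULT_SENSOR"]


@dataclass(frozen=True)
class SensorGeometry:
    """Camera sensor format and optical magnification."""

    width_px: int = 2448
    height_px: int = 2048
    pixel_pitch_um: float = 3.45
    magnification: float = 20.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0 or self.pixel_pitch_um <= 0:
            raise ConfigurationError("sensor dimensions must be positive")
        if self.magnification <= 0:
            raise ConfigurationError("magnification must be positive")


DEFAULT_SENSOR = SensorGeometry()


class FieldOfView(NamedTuple):
    width_um: float
    height_um: float
    width_um_rounded: int
    height_um_rounded: int


def field_of_view(geom: SensorGeometry = DEFAULT_SENSOR) -> FieldOfView:
    """Specimen-plane field of view: sensor extent divided by magnification.

    The default 2448 x 2048 px sensor with 3.45 um pixels under a 20x
    objective gives 422 x 353 um (rounded to the nearest micrometre).
    """
    w = geom.width_px * geom.pixel_pitch_um / geom.magnification
    h = geom.height_px * geom.pixel_pitch_um / geom.magnification
    if w <= 0 or h <= 0:
        raise ConfigurationError("non-positive field of view")
    return FieldOfView(w, h, int(round(w)), int(round(h)))
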