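"""Display products built from unmixed abundance maps.

Two compositing algebras are used:

* brightfield (transmittance): per plane, each stain multiplies in its
  unit-abundance transmittance color raised to the local abundance,
  ``T_p = prod_i c_ip ** a_i`` on a white background — the display-space
  analogue of Beer-Lambert absorption;
* fluorescence-like (absorbance): abundances add in color space,
  ``RGB = clip(sum_i a_i * f_i)`` on a black background.

The DAB-mimic view (brown biomarker + blue hematoxylin) and the
reconstructed H&E are brightfield composites with fixed color choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

from .errors import ConfigurationError
from .slides import ChannelCapture
from .spectral import PLANES
from .unmixing import AbundanceResult

__all__ = [
    "CompositeSpec",
    "DEFAULT_DAB_BROWN",
    "DEFAULT_HEMATOXYLIN_BLUE",
    "brightfield_composite",
    "dab_mimic",
    "he_reconstruction",
    "fluorescence_composite",
    "grayscale_view",
    "adjust_saturation",
]

MODES = ("brightfield", "fluorescence_like", "dab_mimic", "he_reconstruction")

#: Fixed pseudo-colors for the DAB-mimic view (unit-abundance transmittance).
DEFAULT_DAB_BROWN = (0.52, 0.26, 0.14)
DEFAULT_HEMATOXYLIN_BLUE = (0.35, 0.42, 0.85)


@dataclass
class CompositeSpec:
    """Which stains to composite, in which mode, with which colors.

    ``colors`` maps stain name to its color triple: unit-abundance
    transmittance for the brightfield modes, additive RGB for the
    fluorescence-like mode (typically taken from
    ``StainDefinition.display_color_rgb`` / ``fluor_color_rgb``).
    """

    included_stains: tuple[str, ...]
    mode: str
    colors: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown composite mode {self.mode!r}")
        missing = set(self.included_stains) - set(self.colors)
        if missing:
            raise ConfigurationError(f"no colors for stains: {sorted(missing)}")

    @property
    def background(self) -> str:
        return "black" if self.mode == "fluorescence_like" else "white"


def _maps_from(result: AbundanceResult | dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return result.maps if isinstance(result, AbundanceResult) else result


def brightfield_composite(
    result: AbundanceResult | dict[str, np.ndarray],
    spec: CompositeSpec,
) -> np.ndarray:
    """Multiplicative transmittance composite on a white background."""
    if spec.mode == "fluorescence_like":
        raise ConfigurationError("use fluorescence_composite for this mode")
    maps = _maps_from(result)
    missing = set(spec.included_stains) - set(maps)
    if missing:
        raise ConfigurationError(f"missing abundance maps: {sorted(missing)}")
    first = maps[spec.included_stains[0]] if spec.included_stains else None
    shape = first.shape if first is not None else (1, 1)
    t = np.ones((*shape, 3))
    for name in spec.included_stains:
        a = maps[name]
        if a.shape != shape:
            raise ConfigurationError(f"map {name!r} shape {a.shape} != {shape}")
        color = np.asarray(spec.colors[name], dtype=float)
        # power law per plane; 0**0 == 1 keeps unstained pixels white
        t *= np.power(color[None, None, :], a[..., None])
    return np.clip(t, 0.0, 1.0)


def dab_mimic(
    biomarker_map: np.ndarray,
    hematoxylin_map: np.ndarray,
    brown: tuple[float, float, float] = DEFAULT_DAB_BROWN,
    blue: tuple[float, float, float] = DEFAULT_HEMATOXYLIN_BLUE,
) -> np.ndarray:
    """Brown-biomarker / blue-hematoxylin pseudo-color composite.

    Imitates the familiar DAB IHC plus hematoxylin counterstain appearance
    for a single unmixed biomarker.
    """
    if biomarker_map.shape != hematoxylin_map.shape:
        raise ConfigurationError("biomarker and hematoxylin map shapes differ")
    spec = CompositeSpec(
        included_stains=("biomarker", "hematoxylin"),
        mode="dab_mimic",
        colors={"biomarker": brown, "hematoxylin": blue},
    )
    return brightfield_composite(
        {"biomarker": biomarker_map, "hematoxylin": hematoxylin_map}, spec
    )


def he_reconstruction(
    hematoxylin_map: np.ndarray,
    eosin_map: np.ndarray,
    hematoxylin_color: tuple[float, float, float],
    eosin_color: tuple[float, float, float],
    gains: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Composite H&E rebuilt from the unmixed hematoxylin and eosin maps.

    ``gains`` rescale the two dye abundances before compositing, emulating
    the ability to tune relative staining intensity to preference.  With the
    model-derived display colors and unit gains the result approximates the
    white-light capture in display (transmittance) space.
    """
    if hematoxylin_map.shape != eosin_map.shape:
        raise ConfigurationError("hematoxylin and eosin map shapes differ")
    g_h, g_e = gains
    if g_h < 0 or g_e < 0:
        raise ConfigurationError("gains must be nonnegative")
    spec = CompositeSpec(
        included_stains=("hematoxylin", "eosin"),
        mode="he_reconstruction",
        colors={"hematoxylin": hematoxylin_color, "eosin": eosin_color},
    )
    return brightfield_composite(
        {"hematoxylin": g_h * hematoxylin_map, "eosin": g_e * eosin_map}, spec
    )


def fluorescence_composite(
    result: AbundanceResult | dict[str, np.ndarray],
    spec: CompositeSpec,
) -> np.ndarray:
    """Additive absorbance composite on a black background."""
    if spec.mode != "fluorescence_like":
        raise ConfigurationError(
            f"fluorescence_composite requires mode 'fluorescence_like', got {spec.mode!r}"
        )
    maps = _maps_from(result)
    missing = set(spec.included_stains) - set(maps)
    if missing:
        raise ConfigurationError(f"missing abundance maps: {sorted(missing)}")
    first = maps[spec.included_stains[0]] if spec.included_stains else None
    shape = first.shape if first is not None else (1, 1)
    rgb = np.zeros((*shape, 3))
    for name in spec.included_stains:
        a = maps[name]
        if a.shape != shape:
            raise ConfigurationError(f"map {name!r} shape {a.shape} != {shape}")
        rgb += a[..., None] * np.asarray(spec.colors[name], dtype=float)[None, None, :]
    return np.clip(rgb, 0.0, 1.0)


def grayscale_view(capture: ChannelCapture, plane: str) -> np.ndarray:
    """The selected color plane of a capture as an unscaled monochrome image.

    This is how invisible-chromogen captures are presented when the colored
    rendering (e.g. the deep blue of an 880 nm image) is hard to perceive.
    """
    if plane not in PLANES:
        raise ConfigurationError(f"plane must be one of {PLANES}, got {plane!r}")
    return capture.rgb[..., PLANES.index(plane)].copy()


def adjust_saturation(rgb: np.ndarray, factor: float) -> np.ndarray:
    """Scale the HSV saturation of an RGB image, preserving hue and value.

    Used at factor 0.6 to make deep-blue prints of UV/NIR captures easier to
    read; factor 1 is the identity and factor 0 yields grayscale.
    """
    if not 0.0 <= factor <= 1.0:
        raise ConfigurationError(f"saturation factor {factor} outside [0, 1]")
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ConfigurationError(f"expected an (H, W, 3) image, got {rgb.shape}")
    hsv = rgb2hsv(rgb)
    hsv[..., 1] *= factor
    return hsv2rgb(hsv)
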