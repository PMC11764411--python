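"""Optical-density conversion and single-stain reference calibration.

Reference coefficients — the per-channel OD signature of each stain at unit
abundance — are measured from calibration slides carrying a single dye
without counterstain, imaged under exactly the channel set and matched color
planes of the multiplex assay.  Stained pixels are segmented automatically
(Otsu threshold on the stain's own channel) and the median OD per channel
over that mask forms the stain's reference column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import CalibrationError, ConfigurationError, MissingInputError
from .slides import ChannelCapture, NoiseModel, VirtualSlide, render_assay
from .spectral import PLANES, ChannelConfig

__all__ = [
    "ODImage",
    "ReferenceMatrix",
    "SingleStainSet",
    "od_from_capture",
    "reference_vector",
    "assemble_reference_matrix",
    "simulate_single_stain_set",
    "calibrate_assay",
    "truth_reference_matrix",
]

logger = logging.getLogger(__name__)

#: OD values are clipped into [0, OD_CAP]; intensities are floored at
#: OD_FLOOR of full scale before taking logs so dark pixels stay finite.
OD_CAP = 4.0
OD_FLOOR = 1e-4

NORMALIZATIONS = ("matched_channel_unit", "unit_l2")


@dataclass
class ODImage:
    """Per-pixel optical density of one channel on one color plane."""

    channel_name: str
    plane: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise CalibrationError(f"non-finite OD in channel {self.channel_name!r}")
        if np.any(self.values < 0):
            raise CalibrationError(f"negative OD in channel {self.channel_name!r}")


@dataclass
class ReferenceMatrix:
    """Channels x stains matrix of calibrated reference coefficients."""

    matrix: np.ndarray
    channel_order: tuple[str, ...]
    stain_order: tuple[str, ...]
    normalization: str = "matched_channel_unit"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.channel_order), len(self.stain_order)):
            raise ConfigurationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.channel_order)} channels x {len(self.stain_order)} stains"
            )
        if np.any(self.matrix < 0):
            raise ConfigurationError("reference coefficients must be nonnegative")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")

    @property
    def condition_number(self) -> float:
        norms = np.linalg.norm(self.matrix, axis=0)
        if np.any(norms == 0):
            return float("inf")
        return float(np.linalg.cond(self.matrix / norms))

    def column(self, stain_name: str) -> np.ndarray:
        return self.matrix[:, self.stain_order.index(stain_name)]


@dataclass
class SingleStainSet:
    """Captures of one single-stain calibration slide across all channels."""

    stain_name: str
    captures: dict[str, ChannelCapture]
    mask: np.ndarray | None = None


def od_from_capture(
    capture: ChannelCapture,
    plane: str,
    od_cap: float = OD_CAP,
    floor: float = OD_FLOOR,
) -> ODImage:
    """Convert one color plane of a capture to optical density.

    OD = -log10(max(I, floor) / I0), clipped to [0, od_cap]; pixels brighter
    than the blank clip to 0.
    """
    if plane not in PLANES:
        raise ConfigurationError(f"plane must be one of {PLANES}, got {plane!r}")
    if floor <= 0:
        raise ConfigurationError("floor must be > 0")
    if capture.blank_rgb is None:
        raise MissingInputError(f"capture {capture.channel_name!r} has no blank")
    idx = PLANES.index(plane)
    i = np.maximum(capture.rgb[..., idx], floor)
    i0 = capture.blank_rgb[..., idx]
    od = np.clip(-np.log10(i / i0), 0.0, od_cap)
    return ODImage(channel_name=capture.channel_name, plane=plane, values=od)


def _normalize(vector: np.ndarray, own_index: int, normalization: str) -> np.ndarray:
    if normalization == "matched_channel_unit":
        # Calibration units: the column is the raw OD signature of one
        # calibration-level (unit-abundance) deposit, so unmixed abundances
        # read as fractions of calibration-level staining and a perfectly
        # recovered calibration slide unmixes to exactly 1.  The own-channel
        # entry is the column's largest, but is deliberately NOT rescaled to
        # 1: doing so would fold each stain's own-channel OD into its
        # abundance scale and bias recovery.
        own = vector[own_index]
        if own <= 0:
            raise CalibrationError("no signal in the stain's own channel")
        if own < vector.max():
            raise CalibrationError(
                "stain absorbs more in another channel than its own; "
                "mis-assigned calibration channel"
            )
        return vector
    if normalization == "unit_l2":
        n = np.linalg.norm(vector)
        if n == 0:
            raise CalibrationError("all-zero reference vector")
        return vector / n
    raise ConfigurationError(f"unknown normalization {normalization!r}")


def reference_vector(
    single: SingleStainSet,
    config: ChannelConfig,
    normalization: str = "matched_channel_unit",
    od_cap: float = OD_CAP,
    floor: float = OD_FLOOR,
) -> np.ndarray:
    """Measure one stain's reference column from its calibration captures.

    The stained-pixel mask is Otsu-thresholded OD in the stain's own channel
    (unless ``single.mask`` overrides it); the column is the per-channel
    median OD over that mask, normalized per ``normalization``.
    """
    channels = config.unmixing_channels
    missing = [c.name for c in channels if c.name not in single.captures]
    if missing:
        raise CalibrationError(
            f"single-stain set {single.stain_name!r} lacks captures for {missing}"
        )

    own = config.channel_for_stain(single.stain_name)
    own_index = [c.name for c in channels].index(own.name)
    own_od = od_from_capture(
        single.captures[own.name], own.matched_plane, od_cap, floor
    ).values

    if single.mask is not None:
        mask = single.mask.astype(bool)
    else:
        if own_od.max() <= 1e-6:
            raise CalibrationError(
                f"no stained pixels on the {single.stain_name!r} calibration slide"
            )
        mask = own_od > threshold_otsu(own_od)
    if not mask.any():
        raise CalibrationError(
            f"empty stained-pixel mask for {single.stain_name!r}"
        )

    vector = np.array(
        [
            np.median(
                od_from_capture(
                    single.captures[c.name], c.matched_plane, od_cap, floor
                ).values[mask]
            )
            for c in channels
        ]
    )
    return _normalize(vector, own_index, normalization)


def assemble_reference_matrix(
    columns: list[np.ndarray],
    config: ChannelConfig,
    stain_order: list[str] | None = None,
    normalization: str = "matched_channel_unit",
) -> ReferenceMatrix:
    """Stack per-stain reference columns into the mixing matrix.

    Logs a warning (but does not fail) when the column-normalized condition
    number exceeds 1e3, the point past which unmixing amplifies noise badly.
    """
    stain_order = list(stain_order if stain_order is not None else config.unmix_stains)
    if len(set(stain_order)) != len(stain_order):
        raise ConfigurationError(f"duplicate stain names: {stain_order}")
    if len(columns) != len(stain_order):
        raise ConfigurationError(
            f"{len(columns)} columns for {len(stain_order)} stains"
        )
    n_ch = len(config.unmixing_channels)
    for name, col in zip(stain_order, columns):
        if np.asarray(col).shape != (n_ch,):
            raise ConfigurationError(
                f"column for {name!r} has shape {np.asarray(col).shape}, "
                f"expected ({n_ch},)"
            )
    ref = ReferenceMatrix(
        matrix=np.column_stack(columns),
        channel_order=tuple(c.name for c in config.unmixing_channels),
        stain_order=tuple(stain_order),
        normalization=normalization,
    )
    cond = ref.condition_number
    if cond > 1e3:
        logger.warning(
            "reference matrix for %s is ill-conditioned (cond=%.3g)",
            config.assay_name,
            cond,
        )
    return ref


def simulate_single_stain_set(
    stain_name: str,
    config: ChannelConfig,
    width: int = 96,
    height: int = 96,
    seed: int = 0,
    abundance: float = 1.0,
    n_spots: int = 12,
    noise: NoiseModel | None = None,
) -> SingleStainSet:
    """Emulate a single-dye, uncounterstained calibration slide.

    Deposits ``abundance`` (calibration level, default 1.0) of one stain in
    randomly placed disks and renders the full channel set of the assay.
    """
    if stain_name not in {s.name for s in config.stains}:
        raise ConfigurationError(f"stain {stain_name!r} not in {config.assay_name!r}")
    rng = np.random.default_rng(seed)
    amap = np.zeros((height, width))
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    for _ in range(n_spots):
        r = rng.uniform(6.0, 12.0)
        cx = rng.uniform(r, width - r)
        cy = rng.uniform(r, height - r)
        amap[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = abundance
    slide = VirtualSlide(
        width=width,
        height=height,
        abundance_maps={stain_name: amap},
        phenotype_table=[],
        seed=seed,
    )
    captures = {
        cap.channel_name: cap for cap in render_assay(slide, config, noise=noise)
    }
    return SingleStainSet(stain_name=stain_name, captures=captures)


def calibrate_assay(
    config: ChannelConfig,
    seed: int = 0,
    normalization: str = "matched_channel_unit",
    noise: NoiseModel | None = None,
    width: int = 96,
    height: int = 96,
) -> ReferenceMatrix:
    """Run the full calibration: one simulated single-stain slide per stain."""
    columns = []
    for k, stain_name in enumerate(config.unmix_stains):
        single = simulate_single_stain_set(
            stain_name, config, width=width, height=height, seed=seed + k, noise=noise
        )
        columns.append(reference_vector(single, config, normalization))
    return assemble_reference_matrix(columns, config, normalization=normalization)


def truth_reference_matrix(
    config: ChannelConfig,
    normalization: str = "matched_channel_unit",
) -> ReferenceMatrix:
    """Reference matrix computed directly from the forward model.

    Entry (k, i) is the band-integrated OD of stain i at unit abundance in
    channel k on its matched plane — the noiseless, segmentation-free value
    that :func:`calibrate_assay` estimates from simulated slides.  Useful as
    an oracle in round-trip tests.
    """
    channels = config.unmixing_channels
    grid = config.grid
    cols = []
    for stain_name in config.unmix_stains:
        stain = config.stain(stain_name)
        own_index = [c.name for c in channels].index(
            config.channel_for_stain(stain_name).name
        )
        vec = []
        for ch in channels:
            L = ch.band_profile(grid)
            w = L * config.camera.plane_curves[ch.matched_plane]
            t = float((w * 10.0 ** (-stain.spectrum.values)).sum() / w.sum())
            vec.append(min(-np.log10(max(t, 10.0**-OD_CAP)), OD_CAP))
        cols.append(_normalize(np.array(vec), own_index, normalization))
    return ReferenceMatrix(
        matrix=np.column_stack(cols),
        channel_order=tuple(c.name for c in channels),
        stain_order=tuple(config.unmix_stains),
        normalization=normalization,
    )
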