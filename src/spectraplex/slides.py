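"""Virtual slide generation and Beer-Lambert forward rendering.

A virtual slide is a set of per-stain ground-truth abundance maps for a
simulated FFPE tissue field: every cell carries hematoxylin in its nucleus
and eosin in its cytoplasm, and phenotype-specific biomarkers deposit
chromogen into nuclear, membrane, or cytoplasmic compartments.  The forward
renderer produces what the color camera records under each illumination
channel — a three-plane image plus a matching blank (flat-field) reference —
by integrating Beer-Lambert transmission over wavelength against the band
profile and the per-plane responsivity.

Abundance 1.0 corresponds to calibration-level deposition (the staining
density of the single-stain reference slides); abundances are capped at 3 so
no simulated pixel is fully opaque.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateChannelError, GenerationError
from .spectral import (
    PLANES,
    ChannelConfig,
    DEGENERATE_RESPONSE,
    IlluminationChannel,
)

__all__ = [
    "TissuePhenotype",
    "NoiseModel",
    "ChannelCapture",
    "VirtualSlide",
    "generate_tissue",
    "render_channel",
    "render_assay",
    "default_phenotypes",
]

#: Maximum simulated abundance per stain (optical densities above ~3 are
#: effectively opaque and heavy staining promotes non-specific adsorption).
ABUNDANCE_CAP = 3.0

_COMPARTMENTS = ("nuclear", "membrane", "cytoplasmic")


@dataclass(frozen=True)
class TissuePhenotype:
    """A cell population defined by which stains it deposits where.

    ``marker_pattern`` maps stain name to compartment ("nuclear",
    "membrane", or "cytoplasmic"); ``frequency`` is the fraction of cells of
    this phenotype; marker abundances are drawn uniformly from
    ``intensity_range`` (in calibration units, within [0, 3]).
    """

    name: str
    marker_pattern: dict[str, str]
    frequency: float
    intensity_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ConfigurationError(f"frequency {self.frequency} outside [0, 1]")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= ABUNDANCE_CAP):
            raise ConfigurationError(
                f"intensity_range {self.intensity_range} outside [0, {ABUNDANCE_CAP}]"
            )
        for stain, comp in self.marker_pattern.items():
            if comp not in _COMPARTMENTS:
                raise ConfigurationError(
                    f"unknown compartment {comp!r} for marker {stain!r}"
                )


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: Poisson shot noise plus Gaussian read noise.

    ``shot_noise_scale`` is the photon count corresponding to full-scale
    intensity 1.0 (0 disables shot noise); ``read_noise_sd`` is in intensity
    units (0 disables read noise).  The all-zero model renders exactly.
    """

    read_noise_sd: float = 0.0
    shot_noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.shot_noise_scale < 0:
            raise ConfigurationError("noise parameters must be nonnegative")

    @property
    def is_noiseless(self) -> bool:
        return self.read_noise_sd == 0.0 and self.shot_noise_scale == 0.0


@dataclass
class ChannelCapture:
    """One color-camera exposure: specimen RGB plus blank flat-field."""

    channel_name: str
    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    blank_rgb: np.ndarray  # same shape, > 0 everywhere
    exposure_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.rgb.shape != self.blank_rgb.shape:
            raise ConfigurationError("rgb and blank_rgb shapes differ")
        if np.any(self.blank_rgb <= 0):
            raise ConfigurationError("blank_rgb must be positive everywhere")

    def transmittance(self) -> np.ndarray:
        """Per-pixel, per-plane I/I0."""
        return self.rgb / self.blank_rgb


@dataclass
class VirtualSlide:
    """Ground-truth per-stain abundance maps plus the cell table behind them."""

    width: int
    height: int
    abundance_maps: dict[str, np.ndarray]
    phenotype_table: list[dict]
    seed: int

    def __post_init__(self) -> None:
        for name, m in self.abundance_maps.items():
            if m.shape != (self.height, self.width):
                raise ConfigurationError(f"map {name!r} has shape {m.shape}")
            if np.any(m < 0):
                raise ConfigurationError(f"negative abundance in map {name!r}")

    def map(self, stain_name: str) -> np.ndarray:
        return self.abundance_maps[stain_name]

    @property
    def stain_names(self) -> tuple[str, ...]:
        return tuple(self.abundance_maps)


def default_phenotypes(assay_name: str) -> list[TissuePhenotype]:
    """Marker panels emulating the demonstrated specimen classes.

    Compartments follow the biology of each marker: membrane for HER2, CD15,
    CD30, PD-L1, PSMA, CD8 and the basal-cell cocktail; nuclear for ER and
    PR; cytoplasmic for P504S.  Markers are keyed by the chromogen that
    detects them, since abundance maps are per-stain.
    """
    panels: dict[str, list[TissuePhenotype]] = {
        "melanoma_1plex": [
            TissuePhenotype("lag3_pos", {"sCy7": "membrane"}, 0.30),
        ],
        "breast_her2_1plex": [
            TissuePhenotype("her2_pos", {"ir870": "membrane"}, 0.40),
        ],
        "hodgkin_2plex": [
            # Reed/Sternberg cells co-express CD30 (AMC) and CD15 (sCy7) on
            # the same membranes.
            TissuePhenotype(
                "reed_sternberg",
                {"AMC": "membrane", "sCy7": "membrane"},
                0.10,
            ),
        ],
        "breast_3plex": [
            TissuePhenotype(
                "triple_pos",
                {"AMC": "membrane", "sCy7": "nuclear", "ir870": "nuclear"},
                0.25,
            ),
            TissuePhenotype(
                "her2_er_pos",
                {"AMC": "membrane", "sCy7": "nuclear"},
                0.20,
            ),
        ],
        "breast_dab_duplex": [
            TissuePhenotype("her2_pos", {"DAB": "membrane"}, 0.30),
            TissuePhenotype("pdl1_pos", {"sCy7": "membrane"}, 0.20),
        ],
        "prostate_4plex": [
            TissuePhenotype(
                "tumor", {"AMC": "membrane", "ir870": "cytoplasmic"}, 0.30
            ),
            TissuePhenotype("basal", {"sCy7": "membrane"}, 0.15),
            TissuePhenotype("cytotoxic_t", {"NMC": "membrane"}, 0.15),
        ],
    }
    if assay_name not in panels:
        raise ConfigurationError(f"no default phenotype panel for {assay_name!r}")
    return panels[assay_name]


def generate_tissue(
    config: ChannelConfig,
    phenotypes: list[TissuePhenotype],
    width: int,
    height: int,
    seed: int,
    n_cells: int | None = None,
    hematoxylin_range: tuple[float, float] = (0.6, 1.2),
    eosin_range: tuple[float, float] = (0.3, 0.8),
) -> VirtualSlide:
    """Generate a seeded virtual slide for one assay configuration.

    Cells are non-overlapping ellipses: an elliptical nucleus, a concentric
    cytoplasm, and a 2-pixel membrane ring just outside the nucleus.  Every
    cell receives hematoxylin in its nucleus and (when eosin is part of the
    assay) eosin in its cytoplasm; each cell is assigned a phenotype by its
    frequency and deposits that phenotype's markers in their compartments.
    Regeneration with the same seed is bit-identical.
    """
    if width < 32 or height < 32:
        raise ConfigurationError("width and height must be at least 32 pixels")
    total_freq = sum(p.frequency for p in phenotypes)
    if total_freq > 1.0 + 1e-12:
        raise ConfigurationError(f"phenotype frequencies sum to {total_freq} > 1")

    stain_names = [s.name for s in config.stains]
    for p in phenotypes:
        unknown = set(p.marker_pattern) - set(stain_names)
        if unknown:
            raise ConfigurationError(
                f"phenotype {p.name!r} uses stains not in config: {unknown}"
            )

    rng = np.random.default_rng(seed)
    if n_cells is None:
        n_cells = (width * height) // 800

    maps = {name: np.zeros((height, width)) for name in stain_names}
    yy, xx = np.mgrid[0:height, 0:width].astype(float)

    # Rejection-sampled circle packing on the cytoplasm bounding radius.
    placed: list[tuple[float, float, float]] = []
    cells: list[dict] = []
    attempts, max_attempts = 0, max(200, 60 * n_cells)
    while len(cells) < n_cells and attempts < max_attempts:
        attempts += 1
        a_nuc = rng.uniform(3.5, 5.5)  # nuclear semi-axes, px
        b_nuc = rng.uniform(3.5, 5.5)
        cyto_scale = rng.uniform(1.6, 2.0)
        r_out = cyto_scale * max(a_nuc, b_nuc)
        cx = rng.uniform(r_out, width - r_out)
        cy = rng.uniform(r_out, height - r_out)
        if any((cx - x) ** 2 + (cy - y) ** 2 < (r_out + r) ** 2 for x, y, r in placed):
            continue
        placed.append((cx, cy, r_out))
        cells.append(
            dict(center=(cx, cy), nuc=(a_nuc, b_nuc), cyto_scale=cyto_scale)
        )
    if len(cells) < n_cells:
        raise GenerationError(
            f"could not place {n_cells} non-overlapping cells in "
            f"{width}x{height} px (placed {len(cells)})"
        )

    pheno_probs = [p.frequency for p in phenotypes] + [1.0 - total_freq]
    pheno_choices = list(range(len(phenotypes))) + [-1]

    table: list[dict] = []
    for cell in cells:
        cx, cy = cell["center"]
        a_nuc, b_nuc = cell["nuc"]
        rho_nuc = np.sqrt(((xx - cx) / a_nuc) ** 2 + ((yy - cy) / b_nuc) ** 2)
        rho_cyto = rho_nuc / cell["cyto_scale"]
        nucleus = rho_nuc <= 1.0
        membrane = (rho_nuc > 1.0) & (rho_nuc <= 1.0 + 2.0 / min(a_nuc, b_nuc))
        cytoplasm = (rho_cyto <= 1.0) & ~nucleus
        comp_masks = {
            "nuclear": nucleus,
            "membrane": membrane,
            "cytoplasmic": cytoplasm,
        }

        if "hematoxylin" in maps:
            maps["hematoxylin"][nucleus] += rng.uniform(*hematoxylin_range)
        if "eosin" in maps:
            maps["eosin"][cytoplasm] += rng.uniform(*eosin_range)

        idx = rng.choice(pheno_choices, p=pheno_probs)
        markers: dict[str, float] = {}
        if idx >= 0:
            p = phenotypes[idx]
            for stain, comp in p.marker_pattern.items():
                level = rng.uniform(*p.intensity_range)
                maps[stain][comp_masks[comp]] += level
                markers[stain] = level
        table.append(
            dict(
                center=(float(cx), float(cy)),
                nuclear_radii=(float(a_nuc), float(b_nuc)),
                cyto_scale=float(cell["cyto_scale"]),
                phenotype=phenotypes[idx].name if idx >= 0 else "background",
                markers=markers,
            )
        )

    for m in maps.values():
        np.clip(m, 0.0, ABUNDANCE_CAP, out=m)

    return VirtualSlide(
        width=width,
        height=height,
        abundance_maps=maps,
        phenotype_table=table,
        seed=seed,
    )


def _channel_rng(noise: NoiseModel, channel_name: str) -> np.random.Generator:
    # Distinct but reproducible stream per channel.
    return np.random.default_rng([noise.seed, zlib.crc32(channel_name.encode())])


def render_channel(
    slide: VirtualSlide,
    channel: IlluminationChannel,
    config: ChannelConfig,
    noise: NoiseModel | None = None,
    exposure_scale: float = 1.0,
    _chunk: int = 64,
) -> ChannelCapture:
    """Render one illumination channel of a slide to a color-camera capture.

    Per plane p the specimen intensity is the white-balanced band average of
    Beer-Lambert transmission::

        I_p = wb_p * sum_l L(l) S_p(l) 10^(-sum_i a_i eps_i(l)) / sum_l L(l) S_p(l)

    followed by exposure scaling, optional noise, and clipping to [0, 1].
    The blank is the same expression with all abundances zero.  Wavelengths
    are integrated in chunks to bound memory.
    """
    noise = noise or NoiseModel()
    grid = config.grid
    L_full = channel.band_profile(grid)
    support = L_full > 1e-8 * L_full.max()
    L = L_full[support]

    curves = {p: config.camera.plane_curves[p][support] for p in PLANES}
    weights = {p: L * curves[p] for p in PLANES}
    l_sum = L_full.sum()
    if max(weights[p].sum() for p in PLANES) < DEGENERATE_RESPONSE * l_sum:
        raise DegenerateChannelError(
            f"channel {channel.name!r}: camera has no response within the band"
        )

    stains = [s for s in config.stains if s.name in slide.abundance_maps]
    missing = set(slide.abundance_maps) - {s.name for s in config.stains}
    if missing:
        raise ConfigurationError(f"slide stains not in config: {missing}")
    eps = np.stack([s.spectrum.values[support] for s in stains])  # (S, l)
    a_flat = np.stack(
        [slide.abundance_maps[s.name].ravel() for s in stains]
    )  # (S, N)

    n_px = a_flat.shape[1]
    n_l = L.size
    accum = {p: np.zeros(n_px) for p in PLANES}
    for start in range(0, n_l, _chunk):
        sl = slice(start, min(start + _chunk, n_l))
        # (l_chunk, N) transmission
        t = 10.0 ** (-(eps[:, sl].T @ a_flat))
        for p in PLANES:
            accum[p] += weights[p][sl] @ t

    # unstained pixels transmit exactly: pin them to the blank level so the
    # conservation invariant (zero abundance -> capture == blank) is exact
    # rather than within summation roundoff
    unstained = a_flat.sum(axis=0) == 0

    planes = []
    blanks = []
    for p in PLANES:
        wsum = weights[p].sum()
        gain = config.camera.gain(p)
        if wsum > 0:
            intensity = gain * accum[p] / wsum
            intensity[unstained] = gain
        else:
            intensity = np.zeros(n_px)
        planes.append(intensity.reshape(slide.height, slide.width))
        blanks.append(np.full((slide.height, slide.width), gain if wsum > 0 else 1e-6))

    rgb = np.stack(planes, axis=-1) * exposure_scale
    blank = np.stack(blanks, axis=-1) * exposure_scale

    if not noise.is_noiseless:
        rng = _channel_rng(noise, channel.name)
        if noise.shot_noise_scale > 0:
            rgb = rng.poisson(rgb * noise.shot_noise_scale) / noise.shot_noise_scale
        if noise.read_noise_sd > 0:
            rgb = rgb + rng.normal(0.0, noise.read_noise_sd, size=rgb.shape)

    rgb = np.clip(rgb, 0.0, 1.0)
    blank = np.clip(blank, 1e-6, 1.0)
    return ChannelCapture(
        channel_name=channel.name,
        rgb=rgb,
        blank_rgb=blank,
        exposure_scale=exposure_scale,
    )


def render_assay(
    slide: VirtualSlide,
    config: ChannelConfig,
    noise: NoiseModel | None = None,
    exposure_scale: float = 1.0,
) -> list[ChannelCapture]:
    """Render every channel of the assay, in configuration order.

    The white-light H&E capture is included (first, per the default channel
    ordering) alongside the narrowband unmixing channels.
    """
    return [
        render_channel(slide, ch, config, noise=noise, exposure_scale=exposure_scale)
        for ch in config.channels
    ]
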