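"""Spectral models: wavelength grids, stain absorbance spectra, illumination
bands, color-camera responsivity, and per-channel effective absorbance.

The physical picture: a brightfield microscope illuminates the specimen with
one band of light at a time (a filtered tungsten lamp or an LED), and a color
camera with its IR-blocking filter removed records an RGB image.  Each stain
attenuates the band according to its absorbance spectrum ``eps_i(lambda)``
(amplitude-normalized, Beer-Lambert), the band has a transmission profile
``L_k(lambda)``, and each sensor plane has a responsivity ``S_p(lambda)``.
The band-and-responsivity-weighted mean absorbance of a stain in a channel is
the scalar that couples the stain into that channel's monochrome image, and
the matrix of those scalars is what spectral unmixing inverts.

The camera and lamp curves used here are synthetic parametric stand-ins
(logistic-edged Gaussians with a shared NIR tail); the real sensor curves are
not published in a tabulated form.  They reproduce the qualitative behavior
that matters: blue-plane sensitivity in the near UV, red-plane dominance
around 769 nm, and all three planes responsive at 880 nm once the IR-blocking
filter is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateChannelError

__all__ = [
    "PLANES",
    "WavelengthGrid",
    "AbsorbanceSpectrum",
    "IlluminationChannel",
    "CameraResponsivity",
    "StainDefinition",
    "ChannelConfig",
    "default_stain_library",
    "assay_config",
    "effective_absorbance",
    "select_plane",
    "ASSAY_NAMES",
]

#: Sensor plane order used for argmax tie-breaking (red beats green beats blue).
PLANES = ("red", "green", "blue")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: In-band mean responsivity (relative to a unit-peak plane curve) below which
#: a channel/plane combination is considered unusable by the camera.
DEGENERATE_RESPONSE = 1e-3


def _gaussian(lam: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def _logistic(x: np.ndarray | float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nanometres.

    The default 350-950 nm range covers the UV chromogen bands (AMC at
    375 nm) through the NIR (ir870 at 880 nm) at 1 nm resolution.
    """

    start_nm: float = 350.0
    stop_nm: float = 950.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ConfigurationError(
                f"start_nm must be < stop_nm, got {self.start_nm} >= {self.stop_nm}"
            )
        if self.step_nm <= 0:
            raise ConfigurationError(f"step_nm must be > 0, got {self.step_nm}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return self.wavelengths.size


DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Amplitude-normalized absorbance of one stain versus wavelength.

    ``values`` is dimensionless, non-negative, and normalized so its maximum
    equals 1; a stain at unit abundance contributes an optical density equal
    to ``values`` at each wavelength.  ``components`` retains the parametric
    (center, fwhm, amplitude) Gaussian description used to build the spectrum
    so configurations can be serialized compactly.
    """

    stain_name: str
    values: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID
    components: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ConfigurationError(
                f"spectrum of {self.stain_name!r} has {vals.shape} values for a "
                f"{len(self.grid)}-point grid"
            )
        if np.any(vals < 0):
            raise ConfigurationError(f"negative absorbance in {self.stain_name!r}")
        peak = vals.max()
        if abs(peak - 1.0) > 1e-9:
            raise ConfigurationError(
                f"spectrum of {self.stain_name!r} is not amplitude-normalized "
                f"(max={peak!r})"
            )
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_gaussians(
        cls,
        stain_name: str,
        components: Sequence[tuple[float, float, float]],
        grid: WavelengthGrid = DEFAULT_GRID,
    ) -> "AbsorbanceSpectrum":
        """Build a spectrum as a peak-normalized sum of Gaussian bands.

        Each component is ``(center_nm, fwhm_nm, amplitude)``.
        """
        lam = grid.wavelengths
        vals = np.zeros_like(lam)
        for center, fwhm, amp in components:
            vals += amp * _gaussian(lam, center, fwhm)
        peak = vals.max()
        if peak <= 0:
            raise ConfigurationError(f"empty spectrum for {stain_name!r}")
        return cls(
            stain_name,
            vals / peak,
            grid,
            tuple((float(c), float(f), float(a)) for c, f, a in components),
        )

    def absorbance_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated absorbance at one wavelength."""
        return float(np.interp(wavelength_nm, self.grid.wavelengths, self.values))

    def to_text(self) -> str:
        """Two-column wavelength/absorbance text block for plotting."""
        lines = ["# wavelength_nm\tabsorbance"]
        for lam, v in zip(self.grid.wavelengths, self.values):
            lines.append(f"{lam:.1f}\t{v:.6f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IlluminationChannel:
    """One illumination band.

    ``matched_plane`` is the sensor plane used as this channel's monochrome
    image ("all" marks the broadband white-light H&E channel, which is viewed
    in full color and never unmixed).  ``target_stain`` names the chromogen
    the band was chosen to interrogate; it is used to locate each stain's own
    channel during calibration.
    """

    name: str
    source: str  # "tungsten" | "led"
    center_nm: float
    fwhm_nm: float
    matched_plane: str = "all"
    profile: str = "gaussian"  # "gaussian" | "tophat"
    target_stain: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("tungsten", "led"):
            raise ConfigurationError(f"unknown source {self.source!r}")
        if self.fwhm_nm <= 0:
            raise ConfigurationError("fwhm_nm must be > 0")
        if self.matched_plane not in PLANES + ("all",):
            raise ConfigurationError(f"unknown plane {self.matched_plane!r}")
        if self.profile not in ("gaussian", "tophat"):
            raise ConfigurationError(f"unknown band profile {self.profile!r}")

    def band_profile(self, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
        """Band transmission L_k(lambda) on the grid, unit peak."""
        lam = grid.wavelengths
        if self.profile == "tophat":
            half = 0.5 * self.fwhm_nm
            return (
                (lam >= self.center_nm - half) & (lam <= self.center_nm + half)
            ).astype(float)
        return _gaussian(lam, self.center_nm, self.fwhm_nm)

    @property
    def is_white(self) -> bool:
        return self.matched_plane == "all"


def _default_plane_curves(
    lam: np.ndarray, ir_blocking_removed: bool
) -> dict[str, np.ndarray]:
    # Synthetic stand-in for the sensor's RGB responsivity: one visible
    # Gaussian per plane plus per-plane NIR tails.  The tails are shaped so
    # the red plane dominates near 769 nm while the blue plane dominates at
    # 880 nm, and all three stay positive at 880 nm.
    red = _gaussian(lam, 605.0, 113.0) + 0.38 * _logistic((lam - 660.0) / 25.0) * _logistic(
        (840.0 - lam) / 70.0
    )
    green = _gaussian(lam, 532.0, 106.0) + 0.22 * _logistic((lam - 780.0) / 30.0)
    blue = _gaussian(lam, 460.0, 99.0) + 0.30 * _logistic((lam - 760.0) / 25.0)
    curves = {"red": red, "green": green, "blue": blue}
    for name, c in curves.items():
        if not ir_blocking_removed:
            c = np.where(lam > 700.0, 0.0, c)
        curves[name] = c / c.max()
    return curves


@dataclass(frozen=True)
class CameraResponsivity:
    """Relative RGB plane responsivity of the color camera.

    With ``ir_blocking_removed`` the sensor keeps its native silicon NIR
    response, which is required to image the 769/880 nm chromogens; with the
    blocking filter in place the response above 700 nm is zero and the NIR
    channels become unusable.  ``white_balance_gains`` scale each plane so a
    blank field renders as neutral gray at 90% of full scale.
    """

    plane_curves: dict[str, np.ndarray]
    ir_blocking_removed: bool = True
    white_balance_gains: tuple[float, float, float] = (0.9, 0.9, 0.9)
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        lam = self.grid.wavelengths
        for p in PLANES:
            if p not in self.plane_curves:
                raise ConfigurationError(f"missing plane curve {p!r}")
            c = np.asarray(self.plane_curves[p], dtype=float)
            if c.shape != lam.shape or np.any(c < 0):
                raise ConfigurationError(f"invalid responsivity curve for {p!r}")
        at_880 = {p: float(np.interp(880.0, lam, self.plane_curves[p])) for p in PLANES}
        if self.ir_blocking_removed and any(v <= 0 for v in at_880.values()):
            raise ConfigurationError(
                "IR-blocking filter removed but a plane has zero response at 880 nm"
            )
        if not self.ir_blocking_removed:
            for p in PLANES:
                if np.any(self.plane_curves[p][lam > 700.0] > 0):
                    raise ConfigurationError(
                        "IR-blocking filter in place but response above 700 nm is nonzero"
                    )

    @classmethod
    def default(
        cls,
        grid: WavelengthGrid = DEFAULT_GRID,
        ir_blocking_removed: bool = True,
    ) -> "CameraResponsivity":
        return cls(
            plane_curves=_default_plane_curves(grid.wavelengths, ir_blocking_removed),
            ir_blocking_removed=ir_blocking_removed,
            grid=grid,
        )

    def gain(self, plane: str) -> float:
        return self.white_balance_gains[PLANES.index(plane)]


@dataclass(frozen=True)
class StainDefinition:
    """One stain: its spectrum plus how it is rendered in composites.

    ``display_color_rgb`` is the per-plane transmittance of the stain at unit
    abundance (brightfield compositing raises it to the power of the local
    abundance); ``fluor_color_rgb`` is the additive color used in the
    fluorescence-like representation.  ``visible`` is True for the
    conventional dyes (hematoxylin, eosin, DAB) whose absorbance lies in the
    420-690 nm photopic band.
    """

    name: str
    spectrum: AbsorbanceSpectrum
    display_color_rgb: tuple[float, float, float]
    fluor_color_rgb: tuple[float, float, float]
    visible: bool

    def __post_init__(self) -> None:
        for c in (*self.display_color_rgb, *self.fluor_color_rgb):
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(
                    f"color component {c!r} of {self.name!r} outside [0, 1]"
                )
        if not self.visible:
            # Invisible chromogens must be transparent across the visible
            # core; the 460-680 nm window excludes the band edges where the
            # UV (375/405 nm) and NIR (769 nm) peaks tail off.
            lam = self.spectrum.grid.wavelengths
            core = (lam >= 460.0) & (lam <= 680.0)
            if np.any(self.spectrum.values[core] >= 0.1):
                raise ConfigurationError(
                    f"invisible chromogen {self.name!r} absorbs more than 10% of "
                    "peak inside the visible core (460-680 nm)"
                )


# Pseudo-colors for the invisible chromogens (display = unit-abundance
# transmittance, fluor = additive).  Chosen for legibility, not physics;
# user-overridable via dataclasses.replace.
_CHROMOGEN_COLORS = {
    "AMC": ((0.25, 0.80, 0.30), (0.0, 1.0, 1.0)),
    "NMC": ((0.90, 0.55, 0.15), (1.0, 1.0, 0.0)),
    "sCy7": ((0.90, 0.20, 0.20), (1.0, 0.0, 0.0)),
    "ir870": ((0.55, 0.20, 0.75), (1.0, 0.0, 1.0)),
}

# Gaussian components (center_nm, fwhm_nm, amplitude) for each stain.
# Chromogen peaks sit at their Table-like channel centers; hematoxylin is a
# broad visible band with a small UV shoulder (the source of the documented
# hematoxylin-into-UV bleed); DAB is a very broad visible absorber, strongest
# toward 405-460 nm and decaying into the NIR.
_STAIN_COMPONENTS = {
    "hematoxylin": ((599.0, 170.0, 1.0), (370.0, 70.0, 0.12)),
    "eosin": ((520.0, 106.0, 1.0),),
    "DAB": ((460.0, 259.0, 1.0),),
    "AMC": ((375.0, 61.0, 1.0),),
    "NMC": ((405.0, 59.0, 1.0),),
    "sCy7": ((769.0, 85.0, 1.0),),
    "ir870": ((880.0, 106.0, 1.0),),
}


def white_channel() -> IlluminationChannel:
    """The broadband visible H&E channel (420-690 nm top-hat)."""
    return IlluminationChannel(
        name="white",
        source="tungsten",
        center_nm=555.0,
        fwhm_nm=270.0,
        matched_plane="all",
        profile="tophat",
    )


def band_averaged_transmittance(
    stain: StainDefinition,
    channel: IlluminationChannel,
    camera: CameraResponsivity,
    abundance: float = 1.0,
) -> tuple[float, float, float]:
    """Per-plane transmittance of a uniform stain layer under one channel.

    This is the forward model of :func:`spectraplex.slides.render_channel`
    restricted to a single stain and divided by the blank; it is how the
    default display colors for hematoxylin, eosin and DAB are derived so
    that brightfield composites match the simulated white-light appearance.
    """
    grid = stain.spectrum.grid
    L = channel.band_profile(grid)
    t = 10.0 ** (-abundance * stain.spectrum.values)
    out = []
    for p in PLANES:
        w = L * camera.plane_curves[p]
        s = w.sum()
        out.append(float((w * t).sum() / s) if s > 0 else 0.0)
    return tuple(out)


def default_stain_library(grid: WavelengthGrid = DEFAULT_GRID) -> list[StainDefinition]:
    """The seven-stain library: hematoxylin, eosin, DAB, AMC, NMC, sCy7, ir870.

    Spectra are parametric Gaussian stand-ins shaped to the qualitative
    behavior of the deposited dyes: the hematoxylin UV shoulder overlaps the
    AMC band, the two coumarins (375/405 nm) overlap each other, and ir870
    tails into the 769 nm band.  Display colors of the visible dyes are
    band-averaged transmittances computed from these spectra under the
    white-light channel, so composite rendering is self-consistent with the
    forward model.
    """
    camera = CameraResponsivity.default(grid)
    white = white_channel()
    stains: list[StainDefinition] = []
    fluor_visible = {
        "hematoxylin": (0.25, 0.40, 1.0),
        "eosin": (0.10, 1.0, 0.35),
        "DAB": (1.0, 0.55, 0.10),
    }
    for name, comps in _STAIN_COMPONENTS.items():
        spectrum = AbsorbanceSpectrum.from_gaussians(name, comps, grid)
        visible = name in ("hematoxylin", "eosin", "DAB")
        if visible:
            display = band_averaged_transmittance(
                StainDefinition(
                    name, spectrum, (0.5, 0.5, 0.5), (0.5, 0.5, 0.5), True
                ),
                white,
                camera,
            )
            fluor = fluor_visible[name]
        else:
            display, fluor = _CHROMOGEN_COLORS[name]
        stains.append(StainDefinition(name, spectrum, display, fluor, visible))
    return stains


def effective_absorbance(
    stain: StainDefinition,
    channel: IlluminationChannel,
    camera: CameraResponsivity,
    plane: str,
) -> float:
    """Band-and-responsivity-weighted mean absorbance of a stain in a channel.

    Returns ``sum(L*S_p*eps) / sum(L*S_p)`` over the wavelength grid, a value
    in [0, 1].  Raises :class:`DegenerateChannelError` when the band carries
    essentially no response on the requested plane (e.g. any NIR band with
    the camera's IR-blocking filter in place).
    """
    if plane not in PLANES:
        raise ConfigurationError(f"plane must be one of {PLANES}, got {plane!r}")
    grid = stain.spectrum.grid
    L = channel.band_profile(grid)
    w = L * camera.plane_curves[plane]
    if w.sum() < DEGENERATE_RESPONSE * L.sum():
        raise DegenerateChannelError(
            f"channel {channel.name!r} carries no usable response on the "
            f"{plane} plane"
        )
    return float((w * stain.spectrum.values).sum() / w.sum())


def select_plane(
    stain: StainDefinition,
    channel: IlluminationChannel,
    camera: CameraResponsivity,
) -> str:
    """Pick the sensor plane best matched to a stain in a channel.

    Scores each plane by effective absorbance weighted by in-band mean
    responsivity, so the winning plane is the one that both sees the band and
    sees the stain absorb in it.  Ties break red > green > blue.
    """
    grid = stain.spectrum.grid
    L = channel.band_profile(grid)
    l_sum = L.sum()
    best_plane, best_score = None, -1.0
    for p in PLANES:
        w = L * camera.plane_curves[p]
        if w.sum() < DEGENERATE_RESPONSE * l_sum:
            continue
        eff = float((w * stain.spectrum.values).sum() / w.sum())
        score = eff * float(w.sum() / l_sum)
        if score > best_score + 1e-12:
            best_plane, best_score = p, score
    if best_plane is None:
        raise DegenerateChannelError(
            f"channel {channel.name!r} carries no usable response on any plane"
        )
    return best_plane


@dataclass(frozen=True)
class ChannelConfig:
    """Full imaging configuration for one assay.

    ``channels`` is ordered and includes the white-light H&E channel;
    ``stains`` lists every stain deposited on the slide; ``unmix_stains``
    names the subset resolved by spectral unmixing (it must not exceed the
    number of narrowband channels).  Identifiability — every unmixed stain
    dominating at least one channel, and a well-conditioned effective
    absorbance matrix — is checked at construction.
    """

    assay_name: str
    channels: tuple[IlluminationChannel, ...]
    stains: tuple[StainDefinition, ...]
    camera: CameraResponsivity
    unmix_stains: tuple[str, ...]
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate channel names in {names}")
        stain_names = [s.name for s in self.stains]
        if len(set(stain_names)) != len(stain_names):
            raise ConfigurationError(f"duplicate stain names in {stain_names}")
        missing = set(self.unmix_stains) - set(stain_names)
        if missing:
            raise ConfigurationError(f"unmix stains not in stain list: {missing}")
        n_unmix_ch = len(self.unmixing_channels)
        if len(self.unmix_stains) > n_unmix_ch:
            raise ConfigurationError(
                f"{len(self.unmix_stains)} stains cannot be unmixed from "
                f"{n_unmix_ch} channels (underdetermined)"
            )
        if self.unmix_stains:
            self._check_identifiability()

    @property
    def unmixing_channels(self) -> tuple[IlluminationChannel, ...]:
        """Narrowband channels that feed the unmixer (white light excluded)."""
        return tuple(c for c in self.channels if not c.is_white)

    def stain(self, name: str) -> StainDefinition:
        for s in self.stains:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown stain {name!r} in {self.assay_name!r}")

    def channel(self, name: str) -> IlluminationChannel:
        for c in self.channels:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown channel {name!r} in {self.assay_name!r}")

    def channel_for_stain(self, stain_name: str) -> IlluminationChannel:
        """The channel dedicated to a stain (its calibration channel)."""
        for c in self.unmixing_channels:
            if c.target_stain == stain_name:
                return c
        raise ConfigurationError(
            f"no channel targets stain {stain_name!r} in {self.assay_name!r}"
        )

    def effective_absorbance_matrix(self) -> np.ndarray:
        """Channels x unmix-stains matrix of effective absorbances.

        Row order follows :attr:`unmixing_channels` (each on its matched
        plane); column order follows :attr:`unmix_stains`.
        """
        rows = []
        for ch in self.unmixing_channels:
            rows.append(
                [
                    effective_absorbance(self.stain(s), ch, self.camera, ch.matched_plane)
                    for s in self.unmix_stains
                ]
            )
        return np.asarray(rows, dtype=float)

    def _check_identifiability(self) -> None:
        m = self.effective_absorbance_matrix()
        for j, s in enumerate(self.unmix_stains):
            dominates = any(
                m[k, j] > max((m[k, i] for i in range(m.shape[1]) if i != j), default=0.0)
                for k in range(m.shape[0])
            )
            if not dominates:
                raise ConfigurationError(
                    f"stain {s!r} does not dominate any channel; not identifiable"
                )
        norms = np.linalg.norm(m, axis=0)
        cond = float(np.linalg.cond(m / norms))
        if cond >= 1e3:
            raise ConfigurationError(
                f"effective absorbance matrix of {self.assay_name!r} is "
                f"ill-conditioned (cond={cond:.3g})"
            )


def _chromogen_channel(
    name: str,
    center: float,
    fwhm: float,
    target: str,
    stains: dict[str, StainDefinition],
    camera: CameraResponsivity,
    source: str = "tungsten",
) -> IlluminationChannel:
    ch = IlluminationChannel(
        name=name,
        source=source,
        center_nm=center,
        fwhm_nm=fwhm,
        matched_plane="red",  # provisional; replaced below
        target_stain=target,
    )
    plane = select_plane(stains[target], ch, camera)
    return replace(ch, matched_plane=plane)


#: Assay definitions: (chromogen channels, visible unmixing channels, stains
#: on the slide, stains to unmix).  Channel tuples are
#: (name, center, fwhm, target stain, source).
_ASSAYS: dict[str, dict] = {
    "melanoma_1plex": dict(
        bands=[("nir770", 770.0, 30.0, "sCy7", "led")],
        visible_bands=[],
        stains=["hematoxylin", "eosin", "sCy7"],
        unmix=["sCy7"],
    ),
    "breast_her2_1plex": dict(
        bands=[("nir880", 880.0, 40.0, "ir870", "tungsten")],
        visible_bands=[],
        stains=["hematoxylin", "eosin", "ir870"],
        unmix=["ir870"],
    ),
    "hodgkin_2plex": dict(
        bands=[
            ("uv375", 375.0, 28.0, "AMC", "led"),
            ("nir769", 769.0, 49.0, "sCy7", "tungsten"),
        ],
        visible_bands=[],
        stains=["hematoxylin", "eosin", "AMC", "sCy7"],
        unmix=["AMC", "sCy7"],
    ),
    "breast_3plex": dict(
        bands=[
            ("uv375", 375.0, 28.0, "AMC", "led"),
            ("nir769", 769.0, 49.0, "sCy7", "tungsten"),
            ("nir880", 880.0, 40.0, "ir870", "tungsten"),
        ],
        visible_bands=[
            ("eosin520", 520.0, 20.0, "eosin"),
            ("hematoxylin599", 599.0, 25.0, "hematoxylin"),
        ],
        stains=["hematoxylin", "eosin", "AMC", "sCy7", "ir870"],
        unmix=["AMC", "sCy7", "ir870", "eosin", "hematoxylin"],
    ),
    "breast_dab_duplex": dict(
        bands=[
            ("blue405", 405.0, 30.0, "DAB", "tungsten"),
            ("nir769", 769.0, 49.0, "sCy7", "tungsten"),
        ],
        visible_bands=[("hematoxylin599", 599.0, 25.0, "hematoxylin")],
        stains=["hematoxylin", "DAB", "sCy7"],
        unmix=["DAB", "sCy7", "hematoxylin"],
    ),
    "prostate_4plex": dict(
        bands=[
            ("uv375", 375.0, 28.0, "AMC", "led"),
            ("blue405", 405.0, 30.0, "NMC", "tungsten"),
            ("nir769", 769.0, 49.0, "sCy7", "tungsten"),
            ("nir880", 880.0, 40.0, "ir870", "tungsten"),
        ],
        visible_bands=[
            ("eosin530", 530.0, 20.0, "eosin"),
            ("hematoxylin599", 599.0, 25.0, "hematoxylin"),
        ],
        stains=["hematoxylin", "eosin", "AMC", "NMC", "sCy7", "ir870"],
        unmix=["AMC", "NMC", "sCy7", "ir870", "eosin", "hematoxylin"],
    ),
}

ASSAY_NAMES = tuple(_ASSAYS)


def assay_config(
    assay_name: str,
    grid: WavelengthGrid = DEFAULT_GRID,
    ir_blocking_removed: bool = True,
) -> ChannelConfig:
    """Build the channel configuration for one of the demonstrated assays.

    Every assay carries the broadband white-light H&E channel first, then its
    chromogen bands, then (for the multiplex unmixing assays) the narrowband
    visible eosin and hematoxylin channels.  The prostate H&E + 4-plex assay
    therefore supplies six unmixing channels in total.
    """
    if assay_name not in _ASSAYS:
        raise ConfigurationError(
            f"unknown assay {assay_name!r}; expected one of {sorted(_ASSAYS)}"
        )
    spec = _ASSAYS[assay_name]
    library = {s.name: s for s in default_stain_library(grid)}
    camera = CameraResponsivity.default(grid, ir_blocking_removed=ir_blocking_removed)
    channels: list[IlluminationChannel] = [white_channel()]
    for name, center, fwhm, target, source in spec["bands"]:
        channels.append(
            _chromogen_channel(name, center, fwhm, target, library, camera, source)
        )
    for name, center, fwhm, target in spec["visible_bands"]:
        channels.append(
            _chromogen_channel(name, center, fwhm, target, library, camera)
        )
    return ChannelConfig(
        assay_name=assay_name,
        channels=tuple(channels),
        stains=tuple(library[s] for s in spec["stains"]),
        camera=camera,
        unmix_stains=tuple(spec["unmix"]),
    )
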