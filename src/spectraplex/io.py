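"""File formats and the run manifest.

Conventions:

* captures and blanks: 16-bit multi-page TIFF, one page per color plane
  (red, green, blue), plus a JSON sidecar naming the channel, exposure
  scale, and seed;
* ground-truth and abundance maps: 32-bit float TIFF;
* composites: 8-bit PNG;
* reference matrices: JSON (authoritative) plus CSV (for spreadsheets);
* channel configurations: YAML, validated on load by reconstructing the
  :class:`~spectraplex.spectral.ChannelConfig` (which re-runs the
  identifiability checks);
* run manifest: JSON, round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import __version__ as _pkg_version
from .calibration import ReferenceMatrix
from .errors import ConfigurationError, MissingInputError
from .slides import ChannelCapture
from .spectral import (
    AbsorbanceSpectrum,
    CameraResponsivity,
    ChannelConfig,
    IlluminationChannel,
    StainDefinition,
    WavelengthGrid,
)

__all__ = [
    "RunManifest",
    "write_capture",
    "read_capture",
    "write_float_map",
    "read_float_map",
    "write_composite_png",
    "write_reference_matrix",
    "read_reference_matrix",
    "config_to_yaml",
    "config_from_yaml",
]

_U16 = 65535


def write_capture(capture: ChannelCapture, path: str | Path, seed: int | None = None) -> None:
    """Write a capture as 16-bit multi-page TIFF (+ blank + JSON sidecar)."""
    path = Path(path)
    pages = np.moveaxis(
        np.round(np.clip(capture.rgb, 0, 1) * _U16).astype(np.uint16), -1, 0
    )
    blank_pages = np.moveaxis(
        np.round(np.clip(capture.blank_rgb, 0, 1) * _U16).astype(np.uint16), -1, 0
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    tifffile.imwrite(path.with_suffix(".blank.tiff"), blank_pages, photometric="minisblack")
    sidecar = {
        "channel_name": capture.channel_name,
        "exposure_scale": capture.exposure_scale,
        "seed": seed,
        "planes": ["red", "green", "blue"],
        "bit_depth": 16,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_capture(path: str | Path) -> ChannelCapture:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"capture not found: {path}")
    blank_path = path.with_suffix(".blank.tiff")
    if not blank_path.exists():
        raise MissingInputError(f"blank reference not found: {blank_path}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MissingInputError(f"sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    rgb = np.moveaxis(tifffile.imread(path).astype(float) / _U16, 0, -1)
    blank = np.moveaxis(tifffile.imread(blank_path).astype(float) / _U16, 0, -1)
    return ChannelCapture(
        channel_name=sidecar["channel_name"],
        rgb=rgb,
        blank_rgb=np.maximum(blank, 1e-6),
        exposure_scale=sidecar.get("exposure_scale", 1.0),
    )


def write_float_map(values: np.ndarray, path: str | Path) -> None:
    """Write a quantitative map (truth or abundance) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), values.astype(np.float32))


def read_float_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"map not found: {path}")
    return tifffile.imread(path).astype(float)


def write_composite_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write a composite as 8-bit PNG (gamma 1.0, no tone mapping)."""
    img = Image.fromarray(np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    img.save(Path(path), format="PNG")


def write_reference_matrix(ref: ReferenceMatrix, path: str | Path) -> None:
    """Write a reference matrix as JSON plus a CSV beside it."""
    path = Path(path)
    doc = {
        "matrix": ref.matrix.tolist(),
        "channel_order": list(ref.channel_order),
        "stain_order": list(ref.stain_order),
        "normalization": ref.normalization,
        "condition_number": ref.condition_number,
    }
    path.write_text(json.dumps(doc, indent=2))
    pd.DataFrame(
        ref.matrix, index=list(ref.channel_order), columns=list(ref.stain_order)
    ).to_csv(path.with_suffix(".csv"))


def read_reference_matrix(path: str | Path) -> ReferenceMatrix:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"reference matrix not found: {path}")
    doc = json.loads(path.read_text())
    return ReferenceMatrix(
        matrix=np.asarray(doc["matrix"], dtype=float),
        channel_order=tuple(doc["channel_order"]),
        stain_order=tuple(doc["stain_order"]),
        normalization=doc["normalization"],
    )


def config_to_yaml(config: ChannelConfig, path: str | Path) -> None:
    """Serialize an assay configuration to YAML.

    Stain spectra are stored as their parametric Gaussian components; custom
    non-parametric camera curves are not serialized (the default parametric
    camera is reconstructed on load).
    """
    doc = {
        "assay_name": config.assay_name,
        "grid": {
            "start_nm": config.grid.start_nm,
            "stop_nm": config.grid.stop_nm,
            "step_nm": config.grid.step_nm,
        },
        "camera": {
            "ir_blocking_removed": config.camera.ir_blocking_removed,
            "white_balance_gains": list(config.camera.white_balance_gains),
        },
        "channels": [
            {
                "name": c.name,
                "source": c.source,
                "center_nm": c.center_nm,
                "fwhm_nm": c.fwhm_nm,
                "matched_plane": c.matched_plane,
                "profile": c.profile,
                "target_stain": c.target_stain,
            }
            for c in config.channels
        ],
        "stains": [
            {
                "name": s.name,
                "components": [list(c) for c in s.spectrum.components],
                "display_color_rgb": list(s.display_color_rgb),
                "fluor_color_rgb": list(s.fluor_color_rgb),
                "visible": s.visible,
            }
            for s in config.stains
        ],
        "unmix_stains": list(config.unmix_stains),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_CONFIG_KEYS = {"assay_name", "grid", "camera", "channels", "stains", "unmix_stains"}


def config_from_yaml(path: str | Path) -> ChannelConfig:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or not _CONFIG_KEYS <= set(doc):
        missing = _CONFIG_KEYS - set(doc or {})
        raise ConfigurationError(f"config {path} missing keys: {sorted(missing)}")
    grid = WavelengthGrid(**doc["grid"])
    camera = CameraResponsivity.default(
        grid, ir_blocking_removed=doc["camera"]["ir_blocking_removed"]
    )
    if "white_balance_gains" in doc["camera"]:
        camera = CameraResponsivity(
            plane_curves=camera.plane_curves,
            ir_blocking_removed=camera.ir_blocking_removed,
            white_balance_gains=tuple(doc["camera"]["white_balance_gains"]),
            grid=grid,
        )
    channels = tuple(IlluminationChannel(**c) for c in doc["channels"])
    stains = []
    for s in doc["stains"]:
        spectrum = AbsorbanceSpectrum.from_gaussians(
            s["name"], [tuple(c) for c in s["components"]], grid
        )
        stains.append(
            StainDefinition(
                name=s["name"],
                spectrum=spectrum,
                display_color_rgb=tuple(s["display_color_rgb"]),
                fluor_color_rgb=tuple(s["fluor_color_rgb"]),
                visible=s["visible"],
            )
        )
    return ChannelConfig(
        assay_name=doc["assay_name"],
        channels=channels,
        stains=tuple(stains),
        camera=camera,
        unmix_stains=tuple(doc["unmix_stains"]),
        grid=grid,
    )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run; serializes losslessly to JSON."""

    assay_name: str
    seed: int
    channels: list[str]
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    software_version: str = _pkg_version
    timestamp: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunManifest":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def verify_outputs(self) -> list[str]:
        """Paths referenced by the manifest that do not exist on disk."""
        return [
            p
            for p in list(self.inputs.values()) + list(self.outputs.values())
            if not Path(p).exists()
        ]
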