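"""Per-pixel constrained linear spectral unmixing.

Each pixel's vector of per-channel optical densities ``b`` is modeled as
``M a`` where ``M`` is the calibrated reference matrix and ``a`` the
non-negative per-stain abundances.  The solver is non-negative least squares
(abundances are physical stain quantities), applied independently per pixel:
no spatial coupling, so results are invariant to pixel visitation order.

For speed, the unconstrained least-squares solution is computed for all
pixels at once; it coincides with the NNLS optimum wherever it is already
non-negative, and only the remaining pixels fall back to the iterative NNLS
solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .calibration import OD_CAP, OD_FLOOR, ODImage, ReferenceMatrix, od_from_capture
from .errors import ChannelMismatchError, ConfigurationError
from .slides import ChannelCapture, VirtualSlide
from .spectral import ChannelConfig

__all__ = [
    "ODStack",
    "AbundanceResult",
    "unmix_pixel",
    "unmix_stack",
    "od_stack_from_captures",
    "crosstalk_report",
]


@dataclass
class ODStack:
    """Ordered per-channel OD images ready for unmixing."""

    layers: list[ODImage]
    registered: bool = True

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("empty OD stack")
        shape = self.layers[0].values.shape
        for layer in self.layers:
            if layer.values.shape != shape:
                raise ChannelMismatchError(
                    f"layer {layer.channel_name!r} has shape {layer.values.shape}, "
                    f"expected {shape}"
                )

    @property
    def channel_order(self) -> tuple[str, ...]:
        return tuple(layer.channel_name for layer in self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].values.shape

    def as_array(self) -> np.ndarray:
        """(channels, H, W) array."""
        return np.stack([layer.values for layer in self.layers])


@dataclass
class AbundanceResult:
    """Unmixed per-stain abundance maps plus the per-pixel residual norm."""

    maps: dict[str, np.ndarray]
    residual_rms: np.ndarray
    stain_order: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in self.stain_order:
            if name not in self.maps:
                raise ConfigurationError(f"missing abundance map {name!r}")
        for name, m in self.maps.items():
            if np.any(m < 0):
                raise ConfigurationError(f"negative abundance in {name!r}")
        if np.any(self.residual_rms < 0):
            raise ConfigurationError("negative residual")

    def map(self, stain_name: str) -> np.ndarray:
        return self.maps[stain_name]


def unmix_pixel(b: np.ndarray, m: ReferenceMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Solve one pixel: a = argmin_{a >= 0} ||M a - b||_2.

    Returns the abundance vector and the residual 2-norm.
    """
    matrix = m.matrix if isinstance(m, ReferenceMatrix) else np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    if b.shape != (matrix.shape[0],):
        raise ChannelMismatchError(
            f"OD vector length {b.shape} does not match {matrix.shape[0]} channels"
        )
    a, rnorm = _scipy_nnls(matrix, b)
    return a, float(rnorm)


def _solve_nnls_batch(matrix: np.ndarray, b: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """NNLS for every column of b (channels x pixels) -> stains x pixels.

    Strategy: solve the unconstrained LS for all pixels at once (it equals
    the NNLS optimum wherever already non-negative), then iteratively drop
    negative supports, solving pixels grouped by identical support pattern
    so each group is one vectorized restricted LS.  Pixels whose final
    solution violates the NNLS KKT conditions (rare) are re-solved exactly
    with the reference per-pixel solver.
    """
    n_st = matrix.shape[1]
    n_px = b.shape[1]
    a = np.zeros((n_st, n_px))
    work = np.nonzero(np.any(b > 0, axis=0))[0]
    if work.size == 0:
        return a
    bw = b[:, work]
    active = np.ones((n_st, work.size), dtype=bool)
    sol = np.zeros((n_st, work.size))
    for _ in range(n_st):
        uniq, inverse = np.unique(active.T, axis=0, return_inverse=True)
        changed = False
        for k in range(uniq.shape[0]):
            supp = uniq[k]
            cols = np.nonzero(inverse == k)[0]
            if not supp.any():
                sol[:, cols] = 0.0
                continue
            ls = np.linalg.lstsq(matrix[:, supp], bw[:, cols], rcond=None)[0]
            full = np.zeros((n_st, cols.size))
            full[supp] = ls
            neg = full < -tol
            if neg.any():
                changed = True
                active[:, cols] &= ~neg
            sol[:, cols] = full
        if not changed:
            break
    sol = np.clip(sol, 0.0, None)
    # KKT: for zeroed components the gradient of 0.5||Ma-b||^2 must be >= 0.
    grad = matrix.T @ (matrix @ sol - bw)
    viol = np.any((sol <= tol) & (grad < -1e-8), axis=0)
    for j in np.nonzero(viol)[0]:
        sol[:, j] = _scipy_nnls(matrix, bw[:, j])[0]
    a[:, work] = sol
    return a


def unmix_stack(stack: ODStack, m: ReferenceMatrix) -> AbundanceResult:
    """Unmix every pixel of an OD stack against a reference matrix."""
    if not stack.registered:
        raise ConfigurationError("OD stack is not registered")
    if stack.channel_order != m.channel_order:
        offending = [
            f"{a!r} vs {b!r}"
            for a, b in zip(stack.channel_order, m.channel_order)
            if a != b
        ] or [f"{stack.channel_order} vs {m.channel_order}"]
        raise ChannelMismatchError(
            "stack channel order does not match reference matrix: "
            + "; ".join(offending)
        )
    h, w = stack.shape
    b = stack.as_array().reshape(len(stack.layers), -1)
    a = _solve_nnls_batch(m.matrix, b)
    resid = m.matrix @ a - b
    residual_rms = np.sqrt(np.mean(resid**2, axis=0)).reshape(h, w)
    maps = {
        name: a[i].reshape(h, w) for i, name in enumerate(m.stain_order)
    }
    return AbundanceResult(
        maps=maps, residual_rms=residual_rms, stain_order=m.stain_order
    )


def od_stack_from_captures(
    captures: list[ChannelCapture] | dict[str, ChannelCapture],
    config: ChannelConfig,
    od_cap: float = OD_CAP,
    floor: float = OD_FLOOR,
) -> ODStack:
    """Build the unmixing OD stack from an assay's captures.

    Uses each unmixing channel's matched color plane; the white-light H&E
    capture is display-only and never enters the stack.
    """
    if not isinstance(captures, dict):
        captures = {c.channel_name: c for c in captures}
    layers = []
    for ch in config.unmixing_channels:
        if ch.name not in captures:
            raise ChannelMismatchError(f"no capture for channel {ch.name!r}")
        layers.append(
            od_from_capture(captures[ch.name], ch.matched_plane, od_cap, floor)
        )
    return ODStack(layers=layers)


def crosstalk_report(
    result: AbundanceResult,
    slide: VirtualSlide,
    min_abundance: float = 1e-6,
) -> pd.DataFrame:
    """Per-stain-pair contamination fractions against simulator ground truth.

    Entry (i, j) is the mean recovered abundance of stain j over pixels where
    only stain i is truly present, divided by the mean true abundance of i
    there.  Diagonal entries near 1 mean faithful recovery; off-diagonal
    entries near 0 mean crosstalk was removed.  Pairs with no exclusive
    pixels are reported as NaN.
    """
    true_stains = [s for s in result.stain_order if s in slide.abundance_maps]
    recovered_stains = list(result.stain_order)
    if not true_stains:
        raise ConfigurationError("no common stains between result and slide")
    shape = slide.abundance_maps[true_stains[0]].shape
    if result.residual_rms.shape != shape:
        raise ChannelMismatchError(
            f"result shape {result.residual_rms.shape} does not match slide {shape}"
        )
    table = np.full((len(true_stains), len(recovered_stains)), np.nan)
    for i, src in enumerate(true_stains):
        true_i = slide.abundance_maps[src]
        only_i = true_i > min_abundance
        for other in slide.abundance_maps:
            if other != src:
                only_i &= slide.abundance_maps[other] <= min_abundance
        if not only_i.any():
            continue
        denom = float(true_i[only_i].mean())
        for j, dst in enumerate(recovered_stains):
            table[i, j] = float(result.maps[dst][only_i].mean()) / denom
    return pd.DataFrame(
        table, index=true_stains, columns=recovered_stains
    ).rename_axis(index="true_stain", columns="recovered_stain")
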