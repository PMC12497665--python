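"""Segmented IVIM fitting: ADC and fractional blood volume maps.

The segmented approach exploits that pseudo-diffusion (D*) decays an order
of magnitude faster than tissue diffusion: at b >= 200 s/mm^2 the perfusion
compartment has essentially vanished, so a log-linear fit over the
200-800 s/mm^2 b-values estimates the tissue diffusion coefficient (the
ADC), and the deficit of the back-extrapolated intercept relative to the
measured b=0 signal estimates the perfusion fraction, reported here as the
fractional blood volume (fBV):

    ln S(b) = A - b * D        for 200 <= b <= 800
    ADC = D,   fBV = 1 - exp(A) / S(0)

Negative fitted ADC or fBV voxels carry no physical meaning and are set to
zero; fBV is capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RegionMask, VolumeGrid

# Inclusive b-value window entering the diffusion fit.
B_SELECT_MIN = 200.0
B_SELECT_MAX = 800.0


class IvimConfigurationError(ValueError):
    pass


@dataclass
class DwiStack:
    """Multi-b DWI stack on a common grid, optionally restricted by a mask."""

    volumes: dict[float, VolumeGrid]
    mask: RegionMask | None = None

    def __post_init__(self) -> None:
        geoms = [v.geometry for v in self.volumes.values()]
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1 or any(not g.approx_equal(geoms[0]) for g in geoms):
            raise ValueError("all DWI volumes must share one grid geometry")
        bs = sorted(self.volumes)
        if 0.0 not in bs:
            raise IvimConfigurationError("DWI stack must contain b=0")
        if sum(1 for b in bs if B_SELECT_MIN <= b <= B_SELECT_MAX) < 2:
            raise IvimConfigurationError(
                f"need >= 2 b-values in [{B_SELECT_MIN:g}, {B_SELECT_MAX:g}] s/mm^2"
            )

    @property
    def b_values(self) -> list[float]:
        return sorted(self.volumes)

    @property
    def selected_b(self) -> list[float]:
        return [b for b in self.b_values if B_SELECT_MIN <= b <= B_SELECT_MAX]


@dataclass
class ParameterMaps:
    adc: VolumeGrid
    fbv: VolumeGrid
    fit_failed: np.ndarray  # True where a voxel could not be fitted

    def n_failed(self) -> int:
        return int(self.fit_failed.sum())


def fit_segmented_ivim(stack: DwiStack, clamp: bool = True) -> ParameterMaps:
    """Voxelwise segmented IVIM fit over the 200-800 s/mm^2 window.

    Ordinary least squares on ln S(b) vs b, restricted to the selected
    b-values, gives slope -ADC and intercept A; fBV = 1 - exp(A)/S(0).
    Voxels with a non-positive signal at b=0 or at any selected b-value are
    flagged in ``fit_failed`` and set to ADC = fBV = 0.
    """
    sel_b = np.array(stack.selected_b)
    s0 = stack.volumes[0.0].data.astype(float)
    sel = np.stack([stack.volumes[b].data.astype(float) for b in sel_b], axis=-1)

    geom = stack.volumes[0.0].geometry
    shape = s0.shape

    domain = np.ones(shape, dtype=bool)
    if stack.mask is not None:
        if stack.mask.voxels.shape != shape:
            raise ValueError("fit mask must live on the DWI grid")
        domain = stack.mask.voxels

    usable = domain & (s0 > 0) & np.all(sel > 0, axis=-1)
    failed = domain & ~usable

    adc = np.zeros(shape)
    fbv = np.zeros(shape)
    if usable.any():
        y = np.log(sel[usable])                       # (n_vox, n_b)
        bc = sel_b - sel_b.mean()
        slope = (y * bc).sum(axis=1) / (bc ** 2).sum()
        intercept = y.mean(axis=1) - slope * sel_b.mean()
        adc[usable] = -slope
        fbv[usable] = 1.0 - np.exp(intercept) / s0[usable]

    maps = ParameterMaps(
        adc=VolumeGrid(data=adc, geometry=geom),
        fbv=VolumeGrid(data=fbv, geometry=geom),
        fit_failed=failed,
    )
    return clamp_nonphysical(maps) if clamp else maps


def clamp_nonphysical(maps: ParameterMaps) -> ParameterMaps:
    """Zero out negative ADC/fBV voxels and cap fBV at 1. Idempotent."""
    adc = np.maximum(maps.adc.data, 0.0)
    fbv = np.clip(maps.fbv.data, 0.0, 1.0)
    return ParameterMaps(
        adc=maps.adc.with_data(adc),
        fbv=maps.fbv.with_data(fbv),
        fit_failed=maps.fit_failed,
    )


def read_bvals(path) -> list[float]:
    """Read a one-value-per-line (or whitespace-separated) b-value text file."""
    text = open(path).read().split()
    return [float(t) for t in text]
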