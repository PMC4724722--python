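"""Shared comparison-result contract for the permutation and parametric engines.

Both engines run the identical pipeline up to the voxelwise t-map and differ
only in the inference step, so they share the record types here: a
:class:`Peak` per suprathreshold local maximum and one :class:`ComparisonRecord`
per direction (increase / decrease) carrying the family-wise-error flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthdata import BrainMask

__all__ = ["Peak", "ComparisonRecord", "SingleCaseResult", "find_peaks", "world_coordinates"]


#: 3x3x3 footprint of the 18-connected neighbourhood (faces + edges, no corners)
_FOOTPRINT_18 = (np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0) <= 2)


@dataclass
class Peak:
    """A suprathreshold local maximum of the statistic map."""

    voxel: tuple[int, int, int]
    world_mm: tuple[float, float, float]
    t: float
    p_fwe: float


@dataclass
class ComparisonRecord:
    """Outcome of one single-case comparison in one direction."""

    comparison_id: str
    engine: str                 # {"permutation", "parametric"}
    smoothing_fwhm: float
    condition_tag: str
    direction: str              # {"increase", "decrease"}
    fwe_flag: bool
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fwe_flag != bool(self.peaks):
            raise ValueError("fwe_flag must be true exactly when peaks is nonempty")


@dataclass
class SingleCaseResult:
    """Full output of one single-case comparison: both directions plus maps."""

    records: list[ComparisonRecord]
    tmap: "object"                       # massglm.TMap for the increase contrast
    mask: BrainMask
    p_increase: np.ndarray               # per in-mask voxel FWE-corrected p
    p_decrease: np.ndarray
    extras: dict = field(default_factory=dict)

    def record(self, direction: str) -> ComparisonRecord:
        for r in self.records:
            if r.direction == direction:
                return r
        raise KeyError(direction)


def world_coordinates(
    voxel: tuple[int, int, int],
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Grid-centred world coordinates in mm: (index - centre) * voxel size."""
    return tuple(
        float((voxel[a] - (grid_shape[a] - 1) / 2.0) * voxel_size[a]) for a in range(3)
    )


def find_peaks(
    t_flat: np.ndarray,
    p_flat: np.ndarray,
    mask: BrainMask,
    alpha: float,
    voxel_size: tuple[float, float, float],
) -> list[Peak]:
    """Suprathreshold local maxima under 18-connectivity.

    A voxel is suprathreshold when its FWE-corrected p is below ``alpha``
    (``alpha = 1`` accepts every voxel); a peak is a suprathreshold voxel whose
    t is not exceeded by any 18-connected in-mask neighbour. For the decrease
    direction, pass the negated t-map.
    """
    supra = p_flat < alpha if alpha < 1.0 else np.ones_like(p_flat, dtype=bool)
    if not supra.any():
        return []
    shape = mask.include.shape
    tvol = np.full(shape, -np.inf)
    tvol[mask.include] = t_flat
    neigh_max = ndimage.maximum_filter(tvol, footprint=_FOOTPRINT_18, mode="constant", cval=-np.inf)
    supra_vol = np.zeros(shape, dtype=bool)
    supra_vol[mask.include] = supra
    is_peak = supra_vol & (tvol >= neigh_max)
    peaks = []
    p_vol = np.ones(shape)
    p_vol[mask.include] = p_flat
    for ijk in np.argwhere(is_peak):
        vox = tuple(int(v) for v in ijk)
        peaks.append(
            Peak(
                voxel=vox,
                world_mm=world_coordinates(vox, shape, voxel_size),
                t=float(tvol[vox]),
                p_fwe=float(p_vol[vox]),
            )
        )
    peaks.sort(key=lambda p: -abs(p.t))
    return peaks
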