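"""Scoring of a CT ventilation map against a reference ventilation image.

The scores follow the convention of multi-institutional CT-ventilation
validation studies: the voxelwise Spearman rank correlation over the
lung mask, and the Dice overlap of the 25% highest (DSC-high) and 25%
lowest (DSC-low) functional regions, each map thresholded at its own
within-mask quartile.  All three scores are invariant to strictly
monotone transforms of either map.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.stats import rankdata

from .ventilation import VentilationMap
from .volume import DegenerateInputError, DomainError, GeometryError, LungMask


@dataclass
class EvalResult:
    spearman: float
    dsc_high: float
    dsc_low: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.spearman <= 1 + 1e-12):
            raise ValueError(f"spearman out of [-1, 1]: {self.spearman}")
        for name in ("dsc_high", "dsc_low"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if self.n_voxels < 2:
            raise DomainError("evaluation needs at least 2 mask voxels")

    def to_dict(self) -> dict:
        return {"spearman": self.spearman, "dsc_high": self.dsc_high,
                "dsc_low": self.dsc_low, "n_voxels": self.n_voxels}


def _masked_pair(ctvi: VentilationMap, refvi: VentilationMap,
                 mask: LungMask) -> tuple[np.ndarray, np.ndarray]:
    if ctvi.shape != refvi.shape or ctvi.shape != mask.shape:
        raise GeometryError("maps and mask must share one grid")
    if mask.n_voxels < 2:
        raise DomainError("evaluation needs at least 2 mask voxels")
    return ctvi.values[mask.values], refvi.values[mask.values]


def spearman(ctvi: VentilationMap, refvi: VentilationMap, mask: LungMask) -> float:
    """Spearman rank correlation: Pearson correlation of fractional ranks."""
    a, b = _masked_pair(ctvi, refvi, mask)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("Spearman undefined for a constant map")
    ra, rb = rankdata(a, method="average"), rankdata(b, method="average")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / math.sqrt((ra @ ra) * (rb @ rb)))


def _quartile_set(x: np.ndarray, tail: str) -> np.ndarray:
    """Boolean selection of the ceil(N/4) most extreme voxels, ties by rank.

    Stable argsort order resolves exact ties deterministically so each
    set holds exactly ceil(N/4) voxels even on maps with many ties.
    """
    n = x.size
    k = math.ceil(n / 4)
    order = np.argsort(x, kind="stable")
    sel = np.zeros(n, dtype=bool)
    if tail == "high":
        sel[order[n - k:]] = True
    elif tail == "low":
        sel[order[:k]] = True
    else:
        raise ValueError(f"tail must be 'high' or 'low', got {tail!r}")
    return sel


def dsc_quartile(ctvi: VentilationMap, refvi: VentilationMap, mask: LungMask,
                 tail: str = "high") -> float:
    """Dice overlap of the 25% highest (or lowest) functional regions.

    Each map is binarized at its own within-mask quartile; the sets are
    rank-determined, so the score only sees each map's voxel ordering.
    """
    a, b = _masked_pair(ctvi, refvi, mask)
    sa, sb = _quartile_set(a, tail), _quartile_set(b, tail)
    inter = int((sa & sb).sum())
    return 2.0 * inter / (int(sa.sum()) + int(sb.sum()))


def evaluate(ctvi: VentilationMap, refvi: VentilationMap, mask: LungMask) -> EvalResult:
    """Bundle Spearman, DSC-high and DSC-low over the lung mask."""
    return EvalResult(
        spearman=spearman(ctvi, refvi, mask),
        dsc_high=dsc_quartile(ctvi, refvi, mask, "high"),
        dsc_low=dsc_quartile(ctvi, refvi, mask, "low"),
        n_voxels=mask.n_voxels,
    )
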