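"""Rank-ordering normalization and smooth-minimum fusion of ventilation maps.

Two surrogate ventilation maps computed in unrelated units can only be
combined consistently if the combination depends on each map through its
voxel ordering alone (local rescaling invariance): F(f(A), g(B)) = F(A, B)
for any strictly increasing f, g.  Each map is therefore converted to a
normalized *ordering map* — in-mask voxels ranked ascending, rescaled so
the smallest value maps to 0 and the largest to 1 — and the two ordering
maps are fused with a smooth minimum, which highlights regions flagged as
dysfunctional by either component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .ventilation import VentilationMap
from .volume import DegenerateInputError, GeometryError, LungMask


@dataclass
class OrderingMap:
    """Rank-normalized map: in-mask values in [0, 1], monotone in the source."""

    values: np.ndarray
    mask: LungMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise GeometryError("ordering map grid does not match its mask")
        inmask = self.values[self.mask.values]
        if inmask.min() < -1e-12 or inmask.max() > 1 + 1e-12:
            raise ValueError("ordering-map values must lie in [0, 1] on the mask")

    def masked(self) -> np.ndarray:
        return self.values[self.mask.values]


def ordering_map(vmap: VentilationMap, mask: LungMask | None = None,
                 background: float = 0.0) -> OrderingMap:
    """Rank in-mask voxels ascending and rescale the ranks onto [0, 1].

    Ties receive the mean of their rank span (fractional ranks), the
    unique choice that keeps the result invariant under weakly monotone
    transforms of the input.  Voxels outside the mask are set to
    ``background``.
    """
    mask = vmap.mask if mask is None else mask
    if mask.shape != vmap.shape:
        raise GeometryError("map and mask must share one grid")
    if mask.n_voxels < 2:
        raise DegenerateInputError("ordering needs at least 2 mask voxels")
    src = vmap.values[mask.values]
    if np.ptp(src) == 0:
        raise DegenerateInputError("ordering map undefined for an all-equal input")
    ranks = rankdata(src, method="average")  # 1..N with fractional ties
    # rescale by the attained rank extremes so the smallest value maps to
    # exactly 0 and the largest to exactly 1 even when they are tied
    # (tie groups carry mean ranks, so rank 1 / rank N need not occur)
    normalized = (ranks - ranks.min()) / (ranks.max() - ranks.min())
    out = np.full(vmap.shape, background, dtype=np.float64)
    out[mask.values] = normalized
    return OrderingMap(values=out, mask=mask)


def smooth_min(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise smooth minimum (a e^-a + b e^-b) / (e^-a + e^-b).

    Symmetric, equals its arguments when they agree, and lies between
    min(a, b) and the arithmetic mean: the e^-x weights favor the
    smaller argument.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"grids differ: {a.shape} vs {b.shape}")
    wa, wb = np.exp(-a), np.exp(-b)
    return (a * wa + b * wb) / (wa + wb)


def fuse_hector(
    vol_map: VentilationMap,
    hu_map: VentilationMap,
    mask: LungMask,
    background: float = 0.0,
) -> VentilationMap:
    """The hybrid metric: Smin(ON(CTVI_HU), ON(CTVI_vol)) on the exhale mask."""
    if vol_map.shape != hu_map.shape or vol_map.shape != mask.shape:
        raise GeometryError("both maps and the mask must share the exhale grid")
    on_hu = ordering_map(hu_map, mask)
    on_vol = ordering_map(vol_map, mask)
    fused = smooth_min(on_hu.values, on_vol.values)
    out = np.full(mask.shape, background, dtype=np.float64)
    out[mask.values] = fused[mask.values]
    return VentilationMap(values=out, mask=mask, label="hector")
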