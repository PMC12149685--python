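"""Ventilation metrics: the volume-based map from the registration
divergence and the HU-based air-tissue density map from the exhale CT.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Literal

import numpy as np
from scipy import ndimage

from .registration import DisplacementField, DivCurlField
from .volume import GeometryError, LungMask, ScalarVolume, UnitError, median_filter

logger = logging.getLogger(__name__)

MetricLabel = Literal["vol", "hu", "hector", "truth"]


@dataclass
class VentilationMap:
    """Scalar functional map on lung voxels; values outside the mask are
    carried but carry no meaning."""

    values: np.ndarray
    mask: LungMask
    label: MetricLabel = "vol"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise GeometryError(
                f"map grid {self.values.shape} does not match mask {self.mask.shape}")
        if not np.isfinite(self.values[self.mask.values]).all():
            raise ValueError("non-finite ventilation values inside the lung mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def masked(self) -> np.ndarray:
        """The in-mask values as a flat array."""
        return self.values[self.mask.values]


def specific_volume_change(divcurl: DivCurlField, mask: LungMask) -> VentilationMap:
    """Specific volume change sVol* = 1 - Jac ~= -div(u) = -f1 on the inhale grid.

    The first-order Jacobian approximation reads the volume change
    directly off the registration's divergence variable, avoiding any
    derivative post-processing of the displacement.
    """
    if divcurl.shape != mask.shape:
        raise GeometryError("div-curl field and mask must share one grid")
    return VentilationMap(values=-divcurl.f1, mask=mask, label="vol")


def invert_displacement(
    displacement: DisplacementField,
    max_iter: int = 20,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point inverse of y = x + u(x) on the grid of y.

    Returns ``(x, converged)`` where ``x`` holds the pre-image coordinates
    (3, nx, ny, nz) and ``converged`` flags voxels whose fixed-point
    iteration ``x <- y - u(x)`` reached ``tol`` voxels.
    """
    u = displacement.u
    y = np.indices(u.shape[1:], dtype=np.float64)
    x = y.copy()
    for _ in range(max_iter):
        ux = np.stack([
            ndimage.map_coordinates(u[a], x, order=1, mode="nearest") for a in range(3)
        ])
        x_new = y - ux
        delta = np.sqrt(((x_new - x) ** 2).sum(axis=0))
        x = x_new
        if delta.max() < tol:
            break
    converged = delta < tol
    return x, converged


def transport_to_exhale(
    map_inhale: VentilationMap,
    displacement: DisplacementField,
    exhale_mask: LungMask,
    max_iter: int = 20,
    tol: float = 0.01,
) -> VentilationMap:
    """Push the inhale-grid map forward onto the exhale anatomy.

    Realizes CTVIvol(x + u(x)) = -f1(x): for every exhale voxel y the
    pre-image x with y = x + u(x) is found by fixed-point iteration and
    the map is sampled there trilinearly.  Exhale-mask voxels whose
    pre-image leaves the grid are filled from the nearest valid in-mask
    voxel.
    """
    if displacement.shape != map_inhale.shape or exhale_mask.shape != map_inhale.shape:
        raise GeometryError("map, displacement and exhale mask must share one grid")
    x, converged = invert_displacement(displacement, max_iter=max_iter, tol=tol)

    n_bad = int((~converged[exhale_mask.values]).sum())
    n_mask = exhale_mask.n_voxels
    if n_bad > 0.05 * n_mask:
        logger.warning("fixed-point inversion failed at %d / %d exhale-mask voxels",
                       n_bad, n_mask)

    out = ndimage.map_coordinates(map_inhale.values, x, order=1, mode="nearest")

    shape = np.asarray(map_inhale.shape, dtype=np.float64)
    inside = np.ones(map_inhale.shape, bool)
    for a in range(3):
        inside &= (x[a] >= 0) & (x[a] <= shape[a] - 1)
    invalid = exhale_mask.values & ~inside
    if invalid.any():
        valid = exhale_mask.values & inside
        if valid.any():
            _, nearest = ndimage.distance_transform_edt(~valid, return_indices=True)
            out[invalid] = out[tuple(idx[invalid] for idx in nearest)]
        logger.warning("%d exhale-mask voxels had out-of-grid pre-images; "
                       "filled from nearest valid voxel", int(invalid.sum()))

    return VentilationMap(values=out, mask=exhale_mask, label="vol")


def ctvi_hu(
    exhale_hu: ScalarVolume,
    mask: LungMask,
    filter_patch: int = 5,
) -> VentilationMap:
    """HU-based ventilation: product of air and tissue fractional densities.

    With rho_air = -HU/1000 and rho_tissue = (HU + 1000)/1000 the map is
    rho_air * rho_tissue, maximal (0.25) at HU = -500 and zero at pure
    air (-1000) or pure tissue (0).  HU outside [-1000, 0] (vessels,
    calcifications) is clamped first so the product stays non-negative.
    A cubic median filter (default patch 5) suppresses noise; it runs on
    the full grid before masking to avoid mask-edge bias.
    """
    if exhale_hu.unit == "normalized":
        raise UnitError("ctvi_hu needs the HU copy of the exhale scan, "
                        "not the 0-1 normalized volume")
    if exhale_hu.shape != mask.shape:
        raise GeometryError("exhale volume and mask must share one grid")
    hu = np.clip(exhale_hu.values, -1000.0, 0.0)
    rho_air = -hu / 1000.0
    rho_tissue = (hu + 1000.0) / 1000.0
    vals = rho_air * rho_tissue
    if filter_patch > 1:
        vals = median_filter(ScalarVolume(vals, spacing=exhale_hu.spacing),
                             patch=filter_patch).values
    return VentilationMap(values=vals, mask=mask, label="hu")
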