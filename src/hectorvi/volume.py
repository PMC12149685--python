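"""Volume and mask containers, file I/O, and grid preprocessing.

All 3-D grids are stored as numpy arrays indexed ``[i, j, k]`` in the
image coordinate frame (the same axis order SimpleITK uses for physical
coordinates).  World coordinates are ``origin + direction @ (index *
spacing)``.  After preprocessing the pipeline treats voxels as isotropic
units of the resampled grid; anisotropic input spacing is absorbed by the
resampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

HU_AIR = -1000.0
HU_MIN, HU_MAX = -1024.0, 3071.0

Unit = Literal["hu", "normalized", "none"]
Phase = Literal["inhale", "exhale"]


class FormatError(ValueError):
    """Unreadable file, unsupported format, or non-3-D payload."""


class DomainError(ValueError):
    """Invalid spatial domain (e.g. an empty lung mask)."""


class DegenerateInputError(ValueError):
    """Input without enough variation for the operation (e.g. constant volume)."""


class ParameterError(ValueError):
    """Invalid parameter value (e.g. even median-filter patch)."""


class UnitError(ValueError):
    """Volume carries the wrong intensity unit for the operation."""


class GeometryError(ValueError):
    """Grids that must share a geometry do not."""


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.asarray(x).ravel())
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ScalarVolume:
    """A 3-D scalar grid (HU or dimensionless) with geometry metadata.

    Parameters
    ----------
    values : ndarray
        3-D array indexed ``[i, j, k]``.
    spacing : tuple of float
        Voxel size in mm along each axis; strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    direction : ndarray
        3x3 orientation matrix (rows of direction cosines).
    unit : {"hu", "normalized", "none"}
        Intensity semantics.  HU volumes must lie in [-1024, 3071],
        normalized volumes in [0, 1].
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    unit: Unit = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3-D grid, got {self.values.ndim}-D")
        if min(self.values.shape) < 2:
            raise FormatError(f"grid dimensions must be >= 2, got {self.values.shape}")
        self.spacing = _as_tuple3(self.spacing)
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if self.unit == "hu":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < HU_MIN or hi > HU_MAX:
                raise ValueError(f"HU values out of [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]")
        elif self.unit == "normalized":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"normalized values out of [0, 1]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "ScalarVolume":
        """New volume with the same geometry and different values."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       unit=self.unit if unit is None else unit)

    def same_grid(self, other: "ScalarVolume | LungMask") -> bool:
        return self.shape == other.shape


@dataclass
class LungMask:
    """Binary lung mask aligned with a companion :class:`ScalarVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    phase: Phase = "inhale"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got {self.values.ndim}-D")
        if not self.values.any():
            raise DomainError("lung mask has no foreground voxel")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# File I/O (NIfTI .nii/.nii.gz and MetaImage .mha/.mhd via SimpleITK)
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported format: {path.name} (expected one of {_SUPPORTED_SUFFIXES})")


def read_volume(path: str | Path, unit: Unit = "none") -> ScalarVolume:
    """Read a NIfTI or MetaImage volume, preserving spacing/origin/orientation."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - sitk raises bare RuntimeError
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3-D payload, got {img.GetDimension()}-D in {path}")
    # sitk arrays are [z, y, x]; transpose to [x, y, z]
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ScalarVolume(
        values=values,
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
        unit=unit,
    )


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a volume as NIfTI or MetaImage; ``read_volume`` inverts it exactly."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(vol.values.transpose(2, 1, 0))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(tuple(vol.direction.ravel()))
    sitk.WriteImage(img, str(path))


def write_vector_field(field: np.ndarray, path: str | Path,
                       spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    """Write an (m, nx, ny, nz) field as a multi-component NIfTI/MHA image."""
    path = Path(path)
    _check_suffix(path)
    field = np.asarray(field, dtype=np.float64)
    img = sitk.GetImageFromArray(field.transpose(3, 2, 1, 0), isVector=True)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_vector_field(path: str | Path) -> np.ndarray:
    """Read a multi-component image back as an (m, nx, ny, nz) array."""
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img).transpose(3, 2, 1, 0)


def read_mask(path: str | Path, phase: Phase) -> LungMask:
    vol = read_volume(path)
    return LungMask(values=vol.values > 0.5, spacing=vol.spacing,
                    origin=vol.origin, direction=vol.direction, phase=phase)


def write_mask(mask: LungMask, path: str | Path) -> None:
    write_volume(ScalarVolume(values=mask.values.astype(np.float64),
                              spacing=mask.spacing, origin=mask.origin,
                              direction=mask.direction), path)


# ---------------------------------------------------------------------------
# Geometry record: crop/pad offsets + resampling factors, invertible
# ---------------------------------------------------------------------------

@dataclass
class GeometryRecord:
    """Maps processed-grid voxel coordinates back to the original grid.

    ``x_original = crop_offset + x_processed * scale`` per axis, where
    ``scale = (cropped_dim - 1) / (target_dim - 1)``.  The map is affine,
    hence exactly invertible.
    """

    original_shape: tuple[int, int, int]
    crop_offset: tuple[int, int, int]
    cropped_shape: tuple[int, int, int]
    target_shape: tuple[int, int, int]

    @property
    def scale(self) -> np.ndarray:
        return (np.asarray(self.cropped_shape) - 1.0) / (np.asarray(self.target_shape) - 1.0)

    def to_original(self, coords: np.ndarray) -> np.ndarray:
        """Processed-grid voxel coordinates (..., 3) -> original-grid coordinates."""
        return np.asarray(self.crop_offset) + np.asarray(coords) * self.scale

    def to_processed(self, coords: np.ndarray) -> np.ndarray:
        """Original-grid voxel coordinates (..., 3) -> processed-grid coordinates."""
        return (np.asarray(coords) - np.asarray(self.crop_offset)) / self.scale

    def sample_original(self, values: np.ndarray, order: int = 1,
                        cval: float = 0.0) -> np.ndarray:
        """Sample an original-grid array at every processed-grid voxel."""
        proc = np.indices(self.target_shape, dtype=np.float64)
        coords = np.stack([self.crop_offset[a] + proc[a] * self.scale[a]
                           for a in range(3)])
        return ndimage.map_coordinates(np.asarray(values, dtype=np.float64),
                                       coords, order=order, mode="constant", cval=cval)

    def to_dict(self) -> dict:
        return {
            "original_shape": list(self.original_shape),
            "crop_offset": list(self.crop_offset),
            "cropped_shape": list(self.cropped_shape),
            "target_shape": list(self.target_shape),
        }


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def crop_pad_to_margin(
    vol: ScalarVolume,
    mask: LungMask,
    margin: int | Sequence[int],
    fill: float | None = None,
) -> tuple[ScalarVolume, LungMask, GeometryRecord]:
    """Crop/pad so the lung foreground sits exactly ``margin`` voxels from every face.

    Distance is measured per axis to the nearest face (slab distance).
    Cropping removes slabs where the margin is exceeded; padding inserts
    background-filled slabs (air, -1000 HU, for HU volumes) where the lung
    would otherwise touch or cross the boundary.  ``margin`` may be one
    integer or one per axis.
    """
    margins = np.broadcast_to(np.asarray(margin, dtype=int), (3,))
    if margins.min() < 0:
        raise ParameterError(f"margin must be >= 0, got {margin}")
    if vol.shape != mask.shape:
        raise GeometryError(f"volume {vol.shape} and mask {mask.shape} grids differ")
    if fill is None:
        fill = HU_AIR if vol.unit == "hu" else 0.0

    fg = np.argwhere(mask.values)
    lo = fg.min(axis=0) - margins         # may be negative -> pad
    hi = fg.max(axis=0) + margins + 1     # may exceed shape -> pad
    shape = np.asarray(vol.shape)

    out_shape = tuple(int(h - l) for l, h in zip(lo, hi))
    out_vals = np.full(out_shape, fill, dtype=np.float64)
    out_mask = np.zeros(out_shape, dtype=bool)

    src = tuple(slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, shape))
    dst = tuple(slice(max(-l, 0), max(-l, 0) + (min(h, s) - max(l, 0)))
                for l, h, s in zip(lo, hi, shape))
    out_vals[dst] = vol.values[src]
    out_mask[dst] = mask.values[src]

    new_origin = np.asarray(vol.origin) + vol.direction @ (lo * np.asarray(vol.spacing))
    record = GeometryRecord(
        original_shape=vol.shape,
        crop_offset=tuple(int(l) for l in lo),
        cropped_shape=out_shape,
        target_shape=out_shape,
    )
    new_vol = ScalarVolume(out_vals, spacing=vol.spacing, origin=tuple(new_origin),
                           direction=vol.direction, unit=vol.unit)
    new_mask = LungMask(out_mask, spacing=mask.spacing, origin=tuple(new_origin),
                        direction=mask.direction, phase=mask.phase)
    return new_vol, new_mask, record


def resample_to_grid(vol: ScalarVolume, target_dims: Sequence[int]) -> ScalarVolume:
    """Trilinear resampling onto a uniform grid of ``target_dims`` voxels.

    Grid endpoints map to endpoints, so constants and affine ramps are
    reproduced exactly.
    """
    target = tuple(int(d) for d in target_dims)
    if min(target) < 2:
        raise ParameterError(f"target dims must be >= 2 per axis, got {target}")
    n = np.asarray(vol.shape)
    axes = [np.linspace(0.0, n[a] - 1.0, target[a]) for a in range(3)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.values, coords, order=1, mode="nearest")
    new_spacing = tuple(float(s * (n[a] - 1) / (target[a] - 1)) for a, s in enumerate(vol.spacing))
    return ScalarVolume(out, spacing=new_spacing, origin=vol.origin,
                        direction=vol.direction, unit=vol.unit)


def resample_mask_to_grid(mask: LungMask, target_dims: Sequence[int]) -> LungMask:
    """Resample a binary mask trilinearly, then threshold at 0.5."""
    vol = ScalarVolume(mask.values.astype(np.float64), spacing=mask.spacing,
                       origin=mask.origin, direction=mask.direction)
    res = resample_to_grid(vol, target_dims)
    return LungMask(res.values >= 0.5, spacing=res.spacing, origin=res.origin,
                    direction=res.direction, phase=mask.phase)


def normalize_intensity(vol: ScalarVolume) -> ScalarVolume:
    """Affine rescale of the intensity range onto [0, 1]."""
    lo, hi = float(vol.values.min()), float(vol.values.max())
    if hi <= lo:
        raise DegenerateInputError("cannot normalize a constant volume")
    out = (vol.values - lo) / (hi - lo)
    return ScalarVolume(out, spacing=vol.spacing, origin=vol.origin,
                        direction=vol.direction, unit="normalized")


def median_filter(vol: ScalarVolume, patch: int = 5) -> ScalarVolume:
    """Cubic median filter with edge replication at the boundary."""
    if patch < 1 or patch % 2 == 0:
        raise ParameterError(f"patch size must be odd and >= 1, got {patch}")
    out = ndimage.median_filter(vol.values, size=patch, mode="nearest")
    return vol.with_values(out)


# ---------------------------------------------------------------------------
# PreprocessedPair
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedPair:
    """Inhale/exhale pair on one uniform grid, ready for registration.

    ``exhale_hu`` keeps the Hounsfield values of the resampled exhale scan
    because the air-tissue density metric needs HU semantics that the
    0-1 normalization destroys.
    """

    inhale_norm: ScalarVolume
    exhale_norm: ScalarVolume
    exhale_hu: ScalarVolume
    inhale_mask: LungMask
    exhale_mask: LungMask
    geometry: GeometryRecord

    def __post_init__(self) -> None:
        shapes = {self.inhale_norm.shape, self.exhale_norm.shape, self.exhale_hu.shape,
                  self.inhale_mask.shape, self.exhale_mask.shape}
        if len(shapes) != 1:
            raise GeometryError(f"pair members on different grids: {shapes}")


def preprocess_pair(
    inhale: ScalarVolume,
    exhale: ScalarVolume,
    inhale_mask: LungMask,
    exhale_mask: LungMask,
    grid_size: int = 128,
    margin: int = 10,
) -> PreprocessedPair:
    """Crop/pad to the lung margin, resample to a uniform cube, normalize.

    The crop region is defined by the inhale lung mask; both phases are
    cropped and resampled identically so they stay on one grid.  The
    ``margin`` is guaranteed on the *final* resampled grid: the
    original-space margin is scaled per axis so that after resampling the
    lung still sits at least ``margin`` voxels from every face.
    """
    if not (inhale.shape == exhale.shape == inhale_mask.shape == exhale_mask.shape):
        raise GeometryError("all inputs must share one grid before preprocessing")
    target = (grid_size, grid_size, grid_size)
    if grid_size - 1 <= 2 * margin:
        raise ParameterError(
            f"grid size {grid_size} cannot hold a {margin}-voxel margin on both faces")

    # per-axis original-space margin m with m / scale >= margin after
    # resampling, where scale = (bbox + 2m - 1) / (grid_size - 1)
    fg = np.argwhere(inhale_mask.values)
    bbox = fg.max(axis=0) - fg.min(axis=0) + 1
    margins = np.maximum(
        np.ceil(margin * (bbox - 1) / (grid_size - 1 - 2 * margin)).astype(int), 0)

    in_crop, in_mask_crop, record = crop_pad_to_margin(inhale, inhale_mask, margins)
    ex_crop, ex_mask_crop, _ = _crop_like(exhale, exhale_mask, record, fill_unit=exhale.unit)

    in_res = resample_to_grid(in_crop, target)
    ex_res = resample_to_grid(ex_crop, target)
    in_mask_res = resample_mask_to_grid(
        LungMask(in_mask_crop.values, spacing=in_mask_crop.spacing,
                 origin=in_mask_crop.origin, direction=in_mask_crop.direction,
                 phase="inhale"), target)
    ex_mask_res = resample_mask_to_grid(ex_mask_crop, target)
    record = replace(record, target_shape=target)

    return PreprocessedPair(
        inhale_norm=normalize_intensity(in_res),
        exhale_norm=normalize_intensity(ex_res),
        exhale_hu=ex_res,
        inhale_mask=in_mask_res,
        exhale_mask=ex_mask_res,
        geometry=record,
    )


def _crop_like(vol: ScalarVolume, mask: LungMask, record: GeometryRecord,
               fill_unit: Unit) -> tuple[ScalarVolume, LungMask, None]:
    """Apply an existing crop/pad region to another volume+mask."""
    fill = HU_AIR if fill_unit == "hu" else 0.0
    lo = np.asarray(record.crop_offset)
    hi = lo + np.asarray(record.cropped_shape)
    shape = np.asarray(vol.shape)
    out_vals = np.full(record.cropped_shape, fill, dtype=np.float64)
    out_mask = np.zeros(record.cropped_shape, dtype=bool)
    src = tuple(slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, shape))
    dst = tuple(slice(max(-l, 0), max(-l, 0) + (min(h, s) - max(l, 0)))
                for l, h, s in zip(lo, hi, shape))
    out_vals[dst] = vol.values[src]
    out_mask[dst] = mask.values[src]
    new_origin = np.asarray(vol.origin) + vol.direction @ (lo * np.asarray(vol.spacing))
    return (
        ScalarVolume(out_vals, spacing=vol.spacing, origin=tuple(new_origin),
                     direction=vol.direction, unit=vol.unit),
        LungMask(out_mask, spacing=mask.spacing, origin=tuple(new_origin),
                 direction=mask.direction, phase=mask.phase),
        None,
    )
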