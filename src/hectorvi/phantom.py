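"""Seeded synthetic inhale/exhale CT pairs with analytic ground truth.

The phantom emulates a thorax: two ellipsoidal lungs of parenchymal HU
(around -850) carrying a smooth pseudo-random vascular texture, inside a
soft-tissue body (~0 HU) on an air background (-1000 HU).  Breathing
motion is a *potential flow*: the displacement is the gradient of a sum
of Gaussian potentials, u = grad(phi), so the true divergence div(u) =
lap(phi) is closed-form at every point and the curl is identically zero.
The exhale scan is synthesized by evaluating the analytic inverse map
point-by-point (pure advection of the inhale anatomy, no numerical
warping), so ground truth never passes through the pipeline's
interpolators and the two ventilation metrics see cleanly separated
defect signatures: motion defects change only the deformation, density
defects change only the HU.

Defects emulate disease: *motion* defects locally cancel a fraction of
the contraction potential (hypoventilation with normal density),
*density* defects shift parenchymal HU toward air (emphysema-like tissue
loss with normal motion), and *both* combines them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .registration import DisplacementField
from .ventilation import VentilationMap
from .volume import HU_MAX, HU_MIN, LungMask, ScalarVolume

DefectType = Literal["motion", "density", "both"]


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification (e.g. defect outside the lungs)."""


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def level(self, pts: np.ndarray) -> np.ndarray:
        """Normalized radius: <1 inside, 1 on the surface."""
        q = np.zeros(pts.shape[1:])
        for a in range(3):
            q += ((pts[a] - self.center[a]) / self.radii[a]) ** 2
        return np.sqrt(q)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.level(pts) <= 1.0


@dataclass(frozen=True)
class PotentialBlob:
    """One Gaussian term of the motion potential phi."""

    center: tuple[float, float, float]
    amplitude: float  # phi amplitude; >0 pulls tissue toward the center
    width: float      # Gaussian sigma in voxels


@dataclass(frozen=True)
class Defect:
    center: tuple[float, float, float]
    radius: float
    kind: DefectType
    severity: float  # in [0, 1]; 1 = complete loss of motion / full HU shift

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise PhantomSpecError(f"defect severity must lie in [0, 1], got {self.severity}")


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (64, 64, 64)
    lungs: tuple[Ellipsoid, ...] = ()
    blobs: tuple[PotentialBlob, ...] = ()
    defects: tuple[Defect, ...] = ()
    parenchyma_hu: float = -850.0
    body_hu: float = 0.0
    background_hu: float = -1000.0
    texture_hu: float = 90.0        # amplitude scale of the parenchymal texture (~64 HU std)
    texture_waves: int = 80
    texture_band: tuple[float, float] = (2.5, 7.0)   # wavelengths in voxels
    noise_sigma: float = 0.0        # additive Gaussian HU noise
    seed: int = 0
    edge_width: float = 1.2         # smooth transition width at tissue interfaces

    def __post_init__(self) -> None:
        if min(self.dims) < 32:
            raise PhantomSpecError(f"phantom dims must be >= 32 per axis, got {self.dims}")
        for d in self.defects:
            c = np.asarray(d.center)[:, None]
            if not any(lung.contains(c)[0] for lung in self.lungs):
                raise PhantomSpecError(f"defect at {d.center} lies outside every lung")


def default_spec(
    dims: int | Sequence[int] = 64,
    peak_contraction: float = 0.25,
    defects: Sequence[Defect] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Canonical two-lung phantom scaled to the grid size.

    ``peak_contraction`` is the magnitude of the true divergence at the
    strongest potential center (0.25 by default — a typical tidal-breathing
    local volume change; values near 1 emulate exaggerated contraction).
    One broad potential blob per lung (width ~ the mean lung radius) keeps
    healthy within-lung ventilation fairly homogeneous — as in healthy
    physiology — while a mild left/right amplitude difference and the
    radial falloff provide global structure.
    """
    if isinstance(dims, int):
        dims = (dims, dims, dims)
    n = np.asarray(dims, dtype=float)
    lungs = tuple(
        Ellipsoid(center=(cx * n[0], 0.5 * n[1], 0.5 * n[2]),
                  radii=(0.14 * n[0], 0.20 * n[1], 0.26 * n[2]))
        for cx in (0.32, 0.68)
    )
    blobs = []
    for lung, rel in zip(lungs, (1.0, 0.78)):
        w = 0.85 * float(np.mean(lung.radii))
        a = rel * peak_contraction * w * w / 3.0
        blobs.append(PotentialBlob(center=lung.center, amplitude=a, width=w))
    return PhantomSpec(dims=tuple(int(d) for d in dims), lungs=lungs,
                       blobs=tuple(blobs), defects=tuple(defects),
                       noise_sigma=noise_sigma, seed=seed)


# ---------------------------------------------------------------------------
# Analytic potential-flow machinery
# ---------------------------------------------------------------------------

def _blob_fields(blobs: Sequence[PotentialBlob]):
    """Closures evaluating u = grad(phi), lap(phi) and the Hessian anywhere."""

    def grad_phi(pts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pts, dtype=np.float64)
        for b in blobs:
            d = pts - np.asarray(b.center).reshape((3,) + (1,) * (pts.ndim - 1))
            g = b.amplitude * np.exp(-(d ** 2).sum(axis=0) / (2 * b.width ** 2))
            out += -d / b.width ** 2 * g
        return out

    def lap_phi(pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[1:], dtype=np.float64)
        for b in blobs:
            d = pts - np.asarray(b.center).reshape((3,) + (1,) * (pts.ndim - 1))
            r2 = (d ** 2).sum(axis=0)
            g = b.amplitude * np.exp(-r2 / (2 * b.width ** 2))
            out += (r2 / b.width ** 4 - 3.0 / b.width ** 2) * g
        return out

    return grad_phi, lap_phi


def _with_motion_defects(spec: PhantomSpec) -> tuple[PotentialBlob, ...]:
    """Append cancellation blobs so lap(phi) at each motion-defect center is
    scaled by (1 - severity).

    The cancellation Gaussian's width equals the defect radius, so the
    divergence reduction stays above 60% of its central value throughout
    the defect sphere and the Laplacian's positive side lobes fall well
    outside it.
    """
    blobs = list(spec.blobs)
    _, lap_base = _blob_fields(spec.blobs)
    for d in spec.defects:
        if d.kind not in ("motion", "both"):
            continue
        w_d = d.radius
        c = np.asarray(d.center, dtype=float).reshape(3, 1)
        base = float(lap_base(c)[0])
        # lap of a*exp(-r^2/2w^2) at its own center is -3a/w^2
        a_d = d.severity * base * w_d ** 2 / 3.0
        blobs.append(PotentialBlob(center=d.center, amplitude=a_d, width=w_d))
    return tuple(blobs)


class _Texture:
    """Smooth band-limited pseudo-random field evaluable at arbitrary points.

    A sum of random 3-D cosine waves at vessel/airway scale — the
    parenchymal structure that gives the registration something to
    track.  Defined in inhale material coordinates so it advects with the
    tissue.
    """

    def __init__(self, rng: np.random.Generator, n_waves: int, amplitude: float,
                 band: tuple[float, float] = (2.5, 7.0)) -> None:
        wavelengths = rng.uniform(band[0], band[1], n_waves)
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self.k = (2 * np.pi / wavelengths)[:, None] * dirs   # (n, 3)
        self.phase = rng.uniform(0, 2 * np.pi, n_waves)
        self.amp = amplitude * rng.normal(size=n_waves) / np.sqrt(n_waves)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        flat = pts.reshape(3, -1)
        out = np.zeros(flat.shape[1])
        for m in range(len(self.phase)):
            out += self.amp[m] * np.cos(self.k[m] @ flat + self.phase[m])
        return out.reshape(pts.shape[1:])


def _smoothstep(level: np.ndarray, width_voxels: float, radius: float) -> np.ndarray:
    """1 inside (level < 1), 0 outside, logistic edge ~width_voxels wide.

    ``level`` is the normalized ellipsoid radius; ``radius`` converts the
    edge width from voxels to level units.
    """
    steep = 4.0 * radius / max(width_voxels, 1e-6)
    return 1.0 / (1.0 + np.exp(np.clip((level - 1.0) * steep, -60, 60)))


# ---------------------------------------------------------------------------
# Phantom case
# ---------------------------------------------------------------------------

@dataclass
class PhantomCase:
    """A generated inhale/exhale pair with its analytic ground truth."""

    spec: PhantomSpec
    inhale: ScalarVolume
    exhale: ScalarVolume
    inhale_mask: LungMask
    exhale_mask: LungMask
    true_displacement: DisplacementField   # on the inhale grid
    true_divergence: np.ndarray            # lap(phi) on the inhale grid
    true_ventilation: VentilationMap       # -lap(phi) at pre-images, exhale grid
    defect_masks_inhale: list[np.ndarray] = field(default_factory=list)
    defect_masks_exhale: list[np.ndarray] = field(default_factory=list)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a phantom case; byte-identical outputs for identical spec."""
    rng = np.random.default_rng(spec.seed)
    texture = _Texture(rng, spec.texture_waves, spec.texture_hu, spec.texture_band)
    blobs = _with_motion_defects(spec)
    grad_phi, lap_phi = _blob_fields(blobs)

    grid = np.indices(spec.dims, dtype=np.float64)

    def anatomy_hu(pts: np.ndarray) -> np.ndarray:
        """Continuous inhale HU model evaluated at arbitrary points."""
        body = Ellipsoid(
            center=(spec.dims[0] / 2.0, spec.dims[1] / 2.0, spec.dims[2] / 2.0),
            radii=(0.45 * spec.dims[0], 0.38 * spec.dims[1], 0.47 * spec.dims[2]))
        hu = spec.background_hu + (spec.body_hu - spec.background_hu) * _smoothstep(
            body.level(pts), spec.edge_width, float(np.mean(body.radii)))
        lung_m = np.zeros(pts.shape[1:])
        for lung in spec.lungs:
            m = _smoothstep(lung.level(pts), spec.edge_width, float(np.mean(lung.radii)))
            lung_m = np.maximum(lung_m, m)
        paren = spec.parenchyma_hu + texture(pts)
        for d in spec.defects:
            if d.kind not in ("density", "both"):
                continue
            c = np.asarray(d.center).reshape((3,) + (1,) * (pts.ndim - 1))
            r2 = ((pts - c) ** 2).sum(axis=0)
            # sigma = 3/4 radius keeps the HU shift above 40% of its central
            # value throughout the nominal defect sphere
            bump = np.exp(-r2 / (2 * (0.75 * d.radius) ** 2))
            paren = paren + d.severity * bump * (spec.background_hu - paren)
        return hu + (paren - hu) * lung_m

    inhale_vals = anatomy_hu(grid)
    u_true = grad_phi(grid)
    div_true = lap_phi(grid)

    # analytic inverse of y = x + grad(phi)(x), evaluated with the closed-form
    # field only (independent of any grid interpolation)
    x = grid.copy()
    for _ in range(40):
        x_new = grid - grad_phi(x)
        if np.abs(x_new - x).max() < 1e-4:
            x = x_new
            break
        x = x_new

    exhale_vals = anatomy_hu(x)

    lung_in = np.zeros(spec.dims, dtype=bool)
    lung_ex = np.zeros(spec.dims, dtype=bool)
    for lung in spec.lungs:
        lung_in |= lung.contains(grid)
        lung_ex |= lung.contains(x)

    vent_ex = -lap_phi(x)

    if spec.noise_sigma > 0:
        inhale_vals = inhale_vals + rng.normal(0, spec.noise_sigma, spec.dims)
        exhale_vals = exhale_vals + rng.normal(0, spec.noise_sigma, spec.dims)
    inhale_vals = np.clip(inhale_vals, HU_MIN, HU_MAX)
    exhale_vals = np.clip(exhale_vals, HU_MIN, HU_MAX)

    dmask_in, dmask_ex = [], []
    for d in spec.defects:
        c_in = np.asarray(d.center).reshape(3, 1, 1, 1)
        dmask_in.append((((grid - c_in) ** 2).sum(axis=0) <= d.radius ** 2) & lung_in)
        dmask_ex.append((((x - c_in) ** 2).sum(axis=0) <= d.radius ** 2) & lung_ex)

    exhale_mask = LungMask(lung_ex, phase="exhale")
    return PhantomCase(
        spec=spec,
        inhale=ScalarVolume(inhale_vals, unit="hu"),
        exhale=ScalarVolume(exhale_vals, unit="hu"),
        inhale_mask=LungMask(lung_in, phase="inhale"),
        exhale_mask=exhale_mask,
        true_displacement=DisplacementField(u_true),
        true_divergence=div_true,
        true_ventilation=VentilationMap(vent_ex, mask=exhale_mask, label="truth"),
        defect_masks_inhale=dmask_in,
        defect_masks_exhale=dmask_ex,
    )


def phantom_suite(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Deterministic suite of cases varying defect placement and severity.

    Case ``i`` derives its RNG stream and spec from ``seed``; defect type
    cycles through motion / density / both, one defect per case placed
    well inside a lung with severity drawn from [0.5, 0.9].
    """
    if base_spec is None:
        base_spec = default_spec()
    cases = []
    kinds: list[DefectType] = ["motion", "density", "both"]
    rng = np.random.default_rng(seed)
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        lung = base_spec.lungs[i % len(base_spec.lungs)]
        offset = rng.uniform(-0.35, 0.35, 3)
        center = tuple(lung.center[a] + offset[a] * lung.radii[a] for a in range(3))
        radius = 0.55 * float(min(lung.radii))
        severity = float(rng.uniform(0.5, 0.9))
        defect = Defect(center=center, radius=radius,
                        kind=kinds[i % 3], severity=severity)
        spec = replace(base_spec, defects=(defect,), seed=case_seed)
        cases.append(generate_phantom(spec))
    return cases
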