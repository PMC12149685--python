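"""Divergence-constrained deformable registration in div-curl variables.

The exhale (moving) image is registered to the inhale (fixed) image by
minimizing

    E(f) = D(F, M, u) + a1 <f1^2> + a2 <|grad f1|^2> + b <|grad (f2,f3,f4)|^2>

over the *divergence* f1 = div(u) and the three *curl* components
(f2, f3, f4) = curl(u), with the hard box constraint |f1| <= 0.5 applied
by projection after every update.  The data term D is one minus the
masked mean of a Gaussian-windowed squared local cross-correlation (LCC),
so D is invariant to affine intensity maps of either image.

The displacement is recovered from the primary variables through the
vector identity  lap(u) = grad(div u) - curl(curl u):  each Cartesian
component solves a Poisson equation with homogeneous Dirichlet boundary
(solved spectrally by a type-I discrete sine transform), which pins the
displacement to zero at the air-padded image boundary.

Optimization is projected gradient descent with backtracking (accept a
step only when it strictly decreases the energy), run coarse-to-fine over
a Gaussian-antialiased multiresolution pyramid.  There is no randomness
anywhere: results are fully determined by the inputs and the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .volume import GeometryError, LungMask, ScalarVolume

logger = logging.getLogger(__name__)


class NumericalFailure(RuntimeError):
    """Non-finite energy encountered during descent."""


# ---------------------------------------------------------------------------
# Finite-difference operators (central interior, one-sided at boundaries)
# ---------------------------------------------------------------------------

def grad_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Central-difference derivative along one axis, second-order one-sided
    stencils at the faces."""
    return np.gradient(x, axis=axis, edge_order=2)


def grad_axis_adjoint(y: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`grad_axis` (transpose of the difference matrix)."""
    y = np.moveaxis(y, axis, 0)
    z = np.zeros_like(y)
    n = y.shape[0]
    # row 0: (-3 x0 + 4 x1 - x2) / 2
    z[0] += -1.5 * y[0]
    z[1] += 2.0 * y[0]
    z[2] += -0.5 * y[0]
    # interior rows i: (x_{i+1} - x_{i-1}) / 2
    z[0:n - 2] -= 0.5 * y[1:n - 1]
    z[2:n] += 0.5 * y[1:n - 1]
    # row n-1: (x_{n-3} - 4 x_{n-2} + 3 x_{n-1}) / 2
    z[n - 3] += 0.5 * y[n - 1]
    z[n - 2] += -2.0 * y[n - 1]
    z[n - 1] += 1.5 * y[n - 1]
    return np.moveaxis(z, 0, axis)


def divergence(u: np.ndarray) -> np.ndarray:
    """div(u) for a (3, nx, ny, nz) displacement, central differences."""
    return sum(grad_axis(u[a], a) for a in range(3))


def curl(u: np.ndarray) -> np.ndarray:
    """curl(u) for a (3, nx, ny, nz) field -> (3, nx, ny, nz)."""
    return np.stack([
        grad_axis(u[2], 1) - grad_axis(u[1], 2),
        grad_axis(u[0], 2) - grad_axis(u[2], 0),
        grad_axis(u[1], 0) - grad_axis(u[0], 1),
    ])


# ---------------------------------------------------------------------------
# Spectral Poisson solver (homogeneous Dirichlet via DST-I)
# ---------------------------------------------------------------------------

def poisson_solve_dirichlet(rhs: np.ndarray) -> np.ndarray:
    """Solve lap(x) = rhs with x = 0 on the (virtual) boundary ring.

    Grid nodes are treated as the interior of a Dirichlet problem whose
    boundary lies half outside the array; the 7-point Laplacian is
    diagonalized by the type-I DST.  The operator is symmetric, so this
    solver is its own adjoint.
    """
    n = rhs.shape
    hat = sp_fft.dstn(rhs, type=1)
    eig = [2.0 * (np.cos(np.pi * (np.arange(n[a]) + 1) / (n[a] + 1)) - 1.0) for a in range(3)]
    lam = (eig[0][:, None, None] + eig[1][None, :, None] + eig[2][None, None, :])
    hat /= lam
    return sp_fft.idstn(hat, type=1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DivCurlField:
    """Primary registration variables on the fixed-image grid.

    ``f1`` is the displacement divergence (dimensionless local volume
    change to first order); ``f2..f4`` are the curl components.
    """

    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    f4: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.f1.shape, self.f2.shape, self.f3.shape, self.f4.shape}
        if len(shapes) != 1:
            raise GeometryError(f"div-curl component grids differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f1.shape  # type: ignore[return-value]

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "DivCurlField":
        return cls(*(np.zeros(shape) for _ in range(4)))

    def as_array(self) -> np.ndarray:
        return np.stack([self.f1, self.f2, self.f3, self.f4])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "DivCurlField":
        return cls(arr[0], arr[1], arr[2], arr[3])


@dataclass
class DisplacementField:
    """Displacement u in voxel units on the fixed grid: x_moving = x_fixed + u."""

    u: np.ndarray  # (3, nx, ny, nz)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise GeometryError(f"expected (3, nx, ny, nz) displacement, got {self.u.shape}")
        if not np.isfinite(self.u).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]  # type: ignore[return-value]


@dataclass
class RegistrationConfig:
    """Energy weights and optimizer settings.

    Defaults follow the tuned values for human inhale/exhale CT:
    ``alpha1=0.1`` (divergence magnitude), ``alpha2=2.0`` (divergence
    gradient), ``beta=0.05`` (curl), a Gaussian LCC window of sigma 1.5
    voxels, and the physiological-plausibility bound |f1| <= 0.5.
    """

    alpha1: float = 0.1
    alpha2: float = 2.0
    beta: float = 0.05
    lcc_sigma: float = 1.5
    n_levels: int = 3
    iters_per_level: int = 100
    div_bound: float = 0.5
    conv_tol: float = 1e-5
    conv_window: int = 5
    step_init: float = 0.05        # first trial step scales max |grad f1| change to this
    step_growth: float = 1.25
    max_backtracks: int = 25
    mask_dilation: int = 3         # voxels of lung-mask dilation for the data term

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.beta) < 0:
            raise ValueError("regularization weights must be >= 0")
        if not (0.0 < self.div_bound <= 1.0):
            raise ValueError(f"divergence bound must lie in (0, 1], got {self.div_bound}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.lcc_sigma <= 0:
            raise ValueError("lcc_sigma must be > 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RegistrationResult:
    """Registration output.  ``energy_trace`` holds one list of accepted
    energies per resolution level (energies at different levels are not
    comparable: grids and image pyramids differ); each per-level list is
    non-increasing."""

    divcurl: DivCurlField
    displacement: DisplacementField
    energy_trace: list[list[float]] = field(default_factory=list)
    final_data_term: float = float("nan")


# ---------------------------------------------------------------------------
# Local cross-correlation
# ---------------------------------------------------------------------------

_LCC_EPS = 1e-8


def _smooth(x: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(x, sigma, mode="nearest")


def lcc_similarity(
    fixed: ScalarVolume | np.ndarray,
    warped_moving: ScalarVolume | np.ndarray,
    sigma: float = 1.5,
    mask: LungMask | np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Masked mean of local squared correlation between two images.

    Each voxel's term is ``cov^2 / (varF * varM)`` computed under a
    Gaussian window of scale ``sigma``, so the similarity is 1 for a
    perfect local linear (affine-intensity) relation and near 0 for
    unrelated images.  Windows where either image is locally constant
    contribute 0.  Returns ``(masked mean, voxelwise term grid)``.
    """
    F = fixed.values if isinstance(fixed, ScalarVolume) else np.asarray(fixed, float)
    M = warped_moving.values if isinstance(warped_moving, ScalarVolume) else np.asarray(warped_moving, float)
    if F.shape != M.shape:
        raise GeometryError(f"image grids differ: {F.shape} vs {M.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if mask is None:
        w = np.ones(F.shape, bool)
    else:
        w = mask.values if isinstance(mask, LungMask) else np.asarray(mask, bool)

    muF, muM = _smooth(F, sigma), _smooth(M, sigma)
    A = _smooth(F * M, sigma) - muF * muM
    B = np.maximum(_smooth(F * F, sigma) - muF * muF, 0.0)
    C = np.maximum(_smooth(M * M, sigma) - muM * muM, 0.0)
    BC = B * C
    valid = BC > _LCC_EPS
    lcc = np.zeros_like(F)
    lcc[valid] = (A[valid] ** 2) / BC[valid]
    np.clip(lcc, 0.0, 1.0, out=lcc)
    return float(lcc[w].mean()), lcc


# ---------------------------------------------------------------------------
# Displacement reconstruction and its adjoint
# ---------------------------------------------------------------------------

def reconstruct_displacement(divcurl: DivCurlField) -> DisplacementField:
    """Recover u from (f1, f2, f3, f4) by Helmholtz potentials.

    Solves the scalar Poisson problem  lap(psi) = f1  and the vector
    problem  lap(A) = -(f2, f3, f4), both with homogeneous Dirichlet
    boundary (sine-transform solver), and returns

        u = grad(psi) + curl(A),

    the least-squares field whose divergence matches f1 and whose curl
    matches the curl data (exactly so, in the continuum, when the curl
    data is solenoidal).  Central-difference div(u) reproduces f1 up to
    O(h^2) discretization error.  The Dirichlet potentials pin the field
    to the air-padded boundary: divergence/curl sources well inside the
    grid produce displacements that decay toward the faces.
    """
    psi = poisson_solve_dirichlet(divcurl.f1)
    A = [poisson_solve_dirichlet(-c) for c in (divcurl.f2, divcurl.f3, divcurl.f4)]
    u = np.stack([
        grad_axis(psi, 0) + grad_axis(A[2], 1) - grad_axis(A[1], 2),
        grad_axis(psi, 1) + grad_axis(A[0], 2) - grad_axis(A[2], 0),
        grad_axis(psi, 2) + grad_axis(A[1], 0) - grad_axis(A[0], 1),
    ])
    return DisplacementField(u)


def _reconstruct_adjoint(g_u: np.ndarray) -> np.ndarray:
    """Adjoint of the f -> u map; g_u is (3, ...) -> returns (4, ...) grads."""
    # u = grad(P f1) + curl(P (-c)); the Poisson solver P is self-adjoint
    g_psi = sum(grad_axis_adjoint(g_u[a], a) for a in range(3))
    g_f1 = poisson_solve_dirichlet(g_psi)
    g_A1 = grad_axis_adjoint(g_u[1], 2) - grad_axis_adjoint(g_u[2], 1)
    g_A2 = grad_axis_adjoint(g_u[2], 0) - grad_axis_adjoint(g_u[0], 2)
    g_A3 = grad_axis_adjoint(g_u[0], 1) - grad_axis_adjoint(g_u[1], 0)
    g_c = [-poisson_solve_dirichlet(g) for g in (g_A1, g_A2, g_A3)]
    return np.stack([g_f1, g_c[0], g_c[1], g_c[2]])


# ---------------------------------------------------------------------------
# Energy and gradient
# ---------------------------------------------------------------------------

def _warp(moving: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample moving at x + u(x), trilinear; outside the grid -> background 0."""
    idx = np.indices(moving.shape, dtype=np.float64)
    return ndimage.map_coordinates(moving, idx + u, order=1, mode="constant", cval=0.0)


def _reg_terms(f: np.ndarray, cfg: RegistrationConfig, n: int) -> float:
    """Regularization energy; ``n`` is the integration-domain voxel count so
    data term and penalties discretize the same per-voxel integrand."""
    r = cfg.alpha1 * float(np.sum(f[0] ** 2)) / n
    r += cfg.alpha2 * sum(float(np.sum(grad_axis(f[0], a) ** 2)) for a in range(3)) / n
    for i in (1, 2, 3):
        r += cfg.beta * sum(float(np.sum(grad_axis(f[i], a) ** 2)) for a in range(3)) / n
    return r


def _reg_grad(f: np.ndarray, cfg: RegistrationConfig, n: int) -> np.ndarray:
    g = np.zeros_like(f)
    g[0] = 2.0 * cfg.alpha1 * f[0] / n
    g[0] += 2.0 * cfg.alpha2 * sum(grad_axis_adjoint(grad_axis(f[0], a), a) for a in range(3)) / n
    for i in (1, 2, 3):
        g[i] = 2.0 * cfg.beta * sum(grad_axis_adjoint(grad_axis(f[i], a), a) for a in range(3)) / n
    return g


class _EnergyModel:
    """Energy and analytic gradient of the variational problem at one level."""

    def __init__(self, fixed: np.ndarray, moving: np.ndarray, mask: np.ndarray,
                 cfg: RegistrationConfig) -> None:
        self.F = fixed
        self.M = moving
        self.cfg = cfg
        if cfg.mask_dilation > 0:
            mask = ndimage.binary_dilation(mask, iterations=cfg.mask_dilation)
        self.n_domain = int(mask.sum())
        self.w = mask.astype(np.float64)
        self.w /= self.n_domain
        s = cfg.lcc_sigma
        self.muF = _smooth(self.F, s)
        self.B = np.maximum(_smooth(self.F * self.F, s) - self.muF ** 2, 0.0)
        self.gradM = np.stack([grad_axis(self.M, a) for a in range(3)])
        self._idx = np.indices(self.F.shape, dtype=np.float64)

    def _data_fields(self, Mw: np.ndarray):
        s = self.cfg.lcc_sigma
        muM = _smooth(Mw, s)
        A = _smooth(self.F * Mw, s) - self.muF * muM
        C = np.maximum(_smooth(Mw * Mw, s) - muM ** 2, 0.0)
        BC = self.B * C
        valid = BC > _LCC_EPS
        lcc = np.zeros_like(A)
        lcc[valid] = (A[valid] ** 2) / BC[valid]
        np.clip(lcc, 0.0, 1.0, out=lcc)
        return muM, A, C, BC, valid, lcc

    def energy(self, f: np.ndarray) -> float:
        u = reconstruct_displacement(DivCurlField.from_array(f)).u
        Mw = ndimage.map_coordinates(self.M, self._idx + u, order=1,
                                     mode="constant", cval=0.0)
        *_, lcc = self._data_fields(Mw)
        data = 1.0 - float((self.w * lcc).sum())
        return data + _reg_terms(f, self.cfg, self.n_domain)

    def energy_grad(self, f: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Returns (energy, gradient wrt (f1..f4), data-term value)."""
        cfg = self.cfg
        u = reconstruct_displacement(DivCurlField.from_array(f)).u
        coords = self._idx + u
        Mw = ndimage.map_coordinates(self.M, coords, order=1, mode="constant", cval=0.0)
        muM, A, C, BC, valid, lcc = self._data_fields(Mw)
        data = 1.0 - float((self.w * lcc).sum())
        energy = data + _reg_terms(f, cfg, self.n_domain)

        # d(data)/dMw: data = 1 - sum_y w(y) A(y)^2 / (B(y) C(y))
        q1 = np.zeros_like(A)   # 2 w A / (B C)
        q2 = np.zeros_like(A)   # w A^2 / (B C^2)
        q1[valid] = 2.0 * self.w[valid] * A[valid] / BC[valid]
        q2[valid] = self.w[valid] * (A[valid] ** 2) / (BC[valid] * C[valid])
        s = cfg.lcc_sigma
        # gaussian kernel is symmetric -> smoothing is self-adjoint
        dP_dMw = (self.F * _smooth(q1, s) - _smooth(q1 * self.muF, s)
                  - 2.0 * Mw * _smooth(q2, s) + 2.0 * _smooth(q2 * muM, s))
        dD_dMw = -dP_dMw

        # chain through the warp: dMw/du_a = (dM/dx_a)(x + u)
        g_u = np.stack([
            dD_dMw * ndimage.map_coordinates(self.gradM[a], coords, order=1,
                                             mode="constant", cval=0.0)
            for a in range(3)
        ])
        g = _reconstruct_adjoint(g_u) + _reg_grad(f, cfg, self.n_domain)
        return energy, g, data


# ---------------------------------------------------------------------------
# Multiresolution projected-gradient registration
# ---------------------------------------------------------------------------

def _downsample(x: np.ndarray, shape: tuple[int, int, int], antialias: bool) -> np.ndarray:
    if x.shape == shape:
        return x.copy()
    if antialias:
        sig = [0.5 * (x.shape[a] / shape[a]) for a in range(3)]
        x = ndimage.gaussian_filter(x, sig, mode="nearest")
    axes = [np.linspace(0, x.shape[a] - 1, shape[a]) for a in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(x, grid, order=1, mode="nearest")


def _upsample(x: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if x.shape == shape:
        return x.copy()
    axes = [np.linspace(0, x.shape[a] - 1, shape[a]) for a in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(x, grid, order=1, mode="nearest")


def register(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    mask: LungMask,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Register moving (exhale) to fixed (inhale) over div-curl variables.

    Coarse-to-fine projected gradient descent on the variational energy,
    initialized at zero; after every accepted update ``f1`` is projected
    onto ``[-div_bound, +div_bound]``.  The energy trace over accepted
    iterations is non-increasing at every level, and the returned field
    satisfies the bound exactly.
    """
    cfg = config or RegistrationConfig()
    if fixed.shape != moving.shape or fixed.shape != mask.shape:
        raise GeometryError("fixed, moving and mask must share one grid")

    shapes = []
    for lvl in range(cfg.n_levels):
        fac = 2 ** (cfg.n_levels - 1 - lvl)
        shapes.append(tuple(max(8, int(round(s / fac))) for s in fixed.shape))
    shapes[-1] = fixed.shape

    f = np.zeros((4,) + shapes[0])
    trace: list[list[float]] = []
    data_term = float("nan")

    for lvl, shape in enumerate(shapes):
        F = _downsample(fixed.values, shape, antialias=True)
        M = _downsample(moving.values, shape, antialias=True)
        msk = _downsample(mask.values.astype(np.float64), shape, antialias=False) >= 0.5
        if not msk.any():
            msk = _downsample(mask.values.astype(np.float64), shape, antialias=False) > 0
        if f.shape[1:] != shape:
            f = np.stack([_upsample(f[i], shape) for i in range(4)])
            np.clip(f[0], -cfg.div_bound, cfg.div_bound, out=f[0])
        model = _EnergyModel(F, M, msk, cfg)

        energy, g, data_term = model.energy_grad(f)
        if not np.isfinite(energy):
            raise NumericalFailure(f"non-finite energy at level {lvl}, iteration 0")
        level_trace = [energy]
        trace.append(level_trace)
        gmax = float(np.abs(g).max())
        step = cfg.step_init / gmax if gmax > 0 else 1.0
        recent: list[float] = [energy]

        for it in range(cfg.iters_per_level):
            accepted = False
            for _ in range(cfg.max_backtracks):
                f_try = f - step * g
                np.clip(f_try[0], -cfg.div_bound, cfg.div_bound, out=f_try[0])
                e_try = model.energy(f_try)
                if not np.isfinite(e_try):
                    raise NumericalFailure(
                        f"non-finite energy at level {lvl}, iteration {it}")
                if e_try < energy:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                logger.debug("level %d: no descent step at iter %d, stopping", lvl, it)
                break
            f = f_try
            _, g, data_term = model.energy_grad(f)
            energy = e_try
            level_trace.append(energy)
            step *= cfg.step_growth
            recent.append(energy)
            if len(recent) > cfg.conv_window + 1:
                recent.pop(0)
                rel = (recent[0] - recent[-1]) / max(abs(recent[0]), 1e-12)
                if rel < cfg.conv_tol:
                    logger.debug("level %d converged after %d iterations", lvl, it + 1)
                    break
        logger.info("level %d (%s): energy %.6f, data term %.6f",
                    lvl, "x".join(map(str, shape)), energy, data_term)

    np.clip(f[0], -cfg.div_bound, cfg.div_bound, out=f[0])
    divcurl = DivCurlField.from_array(f)
    return RegistrationResult(
        divcurl=divcurl,
        displacement=reconstruct_displacement(divcurl),
        energy_trace=trace,
        final_data_term=data_term,
    )


def energy(
    divcurl: DivCurlField,
    fixed: ScalarVolume,
    moving: ScalarVolume,
    config: RegistrationConfig | None = None,
    mask: LungMask | None = None,
) -> float:
    """Evaluate the full variational energy for a given div-curl field."""
    cfg = config or RegistrationConfig()
    msk = mask.values if mask is not None else np.ones(fixed.shape, bool)
    model = _EnergyModel(fixed.values, moving.values, msk, cfg)
    return model.energy(divcurl.as_array())
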