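"""Three-pool T2 relaxometry: bounded NLLS fitting and water-fraction maps.

Each voxel's magnitude decay over the echo schedule is modelled as the sum
of three exponentials — myelin water (short T2), intra/extra-cellular
water (intermediate T2) and CSF (long T2):

    S(TE) = A_MW exp(-TE/T2_MW) + A_IEW exp(-TE/T2_IEW) + A_CSF exp(-TE/T2_CSF)

with amplitudes constrained nonnegative and each T2 boxed inside its
pool's interval ([5, 20], [20, 200] and [200, 2000] ms by default).  Water
exchange between compartments and compartmental T1 weighting are not
modelled.  The six-parameter problem is solved per voxel by L-BFGS-B from
a deterministic initialization; T2s are optimized in log-space for
conditioning.  Water fractions are the amplitude ratios to the total
water signal.

Volume fitting optionally adds a Laplacian spatial smoothness penalty
coupling neighbouring voxels, minimized by Gauss-Seidel sweeps over the
independently-fitted solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .volume import EchoVolume

__all__ = [
    "PoolBounds",
    "VoxelPools",
    "WFMaps",
    "FitConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "loglinear_init_t2",
    "init_pools",
    "fit_voxel",
    "fit_volume",
    "compute_wf",
]

# quality codes for the per-voxel flag map
Q_OUTSIDE = 0
Q_OK = 1
Q_UNFITTABLE = 2
Q_NONCONVERGED = 3


@dataclass(frozen=True)
class PoolBounds:
    """Per-pool (lower, upper) T2 intervals in ms."""

    mw: tuple[float, float] = (5.0, 20.0)
    iew: tuple[float, float] = (20.0, 200.0)
    csf: tuple[float, float] = (200.0, 2000.0)

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for name in ("mw", "iew", "csf"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"invalid T2 bounds for pool {name}: ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("pool T2 intervals overlap beyond shared endpoints")
            prev_hi = hi

    def as_tuple(self):
        return (self.mw, self.iew, self.csf)


DEFAULT_BOUNDS = PoolBounds()


@dataclass
class VoxelPools:
    """Three amplitudes and three T2 values for one voxel."""

    amplitudes: tuple[float, float, float]
    t2s: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be nonnegative")
        if any(t <= 0 for t in self.t2s):
            raise ValueError("T2 values must be positive")


@dataclass
class WFMaps:
    """Voxelwise water-fraction maps with an explicit validity mask."""

    mwf: np.ndarray
    iewf: np.ndarray
    csff: np.ndarray
    defined: np.ndarray  # bool: True where fractions are meaningful


@dataclass
class FitConfig:
    """Optimizer and spatial-regularization settings.

    ``lambda_laplacian = 0`` fits every voxel independently; positive
    values add a squared-Laplacian penalty (on coil-normalized amplitudes
    and log-T2 maps, 6-neighbourhood, spacing-scaled) and run
    ``n_sweeps`` Gauss-Seidel refinement passes over the volume.
    """

    lambda_laplacian: float = 0.0
    gtol: float = 1e-8
    max_iter: int = 500
    n_sweeps: int = 2
    chunk_size: int = 4096

    def __post_init__(self) -> None:
        if self.lambda_laplacian < 0:
            raise ValueError("lambda_laplacian must be >= 0")


@dataclass
class FitResult:
    """Output of :func:`fit_volume`."""

    amplitudes: np.ndarray      # (nx, ny, nz, 3) fitted pool amplitudes
    t2s: np.ndarray             # (nx, ny, nz, 3) fitted pool T2s, ms
    wf: WFMaps
    residual: np.ndarray        # (nx, ny, nz) final residual norm
    quality: np.ndarray         # int codes: Q_OUTSIDE/Q_OK/Q_UNFITTABLE/Q_NONCONVERGED
    n_at_bound: int             # voxels with any T2 binding at a pool bound
    n_nonconverged: int


# ---------------------------------------------------------------------------
# initialization


def loglinear_init_t2(signal: np.ndarray, schedule: np.ndarray) -> float:
    """Initial intermediate-pool T2 from a log-linear fit of 4 echoes.

    Ordinary least squares of ln(S) on TE over the first four echoes gives
    slope b; T2 = -1/b clamped into [20, 200] ms.  Degenerate inputs (any
    nonpositive signal, or a nonnegative slope that would imply infinite
    or negative T2) fall back to 70 ms; a flat signal clamps to 200 ms.
    """
    s = np.asarray(signal, dtype=float)[:4]
    te = np.asarray(schedule, dtype=float)[:4]
    if s.shape != te.shape or s.size != 4:
        raise ValueError("need 4 echoes with matching TEs")
    if np.any(s <= 0):
        return 70.0
    b = np.polyfit(te, np.log(s), 1)[0]
    if abs(b) < 1e-9:  # flat decay (within rounding): +inf T2, clamp to upper
        return 200.0
    if b > 0:
        return 70.0
    return float(np.clip(-1.0 / b, 20.0, 200.0))


def init_pools(
    signal: np.ndarray,
    schedule: np.ndarray,
    bounds: PoolBounds = DEFAULT_BOUNDS,
) -> VoxelPools | None:
    """Deterministic starting point for the three-pool fit.

    Myelin and CSF T2 start at 10 and 2000 ms; the intermediate T2 comes
    from :func:`loglinear_init_t2`.  Amplitudes start at 10% and 90% of
    the first-echo signal for the myelin and intra/extra-cellular pools
    and at the last-echo signal for CSF.  All values are projected into
    their boxes.  Returns ``None`` for an all-zero (unfittable) voxel.
    """
    s = np.asarray(signal, dtype=float)
    te = np.asarray(schedule, dtype=float)
    if s.size < 5:
        raise ValueError("need at least 5 echoes")
    if np.all(s == 0):
        return None
    t2 = (10.0, loglinear_init_t2(s, te), 2000.0)
    t2 = tuple(
        float(np.clip(t, lo, hi)) for t, (lo, hi) in zip(t2, bounds.as_tuple())
    )
    amps = (0.10 * s[0], 0.90 * s[0], s[-1])
    amps = tuple(max(a, 0.0) for a in amps)
    return VoxelPools(amplitudes=amps, t2s=t2)


# ---------------------------------------------------------------------------
# single-voxel fit


def _pack(pools: VoxelPools) -> np.ndarray:
    return np.concatenate([pools.amplitudes, np.log(pools.t2s)])


def _unpack(theta: np.ndarray) -> VoxelPools:
    return VoxelPools(
        amplitudes=tuple(float(a) for a in theta[:3]),
        t2s=tuple(float(t) for t in np.exp(theta[3:])),
    )


def _objective(theta, te, s, lam=0.0, quad_a=None, quad_b=None, a_ref=1.0):
    """Sum-of-squares misfit (+ optional local quadratic penalty) and gradient.

    ``theta`` is (A1, A2, A3, log T2_1, log T2_2, log T2_3).  The penalty,
    used by the Gauss-Seidel volume sweeps, is quadratic per component in
    the normalized map value (A/a_ref for amplitudes, log T2 for times):
    ``sum_j lam * (quad_a[j] * v_j^2 + quad_b[j] * v_j)``.
    """
    a = theta[:3]
    t2 = np.exp(theta[3:])
    e = np.exp(-te[:, None] / t2[None, :])        # (n_echo, 3)
    model = e @ a
    r = model - s
    f = float(r @ r)
    grad = np.empty(6)
    grad[:3] = 2.0 * (r @ e)
    grad[3:] = 2.0 * (r @ (e * te[:, None])) * a / t2
    if lam > 0.0:
        v = np.concatenate([a / a_ref, theta[3:]])
        f += float(lam * np.sum(quad_a * v**2 + quad_b * v))
        gpen = lam * (2.0 * quad_a * v + quad_b)
        gpen[:3] /= a_ref
        grad += gpen
    return f, grad


def _theta_bounds(bounds: PoolBounds):
    box = [(0.0, None)] * 3
    box += [(np.log(lo), np.log(hi)) for lo, hi in bounds.as_tuple()]
    return box


def fit_voxel(
    signal: np.ndarray,
    schedule: np.ndarray,
    bounds: PoolBounds = DEFAULT_BOUNDS,
    init: VoxelPools | None = None,
    config: FitConfig | None = None,
) -> tuple[VoxelPools | None, float, bool]:
    """Bounded NLLS fit of one voxel.

    Returns ``(pools, residual_norm, converged)``; ``pools`` is ``None``
    for an unfittable (all-zero) voxel.  Deterministic given the
    initialization.  The objective at the solution never exceeds the
    objective at the starting point.
    """
    config = config or FitConfig()
    s = np.asarray(signal, dtype=float)
    te = np.asarray(schedule, dtype=float)
    if s.size < 6:
        raise ValueError("need >= 6 echoes for a 6-parameter fit")
    if init is None:
        init = init_pools(s, te, bounds)
    if init is None:
        return None, float(np.linalg.norm(s)), True
    theta0 = _pack(init)
    res = minimize(
        _objective,
        theta0,
        args=(te, s),
        jac=True,
        method="L-BFGS-B",
        bounds=_theta_bounds(bounds),
        options={"maxiter": config.max_iter, "gtol": config.gtol, "ftol": 1e-14},
    )
    f0 = _objective(theta0, te, s)[0]
    if res.fun > f0:  # never accept a step uphill from the init
        theta, fval = theta0, f0
    else:
        theta, fval = res.x, res.fun
    return _unpack(theta), float(np.sqrt(fval)), bool(res.success or res.fun <= f0)


def compute_wf(pools: VoxelPools) -> tuple[float, float, float] | None:
    """Water fractions = amplitude / total amplitude; None if total is 0."""
    total = sum(pools.amplitudes)
    if total <= 0:
        return None
    return tuple(a / total for a in pools.amplitudes)


# ---------------------------------------------------------------------------
# volume fit with optional Laplacian smoothing

_NEIGHBOR_OFFSETS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def _laplacian_quad_coeffs(idx, params, mask, inv_h2, n_params):
    """Local quadratic penalty coefficients for updating one voxel.

    Writing the squared-Laplacian penalty restricted to the stencils that
    contain voxel ``idx`` as ``a*v^2 + b*v + const`` per parameter map
    (``v`` the voxel's normalized map value), returns arrays ``a, b`` of
    length ``n_params``.
    """
    shape = mask.shape
    x, y, z = idx
    # stencil centered at idx: lap = c0 - s0*v
    s0 = 0.0
    c0 = np.zeros(n_params)
    nbrs = []
    for ax, (dx, dy, dz) in enumerate(_NEIGHBOR_OFFSETS):
        nx, ny, nz = x + dx, y + dy, z + dz
        if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
            continue
        if not mask[nx, ny, nz]:
            continue
        w = inv_h2[ax // 2]
        s0 += w
        c0 += w * params[:, nx, ny, nz]
        nbrs.append(((nx, ny, nz), w))
    quad_a = np.full(n_params, s0 * s0)
    quad_b = -2.0 * c0 * s0
    # stencils centered at each in-mask neighbour n: lap_n = K_n + w*v
    for (nx, ny, nz), w in nbrs:
        k = np.zeros(n_params)
        s_n = 0.0
        for ax2, (dx, dy, dz) in enumerate(_NEIGHBOR_OFFSETS):
            mx, my, mz = nx + dx, ny + dy, nz + dz
            if not (0 <= mx < shape[0] and 0 <= my < shape[1] and 0 <= mz < shape[2]):
                continue
            if not mask[mx, my, mz]:
                continue
            w2 = inv_h2[ax2 // 2]
            s_n += w2
            if (mx, my, mz) != (x, y, z):
                k += w2 * params[:, mx, my, mz]
        k -= s_n * params[:, nx, ny, nz]       # K_n excludes v's contribution
        quad_a += w * w
        quad_b += 2.0 * w * k
    return quad_a, quad_b


def fit_volume(
    volume: EchoVolume,
    mask: np.ndarray,
    bounds: PoolBounds = DEFAULT_BOUNDS,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the three-pool model over every voxel in ``mask``.

    With ``lambda_laplacian = 0`` this reduces exactly to independent
    :func:`fit_voxel` calls.  With a positive weight, independently fitted
    maps are refined by Gauss-Seidel sweeps that re-solve each voxel with
    a local quadratic expansion of the squared-Laplacian smoothness
    penalty over its 6-neighbourhood (physical spacing in mm).
    """
    config = config or FitConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("mask is empty")
    if not np.all(np.isfinite(volume.data[mask])):
        bad = np.argwhere(mask & ~np.all(np.isfinite(volume.data), axis=-1))[0]
        raise ValueError(f"non-finite input signal at voxel {tuple(int(i) for i in bad)}")

    te = np.asarray(volume.te_ms)
    shape = volume.shape
    amps = np.zeros(shape + (3,))
    t2s = np.zeros(shape + (3,))
    residual = np.zeros(shape)
    quality = np.zeros(shape, dtype=np.int8)
    n_nonconv = 0

    voxels = np.argwhere(mask)
    for x, y, z in voxels:
        s = volume.data[x, y, z]
        pools, rnorm, conv = fit_voxel(s, te, bounds, config=config)
        residual[x, y, z] = rnorm
        if pools is None:
            quality[x, y, z] = Q_UNFITTABLE
            continue
        amps[x, y, z] = pools.amplitudes
        t2s[x, y, z] = pools.t2s
        quality[x, y, z] = Q_OK if conv else Q_NONCONVERGED
        n_nonconv += 0 if conv else 1

    if config.lambda_laplacian > 0 and len(voxels) > 1:
        _smooth_sweeps(volume, mask, bounds, config, amps, t2s, residual, quality)

    fitted = quality == Q_OK
    fitted |= quality == Q_NONCONVERGED
    wf = _wf_from_maps(amps, fitted)
    lo = np.array([b[0] for b in bounds.as_tuple()])
    hi = np.array([b[1] for b in bounds.as_tuple()])
    at_bound = fitted & np.any(
        np.isclose(t2s, lo, rtol=1e-6) | np.isclose(t2s, hi, rtol=1e-6), axis=-1
    )
    return FitResult(
        amplitudes=amps,
        t2s=t2s,
        wf=wf,
        residual=residual,
        quality=quality,
        n_at_bound=int(at_bound.sum()),
        n_nonconverged=n_nonconv,
    )


def _smooth_sweeps(volume, mask, bounds, config, amps, t2s, residual, quality):
    """In-place Gauss-Seidel refinement under the Laplacian penalty."""
    te = np.asarray(volume.te_ms)
    inv_h2 = np.array([1.0 / v**2 for v in volume.voxel_size])
    a_ref = float(volume.data[mask][:, 0].mean())
    if a_ref <= 0:
        a_ref = 1.0
    # normalized parameter maps: (A/a_ref handled inside objective), log T2
    fittable = mask & (quality != Q_UNFITTABLE)
    with np.errstate(divide="ignore"):
        logt2 = np.where(t2s > 0, np.log(np.maximum(t2s, 1e-30)), 0.0)
    params = np.concatenate(
        [np.moveaxis(amps, -1, 0) / a_ref, np.moveaxis(logt2, -1, 0)], axis=0
    )
    box = _theta_bounds(bounds)
    voxels = np.argwhere(fittable)
    for _ in range(config.n_sweeps):
        for x, y, z in voxels:
            quad_a, quad_b = _laplacian_quad_coeffs(
                (x, y, z), params, fittable, inv_h2, 6
            )
            s = volume.data[x, y, z]
            theta0 = np.concatenate(
                [params[:3, x, y, z] * a_ref, params[3:, x, y, z]]
            )
            res = minimize(
                _objective,
                theta0,
                args=(te, s, config.lambda_laplacian, quad_a, quad_b, a_ref),
                jac=True,
                method="L-BFGS-B",
                bounds=box,
                options={"maxiter": config.max_iter, "gtol": config.gtol, "ftol": 1e-14},
            )
            f0 = _objective(theta0, te, s, config.lambda_laplacian, quad_a, quad_b, a_ref)[0]
            theta = res.x if res.fun <= f0 else theta0
            params[:3, x, y, z] = theta[:3] / a_ref
            params[3:, x, y, z] = theta[3:]
    for x, y, z in voxels:
        amps[x, y, z] = params[:3, x, y, z] * a_ref
        t2s[x, y, z] = np.exp(params[3:, x, y, z])
        e = np.exp(-te[:, None] / t2s[x, y, z][None, :])
        residual[x, y, z] = float(
            np.linalg.norm(e @ amps[x, y, z] - volume.data[x, y, z])
        )


def _wf_from_maps(amps: np.ndarray, fitted: np.ndarray) -> WFMaps:
    total = amps.sum(axis=-1)
    defined = fitted & (total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(defined[..., None], amps / total[..., None], np.nan)
    return WFMaps(
        mwf=frac[..., 0], iewf=frac[..., 1], csff=frac[..., 2], defined=defined
    )
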