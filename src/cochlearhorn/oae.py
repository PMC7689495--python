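"""Stimulus-frequency otoacoustic emissions by coherent reflection.

Small random irregularities ("roughness") in the partition admittance
scatter the forward traveling wave; the coherently backscattered
components superpose into a backward wave observable at the stapes.  The
first-order (Born) reflectance for a multiplicative admittance
perturbation Y -> Y (1 + eps(x)), which perturbs kappa^2 by kappa^2*eps,
is

    R(f) = -(i/2) Int_0^L eps(x) kappa(x, f) exp(-2 i Int_0^x kappa dx') dx,

referenced to the forward wave at the base.  (The sign follows from the
outgoing 1-D Green's function under the exp(+i w t) time convention and
is verified against the perturbed finite-difference horn solution; all
derived observables |R| and N_SFOAE are sign-independent.)  The phase-gradient delay
N_SFOAE(f) = -(f/2 pi) d phi/d f (phi = unwrapped phase of R) expresses
the emission latency in stimulus periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import CochlearModel
from . import wkb

__all__ = [
    "RoughnessProfile",
    "SfoaeResult",
    "make_roughness",
    "sfoae_reflectance",
    "n_sfoae",
    "ensemble_run",
    "tuning_ratio",
    "median_trend",
]


@dataclass
class RoughnessProfile:
    """Seeded, zero-mean Gaussian per-point admittance perturbation."""

    seed: int
    amplitude: float
    eps: np.ndarray


@dataclass
class SfoaeResult:
    f_grid: np.ndarray
    R: np.ndarray
    n_sfoae: np.ndarray | None = None


def make_roughness(grid: np.ndarray, amplitude: float, seed: int) -> RoughnessProfile:
    """Independent N(0, amplitude^2) draws per grid point, reproducible from seed."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    eps = amplitude * rng.standard_normal(np.asarray(grid).size)
    return RoughnessProfile(seed=seed, amplitude=amplitude, eps=eps)


def _born_reflectance_from_field(x, kappa, eps_matrix):
    """R = -(i/2) Int eps kappa e^{-2i Int kappa} dx for each row of eps_matrix."""
    phase = cumulative_trapezoid(kappa, x, initial=0.0)
    integrand = kappa * np.exp(-2j * phase)
    # trapezoidal weights on the uniform grid
    wgt = np.full(x.size, x[1] - x[0])
    wgt[0] *= 0.5
    wgt[-1] *= 0.5
    return -0.5j * (eps_matrix * integrand) @ wgt


def sfoae_reflectance(
    model: CochlearModel, roughness: RoughnessProfile, f_grid: np.ndarray
) -> SfoaeResult:
    """First-order basal reflectance R(f) for one rough ear."""
    f_grid = np.asarray(f_grid, float)
    R = np.empty(f_grid.size, dtype=complex)
    eps = roughness.eps[np.newaxis, :]
    for j, f in enumerate(f_grid):
        field = wkb.solve_alpha_kappa(model.profile, model.micro, float(f),
                                      model.tol, model.max_iter)
        if not field.converged:
            raise RuntimeError(f"wave field did not converge at f = {f:.1f} Hz")
        R[j] = _born_reflectance_from_field(model.profile.x, field.kappa, eps)[0]
    return SfoaeResult(f_grid=f_grid, R=R)


def fd_reflectance(model: CochlearModel, roughness: RoughnessProfile, f: float) -> complex:
    """Independent oracle: scattered basal wave from the perturbed FD horn solution.

    Solves the horn equation with an incident-wave basal boundary condition
    for the unperturbed and the eps-perturbed wavenumber (kappa^2 ->
    kappa^2*(1+eps)) and returns the difference of the basal pressures —
    the backscattered (emitted) wave.  The roughness should vanish near
    the two boundary points, whose local kappa enters the radiation
    conditions.
    """
    field = wkb.solve_alpha_kappa(model.profile, model.micro, float(f),
                                  model.tol, model.max_iter)
    k0 = field.kappa
    kp = np.sqrt(k0**2 * (1.0 + roughness.eps))
    kp = np.where(kp.real < 0, -kp, kp)
    p0 = wkb.solve_horn_fd(model.profile, k0, basal_bc="incident")
    pe = wkb.solve_horn_fd(model.profile, kp, basal_bc="incident")
    return complex(pe[0] - p0[0])


def n_sfoae(result: SfoaeResult, floor: float = 0.0) -> np.ndarray:
    """Phase-gradient delay in stimulus periods, N = -(f/2 pi) d phi/df.

    Centered differences on the (possibly log-spaced) grid; points where
    |R| falls below ``floor`` are returned as NaN (gaps).
    """
    if np.all(result.R == 0):
        raise ValueError("reflectance identically zero (no roughness?)")
    phi = np.unwrap(np.angle(result.R))
    N = -(result.f_grid / (2.0 * np.pi)) * np.gradient(phi, result.f_grid)
    if floor > 0:
        N = np.where(np.abs(result.R) < floor, np.nan, N)
    result.n_sfoae = N
    return N


def ensemble_run(
    model: CochlearModel,
    f_grid: np.ndarray,
    n_ears: int = 128,
    amplitude: float = 0.01,
    seeds: np.ndarray | None = None,
):
    """Simulate SFOAEs in ``n_ears`` rough ears sharing one smooth cochlea.

    The unperturbed wave field is computed once per frequency and reused
    across ears (the Born integral is linear in the roughness).  Returns
    (results, N_matrix, N_median): per-ear SfoaeResult list, the per-ear
    delay curves, and their per-frequency median.
    """
    if n_ears < 1:
        raise ValueError("n_ears must be >= 1")
    f_grid = np.asarray(f_grid, float)
    if seeds is None:
        seeds = np.arange(n_ears)
    seeds = np.asarray(seeds)
    if seeds.size != n_ears:
        raise ValueError("need one seed per ear")
    eps_matrix = np.stack(
        [make_roughness(model.profile.x, amplitude, int(s)).eps for s in seeds]
    )
    R = np.empty((n_ears, f_grid.size), dtype=complex)
    for j, f in enumerate(f_grid):
        field = wkb.solve_alpha_kappa(model.profile, model.micro, float(f),
                                      model.tol, model.max_iter)
        R[:, j] = _born_reflectance_from_field(model.profile.x, field.kappa, eps_matrix)
    results = [SfoaeResult(f_grid=f_grid, R=R[i]) for i in range(n_ears)]
    if amplitude == 0:
        N = np.zeros((n_ears, f_grid.size))
        return results, N, np.zeros(f_grid.size)
    N = np.stack([n_sfoae(r) for r in results])
    return results, N, np.median(N, axis=0)


def tuning_ratio(f_common, q_trend, n_trend):
    """Pointwise tuning ratio Q_ERB / N_SFOAE on a common frequency grid.

    Points with non-positive or missing N are returned as NaN (gaps).
    """
    q = np.asarray(q_trend, float)
    n = np.asarray(n_trend, float)
    f = np.asarray(f_common, float)
    if not (q.shape == n.shape == f.shape):
        raise ValueError("trends must share the common frequency grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n > 0, q / n, np.nan)
    return ratio


def median_trend(values, window: int = 31):
    """Centered rolling-median trend line (for delay curves with fine structure).

    NaNs are ignored within each window; the window shrinks at the edges.
    """
    v = np.asarray(values, float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        seg = v[max(0, i - half): i + half + 1]
        out[i] = np.nanmedian(seg) if np.any(np.isfinite(seg)) else np.nan
    return out


def interp_trend_loglog(f_target, f_known, values):
    """Interpolate a positive trend in log-log coordinates onto f_target."""
    f_target = np.asarray(f_target, float)
    v = np.exp(np.interp(np.log(f_target), np.log(np.asarray(f_known, float)),
                         np.log(np.asarray(values, float))))
    return v
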