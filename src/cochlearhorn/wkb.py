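"""WKB solution of the cochlear horn equation.

The cross-section-averaged transpartition pressure Pbar obeys a Webster
horn equation (1/S)(S Pbar')' + kappa^2 Pbar = 0 with a complex
wavenumber kappa = sqrt(-alpha * Zbar * Y_CP), where Zbar = i w rho b / S
is the series (fluid-mass) impedance and alpha = kappa*h/tanh(kappa*h) is
the short-wave pressure gain — the ratio of the pressure driving the
partition to the scalae average.  alpha and kappa depend on each other
and are solved by pointwise fixed-point iteration; the WKB forward wave
then gives the driving pressure

    P0(x) = alpha(x) * sqrt(S(0)/S(x)) * sqrt(kappa(0)/kappa(x))
            * exp(-i Int_0^x kappa dx'),

with time convention exp(+i w t), so decaying waves have Im kappa < 0.

A second-order finite-difference solver for the same horn equation is
provided as an independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded

from .geometry import GeometryProfile
from .micromechanics import MicromechanicsParams, admittance

__all__ = [
    "WaveField",
    "series_impedance",
    "alpha_of",
    "wavenumber",
    "select_bounded_branch",
    "solve_alpha_kappa",
    "wkb_pressure",
    "partition_velocity",
    "characteristic_impedance",
    "horn_residual",
    "solve_horn_fd",
]


@dataclass
class WaveField:
    """Converged per-frequency wave solution on the geometry grid."""

    f: float
    x: np.ndarray
    kappa: np.ndarray
    alpha: np.ndarray
    P0: np.ndarray | None = None
    Vcp: np.ndarray | None = None
    iterations: int = 0
    converged: bool = True
    max_residual: float = 0.0


def series_impedance(profile: GeometryProfile, f, x_index=slice(None)):
    """Series acoustic impedance Zbar = i*2*pi*f*rho*b/S (pure mass reactance)."""
    if np.any(np.asarray(f) <= 0):
        raise ValueError("frequency must be positive")
    return 1j * 2.0 * np.pi * np.asarray(f, float) * profile.m_bar[x_index]


def alpha_of(kh, check_poles: bool = True):
    """Short-wave pressure gain alpha = kh / tanh(kh).

    Even in kh, with the removable singularity at kh = 0 filled by its
    limit 1.  Raises for arguments at the poles of 1/tanh (kh = i n pi,
    n != 0), detected to floating-point resolution.
    """
    kh = np.asarray(kh, dtype=complex)
    t = np.tanh(kh)
    small = np.abs(kh) < 1e-6
    if check_poles and np.any((np.abs(t) < 1e-9) & ~small):
        raise ZeroDivisionError("alpha(kh) singular: kh at a pole of 1/tanh")
    safe_t = np.where(small | (t == 0.0), 1.0, t)
    out = np.where(small, 1.0 + kh**2 / 3.0, kh / safe_t)
    return out if out.ndim else complex(out)


def wavenumber(alpha, Zbar, Ycp):
    """Forward-branch wavenumber kappa = sqrt(-alpha * Zbar * Y_CP).

    The principal square root already has Re kappa >= 0; purely imaginary
    results (ties) are broken toward Im kappa <= 0, the decaying forward
    wave under the exp(+i w t), exp(-i Int kappa dx) convention.
    """
    w = np.sqrt(-np.asarray(alpha, complex) * np.asarray(Zbar, complex)
                * np.asarray(Ycp, complex))
    w = np.where(w.real < 0.0, -w, w)  # safety: enforce forward branch
    out = np.where((w.real == 0.0) & (w.imag > 0.0), -w, w)
    return out if out.ndim else complex(out)


def select_bounded_branch(kappa):
    """Bounded-solution branch past the turning point.

    Where the wave is evanescent-dominated (Re kappa^2 < 0, i.e.
    |Im kappa| > |Re kappa|) the physical, apically bounded solution is
    the decaying exponential — the standard WKB connection across a
    turning point.  Growing evanescent points are therefore flipped to
    Im kappa < 0.  Because alpha = kappa*h/tanh(kappa*h) is even in
    kappa, the flipped wavenumber satisfies the same dispersion relation.
    """
    kappa = np.asarray(kappa, complex)
    flip = (np.abs(kappa.imag) > np.abs(kappa.real)) & (kappa.imag > 0.0)
    out = np.where(flip, -kappa, kappa)
    return out if out.ndim else complex(out)


def _dispersion_root(w: complex, u0: complex, tol: float = 1e-12, max_iter: int = 50) -> complex:
    """Damped Newton solution of u*tanh(u) = w from seed u0.

    This is the alpha-kappa fixed point in scalar form (u = kappa*h,
    w = -Zbar*Y*h^2): kappa^2 = -alpha*Zbar*Y with alpha = u/tanh(u)
    is equivalent to u*tanh(u) = w.
    """
    u = complex(u0)
    for _ in range(max_iter):
        t = np.tanh(u)
        g = u * t - w
        if abs(g) <= tol * max(1.0, abs(w)):
            return u
        dg = t + u * (1.0 - t * t)
        if dg == 0:
            dg = 1e-12
        step = g / dg
        # clip oversized steps to stay on the local branch
        cap = 0.5 * max(abs(u), 1.0)
        if abs(step) > cap:
            step *= cap / abs(step)
        u = u - step
    return u


def solve_alpha_kappa(
    profile: GeometryProfile,
    micro: MicromechanicsParams,
    f: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> WaveField:
    """Solve the pointwise alpha-kappa fixed point at frequency ``f``.

    Starts from the long-wave seed alpha = 1 and iterates
    kappa = sqrt(-alpha Zbar Y), alpha = kappa h / tanh(kappa h) until the
    relative change of alpha falls below ``tol`` everywhere.  If the
    residual stalls or oscillates, under-relaxation (mixing factor 0.5)
    is engaged automatically.

    The iteration runs on the principal (Re kappa >= 0) branch, where
    tanh is well behaved; the returned kappa is then mapped through
    :func:`select_bounded_branch` so that evanescent regions beyond the
    wave peak decay apically.  alpha is even in kappa*h, so the fixed
    point is unchanged by this branch selection.

    Points where the fixed-point iteration stalls (typically the
    evanescent strip just apical of the wave peak, where tanh oscillates
    near its imaginary-axis poles) are repaired by a Newton solution of
    the equivalent scalar dispersion relation u*tanh(u) = -Zbar*Y*h^2,
    continued point-by-point in x from the nearest converged basal
    neighbor so that the fundamental transverse mode is followed.
    """
    Zbar = series_impedance(profile, f)
    Y = admittance(micro, profile.k, profile.cf, f)
    h = profile.h
    alpha = np.ones(profile.x.size, dtype=complex)
    kappa = wavenumber(alpha, Zbar, Y)
    mix = 1.0
    prev_res = np.inf
    res = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        kappa = wavenumber(alpha, Zbar, Y)
        alpha_new = alpha_of(kappa * h, check_poles=False)
        resv = np.abs(alpha_new - alpha) / np.maximum(np.abs(alpha_new), 1e-300)
        res = float(np.max(resv))
        if res < tol:
            alpha = alpha_new
            kappa = wavenumber(alpha, Zbar, Y)
            break
        if res >= prev_res:
            mix = 0.5
        prev_res = res
        alpha = mix * alpha_new + (1.0 - mix) * alpha
    converged = res < tol

    if not converged:
        # Newton repair on the scalar dispersion relation, with x-continuation
        w_all = -Zbar * Y * h * h
        u_all = kappa * h
        resv = np.abs(alpha_of(u_all, check_poles=False) * Zbar * Y + kappa**2) / np.maximum(
            np.abs(kappa**2), 1e-300
        )
        bad = np.flatnonzero(resv > tol)
        for i in bad:
            j = i - 1
            while j >= 0 and resv[j] > tol:
                j -= 1
            u_seed = u_all[j] if j >= 0 else np.sqrt(w_all[i])
            u = _dispersion_root(w_all[i], u_seed)
            u_all[i] = u
            t = np.tanh(u)
            resv[i] = abs(u * t - w_all[i]) / max(1.0, abs(w_all[i]))
            kappa[i] = u / h[i]
            alpha[i] = u / t if abs(u) > 1e-6 else 1.0 + u * u / 3.0
        kappa = np.where(kappa.real < 0.0, -kappa, kappa)
        res = float(np.max(resv))
        converged = res < max(tol, 1e-9)

    kappa = select_bounded_branch(kappa)
    return WaveField(
        f=float(f), x=profile.x, kappa=kappa, alpha=alpha,
        iterations=it, converged=bool(converged), max_residual=res,
    )


def wkb_pressure(
    profile: GeometryProfile, field: WaveField, drive: complex = 1.0,
    min_points_per_wavelength: float = 20.0,
) -> WaveField:
    """Fill in the WKB driving pressure P0 (basal mean pressure = ``drive``).

    The phase integral uses the trapezoidal rule on the profile grid.  A
    warning is issued if the grid resolves the shortest wavelength with
    fewer than ``min_points_per_wavelength`` points, or if |kappa| passes
    near zero (turning point), where the WKB amplitude is unreliable.
    """
    import warnings

    kappa = field.kappa
    lam_min = 2.0 * np.pi / np.max(np.abs(kappa.real) + 1e-300)
    if lam_min / profile.dx < min_points_per_wavelength:
        warnings.warn(
            "grid resolves the shortest wavelength with fewer than "
            f"{min_points_per_wavelength:.0f} points; refine n_points",
            RuntimeWarning, stacklevel=2,
        )
    if np.min(np.abs(kappa)) < 1e-12 * np.max(np.abs(kappa)):
        warnings.warn("kappa crosses zero (turning point): WKB amplitude unreliable",
                      RuntimeWarning, stacklevel=2)
    phase = cumulative_trapezoid(kappa, profile.x, initial=0.0)
    pref = field.alpha * np.sqrt(profile.S[0] / profile.S) * np.sqrt(kappa[0] / kappa)
    field.P0 = drive * pref * np.exp(-1j * phase)
    return field


def partition_velocity(
    field: WaveField, profile: GeometryProfile, micro: MicromechanicsParams
) -> WaveField:
    """Fill partition velocity Vcp = Y_CP * P0."""
    if field.P0 is None:
        raise ValueError("P0 not filled; call wkb_pressure first")
    Y = admittance(micro, profile.k, profile.cf, field.f)
    field.Vcp = Y * field.P0
    return field


def characteristic_impedance(
    profile: GeometryProfile, micro: MicromechanicsParams, f: float, x_index=slice(None)
):
    """Characteristic impedance Z0 = sqrt(Zbar / Y_CP).

    In the stiffness-dominated long-wave tail this reduces to
    sqrt(m_bar * k): real, and spatially constant under tapering symmetry.
    """
    Zbar = series_impedance(profile, f, x_index)
    Y = admittance(micro, profile.k[x_index], profile.cf[x_index], f)
    return np.sqrt(Zbar / Y)


def horn_residual(profile: GeometryProfile, kappa: np.ndarray, pbar: np.ndarray) -> np.ndarray:
    """Normalized residual of the horn equation for a candidate Pbar.

    r = [(1/S)(S Pbar')' + kappa^2 Pbar] / max|kappa^2 Pbar|, with
    second-order central differences; endpoints are set to 0 (one-sided
    stencils there would be lower order).
    """
    dx = profile.dx
    S = profile.S
    Sm = 0.5 * (S[1:] + S[:-1])  # S at half-points
    r = np.zeros(pbar.size, dtype=complex)
    flux = Sm * np.diff(pbar) / dx
    r[1:-1] = (flux[1:] - flux[:-1]) / (S[1:-1] * dx) + (kappa[1:-1] ** 2) * pbar[1:-1]
    scale = float(np.max(np.abs(kappa**2 * pbar)))
    return r / (scale if scale > 0 else 1.0)


def solve_horn_fd(
    profile: GeometryProfile,
    kappa: np.ndarray,
    basal_drive: complex = 1.0,
    apical_bc: str = "outgoing",
    basal_bc: str = "dirichlet",
) -> np.ndarray:
    """Direct second-order finite-difference solution of the horn equation.

    Solves (1/S)(S Pbar')' + kappa^2 Pbar = 0 as a banded linear system.

    basal_bc:
      ``dirichlet`` — Pbar(0) = basal_drive;
      ``incident``  — radiation condition injecting a unit-amplitude
        forward wave while letting any backscattered wave leave freely:
        Pbar'(0) - i kappa(0) Pbar(0) = -2 i kappa(0) * basal_drive.
        The backscattered (emitted) wave at the stapes is then
        Pbar(0) - basal_drive.
    apical_bc:
      ``outgoing`` — Pbar'(L) = -i kappa(L) Pbar(L) (no reflection);
      ``pressure-release`` — Pbar(L) = 0.
    """
    kappa = np.asarray(kappa, complex)
    n = profile.x.size
    if kappa.shape != (n,):
        raise ValueError("kappa must be on the profile grid")
    dx = profile.dx
    S = profile.S
    Sm = 0.5 * (S[1:] + S[:-1])
    # interior stencil coefficients: a_i P_{i-1} + c_i P_i + e_i P_{i+1} = 0
    lower = np.zeros(n, complex)
    diag = np.zeros(n, complex)
    upper = np.zeros(n, complex)
    rhs = np.zeros(n, complex)
    lower[1:-1] = Sm[:-1] / (S[1:-1] * dx**2)
    upper[1:-1] = Sm[1:] / (S[1:-1] * dx**2)
    diag[1:-1] = -(Sm[:-1] + Sm[1:]) / (S[1:-1] * dx**2) + kappa[1:-1] ** 2

    if basal_bc == "dirichlet":
        diag[0] = 1.0
        rhs[0] = basal_drive
    elif basal_bc == "incident":
        # ghost node via centered derivative: (P_1 - P_-1)/(2 dx) - i k0 P_0 = -2 i k0 d
        # interior stencil at 0 with S_{-1/2} ~ S_0: eliminate P_-1
        k0 = kappa[0]
        a = S[0] / (S[0] * dx**2)  # ghost-side coefficient
        e = Sm[0] / (S[0] * dx**2)
        c = -(S[0] + Sm[0]) / (S[0] * dx**2) + k0**2
        # P_-1 = P_1 - 2 dx (i k0 P_0 - 2 i k0 d)
        diag[0] = c - a * 2.0 * dx * 1j * k0
        upper[0] = e + a
        rhs[0] = -a * 4.0 * dx * 1j * k0 * basal_drive
    else:
        raise ValueError("basal_bc must be 'dirichlet' or 'incident'")

    if apical_bc == "outgoing":
        kN = kappa[-1]
        a = Sm[-1] / (S[-1] * dx**2)
        e = S[-1] / (S[-1] * dx**2)  # ghost-side coefficient
        c = -(Sm[-1] + S[-1]) / (S[-1] * dx**2) + kN**2
        # ghost: (P_{N+1} - P_{N-1})/(2 dx) = -i kN P_N
        diag[-1] = c - e * 2.0 * dx * 1j * kN
        lower[-1] = a + e
        rhs[-1] = 0.0
    elif apical_bc == "pressure-release":
        diag[-1] = 1.0
        lower[-1] = 0.0
        rhs[-1] = 0.0
    else:
        raise ValueError("apical_bc must be 'outgoing' or 'pressure-release'")

    ab = np.zeros((3, n), complex)
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, rhs)
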