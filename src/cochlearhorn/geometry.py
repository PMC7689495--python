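"""Tonotopic map and spatial tapers of the cochlear duct.

The cochlea maps frequency onto position (the tonotopic map) while its
geometry — partition stiffness, scalae cross-sectional area, scalae
height, and basilar-membrane (BM) width — tapers from base to apex.
This module builds those profiles on a shared uniform grid.

All quantities are SI internally (m, Hz, Pa, kg); conversion to mm/kHz
happens only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TonotopicMap",
    "TaperParams",
    "GeometryProfile",
    "effective_area",
    "build_geometry",
    "box_control_profile",
    "load_profile_table",
]

_LOG10 = math.log(10.0)
#: exponent of the Greenwood map per unit normalized distance
GREENWOOD_EXPONENT = 2.1


@dataclass(frozen=True)
class TonotopicMap:
    """Greenwood frequency-position map CF(x) = A (10^{2.1(1-x/L)} - gamma).

    Parameters
    ----------
    A : float
        Base frequency scale in Hz (CF at the apex is ``A*(1-gamma)``).
    gamma : float
        Bend parameter in [0, 1). gamma=0 gives a purely exponential map;
        gamma near 1 bends the map downward in the apex.
    L : float
        Basilar-membrane length in meters.
    """

    A: float
    gamma: float
    L: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.L > 0):
            raise ValueError("A and L must be positive")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")

    @property
    def l(self) -> float:
        """Basal space constant l = L / (2.1 ln 10), in meters."""
        return self.L / (GREENWOOD_EXPONENT * _LOG10)

    def cf(self, x):
        """Characteristic frequency (Hz) at position x (m from the stapes)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.L):
            raise ValueError("position outside [0, L]")
        out = self.A * (10.0 ** (GREENWOOD_EXPONENT * (1.0 - x / self.L)) - self.gamma)
        return out if out.ndim else float(out)

    def eta(self, x):
        """Local map-warping factor eta(x) = (l/x) ln(CF(0)/CF(x)).

        Defined so that CF(x) = CF(0) exp(-x eta(x) / l); the local space
        constant of the map is l/eta.  eta -> 10^2.1/(10^2.1 - gamma)
        (approximately 1) as x -> 0, and grows toward the apex for gamma > 0.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.L):
            raise ValueError("position outside [0, L]")
        cf0 = self.cf(0.0)
        u = 10.0 ** GREENWOOD_EXPONENT
        eta0 = u / (u - self.gamma)  # continuous x->0 limit of the log-slope
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(
                x > 0,
                (self.l / np.where(x > 0, x, 1.0)) * np.log(cf0 / self.cf(x)),
                eta0,
            )
        return val if val.ndim else float(val)

    def x_of_cf(self, f):
        """Inverse map: position (m) whose CF is ``f`` (Hz)."""
        f = np.asarray(f, dtype=float)
        lo, hi = self.cf(self.L), self.cf(0.0)
        if np.any(f < lo) or np.any(f > hi):
            raise ValueError("frequency outside the range of the map")
        x = self.L * (1.0 - np.log10(f / self.A + self.gamma) / GREENWOOD_EXPONENT)
        x = np.clip(x, 0.0, self.L)
        return x if x.ndim else float(x)


@dataclass(frozen=True)
class TaperParams:
    """Parameters of the built-in parametric tapers.

    The default values describe a cat-like cochlea: partition stiffness
    k(x) = k0 exp(-x/l) (one decade of stiffness per decade of CF in the
    base), scalae area falling as exp(-x/l) in the base and exp(-x/2l) in
    the apex with a smooth logistic blend of log-slopes, scalae radius
    h(x)/L = 0.0475 exp(-x/2l) + 0.015, and a BM width increasing linearly
    from b0 to b1.  ``regime="chinchilla"`` uses exp(-x/2l) area throughout.

    k0 is chosen so that the basal wave-front delay l*sqrt(mbar/k)*CF is
    about 1.5 CF periods, the constant value seen in basal mechanical data.
    """

    k0: float = 4.0e9  # Pa/m, volumetric stiffness at the stapes
    S0: float = 1.0e-6  # m^2, effective scalae area at the stapes
    b0: float = 1.0e-4  # m, BM width at the stapes
    b1: float = 3.0e-4  # m, BM width at the apex
    rho: float = 1000.0  # kg/m^3, perilymph density
    regime: str = "cat"  # "cat" | "chinchilla"
    s_transition_center: float = 0.6  # fraction of L, center of area-slope blend
    s_transition_width: float = 0.1  # fraction of L, width of the blend

    def __post_init__(self) -> None:
        for name in ("k0", "S0", "b0", "b1", "rho", "s_transition_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.regime not in ("cat", "chinchilla"):
            raise ValueError("regime must be 'cat' or 'chinchilla'")
        if not 0.0 < self.s_transition_center < 1.0:
            raise ValueError("s_transition_center must lie in (0, 1)")


@dataclass(frozen=True)
class GeometryProfile:
    """Discretized geometry on a shared uniform grid.

    Fields
    ------
    x : positions (m), strictly increasing, x[0]=0, x[-1]=L
    S : effective scalae area (m^2)
    h : scalae radius/height (m)
    b : BM width (m)
    k : partition volumetric stiffness (Pa/m)
    cf : local characteristic frequency (Hz), from the tonotopic map
    rho : fluid density (kg/m^3)
    """

    x: np.ndarray
    S: np.ndarray
    h: np.ndarray
    b: np.ndarray
    k: np.ndarray
    cf: np.ndarray
    rho: float
    _skip_taper_checks: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0) or x[0] != 0.0:
            raise ValueError("x must be strictly increasing with x[0] = 0")
        for name in ("S", "h", "b", "k", "cf"):
            arr = getattr(self, name)
            if np.asarray(arr).shape != x.shape:
                raise ValueError(f"{name} must match the grid shape")
            if np.any(np.asarray(arr) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not self._skip_taper_checks:
            tol = 1e-12
            for name in ("S", "h", "k"):
                arr = np.asarray(getattr(self, name))
                if np.any(np.diff(arr) > tol * arr[:-1]):
                    raise ValueError(f"{name} must be non-increasing (a taper)")

    @property
    def L(self) -> float:
        return float(self.x[-1])

    @property
    def m_bar(self) -> np.ndarray:
        """Acoustic mass of the scalae fluids, rho*b/S (kg/m^4)."""
        return self.rho * self.b / self.S

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])


def effective_area(Sv, St):
    """Harmonic combination Sv*St/(Sv+St) of the two scalae areas.

    Symmetric in its arguments and never larger than the smaller scala.
    """
    Sv = np.asarray(Sv, float)
    St = np.asarray(St, float)
    if np.any(Sv <= 0) or np.any(St <= 0):
        raise ValueError("scalae areas must be positive")
    out = Sv * St / (Sv + St)
    return out if out.ndim else float(out)


def _logistic_blend_log_area(x: np.ndarray, l: float, xc: float, w: float) -> np.ndarray:
    """log of S(x)/S0 with log-slope blending from -1/l (base) to -1/2l (apex).

    d ln S / dx = -(1/l) + (1/2l) * sigma((x - xc)/w); the integral of the
    logistic has the closed softplus form used here, so the blend is smooth
    and the slopes are exact asymptotically.
    """
    # integral of sigma((x-xc)/w) from 0 to x
    int_sigma = w * (np.logaddexp(0.0, (x - xc) / w) - np.logaddexp(0.0, -xc / w))
    return -x / l + int_sigma / (2.0 * l)


def build_geometry(
    tono: TonotopicMap, taper: TaperParams | None = None, n_points: int = 4096
) -> GeometryProfile:
    """Construct all spatial profiles on a uniform grid of ``n_points``.

    k(x) = k0 exp(-x/l); h(x) = L (0.0475 exp(-x/2l) + 0.015);
    S(x) follows the species regime; b(x) is linear from b0 to b1.
    """
    if n_points < 64:
        raise ValueError("n_points must be at least 64")
    taper = taper or TaperParams()
    L, l = tono.L, tono.l
    x = np.linspace(0.0, L, n_points)
    k = taper.k0 * np.exp(-x / l)
    h = L * (0.0475 * np.exp(-x / (2.0 * l)) + 0.015)
    if taper.regime == "chinchilla":
        S = taper.S0 * np.exp(-x / (2.0 * l))
    else:
        xc = taper.s_transition_center * L
        w = taper.s_transition_width * L
        S = taper.S0 * np.exp(_logistic_blend_log_area(x, l, xc, w))
    b = taper.b0 + (taper.b1 - taper.b0) * x / L
    return GeometryProfile(x=x, S=S, h=h, b=b, k=k, cf=np.asarray(tono.cf(x)), rho=taper.rho)


def box_control_profile(profile: GeometryProfile, match_wavenumber: bool = True) -> GeometryProfile:
    """Constant-cross-section ("box") control geometry.

    S, h and b are held at their basal values.  With ``match_wavenumber``
    (default) the stiffness is rescaled so that the long-wave wavenumber
    profile omega*sqrt(m_bar/k) matches the tapered model pointwise — the
    standard comparison in which only the geometric (horn) factor differs
    between the two models.
    """
    n = profile.x.size
    S = np.full(n, profile.S[0])
    h = np.full(n, profile.h[0])
    b = np.full(n, profile.b[0])
    k = profile.k.copy()
    if match_wavenumber:
        m_box = profile.rho * b / S
        k = profile.k * m_box / profile.m_bar
    return GeometryProfile(
        x=profile.x.copy(), S=S, h=h, b=b, k=k, cf=profile.cf.copy(),
        rho=profile.rho, _skip_taper_checks=True,
    )


def load_profile_table(path, tono: TonotopicMap, n_points: int = 4096,
                       rho: float = 1000.0) -> GeometryProfile:
    """Read a user-supplied anatomical profile and resample onto the grid.

    The file is whitespace- or comma-separated columnar text with header
    ``x_mm,S_mm2,h_mm,b_mm,k_Pa_per_m``; values are interpolated linearly
    onto a uniform ``n_points`` grid spanning [0, L].
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = ["x_mm", "S_mm2", "h_mm", "b_mm", "k_Pa_per_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    x_in = df["x_mm"].to_numpy() * 1e-3
    if np.any(np.diff(x_in) <= 0):
        raise ValueError("x_mm must be strictly increasing")
    x = np.linspace(0.0, tono.L, n_points)
    interp = lambda col, scale: np.interp(x, x_in, df[col].to_numpy() * scale)
    return GeometryProfile(
        x=x,
        S=interp("S_mm2", 1e-6),
        h=interp("h_mm", 1e-3),
        b=interp("b_mm", 1e-3),
        k=interp("k_Pa_per_m", 1.0),
        cf=np.asarray(tono.cf(x)),
        rho=rho,
    )
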