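"""Canonical model computations with analytic expectations.

Each function builds its inputs from the package's own primitives and
measures a single headline quantity of the tapered-cochlea model:

- the tail-frequency attenuation space constant of the apical taper
  regime (analytically 8 l);
- the decay space constant of the constant-area box control with the
  basal wavenumber profile (analytically 2 l);
- the wave-front-delay scaling exponent in the apical regime (1/4 for a
  purely exponential map, steeper with the bent map);
- the characteristic frequency at which the click-response glide
  changes direction.

They are used by the test suite and by scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np

from .geometry import GeometryProfile, TonotopicMap
from .micromechanics import MicromechanicsParams
from .model import CochlearModel
from . import response, wkb

__all__ = [
    "tail_decay_space_constant",
    "box_decay_space_constant",
    "wavefront_delay_exponent",
    "glide_sign_change_cf",
]


def _tail_profile(tono: TonotopicMap, s_slope_l: float, k_slope_l: float,
                  n_points: int) -> GeometryProfile:
    """Exponential-taper profile with configurable log-slopes (in 1/l)."""
    x = np.linspace(0.0, tono.L, n_points)
    l = tono.l
    return GeometryProfile(
        x=x,
        S=1e-6 * np.exp(s_slope_l * x / l),
        h=tono.L * (0.0475 * np.exp(-x / (2 * l)) + 0.015),
        b=np.full(n_points, 1e-4),
        k=4e9 * np.exp(k_slope_l * x / l),
        cf=np.asarray(tono.cf(x)),
        rho=1000.0,
        _skip_taper_checks=True,
    )


def tail_decay_space_constant(n_points: int = 4096, f: float = 10.0) -> float:
    """Space constant (in units of l) of the tail-frequency |P0| decay.

    Geometry: S ~ e^{-x/2l} (apical regime), k ~ e^{-x/l}, constant BM
    width; stiffness-dominated admittance, long-wave alpha ~ 1.  The
    amplitude prefactor of the WKB wave then decays as e^{-x/8l}; the
    value is measured by fitting log |P0| against x from the solver.
    """
    tono = TonotopicMap(A=456.0, gamma=0.8, L=25e-3)
    prof = _tail_profile(tono, s_slope_l=-0.5, k_slope_l=-1.0, n_points=n_points)
    micro = MicromechanicsParams(mode="tail")
    field = wkb.wkb_pressure(prof, wkb.solve_alpha_kappa(prof, micro, f))
    slope = np.polyfit(prof.x, np.log(np.abs(field.P0)), 1)[0]
    return float(-1.0 / (slope * tono.l))


def box_decay_space_constant(n_points: int = 4096, f: float = 10.0) -> float:
    """Space constant (in units of l) of the box-model |P0| decay.

    Constant S and h, with the stiffness arranged so the long-wave
    wavenumber matches the tapered basal model (kappa ~ e^{x/l}); only
    the sqrt(kappa(0)/kappa) prefactor remains and |P0| ~ e^{-x/2l}.
    """
    tono = TonotopicMap(A=456.0, gamma=0.8, L=25e-3)
    x = np.linspace(0.0, tono.L, n_points)
    prof = GeometryProfile(
        x=x,
        S=np.full(n_points, 1e-6),
        h=np.full(n_points, 1.5e-3),
        b=np.full(n_points, 1e-4),
        k=4e9 * np.exp(-2.0 * x / tono.l),
        cf=np.asarray(tono.cf(x)),
        rho=1000.0,
        _skip_taper_checks=True,
    )
    micro = MicromechanicsParams(mode="tail")
    field = wkb.wkb_pressure(prof, wkb.solve_alpha_kappa(prof, micro, f))
    slope = np.polyfit(prof.x, np.log(np.abs(field.P0)), 1)[0]
    return float(-1.0 / (slope * tono.l))


def wavefront_delay_exponent(gamma: float = 0.0, n_points: int = 2048) -> float:
    """d ln tau_wf / d ln CF in the apical taper regime.

    m_bar ~ e^{x/2l} and k ~ e^{-x/l}; with a purely exponential map the
    exponent is exactly 1/4, and the bent (gamma > 0) map makes it
    steeper.
    """
    tono = TonotopicMap(A=456.0, gamma=gamma, L=25e-3)
    prof = _tail_profile(tono, s_slope_l=-0.5, k_slope_l=-1.0, n_points=n_points)
    x = np.linspace(0.0, tono.L, 64)
    tau = response.wavefront_delay_analytic(prof, tono, x)
    p, _ = response.scaling_exponent(np.asarray(tono.cf(x)), tau)
    return float(p)


def glide_sign_change_cf(
    n_sites: int = 24,
    cf_min: float = 110.0,
    cf_max: float = 10e3,
    n_points: int = 3072,
    n_band: int = 256,
    model: CochlearModel | None = None,
    return_table: bool = False,
):
    """CF (kHz) at which the click-response glide reverses direction.

    Synthesizes click responses at log-spaced sites of the cat model and
    measures the dimensionless glide slope near the envelope peak at
    each; the sign-change CF is located by log-linear interpolation
    between the bracketing sites.  The default site range extends below
    0.2 kHz because in this model the reversal occurs close to the
    apical end of the map (see the methods note on known limitations).
    Returns NaN if the slope does not change sign in the range.
    """
    model = model or CochlearModel.cat(n_points=n_points)
    cfs = np.geomspace(cf_min, cf_max, n_sites)
    slopes = np.empty(n_sites)
    for i, cf in enumerate(cfs):
        x = model.tono.x_of_cf(cf)
        band = (cf / 16.0, min(4.0 * cf, 4.0 * model.profile.cf[0]))
        cr = response.click_response(model, x, n_band=n_band, band=band)
        slopes[i] = response.glide_slope(cr)
    crossing = np.nan
    sign = np.sign(slopes)
    for i in range(n_sites - 1):
        if sign[i] < 0 <= sign[i + 1] or sign[i] > 0 >= sign[i + 1]:
            lo, hi = np.log(cfs[i]), np.log(cfs[i + 1])
            t = slopes[i] / (slopes[i] - slopes[i + 1])
            crossing = float(np.exp(lo + t * (hi - lo)) / 1e3)
            break
    if return_table:
        return crossing, cfs, slopes
    return crossing
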