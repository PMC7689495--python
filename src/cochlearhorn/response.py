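"""Observables derived from wave fields.

Gain (velocity transfer) functions, equivalent-rectangular-bandwidth
quality factors, click responses synthesized by inverse Fourier
transform, instantaneous-frequency glides, and wave-front delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryProfile, TonotopicMap
from .model import CochlearModel

__all__ = [
    "TransferFunction",
    "ClickResponse",
    "TuningMetrics",
    "gain_function",
    "q_erb",
    "click_response",
    "click_from_transfer",
    "glide_slope",
    "wavefront_delay_analytic",
    "scaling_exponent",
]


@dataclass
class TransferFunction:
    """BM velocity vs frequency re input pressure at the base, at one site."""

    x_obs: float
    cf_local: float
    f_grid: np.ndarray
    T: np.ndarray
    converged: np.ndarray | None = None


@dataclass
class ClickResponse:
    """Time-domain click response at one site.

    w is the real waveform (velocity, arbitrary units), envelope the
    magnitude of the analytic signal, f_inst the instantaneous frequency
    (Hz) from the phase derivative of the analytic signal.
    """

    t_grid: np.ndarray
    w: np.ndarray
    envelope: np.ndarray
    f_inst: np.ndarray
    cf_local: float


@dataclass
class TuningMetrics:
    f_peak: float
    q_erb: float
    glide_slope_dimensionless: float
    tau_wf_periods: float


def gain_function(model: CochlearModel, x_obs: float, f_grid: np.ndarray) -> TransferFunction:
    """Velocity transfer function T(f) = V_CP(x_obs, f) with unit basal drive.

    Frequencies whose alpha-kappa iteration failed to converge are flagged
    in ``converged`` and excluded by downstream metrics.
    """
    f_grid = np.asarray(f_grid, float)
    if np.any(np.diff(f_grid) <= 0):
        raise ValueError("f_grid must be strictly increasing")
    T, ok = model.transfer(x_obs, f_grid)
    return TransferFunction(
        x_obs=x_obs, cf_local=model.cf_at_site(x_obs), f_grid=f_grid, T=T, converged=ok
    )


def q_erb(tf: TransferFunction) -> float:
    """Quality factor f_peak / ERB with ERB = Int |T|^2 df / max |T|^2."""
    mask = tf.converged if tf.converged is not None else np.ones(tf.T.size, bool)
    f = tf.f_grid[mask]
    mag2 = np.abs(tf.T[mask]) ** 2
    i_pk = int(np.argmax(mag2))
    if i_pk == 0 or i_pk == mag2.size - 1:
        raise ValueError("|T| maximum at grid edge; enlarge f_grid")
    erb = np.trapezoid(mag2, f) / mag2[i_pk]
    return float(f[i_pk] / erb)


def _analytic_from_spectrum(spec_onesided: np.ndarray, n_fft: int) -> np.ndarray:
    """Analytic signal whose real part is the irfft of the one-sided spectrum."""
    z_spec = np.zeros(n_fft, dtype=complex)
    z_spec[: spec_onesided.size] = spec_onesided
    z_spec[1:] *= 2.0  # analytic-signal convention (DC unscaled)
    return np.fft.ifft(z_spec)


def click_from_transfer(
    f_uniform: np.ndarray, T: np.ndarray, n_fft: int, cf_local: float,
    edge_fraction: float = 0.1,
) -> ClickResponse:
    """Synthesize a click response from T sampled on a uniform f grid.

    A flat click spectrum with raised-cosine band edges (each a fraction
    ``edge_fraction`` of the band) multiplies T; the waveform is the
    inverse FFT, and envelope/instantaneous frequency come from the
    analytic signal.
    """
    f_uniform = np.asarray(f_uniform, float)
    df = f_uniform[1] - f_uniform[0]
    if not np.allclose(np.diff(f_uniform), df, rtol=1e-9):
        raise ValueError("frequency grid must be uniform")
    if n_fft & (n_fft - 1):
        raise ValueError("n_fft must be a power of two")
    j0 = int(round(f_uniform[0] / df))
    if abs(f_uniform[0] - j0 * df) > 1e-6 * df:
        raise ValueError("grid must align with multiples of its spacing")
    if j0 + f_uniform.size > n_fft // 2:
        raise ValueError("band exceeds the FFT Nyquist range; increase n_fft")
    n_band = f_uniform.size
    n_edge = max(2, int(round(edge_fraction * n_band)))
    window = np.ones(n_band)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
    window[:n_edge] = ramp
    window[-n_edge:] = ramp[::-1]
    spec = np.zeros(n_fft // 2 + 1, dtype=complex)
    spec[j0 : j0 + n_band] = window * T
    z = _analytic_from_spectrum(spec, n_fft)
    dt = 1.0 / (n_fft * df)
    t = np.arange(n_fft) * dt
    envelope = np.abs(z)
    phase = np.unwrap(np.angle(z))
    f_inst = np.gradient(phase, dt) / (2.0 * np.pi)
    return ClickResponse(t_grid=t, w=z.real, envelope=envelope, f_inst=f_inst,
                         cf_local=cf_local)


def click_response(
    model: CochlearModel, x_obs: float, n_band: int = 512, n_fft: int = 2**14,
    band: tuple[float, float] | None = None,
) -> ClickResponse:
    """Model click response at ``x_obs`` via inverse FFT of the transfer function.

    The band defaults to [CF/16, 4*CF] around the local CF.  The transfer
    function is sampled at ``n_band`` uniform frequencies, embedded in an
    ``n_fft``-point spectrum, and inverted.
    """
    cf = model.cf_at_site(x_obs)
    f_lo, f_hi = band if band is not None else (cf / 16.0, 4.0 * cf)
    cf_max = float(model.profile.cf[0])
    if f_hi > 4.0 * cf_max or f_lo <= 0:
        raise ValueError("requested band clipped by the model range")
    df = (f_hi - f_lo) / n_band
    j0 = max(1, int(np.floor(f_lo / df)))
    j1 = int(np.ceil(f_hi / df))
    f_uniform = np.arange(j0, j1 + 1) * df
    T, _ = model.transfer(x_obs, f_uniform)
    return click_from_transfer(f_uniform, T, n_fft, cf)


def glide_slope(cr: ClickResponse, cf_local: float | None = None,
                gate: float = 0.5) -> float:
    """Dimensionless glide slope near the envelope peak.

    Least-squares slope of f_inst(t) over the contiguous window where the
    envelope exceeds ``gate`` (default 50%) of its maximum, normalized by
    the local CF squared.  Positive = upward glide.
    """
    cf = cf_local if cf_local is not None else cr.cf_local
    env = cr.envelope
    i_pk = int(np.argmax(env))
    if i_pk == 0 or i_pk == env.size - 1:
        raise ValueError("envelope maximum at edge of the time window")
    thr = gate * env[i_pk]
    lo = i_pk
    while lo > 0 and env[lo - 1] >= thr:
        lo -= 1
    hi = i_pk
    while hi < env.size - 1 and env[hi + 1] >= thr:
        hi += 1
    if hi - lo + 1 < 5:
        raise ValueError("fewer than 5 samples above the envelope gate")
    t = cr.t_grid[lo : hi + 1]
    fi = cr.f_inst[lo : hi + 1]
    slope = np.polyfit(t - t[0], fi, 1)[0]
    return float(slope / cf**2)


def wavefront_delay_analytic(profile: GeometryProfile, tono: TonotopicMap, x) -> float:
    """Wave-front delay in periods of the local CF: l * sqrt(m_bar/k) * CF.

    In the base (m_bar ~ e^{x/l}, k ~ e^{-x/l}, CF ~ e^{-x/l}) this is
    constant; in the apex it falls at least as fast as CF^{1/4}.
    """
    x = np.asarray(x, float)
    mk = np.interp(x, profile.x, profile.m_bar / profile.k)
    out = tono.l * np.sqrt(mk) * np.asarray(tono.cf(x))
    return out if out.ndim else float(out)


def scaling_exponent(cf, values):
    """OLS power-law exponent of ``values`` vs ``cf`` on log-log axes.

    Returns (exponent, stderr).
    """
    cf = np.asarray(cf, float)
    values = np.asarray(values, float)
    if cf.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(cf <= 0) or np.any(values <= 0):
        raise ValueError("power-law fit needs positive data")
    from scipy.stats import linregress

    res = linregress(np.log(cf), np.log(values))
    return float(res.slope), float(res.stderr)
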