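"""Cochlear-partition admittance models.

The partition is modeled as a distributed admittance Y_CP(x, omega)
relating transpartition driving pressure to partition velocity.  Its
dimensionless frequency response is a function of beta = f/CF(x) only
(scaling symmetry): the sharpness of micromechanical tuning is everywhere
identical, and all tonotopic variation of the simulated responses comes
from macromechanics (the map and the geometric tapers).

Three modes are provided:

``tail``
    The stiffness-dominated low-frequency limit Y = i*2*pi*f / k(x).
``passive``
    A broadly damped harmonic-oscillator filter (delta > 0).
``active``
    The same broad oscillator with a localized undamping window just
    basal of resonance:

        D(b) = 1 - b^2 + i*b*[delta + delta_act*exp(-(b-beta_act)^2 /
               (2*w_act^2))] + rho_f*exp(-2i*pi*b*T_f),

    with b = beta/beta_r and beta = f/CF(x).  The Gaussian undamping
    term (delta_act < 0) feeds energy into the traveling wave over the
    narrow region where it approaches its peak, while the broad baseline
    damping (delta) keeps the local resonance low-Q, as required for the
    broad tuning seen at apical sites; the sharp basal tuning then comes
    from short-wave hydrodynamic focusing, not from the filter.
    beta_r places the partition resonance slightly above the nominal CF
    of the map so that the simulated gain functions peak at CF.  An
    optional delayed stiffness-feedback term (rho_f, T_f) is retained
    for experimentation but defaults to zero.

All modes are functions of beta only — strict scaling symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MicromechanicsParams", "tail_admittance", "admittance", "SingularAdmittanceError"]

#: configurations with min |D(beta)| below this are rejected as (nearly) singular
MIN_ABS_D = 1e-3


class SingularAdmittanceError(ValueError):
    """The dimensionless filter D(beta) vanishes on the simulated band."""


@dataclass(frozen=True)
class MicromechanicsParams:
    """Parameters of the dimensionless partition filter.

    delta     : baseline damping coefficient (> 0; sets the broad local Q)
    delta_act : depth of the active undamping window (< 0 for gain)
    beta_act  : center of the undamping window (units of beta/beta_r)
    w_act     : Gaussian width of the undamping window
    beta_r    : resonance placement, f_resonance = beta_r * CF(x)
    rho_f     : delayed stiffness-feedback strength (0 disables)
    T_f       : feedback delay in periods of the local CF
    mode      : "tail" | "passive" | "active"
    """

    mode: str = "active"
    delta: float = 0.4
    delta_act: float = -0.55
    beta_act: float = 0.75
    w_act: float = 0.15
    beta_r: float = 1.07
    rho_f: float = 0.0
    T_f: float = 1.74

    def __post_init__(self) -> None:
        if self.mode not in ("tail", "passive", "active"):
            raise ValueError("mode must be 'tail', 'passive' or 'active'")
        if self.mode != "tail":
            if self.delta <= 0 and self.mode == "passive":
                raise ValueError("passive mode requires delta > 0")
            if self.mode == "passive" and self.rho_f != 0:
                raise ValueError("passive mode requires rho_f = 0")
            if self.w_act <= 0 or self.beta_r <= 0:
                raise ValueError("w_act and beta_r must be positive")

    def damping(self, b):
        """Effective damping profile delta(b) including the active window."""
        d = np.full_like(np.asarray(b, float), self.delta)
        if self.mode == "active" and self.delta_act != 0.0:
            d = d + self.delta_act * np.exp(-((b - self.beta_act) ** 2)
                                            / (2.0 * self.w_act**2))
        return d

    def filter(self, beta):
        """Dimensionless filter D(beta); Y_CP = i*2*pi*f / (k * D)."""
        beta = np.asarray(beta, dtype=float)
        if self.mode == "tail":
            out = np.ones(beta.shape, dtype=complex)
            return out if out.ndim else complex(out)
        b = beta / self.beta_r
        out = 1.0 - b**2 + 1j * self.damping(b) * b
        if self.rho_f != 0.0:
            out = out + self.rho_f * np.exp(-2j * np.pi * b * self.T_f)
        return out if out.ndim else complex(out)

    def validate_band(self, beta_max: float = 4.0, n: int = 4096) -> float:
        """Check min|D| over beta in (0, beta_max]; returns the minimum.

        Raises SingularAdmittanceError if the filter comes within MIN_ABS_D
        of a singularity (an undamped or marginally stable section).
        """
        beta = np.linspace(beta_max / n, beta_max, n)
        dmin = float(np.min(np.abs(self.filter(beta))))
        if dmin < MIN_ABS_D:
            raise SingularAdmittanceError(
                f"min |D(beta)| = {dmin:.2e} < {MIN_ABS_D:g}: admittance (nearly) singular"
            )
        return dmin


def tail_admittance(k_local, f):
    """Stiffness-dominated admittance i*2*pi*f / k (f << CF)."""
    k_local = np.asarray(k_local, float)
    f = np.asarray(f, float)
    if np.any(k_local <= 0) or np.any(f <= 0):
        raise ValueError("stiffness and frequency must be positive")
    out = 1j * 2.0 * np.pi * f / k_local
    return out if out.ndim else complex(out)


def admittance(params: MicromechanicsParams, k_local, cf_local, f):
    """Partition admittance Y_CP = i*2*pi*f / (k(x) * D(f/CF(x))).

    The product k*Y/(i*2*pi*f) = 1/D(beta) depends on position and
    frequency only through beta = f/CF(x) — the scaling symmetry the model
    stipulates.
    """
    k_local = np.asarray(k_local, float)
    cf_local = np.asarray(cf_local, float)
    f = np.asarray(f, float)
    if np.any(f <= 0) or np.any(cf_local <= 0):
        raise ValueError("frequencies must be positive")
    D = params.filter(f / cf_local)
    if np.any(np.abs(D) == 0.0):
        raise SingularAdmittanceError("D(beta) = 0: undamped resonance")
    out = 1j * 2.0 * np.pi * f / (k_local * D)
    return out if np.ndim(out) else complex(out)
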