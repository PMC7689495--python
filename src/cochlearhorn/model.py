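"""Convenience wrapper bundling map, geometry and micromechanics."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    GeometryProfile,
    TaperParams,
    TonotopicMap,
    box_control_profile,
    build_geometry,
)
from .micromechanics import MicromechanicsParams
from . import wkb

__all__ = ["CochlearModel"]


@dataclass
class CochlearModel:
    """A complete linear cochlea: tonotopic map + geometry + partition filter."""

    tono: TonotopicMap
    profile: GeometryProfile
    micro: MicromechanicsParams
    tol: float = 1e-6
    max_iter: int = 100

    @classmethod
    def cat(
        cls,
        gamma: float = 0.8,
        A: float = 456.0,
        L: float = 25e-3,
        n_points: int = 4096,
        taper: TaperParams | None = None,
        micro: MicromechanicsParams | None = None,
    ) -> "CochlearModel":
        """Cat-like default parameterization (Greenwood A=456 Hz, L=25 mm)."""
        tono = TonotopicMap(A=A, gamma=gamma, L=L)
        profile = build_geometry(tono, taper or TaperParams(), n_points)
        micro = micro or MicromechanicsParams()
        if micro.mode != "tail":
            micro.validate_band()
        return cls(tono=tono, profile=profile, micro=micro)

    @classmethod
    def chinchilla_like(cls, **kwargs) -> "CochlearModel":
        taper = kwargs.pop("taper", TaperParams(regime="chinchilla"))
        return cls.cat(taper=taper, **kwargs)

    def box(self, match_wavenumber: bool = True) -> "CochlearModel":
        """Constant-cross-section control with matched long-wave wavenumbers."""
        return replace(self, profile=box_control_profile(self.profile, match_wavenumber))

    def solve(self, f: float, drive: complex = 1.0) -> wkb.WaveField:
        """Converged WaveField (kappa, alpha, P0, Vcp) at one frequency."""
        field = wkb.solve_alpha_kappa(self.profile, self.micro, f, self.tol, self.max_iter)
        wkb.wkb_pressure(self.profile, field, drive)
        wkb.partition_velocity(field, self.profile, self.micro)
        return field

    def transfer(self, x_obs: float, f_grid: np.ndarray, drive: complex = 1.0):
        """Complex velocity transfer V_CP(x_obs, f) / Pbar(0) over ``f_grid``.

        Returns (T, converged_mask).  Non-converged frequencies are
        reported in the mask; their values are still filled.
        """
        i_obs = int(np.argmin(np.abs(self.profile.x - x_obs)))
        T = np.empty(len(f_grid), dtype=complex)
        ok = np.ones(len(f_grid), dtype=bool)
        for j, f in enumerate(f_grid):
            field = self.solve(float(f), drive)
            T[j] = field.Vcp[i_obs]
            ok[j] = field.converged
        return T, ok

    def cf_at_site(self, x_obs: float) -> float:
        return float(self.tono.cf(min(max(x_obs, 0.0), self.tono.L)))
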