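"""TOML run configuration: parsing, validation, defaults, serialization."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .geometry import TaperParams, TonotopicMap, build_geometry, load_profile_table
from .micromechanics import MicromechanicsParams
from .model import CochlearModel

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_SPECIES = ("cat", "chinchilla-like", "custom")


@dataclass
class RunConfig:
    """Fully serializable description of one simulation run."""

    geometry: dict = field(default_factory=dict)
    micromechanics: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    output_dir: str = "cochlearhorn-out"

    def as_dict(self) -> dict:
        return {
            "geometry": dict(self.geometry),
            "micromechanics": dict(self.micromechanics),
            "solver": dict(self.solver),
            "experiment": dict(self.experiment),
            "output_dir": self.output_dir,
        }

    def digest(self) -> str:
        """Stable hash of the full configuration (for output provenance)."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_model(self) -> CochlearModel:
        g = dict(_GEOMETRY_DEFAULTS, **self.geometry)
        m = dict(_MICRO_DEFAULTS, **self.micromechanics)
        s = dict(_SOLVER_DEFAULTS, **self.solver)
        species = g.pop("species")
        if species not in _SPECIES:
            raise ValueError(f"species must be one of {_SPECIES}")
        regime = "chinchilla" if species == "chinchilla-like" else "cat"
        tono = TonotopicMap(A=g["A_Hz"], gamma=g["gamma"], L=g["L_mm"] * 1e-3)
        taper = TaperParams(
            k0=g["k0_Pa_per_m"],
            S0=g["S0_mm2"] * 1e-6,
            b0=g["b0_mm"] * 1e-3,
            b1=g["b1_mm"] * 1e-3,
            rho=g["rho_kg_m3"],
            regime=regime,
            s_transition_center=g["s_transition_center"],
            s_transition_width=g["s_transition_width"],
        )
        micro = MicromechanicsParams(
            mode=m["mode"], delta=m["delta"], delta_act=m["delta_act"],
            beta_act=m["beta_act"], w_act=m["w_act"], beta_r=m["beta_r"],
            rho_f=m["rho_f"], T_f=m["T_f"],
        )
        if micro.mode != "tail":
            micro.validate_band()
        n_points = int(s["n_points"])
        table = g.get("profile_table")
        if table:
            profile = load_profile_table(table, tono, n_points, rho=g["rho_kg_m3"])
        else:
            profile = build_geometry(tono, taper, n_points)
        return CochlearModel(
            tono=tono, profile=profile, micro=micro,
            tol=float(s["tol"]), max_iter=int(s["max_iter"]),
        )


_GEOMETRY_DEFAULTS = {
    "species": "cat",
    "A_Hz": 456.0,
    "gamma": 0.8,
    "L_mm": 25.0,
    "k0_Pa_per_m": 4.0e9,
    "S0_mm2": 1.0,
    "b0_mm": 0.1,
    "b1_mm": 0.3,
    "rho_kg_m3": 1000.0,
    "s_transition_center": 0.6,
    "s_transition_width": 0.1,
    "profile_table": "",
}
_MICRO_DEFAULTS = {
    "mode": "active", "delta": 0.4, "delta_act": -0.55, "beta_act": 0.75,
    "w_act": 0.15, "beta_r": 1.07, "rho_f": 0.0, "T_f": 1.74,
}
_SOLVER_DEFAULTS = {"n_points": 4096, "tol": 1e-6, "max_iter": 100}
_EXPERIMENT_DEFAULTS = {
    "n_sites": 20,
    "cf_min_kHz": 0.2,
    "cf_max_kHz": 10.0,
    "n_freq": 200,
    "n_band": 512,
    "n_fft": 16384,
    "n_ears": 128,
    "roughness_amplitude": 0.01,
    "seed": 0,
    "n_oae_freq": 512,
}


def default_config_dict() -> dict:
    return {
        "geometry": dict(_GEOMETRY_DEFAULTS),
        "micromechanics": dict(_MICRO_DEFAULTS),
        "solver": dict(_SOLVER_DEFAULTS),
        "experiment": dict(_EXPERIMENT_DEFAULTS),
        "output_dir": "cochlearhorn-out",
    }


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML config; missing sections/keys fall back to defaults."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    cfg = RunConfig(
        geometry=data.get("geometry", {}),
        micromechanics=data.get("micromechanics", {}),
        solver=data.get("solver", {}),
        experiment={**_EXPERIMENT_DEFAULTS, **data.get("experiment", {})},
        output_dir=data.get("output_dir", "cochlearhorn-out"),
    )
    _validate_keys(cfg)
    return cfg


def _validate_keys(cfg: RunConfig) -> None:
    for section, defaults in (
        (cfg.geometry, _GEOMETRY_DEFAULTS),
        (cfg.micromechanics, _MICRO_DEFAULTS),
        (cfg.solver, _SOLVER_DEFAULTS),
        (cfg.experiment, _EXPERIMENT_DEFAULTS),
    ):
        unknown = set(section) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
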