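"""Named experiments: reproducible output bundles for the standard figures.

Each experiment writes CSV tables (with a header comment carrying the
config hash) plus a JSON manifest echoing the full configuration and
seeds, so every output is regenerable from its manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, oae, response
from .config import RunConfig
from .model import CochlearModel

__all__ = ["run_experiment", "EXPERIMENTS"]

log = logging.getLogger("cochlearhorn")


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cochlearhorn {__version__} config={cfg_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def _site_grid(model: CochlearModel, exp: dict) -> np.ndarray:
    cfs = np.geomspace(exp["cf_min_kHz"] * 1e3, exp["cf_max_kHz"] * 1e3,
                       int(exp["n_sites"]))
    return np.asarray([model.tono.x_of_cf(c) for c in cfs])


def _gain_tables(model: CochlearModel, exp: dict):
    rows = []
    for x_obs in _site_grid(model, exp):
        cf = model.cf_at_site(x_obs)
        fg = np.geomspace(cf / 16.0, 4.0 * cf, int(exp["n_freq"]))
        tf = response.gain_function(model, x_obs, fg)
        rows.append(pd.DataFrame({
            "x_mm": x_obs * 1e3, "CF_Hz": cf, "f_Hz": fg,
            "ReT": tf.T.real, "ImT": tf.T.imag, "absT": np.abs(tf.T),
            "converged": tf.converged.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def _metrics_table(model: CochlearModel, exp: dict) -> pd.DataFrame:
    rows = []
    for x_obs in _site_grid(model, exp):
        cf = model.cf_at_site(x_obs)
        fg = np.geomspace(cf / 16.0, 4.0 * cf, int(exp["n_freq"]))
        tf = response.gain_function(model, x_obs, fg)
        cr = response.click_response(model, x_obs, n_band=int(exp["n_band"]),
                                     n_fft=int(exp["n_fft"]))
        rows.append({
            "x_mm": x_obs * 1e3,
            "CF_Hz": cf,
            "f_peak_Hz": float(fg[np.argmax(np.abs(tf.T))]),
            "Q_erb": response.q_erb(tf),
            "glide_slope": response.glide_slope(cr),
            "tau_wf_periods": response.wavefront_delay_analytic(
                model.profile, model.tono, x_obs),
        })
    return pd.DataFrame(rows)


def _experiment_gain_functions(model, exp, out, cfg_hash, box=False):
    if box:
        model = model.box()
    df = _gain_tables(model, exp)
    name = "gain_functions_box.csv" if box else "gain_functions.csv"
    _write_csv(df, out / name, cfg_hash)
    return [name]


def _experiment_tuning_metrics(model, exp, out, cfg_hash):
    df = _metrics_table(model, exp)
    _write_csv(df, out / "tuning_metrics.csv", cfg_hash)
    return ["tuning_metrics.csv"]


def _experiment_click_glides(model, exp, out, cfg_hash):
    files = []
    met = []
    for x_obs in _site_grid(model, exp):
        cf = model.cf_at_site(x_obs)
        cr = response.click_response(model, x_obs, n_band=int(exp["n_band"]),
                                     n_fft=int(exp["n_fft"]))
        keep = cr.envelope > 1e-4 * cr.envelope.max()
        n_keep = int(np.max(np.flatnonzero(keep))) + 1 if keep.any() else cr.w.size
        df = pd.DataFrame({
            "t_s": cr.t_grid[:n_keep], "w": cr.w[:n_keep],
            "envelope": cr.envelope[:n_keep], "f_inst_Hz": cr.f_inst[:n_keep],
        })
        fn = f"click_cf{cf:.0f}Hz.csv"
        _write_csv(df, out / fn, cfg_hash)
        files.append(fn)
        met.append({"x_mm": x_obs * 1e3, "CF_Hz": cf,
                    "glide_slope": response.glide_slope(cr)})
    _write_csv(pd.DataFrame(met), out / "glide_slopes.csv", cfg_hash)
    files.append("glide_slopes.csv")
    return files


def _experiment_sfoae(model, exp, out, cfg_hash):
    rng = np.random.default_rng(int(exp["seed"]))
    n_ears = int(exp["n_ears"])
    seeds = rng.integers(0, 2**31 - 1, size=n_ears)
    f_lo = max(exp["cf_min_kHz"] * 1e3, model.profile.cf[-1] * 1.5)
    f_grid = np.geomspace(f_lo, exp["cf_max_kHz"] * 1e3, int(exp["n_oae_freq"]))
    results, N, N_med = oae.ensemble_run(
        model, f_grid, n_ears=n_ears, amplitude=float(exp["roughness_amplitude"]),
        seeds=seeds)
    per_ear = pd.concat([
        pd.DataFrame({"ear": i, "seed": int(seeds[i]), "f_Hz": f_grid,
                      "ReR": results[i].R.real, "ImR": results[i].R.imag,
                      "N_periods": N[i]})
        for i in range(n_ears)
    ], ignore_index=True)
    _write_csv(per_ear, out / "sfoae_per_ear.csv", cfg_hash)
    summary = pd.DataFrame({
        "f_Hz": f_grid, "N_median": N_med,
        "N_iqr": np.subtract(*np.percentile(N, [75, 25], axis=0)),
    })
    _write_csv(summary, out / "sfoae_summary.csv", cfg_hash)

    met = _metrics_table(model, exp)
    q_trend = oae.interp_trend_loglog(f_grid, met["CF_Hz"].to_numpy()[::-1],
                                      met["Q_erb"].to_numpy()[::-1])
    n_trend = oae.median_trend(N_med)
    ratio = oae.tuning_ratio(f_grid, q_trend, n_trend)
    _write_csv(pd.DataFrame({"f_Hz": f_grid, "Q_erb_trend": q_trend,
                             "N_trend": n_trend, "ratio": ratio}),
               out / "tuning_ratio.csv", cfg_hash)
    return ["sfoae_per_ear.csv", "sfoae_summary.csv", "tuning_ratio.csv"]


def _experiment_scaling_report(model, exp, out, cfg_hash):
    prof, tono = model.profile, model.tono
    x = prof.x
    third = x <= prof.L / 3.0
    apex = x >= 0.8 * prof.L
    rows = []
    for name, arr in (("k", prof.k), ("S", prof.S), ("m_bar", prof.m_bar)):
        slope = np.polyfit(x[third], np.log(arr[third]), 1)[0]
        rows.append({"quantity": f"log-slope {name} (basal third)",
                     "value": slope * tono.l, "units": "1/l"})
    tau = response.wavefront_delay_analytic(prof, tono, x)
    cf = np.asarray(tono.cf(x))
    for region, m in (("base", third), ("apex", apex)):
        p, se = response.scaling_exponent(cf[m], tau[m])
        rows.append({"quantity": f"d ln tau_wf / d ln CF ({region})",
                     "value": p, "units": "-", })
    _write_csv(pd.DataFrame(rows), out / "scaling_report.csv", cfg_hash)
    return ["scaling_report.csv"]


EXPERIMENTS = {
    "gain-functions": _experiment_gain_functions,
    "gain-functions-box": lambda m, e, o, h: _experiment_gain_functions(m, e, o, h, box=True),
    "tuning-metrics": _experiment_tuning_metrics,
    "click-glides": _experiment_click_glides,
    "sfoae-ensemble": _experiment_sfoae,
    "scaling-report": _experiment_scaling_report,
}


def run_experiment(cfg: RunConfig, experiment: str, out_dir: str | Path | None = None,
                   seed: int | None = None) -> Path:
    """Run a named experiment; returns the output directory.

    ``seed`` overrides the config's experiment seed (SFOAE ensembles).
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    if seed is not None:
        cfg.experiment = {**cfg.experiment, "seed": int(seed)}
    out = Path(out_dir) if out_dir is not None else Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = cfg.build_model()
    cfg_hash = cfg.digest()
    t0 = time.time()
    log.info("running experiment %s (config %s)", experiment, cfg_hash)
    files = EXPERIMENTS[experiment](model, cfg.experiment, out, cfg_hash)
    manifest = {
        "experiment": experiment,
        "config": cfg.as_dict(),
        "config_hash": cfg_hash,
        "version": __version__,
        "files": files,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / f"manifest_{experiment}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("experiment %s finished in %.1f s", experiment, time.time() - t0)
    return out
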