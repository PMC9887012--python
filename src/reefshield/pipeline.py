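"""End-to-end orchestration: synth → reef → roughness → ensemble → extremes → bayes.

Each stage is independently invokable on the files written by the previous
stage (the CLI subcommands map one-to-one onto the ``stage_*`` functions),
and a single global seed is fanned out per stage through a counter-based
scheme so stage order never perturbs a stage's random stream. The ``desk``
profile shrinks replicate counts, percentile grids and run durations to
workstation scale; ``full`` matches the study-scale defaults (100
replicates x 10 years, 1000 percentile conditions, 10 states).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, climate, extremes, reef3d, roughness, synthgen
from ._utils import stage_seed

DESK_PROFILE = {
    "synth": {"n_years_climate": 10, "shapes_per_taxon": 3},
    "bathymetry": {"flat_length": 40.0, "sand_length": 30.0, "offshore_pad": 100.0},
    "reef": {
        "strip_length": 20.0,
        "strip_width": 0.5,
        "cell": 0.01,
        "n_replicates": 20,
    },
    "ensemble": {
        "n_percentiles": 30,
        "n_states": 2,
        "duration": 150.0,
    },
    "extremes": {"threshold_quantile": 0.5, "min_exceedances": 10, "T_grid": [5, 10, 20]},
    "bayes": {"chains": 4, "draws": 1500, "warmup": 500},
}

FULL_PROFILE = {
    "synth": {"n_years_climate": 30, "shapes_per_taxon": 10},
    "bathymetry": {},
    "reef": {
        "strip_length": 160.0,
        "strip_width": 1.0,
        "cell": 0.01,
        "n_replicates": 100,
    },
    "ensemble": {"n_percentiles": 1000, "n_states": 10, "duration": 600.0},
    "extremes": {
        "threshold_quantile": 0.9,
        "min_exceedances": 30,
        "T_grid": [10, 50, 100, 500],
    },
    "bayes": {"chains": 4, "draws": 5000, "warmup": 1000},
}


def load_config(path=None, profile: str = "desk", overrides: dict | None = None) -> dict:
    base = {k: dict(v) for k, v in (DESK_PROFILE if profile == "desk" else FULL_PROFILE).items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            base.setdefault(k, {}).update(v or {})
    for k, v in (overrides or {}).items():
        base.setdefault(k, {}).update(v or {})
    return base


def _log(out: Path, stage: str, **fields) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    with open(out / "pipeline.log", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


# ------------------------------------------------------------------ stages


def stage_synth(cfg: dict, seed: int, out: Path) -> dict:
    s = cfg.get("synth", {})
    survey = synthgen.generate_survey_table(seed=stage_seed(seed, "survey"))
    survey.to_csv(out / "survey_cover.csv", out / "survey_sizes.csv")
    bcfg = synthgen.BathymetryConfig(**cfg.get("bathymetry", {}))
    bathy = synthgen.generate_bathymetry(bcfg)
    bathy.to_csv(out / "bathymetry.csv", out / "sections.json")
    clim = synthgen.generate_wave_climate(
        n_years=s.get("n_years_climate", 30), seed=stage_seed(seed, "climate")
    )
    clim.to_csv(out / "climate.csv")
    bank = synthgen.generate_shape_bank(
        n_per_taxon=s.get("shapes_per_taxon", 10), seed=stage_seed(seed, "shapes")
    )
    synthgen.save_shape_bank(bank, out / "shapes")
    return {
        "survey": "survey_cover.csv",
        "bathymetry": "bathymetry.csv",
        "climate": "climate.csv",
        "shapes": "shapes/",
    }


def stage_reef(cfg: dict, seed: int, out: Path) -> dict:
    r = cfg.get("reef", {})
    survey = synthgen.SurveyTable.from_csv(
        out / "survey_cover.csv", out / "survey_sizes.csv"
    )
    bank = synthgen.load_shape_bank(out / "shapes")
    strip = reef3d.SubstrateStrip(
        length=r.get("strip_length", 160.0),
        width=r.get("strip_width", 1.0),
        cell=r.get("cell", 0.01),
    )
    sc = reef3d.complexity_ensemble(
        survey,
        strip,
        bank,
        n_replicates=r.get("n_replicates", 100),
        seed=stage_seed(seed, "reef"),
    )
    sc.to_csv(out / "sc.csv", index=False)
    reef3d.summarize_complexity(sc).to_csv(out / "sc_summary.csv", index=False)
    return {"sc": "sc.csv"}


def stage_roughness(cfg: dict, seed: int, out: Path) -> dict:
    sc = pd.read_csv(out / "sc.csv")
    bathy = synthgen.BathymetryProfile.from_csv(out / "bathymetry.csv")
    coeff = roughness.SectionCoefficients(**cfg.get("roughness", {}).get("alphas", {}))
    profiles = roughness.kn_profile_ensemble(sc, bathy, coeff)
    pd.concat([p.to_frame() for p in profiles]).to_csv(
        out / "kn_profiles.csv", index=False
    )
    reps = []
    for year in sorted(sc.year.unique()):
        med = roughness.median_kn_profile(
            [p for p in profiles if p.state == year], state=year
        )
        reps.append(med.to_frame())
    pd.concat(reps).to_csv(out / "state_kn.csv", index=False)
    return {"kn_profiles": "kn_profiles.csv", "state_kn": "state_kn.csv"}


def stage_conditions(cfg: dict, seed: int, out: Path) -> dict:
    clim = synthgen.WaveClimate.from_csv(out / "climate.csv")
    copula = climate.fit_hs_tp_copula(clim)
    conds = climate.build_conditions(
        clim, copula, n_percentiles=cfg.get("ensemble", {}).get("n_percentiles", 1000)
    )
    conds.to_csv(out / "conditions.csv", index=False)
    (out / "copula.json").write_text(
        json.dumps({"family": "gaussian", "rho": copula.rho, "tau": copula.tau})
    )
    return {"conditions": "conditions.csv", "copula": "copula.json"}


def _select_states(sc_summary: pd.DataFrame, n_states: int) -> list:
    """Representative states: all years at full scale; at desk scale the
    extremes of the complexity gradient (healthiest and most degraded)."""
    ordered = sc_summary.sort_values("median")
    if n_states >= len(ordered):
        return ordered.year.tolist()
    picks = [ordered.year.iloc[0], ordered.year.iloc[-1]]
    if n_states > 2:
        extra = ordered.year.iloc[1:-1].tolist()
        step = max(len(extra) // (n_states - 2), 1)
        picks = [ordered.year.iloc[0]] + extra[::step][: n_states - 2] + [
            ordered.year.iloc[-1]
        ]
    return picks


def stage_ensemble(cfg: dict, seed: int, out: Path) -> dict:
    e = cfg.get("ensemble", {})
    bathy = synthgen.BathymetryProfile.from_csv(out / "bathymetry.csv")
    conds = pd.read_csv(out / "conditions.csv")
    state_kn = pd.read_csv(out / "state_kn.csv")
    sc_summary = pd.read_csv(out / "sc_summary.csv")
    years = _select_states(sc_summary, e.get("n_states", 10))
    states = []
    for year in years:
        g = state_kn[state_kn.state == year]
        states.append(
            roughness.KnProfile(
                x=g.x.to_numpy(float), kn=g.kn.to_numpy(float), state=year
            )
        )
    sc_by_year = dict(zip(sc_summary.year, sc_summary["median"]))
    resume = None
    if (out / "ensemble.csv").exists():
        resume = pd.read_csv(out / "ensemble.csv")
    table = climate.run_ensemble(
        states,
        conds,
        bathy,
        seed=stage_seed(seed, "ensemble"),
        duration=e.get("duration", 600.0),
        state_sc=sc_by_year,
        resume=resume,
    )
    table.to_csv(out / "ensemble.csv", index=False)
    _log(out, "ensemble", rows=len(table), failed=int(table.failed.sum()))
    return {"ensemble": "ensemble.csv"}


def stage_extremes(cfg: dict, seed: int, out: Path) -> dict:
    x = cfg.get("extremes", {})
    table = pd.read_csv(out / "ensemble.csv")
    ok = table[~table.failed]
    curves, fit_errors = {}, {}
    for state, g in ok.groupby("state"):
        n = len(g)
        rates = np.full(n, extremes.WEEKS_PER_YEAR / n)
        try:
            curves[state] = extremes.fit_gpd(
                g.r2.to_numpy(float),
                rates,
                threshold_quantile=x.get("threshold_quantile", 0.9),
                min_exceedances=x.get("min_exceedances", 30),
                state=state,
            )
        except ValueError as exc:
            fit_errors[str(state)] = str(exc)
    if not curves:
        raise RuntimeError(f"no state could be fitted: {fit_errors}")
    sc_summary = pd.read_csv(out / "sc_summary.csv")
    order = sc_summary.set_index("year")["median"]
    states_sorted = sorted(curves, key=lambda s: order.get(s, 0.0))
    degraded, healthy = states_sorted[0], states_sorted[-1]
    T_grid = x.get("T_grid", [10, 50, 100, 500])
    rows, amps = [], {}
    for T in T_grid:
        for state, curve in curves.items():
            try:
                rows.append((state, T, float(extremes.return_level(curve, T))))
            except ValueError:
                rows.append((state, T, np.nan))
        try:
            amp = extremes.frequency_amplification(curves[healthy], curves[degraded], T)
            amps[str(T)] = {
                "factor": amp.factor,
                "level": amp.level,
                "lower_bound": amp.lower_bound,
            }
        except ValueError as exc:
            amps[str(T)] = {"error": str(exc)}
    pd.DataFrame(rows, columns=["state", "T", "r2"]).to_csv(
        out / "return_levels.csv", index=False
    )
    payload = {
        "healthy_state": str(healthy),
        "degraded_state": str(degraded),
        "curves": {
            str(s): {
                "threshold": c.threshold,
                "sigma": c.sigma,
                "xi": c.xi,
                "rate": c.rate,
                "n_exceedances": c.n_exceedances,
            }
            for s, c in curves.items()
        },
        "amplification": amps,
        "fit_errors": fit_errors,
    }
    (out / "return_curves.json").write_text(json.dumps(payload, indent=1))
    return {"return_curves": "return_curves.json", "return_levels": "return_levels.csv"}


def stage_bayes(cfg: dict, seed: int, out: Path) -> dict:
    b = cfg.get("bayes", {})
    table = pd.read_csv(out / "ensemble.csv")
    ok = table[~table.failed].dropna(subset=["r2", "hs_offshore", "sc"])
    if len(ok) < 50:
        (out / "posterior_summary.json").write_text(
            json.dumps({"skipped": f"only {len(ok)} usable rows (need >= 50)"})
        )
        return {"posterior": "posterior_summary.json"}
    scfg = bayes.SamplerConfig(
        chains=b.get("chains", 4), draws=b.get("draws", 5000), warmup=b.get("warmup", 1000)
    )
    post = bayes.fit_runup_model(ok, config=scfg, seed=stage_seed(seed, "bayes"))
    post.summary.to_csv(out / "posterior_summary.csv", index=False)
    (out / "posterior_summary.json").write_text(
        json.dumps(
            {
                "rhat": post.rhat,
                "ess": post.ess,
                "n_retained": post.n_retained,
                "accept_rate": post.accept_rate,
            },
            indent=1,
        )
    )
    sc_grid = np.linspace(ok.sc.min(), ok.sc.max(), 11)
    preds = bayes.predict_runup(post, np.arange(1.0, 7.0), sc_grid)
    bayes.residual_runup(preds).to_csv(out / "predictions.csv", index=False)
    return {"posterior": "posterior_summary.csv", "predictions": "predictions.csv"}


STAGES = {
    "synth": stage_synth,
    "reef": stage_reef,
    "roughness": stage_roughness,
    "conditions": stage_conditions,
    "ensemble": stage_ensemble,
    "extremes": stage_extremes,
    "bayes": stage_bayes,
}


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out="runs/default",
    profile: str = "desk",
    stages=None,
) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    cfg = config if isinstance(config, dict) else load_config(config, profile=profile)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "profile": profile,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "config": cfg,
        "stages": {},
    }
    for name in stages or STAGES:
        t0 = time.time()
        try:
            outputs = STAGES[name](cfg, seed, out)
        except Exception:
            _log(out, name, status="failed")
            raise
        manifest["stages"][name] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 2),
        }
        _log(out, name, status="ok", seconds=round(time.time() - t0, 2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
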