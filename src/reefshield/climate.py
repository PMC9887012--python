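"""Percentile wave conditions, Hs–Tp copula, and the simulation ensemble.

From the weekly offshore climate, significant-wave-height percentiles
(0.1 to 100 in steps of 0.1 at full scale — 1000 conditions) are each
linked to a peak period through a fitted one-parameter copula (Gaussian by
default; Tp is the conditional median given Hs). The ensemble runs one
wave-propagation simulation per (reef state, condition) pair; per-run
seeds derive from the condition only, so relabelling states permutes rows
without changing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.copula.api import GaussianCopula

from ._utils import empirical_quantile, stage_seed
from .boussiflow import ModelConfig, SimulationResult, run_simulation
from .roughness import KnProfile


# ----------------------------------------------------------------- copula


@dataclass
class HsTpCopula:
    """Fitted Gaussian copula + empirical marginals for (Hs, Tp)."""

    rho: float
    tau: float
    hs_samples: np.ndarray
    tp_samples: np.ndarray

    def conditional_tp(self, u_hs) -> np.ndarray:
        """Conditional median of Tp given the Hs marginal quantile u_hs."""
        u = np.clip(np.atleast_1d(np.asarray(u_hs, dtype=float)), 1e-6, 1.0 - 1e-6)
        z = stats.norm.ppf(u)
        u_tp = stats.norm.cdf(self.rho * z)
        return empirical_quantile(self.tp_samples, u_tp)


def fit_hs_tp_copula(climate) -> HsTpCopula:
    """Fit a Gaussian copula to the (Hs, Tp) dependence by ML on ranks.

    Marginals are empirical; the pseudo-observations rank/(n+1) feed the
    copula likelihood. Reports the dependence parameter rho and the
    implied Kendall tau = (2/pi) asin(rho).
    """
    hs = np.asarray(climate.hs, dtype=float)
    tp = np.asarray(climate.tp, dtype=float)
    if hs.size < 100:
        raise ValueError("need at least 100 (hs, tp) pairs")
    if hs.std() == 0 or tp.std() == 0:
        raise ValueError("degenerate (constant) series")
    n = hs.size
    u = np.column_stack(
        [stats.rankdata(hs) / (n + 1.0), stats.rankdata(tp) / (n + 1.0)]
    )
    rho = float(GaussianCopula().fit_corr_param(u))
    tau = float(2.0 / np.pi * np.arcsin(np.clip(rho, -1.0, 1.0)))
    return HsTpCopula(rho=rho, tau=tau, hs_samples=hs, tp_samples=tp)


# -------------------------------------------------------------- conditions


def build_conditions(
    climate,
    copula: HsTpCopula,
    n_percentiles: int = 1000,
    percentiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percentile wave conditions with copula-linked peak periods.

    At full scale the percentiles run 0.1, 0.2, ..., 100 (1000 values); Hs
    is the empirical quantile of the weekly series and Tp the conditional
    median of the copula at that quantile. ``n_percentiles`` scales the
    grid down for desk-scale runs (always ending at the sample maximum);
    an explicit ``percentiles`` array overrides the uniform grid.
    """
    hs = np.asarray(climate.hs, dtype=float)
    if percentiles is not None:
        pct = np.asarray(percentiles, dtype=float)
        n_percentiles = pct.size
    else:
        pct = np.arange(1, n_percentiles + 1) * (100.0 / n_percentiles)
    hs_q = empirical_quantile(hs, pct / 100.0)
    tp_q = copula.conditional_tp(pct / 100.0)
    return pd.DataFrame(
        {
            "condition": np.arange(n_percentiles),
            "percentile": pct,
            "hs": hs_q,
            "tp": tp_q,
        }
    )


# --------------------------------------------------------------- ensemble


def energy_absorption(result: SimulationResult) -> float:
    """Fraction of incoming wave energy absorbed across the reef.

    1 - (energy flux at the inner flat) / (incoming flux at the fore-reef
    toe), clipped to [0, 1].
    """
    if result.flux_x is None or result.incoming_flux is None:
        raise ValueError("flux diagnostics missing from the simulation result")
    if result.incoming_flux <= 0:
        return 0.0
    return float(
        np.clip(1.0 - result.transmitted_flux / result.incoming_flux, 0.0, 1.0)
    )


def run_ensemble(
    states: Sequence[KnProfile],
    conditions: pd.DataFrame,
    bathymetry,
    config: ModelConfig | None = None,
    seed: int = 0,
    duration: float = 300.0,
    solver: Callable[..., SimulationResult] = run_simulation,
    state_sc: dict | None = None,
    resume: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One wave run per (state, condition): the core probabilistic sweep.

    ``states`` holds one representative k_n profile per reef state (at full
    scale: the pointwise median of each state's 100 Monte Carlo replicates).
    Per-run seeds depend only on the global seed and the condition id, so
    every state sees identical wave forcing and rows are state-permutation
    invariant. Failed runs are logged as rows with ``failed=True``; with
    ``resume``, completed (state, condition) rows are skipped.
    """
    done = set()
    rows = []
    if resume is not None and len(resume):
        rows = resume.to_dict("records")
        done = {(r["state"], r["condition"]) for r in rows}
    for kn_prof in states:
        state = kn_prof.state
        sc_val = (state_sc or {}).get(state, np.nan)
        for cond in conditions.itertuples():
            if (state, cond.condition) in done:
                continue
            run_seed = stage_seed(seed, "ensemble-run", int(cond.condition))
            row = {
                "state": state,
                "condition": int(cond.condition),
                "percentile": float(cond.percentile),
                "hs_offshore": float(cond.hs),
                "tp": float(cond.tp),
                "sc": float(sc_val),
                "failed": False,
            }
            try:
                res = solver(
                    bathymetry,
                    kn_prof,
                    float(cond.hs),
                    float(cond.tp),
                    duration=duration,
                    seed=run_seed,
                    config=config,
                )
                row.update(
                    r2=res.r2,
                    hs_nearshore=res.hs_toe,
                    hs_inner=res.hs_inner,
                    dissipated=energy_absorption(res),
                    n_runup_maxima=res.n_runup_maxima,
                )
            except Exception as exc:  # individual failures don't kill the sweep
                row.update(
                    r2=np.nan,
                    hs_nearshore=np.nan,
                    hs_inner=np.nan,
                    dissipated=np.nan,
                    n_runup_maxima=0,
                    failed=True,
                )
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
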