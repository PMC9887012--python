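"""Nikuradse roughness: spectral inversion, SC conversion, transect profiles.

Three pieces tie structural complexity to the hydrodynamic model:

* spectral-attenuation inversion of paired pressure records — the sea-swell
  energy-flux loss between two sensors, attributed to bottom friction, is
  inverted for the wave energy-dissipation factor and converted to a
  Nikuradse roughness k_n through the Jonsson-type friction factor;
* the empirical power law k_n = 0.01 x SC^2.98 mapping rumple-index
  structural complexity to roughness on reef sections;
* assembly of continuous k_n(x) profiles along the transect, with
  per-section coefficients (alpha ratios relative to the fore reef) and a
  grain-size roughness k_n = 2.5 d50 on sand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from ._utils import GRAVITY, RHO_SEAWATER, dispersion_k, group_velocity
from .boussiflow import FW_MAX
from .synthgen import SEA_SWELL_BAND, BathymetryProfile

KN_FLOOR = 1e-4  # m; inversion lower bound (avoids log-domain blowup)


# ------------------------------------------------- pressure -> elevation


def depth_correct_pressure(
    pressure: np.ndarray,
    sensor_depth: float,
    burst_seconds: float,
    rate_hz: float = 4.0,
    sensor_elevation: float | None = None,
    cutoff_hz: float = SEA_SWELL_BAND[1],
    rho: float = RHO_SEAWATER,
) -> np.ndarray:
    """Surface elevation from a bottom-pressure record, burst by burst.

    Each ``burst_seconds`` block is FFT-transformed and multiplied by the
    linear-theory transfer function cosh(kh) / cosh(k (h + z)), with z the
    sensor elevation relative to still water (z = -h at the bed, the
    default) and k from the Airy dispersion relation; frequencies above
    ``cutoff_hz`` are zeroed (noise there would be amplified without
    bound). The burst mean (hydrostatic head) is removed.
    """
    if sensor_depth <= 0:
        raise ValueError("sensor depth must be positive")
    if cutoff_hz > rate_hz / 2.0:
        raise ValueError("cutoff frequency above Nyquist")
    n_burst = int(round(burst_seconds * rate_hz))
    p = np.asarray(pressure, dtype=float)
    if p.size % n_burst != 0:
        raise ValueError("burst length must divide the record length")
    z = -sensor_depth if sensor_elevation is None else float(sensor_elevation)
    h = sensor_depth
    f = np.fft.rfftfreq(n_burst, d=1.0 / rate_hz)
    omega = 2.0 * np.pi * f[1:]
    k = dispersion_k(omega, h)
    kh = np.clip(k * h, 0.0, 50.0)
    khz = np.clip(k * (h + z), 0.0, 50.0)
    gain = np.ones_like(f)
    gain[1:] = np.cosh(kh) / np.cosh(khz)
    gain[f > cutoff_hz] = 0.0

    out = np.empty_like(p)
    for b in range(p.size // n_burst):
        sl = slice(b * n_burst, (b + 1) * n_burst)
        head = p[sl] / (rho * GRAVITY)
        head = head - head.mean()
        Z = np.fft.rfft(head)
        out[sl] = np.fft.irfft(Z * gain, n=n_burst)
    return out


# ------------------------------------------------------- k_n inversion


@dataclass
class KnEstimate:
    kn: float
    burst: int
    pair: str = "A-B"
    section: str = "fore_reef"
    flagged: bool = False
    note: str = ""


def _band_flux_and_orbital(eta, depth, rate_hz):
    """Sea-swell energy flux [W/m] and orbital-velocity variance [m^2/s^2]."""
    f, S = periodogram(eta, fs=rate_hz, detrend="constant")
    band = (f >= SEA_SWELL_BAND[0]) & (f <= SEA_SWELL_BAND[1])
    fb, Sb = f[band], S[band]
    df = f[1] - f[0]
    omega = 2.0 * np.pi * fb
    k = dispersion_k(omega, depth)
    cg = group_velocity(omega, depth)
    flux = RHO_SEAWATER * GRAVITY * np.sum(Sb * cg) * df
    su = (omega / np.sinh(np.clip(k * depth, 1e-6, 50.0))) ** 2 * Sb
    return flux, float(np.sum(su) * df)


def estimate_kn_spectral(
    elev_a: np.ndarray,
    elev_b: np.ndarray,
    separation: float,
    depths: tuple[float, float],
    burst_seconds: float = 900.0,
    rate_hz: float = 4.0,
    tp: float | None = None,
    pair: str = "A-B",
    section: str = "fore_reef",
) -> list[KnEstimate]:
    """Per-burst k_n from the cross-shore decay of sea-swell energy flux.

    Sensor A is seaward of B. For each burst the flux difference (shoaling
    is accounted for by the per-frequency group velocity entering each
    flux) is attributed to friction, D = (F_A - F_B) / dx; the
    friction-dissipation law D = (2 / 3 pi) rho f_w u_b^3 is inverted for
    f_w, and the Jonsson relation f_w = exp[5.213 (kn/a0)^0.194 - 5.977]
    for k_n. Bursts with non-positive inferred dissipation, or with f_w
    outside the invertible range, yield flagged estimates at the bounds.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    h_a, h_b = depths
    n_burst = int(round(burst_seconds * rate_hz))
    ea = np.asarray(elev_a, dtype=float)
    eb = np.asarray(elev_b, dtype=float)
    if ea.size != eb.size or ea.size % n_burst != 0:
        raise ValueError("records must be equal length and whole bursts")
    out: list[KnEstimate] = []
    for b in range(ea.size // n_burst):
        sl = slice(b * n_burst, (b + 1) * n_burst)
        fa, su_a = _band_flux_and_orbital(ea[sl], h_a, rate_hz)
        fb_, su_b = _band_flux_and_orbital(eb[sl], h_b, rate_hz)
        d_rate = (fa - fb_) / separation
        u_b = np.sqrt(2.0 * 0.5 * (su_a + su_b))
        if tp is None:
            # representative angular frequency from the A spectrum peak
            f, S = periodogram(ea[sl], fs=rate_hz, detrend="constant")
            band = (f >= SEA_SWELL_BAND[0]) & (f <= SEA_SWELL_BAND[1])
            omega_r = 2.0 * np.pi * f[band][np.argmax(S[band])]
        else:
            omega_r = 2.0 * np.pi / tp
        a0 = u_b / omega_r
        if d_rate <= 0.0 or u_b <= 0.0:
            out.append(
                KnEstimate(
                    kn=KN_FLOOR, burst=b, pair=pair, section=section,
                    flagged=True, note="no dissipation",
                )
            )
            continue
        fw = d_rate / ((2.0 / (3.0 * np.pi)) * RHO_SEAWATER * u_b**3)
        log_arg = np.log(fw) + 5.977
        if fw >= FW_MAX:
            out.append(
                KnEstimate(
                    kn=float(a0), burst=b, pair=pair, section=section,
                    flagged=True, note="friction factor at cap",
                )
            )
            continue
        if log_arg <= 0.0:
            out.append(
                KnEstimate(
                    kn=KN_FLOOR, burst=b, pair=pair, section=section,
                    flagged=True, note="dissipation below smooth-bed level",
                )
            )
            continue
        kn = float(a0 * (log_arg / 5.213) ** (1.0 / 0.194))
        out.append(
            KnEstimate(
                kn=max(kn, KN_FLOOR), burst=b, pair=pair, section=section
            )
        )
    return out


def estimate_kn_from_records(records, tp: float | None = None) -> list[KnEstimate]:
    """Convenience wrapper running the full inversion on PressureRecords."""
    eta = {
        key: depth_correct_pressure(
            records.pressure[key],
            records.depths[key],
            records.burst_seconds,
            records.rate_hz,
        )
        for key in ("A", "B")
    }
    return estimate_kn_spectral(
        eta["A"],
        eta["B"],
        records.separation,
        (records.depths["A"], records.depths["B"]),
        burst_seconds=records.burst_seconds,
        rate_hz=records.rate_hz,
        tp=tp,
    )


# ----------------------------------------------------- SC -> k_n mapping


def sc_to_kn(sc):
    """Empirical reef power law k_n = 0.01 x SC^2.98 (k_n in m, SC >= 1)."""
    sc = np.asarray(sc, dtype=float)
    if np.any(sc < 1.0):
        raise ValueError("structural complexity must be >= 1")
    kn = 0.01 * sc**2.98
    return kn if kn.ndim else float(kn)


@dataclass
class SectionCoefficients:
    """Roughness ratios of crest and back reef relative to the fore reef."""

    alpha_reef_crest: float = 1.0
    alpha_back_reef: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_reef_crest <= 0 or self.alpha_back_reef <= 0:
            raise ValueError("section coefficients must be positive")


@dataclass
class KnProfile:
    """Continuous Nikuradse roughness k_n(x) tagged by reef state."""

    x: np.ndarray
    kn: np.ndarray
    state: int | str = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.kn) <= 0):
            raise ValueError("kn must be positive everywhere")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "kn": self.kn, "state": self.state, "replicate": self.replicate}
        )


def build_kn_profile(
    sc: float,
    bathymetry: BathymetryProfile,
    coefficients: SectionCoefficients | None = None,
    d50: float = 63e-6,
    state=0,
    replicate: int = 0,
) -> KnProfile:
    """k_n(x) on the bathymetry grid from one SC draw.

    Fore reef takes sc_to_kn(SC); crest and back reef scale it by their
    alpha coefficients; sand (and the beach face) takes the grain-size
    convention k_n = 2.5 d50.
    """
    if d50 <= 0:
        raise ValueError("d50 must be positive")
    coeff = coefficients or SectionCoefficients()
    kn_fore = sc_to_kn(sc)
    labels = np.asarray(bathymetry.section_labels)
    kn = np.full(labels.shape, 2.5 * d50)
    mapping = {
        "fore_reef": kn_fore,
        "reef_crest": kn_fore * coeff.alpha_reef_crest,
        "reef_flat": kn_fore * coeff.alpha_back_reef,
        "back_reef": kn_fore * coeff.alpha_back_reef,
    }
    reef_labels = set(labels) - {"sand", "beach"}
    missing = reef_labels - set(mapping)
    if missing:
        raise ValueError(f"no section coefficient for sections {sorted(missing)}")
    for lab, value in mapping.items():
        kn[labels == lab] = value
    return KnProfile(
        x=np.asarray(bathymetry.x, dtype=float), kn=kn, state=state, replicate=replicate
    )


def kn_profile_ensemble(
    sc_table: pd.DataFrame,
    bathymetry: BathymetryProfile,
    coefficients: SectionCoefficients | None = None,
    d50: float = 63e-6,
) -> list[KnProfile]:
    """One k_n profile per (year, replicate) SC draw (Monte Carlo)."""
    return [
        build_kn_profile(
            row.sc, bathymetry, coefficients, d50, state=row.year, replicate=row.replicate
        )
        for row in sc_table.itertuples()
    ]


def median_kn_profile(profiles: list[KnProfile], state=None) -> KnProfile:
    """Pointwise median profile — the representative profile of a state."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    kn = np.median(np.stack([p.kn for p in profiles]), axis=0)
    return KnProfile(
        x=profiles[0].x, kn=kn, state=state if state is not None else profiles[0].state,
        replicate=-1,
    )
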