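"""Shared helpers: seeding, dispersion relation, spectra."""

from __future__ import annotations

import zlib

import numpy as np

GRAVITY = 9.81
RHO_SEAWATER = 1025.0


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed.

    Counter-based: the stream depends only on (seed, stage name, index), not
    on how many other stages ran before, so pipeline stage order never
    perturbs a stage's random stream.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(index)]))


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """A plain integer sub-seed (< 2**31) on the same counter-based scheme."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), tag, int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def dispersion_k(omega, depth, g: float = GRAVITY):
    """Linear (Airy) wavenumber from angular frequency and depth.

    Solves omega^2 = g k tanh(k h) by Newton iteration from the Eckart
    initial guess; vectorised over omega and/or depth.
    """
    omega = np.asarray(omega, dtype=float)
    h = np.asarray(depth, dtype=float)
    if np.any(h <= 0):
        raise ValueError("depth must be positive")
    o2h = omega**2 * h / g
    # Eckart (1952) explicit approximation as starting point
    k = omega**2 / (g * np.sqrt(np.tanh(np.maximum(o2h, 1e-12))))
    k = np.where(o2h > 0, k, 0.0)
    for _ in range(30):
        kh = k * h
        t = np.tanh(kh)
        f = g * k * t - omega**2
        df = g * t + g * kh * (1.0 - t**2)
        step = np.where(df > 0, f / np.maximum(df, 1e-300), 0.0)
        k = np.maximum(k - step, 1e-12)
    return k


def group_velocity(omega, depth, g: float = GRAVITY):
    """Linear group velocity Cg at angular frequency omega and depth h."""
    k = dispersion_k(omega, depth, g)
    kh = k * depth
    c = omega / k
    n = 0.5 * (1.0 + 2.0 * kh / np.sinh(2.0 * np.clip(kh, 1e-12, 50.0)))
    return n * c


def jonswap_spectrum(f, hs: float, tp: float, gamma: float = 3.3):
    """JONSWAP elevation variance density S(f) [m^2/Hz], scaled to Hs = 4 sqrt(m0).

    The shape is the standard peak-enhanced Pierson–Moskowitz form; the
    absolute level is rescaled so that the discrete integral of S over ``f``
    reproduces the requested significant wave height.
    """
    f = np.asarray(f, dtype=float)
    fp = 1.0 / tp
    sigma = np.where(f <= fp, 0.07, 0.09)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.exp(-((f - fp) ** 2) / (2.0 * sigma**2 * fp**2))
        shape = f**-5 * np.exp(-1.25 * (fp / f) ** 4) * gamma**r
    shape = np.where(f > 0, shape, 0.0)
    m0_target = (hs / 4.0) ** 2
    m0_raw = np.trapezoid(shape, f)
    if m0_raw <= 0:
        raise ValueError("degenerate frequency grid for JONSWAP spectrum")
    return shape * (m0_target / m0_raw)


def empirical_quantile(samples: np.ndarray, q) -> np.ndarray:
    """Empirical quantile with the linear-interpolation convention."""
    return np.quantile(np.asarray(samples, dtype=float), q, method="linear")
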