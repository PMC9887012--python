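"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage (reef construction, roughness inversion, wave
propagation, ensemble statistics) is testable without field downloads:
this module emulates

* per-year, per-taxon coral survey tables over a disturbance–recovery cycle
  (living cover collapsing from ~50% to ~3% and recovering with
  *Pocillopora* dominance),
* a bank of parametric coral colony meshes (tabular *Acropora*,
  corrugated-dome *Pocillopora*, hemispheroidal *Porites*) standing in for
  photogrammetry models,
* a cross-shore bathymetry profile at 1 m resolution (20 m-deep fore reef →
  crest → reef flat → sand → beach),
* a multi-decadal weekly (Hs, Tp) offshore wave climate with copula-linked
  dependence, and
* paired bottom-pressure records whose spectral energy flux decays between
  sensors exactly per the friction-dissipation law inverted by
  :func:`reefshield.roughness.estimate_kn_spectral`.

The mesh families are parametric proxies, not photogrammetry: absolute
rumple values depend on this choice; the per-taxon rumple ordering
(Pocillopora > Acropora > Porites at comparable dimensions) is a documented
default, not a law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from ._utils import (
    GRAVITY,
    RHO_SEAWATER,
    dispersion_k,
    group_velocity,
    jonswap_spectrum,
)
from .boussiflow import friction_factor

TAXA = ("Acropora", "Pocillopora", "Porites")

# ----------------------------------------------------------------- surveys


@dataclass
class SurveyTable:
    """Per-year, per-taxon planar cover and colony size samples.

    ``table`` has columns (year, taxon, cover) with cover as a fraction of
    the substrate strip in [0, 1]; ``sizes[(year, taxon)]`` is an (n, 3)
    array of (width, length, height) in metres.
    """

    table: pd.DataFrame
    sizes: dict = field(default_factory=dict)

    def total_cover(self, year: int) -> float:
        sub = self.table[self.table.year == year]
        return float(sub.cover.sum())

    @property
    def years(self) -> list[int]:
        return sorted(self.table.year.unique().tolist())

    def to_csv(self, cover_path, sizes_path) -> None:
        self.table.to_csv(cover_path, index=False)
        rows = []
        for (year, taxon), arr in self.sizes.items():
            for w, l, h in arr:
                rows.append((year, taxon, w, l, h))
        pd.DataFrame(
            rows, columns=["year", "taxon", "width", "length", "height"]
        ).to_csv(sizes_path, index=False)

    @classmethod
    def from_csv(cls, cover_path, sizes_path) -> "SurveyTable":
        table = pd.read_csv(cover_path)
        sz = pd.read_csv(sizes_path)
        sizes = {}
        for (year, taxon), g in sz.groupby(["year", "taxon"]):
            sizes[(int(year), str(taxon))] = g[["width", "length", "height"]].to_numpy()
        return cls(table=table, sizes=sizes)


#: Disturbance–recovery trajectory emulating a 10-survey cycle: healthy
#: (total cover 0.50), collapse to 0.03 after a predator outbreak + cyclone
#: analogue, then recovery dominated by Pocillopora. Values are
#: (total cover, taxon mix fractions in TAXA order).
DEFAULT_TRAJECTORY: dict[int, tuple[float, tuple[float, float, float]]] = {
    2005: (0.50, (0.45, 0.30, 0.25)),
    2008: (0.35, (0.40, 0.32, 0.28)),
    2009: (0.15, (0.30, 0.38, 0.32)),
    2010: (0.08, (0.22, 0.42, 0.36)),
    2011: (0.03, (0.15, 0.45, 0.40)),
    2012: (0.06, (0.12, 0.55, 0.33)),
    2013: (0.12, (0.10, 0.62, 0.28)),
    2014: (0.22, (0.09, 0.66, 0.25)),
    2015: (0.33, (0.08, 0.70, 0.22)),
    2016: (0.45, (0.08, 0.72, 0.20)),
}

#: Lognormal colony-size parameters per taxon: (median width m, gsd,
#: length/width ratio, height/width ratio). Heights of tabular Acropora are
#: low relative to width; Pocillopora heads are tall for their footprint.
SIZE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "Acropora": (0.45, 1.35, 1.0, 0.40),
    "Pocillopora": (0.28, 1.30, 1.0, 0.75),
    "Porites": (0.35, 1.40, 1.0, 0.50),
}


def generate_survey_table(
    years: Sequence[int] | None = None,
    disturbance_trajectory: Mapping[int, tuple] | None = None,
    seed: int = 0,
    n_size_samples: int = 40,
    size_params: Mapping[str, tuple] | None = None,
) -> SurveyTable:
    """Synthesize a disturbance–recovery survey table.

    ``disturbance_trajectory`` maps year -> (total cover, taxon mix); the
    default is the 10-year healthy → collapsed → recovered cycle. Sizes are
    drawn from per-taxon lognormal width distributions with fixed
    length/width and height/width ratios (mild lognormal jitter).
    """
    traj = dict(disturbance_trajectory or DEFAULT_TRAJECTORY)
    if years is not None:
        traj = {y: traj[y] for y in years}
    params = dict(size_params or SIZE_PARAMS)
    rng = np.random.default_rng(seed)
    rows, sizes = [], {}
    for year in sorted(traj):
        total, mix = traj[year]
        if not 0.0 <= total <= 1.0:
            raise ValueError(f"total cover {total} outside [0, 1] for year {year}")
        mix = np.asarray(mix, dtype=float)
        if np.any(mix < 0) or mix.sum() <= 0 and total > 0:
            raise ValueError("invalid taxon mix")
        if total > 0:
            mix = mix / mix.sum()
        for taxon, frac in zip(TAXA, mix):
            cover = float(total * frac)
            rows.append((year, taxon, cover))
            if cover > 0:
                med_w, gsd, lw, hw = params[taxon]
                w = med_w * np.exp(np.log(gsd) * rng.standard_normal(n_size_samples))
                l = w * lw * np.exp(0.08 * rng.standard_normal(n_size_samples))
                h = w * hw * np.exp(0.10 * rng.standard_normal(n_size_samples))
                sizes[(year, taxon)] = np.column_stack([w, l, h])
            else:
                sizes[(year, taxon)] = np.empty((0, 3))
    table = pd.DataFrame(rows, columns=["year", "taxon", "cover"])
    # summed cover per year must stay a valid fraction
    for year, g in table.groupby("year"):
        if g.cover.sum() > 1.0 + 1e-9:
            raise ValueError(f"summed cover exceeds 1 in year {year}")
    return SurveyTable(table=table, sizes=sizes)


# ------------------------------------------------------------ coral shapes


def _polar_graph_mesh(radial_profile, n_psi: int = 48, n_theta: int = 64):
    """Triangulated graph surface over the unit disc from z = f(psi, theta).

    The radial coordinate is r = sin(psi) with psi uniform in (0, pi/2]
    (equal-angle spacing keeps facets well shaped where hemispheroids turn
    vertical at the rim). Returns (vertices, faces) with an apex vertex.
    """
    psi = np.linspace(0.0, np.pi / 2.0, n_psi + 1)[1:]
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    P, T = np.meshgrid(psi, theta, indexing="ij")
    r = np.sin(P)
    z = radial_profile(P, T)
    x = r * np.cos(T)
    y = r * np.sin(T)
    apex_z = float(radial_profile(np.array([[0.0]]), np.array([[0.0]]))[0, 0])
    verts = np.column_stack(
        [
            np.concatenate([[0.0], x.ravel()]),
            np.concatenate([[0.0], y.ravel()]),
            np.concatenate([[apex_z], z.ravel()]),
        ]
    )
    faces = []
    idx = lambda i, j: 1 + i * n_theta + (j % n_theta)  # noqa: E731
    for j in range(n_theta):  # apex fan
        faces.append((0, idx(0, j), idx(0, j + 1)))
    for i in range(n_psi - 1):
        for j in range(n_theta):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    return verts, np.asarray(faces, dtype=np.int64)


def generate_coral_shape(
    taxon: str,
    width: float,
    length: float,
    height: float,
    seed: int = 0,
    n_psi: int = 48,
    n_theta: int = 64,
) -> trimesh.Trimesh:
    """Parametric colony mesh with an exact (width, length, height) bbox.

    Shape families: tabular plateau (*Acropora*), corrugated dome standing
    in for branching colonies (*Pocillopora*), smooth hemispheroid
    (*Porites*). A full hemisphere proxy (Porites with width = length = 2h)
    has surface/footprint ratio 2 by construction.
    """
    if min(width, length, height) <= 0:
        raise ValueError("colony dimensions must be positive")
    if taxon not in TAXA:
        raise ValueError(f"unknown taxon {taxon!r}; expected one of {TAXA}")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    if taxon == "Porites":
        # massive lobed colony: smooth hemispheroid with low bumps
        def profile(P, T):
            r = np.sin(P)
            bumps = 0.06 * np.sin(6.0 * T + phase) * np.sin(3.5 * np.pi * r)
            return np.cos(P) + bumps * r

    elif taxon == "Acropora":
        # tabular colony: steep-rimmed plate with ridged (anastomosing) top
        p = 8.0

        def profile(P, T):
            r = np.sin(P)
            ridges = 0.18 * (
                np.sin(10.0 * T + phase) * np.sin(4.0 * np.pi * r)
                + 0.6 * np.cos(2.5 * np.pi * r + phase)
            )
            return (1.0 - r**p) * (1.0 + ridges)

    else:  # Pocillopora: corrugated dome proxy for dense branching heads
        n_lobes = 12

        def profile(P, T):
            r = np.sin(P)
            dome = np.cos(P)
            corr = (
                0.45 * np.sin(n_lobes * T + phase) * np.sin(np.pi * r) ** 2
                + 0.35 * np.sin(5.0 * np.pi * r + 0.7 * phase) * r
            )
            return dome + corr * (1.0 - 0.25 * r)

    verts, faces = _polar_graph_mesh(profile, n_psi=n_psi, n_theta=n_theta)
    # normalise z to [0, 1] then scale each axis to the exact bbox
    z = verts[:, 2]
    z0, z1 = z.min(), z.max()
    verts[:, 2] = (z - z0) / max(z1 - z0, 1e-12)
    verts[:, 0] *= width / 2.0
    verts[:, 1] *= length / 2.0
    verts[:, 2] *= height
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.metadata["taxon"] = taxon
    return mesh


def generate_shape_bank(
    n_per_taxon: int = 10, seed: int = 0
) -> dict[str, list[trimesh.Trimesh]]:
    """Bank of unit-bbox colony meshes, ``n_per_taxon`` variants per taxon."""
    bank: dict[str, list[trimesh.Trimesh]] = {}
    for t, taxon in enumerate(TAXA):
        bank[taxon] = [
            generate_coral_shape(taxon, 1.0, 1.0, 1.0, seed=seed * 1000 + t * 100 + i)
            for i in range(n_per_taxon)
        ]
    return bank


def save_shape_bank(bank: Mapping[str, list], directory) -> pd.DataFrame:
    """Write meshes as OBJ plus a manifest CSV (taxon, file, bbox)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for taxon, meshes in bank.items():
        for i, mesh in enumerate(meshes):
            fname = f"{taxon.lower()}_{i:02d}.obj"
            mesh.export(directory / fname)
            ext = mesh.bounds[1] - mesh.bounds[0]
            rows.append((taxon, fname, *ext))
    manifest = pd.DataFrame(
        rows, columns=["taxon", "file", "bbox_w", "bbox_l", "bbox_h"]
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_shape_bank(directory) -> dict[str, list[trimesh.Trimesh]]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    bank: dict[str, list[trimesh.Trimesh]] = {}
    for _, row in manifest.iterrows():
        mesh = trimesh.load(directory / row.file, process=False)
        bank.setdefault(row.taxon, []).append(mesh)
    return bank


# ------------------------------------------------------------- bathymetry


@dataclass
class BathymetryConfig:
    """Piecewise cross-shore profile parameters (metres).

    The transect runs offshore pad (constant depth, for wave generation) →
    fore-reef slope → reef crest → reef flat → sand → plane beach.
    """

    offshore_depth: float = 20.0
    offshore_pad: float = 80.0
    fore_reef_length: float = 160.0
    crest_depth: float = 0.5
    crest_length: float = 10.0
    flat_depth: float = 1.5
    flat_length: float = 60.0
    sand_length: float = 40.0
    beach_slope: float = 0.10
    beach_length: float = 140.0  # beach face extends above extreme run-up
    dx: float = 1.0


@dataclass
class BathymetryProfile:
    """x (m, increasing), bed elevation z (m, negative below SWL), labels."""

    x: np.ndarray
    z: np.ndarray
    section_labels: np.ndarray

    def section(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.section_labels == label)

    def to_csv(self, path, boundaries_path=None) -> None:
        pd.DataFrame({"x": self.x, "z": self.z, "section": self.section_labels}).to_csv(
            path, index=False
        )
        if boundaries_path is not None:
            import json

            bounds = {}
            for lab in np.unique(self.section_labels):
                idx = self.section(str(lab))
                bounds[str(lab)] = [float(self.x[idx[0]]), float(self.x[idx[-1]])]
            Path(boundaries_path).write_text(json.dumps(bounds, indent=1))

    @classmethod
    def from_csv(cls, path) -> "BathymetryProfile":
        df = pd.read_csv(path)
        return cls(
            x=df.x.to_numpy(float),
            z=df.z.to_numpy(float),
            section_labels=df.section.to_numpy(str),
        )


def generate_bathymetry(config: BathymetryConfig | None = None) -> BathymetryProfile:
    """Piecewise-linear reef transect from deep fore reef to subaerial beach."""
    c = config or BathymetryConfig()
    for name in (
        "offshore_depth",
        "fore_reef_length",
        "crest_length",
        "flat_length",
        "sand_length",
        "beach_length",
        "beach_slope",
        "dx",
    ):
        if getattr(c, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if c.offshore_depth < c.crest_depth:
        raise ValueError("non-monotone segments: crest must be shallower than offshore")
    if c.crest_depth > c.flat_depth:
        raise ValueError("non-monotone segments: crest must be shallower than the flat")

    segs = [
        ("fore_reef", c.offshore_pad, -c.offshore_depth, -c.offshore_depth),
        ("fore_reef", c.fore_reef_length, -c.offshore_depth, -c.crest_depth),
        ("reef_crest", c.crest_length, -c.crest_depth, -c.crest_depth),
        ("reef_flat", c.flat_length, -c.flat_depth, -c.flat_depth),
        ("sand", c.sand_length, -c.flat_depth, -c.flat_depth),
        (
            "beach",
            c.beach_length,
            -c.flat_depth,
            -c.flat_depth + c.beach_slope * c.beach_length,
        ),
    ]
    xs, zs, labels = [0.0], [segs[0][2]], ["fore_reef"]
    x0 = 0.0
    for label, length, z_from, z_to in segs:
        n = max(int(round(length / c.dx)), 1)
        xi = x0 + np.arange(1, n + 1) * c.dx
        # piecewise-linear from the previous node's elevation to z_to
        zi = np.linspace(zs[-1], z_to, n + 1)[1:]
        xs.extend(xi)
        zs.extend(zi)
        labels.extend([label] * n)
        x0 = xi[-1]
    return BathymetryProfile(
        x=np.asarray(xs), z=np.asarray(zs), section_labels=np.asarray(labels)
    )


# ------------------------------------------------------------ wave climate


@dataclass
class WaveClimate:
    """Weekly offshore (Hs, Tp) series."""

    table: pd.DataFrame  # columns week_index, hs, tp

    @property
    def hs(self) -> np.ndarray:
        return self.table.hs.to_numpy(float)

    @property
    def tp(self) -> np.ndarray:
        return self.table.tp.to_numpy(float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaveClimate":
        return cls(table=pd.read_csv(path))


@dataclass
class ClimateConfig:
    """Marginals + Gaussian-copula dependence for the weekly wave climate.

    Hs ~ Weibull with mode near 1.5 m (shape 1.8); Tp ~ lognormal with
    median 12 s. rho is the Gaussian-copula correlation (Kendall's
    tau = (2/pi) asin(rho)).
    """

    hs_weibull_shape: float = 1.8
    hs_mode: float = 1.5
    tp_median: float = 12.0
    tp_log_sd: float = 0.22
    rho: float = 0.5


def _hs_marginal(cfg: ClimateConfig):
    c = cfg.hs_weibull_shape
    scale = cfg.hs_mode / ((c - 1.0) / c) ** (1.0 / c)
    return stats.weibull_min(c, scale=scale)


def _tp_marginal(cfg: ClimateConfig):
    return stats.lognorm(cfg.tp_log_sd, scale=cfg.tp_median)


def generate_wave_climate(
    n_years: int = 30,
    config: ClimateConfig | None = None,
    seed: int = 0,
    weeks_per_year: int = 52,
) -> WaveClimate:
    """Weekly (Hs, Tp) with a Gaussian copula linking the two marginals."""
    cfg = config or ClimateConfig()
    if abs(cfg.rho) >= 1.0:
        raise ValueError("Gaussian-copula correlation must satisfy |rho| < 1")
    rng = np.random.default_rng(seed)
    n = weeks_per_year * n_years
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, cfg.rho], [cfg.rho, 1.0]], size=n
    )
    u = stats.norm.cdf(z)
    hs = _hs_marginal(cfg).ppf(u[:, 0])
    tp = _tp_marginal(cfg).ppf(u[:, 1])
    table = pd.DataFrame({"week_index": np.arange(n), "hs": hs, "tp": tp})
    return WaveClimate(table=table)


# ------------------------------------------- paired pressure records (4 Hz)

SEA_SWELL_BAND = (0.04, 0.4)  # Hz


@dataclass
class PressureRecords:
    """Paired bottom-pressure series for the roughness closed loop.

    ``pressure`` maps sensor id ('A' seaward, 'B' shoreward) to dynamic +
    hydrostatic pressure in Pa at ``rate_hz``; sensors sit on the bed.
    """

    time: np.ndarray
    pressure: dict
    depths: dict
    separation: float
    rate_hz: float
    burst_seconds: float
    kn_true: float


def friction_dissipation_rate(u_b: float, f_w: float, rho: float = RHO_SEAWATER) -> float:
    """Wave-averaged frictional dissipation per unit bed area [W/m^2].

    Monochromatic-equivalent law D = (2 / 3 pi) rho f_w u_b^3 with u_b the
    representative near-bed orbital velocity amplitude (sqrt(2) x its rms).
    The roughness inversion in :mod:`reefshield.roughness` inverts exactly
    this law, so forward generation and inversion are mutually consistent.
    """
    return (2.0 / (3.0 * np.pi)) * rho * f_w * u_b**3


def _band_mask(f: np.ndarray) -> np.ndarray:
    return (f >= SEA_SWELL_BAND[0]) & (f <= SEA_SWELL_BAND[1])


def generate_pressure_records(
    wave: tuple[float, float] = (1.5, 10.0),
    sensor_depths: Sequence[float] = (3.0, 3.0),
    kn_true: float = 0.42,
    burst_seconds: float = 900.0,
    rate_hz: float = 4.0,
    n_bursts: int = 8,
    separation: float = 40.0,
    snr: float = 20.0,
    seed: int = 0,
) -> PressureRecords:
    """Synthesize paired bed-pressure bursts with friction-decayed flux.

    The seaward sensor A sees a JONSWAP sea of (Hs, Tp) = ``wave``; the
    spectrum at shoreward sensor B is A's, shoaling-corrected and reduced by
    the frictional flux loss over ``separation`` computed from ``kn_true``
    via the wave friction factor (Jonsson form). Additive Gaussian noise at
    signal-to-noise ratio ``snr`` (std ratio) emulates sensor noise.
    """
    if len(sensor_depths) < 2:
        raise ValueError("need at least two sensors")
    if any(d <= 0 for d in sensor_depths):
        raise ValueError("sensor depth must be positive")
    if kn_true <= 0:
        raise ValueError("kn_true must be positive")
    hs, tp = wave
    h_a, h_b = float(sensor_depths[0]), float(sensor_depths[1])
    rng = np.random.default_rng(seed)

    n_samp = int(round(burst_seconds * rate_hz))
    f = np.fft.rfftfreq(n_samp, d=1.0 / rate_hz)
    band = _band_mask(f)
    fb = f[band]
    df = f[1] - f[0]
    e_a = np.zeros_like(f)
    e_a[band] = jonswap_spectrum(fb, hs, tp)

    omega = 2.0 * np.pi * fb
    k_a = dispersion_k(omega, h_a)
    k_b = dispersion_k(omega, h_b)
    cg_a = group_velocity(omega, h_a)
    cg_b = group_velocity(omega, h_b)
    omega_p = 2.0 * np.pi / tp

    flux_a = RHO_SEAWATER * GRAVITY * np.sum(e_a[band] * cg_a) * df
    # fixed point: dissipation uses the A/B-average orbital velocity, and
    # the B spectrum depends on the dissipation
    ratio = 1.0
    for _ in range(50):
        e_b_band = e_a[band] * (cg_a / cg_b) * ratio
        su_a = (omega / np.sinh(np.clip(k_a * h_a, 1e-6, 50.0))) ** 2 * e_a[band]
        su_b = (omega / np.sinh(np.clip(k_b * h_b, 1e-6, 50.0))) ** 2 * e_b_band
        u_b = np.sqrt(2.0 * 0.5 * (np.sum(su_a) + np.sum(su_b)) * df)
        a0 = u_b / omega_p
        fw = friction_factor(kn_true, a0)
        d_rate = friction_dissipation_rate(u_b, fw)
        new_ratio = max(1.0 - d_rate * separation / max(flux_a, 1e-12), 1e-3)
        if abs(new_ratio - ratio) < 1e-12:
            ratio = new_ratio
            break
        ratio = new_ratio
    e_b = np.zeros_like(f)
    e_b[band] = e_a[band] * (cg_a / cg_b) * ratio

    t = np.arange(n_bursts * n_samp) / rate_hz
    p = {key: np.empty(n_bursts * n_samp) for key in ("A", "B")}
    for bidx in range(n_bursts):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=band.sum())
        sl = slice(bidx * n_samp, (bidx + 1) * n_samp)
        tt = t[sl] - t[sl][0]
        for key, e, h, k in (("A", e_a, h_a, k_a), ("B", e_b, h_b, k_b)):
            amps = np.sqrt(2.0 * e[band] * df)
            attn = 1.0 / np.cosh(np.clip(k * h, 0.0, 50.0))
            lag = k * separation if key == "B" else 0.0
            eta_bed = (amps * attn)[None, :] * np.cos(
                omega[None, :] * tt[:, None] - lag - phases[None, :]
            )
            sig = RHO_SEAWATER * GRAVITY * eta_bed.sum(axis=1)
            noise = rng.standard_normal(n_samp) * (sig.std() / snr if snr > 0 else 0.0)
            p[key][sl] = RHO_SEAWATER * GRAVITY * h + sig + noise
    return PressureRecords(
        time=t,
        pressure=p,
        depths={"A": h_a, "B": h_b},
        separation=separation,
        rate_hz=rate_hz,
        burst_seconds=burst_seconds,
        kn_true=kn_true,
    )
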