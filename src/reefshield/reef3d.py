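"""Coral-populated reef cross-sections and structural complexity (rumple).

A substrate strip (default 160 m along-slope by 1 m across) is populated
colony by colony: for each taxon a mesh is drawn from the shape bank,
resized from the survey size distribution, randomly rotated in
[-pi/2, pi/2] and placed uniformly at random, until the summed planar
colony area first reaches that taxon's target cover. The composite surface
is a rasterized height field (pointwise max of substrate and colony
surfaces, default 1 cm cells), and structural complexity is its rumple
index: 3D surface area divided by planar projected area.

Colonies may overlap; the stopping rule counts each colony's own planar
footprint (the summed-area semantics of survey cover), so the union of
footprints can be slightly below the nominal cover at high densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .synthgen import SurveyTable

__all__ = [
    "SubstrateStrip",
    "CoralColony",
    "ReefCrossSection",
    "rumple_index",
    "populate_cross_section",
    "complexity_ensemble",
]


@dataclass
class SubstrateStrip:
    """Planar substrate strip geometry for reef population.

    The strip is treated as locally planar (unrolled along-slope); optional
    low-amplitude smoothed noise emulates bare-substrate microtopography.
    """

    length: float = 160.0
    width: float = 1.0
    cell: float = 0.01
    relief_amplitude: float = 0.0
    relief_scale: float = 0.5  # correlation length of the microrelief (m)
    seed: int = 0

    def base_height(self) -> np.ndarray:
        nx = int(round(self.length / self.cell))
        ny = int(round(self.width / self.cell))
        z = np.zeros((nx + 1, ny + 1))
        if self.relief_amplitude > 0:
            from scipy.ndimage import gaussian_filter

            rng = np.random.default_rng(self.seed)
            noise = rng.standard_normal(z.shape)
            sig = max(self.relief_scale / self.cell, 1.0)
            sm = gaussian_filter(noise, sig, mode="wrap")
            sm /= max(sm.std(), 1e-12)
            z = self.relief_amplitude * sm
        return z


@dataclass
class CoralColony:
    taxon: str
    position: tuple[float, float]  # centre (x, y) on the strip (m)
    dimensions: tuple[float, float, float]  # width, length, height (m)
    rotation: float  # rad, in [-pi/2, pi/2]
    mesh_index: int
    planar_area: float  # rasterized footprint area (m^2)


@dataclass
class ReefCrossSection:
    strip: SubstrateStrip
    colonies: list[CoralColony]
    height: np.ndarray  # composite surface, node-registered (nx+1, ny+1)
    cover_achieved: dict  # taxon -> summed planar-area fraction

    @property
    def cell(self) -> float:
        return self.strip.cell


# ----------------------------------------------------------------- rumple


def _heightfield_area(z: np.ndarray, cell: float) -> float:
    """3D surface area of a node-registered height field (2 triangles/cell)."""
    dzx = np.diff(z, axis=0)[:, :-1] / cell  # lower-left triangles
    dzy = np.diff(z, axis=1)[:-1, :] / cell
    a1 = 0.5 * cell**2 * np.sqrt(1.0 + dzx**2 + dzy**2)
    dzx2 = np.diff(z, axis=0)[:, 1:] / cell  # upper-right triangles
    dzy2 = np.diff(z, axis=1)[1:, :] / cell
    a2 = 0.5 * cell**2 * np.sqrt(1.0 + dzx2**2 + dzy2**2)
    return float(a1.sum() + a2.sum())


def rumple_index(surface, cell: float | None = None) -> float:
    """Rumple index: 3D surface area / planar projected area (>= 1).

    ``surface`` may be a :class:`ReefCrossSection`, a node-registered 2D
    height-field array (with ``cell`` spacing in m), or a triangulated
    ``trimesh.Trimesh`` graph surface (projected area from the sum of
    |z-components| of facet area vectors).
    """
    if isinstance(surface, ReefCrossSection):
        z, cell = surface.height, surface.cell
        area3d = _heightfield_area(z, cell)
        planar = (z.shape[0] - 1) * (z.shape[1] - 1) * cell**2
    elif isinstance(surface, trimesh.Trimesh):
        cross = surface.triangles_cross  # 2x area vectors
        area3d = float(0.5 * np.linalg.norm(cross, axis=1).sum())
        planar = float(0.5 * np.abs(cross[:, 2]).sum())
    else:
        z = np.asarray(surface, dtype=float)
        if z.ndim != 2 or cell is None or cell <= 0:
            raise ValueError("height-field input needs a 2D array and cell > 0")
        area3d = _heightfield_area(z, cell)
        planar = (z.shape[0] - 1) * (z.shape[1] - 1) * cell**2
    if planar <= 0:
        raise ValueError("degenerate footprint: zero planar area")
    return area3d / planar


# ----------------------------------------------------- mesh -> unit stamps


def _unit_stamp(mesh: trimesh.Trimesh, res: int = 64) -> np.ndarray:
    """Rasterize a graph-surface mesh to a unit height field.

    The mesh footprint is normalised to [-0.5, 0.5]^2 and heights to
    [0, 1]; cells outside the footprint are 0. Piecewise-linear
    interpolation over the projected vertices reproduces the mesh surface
    exactly for graph meshes (which is what the shape generator produces).
    """
    from scipy.interpolate import LinearNDInterpolator

    v = mesh.vertices
    lo = v.min(axis=0)
    ext = np.maximum(v.max(axis=0) - lo, 1e-12)
    xy = (v[:, :2] - lo[:2]) / ext[:2] - 0.5
    zz = (v[:, 2] - lo[2]) / ext[2]
    interp = LinearNDInterpolator(xy, zz, fill_value=0.0)
    g = (np.arange(res) + 0.5) / res - 0.5
    X, Y = np.meshgrid(g, g, indexing="ij")
    return np.maximum(interp(X, Y), 0.0)


def build_stamp_bank(
    shape_bank: Mapping[str, Sequence[trimesh.Trimesh]], res: int = 64
) -> dict[str, list[np.ndarray]]:
    """Precompute unit height-field stamps for every mesh in the bank."""
    return {
        taxon: [_unit_stamp(m, res=res) for m in meshes]
        for taxon, meshes in shape_bank.items()
    }


def _bilinear(stamp: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sample a stamp at fractional unit coordinates in [-0.5, 0.5]."""
    res = stamp.shape[0]
    fu = np.clip((u + 0.5) * res - 0.5, 0.0, res - 1.0)
    fv = np.clip((v + 0.5) * res - 0.5, 0.0, res - 1.0)
    i0 = np.floor(fu).astype(int)
    j0 = np.floor(fv).astype(int)
    i1 = np.minimum(i0 + 1, res - 1)
    j1 = np.minimum(j0 + 1, res - 1)
    du = fu - i0
    dv = fv - j0
    out = (
        stamp[i0, j0] * (1 - du) * (1 - dv)
        + stamp[i1, j0] * du * (1 - dv)
        + stamp[i0, j1] * (1 - du) * dv
        + stamp[i1, j1] * du * dv
    )
    outside = (np.abs(u) > 0.5) | (np.abs(v) > 0.5)
    out[outside] = 0.0
    return out


# ------------------------------------------------------------- population


def populate_cross_section(
    substrate: SubstrateStrip,
    covers: Mapping[str, float],
    sizes: Mapping[str, np.ndarray],
    shape_bank,
    seed: int = 0,
    max_colonies: int = 200_000,
) -> ReefCrossSection:
    """Fill the strip until each taxon's summed planar area meets its cover.

    Colonies are added one at a time — uniform-random position (footprint
    kept inside the strip), uniform rotation in [-pi/2, pi/2], dimensions
    resampled from the survey size distribution — until the taxon's summed
    planar-area fraction first reaches or exceeds the target. Overlapping
    colonies compose by pointwise max.
    """
    total = float(sum(covers.values()))
    if any(c < 0 or c > 1 for c in covers.values()) or total > 1.0 + 1e-9:
        raise ValueError("cover targets must lie in [0, 1] and sum to <= 1")
    stamps = (
        shape_bank
        if all(isinstance(v[0], np.ndarray) for v in shape_bank.values() if len(v))
        else build_stamp_bank(shape_bank)
    )
    for taxon, cov in covers.items():
        if cov > 0 and (taxon not in stamps or len(stamps[taxon]) == 0):
            raise ValueError(f"shape bank has no mesh for taxon {taxon!r}")

    rng = np.random.default_rng(seed)
    cell = substrate.cell
    z = substrate.base_height().copy()
    nx, ny = z.shape[0] - 1, z.shape[1] - 1
    strip_area = substrate.length * substrate.width
    # node coordinates (cell corners)
    gx = np.arange(nx + 1) * cell
    gy = np.arange(ny + 1) * cell

    colonies: list[CoralColony] = []
    achieved: dict[str, float] = {}
    for taxon in covers:
        target = covers[taxon] * strip_area
        placed_area = 0.0
        sz = np.asarray(sizes.get(taxon, np.empty((0, 3))))
        if target > 0 and sz.size == 0:
            raise ValueError(f"no size samples for taxon {taxon!r}")
        n_guard = 0
        while placed_area < target:
            n_guard += 1
            if n_guard > max_colonies:
                raise RuntimeError(
                    f"cover target {covers[taxon]} for {taxon} not reached "
                    f"after {max_colonies} colonies"
                )
            w, l, h = sz[rng.integers(sz.shape[0])]
            theta = rng.uniform(-np.pi / 2.0, np.pi / 2.0)
            ct, st = np.cos(theta), np.sin(theta)
            # rotated half extents; shrink to fit the strip if necessary
            hx = 0.5 * (abs(w * ct) + abs(l * st))
            hy = 0.5 * (abs(w * st) + abs(l * ct))
            shrink = min(
                1.0,
                substrate.length / (2.0 * hx + 1e-12),
                substrate.width / (2.0 * hy + 1e-12),
            )
            if shrink < 1.0:
                w, l, h = w * shrink, l * shrink, h * shrink
                hx, hy = hx * shrink, hy * shrink
            cx = rng.uniform(hx, substrate.length - hx)
            cy = rng.uniform(hy, substrate.width - hy)
            mi = int(rng.integers(len(stamps[taxon])))
            stamp = stamps[taxon][mi]

            i0 = max(int(np.floor((cx - hx) / cell)), 0)
            i1 = min(int(np.ceil((cx + hx) / cell)), nx)
            j0 = max(int(np.floor((cy - hy) / cell)), 0)
            j1 = min(int(np.ceil((cy + hy) / cell)), ny)
            X = gx[i0 : i1 + 1, None] - cx
            Y = gy[None, j0 : j1 + 1] - cy
            u = (X * ct + Y * st) / w
            v = (-X * st + Y * ct) / l
            zc = h * _bilinear(stamp, u + np.zeros_like(v), v + np.zeros_like(u))
            foot = zc > 1e-9
            area = float(foot.sum()) * cell**2
            if area <= 0:
                continue
            window = z[i0 : i1 + 1, j0 : j1 + 1]
            base = window[foot].min() if foot.any() else 0.0
            np.maximum(window, base + zc, out=window)
            placed_area += area
            colonies.append(
                CoralColony(
                    taxon=taxon,
                    position=(float(cx), float(cy)),
                    dimensions=(float(w), float(l), float(h)),
                    rotation=float(theta),
                    mesh_index=mi,
                    planar_area=area,
                )
            )
        achieved[taxon] = placed_area / strip_area
    return ReefCrossSection(
        strip=substrate, colonies=colonies, height=z, cover_achieved=achieved
    )


def complexity_ensemble(
    survey: SurveyTable,
    substrate: SubstrateStrip,
    shape_bank,
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate SC (rumple) values per survey year.

    Returns a long DataFrame (year, replicate, sc); use
    :func:`summarize_complexity` for the per-year median and 5th–95th
    percentile ("very likely") range.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    stamps = build_stamp_bank(shape_bank) if not all(
        isinstance(v[0], np.ndarray) for v in shape_bank.values() if len(v)
    ) else shape_bank
    rows = []
    for yi, year in enumerate(survey.years):
        sub = survey.table[survey.table.year == year]
        covers = dict(zip(sub.taxon, sub.cover))
        sizes = {t: survey.sizes.get((year, t), np.empty((0, 3))) for t in covers}
        for rep in range(n_replicates):
            section = populate_cross_section(
                substrate,
                covers,
                sizes,
                stamps,
                seed=seed * 1_000_003 + yi * 1009 + rep,
            )
            rows.append((year, rep, rumple_index(section)))
    return pd.DataFrame(rows, columns=["year", "replicate", "sc"])


def summarize_complexity(sc_table: pd.DataFrame) -> pd.DataFrame:
    """Median and very-likely (5th–95th percentile) SC range per year."""
    return (
        sc_table.groupby("year")
        .sc.agg(
            median="median",
            q05=lambda s: s.quantile(0.05),
            q95=lambda s: s.quantile(0.95),
        )
        .reset_index()
    )
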