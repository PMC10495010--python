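"""Isosurfaces of potential grids and solvent-accessible surface areas.

The shape object the similarity pipeline compares is the signed isosurface
of the electrostatic potential at ±1 kT/e: a marching-cubes triangulation
of the level set, with all disconnected components pooled.  Points are
sampled area-weighted on the mesh.  The module also provides Shrake-Rupley
solvent-accessible surface areas and the derived buried interface area of a
two-structure complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .electrostatics import PotentialGrid
from .structure_io import ChargedStructure

__all__ = [
    "IsoSurface",
    "PointCloud",
    "EmptySurfaceError",
    "extract_isosurface",
    "signed_isosurfaces",
    "surface_area",
    "sample_surface_points",
    "sasa",
    "buried_interface_area",
]


class EmptySurfaceError(ValueError):
    """The requested level is not bracketed anywhere in the grid."""


@dataclass
class IsoSurface:
    """Triangulated level set of a potential grid, in world coordinates (Å)."""

    level: float  # kT/e
    sign: str  # "+" | "-"
    vertices: np.ndarray  # (n, 3) Å
    faces: np.ndarray  # (m, 3) vertex indices
    parent_label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a missing vertex")

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        # cached: meshes are treated as immutable after extraction
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @cached_property
    def _cum_areas(self) -> np.ndarray:
        return np.cumsum(self.triangle_areas)


@dataclass
class PointCloud:
    """n points in 3-space, Å."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
            raise ValueError("points must be a finite (n, 3) array")
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)


def extract_isosurface(grid: PotentialGrid, level: float) -> IsoSurface:
    """Marching-cubes triangulation of {r : φ(r) = level}.

    Vertices are returned in grid world coordinates (origin + index·spacing);
    all disconnected components are retained in one mesh.  Raises
    :class:`EmptySurfaceError` when the level is outside the grid's value
    range.
    """
    if level == 0:
        raise ValueError("level must be nonzero")
    vals = grid.values
    if not (vals.min() < level < vals.max()):
        raise EmptySurfaceError(
            f"level {level} kT/e not bracketed by grid range "
            f"[{vals.min():.3g}, {vals.max():.3g}]")
    h = grid.spec.spacing
    verts, faces, _, _ = marching_cubes(vals, level=level, spacing=(h, h, h))
    verts = verts + grid.spec.origin
    return IsoSurface(level=level, sign="+" if level > 0 else "-",
                      vertices=verts, faces=faces,
                      parent_label=grid.meta.get("label", ""))


def signed_isosurfaces(grid: PotentialGrid, level: float = 1.0,
                       retry_half: bool = True) -> dict[str, IsoSurface]:
    """The ± pair of isosurfaces at ±|level| kT/e.

    If one sign is empty at the default level the extraction is retried once
    at half the level (pipeline degenerate-case policy); if still empty the
    error propagates.
    """
    level = abs(level)
    out: dict[str, IsoSurface] = {}
    for sgn, lv in (("+", level), ("-", -level)):
        try:
            out[sgn] = extract_isosurface(grid, lv)
        except EmptySurfaceError:
            if not retry_half:
                raise
            out[sgn] = extract_isosurface(grid, lv / 2.0)
    return out


def surface_area(surface: IsoSurface) -> float:
    """Total mesh area, Å² (sum of triangle areas)."""
    if surface.faces.size == 0:
        warnings.warn("degenerate mesh with no faces; area 0")
        return 0.0
    return float(surface.triangle_areas.sum())


def sample_surface_points(surface: IsoSurface, n: int,
                          rng: np.random.Generator) -> PointCloud:
    """n points drawn area-weighted on the mesh.

    A triangle is chosen with probability proportional to its area (across
    all components), then a point is placed uniformly inside it by
    barycentric sampling.  Reproducible given the generator state.
    """
    if n < 2:
        raise ValueError("need n >= 2 sample points")
    cum = surface._cum_areas
    total = cum[-1] if len(cum) else 0.0
    if surface.faces.size == 0 or total <= 0:
        raise EmptySurfaceError("cannot sample from an empty or degenerate surface")
    idx = np.searchsorted(cum, rng.random(n) * total, side="right")
    idx = np.minimum(idx, len(cum) - 1)
    v = surface.vertices
    a = v[surface.faces[idx, 0]]
    b = v[surface.faces[idx, 1]]
    c = v[surface.faces[idx, 2]]
    u = rng.random(n)
    w = rng.random(n)
    flip = u + w > 1
    u[flip], w[flip] = 1 - u[flip], 1 - w[flip]
    pts = a + u[:, None] * (b - a) + w[:, None] * (c - a)
    return PointCloud(points=pts)


def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(structure: ChargedStructure, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom, Å².

    For each atom, test points on a deterministic quasi-uniform sphere of
    radius r_atom + probe; the accessible fraction (points inside no
    neighbor's expanded sphere) times 4π(r_atom + probe)² is the atom's
    contribution.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_sphere_points < 100:
        raise ValueError("need >= 100 sphere points")
    dirs = _golden_spiral(n_sphere_points)
    pos = structure.positions
    rad = structure.radii + probe_radius
    tree = cKDTree(pos)
    r_max = rad.max()
    areas = np.zeros(len(pos))
    tol = 1e-9
    for i in range(len(pos)):
        pts = pos[i] + rad[i] * dirs
        neighbors = [j for j in tree.query_ball_point(pos[i], rad[i] + r_max)
                     if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            r2 = rad[j] ** 2
            inside = d2 < r2 * (1 - tol)
            if j < i:
                # points exactly on a neighbor's expanded sphere belong to the
                # lower-index atom, so coincident atoms split a shared surface
                inside |= np.abs(d2 - r2) <= r2 * tol
            accessible &= ~inside
        areas[i] = accessible.mean() * 4 * np.pi * rad[i] ** 2
    return areas


def buried_interface_area(structure_a: ChargedStructure,
                          structure_b: ChargedStructure,
                          probe_radius: float = 1.4,
                          n_sphere_points: int = 960) -> float:
    """Per-side buried interface area of the A-B complex, Å².

    (SASA(A) + SASA(B) - SASA(A∪B)) / 2 — the area each partner loses upon
    association (the convention of Chimera-style "buriedArea" reports).
    Symmetric in A and B; zero for non-contacting structures.
    """
    if structure_a.label == structure_b.label:
        raise ValueError("structures must carry distinct labels")
    union = ChargedStructure(label=f"{structure_a.label}+{structure_b.label}",
                             atoms=list(structure_a.atoms) + list(structure_b.atoms))
    sa = sasa(structure_a, probe_radius, n_sphere_points).sum()
    sb = sasa(structure_b, probe_radius, n_sphere_points).sum()
    sab = sasa(union, probe_radius, n_sphere_points).sum()
    return float((sa + sb - sab) / 2.0)
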