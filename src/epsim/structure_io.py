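"""Readers and writers for the formats the pipeline touches.

Structures arrive as PQR (PDB-like records carrying per-atom partial charge
and radius in the last two numeric fields, the output of pdb2pqr-class
tools); potential grids travel as OpenDX scalar files, the lingua franca of
Poisson-Boltzmann solvers; the packaged catalog of *Arabidopsis thaliana*
thioredoxins and glutaredoxins ships as a TSV resource.

Units are Å for coordinates and radii, elementary charges (e) for partial
charges, and kT/e for potentials, throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ChargedAtom",
    "ChargedStructure",
    "RedoxinCatalogEntry",
    "PQRParseError",
    "DXParseError",
    "read_pqr",
    "write_pqr",
    "read_dx",
    "write_dx",
    "load_redoxin_catalog",
    "classify_redoxin_motif",
]


class PQRParseError(ValueError):
    """Raised for malformed or empty PQR input; carries the line number."""


class DXParseError(ValueError):
    """Raised for OpenDX input outside the regular scalar-grid dialect."""


@dataclass(frozen=True)
class ChargedAtom:
    """One atom: position (Å), partial charge (e), radius (Å)."""

    name: str
    position: np.ndarray  # shape (3,), Å
    charge: float  # e
    radius: float  # Å
    residue_tag: Optional[str] = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not (self.radius > 0):
            raise ValueError(f"atom {self.name!r}: radius must be positive, got {self.radius}")
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.name!r}: charge must be finite")


@dataclass
class ChargedStructure:
    """A labelled collection of charged atoms."""

    label: str
    atoms: list[ChargedAtom]

    def __post_init__(self):
        if not self.label:
            raise ValueError("structure label must be non-empty")
        if not self.atoms:
            raise ValueError(f"structure {self.label!r} has no atoms")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.atoms)


# --- PQR ------------------------------------------------------------------

def read_pqr(path, label: Optional[str] = None) -> ChargedStructure:
    """Read a whitespace-delimited PQR file.

    One :class:`ChargedAtom` per ATOM/HETATM record; charge and radius are
    the last two numeric fields of the record, positions the three fields
    before them.  Raises :class:`PQRParseError` naming the offending line on
    malformed records, or if no atoms are found.
    """
    path = Path(path)
    atoms: list[ChargedAtom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                x, y, z, q, r = (float(v) for v in rec[-5:])
                name = rec[2] if len(rec) > 2 else rec[0]
                tag = rec[3] if len(rec) > 3 else None
            except (ValueError, IndexError) as exc:
                raise PQRParseError(f"{path.name}:{lineno}: malformed PQR record: {line.rstrip()!r}") from exc
            atoms.append(ChargedAtom(name=name, position=np.array([x, y, z]), charge=q, radius=r, residue_tag=tag))
    if not atoms:
        raise PQRParseError(f"{path.name}: no ATOM/HETATM records found")
    return ChargedStructure(label=label or path.stem, atoms=atoms)


def write_pqr(structure: ChargedStructure, path) -> Path:
    """Write a structure as PQR, re-readable by :func:`read_pqr`.

    Positions and charges are serialized to 4 decimals (the round-trip
    precision contract of the package).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"REMARK epsim structure {structure.label}\n")
        for i, a in enumerate(structure.atoms, start=1):
            tag = a.residue_tag or "UNK"
            x, y, z = a.position
            fh.write(
                f"ATOM  {i:5d} {a.name:<4s} {tag:<4s} {1:4d}    "
                f"{x:10.4f} {y:10.4f} {z:10.4f} {a.charge:8.4f} {a.radius:7.4f}\n"
            )
    return path


# --- OpenDX ---------------------------------------------------------------

_DX_COUNTS = re.compile(
    r"object\s+1\s+class\s+gridpositions\s+counts\s+(\d+)\s+(\d+)\s+(\d+)")


def read_dx(path):
    """Read an OpenDX scalar grid ("regular positions, regular connections").

    Returns a :class:`~epsim.electrostatics.PotentialGrid` with source tag
    ``"file"``.  Values follow the OpenDX convention: the last (z) index
    varies fastest.  Non-regular grids raise :class:`DXParseError`.
    """
    from .electrostatics import GridSpec, PotentialGrid, SolventParams

    path = Path(path)
    shape = origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    n_expected = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            m = _DX_COUNTS.match(s)
            if m:
                shape = tuple(int(g) for g in m.groups())
                n_expected = shape[0] * shape[1] * shape[2]
                continue
            if s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
                continue
            if s.startswith("delta"):
                deltas.append(np.array([float(v) for v in s.split()[1:4]]))
                continue
            if s.startswith("object") or s.startswith("attribute") or s.startswith("component"):
                if "gridconnections" in s and "counts" in s:
                    continue
                continue
            # bare data line
            values.extend(float(v) for v in s.split())
    if shape is None or origin is None or len(deltas) != 3:
        raise DXParseError(f"{path.name}: missing gridpositions/origin/delta header")
    D = np.array(deltas)
    if not np.allclose(D, np.diag(np.diag(D))):
        raise DXParseError(f"{path.name}: non-axis-aligned delta vectors are unsupported")
    steps = np.diag(D)
    if not np.allclose(steps, steps[0]):
        raise DXParseError(f"{path.name}: anisotropic spacing is unsupported")
    if n_expected is not None and len(values) != n_expected:
        raise DXParseError(f"{path.name}: expected {n_expected} values, found {len(values)}")
    vals = np.array(values).reshape(shape)  # z-fastest == C order with (nx,ny,nz)
    spec = GridSpec(origin=origin, spacing=float(steps[0]), shape=shape)
    return PotentialGrid(spec=spec, values=vals, params=SolventParams(), source="file")


def write_dx(grid, path) -> Path:
    """Write a potential grid as an OpenDX scalar file (inverse of read_dx)."""
    path = Path(path)
    nx, ny, nz = grid.spec.shape
    h = grid.spec.spacing
    ox, oy, oz = grid.spec.origin
    flat = np.asarray(grid.values).reshape(-1)  # z-fastest
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar grid written by epsim (potential in kT/e)\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
        fh.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
    return path


# --- Redoxin catalog ------------------------------------------------------

@dataclass(frozen=True)
class RedoxinCatalogEntry:
    """One row of the packaged Arabidopsis redoxin catalog.

    ``family`` is Grx or Trx; ``active_site_motif`` is the CxxC-style motif
    (repeat forms like "3·CGFS" denote multi-domain proteins);
    ``interaction_count`` is the catalog's interactome column, None where the
    source table shows no entry.
    """

    protein_name: str
    uniprot_id: str
    family: str  # "Grx" | "Trx"
    active_site_motif: str
    grx_class: Optional[str] = None  # "I" | "II" | "III"
    interaction_count: Optional[int] = None
    pdb_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.family not in ("Grx", "Trx"):
            raise ValueError(f"{self.protein_name}: family must be Grx or Trx")
        if "C" not in self.active_site_motif.upper():
            raise ValueError(f"{self.protein_name}: motif {self.active_site_motif!r} lacks a cysteine")
        if self.interaction_count is not None and self.interaction_count < 0:
            raise ValueError(f"{self.protein_name}: negative interaction count")


def classify_redoxin_motif(entry: RedoxinCatalogEntry) -> Optional[str]:
    """Assign a glutaredoxin class from the active-site motif.

    Class III (CC-type/ROXY) if the motif starts with "CC"; class II if the
    motif is CGFS (including repeat forms like "3·CGFS"); class I otherwise.
    Trx-family entries return None.  Total on catalog entries.
    """
    if entry.family != "Grx":
        return None
    motif = entry.active_site_motif.upper()
    # strip a repeat prefix like "3·" or "2x"
    core = re.sub(r"^\d+\s*[·x×*]\s*", "", motif)
    if core.startswith("CC"):
        return "III"
    if core == "CGFS":
        return "II"
    return "I"


def load_redoxin_catalog() -> list[RedoxinCatalogEntry]:
    """Load the packaged catalog of A. thaliana Trx/Grx family proteins.

    Entries carry name, UniProtKB accession, family, active-site motif,
    experimentally solved PDB ids where available, and the interactome count
    column; ``grx_class`` is filled by :func:`classify_redoxin_motif`.
    """
    text = resources.files("epsim").joinpath("data/redoxin_catalog.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["name", "uniprot", "family", "motif", "pdb", "interactions"]
    if header != expected:
        raise ValueError(f"catalog fixture corrupt: header {header}")
    entries: list[RedoxinCatalogEntry] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        f = ln.split("\t")
        f += [""] * (6 - len(f))
        name, uniprot, family, motif, pdb, inter = (v.strip() for v in f[:6])
        if uniprot in seen:
            raise ValueError(f"catalog fixture corrupt: duplicate accession {uniprot}")
        seen.add(uniprot)
        entry = RedoxinCatalogEntry(
            protein_name=name,
            uniprot_id=uniprot,
            family=family,
            active_site_motif=motif,
            interaction_count=int(inter) if inter else None,
            pdb_ids=tuple(p for p in pdb.split(",") if p),
        )
        entry = RedoxinCatalogEntry(
            **{**entry.__dict__, "grx_class": classify_redoxin_motif(entry)})
        entries.append(entry)
    return entries
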