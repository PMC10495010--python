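"""Desk-scale fixtures with known ground truth.

Charged-structure archetypes emulate the qualitative potential-surface
classes seen on real redoxins (predominantly one-signed potential versus a
split positive/negative pattern): a monopole, a dipole, a split-patch shell
with positive charges on one hemisphere and negative on the other, and a
planar quadrupole.  Families are jittered copies of an archetype, giving
the clustering pipeline a planted truth to recover.  A planted interactome
realizes exact per-protein exclusive counts and pairwise-shared counts with
fake accession strings, so every overlap statistic has a known value.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interactome import InteractionTable
from .structure_io import ChargedAtom, ChargedStructure, write_pqr

__all__ = [
    "ARCHETYPES",
    "FamilySpec",
    "PlantedInteractomeSpec",
    "make_archetype_structure",
    "make_structure_families",
    "make_planted_interactome",
    "redoxin_interactome_spec",
    "write_fixture_set",
]

ARCHETYPES = ("monopole", "dipole", "split_patch", "quadrupole")
_ATOM_RADIUS = 1.6  # Å, every synthetic atom


@dataclass(frozen=True)
class FamilySpec:
    """A planted family: archetype, member count, jitters, seed."""

    family_id: str
    archetype: str
    n_members: int = 4
    geometry_jitter: float = 0.3  # Å, per-coordinate σ
    charge_jitter: float = 0.02  # e, per-atom σ
    scale: float = 10.0  # Å, overall structure size
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.geometry_jitter < 0 or self.charge_jitter < 0:
            raise ValueError("jitters must be >= 0")


def _sphere_dirs(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_archetype_structure(archetype: str, scale: float = 10.0,
                             label: str = "archetype") -> ChargedStructure:
    """Build one archetype structure of overall size ``scale`` (Å).

    monopole: a single +1 e sphere.  dipole: a ±1 e pair ``scale`` apart.
    split_patch: a neutral 16-atom shell of diameter ``scale`` carrying
    +0.5 e on the upper and −0.5 e on the lower hemisphere, which produces
    non-empty isosurfaces of both signs at ±1 kT/e.  quadrupole: four
    alternating ±1 e charges on a square of side ``scale``/2.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if archetype == "monopole":
        coords = np.array([[0.0, 0.0, 0.0]])
        charges = np.array([1.0])
    elif archetype == "dipole":
        half = scale / 2.0
        coords = np.array([[0.0, 0.0, half], [0.0, 0.0, -half]])
        charges = np.array([1.0, -1.0])
    elif archetype == "split_patch":
        coords = _sphere_dirs(16) * (scale / 2.0)
        charges = np.where(coords[:, 2] > 0, 0.5, -0.5)
    elif archetype == "quadrupole":
        half = scale / 4.0
        coords = np.array([[half, half, 0.0], [-half, half, 0.0],
                           [-half, -half, 0.0], [half, -half, 0.0]])
        charges = np.array([1.0, -1.0, 1.0, -1.0])
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    atoms = [ChargedAtom(name=f"Q{i}", position=c, charge=float(q), radius=_ATOM_RADIUS)
             for i, (c, q) in enumerate(zip(coords, charges))]
    return ChargedStructure(label=label, atoms=atoms)


def make_structure_families(specs: list[FamilySpec]
                            ) -> tuple[list[ChargedStructure], dict[str, str]]:
    """Jittered family members plus their ground-truth family labels.

    Each member perturbs the archetype positions by N(0, geometry_jitter²)
    per coordinate and the charges by N(0, charge_jitter²); member k of a
    family draws from a stream seeded by (spec.seed, k), so fixtures are
    byte-identical across runs.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 families")
    structures: list[ChargedStructure] = []
    truth: dict[str, str] = {}
    for spec in specs:
        base = make_archetype_structure(spec.archetype, spec.scale)
        for k in range(spec.n_members):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed) % 2**31, k]))
            label = f"{spec.family_id}_{k}"
            atoms = []
            for a in base.atoms:
                pos = a.position + rng.normal(0.0, spec.geometry_jitter, 3)
                q = a.charge + rng.normal(0.0, spec.charge_jitter)
                atoms.append(ChargedAtom(name=a.name, position=pos,
                                         charge=float(q), radius=a.radius))
            structures.append(ChargedStructure(label=label, atoms=atoms))
            truth[label] = spec.family_id
    return structures, truth


@dataclass(frozen=True)
class PlantedInteractomeSpec:
    """Planned exclusive and pairwise-shared partner counts.

    ``exclusive`` maps each label to its number of private partners;
    ``shared`` maps a (label, label) pair to the number of partners shared
    by exactly those two proteins.
    """

    labels: tuple[str, ...]
    exclusive: dict = field(default_factory=dict)
    shared: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for lab, c in self.exclusive.items():
            if lab not in self.labels:
                raise ValueError(f"exclusive count for unknown label {lab!r}")
            if c < 0:
                raise ValueError("exclusive counts must be >= 0")
        for pair, c in self.shared.items():
            a, b = pair
            if a not in self.labels or b not in self.labels or a == b:
                raise ValueError(f"invalid shared pair {pair!r}")
            if c < 0:
                raise ValueError("shared counts must be >= 0")

    @classmethod
    def from_totals(cls, totals: dict[str, int], shared: dict, seed: int = 0):
        """Fill exclusive counts so each label reaches a planned total size.

        Raises if a total is smaller than the label's shared commitments
        (an inconsistent plan).
        """
        labels = tuple(totals)
        exclusive = {}
        for lab, total in totals.items():
            committed = sum(c for pair, c in shared.items() if lab in pair)
            if total < committed:
                raise ValueError(
                    f"{lab}: planned total {total} below shared commitments {committed}")
            exclusive[lab] = total - committed
        return cls(labels=labels, exclusive=exclusive, shared=shared, seed=seed)


def make_planted_interactome(spec: PlantedInteractomeSpec
                             ) -> tuple[InteractionTable, dict]:
    """Realize a planted interactome with fake accessions.

    Returns the table and its ground truth: per-label set sizes, the
    planted pairwise overlaps, the exclusive-partner count, and the union
    size.  Accessions are synthetic strings ("X00001", ...), assigned
    deterministically.
    """
    table = InteractionTable(partners={lab: set() for lab in spec.labels})
    counter = 0

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return f"X{counter:05d}"

    for lab in spec.labels:
        for _ in range(spec.exclusive.get(lab, 0)):
            table.partners[lab].add(fresh())
    for (a, b), c in spec.shared.items():
        for _ in range(c):
            acc = fresh()
            table.partners[a].add(acc)
            table.partners[b].add(acc)
    truth = {
        "set_sizes": {lab: len(table.partners[lab]) for lab in spec.labels},
        "overlaps": {tuple(pair): c for pair, c in spec.shared.items()},
        "exclusive_total": sum(spec.exclusive.get(lab, 0) for lab in spec.labels),
        "union_size": len(set().union(*table.partners.values())) if spec.labels else 0,
        "membership_total": sum(len(s) for s in table.partners.values()),
    }
    return table, truth


def redoxin_interactome_spec() -> PlantedInteractomeSpec:
    """Synthetic twin of the five-redoxin overlap analysis.

    Plants the reported per-protein partner totals (GrxC1 30, TrxH1 45,
    TrxH3 70, TrxH5 75, TrxH7 97) and the three reported pairwise overlaps
    (TrxH5∩TrxH7 = 24, GrxC1∩TrxH7 = 7, TrxH3∩TrxH5 = 5), with every other
    pair disjoint.  This is a synthetic stand-in for the real curated
    interactome sheet, not derived from database records.
    """
    totals = {"GrxC1": 30, "TrxH1": 45, "TrxH3": 70, "TrxH5": 75, "TrxH7": 97}
    shared = {("TrxH5", "TrxH7"): 24, ("GrxC1", "TrxH7"): 7, ("TrxH3", "TrxH5"): 5}
    return PlantedInteractomeSpec.from_totals(totals, shared)


def write_fixture_set(structures: list[ChargedStructure], truth: dict[str, str],
                      outdir, seed: int | None = None) -> Path:
    """Write PQR files plus a JSON manifest recording the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for s in structures:
        p = write_pqr(s, outdir / f"{s.label}.pqr")
        files[s.label] = p.name
    manifest = {"files": files, "family": truth}
    if seed is not None:
        manifest["seed"] = int(seed)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
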