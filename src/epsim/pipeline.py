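"""End-to-end runs: similarity pipeline, interactome analysis, catalog summary.

`run_similarity` drives structures (PQR) or precomputed potential grids
(OpenDX) through electrostatics → signed ±1 kT/e isosurfaces → repeated
GW-lower-bound subsampling histograms for every protein pair (self-pairs
included as the subsampling-noise baseline) → earth-mover's distances →
UPGMA → Newick.  Every run writes a JSON manifest capturing the seed and
all parameters, which suffices to reproduce the outputs bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from itertools import combinations_with_replacement
from pathlib import Path

from . import __version__
from .electrostatics import SolventParams, dh_potential_grid, lpb_solve
from .gwdist import DistanceHistogram, bin_samples, pair_histogram
from .interactome import (exclusive_partner_count, overlap_matrix,
                          partner_counts, read_interaction_table, venn_counts)
from .similarity import (Dendrogram, PairwiseDistanceMatrix,
                         build_distance_matrix, to_newick, upgma)
from .structure_io import (classify_redoxin_motif, load_redoxin_catalog,
                           read_dx, read_pqr)
from .surface import signed_isosurfaces

__all__ = ["RunConfig", "PipelineError", "compare_structures",
           "run_similarity", "run_interactome", "run_catalog_summary"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending item."""

    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {item}: {cause}")
        self.stage = stage
        self.item = item


@dataclass
class RunConfig:
    """Parameters of a similarity run.

    Defaults follow the comparison protocol: iso-level ±1 kT/e, 100 sample
    points, 500 repetitions, and the TLB bound.
    """

    input_dir: str = "."
    mode: str = "dh"  # "dh" | "lpb" | "precomputed"
    iso_level: float = 1.0  # kT/e
    n_points: int = 100
    n_reps: int = 500
    bound: str = "TLB"
    seed: int = 0
    out_dir: str = "epsim_out"
    n_bins: int = 64
    solvent: SolventParams = field(default_factory=SolventParams)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        solvent = SolventParams(**raw.pop("solvent", {}))
        return cls(solvent=solvent, **raw)


def _load_inputs(config: RunConfig):
    """Structures or grids from the input directory, by mode."""
    indir = Path(config.input_dir)
    if config.mode == "precomputed":
        files = sorted(indir.glob("*.dx"))
        if len(files) < 2:
            raise PipelineError("load", str(indir), ValueError("need >= 2 .dx grids"))
        grids = {}
        for f in files:
            g = read_dx(f)
            g.meta["label"] = f.stem
            grids[f.stem] = g
        return grids
    files = sorted(indir.glob("*.pqr"))
    if len(files) < 2:
        raise PipelineError("load", str(indir), ValueError("need >= 2 .pqr structures"))
    solver = dh_potential_grid if config.mode == "dh" else lpb_solve
    grids = {}
    for f in files:
        try:
            s = read_pqr(f)
            g = solver(s, params=config.solvent)
            g.meta["label"] = s.label
            grids[s.label] = g
        except Exception as exc:
            raise PipelineError("electrostatics", f.name, exc) from exc
    return grids


def compare_structures(grids: dict, config: RunConfig
                       ) -> tuple[PairwiseDistanceMatrix, Dendrogram,
                                  list[DistanceHistogram], list[str]]:
    """Isosurfaces → pair histograms → EMD matrix → UPGMA, in memory.

    ``grids`` maps label → PotentialGrid.  Returns the distance matrix, the
    dendrogram, the binned histograms (self-pairs included), and any
    warnings gathered along the way.
    """
    warnings_log: list[str] = []
    surfaces = {}
    for label, grid in grids.items():
        try:
            surf = signed_isosurfaces(grid, config.iso_level)
            for sgn in ("+", "-"):
                if abs(surf[sgn].level) != config.iso_level:
                    warnings_log.append(
                        f"{label}: empty {sgn} isosurface at ±{config.iso_level}; "
                        f"fell back to level {surf[sgn].level}")
            if grid.meta.get("capped", 0):
                warnings_log.append(f"{label}: {grid.meta['capped']} near-atom grid nodes capped")
            surfaces[label] = surf
        except Exception as exc:
            raise PipelineError("isosurface", label, exc) from exc
    labels = sorted(surfaces)
    histograms = []
    for la, lb in combinations_with_replacement(labels, 2):
        try:
            histograms.append(pair_histogram(
                surfaces[la], surfaces[lb], (la, lb),
                n_points=config.n_points, n_reps=config.n_reps,
                kind=config.bound, seed=config.seed))
        except Exception as exc:
            raise PipelineError("gw-histogram", f"({la}, {lb})", exc) from exc
    bin_samples(histograms, n_bins=config.n_bins)
    matrix = build_distance_matrix(histograms)
    tree = upgma(matrix)
    return matrix, tree, histograms, warnings_log


def _write_histograms(histograms: list[DistanceHistogram], path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("pair_a\tpair_b\trep\tvalue\n")
        for h in histograms:
            a, b = h.pair_labels
            for r, v in enumerate(h.samples):
                fh.write(f"{a}\t{b}\t{r}\t{v:.6g}\n")


def run_similarity(config: RunConfig) -> dict:
    """Full similarity run; writes TSV/Newick/manifest into the output dir.

    Returns a dict with the in-memory results and the output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grids = _load_inputs(config)
    matrix, tree, histograms, warn = compare_structures(grids, config)
    matrix.to_tsv(out / "distance_matrix.tsv")
    (out / "tree.nwk").write_text(to_newick(tree) + "\n")
    _write_histograms(histograms, out / "histograms.tsv", config.seed)
    manifest = {
        "epsim_version": __version__,
        "config": {**asdict(config), "solvent": asdict(config.solvent)},
        "labels": matrix.labels,
        "warnings": warn,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"matrix": matrix, "tree": tree, "histograms": histograms,
            "out_dir": out, "warnings": warn}


def run_interactome(table_path, venn_labels=None, out_dir="epsim_out",
                    trim_isoforms: bool = True) -> dict:
    """Interactome analysis: counts, overlap matrix, optional Venn regions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_interaction_table(table_path, trim_isoforms=trim_isoforms)
    counts = partner_counts(table)
    exclusive = exclusive_partner_count(table)
    result = {"counts": counts, "exclusive": exclusive,
              "membership_total": sum(counts.values())}
    if len(table.partners) >= 2:
        om = overlap_matrix(table)
        om.to_tsv(out / "overlap_matrix.tsv")
        result["overlaps"] = om
    if venn_labels:
        regions = venn_counts(table, list(venn_labels))
        with open(out / "venn_regions.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for key in sorted(regions, key=lambda k: (len(k), sorted(k))):
                fh.write("&".join(sorted(key)) + f"\t{regions[key]}\n")
        result["venn"] = regions
    (out / "interactome_summary.json").write_text(json.dumps(
        {"counts": counts, "exclusive": exclusive,
         "membership_total": result["membership_total"]}, indent=2))
    return result


def run_catalog_summary() -> dict:
    """Family and Grx-class counts plus the motif table from the catalog."""
    catalog = load_redoxin_catalog()
    family_counts = {"Grx": 0, "Trx": 0}
    class_counts = {"I": 0, "II": 0, "III": 0}
    motifs = []
    for e in catalog:
        family_counts[e.family] += 1
        cls = classify_redoxin_motif(e)
        if cls:
            class_counts[cls] += 1
        motifs.append((e.protein_name, e.family, e.active_site_motif, cls or ""))
    return {"n_entries": len(catalog), "family_counts": family_counts,
            "grx_class_counts": class_counts, "motif_table": motifs}
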