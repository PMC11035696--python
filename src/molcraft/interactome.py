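"""Drug-target interactome curation.

Raw bioactivity tables (ligand SMILES, target, affinity) are washed, filtered
and assembled into a bipartite ligand-target graph whose edges are binding
affinities at or below a cutoff (default 200 nM).  The graph is the training
substrate for both design modes: in ligand-based mode, training pairs are
ligands that share a target; in structure-based mode, a target's binding
pocket is paired with each of its ligands.

Affinities are kept on the pActivity scale, -log10(affinity in molar), so a
200 nM cutoff corresponds to pActivity >= ~6.70.  Duplicate (ligand, target)
measurements are aggregated as the median pActivity before the cutoff is
applied.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from statistics import median

import pandas as pd
from rdkit import Chem

from .chem import canonical_smiles, randomized_smiles

__all__ = [
    "AFFINITY_TYPES",
    "BioactivityRecord",
    "InteractomeGraph",
    "PDBEntry",
    "TrainingPair",
    "WashResult",
    "build_interactome",
    "filter_structural",
    "make_training_pairs",
    "read_bioactivity_table",
    "smiles_length_filter",
    "split_allosteric",
    "wash_molecule",
    "write_training_pairs",
]

AFFINITY_TYPES = ("Ki", "IC50", "Kd", "EC50")
SITES = ("orthosteric", "allosteric", "unknown")


def p_activity(affinity_nM: float) -> float:
    """-log10 of the affinity in molar units; 1 uM -> 6.0, 200 nM -> ~6.70."""
    if affinity_nM <= 0:
        raise ValueError("affinity must be positive")
    return 9.0 - math.log10(affinity_nM)


@dataclass(frozen=True)
class BioactivityRecord:
    ligand_smiles: str
    target_id: str
    affinity_nM: float
    affinity_type: str = "Ki"
    site: str = "unknown"
    pdb_id: str | None = None

    def __post_init__(self):
        if self.affinity_nM <= 0:
            raise ValueError("affinity_nM must be > 0")
        if self.affinity_type not in AFFINITY_TYPES:
            raise ValueError(f"affinity_type must be one of {AFFINITY_TYPES}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")


@dataclass(frozen=True)
class WashResult:
    """Outcome of molecule washing: canonical SMILES or a rejection reason."""

    ok: bool
    smiles: str | None = None
    reason: str | None = None  # too_small | too_large | radical | unparseable


def wash_molecule(smiles: str, min_heavy: int = 3, max_heavy: int = 100) -> WashResult:
    """Neutralize, strip salts/solvents, and canonicalize one SMILES.

    Keeps the fragment with the most heavy atoms, neutralizes charged atoms
    where valence permits (quaternary nitrogens stay charged), and rejects
    radicals and molecules outside the [min_heavy, max_heavy] size window.
    Unparseable input yields a rejection, not an exception, so batch curation
    continues.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        return WashResult(False, reason="unparseable")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = rdMolStandardize.Uncharger().uncharge(mol)
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()):
        return WashResult(False, reason="radical")
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < min_heavy:
        return WashResult(False, reason="too_small")
    if n_heavy > max_heavy:
        return WashResult(False, reason="too_large")
    return WashResult(True, smiles=Chem.MolToSmiles(mol))


def smiles_length_filter(smiles: str, n_random: int = 5, max_len: int = 97, seed: int = 0) -> bool:
    """True iff the longest of `n_random` randomized renderings is <= max_len."""
    renderings = randomized_smiles(smiles, n_random, seed=seed)
    return max(len(r) for r in renderings) <= max_len


@dataclass
class InteractomeGraph:
    """Bipartite ligand-target graph; edges carry pActivity values."""

    ligand_nodes: set[str] = field(default_factory=set)
    target_nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)  # (ligand, target) -> pActivity
    mode: str = "ligand_based"
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def ligands_of(self, target: str) -> list[str]:
        return sorted(l for (l, t) in self.edges if t == target)

    def is_empty(self) -> bool:
        return not self.edges

    def to_records(self) -> list[BioactivityRecord]:
        """Re-express edges as bioactivity records (affinity back in nM)."""
        return [
            BioactivityRecord(l, t, affinity_nM=10 ** (9.0 - p))
            for (l, t), p in sorted(self.edges.items())
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "ligand_nodes": sorted(self.ligand_nodes),
                "target_nodes": sorted(self.target_nodes),
                "edges": [[l, t, p] for (l, t), p in sorted(self.edges.items())],
                "diagnostics": self.diagnostics,
            },
            indent=1,
        )

    @staticmethod
    def from_json(s: str) -> "InteractomeGraph":
        d = json.loads(s)
        return InteractomeGraph(
            ligand_nodes=set(d["ligand_nodes"]),
            target_nodes=set(d["target_nodes"]),
            edges={(l, t): p for l, t, p in d["edges"]},
            mode=d["mode"],
            diagnostics=d.get("diagnostics", {}),
        )


def build_interactome(
    records: list[BioactivityRecord],
    cutoff_nM: float = 200.0,
    min_ligands: int = 5,
    mode: str = "ligand_based",
) -> InteractomeGraph:
    """Assemble the curated bipartite graph from washed bioactivity records.

    Duplicate (ligand, target) rows collapse to their median pActivity; edges
    with affinity above the cutoff are dropped (an affinity exactly equal to
    the cutoff is kept); targets with fewer than `min_ligands` ligands are
    removed together with any ligand nodes this leaves isolated.  An empty
    result is a valid empty graph with diagnostics, never an exception.
    """
    cutoff_p = p_activity(cutoff_nM)
    grouped: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        grouped.setdefault((rec.ligand_smiles, rec.target_id), []).append(
            p_activity(rec.affinity_nM)
        )
    n_duplicates = sum(len(v) - 1 for v in grouped.values())

    edges = {
        key: median(vals)
        for key, vals in grouped.items()
        if median(vals) >= cutoff_p - 1e-12  # inclusive at the cutoff affinity
    }
    n_above_cutoff = len(grouped) - len(edges)

    per_target: dict[str, set[str]] = {}
    for (lig, tgt) in edges:
        per_target.setdefault(tgt, set()).add(lig)
    kept_targets = {t for t, ligs in per_target.items() if len(ligs) >= min_ligands}
    n_small_targets = len(per_target) - len(kept_targets)

    edges = {(l, t): p for (l, t), p in edges.items() if t in kept_targets}
    ligands = {l for (l, _t) in edges}

    return InteractomeGraph(
        ligand_nodes=ligands,
        target_nodes=set(kept_targets),
        edges=edges,
        mode=mode,
        diagnostics={
            "n_records": len(records),
            "n_duplicate_rows_collapsed": n_duplicates,
            "n_pairs_above_cutoff": n_above_cutoff,
            "n_targets_below_min_ligands": n_small_targets,
            "cutoff_nM": cutoff_nM,
            "min_ligands": min_ligands,
        },
    )


def split_allosteric(graph: InteractomeGraph, allosteric_ligands: set[str]) -> InteractomeGraph:
    """Duplicate targets that bind both allosteric and orthosteric ligands.

    Each such target becomes two nodes (``<id>::allosteric`` and
    ``<id>::orthosteric``); the edge multiset and the ligand set are
    conserved.  Allosteric ligands absent from the graph are ignored with a
    warning.
    """
    unknown = set(allosteric_ligands) - graph.ligand_nodes
    if unknown:
        warnings.warn(f"{len(unknown)} allosteric ligands not present in graph; ignored")
    allo = set(allosteric_ligands) & graph.ligand_nodes

    new_edges: dict[tuple[str, str], float] = {}
    new_targets: set[str] = set()
    for target in graph.target_nodes:
        incident = [(l, p) for (l, t), p in graph.edges.items() if t == target]
        has_allo = any(l in allo for l, _ in incident)
        has_ortho = any(l not in allo for l, _ in incident)
        if has_allo and has_ortho:
            for l, p in incident:
                suffix = "allosteric" if l in allo else "orthosteric"
                new_edges[(l, f"{target}::{suffix}")] = p
            new_targets.update({f"{target}::allosteric", f"{target}::orthosteric"})
        else:
            for l, p in incident:
                new_edges[(l, target)] = p
            new_targets.add(target)
    return InteractomeGraph(
        ligand_nodes=set(graph.ligand_nodes),
        target_nodes=new_targets,
        edges=new_edges,
        mode=graph.mode,
        diagnostics=dict(graph.diagnostics),
    )


@dataclass(frozen=True)
class PDBEntry:
    pdb_id: str
    ligand_mw: float
    affinity_uM: float


def filter_structural(
    graph: InteractomeGraph,
    pdb_index: dict[str, list[PDBEntry]],
    mw_range: tuple[float, float] = (100.0, 1200.0),
    max_affinity_uM: float = 10.0,
) -> InteractomeGraph:
    """Restrict the graph to targets with at least one usable structure.

    A structure survives if its ligand molecular weight lies in `mw_range`
    and its annotated affinity is <= `max_affinity_uM`.  Targets without any
    surviving structure are dropped (and logged in diagnostics), as are the
    ligand nodes this isolates.
    """
    lo, hi = mw_range
    surviving: dict[str, list[str]] = {}
    for target, entries in pdb_index.items():
        good = [
            e.pdb_id
            for e in entries
            if lo <= e.ligand_mw <= hi and e.affinity_uM <= max_affinity_uM
        ]
        if good:
            surviving[target] = good

    kept_targets = graph.target_nodes & set(surviving)
    dropped = sorted(graph.target_nodes - kept_targets)
    edges = {(l, t): p for (l, t), p in graph.edges.items() if t in kept_targets}
    diagnostics = dict(graph.diagnostics)
    diagnostics["structural_filter"] = {
        "targets_dropped_no_structure": dropped,
        "pdb_entries_kept": {t: surviving[t] for t in sorted(kept_targets)},
        "mw_range": list(mw_range),
        "max_affinity_uM": max_affinity_uM,
    }
    return InteractomeGraph(
        ligand_nodes={l for (l, _t) in edges},
        target_nodes=kept_targets,
        edges=edges,
        mode="structure_based",
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class TrainingPair:
    input_ref: str  # ligand SMILES, or "pocket:<target>" in structure mode
    output_smiles: str
    shared_target: str


def make_training_pairs(graph: InteractomeGraph, mode: str | None = None) -> list[TrainingPair]:
    """Enumerate training pairs through shared targets, deterministically ordered.

    Ligand mode: all ordered pairs (L_i, L_j), i != j, of ligands sharing a
    target (n ligands -> n(n-1) pairs per target).  Structure mode: one pair
    (pocket of T, L) per edge.
    """
    if graph.is_empty():
        raise ValueError("cannot enumerate training pairs of an empty graph")
    mode = mode or graph.mode
    pairs: list[TrainingPair] = []
    for target in sorted(graph.target_nodes):
        ligands = graph.ligands_of(target)
        if mode.startswith("ligand"):
            for li in ligands:
                for lj in ligands:
                    if li != lj:
                        pairs.append(TrainingPair(li, lj, target))
        else:
            for l in ligands:
                pairs.append(TrainingPair(f"pocket:{target}", l, target))
    return pairs


def read_bioactivity_table(path, sep: str | None = None) -> list[BioactivityRecord]:
    """Load a CSV/TSV with columns smiles,target_id,affinity_nM[,affinity_type,site,pdb_id]."""
    df = pd.read_csv(path, sep=sep, engine="python")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BioactivityRecord(
                ligand_smiles=row.smiles,
                target_id=str(row.target_id),
                affinity_nM=float(row.affinity_nM),
                affinity_type=getattr(row, "affinity_type", "Ki"),
                site=getattr(row, "site", "unknown"),
                pdb_id=getattr(row, "pdb_id", None) or None,
            )
        )
    return records


def write_training_pairs(pairs: list[TrainingPair], path) -> None:
    pd.DataFrame(
        [(p.input_ref, p.output_smiles, p.shared_target) for p in pairs],
        columns=["input_ref", "output_smiles", "shared_target"],
    ).to_csv(path, sep="\t", index=False)


def curate_records(
    records: list[BioactivityRecord],
    min_heavy: int = 3,
    max_heavy: int = 100,
    max_smiles_len: int = 97,
    n_random: int = 5,
    seed: int = 0,
) -> tuple[list[BioactivityRecord], dict]:
    """Wash + length-filter a raw table; returns surviving records and a log."""
    kept: list[BioactivityRecord] = []
    rejected: dict[str, int] = {}
    for rec in records:
        washed = wash_molecule(rec.ligand_smiles, min_heavy=min_heavy, max_heavy=max_heavy)
        if not washed.ok:
            rejected[washed.reason] = rejected.get(washed.reason, 0) + 1
            continue
        if not smiles_length_filter(washed.smiles, n_random=n_random, max_len=max_smiles_len, seed=seed):
            rejected["too_long"] = rejected.get("too_long", 0) + 1
            continue
        kept.append(
            BioactivityRecord(
                ligand_smiles=washed.smiles,
                target_id=rec.target_id,
                affinity_nM=rec.affinity_nM,
                affinity_type=rec.affinity_type,
                site=rec.site,
                pdb_id=rec.pdb_id,
            )
        )
    return kept, {"kept": len(kept), "rejected": rejected}


def canonicalize_or_none(smiles: str) -> str | None:
    return canonical_smiles(smiles)
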