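"""Featurized molecular graphs for the encoder.

Ligands become 2D graphs: one node per heavy atom carrying (atom type, ring
membership, aromaticity, hybridization), edges from covalent bonds.  Protein
binding pockets become 3D graphs: all protein atoms within 5 A of any ligand
atom, each node carrying (element, residue/atom-name combination, distance to
the closest ligand atom, B factor), with radius edges (4 A) whose lengths are
encoded as sine/cosine Fourier features.  All geometry is distance-based, so
pocket graphs are invariant under rigid rotation and translation.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from rdkit import Chem

from .chem import mol_from_smiles

__all__ = [
    "ATOM_TYPES",
    "ELEMENTS_3D",
    "EmptyPocketError",
    "LigandGraph2D",
    "PocketGraph3D",
    "ProteinAtom",
    "build_edges_3d",
    "extract_pocket",
    "featurize_ligand_2d",
    "featurize_pocket",
    "fourier_distance_features",
    "read_pdb",
]

# Ligand 2D vocabulary -------------------------------------------------------

ATOM_TYPES = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
_ATOM_TYPE_IDX = {s: i for i, s in enumerate(ATOM_TYPES)}

_HYBRIDIZATIONS = {
    Chem.HybridizationType.SP3: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP: 2,
    Chem.HybridizationType.S: 3,
    Chem.HybridizationType.UNSPECIFIED: 3,
}

# Pocket 3D vocabulary -------------------------------------------------------

#: 22 element slots: the ligand elements, common protein/cofactor elements,
#: and a reserved "other" slot at the last index.
ELEMENTS_3D = (
    "C", "N", "O", "S", "H", "P", "F", "Cl", "Br", "I",
    "Se", "Zn", "Mg", "Ca", "Fe", "Mn", "Na", "K", "Cu", "Ni", "Co",
    "other",
)
_ELEMENT_3D_IDX = {s: i for i, s in enumerate(ELEMENTS_3D)}
OTHER_ELEMENT_IDX = len(ELEMENTS_3D) - 1

_BACKBONE = ("N", "CA", "C", "O")
_SIDECHAINS = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "PRO": ("CB", "CG", "CD"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "MET": ("CB", "CG", "SD", "CE"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: Frozen (residue, atom-name) vocabulary: 167 standard heavy-atom
#: combinations of the 20 amino acids, a terminal-OXT slot, then reserved
#: slots up to a fixed size of 225 with "other" at the last index.
AA_ATOM_VOCAB: tuple[tuple[str, str], ...] = tuple(
    (res, atom)
    for res in sorted(_SIDECHAINS)
    for atom in _BACKBONE + _SIDECHAINS[res]
) + (("ANY", "OXT"),)
AA_ATOM_VOCAB_SIZE = 225
_AA_ATOM_IDX = {pair: i for i, pair in enumerate(AA_ATOM_VOCAB)}
OTHER_AA_ATOM_IDX = AA_ATOM_VOCAB_SIZE - 1

assert len(AA_ATOM_VOCAB) < AA_ATOM_VOCAB_SIZE


def aa_atom_index(res_name: str, atom_name: str) -> int:
    """Index of a (residue, atom-name) combination; unknowns map to "other"."""
    res_name, atom_name = res_name.upper(), atom_name.upper()
    if atom_name == "OXT":
        return _AA_ATOM_IDX[("ANY", "OXT")]
    return _AA_ATOM_IDX.get((res_name, atom_name), OTHER_AA_ATOM_IDX)


# Ligand 2D graphs -----------------------------------------------------------


@dataclass
class LigandGraph2D:
    atom_type_idx: np.ndarray  # (n,) int in 0..9
    ring_flag: np.ndarray      # (n,) int in {0,1}
    aromatic_flag: np.ndarray  # (n,) int in {0,1}
    hybridization_idx: np.ndarray  # (n,) int in 0..3
    edges: np.ndarray          # (m, 2) int, i < j, each covalent bond once

    @property
    def n_atoms(self) -> int:
        return len(self.atom_type_idx)


def featurize_ligand_2d(mol: "Chem.Mol | str", explicit_h: bool = False) -> LigandGraph2D:
    """2D graph of a washed molecule: heavy atoms by default (H optional).

    Raises ValueError naming the element if an atom falls outside the 10-type
    vocabulary [H, C, N, O, F, P, S, Cl, Br, I].
    """
    if isinstance(mol, str):
        parsed = mol_from_smiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    if explicit_h:
        mol = Chem.AddHs(mol)
    atom_type, ring, arom, hyb = [], [], [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _ATOM_TYPE_IDX:
            raise ValueError(f"atom type {sym!r} outside the supported element list {ATOM_TYPES}")
        atom_type.append(_ATOM_TYPE_IDX[sym])
        ring.append(int(atom.IsInRing()))
        arom.append(int(atom.GetIsAromatic()))
        hyb.append(_HYBRIDIZATIONS.get(atom.GetHybridization(), 3))
    edges = sorted(
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()
    )
    return LigandGraph2D(
        atom_type_idx=np.array(atom_type, dtype=np.int64),
        ring_flag=np.array(ring, dtype=np.int64),
        aromatic_flag=np.array(arom, dtype=np.int64),
        hybridization_idx=np.array(hyb, dtype=np.int64),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
    )


# Pocket extraction and 3D graphs -------------------------------------------


@dataclass(frozen=True)
class ProteinAtom:
    element: str
    res_name: str
    atom_name: str
    coord: tuple[float, float, float]
    b_factor: float
    dist_to_ligand: float | None = None


class EmptyPocketError(ValueError):
    """No protein atom within the pocket radius: wrong ligand/structure pairing."""


def extract_pocket(
    protein_atoms: list[ProteinAtom],
    ligand_coords: np.ndarray,
    radius: float = 5.0,
) -> list[ProteinAtom]:
    """Protein atoms whose minimum distance to any ligand atom is <= radius.

    The boundary is inclusive; each surviving atom is annotated with that
    minimum distance.
    """
    ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    if len(ligand_coords) == 0:
        raise ValueError("ligand_coords must be nonempty")
    if not protein_atoms:
        raise EmptyPocketError("no protein atoms supplied")
    coords = np.array([a.coord for a in protein_atoms], dtype=float)
    dmin = cKDTree(ligand_coords).query(coords)[0]
    kept = [
        ProteinAtom(a.element, a.res_name, a.atom_name, a.coord, a.b_factor, float(d))
        for a, d in zip(protein_atoms, dmin)
        if d <= radius
    ]
    if not kept:
        raise EmptyPocketError(
            f"no protein atom within {radius} A of the ligand "
            f"(closest at {dmin.min():.2f} A)"
        )
    return kept


def build_edges_3d(coords: np.ndarray, radius: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """All unordered atom pairs within `radius` (inclusive), with distances."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("need at least one atom")
    # KD-tree pair query is exclusive-prone at the boundary; pad then verify.
    pairs = sorted(cKDTree(coords).query_pairs(radius * (1 + 1e-9)))
    edges, dists = [], []
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= radius * (1 + 1e-12):
            edges.append((i, j))
            dists.append(d)
    return np.array(edges, dtype=np.int64).reshape(-1, 2), np.array(dists)


def fourier_distance_features(
    d, n_freq: int = 8, d_cut: float = 4.0
) -> np.ndarray:
    """Sine/cosine encoding of an inter-atomic distance.

    Frequency ladder omega_k = k*pi/d_cut for k = 1..n_freq; output is
    [sin(w_1 d), cos(w_1 d), ..., sin(w_n d), cos(w_n d)] (length 2*n_freq),
    smooth in d.  Accepts a scalar or an array of distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if n_freq < 1:
        raise ValueError("n_freq must be >= 1")
    k = np.arange(1, n_freq + 1)
    omega = k * np.pi / d_cut
    phase = d[..., None] * omega
    out = np.empty(d.shape + (2 * n_freq,))
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out


@dataclass
class PocketGraph3D:
    element_idx: np.ndarray     # (n,) int in 0..21
    aa_atom_idx: np.ndarray     # (n,) int in 0..224
    dist_to_ligand: np.ndarray  # (n,) Angstrom
    b_factor: np.ndarray        # (n,) Angstrom^2
    coords: np.ndarray          # (n, 3) Angstrom
    edges: np.ndarray           # (m, 2) int
    edge_dist: np.ndarray       # (m,) Angstrom
    edge_fourier: np.ndarray    # (m, 2*n_freq)
    n_freq: int = 8

    @property
    def n_atoms(self) -> int:
        return len(self.element_idx)

    def to_json(self) -> str:
        return json.dumps(
            {
                "element_idx": self.element_idx.tolist(),
                "aa_atom_idx": self.aa_atom_idx.tolist(),
                "dist_to_ligand": self.dist_to_ligand.tolist(),
                "b_factor": self.b_factor.tolist(),
                "coords": self.coords.tolist(),
                "edges": self.edges.tolist(),
                "edge_dist": self.edge_dist.tolist(),
                "edge_fourier": self.edge_fourier.tolist(),
                "n_freq": self.n_freq,
            }
        )

    @staticmethod
    def from_json(s: str) -> "PocketGraph3D":
        d = json.loads(s)
        return PocketGraph3D(
            element_idx=np.array(d["element_idx"], dtype=np.int64),
            aa_atom_idx=np.array(d["aa_atom_idx"], dtype=np.int64),
            dist_to_ligand=np.array(d["dist_to_ligand"], dtype=float),
            b_factor=np.array(d["b_factor"], dtype=float),
            coords=np.array(d["coords"], dtype=float).reshape(-1, 3),
            edges=np.array(d["edges"], dtype=np.int64).reshape(-1, 2),
            edge_dist=np.array(d["edge_dist"], dtype=float),
            edge_fourier=np.array(d["edge_fourier"], dtype=float),
            n_freq=int(d["n_freq"]),
        )


def featurize_pocket(
    pocket_atoms: list[ProteinAtom],
    ligand_coords: np.ndarray,
    edge_radius: float = 4.0,
    n_freq: int = 8,
) -> PocketGraph3D:
    """3D pocket graph from atoms selected by :func:`extract_pocket`."""
    if not pocket_atoms:
        raise EmptyPocketError("empty pocket")
    ligand_coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    coords = np.array([a.coord for a in pocket_atoms], dtype=float)
    dmin = cKDTree(ligand_coords).query(coords)[0]

    element_idx = []
    unknown_elements = set()
    for a in pocket_atoms:
        sym = a.element.capitalize()
        idx = _ELEMENT_3D_IDX.get(sym, OTHER_ELEMENT_IDX)
        if idx == OTHER_ELEMENT_IDX and sym != "Other":
            unknown_elements.add(sym)
        element_idx.append(idx)
    if unknown_elements:
        warnings.warn(f"elements mapped to 'other': {sorted(unknown_elements)}")

    aa_idx = np.array(
        [aa_atom_index(a.res_name, a.atom_name) for a in pocket_atoms], dtype=np.int64
    )
    edges, edge_dist = build_edges_3d(coords, radius=edge_radius)
    fourier = (
        fourier_distance_features(edge_dist, n_freq=n_freq, d_cut=edge_radius)
        if len(edge_dist)
        else np.zeros((0, 2 * n_freq))
    )
    return PocketGraph3D(
        element_idx=np.array(element_idx, dtype=np.int64),
        aa_atom_idx=aa_idx,
        dist_to_ligand=dmin.astype(float),
        b_factor=np.array([a.b_factor for a in pocket_atoms], dtype=float),
        coords=coords,
        edges=edges,
        edge_dist=edge_dist,
        edge_fourier=fourier,
        n_freq=n_freq,
    )


# PDB input ------------------------------------------------------------------

_STANDARD_RESNAMES = set(_SIDECHAINS)


def read_pdb(source: str, ligand_resname: str | None = None):
    """Read ATOM/HETATM records from a PDB file path or raw text.

    Returns (protein_atoms, ligand_coords) where ligand_coords collects the
    HETATM coordinates of `ligand_resname` (None if not requested).  For
    disordered atoms the highest-occupancy alternate location is kept.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    handle = io.StringIO(source) if "\n" in source else source
    structure = parser.get_structure("s", handle)

    protein_atoms: list[ProteinAtom] = []
    ligand_coords: list[list[float]] = []
    for residue in structure.get_residues():
        hetfield = residue.id[0]
        resname = residue.get_resname().strip()
        for atom in residue.get_list():
            # a DisorderedAtom proxies its highest-occupancy altloc child
            if hetfield == " " and resname in _STANDARD_RESNAMES:
                protein_atoms.append(
                    ProteinAtom(
                        element=atom.element.capitalize() if atom.element else atom.get_name()[0],
                        res_name=resname,
                        atom_name=atom.get_name(),
                        coord=tuple(float(x) for x in atom.coord),
                        b_factor=float(atom.get_bfactor()),
                    )
                )
            elif ligand_resname is not None and resname == ligand_resname:
                ligand_coords.append([float(x) for x in atom.coord])
    coords = np.array(ligand_coords, dtype=float).reshape(-1, 3)
    return protein_atoms, coords


def ligand_coords_from_sdf(sdf_text_or_path: str) -> np.ndarray:
    """Heavy-atom coordinates of the first molecule in an SDF file or text."""
    if "\n" in sdf_text_or_path:
        supplier = Chem.SDMolSupplier()
        supplier.SetData(sdf_text_or_path, removeHs=True)
    else:
        supplier = Chem.SDMolSupplier(sdf_text_or_path, removeHs=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError("no parseable molecule in SDF input")
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
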