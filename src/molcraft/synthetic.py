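"""Seeded synthetic data: interactomes, property-labelled molecules, pockets.

Every generator here is a pure function of its spec + seed, so the rest of
the package is testable without any database download.  Ligand families are
built by decorating ring scaffolds with a fixed substituent grammar
(halogens, small alkyls, OH/NH2/OMe, acids/amides/nitriles), which
guarantees chemical validity and scaffold control: ligands of the same
target share a scaffold, ligands of different targets mostly do not.

Affinities are drawn log-uniformly over a configurable range with a
requested fraction falling above the 200 nM interactome cutoff, emulating
the shape of a curated bioactivity extract at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import canonical_smiles, ecfp4_512, mol_from_smiles
from .generator import PropertyWishlist
from .interactome import BioactivityRecord
from .pipeline import property_profile

__all__ = [
    "SyntheticSpec",
    "SyntheticPocket",
    "PropertyRecord",
    "gen_interactome",
    "gen_property_set",
    "gen_pocket",
    "gen_qsar_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_targets: int = 5
    ligands_per_target: int = 8
    scaffold_pool_size: int = 8
    affinity_range_nM: tuple[float, float] = (1.0, 2000.0)
    frac_above_cutoff: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.n_targets, self.ligands_per_target, self.scaffold_pool_size) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.frac_above_cutoff <= 1.0:
            raise ValueError("frac_above_cutoff must be in [0, 1]")


#: Ring scaffolds with one substitution slot ({}) — all decorations verified
#: parseable at generation time.
SCAFFOLD_TEMPLATES = (
    "c1ccc({})cc1",        # benzene
    "c1ccc({})nc1",        # pyridine
    "c1cc({})cs1",         # thiophene
    "c1cc({})co1",         # furan
    "c1cc({})c[nH]1",      # pyrrole
    "C1CCC({})CC1",        # cyclohexane
    "C1CCC({})NC1",        # piperidine
    "c1ccc2cc({})ccc2c1",  # naphthalene
)

SUBSTITUENTS = (
    "C", "CC", "CCC", "CC(C)C", "O", "OC", "OCC", "N", "NC",
    "F", "Cl", "Br", "C(=O)O", "C(=O)N", "C#N", "CO", "CN", "CCO", "CCN", "S",
)


def _decorate(template: str, sub: str) -> str | None:
    return canonical_smiles(template.format(sub))


def gen_interactome(spec: SyntheticSpec) -> list[BioactivityRecord]:
    """Bioactivity table for a small synthetic interactome.

    Each target owns one scaffold from the pool; its ligands are distinct
    single-substituent decorations of that scaffold.  Affinities are
    log-uniform over `affinity_range_nM` with `frac_above_cutoff` of each
    target's records placed above 200 nM.
    """
    rng = np.random.default_rng(spec.seed)
    pool = SCAFFOLD_TEMPLATES[: min(spec.scaffold_pool_size, len(SCAFFOLD_TEMPLATES))]
    if spec.ligands_per_target > len(SUBSTITUENTS):
        raise ValueError(
            f"cannot enumerate {spec.ligands_per_target} distinct ligands per target "
            f"(max {len(SUBSTITUENTS)} with the fixed substituent grammar)"
        )
    cutoff = 200.0
    lo, hi = spec.affinity_range_nM
    records: list[BioactivityRecord] = []
    for t in range(spec.n_targets):
        template = pool[t % len(pool)]
        ligands = []
        for sub in SUBSTITUENTS:
            smi = _decorate(template, sub)
            if smi is not None and smi not in ligands:
                ligands.append(smi)
            if len(ligands) == spec.ligands_per_target:
                break
        if len(ligands) < spec.ligands_per_target:
            raise ValueError(f"scaffold {template!r} yields too few valid decorations")
        n_above = int(round(spec.frac_above_cutoff * len(ligands)))
        above = set(rng.choice(len(ligands), size=n_above, replace=False).tolist())
        for i, smi in enumerate(ligands):
            if i in above and hi > cutoff:
                log_aff = rng.uniform(np.log10(max(cutoff * 1.001, lo)), np.log10(hi))
            else:
                log_aff = rng.uniform(np.log10(lo), np.log10(min(cutoff, hi)))
            records.append(
                BioactivityRecord(
                    ligand_smiles=smi,
                    target_id=f"T{t:03d}",
                    affinity_nM=float(10 ** log_aff),
                    affinity_type="Ki",
                    site="orthosteric",
                )
            )
    return records


# -- property-labelled molecules ---------------------------------------------

_RING_PREFIXES = ("", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccc2ccccc2c1")
_TERMINALS = ("", "O", "N", "Cl", "OC", "C(=O)O", "C(=O)N", "C#N")
_MAX_CHAIN = 14


@dataclass(frozen=True)
class PropertyRecord:
    smiles: str
    profile: PropertyWishlist   # computed from the structure
    wishlist: PropertyWishlist  # equals the profile by construction


def gen_property_set(n: int, seed: int = 0) -> list[PropertyRecord]:
    """`n` molecules spanning a wide property range, labelled with their own
    computed profiles (a perfect property-conditioned generator reaches
    Pearson r = 1 on this set).

    Molecules are ring-prefix + alkyl-chain + terminal-group combinations;
    molecular weight spans well over 200 g/mol across the set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PropertyRecord] = []
    while len(records) < n:
        ring = _RING_PREFIXES[rng.integers(len(_RING_PREFIXES))]
        chain_len = int(rng.integers(1, _MAX_CHAIN + 1))
        if not ring and chain_len < 2:
            chain_len = 2
        terminal = _TERMINALS[rng.integers(len(_TERMINALS))]
        smi = canonical_smiles(ring + "C" * chain_len + terminal)
        if smi is None:
            continue
        profile = property_profile(smi)
        records.append(PropertyRecord(smiles=smi, profile=profile, wishlist=profile))
    return records


# -- toy pocket structure -----------------------------------------------------

# Pocket geometry fixed by construction: the ligand (ethanol-like, 3 heavy
# atoms) sits near the origin; exactly 7 protein atoms lie within 5 A of a
# ligand atom and exactly 2 of their pairwise distances are <= 4 A
# (P1-P2 and P2-P3, both 3.0 A).  All remaining protein atoms are > 25 A away.
_LIGAND_COORDS = ((0.0, 0.0, 0.0), (1.4, 0.0, 0.0), (2.4, 1.0, 0.0))
_POCKET_COORDS = (
    (0.0, 3.0, 0.0),    # P1
    (3.0, 3.0, 0.0),    # P2
    (3.0, 0.0, 0.0),    # P3
    (0.0, 0.0, 3.0),    # P4
    (0.0, -3.0, 0.0),   # P5
    (-3.0, 0.0, 0.0),   # P6
    (0.0, 0.0, -3.0),   # P7
)
N_POCKET_EXPECTED = 7
N_POCKET_EDGES_EXPECTED = 2

# residue layout: GLY backbone takes P1-P4; SER N/CA/C take P5-P7 and its
# O/CB/OG are remote; ALA is entirely remote.
_RESIDUES = (
    ("GLY", ("N", "CA", "C", "O")),
    ("SER", ("N", "CA", "C", "O", "CB", "OG")),
    ("ALA", ("N", "CA", "C", "O", "CB")),
)
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O"}


@dataclass(frozen=True)
class SyntheticPocket:
    pdb_text: str
    sdf_text: str
    n_pocket_expected: int
    n_pocket_edges_expected: int
    ligand_coords: np.ndarray


def gen_pocket(seed: int = 0) -> SyntheticPocket:
    """PDB text (mini-protein with B factors) + ligand SDF with known geometry."""
    rng = np.random.default_rng(seed)
    near = list(_POCKET_COORDS)
    lines = []
    serial = 0
    atom_idx = 0
    far_idx = 0
    for res_seq, (res_name, atom_names) in enumerate(_RESIDUES, start=1):
        for name in atom_names:
            serial += 1
            if atom_idx < len(near):
                x, y, z = near[atom_idx]
            else:
                # remote filler atoms on a 3 A-spaced line far from the ligand
                x, y, z = 30.0 + 3.0 * far_idx, 30.0, 30.0
                far_idx += 1
            atom_idx += 1
            b = round(float(rng.uniform(10.0, 50.0)), 2)
            element = _ELEMENT_OF[name]
            lines.append(
                f"ATOM  {serial:5d} {' ' + name:<4s} {res_name:3s} A{res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          {element:>2s}"
            )
    for i, (x, y, z) in enumerate(_LIGAND_COORDS, start=1):
        serial += 1
        element = "O" if i == 3 else "C"
        lines.append(
            f"HETATM{serial:5d} {' ' + element + str(i):<4s} LIG A{99:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}          {element:>2s}"
        )
    pdb_text = "\n".join(lines) + "\nEND\n"

    sdf_lines = [
        "ligand", "  molcraft synthetic pocket ligand", "",
        "  3  2  0  0  0  0  0  0  0  0999 V2000",
    ]
    elements = ("C", "C", "O")
    for (x, y, z), el in zip(_LIGAND_COORDS, elements):
        sdf_lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    sdf_lines += ["  1  2  1  0", "  2  3  1  0", "M  END", "$$$$"]
    return SyntheticPocket(
        pdb_text=pdb_text,
        sdf_text="\n".join(sdf_lines) + "\n",
        n_pocket_expected=N_POCKET_EXPECTED,
        n_pocket_edges_expected=N_POCKET_EDGES_EXPECTED,
        ligand_coords=np.array(_LIGAND_COORDS),
    )


# -- synthetic structure-activity data ----------------------------------------


def gen_qsar_dataset(n: int, seed: int = 0, noise_sd: float = 0.2):
    """Synthetic structure-activity data: pActivity is a smooth linear
    function of the ECFP descriptor plus Gaussian noise.

    Returns (smiles, X (n, 512) float, y (n,)).  Used to test that KRR
    recovers the underlying landscape to within the label noise.
    """
    rng = np.random.default_rng(seed)
    mols = gen_property_set(n, seed=seed + 1)
    X = np.array([ecfp4_512(mol_from_smiles(r.smiles)) for r in mols], dtype=float)
    w = rng.normal(0.0, 1.0, size=X.shape[1])
    raw = X @ w
    # scale the landscape to a pActivity-like range around 7 +/- 1
    y_clean = 7.0 + (raw - raw.mean()) / max(raw.std(), 1e-9)
    y = y_clean + rng.normal(0.0, noise_sd, size=n)
    return [r.smiles for r in mols], X, y
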