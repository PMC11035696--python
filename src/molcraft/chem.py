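"""Shared cheminformatics helpers: one canonicalization dialect for the repo.

Uniqueness and novelty throughout the package are defined on the canonical
SMILES produced here (RDKit canonical writer, no explicit H, isomeric).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")  # parse failures are data, not console noise

_ECFP4_512 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=512)


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string; returns None on failure instead of raising."""
    if not isinstance(smiles, str) or not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical form under the repo-wide dialect, or None if unparseable."""
    mol = mol_from_smiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def randomized_smiles(smiles: str, n: int, seed: int = 0) -> list[str]:
    """`n` randomized (non-canonical) SMILES renderings, deterministic per seed."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return list(Chem.MolToRandomSmilesVect(mol, n, randomSeed=seed))


def ecfp4_512(mol: Chem.Mol):
    """512-bit ECFP4 (Morgan radius 2) as a numpy uint8 array."""
    return _ECFP4_512.GetFingerprintAsNumPy(mol).astype("uint8")
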