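"""Design scoring: descriptors, kernel ridge regression QSAR, novelty.

Three descriptor spaces cover complementary notions of similarity: ECFP4
(512-bit circular substructure fingerprint) for exact structural features,
CATS (pharmacophore-pair counts over topological distances) and USRCAT
(rotation-invariant 3D shape moments) for "fuzzy" similarity.

Bioactivity is estimated by kernel ridge regression with a Laplacian kernel
k(x_i, x_j) = exp(-||x_i - x_j||_1 / sigma) on the pActivity scale
(-log10 molar): alpha = (K + lambda*I)^-1 y and
y_hat(x_q) = sum_i alpha_i k(x_i, x_q), with sigma = 51.2 and
lambda = 1e-7 as defaults.

Novelty of a design against the training set combines a structural term
(Jaccard distance of its ECFP to the nearest training fingerprint, in
[0, 1]) and two scaffold terms worth 0.1 each (atom a.k.a. Murcko scaffold,
and carbon scaffold/skeleton, scoring 0.1 when absent from the training
scaffold sets).  The total ranges from 0 (training-set member) to 1.2
(no shared bits, both scaffolds unseen).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import ecfp4_512, mol_from_smiles

__all__ = [
    "DescriptorVector",
    "NoveltyIndex",
    "NoveltyReport",
    "QSARModel",
    "atom_scaffold",
    "carbon_scaffold",
    "compute_descriptor",
    "jaccard_distance",
    "krr_fit",
    "krr_predict",
    "laplacian_kernel",
    "novelty_score",
    "qsar_ensemble_score",
    "synthesizability",
]

DESCRIPTOR_KINDS = ("ECFP4_512", "CATS_abs", "USRCAT")

# CATS: 6 pharmacophore types -> 21 unordered type pairs x 10 topological
# distance bins (0..9 bonds, longer paths clipped into the last bin) = 210
# absolute counts.
CATS_TYPES = ("D", "A", "P", "N", "L", "R")
CATS_N_BINS = 10
_CATS_FAMILY_MAP = {
    "Donor": "D",
    "Acceptor": "A",
    "PosIonizable": "P",
    "NegIonizable": "N",
    "Hydrophobe": "L",
    "Aromatic": "R",
}
_CATS_PAIRS = [
    (CATS_TYPES[i], CATS_TYPES[j])
    for i in range(len(CATS_TYPES))
    for j in range(i, len(CATS_TYPES))
]
_CATS_PAIR_IDX = {p: k for k, p in enumerate(_CATS_PAIRS)}

_FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
    os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
)

USRCAT_CONFORMER_SEED = 7  # frozen ETKDG seed for the single conformer


@dataclass(frozen=True)
class DescriptorVector:
    kind: str
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, str):
        parsed = mol_from_smiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        return parsed
    return mol


def cats_atom_types(mol) -> dict[int, set[str]]:
    """Pharmacophore types per atom under the frozen feature definitions."""
    mol = _as_mol(mol)
    types: dict[int, set[str]] = {}
    for feat in _FEATURE_FACTORY.GetFeaturesForMol(mol):
        code = _CATS_FAMILY_MAP.get(feat.GetFamily())
        if code is None:
            continue
        for aid in feat.GetAtomIds():
            types.setdefault(aid, set()).add(code)
    return types


def compute_descriptor(mol, kind: str, conformer_seed: int = USRCAT_CONFORMER_SEED) -> DescriptorVector:
    """Deterministic descriptor vector of the requested kind.

    USRCAT embeds a single seeded ETKDG conformer internally; conformer
    failure raises an error naming the molecule.
    """
    mol = _as_mol(mol)
    if kind == "ECFP4_512":
        return DescriptorVector(kind, ecfp4_512(mol).astype(float))
    if kind == "CATS_abs":
        types = cats_atom_types(mol)
        dmat = Chem.GetDistanceMatrix(mol)
        counts = np.zeros(len(_CATS_PAIRS) * CATS_N_BINS)
        order = {t: i for i, t in enumerate(CATS_TYPES)}
        atoms = sorted(types)
        for ii, a in enumerate(atoms):
            for b in atoms[ii:]:
                d = int(min(dmat[a, b], CATS_N_BINS - 1))
                for ta in types[a]:
                    for tb in types[b]:
                        if a == b and order[ta] >= order[tb]:
                            continue  # same atom: each unordered type pair once
                        pair = (ta, tb) if order[ta] <= order[tb] else (tb, ta)
                        counts[_CATS_PAIR_IDX[pair] * CATS_N_BINS + d] += 1
        return DescriptorVector(kind, counts)
    if kind == "USRCAT":
        mh = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = conformer_seed
        if AllChem.EmbedMolecule(mh, params) != 0:
            raise ValueError(f"conformer generation failed for {Chem.MolToSmiles(mol)}")
        return DescriptorVector(kind, np.array(rdMolDescriptors.GetUSRCAT(mh)))
    raise ValueError(f"unknown descriptor kind {kind!r}")


# -- kernel ridge regression --------------------------------------------------


def laplacian_kernel(x_i: np.ndarray, x_j: np.ndarray, sigma: float = 51.2) -> float:
    """exp(-||x_i - x_j||_1 / sigma); 1 iff the vectors coincide."""
    x_i, x_j = np.asarray(x_i, float), np.asarray(x_j, float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"length mismatch: {x_i.shape} vs {x_j.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(np.exp(-np.abs(x_i - x_j).sum() / sigma))


@dataclass
class QSARModel:
    kind: str
    X_train: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    sigma: float = 51.2
    lam: float = 1e-7


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(A, B, metric="cityblock") / sigma)


def krr_fit(X: np.ndarray, y: np.ndarray, sigma: float = 51.2, lam: float = 1e-7,
            kind: str = "ECFP4_512") -> QSARModel:
    """Fit alpha = (K + lambda*I)^-1 y; verifies the residual to 1e-8 relative."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) != len(y) or len(y) < 1:
        raise ValueError("need equally many descriptors and labels (>= 1)")
    K = _kernel_matrix(X, X, sigma)
    A = K + lam * np.eye(len(y))
    try:
        alpha = np.linalg.solve(A, y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular kernel system (duplicated descriptor rows at lambda = 0?); "
            "use a positive ridge strength lambda"
        ) from err
    residual = np.linalg.norm(A @ alpha - y)
    if residual > 1e-8 * max(1.0, np.linalg.norm(y)):
        raise np.linalg.LinAlgError(
            f"kernel solve residual {residual:.2e} exceeds tolerance; "
            "increase lambda for a better-conditioned system"
        )
    return QSARModel(kind=kind, X_train=X, y=y, alpha=alpha, sigma=sigma, lam=lam)


def krr_predict(model: QSARModel, x_q) -> float | np.ndarray:
    """y_hat(x_q) = sum_i alpha_i k(x_i, x_q) on the pActivity scale."""
    if isinstance(x_q, DescriptorVector):
        if x_q.kind != model.kind:
            raise ValueError(f"descriptor kind mismatch: model {model.kind}, query {x_q.kind}")
        x_q = x_q.values
    x_q = np.asarray(x_q, float)
    single = x_q.ndim == 1
    Q = x_q.reshape(1, -1) if single else x_q
    preds = _kernel_matrix(Q, model.X_train, model.sigma) @ model.alpha
    return float(preds[0]) if single else preds


# -- novelty ------------------------------------------------------------------


def jaccard_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on binary fingerprints (1 - Tanimoto)."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero fingerprints")
    return float(1.0 - np.logical_and(a, b).sum() / union)


EMPTY_SCAFFOLD = ""  # sentinel for acyclic molecules


def atom_scaffold(mol) -> str:
    """Murcko scaffold (rings + linkers, substituents removed) as canonical
    SMILES; acyclic molecules yield the empty-scaffold sentinel."""
    mol = _as_mol(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


def carbon_scaffold(mol) -> str:
    """Carbon skeleton: the atom scaffold with every heavy atom turned into
    carbon and every bond into a single bond, canonicalized."""
    mol = _as_mol(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    try:
        generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    except Exception:
        # fall back to manual collapse for exotic valences
        rw = Chem.RWMol(scaffold)
        for atom in rw.GetAtoms():
            atom.SetAtomicNum(6)
            atom.SetFormalCharge(0)
            atom.SetIsAromatic(False)
            atom.SetNoImplicit(False)
        for bond in rw.GetBonds():
            bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)
        generic = rw.GetMol()
        Chem.SanitizeMol(generic)
    return Chem.MolToSmiles(generic)


class NoveltyIndex:
    """Training-set fingerprints and scaffold sets for novelty scoring.

    The nearest-neighbour search is an exact linear scan (vectorized); any
    accelerated search must return identical results.
    """

    def __init__(self, training_smiles: list[str]):
        if not training_smiles:
            raise ValueError("empty training index")
        self.smiles: list[str] = []
        fps = []
        self.atom_scaffolds: set[str] = set()
        self.carbon_scaffolds: set[str] = set()
        for s in training_smiles:
            mol = _as_mol(s)
            self.smiles.append(Chem.MolToSmiles(mol))
            fps.append(ecfp4_512(mol))
            self.atom_scaffolds.add(atom_scaffold(mol))
            self.carbon_scaffolds.add(carbon_scaffold(mol))
        self.fps = np.array(fps, dtype=np.int64)
        self._popcount = self.fps.sum(axis=1)

    def nearest(self, fp: np.ndarray) -> tuple[float, int]:
        """(Jaccard distance, index) of the closest training fingerprint."""
        fp = np.asarray(fp, dtype=np.int64)
        inter = self.fps @ fp
        union = self._popcount + fp.sum() - inter
        dist = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)
        i = int(np.argmin(dist))
        return float(dist[i]), i


@dataclass(frozen=True)
class NoveltyReport:
    s_ecfp: float
    s_atom: float
    s_carbon: float
    nearest_training_neighbor: str

    @property
    def s_scaffold(self) -> float:
        return self.s_atom + self.s_carbon

    @property
    def s_novelty(self) -> float:
        return self.s_ecfp + self.s_atom + self.s_carbon


def novelty_score(mol, index: NoveltyIndex) -> NoveltyReport:
    """Combined novelty in [0, 1.2]; 0 for training members, 1.2 at the ceiling."""
    mol = _as_mol(mol)
    d, i = index.nearest(ecfp4_512(mol))
    s_atom = 0.0 if atom_scaffold(mol) in index.atom_scaffolds else 0.1
    s_carbon = 0.0 if carbon_scaffold(mol) in index.carbon_scaffolds else 0.1
    return NoveltyReport(
        s_ecfp=d, s_atom=s_atom, s_carbon=s_carbon,
        nearest_training_neighbor=index.smiles[i],
    )


# -- ensemble + synthesizability ----------------------------------------------


def qsar_ensemble_score(
    mol,
    models: dict[str, QSARModel],
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted-mean ensemble pActivity across the three descriptor models.

    Default weights double the ECFP contribution: (2*y_ECFP + y_CATS +
    y_USRCAT) / 4.
    """
    weights = weights or {"ECFP4_512": 2.0, "CATS_abs": 1.0, "USRCAT": 1.0}
    missing = set(weights) - set(models)
    if missing:
        raise ValueError(f"missing QSAR models for {sorted(missing)}")
    mol = _as_mol(mol)
    num, den = 0.0, 0.0
    for kind, w in weights.items():
        pred = krr_predict(models[kind], compute_descriptor(mol, kind))
        num += w * pred
        den += w
    return num / den


def _stub_synthesizability(mol: Chem.Mol) -> float:
    """Heuristic stand-in for a retrosynthetic-accessibility classifier.

    Fragment-complexity penalty scaled to [0, 1]: large molecules, many rings,
    stereocentres, spiro/bridgehead atoms and macrocycles score lower.  This
    is NOT the published RAScore model; it exists so the pipeline runs
    end-to-end without the external dependency.
    """
    ri = mol.GetRingInfo()
    n_heavy = mol.GetNumHeavyAtoms()
    n_rings = ri.NumRings()
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_macro = sum(1 for ring in ri.AtomRings() if len(ring) > 8)
    penalty = (
        0.02 * max(0, n_heavy - 25)
        + 0.08 * max(0, n_rings - 3)
        + 0.05 * n_stereo
        + 0.15 * (n_spiro + n_bridge)
        + 0.25 * n_macro
    )
    return float(np.clip(1.0 - penalty, 0.0, 1.0))


def synthesizability(mol, scorer=None, use_stub: bool = True) -> float:
    """Synthesizability in [0, 1] via a pluggable scorer.

    A registered `scorer(mol) -> float` (e.g. an external retrosynthetic
    accessibility model) takes precedence; otherwise the documented heuristic
    stub is used unless disabled.
    """
    mol = _as_mol(mol)
    if scorer is not None:
        return float(scorer(mol))
    if not use_stub:
        raise ValueError("no synthesizability scorer registered and stub disabled")
    return _stub_synthesizability(mol)
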