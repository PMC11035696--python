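"""End-to-end design workflow: generate, score, filter, rank, report.

`run_design_campaign` strings the stages together — sample from a trained
generator, parse and deduplicate, score (properties, novelty, QSAR,
synthesizability), filter (molecular weight, synthesizability, novelty) and
rank survivors by their ensemble QSAR objective — writing a designs CSV, a
library report JSON and a structured run log, reproducibly from config +
seed.

`library_report` computes the virtual-library quality metrics: fractions of
valid/unique/novel molecules, criterion pass rates (novelty >= 0.65 by
default, synthesizability >= 0.5, predicted affinity <= 1 uM i.e. ensemble
pActivity >= 6), within-library diversity (mean pairwise Jaccard distance on
ECFP) and scaffold uniqueness/novelty percentages.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import ecfp4_512, mol_from_smiles
from .generator import PropertyWishlist, sample
from .scoring import (
    NoveltyIndex,
    NoveltyReport,
    QSARModel,
    atom_scaffold,
    carbon_scaffold,
    jaccard_distance,
    krr_predict,
    compute_descriptor,
    novelty_score,
    qsar_ensemble_score,
    synthesizability,
)

__all__ = [
    "DesignCandidate",
    "LibraryReport",
    "evaluate_translation",
    "filter_and_rank",
    "library_report",
    "load_campaign_config",
    "property_profile",
    "run_design_campaign",
]


def property_profile(mol) -> PropertyWishlist:
    """The six physicochemical properties of a parsed molecule.

    Conventions are fixed: average molecular weight, strict rotatable-bond
    count, Lipinski-style H-bond acceptor/donor counts, topological polar
    surface area, and atom-contribution (Crippen) logP.
    """
    if isinstance(mol, str):
        parsed = mol_from_smiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    return PropertyWishlist(
        mw=Descriptors.MolWt(mol),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
        logp=Crippen.MolLogP(mol),
    )


def evaluate_translation(actual: np.ndarray, wished: np.ndarray) -> dict:
    """Property-translation accuracy of a generated set.

    For paired vectors of actual (computed from the generated structures) and
    wished values: MAE = mean |actual - wished|; MAD = mean absolute
    deviation of the actuals from their own mean; MAD/MAE (how many times
    better than predicting the mean); Pearson r.  r is None when either side
    has zero variance.
    """
    actual = np.asarray(actual, float)
    wished = np.asarray(wished, float)
    if actual.shape != wished.shape or actual.ndim != 1 or len(actual) < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 entries")
    mae = float(np.abs(actual - wished).mean())
    mad = float(np.abs(actual - actual.mean()).mean())
    if actual.std() == 0 or wished.std() == 0:
        r = None
    else:
        r = float(np.corrcoef(actual, wished)[0, 1])
    return {
        "mae": mae,
        "mad": mad,
        "mad_over_mae": (mad / mae) if mae > 0 else float("inf"),
        "pearson_r": r,
    }


@dataclass
class DesignCandidate:
    smiles: str | None          # canonical form (None for invalid strings)
    raw: str                    # string as sampled
    valid: bool
    unique: bool = False
    properties: PropertyWishlist | None = None
    novelty: NoveltyReport | None = None
    qsar: dict = field(default_factory=dict)       # target -> {kind: pActivity, "ensemble": ...}
    synthesizability: float | None = None
    rank: int | None = None


@dataclass
class LibraryReport:
    pct_valid_unique: float
    pct_valid_unique_novel: float
    pct_novelty_ge_threshold: float
    pct_rascore_ge_threshold: float
    pct_qsar_le_1uM: float
    pct_all_criteria: float
    mean_jaccard_distance_within_library: float
    pct_unique_atom_scaffolds: float
    pct_unique_novel_atom_scaffolds: float
    pct_unique_carbon_scaffolds: float
    pct_unique_novel_carbon_scaffolds: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _dedupe(candidates: list[DesignCandidate]) -> None:
    seen: set[str] = set()
    for c in candidates:
        if c.valid and c.smiles not in seen:
            c.unique = True
            seen.add(c.smiles)
        else:
            c.unique = False


def library_report(
    candidates: list[DesignCandidate],
    index: NoveltyIndex,
    novelty_threshold: float = 0.65,
    rascore_threshold: float = 0.5,
    qsar_pactivity_threshold: float = 6.0,
) -> LibraryReport:
    """Library quality metrics as percentages of all sampled strings.

    Invalid strings count in every denominator but can satisfy no criterion.
    "Novel" means the canonical SMILES is absent from the training set;
    criterion percentages follow the report conventions: unique+novel,
    novelty score >= 0.65, synthesizability >= 0.5, predicted affinity
    <= 1 uM (ensemble pActivity >= 6), and their conjunction.
    """
    n = len(candidates)
    if n == 0:
        raise ValueError("empty candidate list")
    training = set(index.smiles)
    pct = lambda k: 100.0 * k / n

    valid_unique = [c for c in candidates if c.valid and c.unique]
    vu_novel = [c for c in valid_unique if c.smiles not in training]
    crit_novelty = [
        c for c in valid_unique if c.novelty and c.novelty.s_novelty >= novelty_threshold
    ]
    crit_ra = [
        c for c in valid_unique
        if c.synthesizability is not None and c.synthesizability >= rascore_threshold
    ]
    crit_qsar = [
        c for c in valid_unique
        if c.qsar and max(t["ensemble"] for t in c.qsar.values()) >= qsar_pactivity_threshold
    ]
    all_ids = (
        {id(c) for c in vu_novel}
        & {id(c) for c in crit_novelty}
        & {id(c) for c in crit_ra}
        & {id(c) for c in crit_qsar}
    )

    # diversity: mean pairwise Jaccard distance among valid unique members
    fps = [ecfp4_512(mol_from_smiles(c.smiles)) for c in valid_unique]
    dists = [
        jaccard_distance(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
        if fps[i].any() or fps[j].any()
    ]
    mean_jd = float(np.mean(dists)) if dists else 0.0

    def scaffold_stats(fn, known: set[str]) -> tuple[float, float]:
        scaffolds = [fn(c.smiles) for c in valid_unique]
        uniq = set(scaffolds)
        return pct(len(uniq)), pct(len(uniq - known))

    pct_atom, pct_atom_novel = scaffold_stats(atom_scaffold, index.atom_scaffolds)
    pct_carbon, pct_carbon_novel = scaffold_stats(carbon_scaffold, index.carbon_scaffolds)

    return LibraryReport(
        pct_valid_unique=pct(len(valid_unique)),
        pct_valid_unique_novel=pct(len(vu_novel)),
        pct_novelty_ge_threshold=pct(len(crit_novelty)),
        pct_rascore_ge_threshold=pct(len(crit_ra)),
        pct_qsar_le_1uM=pct(len(crit_qsar)),
        pct_all_criteria=pct(len(all_ids)),
        mean_jaccard_distance_within_library=mean_jd,
        pct_unique_atom_scaffolds=pct_atom,
        pct_unique_novel_atom_scaffolds=pct_atom_novel,
        pct_unique_carbon_scaffolds=pct_carbon,
        pct_unique_novel_carbon_scaffolds=pct_carbon_novel,
    )


def filter_and_rank(
    candidates: list[DesignCandidate],
    mw_max: float = 600.0,
    rascore_min: float = 0.5,
    novelty_min: float = 0.7,
    objective_weights: dict[str, float] | None = None,
) -> list[DesignCandidate]:
    """Filter scored candidates and rank survivors by predicted affinity.

    Filters: molecular weight <= mw_max (600 g/mol), synthesizability >=
    rascore_min (0.5), novelty score >= novelty_min (0.7).  The objective is
    the weighted mean of per-target ensemble pActivities (default: equal
    weights over every scored target); ties break by canonical SMILES.
    Returns a new, ranked list (subset of the input).
    """
    survivors = []
    for c in candidates:
        if not (c.valid and c.unique and c.properties and c.novelty):
            continue
        if c.properties.mw > mw_max:
            continue
        if c.synthesizability is None or c.synthesizability < rascore_min:
            continue
        if c.novelty.s_novelty < novelty_min:
            continue
        survivors.append(c)

    def objective(c: DesignCandidate) -> float:
        if not c.qsar:
            return float("-inf")
        weights = objective_weights or {t: 1.0 for t in c.qsar}
        missing = set(weights) - set(c.qsar)
        if missing:
            raise ValueError(f"objective references unscored targets {sorted(missing)}")
        total_w = sum(weights.values())
        return sum(w * c.qsar[t]["ensemble"] for t, w in weights.items()) / total_w

    ranked = sorted(survivors, key=lambda c: (-objective(c), c.smiles))
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def score_candidates(
    candidates: list[DesignCandidate],
    index: NoveltyIndex,
    qsar_models: dict[str, dict[str, QSARModel]] | None = None,
    synthesizability_scorer=None,
) -> None:
    """Annotate valid unique candidates in place with all scores.

    `qsar_models` maps target id -> {descriptor kind -> QSARModel}.
    """
    for c in candidates:
        if not (c.valid and c.unique):
            continue
        mol = mol_from_smiles(c.smiles)
        c.properties = property_profile(mol)
        c.novelty = novelty_score(mol, index)
        c.synthesizability = synthesizability(mol, scorer=synthesizability_scorer)
        if qsar_models:
            c.qsar = {}
            for target, models in qsar_models.items():
                per_kind = {
                    kind: krr_predict(m, compute_descriptor(mol, kind))
                    for kind, m in models.items()
                }
                per_kind["ensemble"] = qsar_ensemble_score(mol, models)
                c.qsar[target] = per_kind


def load_campaign_config(path) -> dict:
    """Read a campaign configuration from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("campaign config must be a mapping")
    return config


def run_design_campaign(config: dict, model=None, template=None, out_dir=None) -> dict:
    """Orchestrate sample -> parse/dedupe -> score -> filter -> rank.

    `config` keys: n, temperature, seed, wishlist (optional 6 values),
    filters {mw_max, rascore_min, novelty_min}, objective_weights (optional),
    training_smiles (novelty reference), qsar_models (optional, passed
    through).  `model` is a trained GeneratorModel and `template` its input
    graph.  Artifacts (designs.csv, report.json, run.log) are written to
    `out_dir` when given.  Returns the stage log with candidates and ranking.
    """
    from pathlib import Path

    log: list[dict] = []

    def stage(name: str, **counts):
        log.append({"stage": name, "time": time.time(), **counts})

    n = int(config.get("n", 100))
    T = float(config.get("temperature", 0.5))
    seed = int(config.get("seed", 0))
    wishlist = config.get("wishlist")
    if wishlist is not None and not isinstance(wishlist, PropertyWishlist):
        wishlist = PropertyWishlist(*wishlist)

    samples = sample(model, template, wishlist=wishlist, T=T, n=n, seed=seed)
    stage("sample", requested=n, sampled=len(samples))

    candidates = [
        DesignCandidate(smiles=s.canonical, raw=s.string, valid=s.valid) for s in samples
    ]
    _dedupe(candidates)
    n_valid = sum(c.valid for c in candidates)
    n_unique = sum(c.unique for c in candidates)
    stage("parse_dedupe", valid=n_valid, valid_unique=n_unique)

    index = NoveltyIndex(config["training_smiles"])
    score_candidates(
        candidates,
        index,
        qsar_models=config.get("qsar_models"),
        synthesizability_scorer=config.get("synthesizability_scorer"),
    )
    stage("score", scored=n_unique)

    filters = config.get("filters", {})
    ranked = filter_and_rank(
        candidates,
        mw_max=float(filters.get("mw_max", 600.0)),
        rascore_min=float(filters.get("rascore_min", 0.5)),
        novelty_min=float(filters.get("novelty_min", 0.7)),
        objective_weights=config.get("objective_weights"),
    )
    stage("filter_rank", survivors=len(ranked))
    if not ranked:
        stage("warning", message="empty survivor set")

    report = library_report(candidates, index) if candidates else None

    result = {"candidates": candidates, "ranked": ranked, "report": report, "log": log,
              "seed": seed}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for c in candidates:
            rows.append(
                {
                    "raw": c.raw,
                    "smiles": c.smiles,
                    "valid": c.valid,
                    "unique": c.unique,
                    "mw": c.properties.mw if c.properties else None,
                    "s_novelty": c.novelty.s_novelty if c.novelty else None,
                    "synthesizability": c.synthesizability,
                    "ensemble_qsar": (
                        max(t["ensemble"] for t in c.qsar.values()) if c.qsar else None
                    ),
                    "rank": c.rank,
                }
            )
        pd.DataFrame(rows).to_csv(out / "designs.csv", index=False)
        (out / "report.json").write_text(
            json.dumps({"seed": seed, "report": report.to_dict() if report else None}, indent=1)
        )
        (out / "run.log").write_text("\n".join(json.dumps(entry) for entry in log) + "\n")
    return result
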