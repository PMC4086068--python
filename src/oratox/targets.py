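"""Toxicity-target indication: decoy sets, ROC validation, target profiles.

Protein targets associated with adverse drug reactions are represented by
precomputed pharmacophore ("toxicophore") fit tables — one fit value per
(compound, model) pair — plus a set of known ligands with sub-100-μM
activities. The module validates each fit model against an active/decoy
benchmark (retaining models with ROC-AUC strictly above 0.6), scores a
query compound by the average fit of its three nearest database reference
compounds, combines that with the query's similarity to known ligands, and
bins the combined score into a 4-level alert band.

Decoys are property-matched presumed inactives: accepted when molecular
weight is within ±25 Da, logP within ±1, H-bond acceptors within ±2,
donors within ±1, rotatable bonds within ±1 and total charge identical to
the active, while remaining structurally dissimilar to every active
(FP2 Tanimoto < 0.75) and to every already-accepted decoy (< 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import chem
from .chem import MoleculeRecord
from .predictor import PredictionConfig, find_neighbors
from .toxdb import ToxicityDatabase

#: Activity ceiling for a compound to count as a known ligand (molar).
LIGAND_ACTIVITY_MAX = 1e-4
#: Activity ceiling for a validation-set active (molar).
ACTIVE_ACTIVITY_MAX = 1e-9
#: Retain a fit model only when its ROC-AUC is strictly above this.
AUC_RETENTION_BOUND = 0.6
MAX_DECOYS_PER_ACTIVE = 10

# Decoy property windows (absolute differences to the paired active).
DECOY_WINDOWS = {"mw": 25.0, "logp": 1.0, "hba": 2, "hbd": 1, "rotb": 1}
DECOY_MAX_SIM_TO_ACTIVE = 0.75  # FP2 Tanimoto, strict
DECOY_MAX_SIM_TO_DECOY = 0.90

BAND_EDGES = (0.25, 0.5, 0.75)


@dataclass
class ToxTarget:
    """One toxicity target: fit table, retained models, known ligands."""

    name: str
    fit_table: dict[tuple[str, str], float] = field(default_factory=dict)
    retained_models: set[str] | None = None  # None = not yet validated
    ligands: list[tuple[MoleculeRecord, float]] = field(default_factory=list)

    @property
    def model_ids(self) -> set[str]:
        return {m for (_key, m) in self.fit_table}

    def fit(self, dedup_key: str, model_id: str) -> float:
        """Fit value; a compound the model fails to map scores 0."""
        return self.fit_table.get((dedup_key, model_id), 0.0)


@dataclass
class TargetValidationSet:
    actives: list[MoleculeRecord]
    decoys: list[MoleculeRecord]


@dataclass
class TargetScore:
    target: str
    avg_fit: float | None
    ligand_sim: float
    combined: float
    band: int


class UndefinedAUCError(ValueError):
    """ROC-AUC is undefined when only one label class is present."""


def _passes_windows(cand: MoleculeRecord, active: MoleculeRecord) -> bool:
    pc, pa = cand.props, active.props
    return (
        abs(pc.mw - pa.mw) <= DECOY_WINDOWS["mw"]
        and abs(pc.logp - pa.logp) <= DECOY_WINDOWS["logp"]
        and abs(pc.hba - pa.hba) <= DECOY_WINDOWS["hba"]
        and abs(pc.hbd - pa.hbd) <= DECOY_WINDOWS["hbd"]
        and abs(pc.rotb - pa.rotb) <= DECOY_WINDOWS["rotb"]
        and pc.charge == pa.charge
    )


def generate_decoys(
    active: MoleculeRecord,
    pool: list[MoleculeRecord],
    prior_decoys: list[MoleculeRecord] | None = None,
    actives: list[MoleculeRecord] | None = None,
    max_decoys: int = MAX_DECOYS_PER_ACTIVE,
) -> list[MoleculeRecord]:
    """Select up to ``max_decoys`` property-matched decoys for one active.

    Candidates are taken in pool order (first come, first served) and must
    satisfy all property windows against ``active``, be dissimilar to every
    active of the target (FP2 Tanimoto < 0.75; ``actives`` defaults to the
    paired active alone) and to every decoy already accepted for the target
    (``prior_decoys`` plus those accepted during this call; < 0.9).
    """
    actives = actives if actives is not None else [active]
    accepted: list[MoleculeRecord] = []
    accepted_fps = [chem.compute_fingerprint(d, "FP2") for d in (prior_decoys or [])]
    active_fps = [chem.compute_fingerprint(a, "FP2") for a in actives]
    active_keys = {a.dedup_key for a in actives}
    for cand in pool:
        if len(accepted) >= max_decoys:
            break
        if cand.dedup_key in active_keys:
            continue
        if not _passes_windows(cand, active):
            continue
        cfp = chem.compute_fingerprint(cand, "FP2")
        if any(chem.tanimoto(cfp, afp) >= DECOY_MAX_SIM_TO_ACTIVE for afp in active_fps):
            continue
        if any(chem.tanimoto(cfp, dfp) >= DECOY_MAX_SIM_TO_DECOY for dfp in accepted_fps):
            continue
        accepted.append(cand)
        accepted_fps.append(cfp)
    return accepted


def build_validation_set(
    actives: list[MoleculeRecord], pool: list[MoleculeRecord]
) -> TargetValidationSet:
    """Assemble a per-target validation set: actives plus matched decoys."""
    decoys: list[MoleculeRecord] = []
    for active in actives:
        decoys.extend(generate_decoys(active, pool, prior_decoys=decoys, actives=actives))
    return TargetValidationSet(actives=list(actives), decoys=decoys)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank-sum (Mann-Whitney) formulation.

    Equals the probability that a randomly drawn active outscores a randomly
    drawn decoy, with ties counted one half. ``labels`` are truthy for
    actives (or the strings "active"/"decoy").
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.array([l == "active" if isinstance(l, str) else bool(l) for l in labels])
    if len(scores) != len(lab):
        raise ValueError("scores and labels differ in length")
    n_act = int(lab.sum())
    n_dec = int((~lab).sum())
    if n_act == 0 or n_dec == 0:
        raise UndefinedAUCError("both actives and decoys are required")
    ranks = stats.rankdata(scores)  # mid-ranks handle ties as 1/2
    r_act = ranks[lab].sum()
    return float((r_act - n_act * (n_act + 1) / 2) / (n_act * n_dec))


def validate_toxicophores(
    target: ToxTarget, vset: TargetValidationSet
) -> set[str]:
    """Retain the fit models that discriminate actives from decoys.

    Each model is scored on the validation set (a compound it fails to map
    scores 0) and kept iff its ROC-AUC is strictly above 0.6. The retained
    set is stored on the target; an empty set flags it non-predictive.
    """
    labels = ["active"] * len(vset.actives) + ["decoy"] * len(vset.decoys)
    compounds = vset.actives + vset.decoys
    retained = set()
    for model in sorted(target.model_ids):
        fits = [target.fit(c.dedup_key, model) for c in compounds]
        if roc_auc(fits, labels) > AUC_RETENTION_BOUND:
            retained.add(model)
    target.retained_models = retained
    return retained


def average_target_fit(
    query: MoleculeRecord, db: ToxicityDatabase, target: ToxTarget
) -> float | None:
    """Mean toxicophore fit of the query's nearest database references.

    Uses the up-to-three database compounds within FP24 Tanimoto >= 0.7 of
    the query; the mean runs over those references and the target's
    retained models. None when no reference passes the cutoff or the
    target has no retained (or validated) models.
    """
    models = sorted(target.retained_models if target.retained_models is not None
                    else target.model_ids)
    if not models:
        return None
    hits = find_neighbors(query, db, PredictionConfig(scheme="FP24", cutoff=0.7, k=3))
    if not hits:
        return None
    fits = [target.fit(h.record.mol.dedup_key, m) for h in hits for m in models]
    return float(np.mean(fits))


def ligand_similarity_score(query: MoleculeRecord, target: ToxTarget) -> float:
    """Mean FP24 Tanimoto of the query to its 3 most similar known ligands."""
    if not target.ligands:
        raise ValueError(f"target {target.name} has no ligand set")
    qfp = chem.compute_fingerprint(query, "FP24")
    sims = sorted(
        (chem.tanimoto(qfp, chem.compute_fingerprint(mol, "FP24")) for mol, _a in target.ligands),
        reverse=True,
    )
    return float(np.mean(sims[:3]))


def _band(combined: float) -> int:
    for b, edge in enumerate(BAND_EDGES):
        if combined < edge:
            return b
    return 3


def target_profile(
    query: MoleculeRecord, db: ToxicityDatabase, targets: list[ToxTarget]
) -> list[TargetScore]:
    """Combined per-target alert profile for one query compound.

    The average fit is normalized to [0,1] by the target's maximum observed
    fit value and averaged with the ligand-similarity score; when no
    reference compound passes the similarity cutoff the ligand similarity
    stands alone. The combined score falls into four bands at quartile
    edges 0.25 / 0.5 / 0.75 — the higher the band, the stronger the alert.
    """
    out = []
    for target in targets:
        avg_fit = average_target_fit(query, db, target)
        lig_sim = ligand_similarity_score(query, target)
        if avg_fit is None:
            combined = lig_sim
        else:
            models = (target.retained_models if target.retained_models is not None
                      else target.model_ids)
            observed = [v for (_k, m), v in target.fit_table.items() if m in models]
            max_fit = max(observed) if observed else 0.0
            norm_fit = min(avg_fit / max_fit, 1.0) if max_fit > 0 else 0.0
            combined = (norm_fit + lig_sim) / 2.0
        combined = float(min(max(combined, 0.0), 1.0))
        out.append(TargetScore(target.name, avg_fit, lig_sim, combined, _band(combined)))
    return out


def read_fit_table(path) -> dict[tuple[str, str], float]:
    """Read a delimited (compound_key, model_id, fit_value) fit table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    key_c, model_c, fit_c = df.columns[:3]
    return {
        (str(r[key_c]), str(r[model_c])): float(r[fit_c]) for _, r in df.iterrows()
    }


def read_ligand_set(path) -> list[tuple[MoleculeRecord, float]]:
    """Read a ligand set (smiles, activity_molar) and apply the 100-μM filter."""
    out = []
    with open(path) as fh:
        header = fh.readline()  # smiles, activity_molar
        if not header.lower().startswith("smiles"):
            fh.seek(0)
        for i, line in enumerate(fh):
            parts = line.split()
            if len(parts) < 2:
                continue
            activity = float(parts[1])
            if activity < LIGAND_ACTIVITY_MAX:
                out.append((chem.standardize_molecule(parts[0], f"lig{i + 1}"), activity))
    return out
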