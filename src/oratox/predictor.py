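"""Oral toxicity prediction: neighbor search, LD50 combination, consensus class.

The prediction pipeline for a query compound is

1. standardize the structure,
2. rank database compounds by fingerprint Tanimoto similarity and keep the
   top k (default 3) above the admission cutoff (0.7 for FP24, 0.5 for ECFP4),
3. combine the neighbors' LD50 values (median by default) into a predicted
   LD50 and derive the similarity-based GHS class from it,
4. match the query against the toxic-fragment library; the fragment class is
   the most toxic class implicated by any matched fragment,
5. consensus class = the average of similarity and fragment classes, halves
   rounded toward the more toxic class; without fragment evidence the
   similarity class stands.

A query for which no database compound reaches the cutoff is reported as
not covered — the fraction of covered queries is the coverage statistic.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

from . import chem
from .chem import MoleculeRecord
from .fragments import Fragment, ToxicFragmentLibrary, match_toxic_fragments
from .toxdb import ToxicityClass, ToxicityDatabase, ToxicityRecord, assign_toxicity_class

#: Default Tanimoto admission cutoffs per fingerprint scheme.
DEFAULT_CUTOFFS = {"FP24": 0.7, "ECFP4": 0.5}

COMBINERS = ("median", "mean", "min", "tanimoto_weighted")


@dataclass(frozen=True)
class NeighborHit:
    record: ToxicityRecord
    similarity: float


@dataclass(frozen=True)
class PredictionConfig:
    """Similarity-search and consensus parameters.

    ``cutoff=None`` selects the scheme default (0.7 for FP24, 0.5 for ECFP4).
    """

    scheme: str = "FP24"
    cutoff: float | None = None
    k: int = 3
    combiner: str = "median"
    use_fragments: bool = True

    def __post_init__(self):
        if self.scheme not in DEFAULT_CUTOFFS:
            raise chem.SchemeError(f"unsupported prediction scheme: {self.scheme!r}")
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner: {self.combiner!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.cutoff is not None and not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must lie in (0, 1]")

    @property
    def effective_cutoff(self) -> float:
        return self.cutoff if self.cutoff is not None else DEFAULT_CUTOFFS[self.scheme]


@dataclass
class OralToxicityPrediction:
    query_id: str
    query_smiles: str
    covered: bool
    predicted_ld50: float | None  # mg/kg; None = "no prediction"
    similarity_class: ToxicityClass | None
    fragment_class: ToxicityClass | None
    consensus_class: ToxicityClass | None
    neighbors: list[NeighborHit] = field(default_factory=list)
    matched_fragments: list = field(default_factory=list)
    accuracy_note: float | None = None  # CV hit rate of the consensus class, %

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "query_smiles": self.query_smiles,
            "covered": self.covered,
            "predicted_ld50_mg_kg": self.predicted_ld50,
            "similarity_class": int(self.similarity_class) if self.similarity_class else None,
            "fragment_class": int(self.fragment_class) if self.fragment_class else None,
            "consensus_class": int(self.consensus_class) if self.consensus_class else None,
            "neighbors": [
                {
                    "id": h.record.mol.id,
                    "smiles": h.record.mol.smiles_canonical,
                    "similarity": h.similarity,
                    "ld50_mg_kg": h.record.ld50,
                    "tox_class": int(h.record.tox_class),
                }
                for h in self.neighbors
            ],
            "matched_fragments": [
                {"pattern": f.pattern, "implicated_classes": sorted(int(c) for c in cls)}
                for f, cls in self.matched_fragments
            ],
            "accuracy_note": self.accuracy_note,
        }


def find_neighbors(
    query: MoleculeRecord, db: ToxicityDatabase, cfg: PredictionConfig
) -> list[NeighborHit]:
    """Top-k database hits at or above the Tanimoto cutoff.

    Sorted by similarity descending; ties broken by database id so that the
    result is deterministic. Returns fewer than k hits (possibly none) when
    the cutoff admits fewer.
    """
    qfp = chem.compute_fingerprint(query, cfg.scheme)
    cutoff = cfg.effective_cutoff
    hits = []
    for key, rec in db.records.items():
        sim = chem.tanimoto(qfp, db.fingerprint(key, cfg.scheme))
        if sim >= cutoff:
            hits.append(NeighborHit(rec, sim))
    hits.sort(key=lambda h: (-h.similarity, h.record.mol.id))
    return hits[: cfg.k]


def combine_ld50(hits: list[NeighborHit], combiner: str = "median") -> float | None:
    """Combine neighbor LD50 values into one predicted LD50 (mg/kg).

    The median of an even count is the mean of the two middle values; the
    Tanimoto-weighted average is sum(s_i * ld50_i) / sum(s_i). An empty hit
    list yields the no-prediction sentinel None, never zero.
    """
    if not hits:
        return None
    values = [h.record.ld50 for h in hits]
    if combiner == "median":
        return float(statistics.median(values))
    if combiner == "mean":
        return float(statistics.fmean(values))
    if combiner == "min":
        return float(min(values))
    if combiner == "tanimoto_weighted":
        wsum = sum(h.similarity for h in hits)
        if wsum == 0:
            return float(statistics.fmean(values))
        return float(sum(h.similarity * h.record.ld50 for h in hits) / wsum)
    raise ValueError(f"unknown combiner: {combiner!r}")


def fragment_class(
    matches: list[tuple[Fragment, frozenset[ToxicityClass]]]
) -> ToxicityClass | None:
    """Most toxic (lowest-numbered) class implicated by any matched fragment."""
    implicated = [c for _frag, classes in matches for c in classes]
    return ToxicityClass(min(implicated)) if implicated else None


def consensus_class(
    sim: ToxicityClass, frag: ToxicityClass | None
) -> ToxicityClass:
    """Average of the similarity and fragment classes.

    Half-classes round toward the more toxic (lower) class; without a
    fragment class the similarity class is returned unchanged.
    """
    if frag is None:
        return sim
    return ToxicityClass(math.floor((int(sim) + int(frag)) / 2))


def predict(
    raw_smiles: str,
    db: ToxicityDatabase,
    cfg: PredictionConfig | None = None,
    lib: ToxicFragmentLibrary | None = None,
    query_id: str = "",
) -> OralToxicityPrediction:
    """Full oral toxicity prediction for one query SMILES.

    Standardization errors propagate with the query id attached. When no
    neighbor passes the cutoff the report is marked not covered and carries
    no LD50 or class.
    """
    try:
        query = chem.standardize_molecule(raw_smiles, query_id)
    except chem.StandardizationError as exc:
        raise chem.StandardizationError(
            f"query {query_id or '<unnamed>'} failed standardization", exc.smiles
        ) from exc
    cfg = cfg or PredictionConfig()
    hits = find_neighbors(query, db, cfg)
    matches = []
    if cfg.use_fragments and lib is not None:
        matches = match_toxic_fragments(query, lib)
    if not hits:
        return OralToxicityPrediction(
            query_id=query.id,
            query_smiles=query.smiles_canonical,
            covered=False,
            predicted_ld50=None,
            similarity_class=None,
            fragment_class=fragment_class(matches),
            consensus_class=None,
            matched_fragments=matches,
        )
    ld50 = combine_ld50(hits, cfg.combiner)
    sim_class = assign_toxicity_class(ld50)
    frag_class = fragment_class(matches) if cfg.use_fragments else None
    cons = consensus_class(sim_class, frag_class)
    note = None
    if db.cv_accuracy is not None:
        note = db.cv_accuracy.get(int(cons))
    return OralToxicityPrediction(
        query_id=query.id,
        query_smiles=query.smiles_canonical,
        covered=True,
        predicted_ld50=ld50,
        similarity_class=sim_class,
        fragment_class=frag_class,
        consensus_class=cons,
        neighbors=hits,
        matched_fragments=matches,
        accuracy_note=note,
    )
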