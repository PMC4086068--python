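"""Leave-one-out cross-validation and class-wise performance metrics.

Hit rates follow the coverage-aware convention: a compound with no neighbor
above the similarity cutoff is counted against coverage and excluded from
the hit-rate denominators. A hit is an exact class match between the
predicted (consensus) class and the known GHS class.

Class-wise external metrics are one-vs-rest over covered compounds:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
reported per class and as class-size-weighted overall means (weights are
the true-class counts among covered compounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fragments import ToxicFragmentLibrary, match_toxic_fragments
from .predictor import (
    PredictionConfig,
    combine_ld50,
    consensus_class,
    find_neighbors,
    fragment_class,
)
from .toxdb import ToxicityClass, ToxicityDatabase, assign_toxicity_class

NOT_COVERED = "not covered"


@dataclass
class CrossValidationResult:
    per_class_hit_rate: dict[ToxicityClass, float]  # % over covered, NaN if none covered
    overall_hit_rate: float  # % — covered-count-weighted mean of per-class rates
    coverage: float  # %
    n_total: int
    n_covered: int
    per_class_covered: dict[ToxicityClass, int] = field(default_factory=dict)


@dataclass
class ClasswiseMetrics:
    sensitivity: dict[ToxicityClass, float]  # %
    specificity: dict[ToxicityClass, float]  # %
    precision: dict[ToxicityClass, float]  # %
    precision_defined: dict[ToxicityClass, bool]  # False when TP+FP = 0 (flagged)
    overall_sensitivity: float
    overall_specificity: float
    overall_precision: float
    coverage: float
    n_total: int
    n_covered: int


def _predict_class_from_records(query_rec, db, cfg, lib):
    """Consensus class for an already-standardized query; None if uncovered."""
    hits = find_neighbors(query_rec, db, cfg)
    if not hits:
        return None
    sim_class = assign_toxicity_class(combine_ld50(hits, cfg.combiner))
    frag = None
    if cfg.use_fragments and lib is not None:
        frag = fragment_class(match_toxic_fragments(query_rec, lib))
    return consensus_class(sim_class, frag)


def loo_cross_validate(
    db: ToxicityDatabase,
    cfg: PredictionConfig | None = None,
    lib: ToxicFragmentLibrary | None = None,
) -> CrossValidationResult:
    """Leave-one-out cross-validation of the class prediction.

    Each compound is removed from the index and predicted from the
    remainder. The fragment library, when given, is the one mined on the
    full database — it is not re-mined per fold (a small optimism source,
    noted in the methods documentation).
    """
    cfg = cfg or PredictionConfig()
    if len(db) < 2:
        raise ValueError("cross-validation needs at least 2 records")
    hits_per_class = {c: 0 for c in ToxicityClass}
    covered_per_class = {c: 0 for c in ToxicityClass}
    total_per_class = db.class_sizes
    for key, rec in list(db.records.items()):
        held = db.records.pop(key)
        held_fps = {s: db.fp_index[s].pop(key) for s in db.schemes}
        try:
            pred = _predict_class_from_records(rec.mol, db, cfg, lib)
        finally:
            db.records[key] = held
            for s, fp in held_fps.items():
                db.fp_index[s][key] = fp
        if pred is None:
            continue
        covered_per_class[rec.tox_class] += 1
        if pred == rec.tox_class:
            hits_per_class[rec.tox_class] += 1
    n_total = len(db)
    n_covered = sum(covered_per_class.values())
    per_class = {
        c: (100.0 * hits_per_class[c] / covered_per_class[c])
        if covered_per_class[c]
        else float("nan")
        for c in ToxicityClass
    }
    overall = (
        100.0 * sum(hits_per_class.values()) / n_covered if n_covered else float("nan")
    )
    return CrossValidationResult(
        per_class_hit_rate=per_class,
        overall_hit_rate=overall,
        coverage=100.0 * n_covered / n_total,
        n_total=n_total,
        n_covered=n_covered,
        per_class_covered=covered_per_class,
    )


def classwise_metrics(true: list[ToxicityClass], pred: list) -> ClasswiseMetrics:
    """One-vs-rest sensitivity/specificity/precision per GHS class.

    ``pred`` entries are ToxicityClass values or the ``"not covered"``
    sentinel / None; uncovered compounds enter coverage only. Precision of
    a class never predicted is reported as 0 and flagged undefined.
    """
    if len(true) != len(pred):
        raise ValueError("true and pred differ in length")
    covered = [
        (t, p) for t, p in zip(true, pred) if p is not None and p != NOT_COVERED
    ]
    n_total, n_covered = len(true), len(covered)
    sens, spec, prec, prec_def = {}, {}, {}, {}
    weights = {}
    for c in ToxicityClass:
        tp = sum(1 for t, p in covered if t == c and p == c)
        fn = sum(1 for t, p in covered if t == c and p != c)
        fp = sum(1 for t, p in covered if t != c and p == c)
        tn = sum(1 for t, p in covered if t != c and p != c)
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        prec_def[c] = (tp + fp) > 0
        prec[c] = 100.0 * tp / (tp + fp) if prec_def[c] else 0.0
        weights[c] = tp + fn  # true-class count among covered
    wsum = sum(weights.values())

    def _weighted(metric: dict) -> float:
        if not wsum:
            return float("nan")
        return sum(
            weights[c] * metric[c] for c in ToxicityClass if weights[c] and metric[c] == metric[c]
        ) / wsum

    return ClasswiseMetrics(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        precision_defined=prec_def,
        overall_sensitivity=_weighted(sens),
        overall_specificity=_weighted(spec),
        overall_precision=_weighted(prec),
        coverage=100.0 * n_covered / n_total if n_total else float("nan"),
        n_total=n_total,
        n_covered=n_covered,
    )


def evaluate_external(
    db: ToxicityDatabase,
    queries: list[tuple[str, float]],
    cfg: PredictionConfig | None = None,
    lib: ToxicFragmentLibrary | None = None,
) -> ClasswiseMetrics:
    """Classify (smiles, known ld50) queries against ``db`` and score them."""
    from . import chem

    cfg = cfg or PredictionConfig()
    true, pred = [], []
    for smiles, ld50 in queries:
        rec = chem.standardize_molecule(smiles)
        true.append(assign_toxicity_class(ld50))
        pred.append(_predict_class_from_records(rec, db, cfg, lib))
    return classwise_metrics(true, pred)


def compare_configs(
    db: ToxicityDatabase,
    configs: list[PredictionConfig],
    lib: ToxicFragmentLibrary | None = None,
) -> pd.DataFrame:
    """One LOO-CV summary row per configuration, in input order."""
    rows = []
    for i, cfg in enumerate(configs):
        res = loo_cross_validate(db, cfg, lib)
        row = {
            "config": i,
            "scheme": cfg.scheme,
            "cutoff": cfg.effective_cutoff,
            "k": cfg.k,
            "combiner": cfg.combiner,
            "use_fragments": cfg.use_fragments,
            "overall_hit_rate": res.overall_hit_rate,
            "coverage": res.coverage,
        }
        for c in ToxicityClass:
            row[f"hit_rate_{c.name}"] = res.per_class_hit_rate[c]
        rows.append(row)
    return pd.DataFrame(rows)
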