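"""Synthetic reference-data generator.

The real ~38k-compound LD50 collection behind the method is not
redistributable, so every test and demonstration in this package runs on a
synthetic stand-in built here. The generator emulates the structural
features the method exploits:

* scaffold families — each GHS class is populated from one family (a large
  shared core decorated with small substituents), so that compounds of a
  class are mutual fingerprint neighbors while families stay dissimilar;
* class-correlated LD50 values — sampled log-uniformly within each class's
  GHS interval;
* planted toxic substructures — rigid ring markers attached to a chosen
  fraction (penetrance) of the compounds of chosen classes, giving the
  fragment miner a known signal to recover;
* property-twin families — consecutive templates are near-isomers, so a
  family provides property-matched but structurally dissimilar decoy
  candidates for its twin in target-validation fixtures.

Everything is deterministic under the seed. A ground-truth manifest records
each compound's class, LD50 and planted markers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .chem import MoleculeRecord
from .targets import ToxTarget, TargetValidationSet, build_validation_set
from .toxdb import ToxicityClass

# Six scaffold templates; consecutive pairs (0,1), (2,3), (4,5) are
# property twins. Sites: [*:1]/[*:3] substituents, [*:2]/[*:4] planted
# fragments (hydrogen-capped when unused).
SCAFFOLD_TEMPLATES = (
    "O=C(OCC)c1cc([*:1])ccc1Oc1cc([*:4])c([*:2])cc1[*:3]",
    "O=C(NCC)c1cc([*:1])ccc1Cc1cc([*:4])c([*:2])cc1[*:3]",
    "O=S(=O)(NC)c1ccc(-c2cc([*:4])c([*:2])c([*:1])c2)cc1[*:3]",
    "O=S(=O)(CC)Nc1ccc(-c2cc([*:4])c([*:2])c([*:1])c2)cc1[*:3]",
    "O=C(C)Nc1cc([*:4])c2nc([*:1])c([*:2])c(C[*:3])c2c1",
    "O=C(C)Nc1cc([*:4])c2cc([*:1])c([*:2])nc2c1C[*:3]",
)

SUBSTITUENTS_A = tuple(
    "[*:1]" + s
    for s in ("C", "CC", "CCC", "O", "OC", "N", "Cl", "F", "Br", "C(C)C", "C(F)(F)F", "CO")
)
SUBSTITUENTS_B = tuple("[*:3]" + s for s in ("C", "CC", "O", "OC", "Cl", "F", "N", "CO"))

#: GHS interval of each class, clipped to a practical sampling range (mg/kg).
DEFAULT_LD50_BOUNDS = {
    ToxicityClass.I: (0.5, 5.0),
    ToxicityClass.II: (5.0, 50.0),
    ToxicityClass.III: (50.0, 300.0),
    ToxicityClass.IV: (300.0, 2000.0),
    ToxicityClass.V: (2000.0, 5000.0),
    ToxicityClass.VI: (5000.0, 20000.0),
}


@dataclass(frozen=True)
class PlantedFragment:
    """A marker substructure planted into chosen classes at a set penetrance.

    ``attachment`` is a SMILES with one unmapped dummy atom; ``marker`` is
    the substructure pattern the planted compounds are guaranteed to
    contain (the attachment minus its dummy).
    """

    name: str
    attachment: str
    marker: str
    classes: frozenset[int]
    penetrance: float


#: Morpholine ring in 90% of class I — a recoverable toxic-fragment signal.
MARKER_FRAGMENT = PlantedFragment(
    "morpholine-marker", "*N1CCOCC1", "N1CCOCC1", frozenset({1}), 0.9
)
#: Pyrrolidine ring spread uniformly over all classes — must not be selected.
DECOY_FRAGMENT = PlantedFragment(
    "pyrrolidine-decoy", "*N1CCCC1", "N1CCCC1", frozenset(range(1, 7)), 0.5
)


@dataclass
class FixtureSpec:
    n_per_class: int = 30
    n_scaffolds: int = 6
    planted_fragments: list[PlantedFragment] = field(
        default_factory=lambda: [MARKER_FRAGMENT, DECOY_FRAGMENT]
    )
    seed: int = 0
    ld50_bounds: dict = field(default_factory=lambda: dict(DEFAULT_LD50_BOUNDS))

    def validate(self) -> None:
        max_combos = len(SUBSTITUENTS_A) * len(SUBSTITUENTS_B)
        if not 1 <= self.n_per_class <= max_combos:
            raise ValueError(f"n_per_class must be in [1, {max_combos}]")
        if not 1 <= self.n_scaffolds <= len(SCAFFOLD_TEMPLATES):
            raise ValueError(f"n_scaffolds must be in [1, {len(SCAFFOLD_TEMPLATES)}]")
        for pf in self.planted_fragments:
            if not 0 <= pf.penetrance <= 1:
                raise ValueError(f"penetrance of {pf.name} outside [0, 1]")
            if not pf.classes or not pf.classes <= set(range(1, 7)):
                raise ValueError(f"target classes of {pf.name} must be a subset of 1..6")
        for c in ToxicityClass:
            lo, hi = self.ld50_bounds[c]
            glo = 0.0 if c == ToxicityClass.I else float(
                (0, 5, 50, 300, 2000, 5000)[c - 1]
            )
            ghi = math.inf if c == ToxicityClass.VI else float(
                (5, 50, 300, 2000, 5000)[c - 1]
            )
            if not (glo <= lo < hi <= ghi):
                raise ValueError(f"ld50 bounds for class {c.name} leave the GHS interval")


def _attachment_mol(smiles: str, site: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(site)
            return mol
    raise ValueError(f"attachment {smiles!r} has no dummy atom")


def _cap(site: int) -> Chem.Mol:
    return Chem.MolFromSmiles(f"[*:{site}][H]", sanitize=False)


def assemble_compound(
    template: str, sub_a: str, sub_b: str, plants: dict[int, str] | None = None
) -> str:
    """Zip a scaffold template with substituents and optional planted groups.

    ``plants`` maps a plant site (2 or 4) to an attachment SMILES; unused
    sites are hydrogen-capped. Returns the canonical SMILES of the product.
    """
    plants = plants or {}
    parts = [Chem.MolFromSmiles(template), Chem.MolFromSmiles(sub_a), Chem.MolFromSmiles(sub_b)]
    for site in (2, 4):
        if site in plants:
            parts.append(_attachment_mol(plants[site], site))
        else:
            parts.append(_cap(site))
    combined = parts[0]
    for p in parts[1:]:
        combined = Chem.CombineMols(combined, p)
    product = Chem.RemoveHs(Chem.molzip(combined))
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def generate_fixture_db(spec: FixtureSpec | None = None):
    """Generate raw database rows plus a ground-truth manifest.

    Returns ``(rows, manifest)``: rows are ``(id, smiles, ld50, source)``
    tuples ready for database building; the manifest is a DataFrame with
    one row per compound (id, smiles, tox_class, ld50, family, planted
    marker names). Exactly ``round(penetrance * n_per_class)`` compounds of
    each targeted class carry each planted fragment. Deterministic under
    ``spec.seed``.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    if len(spec.planted_fragments) > 2:
        raise ValueError("at most two planted fragments are supported (two plant sites)")
    rng = np.random.default_rng(spec.seed)
    rows, manifest = [], []
    seen_keys: set[str] = set()
    for c in ToxicityClass:
        family = (c - 1) % spec.n_scaffolds
        template = SCAFFOLD_TEMPLATES[family]
        combos = list(itertools.product(SUBSTITUENTS_A, SUBSTITUENTS_B))
        order = rng.permutation(len(combos))
        # which compounds of this class carry which planted fragment
        plant_members: list[set[int]] = []
        for pf in spec.planted_fragments:
            if int(c) in pf.classes:
                n_planted = round(pf.penetrance * spec.n_per_class)
                members = set(rng.choice(spec.n_per_class, size=n_planted, replace=False))
            else:
                members = set()
            plant_members.append(members)
        lo, hi = spec.ld50_bounds[c]
        made = 0
        for idx in order:
            if made >= spec.n_per_class:
                break
            sub_a, sub_b = combos[idx]
            plants = {}
            names = []
            for p_i, pf in enumerate(spec.planted_fragments):
                if made in plant_members[p_i]:
                    plants[2 + 2 * p_i] = pf.attachment
                    names.append(pf.name)
            smiles = assemble_compound(template, sub_a, sub_b, plants)
            rec = chem.standardize_molecule(smiles)
            if rec.dedup_key in seen_keys:
                continue  # symmetry collision; take the next combo
            seen_keys.add(rec.dedup_key)
            # log-uniform LD50 inside the class interval (lower bound exclusive)
            ld50 = float(np.exp(rng.uniform(np.log(lo * 1.0001), np.log(hi))))
            mol_id = f"C{int(c)}F{family}-{made:03d}"
            rows.append((mol_id, smiles, ld50, "synthetic"))
            manifest.append(
                {
                    "id": mol_id,
                    "smiles": smiles,
                    "tox_class": int(c),
                    "ld50": ld50,
                    "family": family,
                    "planted": ",".join(names),
                }
            )
            made += 1
        if made < spec.n_per_class:
            raise RuntimeError(f"could not build {spec.n_per_class} unique compounds for class {c.name}")
    return rows, pd.DataFrame(manifest)


def synthesize_fit_scores(
    n_actives: int, n_decoys: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Draw synthetic pharmacophore fit values with a known expected AUC.

    Decoy fits are N(3, 1) and active fits N(3 + separation, 1), clipped at
    zero, so the analytic ROC-AUC is Phi(separation / sqrt(2)). Returns
    (scores, labels) ordered actives first.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    actives = rng.normal(3.0 + separation, 1.0, size=n_actives)
    decoys = rng.normal(3.0, 1.0, size=n_decoys)
    scores = np.clip(np.concatenate([actives, decoys]), 0.0, None)
    labels = ["active"] * n_actives + ["decoy"] * n_decoys
    return scores, labels


def analytic_auc(separation: float) -> float:
    """Expected AUC of two unit-variance normals separated by ``separation``."""
    from scipy.stats import norm

    return float(norm.cdf(separation / math.sqrt(2.0)))


def _family_compounds(family: int, n: int, rng, plant: str | None = None) -> list[MoleculeRecord]:
    template = SCAFFOLD_TEMPLATES[family]
    combos = list(itertools.product(SUBSTITUENTS_A, SUBSTITUENTS_B))
    order = rng.permutation(len(combos))
    out, seen = [], set()
    for idx in order:
        if len(out) >= n:
            break
        sub_a, sub_b = combos[idx]
        rec = chem.standardize_molecule(
            assemble_compound(template, sub_a, sub_b, {2: plant} if plant else None),
            f"F{family}-{len(out):03d}",
        )
        if rec.dedup_key not in seen:
            seen.add(rec.dedup_key)
            out.append(rec)
    return out


def generate_fixture_targets(
    n_targets: int = 3,
    n_actives: int = 8,
    n_pool: int = 40,
    separation: float = 2.0,
    seed: int = 0,
    model_separations: dict[str, float] | None = None,
    db=None,
) -> list[tuple[ToxTarget, TargetValidationSet]]:
    """Synthesize toxicity targets with ligands, decoy pools and fit tables.

    Target *t* draws its actives (activity 0.1 nM) from scaffold family
    ``2t`` and its decoy pool from the property-twin family ``2t + 1``.
    Fit values follow :func:`synthesize_fit_scores`: per model, actives sit
    ``separation`` above the decoy mean (overridable per model via
    ``model_separations``, default two informative models and one
    uninformative). When ``db`` is given, every database compound also
    receives a fit draw at a separation proportional to its FP24 similarity
    to the target's actives, so that similar queries inherit high fits.
    """
    if n_targets > len(SCAFFOLD_TEMPLATES) // 2:
        raise ValueError("n_targets limited by the number of twin-family pairs")
    rng = np.random.default_rng(seed)
    model_separations = model_separations or {"m1": separation, "m2": separation, "m0": 0.0}
    out = []
    for t in range(n_targets):
        actives = _family_compounds(2 * t, n_actives, rng)
        pool = _family_compounds(2 * t + 1, n_pool, rng)
        vset = build_validation_set(actives, pool)
        ligands = [(a, 1e-10) for a in actives]
        ligands += [(p, 1e-6) for p in pool[: max(2, n_actives // 2)]]
        fit_table: dict[tuple[str, str], float] = {}
        for model, sep in model_separations.items():
            for a in actives:
                fit_table[(a.dedup_key, model)] = max(
                    0.0, float(rng.normal(3.0 + sep, 1.0))
                )
            for d in vset.decoys:
                fit_table[(d.dedup_key, model)] = max(0.0, float(rng.normal(3.0, 1.0)))
        if db is not None:
            active_fps = [chem.compute_fingerprint(a, "FP24") for a in actives]
            for key, rec in db.records.items():
                sim = max(
                    chem.tanimoto(db.fingerprint(key, "FP24"), afp) for afp in active_fps
                )
                for model, sep in model_separations.items():
                    fit_table.setdefault(
                        (key, model), max(0.0, float(rng.normal(3.0 + sim * sep, 1.0)))
                    )
        out.append((ToxTarget(f"T{t}", fit_table, None, ligands), vset))
    return out
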