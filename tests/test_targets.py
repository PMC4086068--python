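"""Decoy generation, ROC validation and the toxicity-target profile."""

import numpy as np
import pytest

from oratox import chem, targets
from oratox.chem import MoleculeRecord, PropertySet
from oratox.targets import (
    ToxTarget,
    TargetValidationSet,
    UndefinedAUCError,
    average_target_fit,
    generate_decoys,
    ligand_similarity_score,
    roc_auc,
    target_profile,
    validate_toxicophores,
)
from oratox.toxdb import build_database


def _mol(smi, mol_id=""):
    return chem.standardize_molecule(smi, mol_id)


def _with_props(record: MoleculeRecord, **overrides) -> MoleculeRecord:
    props = {f: getattr(record.props, f) for f in ("mw", "logp", "hba", "hbd", "rotb", "charge")}
    props.update(overrides)
    return MoleculeRecord(record.id, record.smiles_canonical, record.dedup_key, PropertySet(**props))


class TestDecoys:
    def test_property_matched_dissimilar_candidate_accepted(self):
        active = _mol("CCCCC(=O)OCC")
        # candidate with identical property vector but unrelated structure
        cand = _with_props(
            _mol("NCc1ccncc1"),
            **{f: getattr(active.props, f) for f in ("mw", "logp", "hba", "hbd", "rotb", "charge")},
        )
        sim = chem.tanimoto(
            chem.compute_fingerprint(active, "FP2"), chem.compute_fingerprint(cand, "FP2")
        )
        assert sim < 0.75  # precondition of this case
        assert generate_decoys(active, [cand]) == [cand]

    def test_mw_window_enforced(self):
        active = _mol("CCO")
        cand = _with_props(_mol("CCCCCO"), mw=active.props.mw + 30)
        assert generate_decoys(active, [cand]) == []

    def test_similar_to_active_rejected(self):
        active = _mol("CCCCCCO")
        near = _mol("CCCCCO")  # homologue: high FP2 similarity, windows pass
        fp_a = chem.compute_fingerprint(active, "FP2")
        fp_n = chem.compute_fingerprint(near, "FP2")
        assert chem.tanimoto(fp_a, fp_n) >= 0.75  # precondition of this case
        assert generate_decoys(active, [near]) == []

    def test_cap_at_ten(self, target_fixtures):
        (_target, vset) = target_fixtures[0]
        per_active_max = targets.MAX_DECOYS_PER_ACTIVE
        assert len(vset.decoys) <= per_active_max * len(vset.actives)

    def test_all_emitted_decoys_satisfy_constraints(self, target_fixtures):
        # independent validator pass over every constraint
        for _target, vset in target_fixtures:
            active_fps = [chem.compute_fingerprint(a, "FP2") for a in vset.actives]
            decoy_fps = [chem.compute_fingerprint(d, "FP2") for d in vset.decoys]
            matched = set()
            for d, dfp in zip(vset.decoys, decoy_fps):
                assert all(chem.tanimoto(dfp, afp) < 0.75 for afp in active_fps)
                for other, ofp in zip(vset.decoys, decoy_fps):
                    if other is not d:
                        assert chem.tanimoto(dfp, ofp) < 0.90
                # property windows hold against at least one active
                ok_any = any(
                    abs(d.props.mw - a.props.mw) <= 25
                    and abs(d.props.logp - a.props.logp) <= 1
                    and abs(d.props.hba - a.props.hba) <= 2
                    and abs(d.props.hbd - a.props.hbd) <= 1
                    and abs(d.props.rotb - a.props.rotb) <= 1
                    and d.props.charge == a.props.charge
                    for a in vset.actives
                )
                assert ok_any
                matched.add(d.dedup_key)
            assert len(matched) == len(vset.decoys)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([5, 4, 3, 1, 0], ["active"] * 2 + ["decoy"] * 3) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([1, 1, 1, 1], ["active", "active", "decoy", "decoy"]) == 0.5

    def test_toy_vector_matches_pair_counting_oracle(self):
        scores = [3.0, 1.0, 2.0, 2.0, 0.5, 1.0]
        labels = ["active", "active", "active", "decoy", "decoy", "decoy"]
        acts = [s for s, l in zip(scores, labels) if l == "active"]
        decs = [s for s, l in zip(scores, labels) if l == "decoy"]
        pairs = sum(
            1.0 if a > d else 0.5 if a == d else 0.0 for a in acts for d in decs
        ) / (len(acts) * len(decs))
        assert roc_auc(scores, labels) == pytest.approx(pairs)

    def test_reversal_identity_without_ties(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(20).astype(float)
        labels = ["active"] * 8 + ["decoy"] * 12
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 2], ["active", "active"])

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )


class TestValidation:
    def _vset(self):
        smis = ["CCO", "CCCO", "CCN", "CCCN", "CCOC", "CCCC"]
        mols = [_mol(s, f"v{i}") for i, s in enumerate(smis)]
        return TargetValidationSet(actives=mols[:2], decoys=mols[2:])

    def _target(self, model_fits):
        vset = self._vset()
        table = {}
        for model, fits in model_fits.items():
            for mol, fit in zip(vset.actives + vset.decoys, fits):
                table[(mol.dedup_key, model)] = fit
        return ToxTarget("T", table), vset

    def test_discriminating_model_retained(self):
        target, vset = self._target({"good": [9, 8, 1, 2, 1, 0]})
        assert validate_toxicophores(target, vset) == {"good"}

    def test_auc_exactly_point_six_dropped(self):
        # one active outranking 3 of 5 decoys -> AUC exactly 0.6
        smis = ["CCO", "CCN", "CCCN", "CCOC", "CCCC", "CCCCO"]
        mols = [_mol(s, f"w{i}") for i, s in enumerate(smis)]
        vset = TargetValidationSet(actives=mols[:1], decoys=mols[1:])
        fits = [2.5, 0, 1, 2, 3, 4]
        table = {(m.dedup_key, "edge"): f for m, f in zip(mols, fits)}
        target = ToxTarget("T", table)
        assert roc_auc(fits, ["active"] + ["decoy"] * 5) == pytest.approx(0.6)
        assert validate_toxicophores(target, vset) == set()

    def test_uninformative_target_flagged_non_predictive(self):
        target, vset = self._target({"flat": [1, 1, 1, 1, 1, 1]})
        assert validate_toxicophores(target, vset) == set()
        assert target.retained_models == set()

    def test_fixture_targets_retain_informative_models_only(self, target_fixtures):
        for target, _vset in target_fixtures:
            assert "m1" in target.retained_models or "m2" in target.retained_models

    def test_missing_fit_scores_zero(self):
        target = ToxTarget("T", {("nokey", "m"): 5.0})
        assert target.fit("unknown", "m") == 0.0


class TestScoring:
    def test_single_reference_average_fit(self):
        db, _ = build_database([("a", "CCc1ccccc1CC(=O)OC", 100)])
        key = next(iter(db.records))
        target = ToxTarget("T", {(key, "m1"): 4.0, (key, "m2"): 2.0}, {"m1", "m2"})
        query = _mol("CCc1ccccc1CC(=O)OC")
        assert average_target_fit(query, db, target) == pytest.approx(3.0)

    def test_no_reference_above_cutoff_gives_none(self):
        db, _ = build_database([("a", "c1ccc2ccccc2c1", 100)])
        key = next(iter(db.records))
        target = ToxTarget("T", {(key, "m1"): 4.0}, {"m1"})
        assert average_target_fit(_mol("CCO"), db, target) is None

    def test_three_refs_two_models_hand_mean(self, db, target_fixtures):
        target, _ = target_fixtures[0]
        query = target.ligands[0][0]  # an active: close to family-0 compounds? use db neighbor path
        from oratox.predictor import PredictionConfig, find_neighbors

        hits = find_neighbors(query, db, PredictionConfig(cutoff=0.7, k=3))
        got = average_target_fit(query, db, target)
        if not hits:
            assert got is None
        else:
            models = sorted(target.retained_models)
            expected = np.mean(
                [target.fit(h.record.mol.dedup_key, m) for h in hits for m in models]
            )
            assert got == pytest.approx(expected)

    def test_singleton_ligand_set_self_similarity(self):
        q = _mol("CCOC(=O)c1ccccc1")
        target = ToxTarget("T", {}, set(), ligands=[(q, 1e-6)])
        assert ligand_similarity_score(q, target) == 1.0

    def test_top_three_mean(self):
        q = _mol("CCCCCCCCO")
        ligs = [(_mol(s), 1e-6) for s in ["CCCCCCCCO", "CCCCCCCO", "CCCCCCO", "C1CC1"]]
        target = ToxTarget("T", {}, set(), ligands=ligs)
        qfp = chem.compute_fingerprint(q, "FP24")
        sims = sorted(
            (chem.tanimoto(qfp, chem.compute_fingerprint(m, "FP24")) for m, _ in ligs),
            reverse=True,
        )
        assert ligand_similarity_score(q, target) == pytest.approx(np.mean(sims[:3]))

    def test_full_scan_oracle_on_fixture_ligands(self, target_fixtures):
        target, _ = target_fixtures[1]
        q = target.ligands[-1][0]
        qfp = chem.compute_fingerprint(q, "FP24")
        sims = sorted(
            (
                chem.tanimoto(qfp, chem.compute_fingerprint(m, "FP24"))
                for m, _ in target.ligands
            ),
            reverse=True,
        )
        assert ligand_similarity_score(q, target) == pytest.approx(np.mean(sims[:3]))


class TestProfile:
    def test_active_query_gets_top_band(self, db, target_fixtures):
        # singleton ligand set + maximal fits: combined score 1 -> band 3
        rec = next(iter(db))
        query = rec.mol
        models = {"m"}
        fits = {(k, "m"): 1.0 for k in db.records}
        target = ToxTarget("T", fits, models, ligands=[(query, 1e-6)])
        [score] = target_profile(query, db, [target])
        assert score.ligand_sim == 1.0
        assert score.combined == pytest.approx(1.0)
        assert score.band == 3

    def test_fixture_active_query_scores_high(self, db, target_fixtures):
        target, _ = target_fixtures[0]
        query = target.ligands[0][0]
        [score] = target_profile(query, db, [target])
        assert score.ligand_sim > 0.8
        assert score.band >= 2

    def test_no_reference_low_similarity_gives_band_zero(self, db, target_fixtures):
        target, _ = target_fixtures[0]
        query = _mol("C1CC1")
        [score] = target_profile(query, db, [target])
        assert score.avg_fit is None
        assert score.combined == score.ligand_sim
        if score.combined < 0.25:
            assert score.band == 0

    def test_band_edges(self):
        from oratox.targets import _band

        assert [_band(x) for x in (0.0, 0.24, 0.25, 0.49, 0.5, 0.74, 0.75, 1.0)] == [
            0, 0, 1, 1, 2, 2, 3, 3,
        ]

    def test_band_monotone_in_combined(self):
        from oratox.targets import _band

        xs = np.linspace(0, 1, 1000)
        bands = [_band(x) for x in xs]
        assert all(b1 <= b2 for b1, b2 in zip(bands, bands[1:]))

    def test_combined_in_unit_interval(self, db, target_fixtures):
        tlist = [t for t, _ in target_fixtures]
        for rec in list(db)[::20]:
            for s in target_profile(rec.mol, db, tlist):
                assert 0.0 <= s.combined <= 1.0
                assert s.band in (0, 1, 2, 3)
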