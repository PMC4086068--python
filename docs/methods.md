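# Methods

## Model and assumptions

The oral-toxicity predictor is a k-nearest-neighbor model in chemical
structure space. Its single modelling assumption is the similarity
principle: structurally similar compounds tend to show similar acute
toxicity. The estimate for a query is the median LD50 of its three most
similar reference compounds; the Tanimoto admission cutoff (0.7 for FP24,
0.5 for ECFP4) acts as the applicability domain — queries without a
sufficiently similar reference are declared not covered rather than
guessed at. Worst-case deduplication (minimum LD50 per InChI key) biases
the reference data conservatively toward higher toxicity.

The fragment channel assumes that over-representation of a substructure
among the most toxic classes marks a structural alert. The propensity
score PS(f,c) = (n_fc/N_c)/(n_f/N) is the lift of class-conditional over
marginal occurrence; its class-size-weighted mean is identically 1, so
the selection thresholds have a direct reading: PS > 3 means three-fold
over-representation, PS < 1 means at-or-below expectation. Occurrence is
presence-based (a compound counts once regardless of embedding
multiplicity) — multiplicity would overweight repetitive structures such
as polymers or sugars.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| GHS class bounds | 5, 50, 300, 2000, 5000 | mg/kg | GHS category limits, upper-bound inclusive |
| neighbor count k | 3 | – | best-performing setting of the similarity search |
| Tanimoto cutoff | 0.7 (FP24), 0.5 (ECFP4) | – | coverage/accuracy trade-off of each scheme |
| LD50 combiner | median | – | robust to a single discordant neighbor |
| PS selection | > 3 in I–III, < 1 in IV–VI | – | see lift interpretation above |
| fragment min size | 2 heavy atoms | – | single atoms match almost everything |
| decoy windows | MW ± 25 Da, logP ± 1, HBA ± 2, HBD ± 1, rotb ± 1, same charge | – | property-matched presumed inactives |
| decoy dissimilarity | < 0.75 to actives, < 0.9 pairwise (FP2) | – | prevents actives leaking into the decoy set |
| AUC retention | > 0.6 strict | – | keeps only discriminating fit models |
| ligand activity filter | < 100 μM (ligands), ≤ 1 nM (validation actives) | molar | known-binder vs high-confidence active |

## Fingerprints

FP2-type is a linear-path fingerprint (paths of 1–7 bonds hashed into
1024 bits); FP4-type is the 166 public MACCS substructure keys. FP24 is
their offset concatenation, so path and key information contribute
jointly to the Tanimoto index; ECFP4 is the 2048-bit Morgan fingerprint
of radius 2. Two empty bit sets score 1.0 (indistinguishable featureless
inputs); empty against non-empty scores 0.0.

## Consensus arithmetic

The fragment class is the most toxic class implicated by any matched
library fragment. The consensus is floor((sim + frag)/2): half-classes
round toward the more toxic class, consistent with the worst-case stance
of the deduplication rule. Without fragment evidence the similarity class
stands. The consensus always lies between the two input classes.

## Numerical choices and degenerate inputs

* Even-count medians are the mean of the two middle values.
* Neighbor ties at equal similarity break by database id, so reports are
  byte-identical across runs.
* An empty neighbor list yields a "no prediction" sentinel, never 0 mg/kg.
* Fragments occurring in no compound are flagged "no data" (PS = NaN) and
  never selected; classes absent from a database produce NaN PS columns
  that the selection rule treats as passing no threshold.
* ROC-AUC uses the rank-sum formulation with mid-ranks, counting ties as
  1/2; single-class inputs raise an error rather than returning 0.5.
* A compound a fit model fails to map scores 0, which penalizes the
  model in validation — preferable to silently dropping the compound.
* Molecules with zero rotatable bonds yield no ROTBONDS fragments: the
  intact molecule is deliberately not emitted as its own fragment, so
  rigid compounds do not flood the propensity statistics.
* Stereochemistry is kept in canonical SMILES and in the dedup key but
  ignored in substructure matching: mined fragment patterns are
  constitution-level.

## Open design points resolved here

* The target-profile combination is the mean of the ligand-similarity
  score and the average fit normalized by the target's maximum observed
  fit, binned at quartile edges 0.25/0.5/0.75 into four alert bands.
  When no reference compound passes the similarity cutoff, the ligand
  similarity stands alone.
* RECAP- and ROTBONDS-derived toxic fragments are merged into one library
  for prediction; per-method counts are kept in the library metadata.
* The fragment library used inside leave-one-out cross-validation is
  mined once on the full database, not per fold. This mirrors the
  method's sequencing (fragments belong to the reference set; CV tunes
  the similarity search) but is a small optimism source for the
  fragment-channel CV numbers.
* A CV "hit" is an exact class match; uncovered compounds are excluded
  from hit-rate denominators and reported through coverage instead.

## What the synthetic data emulates — and what it does not

The generator builds six scaffold families (large shared cores, small
substituent variations) and assigns one family per GHS class, sampling
LD50 values log-uniformly inside each class interval. This reproduces the
*neighborhood structure* the method relies on: compounds of a class are
mutual fingerprint neighbors (intra-family 3rd-neighbor FP24 Tanimoto
mostly above 0.7) while families stay below the admission cutoff of other
classes. A morpholine marker is planted in 90% of class-I compounds
(propensity lift 6 in a six-class balanced set) and a pyrrolidine decoy
uniformly at 50% everywhere (lift 1); consecutive scaffold templates are
near-isomers, so each family supplies property-matched but structurally
dissimilar decoy candidates for its twin. A marker planted in two of six
balanced classes would sit exactly at lift 3 and be excluded by the
strict threshold, which is why the default plants into a single class.

Real reference data differ in ways the fixture deliberately does not
model: classes are imbalanced and structurally heterogeneous, the
class–scaffold association is far weaker, LD50 values carry experimental
noise and censoring, and fragment signals are diluted across thousands of
scaffolds. Passing tests therefore demonstrate the *correctness of the
machinery* (retrieval, scoring, selection, metrics) and the qualitative
behavior of the pipeline — not the hit rates to expect on heterogeneous
real data, where coverage and accuracy are substantially lower. The
near-perfect cross-validation numbers on the fixture are a property of
its clustered construction.

Fit values are synthesized directly (normals separated by a chosen shift,
clipped at zero) rather than computed from 3D pharmacophore models, which
are outside this package's scope; the expected ROC-AUC of a separation s
is Φ(s/√2), which the validation machinery recovers within sampling
error.

## Problem sizes

Default fixture: 6 classes × 30 compounds (180 records, ≥ 96 possible
decorations per family). The acceptance script uses 33 per class with 3
per class held out for the external-style evaluation, 3 synthetic targets
with 8 actives each, and n = 500 per class for AUC recovery. These sizes
give stable statistics while keeping a full pipeline run in seconds.

## Known limitations

* FP2/FP4-type fingerprints are path- and key-based analogues, not
  bit-identical to any other toolkit's implementation; cutoffs retain
  their meaning but absolute similarity values differ across toolkits.
* LD50 rows must be plain positive numbers; range or ">" qualified values
  are rejected (no censoring model).
* No tautomer canonicalization; tautomers may receive distinct dedup keys.
* Coverage is the only applicability-domain signal; no confidence
  intervals accompany the predicted LD50.
* Single-species, oral-route data only.
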