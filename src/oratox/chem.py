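"""Molecule standardization, fingerprints, similarity and substructure matching.

All downstream modules operate on :class:`MoleculeRecord` objects produced by
:func:`standardize_molecule`; raw SMILES never travel further than this module.

Fingerprint schemes
-------------------
``FP2``
    Linear-path fingerprint (paths of 1-7 bonds hashed into 1024 bits),
    the open-source analogue of the classic path-based fingerprint.
``FP4``
    Predefined substructure-key fingerprint (166 public MACCS-type keys).
``FP24``
    Concatenation of FP2 and FP4: the FP4 bit indices are offset by the
    FP2 length, so the combined vector carries both path and key information.
``ECFP4``
    Extended-connectivity (circular, Morgan) fingerprint of diameter 4
    (radius 2), 2048 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

FP2_NBITS = 1024
FP4_NBITS = 166  # MACCS bit 0 is unused; we drop it and keep keys 1..166
ECFP4_NBITS = 2048

SCHEMES = ("FP2", "FP4", "FP24", "ECFP4")

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ECFP4_NBITS)
_rdk_gen = rdFingerprintGenerator.GetRDKitFPGenerator(minPath=1, maxPath=7, fpSize=FP2_NBITS)
_largest_fragment = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


class StandardizationError(ValueError):
    """Raised when an input structure cannot be standardized.

    Carries the offending SMILES string in :attr:`smiles`.
    """

    def __init__(self, message: str, smiles: str):
        super().__init__(f"{message}: {smiles!r}")
        self.smiles = smiles


class InorganicMoleculeError(StandardizationError):
    """Raised when the input contains no organic (carbon-bearing) fragment."""


class PatternError(ValueError):
    """Raised for substructure patterns that parse neither as SMARTS nor SMILES."""


class SchemeError(ValueError):
    """Raised for unknown fingerprint scheme names or scheme mismatches."""


@dataclass(frozen=True)
class PropertySet:
    """Physicochemical properties used for display and decoy matching.

    mw is in Da; logp is the Crippen octanol-water partition estimate;
    hba/hbd/rotb are counts; charge is the total formal charge.
    """

    mw: float
    logp: float
    hba: int
    hbd: int
    rotb: int
    charge: int


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized compound.

    ``smiles_canonical`` re-canonicalizes to itself; ``dedup_key`` is the
    InChI key of the standardized structure and is the identity used for
    duplicate removal throughout.
    """

    id: str
    smiles_canonical: str
    dedup_key: str
    props: PropertySet

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule (reparsed from the canonical SMILES)."""
        return Chem.MolFromSmiles(self.smiles_canonical)


@dataclass(frozen=True)
class BitFingerprint:
    scheme: str
    bits: frozenset[int] = field(default_factory=frozenset)
    length: int = 0

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.length):
            raise ValueError("bit index out of range")


def standardize_molecule(raw: str, mol_id: str = "") -> MoleculeRecord:
    """Standardize a raw SMILES string into a :class:`MoleculeRecord`.

    The protocol: parse, keep the largest organic covalent fragment
    (stripping salts and solvents), normalize functional-group
    representations (nitro, azide, ...), neutralize simple protonation
    states, drop explicit hydrogens, and emit canonical SMILES plus an
    InChI-key dedup key and the physicochemical property set.

    Raises
    ------
    StandardizationError
        If ``raw`` is empty or does not parse.
    InorganicMoleculeError
        If no fragment contains carbon.
    """
    if not raw or not raw.strip():
        raise StandardizationError("empty SMILES", raw)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError("unparseable SMILES", raw)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise InorganicMoleculeError("no organic fragment", raw)
    mol = _largest_fragment.choose(mol)
    mol = rdMolStandardize.Normalize(mol)
    mol = _uncharger.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    smiles = Chem.MolToSmiles(mol)
    key = Chem.MolToInchiKey(mol)
    return MoleculeRecord(
        id=mol_id, smiles_canonical=smiles, dedup_key=key, props=_properties(mol)
    )


def _properties(mol: Chem.Mol) -> PropertySet:
    return PropertySet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
        charge=Chem.GetFormalCharge(mol),
    )


def physchem_properties(record: MoleculeRecord) -> PropertySet:
    """Property set of a standardized molecule (recomputed from structure)."""
    return _properties(record.mol())


def _bits(fp) -> frozenset[int]:
    return frozenset(fp.GetOnBits())


def compute_fingerprint(record: MoleculeRecord, scheme: str) -> BitFingerprint:
    """Compute the binary fingerprint of a standardized molecule.

    ``FP24`` is built as the offset union of the FP2 and FP4 bit sets.
    """
    mol = record.mol()
    if scheme == "FP2":
        return BitFingerprint("FP2", _bits(_rdk_gen.GetFingerprint(mol)), FP2_NBITS)
    if scheme == "FP4":
        # MACCS keys: bit 0 is a placeholder, shift to a 0-based 166-bit vector
        on = frozenset(b - 1 for b in MACCSkeys.GenMACCSKeys(mol).GetOnBits() if b >= 1)
        return BitFingerprint("FP4", on, FP4_NBITS)
    if scheme == "FP24":
        fp2 = compute_fingerprint(record, "FP2")
        fp4 = compute_fingerprint(record, "FP4")
        bits = frozenset(fp2.bits) | frozenset(b + FP2_NBITS for b in fp4.bits)
        return BitFingerprint("FP24", bits, FP2_NBITS + FP4_NBITS)
    if scheme == "ECFP4":
        return BitFingerprint("ECFP4", _bits(_morgan_gen.GetFingerprint(mol)), ECFP4_NBITS)
    raise SchemeError(f"unknown fingerprint scheme: {scheme!r}")


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto index |A∩B| / |A∪B| between two same-scheme fingerprints.

    Two empty bit sets are treated as indistinguishable (similarity 1.0);
    an empty set against a non-empty one scores 0.0.
    """
    if a.scheme != b.scheme:
        raise SchemeError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def parse_pattern(pattern: str) -> Chem.Mol:
    """Parse a substructure pattern, accepting SMARTS and plain SMILES."""
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        query = Chem.MolFromSmiles(pattern)
    if query is None:
        raise PatternError(f"invalid substructure pattern: {pattern!r}")
    return query


def substructure_match(record: MoleculeRecord, pattern) -> tuple[bool, int]:
    """Whether (and how many times) a pattern embeds in a molecule.

    Matching is constitution-level: stereochemistry is ignored. ``pattern``
    may be a SMARTS/SMILES string or a pre-parsed query molecule. Returns
    ``(matched, number of distinct embeddings)``.
    """
    query = parse_pattern(pattern) if isinstance(pattern, str) else pattern
    matches = record.mol().GetSubstructMatches(query, uniquify=True, useChirality=False)
    return (len(matches) > 0, len(matches))


def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a SMILES list (one per line, optional whitespace-separated id)."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
            records.append(standardize_molecule(smi, mol_id))
    return records


def read_sdf_file(path, ld50_field: str | None = None):
    """Read an SDF (V2000) file into MoleculeRecords.

    When ``ld50_field`` is given, returns (record, ld50) pairs pulled from
    that SDF property; otherwise returns records only.
    """
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rec = standardize_molecule(Chem.MolToSmiles(mol), name or f"sdf{i + 1}")
        if ld50_field is None:
            out.append(rec)
        elif mol.HasProp(ld50_field):
            out.append((rec, float(mol.GetProp(ld50_field))))
    return out
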