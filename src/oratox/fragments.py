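"""Fragmentation, propensity-score analysis and the toxic-fragment library.

Compounds of the reference database are fragmented with two complementary
schemes — RECAP (retrosynthetic cleavage at 11 chemically meaningful bond
types) and ROTBONDS (cleavage at every rotatable bond) — and each distinct
fragment is scored for over-representation in the most toxic GHS classes.

The propensity score of fragment f in class c is the class-conditional
occurrence rate relative to the overall occurrence rate:

    PS(f, c) = (n_fc / N_c) / (n_f / N)

where n_fc counts compounds of class c containing f (presence, not
embedding multiplicity), N_c is the class size, n_f = Σ_c n_fc and N the
database size. PS > 1 marks over-representation; the class-size-weighted
mean of PS over classes is identically 1 for every fragment that occurs
at all. A fragment enters the toxic-fragment library when PS exceeds 3 in
at least one of classes I-III while staying below 1 in all of IV-VI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Recap

from . import chem
from .chem import MoleculeRecord
from .toxdb import ToxicityClass, ToxicityDatabase

#: PS must exceed this in at least one of classes I-III.
PS_TOXIC_THRESHOLD = 3.0
#: PS must stay below this in every one of classes IV-VI.
PS_SAFE_THRESHOLD = 1.0
MIN_HEAVY_ATOMS = 2

TOXIC_CLASSES = (ToxicityClass.I, ToxicityClass.II, ToxicityClass.III)
SAFE_CLASSES = (ToxicityClass.IV, ToxicityClass.V, ToxicityClass.VI)


@dataclass(frozen=True)
class Fragment:
    """A substructure pattern produced by one of the fragmentation schemes.

    ``pattern`` is the canonical SMILES of the hydrogen-capped fragment;
    identity and matching are constitution-level.
    """

    pattern: str
    origin: str  # RECAP | ROTBONDS
    heavy_atoms: int


def _cap_and_canonicalize(mol: Chem.Mol) -> str | None:
    """Replace attachment-point dummies with hydrogen; canonical SMILES."""
    edit = Chem.RWMol(mol)
    for atom in edit.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
            atom.SetNoImplicit(False)
    try:
        stripped = Chem.RemoveHs(edit.GetMol())
        Chem.SanitizeMol(stripped)
    except Exception:
        return None
    return Chem.MolToSmiles(stripped)


def _emit(smiles_set: set[str], origin: str) -> set[Fragment]:
    frags = set()
    for smi in smiles_set:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        heavy = mol.GetNumHeavyAtoms()
        if heavy >= MIN_HEAVY_ATOMS:
            frags.add(Fragment(smi, origin, heavy))
    return frags


def fragment_recap(record: MoleculeRecord) -> set[Fragment]:
    """RECAP fragmentation of a standardized molecule.

    Cleaves at the canonical retrosynthetic bond types (amide, ester, amine,
    urea, ether, olefin, quaternary N, aromatic N - aliphatic C, lactam
    N - aliphatic C, biaryl, sulphonamide); attachment points are capped
    with hydrogen and fragments below two heavy atoms are discarded.
    Molecules without a cleavable bond yield the empty set.
    """
    mol = record.mol()
    tree = Recap.RecapDecompose(mol)
    leaves = tree.GetLeaves()
    out: set[str] = set()
    for leaf in leaves.values():
        capped = _cap_and_canonicalize(leaf.mol)
        if capped:
            out.add(capped)
    return _emit(out, "RECAP")


# Strict rotatable bond: single, acyclic, both atoms non-terminal, no triple
# bond neighbours; the amide C-N bond is excluded separately.
_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")
_AMIDE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])")


def _rotatable_bond_indices(mol: Chem.Mol) -> list[int]:
    amide_bonds = set()
    for n_idx, c_idx, _o in mol.GetSubstructMatches(_AMIDE):
        bond = mol.GetBondBetweenAtoms(n_idx, c_idx)
        if bond is not None:
            amide_bonds.add(bond.GetIdx())
    out = []
    for a_idx, b_idx in mol.GetSubstructMatches(_ROTATABLE):
        bond = mol.GetBondBetweenAtoms(a_idx, b_idx)
        if bond is not None and bond.GetIdx() not in amide_bonds:
            out.append(bond.GetIdx())
    return sorted(set(out))


def fragment_rotbonds(record: MoleculeRecord) -> set[Fragment]:
    """Cut a molecule at every rotatable bond and return the pieces.

    Rotatable means single, acyclic, with both atoms non-terminal; amide
    C-N bonds do not count. All cuts are applied simultaneously, the
    resulting connected pieces are hydrogen-capped, and pieces below two
    heavy atoms are discarded. A molecule with zero rotatable bonds yields
    the empty set (the intact molecule is not its own fragment).
    """
    mol = record.mol()
    bonds = _rotatable_bond_indices(mol)
    if not bonds:
        return set()
    fragmented = Chem.FragmentOnBonds(mol, bonds, addDummies=True)
    out: set[str] = set()
    for piece in Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False):
        capped = _cap_and_canonicalize(piece)
        if capped:
            out.add(capped)
    return _emit(out, "ROTBONDS")


class PropensityTable:
    """Per-fragment, per-class occurrence counts and propensity scores."""

    def __init__(self, fragments: list[Fragment], class_sizes: dict[ToxicityClass, int]):
        self.fragments = list(fragments)
        self.class_sizes = dict(class_sizes)
        self.N = sum(class_sizes.values())
        self.counts = np.zeros((len(self.fragments), 6), dtype=int)  # n_fc
        self.ps: np.ndarray | None = None  # filled by propensity_scores

    @property
    def n_f(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        data = {"pattern": [f.pattern for f in self.fragments],
                "origin": [f.origin for f in self.fragments],
                "n_f": self.n_f}
        for c in ToxicityClass:
            data[f"n_{c.name}"] = self.counts[:, c - 1]
        if self.ps is not None:
            for c in ToxicityClass:
                data[f"ps_{c.name}"] = self.ps[:, c - 1]
        return pd.DataFrame(data)


def count_occurrences(
    frags: set[Fragment] | list[Fragment], db: ToxicityDatabase
) -> PropensityTable:
    """Count, per class, how many database compounds contain each fragment.

    Occurrence is presence-based: a compound counts once no matter how many
    embeddings of the fragment it contains.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    fragments = sorted(set(frags), key=lambda f: (f.origin, f.pattern))
    table = PropensityTable(fragments, db.class_sizes)
    queries = [chem.parse_pattern(f.pattern) for f in fragments]
    for rec in db:
        mol = rec.mol.mol()
        col = rec.tox_class - 1
        for i, q in enumerate(queries):
            if mol.HasSubstructMatch(q, useChirality=False):
                table.counts[i, col] += 1
    return table


def propensity_scores(table: PropensityTable) -> PropensityTable:
    """Fill PS(f,c) = (n_fc / N_c) / (n_f / N) into the table (in place).

    Fragments with n_f = 0 are flagged "no data": their PS row is NaN and
    they are never selected. Classes absent from the database (N_c = 0)
    get PS = NaN in that column.
    """
    n_f = table.n_f.astype(float)
    n_c = np.array([table.class_sizes.get(c, 0) for c in ToxicityClass], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_class = np.where(n_c > 0, table.counts / n_c, np.nan)
        rate_all = n_f[:, None] / table.N
        ps = np.where(rate_all > 0, rate_class / rate_all, np.nan)
    table.ps = ps
    return table


@dataclass(frozen=True)
class LibraryEntry:
    fragment: Fragment
    implicated: frozenset[ToxicityClass]  # subset of {I, II, III} with PS > 3
    ps: tuple[float, ...]  # PS over the six classes


class ToxicFragmentLibrary:
    """Fragments over-represented in the toxic classes, with metadata."""

    def __init__(self, entries: list[LibraryEntry], meta: dict | None = None):
        self.entries = list(entries)
        self.meta = dict(meta or {})
        self._queries = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def compiled_queries(self):
        if self._queries is None:
            self._queries = [chem.parse_pattern(e.fragment.pattern) for e in self.entries]
        return self._queries


def select_toxic_fragments(table: PropensityTable) -> ToxicFragmentLibrary:
    """Apply the toxic-fragment selection rule to a scored table.

    A fragment is selected iff PS > 3 in at least one of classes I-III and
    PS < 1 in all of classes IV-VI; the implicated classes are those of
    I-III where PS exceeds 3.
    """
    if table.ps is None:
        raise ValueError("propensity scores not computed")
    entries = []
    for i, frag in enumerate(table.fragments):
        row = table.ps[i]
        if np.isnan(row).all():
            continue  # no data
        toxic_ps = [row[c - 1] for c in TOXIC_CLASSES]
        safe_ps = [row[c - 1] for c in SAFE_CLASSES]
        implicated = frozenset(
            c for c, p in zip(TOXIC_CLASSES, toxic_ps) if not np.isnan(p) and p > PS_TOXIC_THRESHOLD
        )
        safe_ok = all(np.isnan(p) or p < PS_SAFE_THRESHOLD for p in safe_ps)
        if implicated and safe_ok:
            entries.append(LibraryEntry(frag, implicated, tuple(float(x) for x in row)))
    return ToxicFragmentLibrary(
        entries,
        meta={
            "ps_toxic_threshold": PS_TOXIC_THRESHOLD,
            "ps_safe_threshold": PS_SAFE_THRESHOLD,
            "n_compounds": table.N,
        },
    )


def match_toxic_fragments(
    query: MoleculeRecord, lib: ToxicFragmentLibrary
) -> list[tuple[Fragment, frozenset[ToxicityClass]]]:
    """All library fragments embedding in the query molecule."""
    mol = query.mol()
    out = []
    for entry, q in zip(lib.entries, lib.compiled_queries()):
        if mol.HasSubstructMatch(q, useChirality=False):
            out.append((entry.fragment, entry.implicated))
    return out


def mine_fragment_library(
    db: ToxicityDatabase, methods: tuple[str, ...] = ("RECAP", "ROTBONDS")
) -> ToxicFragmentLibrary:
    """Fragment every database compound and extract the toxic-fragment library.

    Libraries from the requested fragmentation methods are merged into one
    (duplicate patterns keep the first entry seen).
    """
    fragmenters = {"RECAP": fragment_recap, "ROTBONDS": fragment_rotbonds}
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    meta: dict = {"methods": list(methods)}
    for method in methods:
        frag_fn = fragmenters[method]
        all_frags: set[Fragment] = set()
        for rec in db:
            all_frags |= frag_fn(rec.mol)
        if not all_frags:
            continue
        table = propensity_scores(count_occurrences(all_frags, db))
        lib = select_toxic_fragments(table)
        meta[f"n_fragments_{method}"] = len(table.fragments)
        meta[f"n_selected_{method}"] = len(lib)
        for entry in lib:
            if entry.fragment.pattern not in seen:
                seen.add(entry.fragment.pattern)
                entries.append(entry)
    meta.update(
        ps_toxic_threshold=PS_TOXIC_THRESHOLD,
        ps_safe_threshold=PS_SAFE_THRESHOLD,
        n_compounds=len(db),
    )
    return ToxicFragmentLibrary(entries, meta)


def save_library(lib: ToxicFragmentLibrary, path) -> None:
    """Write the library as a delimited table plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("pattern\timplicated_classes\torigin\theavy_atoms\tps\n")
        for e in lib.entries:
            classes = ",".join(str(int(c)) for c in sorted(e.implicated))
            ps = ",".join(f"{x:.6g}" if not np.isnan(x) else "nan" for x in e.ps)
            fh.write(f"{e.fragment.pattern}\t{classes}\t{e.fragment.origin}"
                     f"\t{e.fragment.heavy_atoms}\t{ps}\n")
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(lib.meta, indent=1))


def load_library(path) -> ToxicFragmentLibrary:
    path = Path(path)
    entries = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pattern, classes, origin, heavy, ps = line.rstrip("\n").split("\t")
            entries.append(
                LibraryEntry(
                    Fragment(pattern, origin, int(heavy)),
                    frozenset(ToxicityClass(int(c)) for c in classes.split(",") if c),
                    tuple(float(x) for x in ps.split(",")),
                )
            )
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ToxicFragmentLibrary(entries, meta)
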