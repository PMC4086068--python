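"""Reference acute oral toxicity database: GHS classes, dedup, persistence.

The database maps standardized structures to their worst-case (minimum
reported) oral LD50 in mg/kg body weight and the derived GHS toxicity class,
and carries per-scheme fingerprint indices for similarity search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

from . import chem
from .chem import BitFingerprint, MoleculeRecord

FORMAT_VERSION = 1

#: GHS acute-oral class boundaries in mg/kg body weight (upper bounds, inclusive).
CLASS_THRESHOLDS = (5.0, 50.0, 300.0, 2000.0, 5000.0)


class ToxicityClass(IntEnum):
    """Six GHS-derived acute oral toxicity classes; I is the most toxic."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6


def assign_toxicity_class(ld50: float) -> ToxicityClass:
    """GHS class for an oral LD50 in mg/kg.

    Intervals are upper-bound inclusive: I ≤ 5 < II ≤ 50 < III ≤ 300
    < IV ≤ 2000 < V ≤ 5000 < VI.
    """
    if not ld50 > 0:
        raise ValueError(f"LD50 must be positive, got {ld50}")
    for i, bound in enumerate(CLASS_THRESHOLDS):
        if ld50 <= bound:
            return ToxicityClass(i + 1)
    return ToxicityClass.VI


@dataclass
class ToxicityRecord:
    mol: MoleculeRecord
    ld50: float
    tox_class: ToxicityClass
    source: str = ""


@dataclass
class BuildReport:
    rows_in: int = 0
    duplicates_merged: int = 0
    rows_rejected: int = 0
    rejected: list = field(default_factory=list)  # (id, smiles, reason)


class DatabaseFormatError(RuntimeError):
    """On-disk database is missing, truncated, or of an incompatible version."""


class ToxicityDatabase:
    """Indexed collection of :class:`ToxicityRecord`, keyed by dedup key."""

    def __init__(self, schemes: tuple[str, ...] = ("FP24", "ECFP4")):
        self.records: dict[str, ToxicityRecord] = {}
        self.schemes = tuple(schemes)
        self.fp_index: dict[str, dict[str, BitFingerprint]] = {s: {} for s in schemes}
        self.cv_accuracy: dict[int, float] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    @property
    def class_sizes(self) -> dict[ToxicityClass, int]:
        sizes = {c: 0 for c in ToxicityClass}
        for rec in self.records.values():
            sizes[rec.tox_class] += 1
        return sizes

    def add(self, record: ToxicityRecord) -> bool:
        """Insert a record, merging duplicates with the worst-case (min) LD50.

        Returns True when the record merged into an existing entry.
        """
        key = record.mol.dedup_key
        existing = self.records.get(key)
        if existing is not None:
            if record.ld50 < existing.ld50:
                existing.ld50 = record.ld50
                existing.tox_class = assign_toxicity_class(record.ld50)
                if record.source:
                    existing.source = record.source
            return True
        self.records[key] = record
        for scheme in self.schemes:
            self.fp_index[scheme][key] = chem.compute_fingerprint(record.mol, scheme)
        return False

    def fingerprint(self, key: str, scheme: str) -> BitFingerprint:
        if scheme not in self.fp_index:
            raise chem.SchemeError(f"database not indexed for scheme {scheme!r}")
        return self.fp_index[scheme][key]


def build_database(
    rows, schemes: tuple[str, ...] = ("FP24", "ECFP4")
) -> tuple[ToxicityDatabase, BuildReport]:
    """Build a database from (id, smiles, ld50[, source]) rows.

    Rows with the same standardized structure (identical dedup key) are
    merged keeping the minimum LD50 — the worst-case toxicity. Unparseable
    rows are skipped and listed in the build report, never silently dropped.
    """
    db = ToxicityDatabase(schemes)
    report = BuildReport()
    for row in rows:
        row = tuple(row)
        mol_id, smiles, ld50 = row[0], row[1], row[2]
        source = row[3] if len(row) > 3 else ""
        report.rows_in += 1
        try:
            ld50 = float(ld50)
            if not ld50 > 0:
                raise ValueError(f"non-positive LD50 {ld50}")
            rec_mol = chem.standardize_molecule(smiles, str(mol_id))
        except (ValueError, chem.StandardizationError) as exc:
            report.rows_rejected += 1
            report.rejected.append((str(mol_id), smiles, str(exc)))
            continue
        merged = db.add(
            ToxicityRecord(rec_mol, ld50, assign_toxicity_class(ld50), str(source))
        )
        if merged:
            report.duplicates_merged += 1
    return db, report


def read_rows_csv(path):
    """Read (id, smiles, ld50, source) rows from a headered CSV/TSV file."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    idc = cols.get("id", df.columns[0])
    smc = cols.get("smiles", df.columns[1])
    ldc = cols.get("ld50_mg_kg", cols.get("ld50", df.columns[2]))
    src = cols.get("source")
    for _, r in df.iterrows():
        yield (r[idc], r[smc], r[ldc], r[src] if src else "")


def save_database(db: ToxicityDatabase, path) -> None:
    """Persist the database as a versioned directory.

    Layout: ``meta.json`` (format version, schemes, cv accuracy),
    ``records.tsv`` (one row per compound) and one ``fps_<scheme>.tsv``
    hex-encoded bit-string sidecar per indexed scheme.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "schemes": list(db.schemes),
        "n_records": len(db),
        "cv_accuracy": {str(k): v for k, v in db.cv_accuracy.items()}
        if db.cv_accuracy
        else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    with open(path / "records.tsv", "w") as fh:
        fh.write("id\tsmiles\tdedup_key\tld50_mg_kg\ttox_class\tsource\n")
        for rec in db:
            fh.write(
                f"{rec.mol.id}\t{rec.mol.smiles_canonical}\t{rec.mol.dedup_key}"
                f"\t{rec.ld50!r}\t{int(rec.tox_class)}\t{rec.source}\n"
            )
    for scheme in db.schemes:
        with open(path / f"fps_{scheme}.tsv", "w") as fh:
            fh.write("dedup_key\tlength\tbits_hex\n")
            for key, fp in db.fp_index[scheme].items():
                n = (fp.length + 3) // 4
                val = 0
                for b in fp.bits:
                    val |= 1 << b
                fh.write(f"{key}\t{fp.length}\t{val:0{n}x}\n")


def _parse_hex_bits(hexstr: str) -> frozenset[int]:
    val = int(hexstr, 16)
    bits, i = [], 0
    while val:
        if val & 1:
            bits.append(i)
        val >>= 1
        i += 1
    return frozenset(bits)


def load_database(path) -> ToxicityDatabase:
    """Load a database directory written by :func:`save_database`.

    Raises :class:`DatabaseFormatError` on missing files, truncation, or a
    format-version mismatch. The round trip is lossless.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise DatabaseFormatError(f"not a database directory: {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise DatabaseFormatError(f"corrupt meta.json: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise DatabaseFormatError(
            f"incompatible format version {meta.get('format_version')!r}, "
            f"expected {FORMAT_VERSION}"
        )
    schemes = tuple(meta["schemes"])
    db = ToxicityDatabase(schemes)
    with open(path / "records.tsv") as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise DatabaseFormatError("records.tsv missing header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise DatabaseFormatError(f"truncated records.tsv row: {line!r}")
            mol_id, smiles, key, ld50, cls, source = parts
            rec_mol = chem.standardize_molecule(smiles, mol_id)
            if rec_mol.dedup_key != key:
                raise DatabaseFormatError(f"dedup key mismatch for {mol_id}")
            db.records[key] = ToxicityRecord(
                rec_mol, float(ld50), ToxicityClass(int(cls)), source
            )
    for scheme in schemes:
        fp_path = path / f"fps_{scheme}.tsv"
        if not fp_path.exists():
            raise DatabaseFormatError(f"missing fingerprint sidecar for {scheme}")
        with open(fp_path) as fh:
            fh.readline()
            for line in fh:
                key, length, hexstr = line.rstrip("\n").split("\t")
                db.fp_index[scheme][key] = BitFingerprint(
                    scheme, _parse_hex_bits(hexstr), int(length)
                )
        if set(db.fp_index[scheme]) != set(db.records):
            raise DatabaseFormatError(f"fingerprint sidecar for {scheme} incomplete")
    if meta.get("n_records") != len(db):
        raise DatabaseFormatError("record count mismatch (truncated records.tsv?)")
    if meta.get("cv_accuracy"):
        db.cv_accuracy = {int(k): float(v) for k, v in meta["cv_accuracy"].items()}
    return db
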