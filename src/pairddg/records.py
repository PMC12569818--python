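"""Data model and tabular I/O for mutation / ligand / ddG datasets.

A dataset is an ordered collection of :class:`MutationRecord`, one row per
experimental observation of a mutation-induced change in protein-ligand
binding free energy (ddG = dG_mutant - dG_wild-type, kcal/mol).  Records are
grouped by UniProt accession; the group label is what the leakage-aware
splitting strategies operate on.

The canonical interchange format is a delimited text file (CSV or TSV) with
header columns ``record_id, uniprot_id, wild_seq, mutation_spec, mutant_seq,
smiles, ddg, distance``.  Unknown extra columns survive a round-trip as
opaque per-record metadata.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "MutationRecord",
    "Dataset",
    "PointMutation",
    "parse_mutation_spec",
    "validate_record",
    "read_dataset",
    "write_dataset",
    "read_fasta_sidecar",
    "write_fasta_sidecar",
    "DatasetFormatError",
    "DatasetValidationError",
]

#: The 20 canonical residues plus X for unknown.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"

_CANONICAL_COLUMNS = [
    "record_id",
    "uniprot_id",
    "wild_seq",
    "mutation_spec",
    "mutant_seq",
    "smiles",
    "ddg",
    "distance",
]
_MANDATORY_COLUMNS = ["record_id", "uniprot_id", "wild_seq", "smiles", "ddg"]

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class DatasetFormatError(ValueError):
    """Raised when a file cannot be parsed into the canonical schema."""


class DatasetValidationError(ValueError):
    """Raised when parsed rows violate dataset-level invariants."""


@dataclass(frozen=True)
class PointMutation:
    """One substitution: wild residue, 1-based position, mutant residue."""

    wild: str
    position: int  # 1-based
    mutant: str

    def __str__(self) -> str:  # e.g. "T315I"
        return f"{self.wild}{self.position}{self.mutant}"


def parse_mutation_spec(spec: str) -> list[PointMutation]:
    """Parse a mutation specification like ``"T315I"`` or ``"G719S+T790M"``.

    Positions are 1-based, following the standard notation.  Multiple
    substitutions are joined by ``+``; whitespace around the separator is
    tolerated.
    """
    muts = []
    for token in spec.split("+"):
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if m is None:
            raise ValueError(f"malformed mutation token {token!r} in spec {spec!r}")
        muts.append(PointMutation(m.group(1), int(m.group(2)), m.group(3)))
    return muts


@dataclass
class MutationRecord:
    """One wild/mutant/ligand/ddG observation.

    Exactly one of ``mutation_spec`` and ``mutant_seq`` may be omitted; the
    other is then authoritative for the mutant sequence.
    """

    record_id: str
    uniprot_id: str
    wild_seq: str
    smiles: str
    ddg: float
    mutation_spec: str | None = None
    mutant_seq: str | None = None
    distance: float | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        violations = validate_record(self)
        if violations:
            raise DatasetValidationError(
                f"invalid record {self.record_id!r}: " + "; ".join(violations)
            )


def validate_record(r: MutationRecord) -> list[str]:
    """Return the list of invariant violations for ``r`` (empty iff valid).

    Validation is total: it never raises on a malformed-but-constructed
    record; every problem becomes one human-readable entry naming the field
    and the rule it breaks.
    """
    violations: list[str] = []
    if not r.record_id:
        violations.append("record_id: must be non-empty")
    if not r.uniprot_id:
        violations.append("uniprot_id: must be non-empty")
    if not r.wild_seq:
        violations.append("wild_seq: must be non-empty")
    else:
        bad = sorted({c for c in r.wild_seq if c not in AMINO_ACIDS})
        if bad:
            violations.append(f"wild_seq: invalid residue(s) {''.join(bad)}")
    if not r.smiles:
        violations.append("smiles: must be non-empty")
    if r.ddg is None or not math.isfinite(r.ddg):
        violations.append("ddg: must be finite")
    if r.distance is not None and (not math.isfinite(r.distance) or r.distance < 0):
        violations.append("distance: must be finite and >= 0")
    if r.mutation_spec is None and r.mutant_seq is None:
        violations.append("mutation_spec/mutant_seq: at least one must be given")
    if r.mutant_seq is not None:
        bad = sorted({c for c in r.mutant_seq if c not in AMINO_ACIDS})
        if bad:
            violations.append(f"mutant_seq: invalid residue(s) {''.join(bad)}")
    if r.mutation_spec is not None and r.wild_seq:
        try:
            muts = parse_mutation_spec(r.mutation_spec)
        except ValueError as exc:
            violations.append(f"mutation_spec: {exc}")
        else:
            seen: set[int] = set()
            for m in muts:
                if m.position in seen:
                    violations.append(
                        f"mutation_spec: duplicate position {m.position}"
                    )
                seen.add(m.position)
                if not (1 <= m.position <= len(r.wild_seq)):
                    violations.append(
                        f"mutation_spec: position {m.position} outside "
                        f"1..{len(r.wild_seq)}"
                    )
                elif r.wild_seq[m.position - 1] != m.wild:
                    violations.append(
                        f"mutation_spec: wild residue mismatch at {m.position} "
                        f"(spec says {m.wild}, sequence has "
                        f"{r.wild_seq[m.position - 1]})"
                    )
    return violations


@dataclass
class Dataset:
    """Ordered collection of records with unique ids."""

    records: list[MutationRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: set[str] = set()
        for r in self.records:
            (dups if r.record_id in seen else seen).add(r.record_id)
        if dups:
            raise DatasetValidationError(f"duplicate record_id(s): {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MutationRecord:
        return self.records[i]

    def by_id(self, record_id: str) -> MutationRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def uniprot_ids(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.uniprot_id, None)
        return list(seen)

    def groups(self) -> dict[str, list[MutationRecord]]:
        out: dict[str, list[MutationRecord]] = {}
        for r in self.records:
            out.setdefault(r.uniprot_id, []).append(r)
        return out

    def subset(self, ids: Iterable[str]) -> "Dataset":
        """Records with the given ids, in this dataset's order."""
        wanted = set(ids)
        return Dataset(
            [r for r in self.records if r.record_id in wanted],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        extra_cols: list[str] = []
        for r in self.records:
            row = {
                "record_id": r.record_id,
                "uniprot_id": r.uniprot_id,
                "wild_seq": r.wild_seq,
                "mutation_spec": r.mutation_spec,
                "mutant_seq": r.mutant_seq,
                "smiles": r.smiles,
                "ddg": r.ddg,
                "distance": r.distance,
            }
            for k, v in r.metadata.items():
                row[k] = v
                if k not in extra_cols:
                    extra_cols.append(k)
            rows.append(row)
        return pd.DataFrame(rows, columns=_CANONICAL_COLUMNS + extra_cols)


def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
        return dialect
    return "tsv" if str(path).endswith((".tsv", ".tab", ".txt")) else "csv"


def read_fasta_sidecar(path: str | Path) -> dict[str, str]:
    """Load a FASTA sidecar of wild-type sequences keyed by record_id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_sidecar(ds: Dataset, path: str | Path) -> Path:
    """Write each record's wild-type sequence to FASTA, keyed by record_id."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    seqio_write(
        (SeqRecord(Seq(r.wild_seq), id=r.record_id, description="") for r in ds),
        str(path),
        "fasta",
    )
    return path


def read_dataset(
    path: str | Path,
    dialect: str | None = None,
    fasta: str | Path | None = None,
) -> Dataset:
    """Read a delimited mutation table into a validated :class:`Dataset`.

    The delimiter is inferred from the file extension (``.tsv``/``.tab``/
    ``.txt`` are tab-separated, anything else comma-separated) unless
    ``dialect`` overrides it.  Row order is preserved; extra columns are kept
    as per-record metadata.  When ``fasta`` names a sidecar file, rows with
    an empty ``wild_seq`` take their sequence from the sidecar entry with
    the same record_id (useful for very long sequences).
    """
    path = Path(path)
    sep = "\t" if _infer_dialect(path, dialect) == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    extra_cols = [c for c in df.columns if c not in _CANONICAL_COLUMNS]
    sidecar = read_fasta_sidecar(fasta) if fasta is not None else {}

    records = []
    errors = []
    for _, row in df.iterrows():
        rid = row["record_id"]
        try:
            ddg = float(row["ddg"])
        except ValueError:
            errors.append(f"record {rid!r}: ddg value {row['ddg']!r} is not a number")
            continue
        dist_raw = str(row.get("distance", "") or "").strip()
        distance = None
        if dist_raw not in ("", "NA", "nan"):
            try:
                distance = float(dist_raw)
            except ValueError:
                errors.append(
                    f"record {rid!r}: distance value {dist_raw!r} is not a number"
                )
                continue
        try:
            records.append(
                MutationRecord(
                    record_id=rid,
                    uniprot_id=row["uniprot_id"],
                    wild_seq=row["wild_seq"] or sidecar.get(rid, ""),
                    mutation_spec=(str(row.get("mutation_spec", "")).strip() or None),
                    mutant_seq=(str(row.get("mutant_seq", "")).strip() or None),
                    smiles=row["smiles"],
                    ddg=ddg,
                    distance=distance,
                    metadata={c: row[c] for c in extra_cols},
                )
            )
        except DatasetValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise DatasetValidationError(f"{path}: " + "; ".join(errors))
    return Dataset(records, provenance=str(path))


def write_dataset(ds: Dataset, path: str | Path, dialect: str | None = None) -> Path:
    """Write ``ds`` so that :func:`read_dataset` round-trips it exactly.

    Floats are written with ``repr`` precision so the round-trip is
    bit-exact for every finite double.
    """
    path = Path(path)
    sep = "\t" if _infer_dialect(path, dialect) == "tsv" else ","
    df = ds.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format=None, na_rep="")
    return path
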