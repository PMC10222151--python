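"""Sequence and metadata I/O.

Defines the canonical in-memory genome record used by every other module
and readers/writers for FASTA (plain or gzip) and the tab-separated
association table linking phages/plasmids to host groups and, when known,
to a lytic or lysogenic lifestyle label.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

Role = Literal["host", "phage", "plasmid"]

_ROLES = ("host", "phage", "plasmid")
_LIFESTYLES = ("lytic", "lysogenic")

# IUPAC nucleotide codes accepted on input (uppercase after loading).
IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One genome (or genome element): an id, ordered contigs, and a role.

    Contigs are uppercase DNA strings; ``length`` is the total number of
    nucleotides across contigs. Multi-contig records arise from draft
    (chromosome-level) assemblies loaded in per-file mode.
    """

    id: str
    contigs: tuple[str, ...]
    role: Role = "host"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        object.__setattr__(self, "contigs", tuple(self.contigs))

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class AssociationTable:
    """Phage/plasmid -> host-group metadata.

    Wraps a DataFrame with columns ``element_id``, ``role``,
    ``host_group``, ``lifestyle`` (nullable) plus any extra columns from
    the source TSV. Lifestyle, when present, is exactly ``lytic`` or
    ``lysogenic``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("element_id", "role", "host_group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"association table missing required columns: {', '.join(missing)}")
        if "lifestyle" not in self.table.columns:
            self.table["lifestyle"] = pd.Series([None] * len(self.table), dtype=object)
        self.table["lifestyle"] = [_normalize_lifestyle(v) for v in self.table["lifestyle"]]
        bad_roles = set(self.table["role"]) - {"phage", "plasmid"}
        if bad_roles:
            raise ValueError(f"unknown element role(s): {sorted(bad_roles)}")

    def __len__(self) -> int:
        return len(self.table)

    def lifestyle_of(self, element_id: str) -> str | None:
        rows = self.table.loc[self.table["element_id"] == element_id, "lifestyle"]
        return None if rows.empty else rows.iloc[0]

    def host_group_of(self, element_id: str) -> str:
        rows = self.table.loc[self.table["element_id"] == element_id, "host_group"]
        if rows.empty:
            raise KeyError(f"element {element_id!r} not in association table")
        return rows.iloc[0]

    def check_elements(self, records: Sequence[SequenceRecord]) -> None:
        """Raise if any element_id does not resolve against *records*."""
        known = {r.id for r in records}
        unknown = [e for e in self.table["element_id"] if e not in known]
        if unknown:
            raise KeyError(f"association table references unknown element id(s): {unknown[:5]}")


def _normalize_lifestyle(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s == "":
        return None
    if s in ("temperate",):  # common synonym in phage metadata
        return "lysogenic"
    if s not in _LIFESTYLES:
        raise ValueError(f"unknown lifestyle value {value!r}; expected lytic or lysogenic")
    return s


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _validate_sequence(seq: str, record_id: str) -> str:
    """Uppercase *seq* and reject non-IUPAC characters (1-based position)."""
    up = seq.upper()
    bad = set(up) - IUPAC_CHARS
    if bad:
        # locate the first offending character for the error message
        pos = min(up.index(ch) for ch in bad)
        raise ValueError(
            f"non-IUPAC character {up[pos]!r} at position {pos + 1} in sequence {record_id!r}"
        )
    return up


def read_fasta(
    path: str | os.PathLike,
    role: Role = "host",
    concatenate: Literal["per-file", "per-record"] = "per-record",
) -> list[SequenceRecord]:
    """Load a FASTA file (plain or ``.gz``) into SequenceRecords.

    ``per-record``: one record per FASTA entry, id from the header token
    before the first whitespace. ``per-file``: a single multi-contig
    record whose id is the file stem — the convention for draft host
    genomes where a file is a genome. Sequences are uppercased; softmask
    is discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with _open_text(path) as handle:
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not entries:
        raise ValueError(f"no sequences in {path}")

    if concatenate == "per-file":
        stem = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        contigs = tuple(_validate_sequence(seq, rid) for rid, seq in entries)
        return [SequenceRecord(id=stem, contigs=contigs, role=role)]

    if concatenate != "per-record":
        raise ValueError(f"unknown concatenate mode {concatenate!r}")

    records = []
    seen: set[str] = set()
    for rid, seq in entries:
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, contigs=(_validate_sequence(seq, rid),), role=role))
    return records


def read_fasta_dir(
    directory: str | os.PathLike,
    role: Role = "host",
    concatenate: Literal["per-file", "per-record"] = "per-file",
) -> list[SequenceRecord]:
    """Load every FASTA file in *directory* (sorted), one genome per file by default."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in (".fasta", ".fa", ".fna") or p.name.endswith((".fasta.gz", ".fa.gz", ".fna.gz"))
    )
    if not paths:
        raise ValueError(f"no FASTA files in {directory}")
    records: list[SequenceRecord] = []
    for p in paths:
        records.extend(read_fasta(p, role=role, concatenate=concatenate))
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate genome id(s) across files: {sorted(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records to FASTA; multi-contig records get ``id|contigN`` headers."""
    path = Path(path)
    with open(path, "wt") as out:
        for rec in records:
            for ci, contig in enumerate(rec.contigs):
                header = rec.id if len(rec.contigs) == 1 else f"{rec.id}|contig{ci + 1}"
                out.write(f">{header}\n")
                for start in range(0, len(contig), width):
                    out.write(contig[start : start + width] + "\n")


def read_associations(path: str | os.PathLike) -> AssociationTable:
    """Parse the association TSV (header: element_id, role, host_group[, lifestyle...])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    return AssociationTable(df)


def write_associations(assoc: AssociationTable, path: str | os.PathLike) -> None:
    assoc.table.to_csv(path, sep="\t", index=False)
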