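"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; trailing stop symbols '*' are stripped and
wrapped lines are handled by the parser.  Group assignments come either from
a two-column TSV (id, group) or from a ``group=NAME`` token in the FASTA
description.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

from Bio import SeqIO

from .seqgroups import SeqRecord


def read_fasta(source: str | Path | _io.TextIOBase) -> list[SeqRecord]:
    """Read (possibly aligned) FASTA into :class:`SeqRecord` objects."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records = [
            SeqRecord(id=rec.id, seq=str(rec.seq).rstrip("*"))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise ValueError(f"no FASTA records found in {source!r}")
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, *,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, group) -> mapping; header row optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() == "id" and len(row) > 1 and row[1].lower() == "group":
                continue
            if len(row) < 2:
                raise ValueError(f"malformed group row: {row!r}")
            mapping[row[0]] = row[1]
    if not mapping:
        raise ValueError(f"no group assignments in {path!r}")
    return mapping


def groups_from_headers(source: str | Path) -> dict[str, str]:
    """Extract ``group=NAME`` tokens from FASTA descriptions."""
    mapping: dict[str, str] = {}
    with open(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            for token in rec.description.split():
                if token.startswith("group="):
                    mapping[rec.id] = token.removeprefix("group=")
    if not mapping:
        raise ValueError(f"no group= tokens found in {source!r}")
    return mapping
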