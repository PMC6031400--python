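"""Format I/O: FASTA/FASTQ via Biopython, TSV via pandas.

Sequences are upper-cased on read (with a logged note); FASTA output is
wrapped at 80 columns.  All interchange coordinates are 1-based
inclusive; internal spans are half-open — the conversion lives here and
nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ureotype")

__all__ = ["read_fasta", "write_fasta", "read_fastq", "write_fastq",
           "read_tsv", "write_tsv"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) pairs."""
    records = []
    lowered = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            lowered = True
        records.append((rec.id, seq.upper()))
    if lowered:
        logger.info("%s: lower-case bases upper-cased on read", path)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as 80-column-wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ into (id, upper-cased sequence, quality string) triples."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq"), 1):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    if not out:
        raise ValueError(f"{path}: no FASTQ records found")
    return out


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"record {rid!r}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
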