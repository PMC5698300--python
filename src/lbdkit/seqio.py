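"""Thin FASTA helpers over Biopython, keeping sequences as plain dicts."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered {id: sequence} dict."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
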