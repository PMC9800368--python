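"""Sequence records and FASTA round-tripping.

A :class:`SequenceRecord` is a named nucleotide sequence carrying a free-form
``role`` (e.g. ``archaeal_genome``, ``viral_genome``, ``plasmid_decoy``,
``metagenome_contig``) so that synthetic communities and pipeline stages can
be written out and reloaded without losing provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with role metadata."""

    id: str
    seq: str
    role: str = "sequence"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA; the role travels in the description line."""
    out = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"role={r.role}")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path: str | Path, default_role: str = "sequence") -> list[SequenceRecord]:
    """Read FASTA written by :func:`write_fasta` (or any plain FASTA)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = default_role
        for token in rec.description.split():
            if token.startswith("role="):
                role = token[len("role="):]
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), role))
    return records


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]
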