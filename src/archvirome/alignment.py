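"""Nucleotide identity/coverage estimation and greedy dereplication.

The pipeline needs one alignment primitive in several places: "does sequence A
match sequence B at >= I% identity over >= C of the query?" — for
dereplicating archaeal contigs, collapsing viral candidates into species
(95% identity over 85% of the shorter sequence), and screening candidates
against bacterial/archaeal genomes (50% identity over 80%/100% of the query).

The primitive is a banded local alignment seeded by shared k-mers (k=16 by
default): exact k-mer seeds shared between query and target are chained on a
near-constant diagonal, the chained query/target spans are aligned globally
with edlib, and identity is read off the extended CIGAR as matched columns /
alignment columns.  Coverage is the chained span as a fraction of the query
(the shorter sequence when used for clustering).  Both strands are examined.

Greedy clustering follows the longest-first convention of classic
dereplicators: sequences are processed by descending length, each joins the
first representative it matches, otherwise founds a new cluster, so every
representative is its cluster's longest member.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import edlib

from .seqs import SequenceRecord, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: k-mers occurring more often than this in the target are treated as
#: repetitive and skipped during seeding.
_MAX_KMER_OCCURRENCES = 64


@dataclass(frozen=True)
class LocalMatch:
    """Best banded match of a query inside a target."""

    identity: float
    query_coverage: float
    strand: str  # '+' or '-'

    @property
    def score(self) -> float:
        return self.identity * self.query_coverage


def cigar_identity(cigar: str) -> float:
    """Fraction of alignment columns that are matches in an extended CIGAR."""
    matched = total = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        total += n
        if op == "=":
            matched += n
    return matched / total if total else 0.0


@lru_cache(maxsize=256)
def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


def _chain_one_strand(query: str, target: str, k: int, band: int) -> tuple[float, float]:
    """(identity, query_coverage) for the best seed chain on this strand."""
    if len(query) < k or len(target) < k:
        return (1.0, 1.0) if query and query in target else (0.0, 0.0)

    tindex = _kmer_positions(target, k)
    qindex = _kmer_positions(query, k)
    seeds: list[tuple[int, int]] = []  # (qpos, tpos)
    for kmer in qindex.keys() & tindex.keys():
        hits = tindex[kmer]
        if len(hits) <= _MAX_KMER_OCCURRENCES:
            seeds.extend((qpos, tpos) for qpos in qindex[kmer] for tpos in hits)
    if not seeds:
        return 0.0, 0.0

    # Anchor on the most populated diagonal, then keep seeds within the band.
    diag_counts: dict[int, int] = defaultdict(int)
    for qpos, tpos in seeds:
        diag_counts[tpos - qpos] += 1
    anchor = max(diag_counts, key=lambda d: (diag_counts[d], -d))
    chained = sorted(
        (qpos, tpos)
        for qpos, tpos in seeds
        if abs((tpos - qpos) - anchor) <= band
    )

    # Enforce monotonicity in target coordinates (greedy left-to-right).
    filtered: list[tuple[int, int]] = []
    last_t = -1
    for qpos, tpos in chained:
        if tpos > last_t:
            filtered.append((qpos, tpos))
            last_t = tpos
    if not filtered:
        return 0.0, 0.0

    q0, t0 = filtered[0]
    q1, t1 = filtered[-1]
    qseg = query[q0 : q1 + k]
    tseg = target[max(0, t0) : t1 + k]
    aln = edlib.align(qseg, tseg, mode="NW", task="path")
    identity = cigar_identity(aln["cigar"] or "")
    coverage = len(qseg) / len(query)
    return identity, coverage


def local_identity_coverage(
    query: str, target: str, k: int = 16, band: int = 64
) -> LocalMatch:
    """Best local match of ``query`` against either strand of ``target``.

    Coverage is measured against the query; callers pass the shorter
    sequence as the query when clustering.
    """
    fwd = _chain_one_strand(query, target, k, band)
    rev = _chain_one_strand(revcomp(query), target, k, band)
    if fwd[0] * fwd[1] >= rev[0] * rev[1]:
        return LocalMatch(identity=fwd[0], query_coverage=fwd[1], strand="+")
    return LocalMatch(identity=rev[0], query_coverage=rev[1], strand="-")


def matches_at(
    query: str,
    target: str,
    min_identity: float,
    min_query_coverage: float,
    k: int = 16,
) -> bool:
    """True if the query aligns to the target at or above both thresholds."""
    if query == target or query in target or revcomp(query) in target:
        return min_query_coverage <= 1.0
    m = local_identity_coverage(query, target, k=k)
    return m.identity >= min_identity and m.query_coverage >= min_query_coverage


@dataclass
class Cluster:
    """A greedy cluster; the representative is the longest (first) member."""

    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def greedy_cluster(
    records: Sequence[SequenceRecord],
    identity: float = 0.95,
    coverage: float = 0.85,
    k: int = 16,
) -> list[Cluster]:
    """Greedy longest-first clustering at identity/coverage thresholds.

    A sequence joins the first existing cluster whose representative it
    matches at >= ``identity`` over >= ``coverage`` of the shorter sequence
    (itself, since processing is longest-first); otherwise it founds a new
    cluster.  Deterministic: ties in length break lexicographically by id.
    """
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    for rec in ordered:
        placed = False
        for cluster in clusters:
            if matches_at(rec.seq, cluster.representative.seq, identity, coverage, k=k):
                cluster.members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters
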