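"""Screening metagenome contigs for archaeal origin.

Each contig's predicted proteins carry one best taxonomy hit (domain plus
per-rank labels, as produced by an aligner against a taxonomy-annotated
protein database). A contig is called archaeal when its archaeal protein
hits strictly outnumber its bacterial hits *and* number at least five; its
taxonomy at each rank is the strict-plurality label among its protein hits.
Called contigs are dereplicated at 95% identity over 85% of the shorter
sequence, keeping the longest sequence of each cluster, after dropping
contigs of 3 kb or less.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment import Cluster, greedy_cluster
from .seqs import SequenceRecord

RANKS = ("phylum", "class", "order", "family", "genus", "species")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ProteinHit:
    """Best taxonomy hit for one predicted protein."""

    protein_id: str
    contig_id: str
    hit_domain: str  # archaeal | bacterial | other | none
    ranks: tuple[str, ...] = ("",) * len(RANKS)  # phylum..species labels
    score: float = 0.0
    evalue: float = 1.0


@dataclass(frozen=True)
class ScreenConfig:
    min_archaeal_hits: int = 5
    min_contig_length: int = 3000  # kept contigs strictly longer
    derep_identity: float = 0.95
    derep_coverage: float = 0.85
    hit_evalue_max: float = 1e-3
    hit_score_min: float = 50.0


@dataclass
class ContigClassification:
    contig_id: str
    n_archaeal: int
    n_bacterial: int
    is_archaeal: bool
    taxonomy: dict[str, str]
    length: int = 0


def filter_hits(hits: Iterable[ProteinHit], config: ScreenConfig = ScreenConfig()) -> list[ProteinHit]:
    """Keep hits passing the e-value/score thresholds used at alignment time."""
    return [
        h
        for h in hits
        if h.hit_domain == "none"
        or (h.evalue <= config.hit_evalue_max and h.score >= config.hit_score_min)
    ]


def classify_contig(
    hits: Sequence[ProteinHit],
    config: ScreenConfig = ScreenConfig(),
    length: int = 0,
) -> ContigClassification:
    """Classify one contig from its (pre-filtered) protein hits.

    Archaeal iff archaeal hits strictly exceed bacterial hits and are at
    least ``min_archaeal_hits``. Hits with domain other/none are ignored by
    the comparison.
    """
    n_arch = sum(1 for h in hits if h.hit_domain == "archaeal")
    n_bact = sum(1 for h in hits if h.hit_domain == "bacterial")
    is_arch = n_arch > n_bact and n_arch >= config.min_archaeal_hits
    contig_id = hits[0].contig_id if hits else ""
    taxonomy = {
        rank: assign_taxonomy(hits, rank) if is_arch else UNASSIGNED
        for rank in RANKS
    }
    return ContigClassification(
        contig_id=contig_id,
        n_archaeal=n_arch,
        n_bacterial=n_bact,
        is_archaeal=is_arch,
        taxonomy=taxonomy,
        length=length,
    )


def assign_taxonomy(hits: Sequence[ProteinHit], rank: str) -> str:
    """Strict-plurality label at a rank; ties and empty label sets → unassigned."""
    idx = RANKS.index(rank)
    labels = [
        h.ranks[idx]
        for h in hits
        if h.hit_domain == "archaeal" and len(h.ranks) > idx and h.ranks[idx]
    ]
    if not labels:
        return UNASSIGNED
    counts = Counter(labels).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return UNASSIGNED
    return counts[0][0]


def screen_contigs(
    hit_table: pd.DataFrame | Iterable[ProteinHit],
    config: ScreenConfig = ScreenConfig(),
    contig_lengths: dict[str, int] | None = None,
) -> list[ContigClassification]:
    """Classify every contig appearing in a hit table."""
    hits = (
        hits_from_table(hit_table) if isinstance(hit_table, pd.DataFrame) else list(hit_table)
    )
    hits = filter_hits(hits, config)
    by_contig: dict[str, list[ProteinHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    lengths = contig_lengths or {}
    return [
        classify_contig(contig_hits, config, length=lengths.get(cid, 0))
        for cid, contig_hits in sorted(by_contig.items())
    ]


def dereplicate(
    sequences: Sequence[SequenceRecord],
    identity: float = 0.95,
    coverage: float = 0.85,
    min_length: int = 3000,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy longest-first dereplication after the length cutoff.

    Returns the representatives and a member→representative map. Coverage
    is measured against the shorter sequence of each compared pair.
    """
    kept = [r for r in sequences if len(r.seq) > min_length]
    clusters: list[Cluster] = greedy_cluster(kept, identity=identity, coverage=coverage)
    membership = {
        member.id: cluster.representative.id
        for cluster in clusters
        for member in cluster.members
    }
    return [c.representative for c in clusters], membership


# ---------------------------------------------------------------------------
# TSV hit-table schema: protein_id, contig_id, domain, <6 rank columns>,
# score, evalue.


def hits_from_table(df: pd.DataFrame) -> list[ProteinHit]:
    return [
        ProteinHit(
            protein_id=row.protein_id,
            contig_id=row.contig_id,
            hit_domain=row.domain,
            ranks=tuple(str(getattr(row, rank, "") or "") for rank in RANKS),
            score=float(row.score),
            evalue=float(row.evalue),
        )
        for row in df.itertuples()
    ]


def hits_to_table(hits: Iterable[ProteinHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {"protein_id": h.protein_id, "contig_id": h.contig_id, "domain": h.hit_domain}
        row.update({rank: h.ranks[i] for i, rank in enumerate(RANKS)})
        row.update({"score": h.score, "evalue": h.evalue})
        rows.append(row)
    return pd.DataFrame(rows, columns=["protein_id", "contig_id", "domain", *RANKS, "score", "evalue"])


def read_hit_table(path: str | Path) -> list[ProteinHit]:
    return hits_from_table(pd.read_csv(path, sep="\t", keep_default_na=False))


def write_hit_table(hits: Iterable[ProteinHit], path: str | Path) -> None:
    hits_to_table(hits).to_csv(path, sep="\t", index=False)
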