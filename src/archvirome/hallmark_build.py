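"""Construction of the archaeal-virus hallmark gene set.

Archaeal viruses lack universal marker genes, so a hallmark protein set is
assembled from four sources and used to confirm that a spacer-matched
sequence is genuinely viral:

1. *exclusive families* — proteins whose annotation family occurs on the
   reference archaeal virus genomes and never on archaeal isolate genomes;
2. *keyword families* — proteins (viral or isolate) whose family description
   contains a virion/lysis keyword (portal, terminase, capsid, tail, ...);
3. *provirus proteins* — proteins predicted on proviruses integrated in
   archaeal isolate genomes;
4. *orthology best hits* — proteins with a best hit in a viral orthologous
   group database at e-value <= 1e-5.

The union is deduplicated by exact protein sequence identity (by id when no
sequences are given); every member keeps the set of reasons it entered by.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Keywords used when building the hallmark set (virion structure and lysis
#: functions diagnostic of viruses).
HALLMARK_KEYWORDS: tuple[str, ...] = (
    "portal", "terminase", "spike", "capsid", "sheath", "tail", "coat",
    "virion", "lysin", "holin", "baseplate", "lysozyme", "head", "fiber",
    "whisker", "neck", "lysis", "tapemeasure", "structural",
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def keyword_matches(description: str, keywords: Sequence[str]) -> bool:
    """Case-insensitive whole-token keyword match.

    A keyword matches if its letters-only form equals a single token of the
    description or the concatenation of two adjacent tokens, so
    "tapemeasure" matches both "tapemeasure" and "tape measure", while
    "tail" does not match "tailless".
    """
    tokens = _TOKEN_RE.findall(description.lower())
    forms = set(tokens)
    forms.update(a + b for a, b in zip(tokens, tokens[1:]))
    return any(kw.replace(" ", "").lower() in forms for kw in keywords)


@dataclass(frozen=True)
class AnnotationHit:
    """Best functional-annotation hit for one protein in one database."""

    protein_id: str
    source_genome_id: str
    source_class: str  # viral_reference | archaeal_isolate | provirus
    family_id: str
    family_description: str = ""
    evalue: float = 0.0
    score: float = 0.0


@dataclass
class HallmarkSet:
    """Deduplicated hallmark proteins with their inclusion reasons."""

    members: dict[str, set[str]] = field(default_factory=dict)
    keywords: tuple[str, ...] = HALLMARK_KEYWORDS

    @property
    def protein_ids(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def add(self, protein_id: str, reason: str) -> None:
        self.members.setdefault(protein_id, set()).add(reason)


def select_exclusive_families(
    viral_annotations: Iterable[AnnotationHit],
    isolate_annotations: Iterable[AnnotationHit],
) -> set[str]:
    """Viral proteins whose family never occurs on an archaeal isolate."""
    isolate_families = {h.family_id for h in isolate_annotations}
    return {
        h.protein_id
        for h in viral_annotations
        if h.family_id and h.family_id not in isolate_families
    }


def select_keyword_families(
    annotations: Iterable[AnnotationHit],
    keywords: Sequence[str] = HALLMARK_KEYWORDS,
) -> set[str]:
    """Proteins whose family description contains a hallmark keyword."""
    return {
        h.protein_id
        for h in annotations
        if keyword_matches(h.family_description, keywords)
    }


def build_hallmark_set(
    exclusive: Iterable[str] = (),
    keyword: Iterable[str] = (),
    provirus_proteins: Iterable[str] = (),
    orthology_hits: Iterable[AnnotationHit] = (),
    evalue_max: float = 1e-5,
    protein_seqs: Mapping[str, str] | None = None,
    keywords: Sequence[str] = HALLMARK_KEYWORDS,
) -> HallmarkSet:
    """Union of the four sources, deduplicated by protein sequence.

    ``protein_seqs`` maps protein id to amino-acid sequence; byte-identical
    proteins collapse onto the first-seen id, merging reasons. Without
    sequences, deduplication is by id.
    """
    hallmark = HallmarkSet(keywords=tuple(keywords))
    for pid in exclusive:
        hallmark.add(pid, "exclusive_family")
    for pid in keyword:
        hallmark.add(pid, "keyword_family")
    for pid in provirus_proteins:
        hallmark.add(pid, "provirus_protein")
    for hit in orthology_hits:
        if hit.evalue <= evalue_max:
            hallmark.add(hit.protein_id, "orthology_best_hit")

    if protein_seqs:
        by_seq: dict[str, str] = {}
        deduped: dict[str, set[str]] = {}
        for pid in sorted(hallmark.members):
            seq = protein_seqs.get(pid)
            if seq is None:
                deduped[pid] = hallmark.members[pid]
                continue
            rep = by_seq.setdefault(seq, pid)
            deduped.setdefault(rep, set()).update(hallmark.members[pid])
        hallmark.members = deduped
    return hallmark


def filter_by_hallmarks(
    candidate_contigs: Sequence[str],
    hallmark_set: HallmarkSet,
    hit_table: pd.DataFrame,
    evalue_max: float = 1e-5,
) -> tuple[list[str], list[str]]:
    """Retain contigs with at least one protein best-hitting a hallmark.

    ``hit_table`` columns: contig_id, protein_id, hallmark_id, evalue — the
    best hit of each candidate protein against the hallmark protein set
    (produced externally or by the built-in matcher).
    Returns (retained, removed) in input order.
    """
    if hit_table.empty:
        qualifying: set[str] = set()
    else:
        ok = hit_table[
            (hit_table["evalue"] <= evalue_max)
            & hit_table["hallmark_id"].isin(hallmark_set.protein_ids)
        ]
        qualifying = set(ok["contig_id"])
    retained = [c for c in candidate_contigs if c in qualifying]
    removed = [c for c in candidate_contigs if c not in qualifying]
    return retained, removed
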