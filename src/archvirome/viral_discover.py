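"""Candidate matching and the viral discovery cascade.

Discovery proceeds in the order used for building a spacer-anchored virome
database:

1. **spacer match** — every contig matched by at least one CRISPR spacer
   becomes a candidate (discovery mode tolerates up to 10% substitutions
   over the full spacer; host mode demands a perfect full-length match);
2. **species clustering** — candidates collapse into species at 95%
   identity over 85% of the shorter sequence, longest member representative
   (candidate I);
3. **bacterial filter** — species whose representative aligns to a
   bacterial genome at >=50% identity over >=80% of the candidate are
   removed as bacterial contamination (candidate II);
4. **archaeal filter** — species aligning to an archaeal genome at >=50%
   identity over 100% of the candidate are removed as host-genome
   contamination, e.g. excised CRISPR loci (candidate III);
5. **hallmark filter** — species whose representative encodes no protein
   best-hitting the archaeal-virus hallmark set are removed (this is what
   excludes spacer-matched plasmids and transposons).

A :class:`StageLedger` records the count at every stage and each removal
with its reason; retained + removed equals the input at every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .alignment import greedy_cluster, matches_at
from .crispr_mine import Spacer
from .hallmark_build import HallmarkSet, filter_by_hallmarks
from .seqs import SequenceRecord, revcomp

Mode = Literal["discovery", "host"]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SpacerMatch:
    """A protospacer hit on a target contig (forward-strand coordinates)."""

    spacer_id: str
    target_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    mode: Mode


@dataclass
class ViralSpecies:
    """A cluster of candidate contigs represented by its longest member."""

    species_id: str
    representative: SequenceRecord
    members: list[SequenceRecord]
    quality: str | None = None

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


@dataclass
class StageLedger:
    """Candidate counts through the cascade, with per-stage removals."""

    counts: dict[str, int]
    removed: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    STAGES = ("spacer_matched", "candidate_i_species", "candidate_ii", "candidate_iii", "final")

    @classmethod
    def from_counts(
        cls,
        spacer_matched: int,
        candidate_i_species: int,
        removed_bacterial: int,
        removed_archaeal: int,
        removed_no_hallmark: int,
    ) -> "StageLedger":
        """Derive the downstream stage counts from stage inputs and removals."""
        candidate_ii = candidate_i_species - removed_bacterial
        candidate_iii = candidate_ii - removed_archaeal
        final = candidate_iii - removed_no_hallmark
        ledger = cls(
            counts={
                "spacer_matched": spacer_matched,
                "candidate_i_species": candidate_i_species,
                "candidate_ii": candidate_ii,
                "candidate_iii": candidate_iii,
                "final": final,
            }
        )
        ledger.validate()
        return ledger

    def validate(self) -> None:
        species_stages = self.STAGES[1:]
        values = [self.counts[s] for s in species_stages]
        if any(v < 0 for v in values):
            raise ValueError(f"negative stage count: {self.counts}")
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError(f"stage counts must be non-increasing: {self.counts}")

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "removed": {k: list(v) for k, v in self.removed.items()},
        }


def _scan_one_strand(
    spacer_arr: np.ndarray, target_arr: np.ndarray, tolerance: int
) -> list[tuple[int, int]]:
    """All (start, mismatches) of the spacer along one strand of the target."""
    m = spacer_arr.size
    if m > target_arr.size:
        return []
    windows = sliding_window_view(target_arr, m)
    mism = (windows != spacer_arr).sum(axis=1)
    hits = np.nonzero(mism <= tolerance)[0]
    return [(int(i), int(mism[i])) for i in hits]


def match_spacers(
    spacers: Sequence[Spacer],
    contigs: Sequence[SequenceRecord],
    mode: Mode = "discovery",
) -> list[SpacerMatch]:
    """All full-length spacer matches on both strands of every contig.

    Host mode: zero mismatches. Discovery mode: at most ``floor(0.1*len)``
    substitutions, no indels. Coordinates are reported on the forward
    strand of the target; a reverse-complement occurrence has strand '-'.
    """
    matches: list[SpacerMatch] = []
    encoded = [(c, np.frombuffer(c.seq.encode(), dtype=np.uint8)) for c in contigs]
    for sp in spacers:
        if set(sp.sequence) - _ACGT:
            warnings.warn(f"spacer {sp.spacer_id} contains non-ACGT characters; skipped")
            continue
        tol = 0 if mode == "host" else len(sp.sequence) // 10
        fwd = np.frombuffer(sp.sequence.encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(sp.sequence).encode(), dtype=np.uint8)
        for contig, arr in encoded:
            for strand, probe in (("+", fwd), ("-", rev)):
                for start, mism in _scan_one_strand(probe, arr, tol):
                    matches.append(
                        SpacerMatch(
                            spacer_id=sp.spacer_id,
                            target_id=contig.id,
                            start=start,
                            end=start + len(sp.sequence),
                            strand=strand,
                            mismatches=mism,
                            mode=mode,
                        )
                    )
    return matches


def _filter_against_genomes(
    candidates: Sequence[SequenceRecord],
    genomes: Sequence[SequenceRecord],
    min_identity: float,
    min_query_coverage: float,
    reason: str,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    retained: list[SequenceRecord] = []
    removed: list[tuple[SequenceRecord, str]] = []
    for cand in candidates:
        culprit = next(
            (
                g
                for g in genomes
                if matches_at(cand.seq, g.seq, min_identity, min_query_coverage)
            ),
            None,
        )
        if culprit is None:
            retained.append(cand)
        else:
            removed.append((cand, f"{reason}:{culprit.id}"))
    return retained, removed


def filter_bacterial(
    candidates: Sequence[SequenceRecord],
    bacterial_genomes: Sequence[SequenceRecord],
    min_identity: float = 0.50,
    min_query_coverage: float = 0.80,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Remove candidates aligning to a bacterial genome at the thresholds."""
    return _filter_against_genomes(
        candidates, bacterial_genomes, min_identity, min_query_coverage, "bacterial"
    )


def filter_archaeal(
    candidates: Sequence[SequenceRecord],
    archaeal_genomes: Sequence[SequenceRecord],
    min_identity: float = 0.50,
    min_query_coverage: float = 1.00,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Remove candidates fully contained in an archaeal genome."""
    return _filter_against_genomes(
        candidates, archaeal_genomes, min_identity, min_query_coverage, "archaeal"
    )


def cluster_species(
    candidates: Sequence[SequenceRecord],
    identity: float = 0.95,
    coverage: float = 0.85,
) -> list[ViralSpecies]:
    """Cluster candidates into species (greedy longest-first, 95%/85%)."""
    clusters = greedy_cluster(candidates, identity=identity, coverage=coverage)
    return [
        ViralSpecies(
            species_id=f"vs_{i + 1:04d}",
            representative=c.representative,
            members=list(c.members),
        )
        for i, c in enumerate(clusters)
    ]


def run_workflow(
    spacers: Sequence[Spacer],
    contigs: Sequence[SequenceRecord],
    bacterial_genomes: Sequence[SequenceRecord] = (),
    archaeal_genomes: Sequence[SequenceRecord] = (),
    hallmark_set: HallmarkSet | None = None,
    hallmark_hits: pd.DataFrame | None = None,
    identity: float = 0.95,
    coverage: float = 0.85,
) -> tuple[list[ViralSpecies], StageLedger]:
    """Execute the full discovery cascade and return species plus ledger.

    ``hallmark_hits`` is the best-hit table of candidate proteins against
    ``hallmark_set`` (columns contig_id, protein_id, hallmark_id, evalue).
    When no hallmark set is supplied the hallmark stage removes nothing.
    """
    matches = match_spacers(spacers, contigs, mode="discovery")
    matched_ids = {m.target_id for m in matches}
    matched = [c for c in contigs if c.id in matched_ids]

    species = cluster_species(matched, identity=identity, coverage=coverage)
    reps = [s.representative for s in species]
    by_rep = {s.representative.id: s for s in species}

    after_bact, removed_bact = filter_bacterial(reps, bacterial_genomes)
    after_arch, removed_arch = filter_archaeal(after_bact, archaeal_genomes)

    if hallmark_set is not None and hallmark_hits is not None:
        retained_ids, removed_ids = filter_by_hallmarks(
            [r.id for r in after_arch], hallmark_set, hallmark_hits
        )
        final_reps = [r for r in after_arch if r.id in set(retained_ids)]
        removed_hallmark = [(rid, "no_hallmark_gene") for rid in removed_ids]
    else:
        final_reps = list(after_arch)
        removed_hallmark = []

    ledger = StageLedger.from_counts(
        spacer_matched=len(matched),
        candidate_i_species=len(species),
        removed_bacterial=len(removed_bact),
        removed_archaeal=len(removed_arch),
        removed_no_hallmark=len(removed_hallmark),
    )
    ledger.removed = {
        "candidate_ii": [(r.id, reason) for r, reason in removed_bact],
        "candidate_iii": [(r.id, reason) for r, reason in removed_arch],
        "final": removed_hallmark,
    }
    final_species = [by_rep[r.id] for r in final_reps]
    return final_species, ledger


def match_table(matches: Iterable[SpacerMatch]) -> pd.DataFrame:
    """Match list as a table; coordinates exported 1-based inclusive."""
    return pd.DataFrame(
        [
            {
                "spacer_id": m.spacer_id,
                "target_id": m.target_id,
                "start": m.start + 1,
                "end": m.end,
                "strand": m.strand,
                "mismatches": m.mismatches,
                "mode": m.mode,
            }
            for m in matches
        ],
        columns=["spacer_id", "target_id", "start", "end", "strand", "mismatches", "mode"],
    )
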