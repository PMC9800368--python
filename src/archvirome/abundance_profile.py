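"""Breadth-filtered abundance, prevalence, and the archaeal virome fraction.

Relative abundance of a contig in a sample is its mapped read count divided
by the sample's total read count, and is only counted when the contig's
breadth of coverage (fraction of positions covered by at least one read)
strictly exceeds 30% — shallow, patchy recruitment is treated as absence.
Prevalence is the percentage of samples in which a contig retains nonzero
breadth-filtered abundance. The archaeal fraction of the virome in a sample
is the summed abundance of archaeal viral contigs over the summed abundance
of all viral contigs; the study-level estimate is the mean over samples
with a nonzero viral denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

BREADTH_MIN = 0.30  # strict: breadth must exceed this


@dataclass(frozen=True)
class MappingSummary:
    """Per-sample, per-contig read-mapping summary."""

    sample_id: str
    contig_id: str
    mapped_read_count: int
    covered_positions: int
    contig_length: int
    sample_total_reads: int

    def __post_init__(self) -> None:
        if self.covered_positions > self.contig_length:
            raise ValueError("covered positions exceed contig length")
        if self.mapped_read_count < 0:
            raise ValueError("negative read count")

    @property
    def breadth(self) -> float:
        return self.covered_positions / self.contig_length


@dataclass
class AbundanceMatrix:
    """Contig x sample normalized abundance plus the breadth matrix."""

    abundance: pd.DataFrame  # rows contigs, columns samples
    breadth: pd.DataFrame

    @property
    def contigs(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


def compute_abundance(
    summaries: Iterable[MappingSummary], breadth_min: float = BREADTH_MIN
) -> AbundanceMatrix:
    """Normalized abundance matrix with the strict breadth filter applied.

    abundance[i, j] = mapped_reads / sample_total_reads when breadth >
    ``breadth_min``, else 0. Samples with zero total reads are rejected.
    """
    summaries = list(summaries)
    totals: dict[str, int] = {}
    for s in summaries:
        if s.sample_total_reads <= 0:
            raise ValueError(f"sample {s.sample_id} has no reads")
        prev = totals.setdefault(s.sample_id, s.sample_total_reads)
        if prev != s.sample_total_reads:
            raise ValueError(f"inconsistent total reads for sample {s.sample_id}")

    contigs = sorted({s.contig_id for s in summaries})
    samples = sorted(totals)
    abundance = pd.DataFrame(0.0, index=contigs, columns=samples)
    breadth = pd.DataFrame(0.0, index=contigs, columns=samples)
    for s in summaries:
        breadth.loc[s.contig_id, s.sample_id] = s.breadth
        if s.breadth > breadth_min:
            abundance.loc[s.contig_id, s.sample_id] = (
                s.mapped_read_count / s.sample_total_reads
            )
    return AbundanceMatrix(abundance=abundance, breadth=breadth)


def prevalence(matrix: AbundanceMatrix) -> pd.Series:
    """Per-contig percentage of samples with nonzero filtered abundance."""
    n_samples = matrix.abundance.shape[1]
    if n_samples == 0:
        raise ValueError("prevalence undefined with zero samples")
    return 100.0 * (matrix.abundance > 0).sum(axis=1) / n_samples


def virome_fraction(
    archaeal_matrix: AbundanceMatrix, total_viral_matrix: AbundanceMatrix
) -> tuple[pd.Series, float, list[str]]:
    """Per-sample archaeal fraction of the virome and its mean.

    The total matrix includes the archaeal contigs. Samples with zero total
    viral abundance are excluded from the mean and reported in the third
    return value.
    """
    samples = list(total_viral_matrix.samples)
    if sorted(archaeal_matrix.samples) != sorted(samples):
        raise ValueError("sample sets differ between matrices")
    arch_sum = archaeal_matrix.abundance.sum(axis=0).reindex(samples)
    total_sum = total_viral_matrix.abundance.sum(axis=0).reindex(samples)
    excluded = [s for s in samples if total_sum[s] == 0]
    valid = total_sum > 0
    fractions = arch_sum[valid] / total_sum[valid]
    mean = float(fractions.mean()) if valid.any() else 0.0
    return fractions, mean, excluded


# ---------------------------------------------------------------------------
# TSV schema: sample_id, contig_id, mapped_read_count, covered_positions,
# contig_length, sample_total_reads.

_COLUMNS = [
    "sample_id",
    "contig_id",
    "mapped_read_count",
    "covered_positions",
    "contig_length",
    "sample_total_reads",
]


def read_mapping_summaries(path: str | Path) -> list[MappingSummary]:
    df = pd.read_csv(path, sep="\t")
    return [
        MappingSummary(
            sample_id=str(r.sample_id),
            contig_id=str(r.contig_id),
            mapped_read_count=int(r.mapped_read_count),
            covered_positions=int(r.covered_positions),
            contig_length=int(r.contig_length),
            sample_total_reads=int(r.sample_total_reads),
        )
        for r in df.itertuples()
    ]


def write_mapping_summaries(summaries: Iterable[MappingSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "contig_id": s.contig_id,
                "mapped_read_count": s.mapped_read_count,
                "covered_positions": s.covered_positions,
                "contig_length": s.contig_length,
                "sample_total_reads": s.sample_total_reads,
            }
            for s in summaries
        ],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def assign_multimapped(
    read_targets: pd.DataFrame, breadth_by_contig: pd.Series
) -> pd.Series:
    """Resolve multi-mapped reads: best-covered contig wins, ties break
    lexicographically.

    ``read_targets`` columns: read_id, contig_id (one row per candidate
    placement). Returns read_id → assigned contig_id.
    """
    def best(contigs: list[str]) -> str:
        return min(contigs, key=lambda c: (-breadth_by_contig.get(c, 0.0), c))

    return (
        read_targets.groupby("read_id")["contig_id"]
        .apply(lambda s: best(sorted(s)))
    )
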