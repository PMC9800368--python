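"""CRISPR array detection, spacer filtering and spacer dereplication.

CRISPR arrays are loci of near-identical direct repeats (here: exact repeats,
19-38 bp by default) separated by unique spacers (19-48 bp at detection).
Detection is a seed-and-extend repeat finder:

1. every k-mer (k=8) occurring at regularly spaced positions — consecutive
   gaps within [min repeat + min spacer, max repeat + max spacer] — anchors a
   candidate run of repeat copies;
2. the repeat unit is the maximal string common to *all* anchored copies
   (extending left/right while every copy agrees), which pins the
   repeat/spacer boundaries without reference to any one pair of copies;
3. runs whose unit length and inter-repeat gaps fall inside the configured
   ranges become arrays; spacers are the gaps between consecutive repeats.

Two spacer sets are derived from the detected arrays. The *database* set
keeps everything (it feeds discovery-mode protospacer matching). The
*host-prediction* set applies the stringent criteria used for host
assignment: source sequence longer than 10 kb, at least three spacers per
array, and spacers longer than 25 bp.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .seqs import SequenceRecord

Purpose = Literal["database", "host_prediction"]


@dataclass(frozen=True)
class Spacer:
    """A single spacer with provenance back to its source array."""

    spacer_id: str
    sequence: str
    source_id: str
    array_id: str
    ordinal: int
    start: int  # 0-based half-open on the source sequence
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus on one source sequence."""

    array_id: str
    source_id: str
    source_length: int
    repeat_consensus: str
    repeat_hits: list[int]  # start of every repeat copy, 0-based
    spacers: list[Spacer]
    start: int
    end: int


@dataclass(frozen=True)
class MineConfig:
    repeat_len_range: tuple[int, int] = (19, 38)
    spacer_len_range: tuple[int, int] = (19, 48)
    min_spacers_per_array: int = 3
    min_spacer_len: int = 25  # spacers must be strictly longer than this
    min_source_len: int = 10_000  # host-prediction sources strictly longer
    k_seed: int = 8

    def __post_init__(self) -> None:
        for lo, hi in (self.repeat_len_range, self.spacer_len_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and nonempty")


def _anchor_runs(positions: Sequence[int], gap_lo: int, gap_hi: int) -> list[list[int]]:
    """Split sorted k-mer positions into maximal regularly spaced runs."""
    runs: list[list[int]] = []
    current = [positions[0]]
    for pos in positions[1:]:
        if gap_lo <= pos - current[-1] <= gap_hi:
            current.append(pos)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [pos]
    if len(current) >= 2:
        runs.append(current)
    return runs


def _common_extension(seq: str, anchors: Sequence[int], k: int) -> tuple[int, int]:
    """Maximal (left, right) extension over which *all* anchored copies agree."""
    left = 0
    while all(a - left - 1 >= 0 for a in anchors) and len(
        {seq[a - left - 1] for a in anchors}
    ) == 1:
        left += 1
    right = 0
    while all(a + k + right < len(seq) for a in anchors) and len(
        {seq[a + k + right] for a in anchors}
    ) == 1:
        right += 1
    return left, right


def detect_arrays(record: SequenceRecord, config: MineConfig = MineConfig()) -> list[CrisprArray]:
    """Detect CRISPR arrays on one sequence.

    Returns maximal non-overlapping arrays sorted by start coordinate; an
    array requires at least two exact repeat copies with every inter-repeat
    gap inside the configured spacer length range.
    """
    seq, k = record.seq, config.k_seed
    rmin, rmax = config.repeat_len_range
    smin, smax = config.spacer_len_range
    gap_lo, gap_hi = rmin + smin, rmax + smax

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)

    candidates: dict[tuple[int, int, str], CrisprArray] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for run in _anchor_runs(positions, gap_lo, gap_hi):
            left, right = _common_extension(seq, run, k)
            unit_len = left + k + right
            if not rmin <= unit_len <= rmax:
                continue
            starts = [a - left for a in run]
            gaps = [
                starts[i + 1] - (starts[i] + unit_len)
                for i in range(len(starts) - 1)
            ]
            if not all(smin <= g <= smax for g in gaps):
                continue
            unit = seq[starts[0] : starts[0] + unit_len]
            arr_start, arr_end = starts[0], starts[-1] + unit_len
            key = (arr_start, arr_end, unit)
            if key in candidates:
                continue
            spacers = [
                Spacer(
                    spacer_id=f"{record.id}|{arr_start}|{i}",
                    sequence=seq[starts[i] + unit_len : starts[i + 1]],
                    source_id=record.id,
                    array_id=f"{record.id}|{arr_start}",
                    ordinal=i,
                    start=starts[i] + unit_len,
                    end=starts[i + 1],
                )
                for i in range(len(starts) - 1)
            ]
            candidates[key] = CrisprArray(
                array_id=f"{record.id}|{arr_start}",
                source_id=record.id,
                source_length=len(seq),
                repeat_consensus=unit,
                repeat_hits=starts,
                spacers=spacers,
                start=arr_start,
                end=arr_end,
            )

    # Resolve overlaps: prefer more repeat copies, then longer span, then
    # leftmost start (arrays sharing a consensus collapse to one).
    ordered = sorted(
        candidates.values(),
        key=lambda a: (-len(a.repeat_hits), -(a.end - a.start), a.start),
    )
    kept: list[CrisprArray] = []
    for arr in ordered:
        if all(arr.end <= other.start or arr.start >= other.end for other in kept):
            kept.append(arr)
    return sorted(kept, key=lambda a: a.start)


def filter_arrays(
    arrays: Iterable[CrisprArray],
    config: MineConfig = MineConfig(),
    purpose: Purpose = "database",
) -> list[CrisprArray]:
    """Apply the host-prediction criteria, or none for the database build.

    Host-prediction order: (i) source longer than ``min_source_len``;
    (ii) arrays with fewer than ``min_spacers_per_array`` spacers dropped;
    (iii) spacers not longer than ``min_spacer_len`` dropped.
    """
    arrays = list(arrays)
    if purpose == "database":
        return arrays
    kept: list[CrisprArray] = []
    for arr in arrays:
        if arr.source_length <= config.min_source_len:
            continue
        if len(arr.spacers) < config.min_spacers_per_array:
            continue
        spacers = [s for s in arr.spacers if s.length > config.min_spacer_len]
        filtered = CrisprArray(
            array_id=arr.array_id,
            source_id=arr.source_id,
            source_length=arr.source_length,
            repeat_consensus=arr.repeat_consensus,
            repeat_hits=list(arr.repeat_hits),
            spacers=spacers,
            start=arr.start,
            end=arr.end,
        )
        kept.append(filtered)
    return kept


def dereplicate_spacers(
    spacers: Iterable[Spacer],
) -> tuple[list[Spacer], dict[str, list[str]]]:
    """Collapse exact full-length duplicate spacers.

    Strand is not canonicalized: a spacer and its reverse complement are
    distinct. The first-seen spacer is the representative; the membership
    map records every collapsed provenance.
    """
    representatives: dict[str, Spacer] = {}
    membership: dict[str, list[str]] = {}
    for sp in spacers:
        rep = representatives.get(sp.sequence)
        if rep is None:
            representatives[sp.sequence] = sp
            membership[sp.spacer_id] = [sp.spacer_id]
        else:
            membership[rep.spacer_id].append(sp.spacer_id)
    return list(representatives.values()), membership


def mine_spacers(
    records: Iterable[SequenceRecord],
    config: MineConfig = MineConfig(),
    purpose: Purpose = "database",
) -> tuple[list[Spacer], list[CrisprArray]]:
    """Detect, filter and pool spacers across a set of source sequences."""
    all_arrays: list[CrisprArray] = []
    for rec in records:
        all_arrays.extend(detect_arrays(rec, config))
    filtered = filter_arrays(all_arrays, config, purpose)
    spacers = [sp for arr in filtered for sp in arr.spacers]
    bad = [sp for sp in spacers if set(sp.sequence) - set("ACGT")]
    if bad:
        warnings.warn(f"{len(bad)} spacers contain non-ACGT characters")
    return spacers, filtered


def spacer_table(spacers: Iterable[Spacer]) -> pd.DataFrame:
    """Spacer set as a table; coordinates exported 1-based inclusive."""
    rows = [
        {
            "spacer_id": sp.spacer_id,
            "source_id": sp.source_id,
            "array_id": sp.array_id,
            "ordinal": sp.ordinal,
            "start": sp.start + 1,
            "end": sp.end,
            "sequence": sp.sequence,
        }
        for sp in spacers
    ]
    return pd.DataFrame(
        rows,
        columns=["spacer_id", "source_id", "array_id", "ordinal", "start", "end", "sequence"],
    )


def write_spacer_table(spacers: Iterable[Spacer], path: str | Path) -> None:
    spacer_table(spacers).to_csv(path, sep="\t", index=False)


def read_spacer_table(path: str | Path) -> list[Spacer]:
    df = pd.read_csv(path, sep="\t")
    return [
        Spacer(
            spacer_id=row.spacer_id,
            sequence=row.sequence,
            source_id=row.source_id,
            array_id=row.array_id,
            ordinal=int(row.ordinal),
            start=int(row.start) - 1,
            end=int(row.end),
        )
        for row in df.itertuples()
    ]
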