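"""Synthetic gut communities with planted ground truth.

The generator emulates the inputs of a spacer-anchored archaeal virome
study: archaeal genomes carrying CRISPR arrays whose protospacer-derived
spacers are verbatim substrings (or reverse complements) of planted viral
genomes; bacterial genomes and excised archaeal fragments acting as
contamination; plasmid-like decoys that match spacers but carry no
hallmark-labeled gene; viral genomes with labeled hallmark genes
(terminase, portal, capsid, integrase, peiW, mazE); and per-protein
taxonomy/annotation hit tables consistent with all placements. Shotgun
read sets support abundance profiling.

Background sequence is i.i.d. with configurable GC content — the simplest
model sufficient for exact-match testing. Repeat/spacer boundaries are made
unambiguous by construction: if every flanking base of an array's repeat
copies were identical the repeat unit itself would be ill-defined, so the
generator perturbs the background base next to the array in that case.

Hit tables are ideal (error-free) by default; a label-noise rate can be
applied to the taxonomy table to separate logic errors from simulated
noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .abundance_profile import MappingSummary
from .archaeal_screen import RANKS
from .seqs import SequenceRecord, read_fasta, revcomp, write_fasta

_ARRAYS_PER_GENOME = 2
_GENES_PER_CELL_GENOME = 9
_FRAGMENT_LEN = 8000

#: gene label → (annotation family id, family description)
GENE_FAMILIES: dict[str, tuple[str, str]] = {
    "terminase": ("PF_TERML", "Phage terminase large subunit"),
    "portal": ("PF_PORTAL", "Phage portal protein"),
    "capsid": ("PF_CAPSID", "Major capsid protein"),
    "integrase": ("PF_INT", "Phage integrase family protein"),
    "peiW": ("PF_PEIW", "Pseudomurein endoisopeptidase PeiW"),
    "mazE": ("PF_MAZE", "Antitoxin MazE superfamily protein"),
    "transposase": ("PF_TNP", "Transposase DDE domain protein"),
    "housekeeping": ("PF_HK", "ABC transporter ATP-binding protein"),
}

#: labels whose carriers count as hallmark-bearing viral genes
HALLMARK_LABELS = ("terminase", "portal", "capsid", "integrase", "peiW", "mazE")

#: archaeal taxa cycled over the archaeal genomes (genus, species)
ARCHAEAL_TAXA = (
    ("Methanobrevibacter_A", "Methanobrevibacter_A smithii"),
    ("Methanobrevibacter_A", "Methanobrevibacter_A smithii_A"),
    ("Methanobrevibacter_A", "Methanobrevibacter_A woesei"),
    ("Methanomassiliicoccus", "Methanomassiliicoccus intestinalis"),
)


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for one synthetic community."""

    n_archaeal_genomes: int = 10
    n_bacterial_decoys: int = 5
    n_viral_genomes: int = 20
    n_plasmid_decoys: int = 5
    genome_length_range: tuple[int, int] = (20_000, 30_000)
    viral_length_range: tuple[int, int] = (15_000, 25_000)
    repeat_length_range: tuple[int, int] = (28, 37)
    spacer_length_range: tuple[int, int] = (25, 45)
    spacers_per_array_range: tuple[int, int] = (4, 8)
    protospacer_fraction: float = 0.6
    gc_content: float = 0.45
    read_length: int = 100
    coverage_per_genome: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "genome_length_range",
            "viral_length_range",
            "repeat_length_range",
            "spacer_length_range",
            "spacers_per_array_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a nonempty positive interval")
        if not 0.0 <= self.protospacer_fraction <= 1.0:
            raise ValueError("protospacer_fraction must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class CommunityTruth:
    """Complete record of everything the generator planted."""

    spacers: pd.DataFrame  # spacer_id, source_id, array_index, ordinal, start, end, sequence, is_protospacer
    protospacer_placements: pd.DataFrame  # spacer_id, viral_id, start, end, strand
    hallmark_gene_placements: pd.DataFrame  # genome_id, gene_id, label, start, end
    host_links_truth: dict[str, set[str]]  # virus id → host species labels
    host_links_by_genome: pd.DataFrame  # virus_id, host_genome_id, host_genus, host_species
    gene_table: pd.DataFrame
    taxonomy_hits: pd.DataFrame
    viral_annotations: pd.DataFrame
    isolate_annotations: pd.DataFrame
    candidate_hallmark_hits: pd.DataFrame
    host_taxonomy: pd.DataFrame  # genome_id, genus, species
    expected_removal: dict[str, str] = field(default_factory=dict)  # contig → stage reason
    sample_compositions: pd.DataFrame | None = None


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(letters, size=length, p=p).tobytes().decode()


def _plant_genes(
    genome_id: str, labels: list[str], gene_len: int = 900, gap: int = 100
) -> list[dict]:
    rows = []
    pos = gap
    for i, label in enumerate(labels):
        rows.append(
            {
                "genome_id": genome_id,
                "gene_id": f"{genome_id}_p{i + 1:02d}",
                "label": label,
                "start": pos,
                "end": pos + gene_len,
            }
        )
        pos += gene_len + gap
    return rows


def _disambiguate_flanks(bg: list[str], pos: int, spacer_seqs: list[str]) -> None:
    """Ensure the array's repeat boundaries are well defined (see module doc)."""
    left = {s[-1] for s in spacer_seqs}
    if pos > 0 and left | {bg[pos - 1]} == left and len(left) == 1:
        bg[pos - 1] = "A" if bg[pos - 1] != "A" else "C"
    right = {s[0] for s in spacer_seqs}
    if pos < len(bg) and right | {bg[pos]} == right and len(right) == 1:
        bg[pos] = "A" if bg[pos] != "A" else "C"


def generate_community(
    config: CommunityConfig, label_noise: float = 0.0
) -> tuple[list[SequenceRecord], CommunityTruth]:
    """Generate one community and the full truth of its construction.

    Deterministic: identical config (and noise rate) gives byte-identical
    sequences and tables.
    """
    if config.n_viral_genomes == 0 and config.protospacer_fraction > 0:
        raise ValueError("protospacers requested but no viral genomes to copy them from")
    if (
        config.n_viral_genomes > 0
        and config.protospacer_fraction > 0
        and config.spacer_length_range[1] > config.viral_length_range[0]
    ):
        raise ValueError("spacers may be longer than the shortest viral genome")

    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    records: list[SequenceRecord] = []

    # --- viral genomes (needed first as protospacer sources) ---------------
    viral: dict[str, str] = {}
    gene_rows: list[dict] = []
    for i in range(config.n_viral_genomes):
        vid = f"vir_{i + 1:03d}"
        length = int(rng.integers(*config.viral_length_range, endpoint=True))
        viral[vid] = random_seq(rng, length, gc)
        n_genes = int(rng.integers(3, 6, endpoint=True))
        labels = [str(rng.choice(["terminase", "portal", "capsid"]))]
        labels += [
            str(rng.choice(["portal", "capsid", "integrase", "peiW", "mazE", "housekeeping"]))
            for _ in range(n_genes - 1)
        ]
        gene_rows.extend(_plant_genes(vid, labels))
    records.extend(SequenceRecord(v, s, "viral_genome") for v, s in viral.items())

    # --- spacer slots across archaeal genomes ------------------------------
    genome_plans = []  # per genome: list of arrays, each a list of slot dicts
    slots: list[dict] = []
    for g in range(config.n_archaeal_genomes):
        gid = f"arch_{g + 1:03d}"
        arrays = []
        for a in range(_ARRAYS_PER_GENOME):
            n_sp = int(rng.integers(*config.spacers_per_array_range, endpoint=True))
            arr_slots = [
                {"source_id": gid, "array_index": a, "ordinal": s}
                for s in range(n_sp)
            ]
            arrays.append(arr_slots)
            slots.extend(arr_slots)
        genome_plans.append((gid, arrays))

    is_proto = rng.random(len(slots)) < config.protospacer_fraction
    virus_cycle = itertools.cycle(rng.permutation(sorted(viral))) if viral else None

    proto_rows: list[dict] = []
    for slot, proto in zip(slots, is_proto):
        length = int(rng.integers(*config.spacer_length_range, endpoint=True))
        sid = f"{slot['source_id']}_a{slot['array_index']}_s{slot['ordinal']}"
        if proto and virus_cycle is not None:
            vid = next(virus_cycle)
            vseq = viral[vid]
            pos = int(rng.integers(0, len(vseq) - length + 1))
            strand = "-" if rng.random() < 0.5 else "+"
            sub = vseq[pos : pos + length]
            slot["sequence"] = revcomp(sub) if strand == "-" else sub
            slot["is_protospacer"] = True
            proto_rows.append(
                {"spacer_id": sid, "viral_id": vid, "start": pos, "end": pos + length, "strand": strand}
            )
        else:
            slot["sequence"] = random_seq(rng, length, gc)
            slot["is_protospacer"] = False
        slot["spacer_id"] = sid

    # --- archaeal genomes with planted arrays ------------------------------
    spacer_rows: list[dict] = []
    host_tax_rows: list[dict] = []
    genome_seqs: dict[str, str] = {}
    for g, (gid, arrays) in enumerate(genome_plans):
        length = int(rng.integers(*config.genome_length_range, endpoint=True))
        bg = list(random_seq(rng, length, gc))
        repeat_units = [
            random_seq(rng, int(rng.integers(*config.repeat_length_range, endpoint=True)), gc)
            for _ in arrays
        ]
        # insertion points in background coordinates, past the gene block
        lo = _GENES_PER_CELL_GENOME * 1000 + 200
        positions = sorted(
            int(p) for p in rng.choice(np.arange(lo, length - 200), size=len(arrays), replace=False)
        )
        offset = 0
        pieces: list[str] = []
        prev = 0
        for arr_slots, unit, pos in zip(arrays, repeat_units, positions):
            seqs = [s["sequence"] for s in arr_slots]
            _disambiguate_flanks(bg, pos, seqs)
            array_str = unit + "".join(s + unit for s in seqs)
            pieces.append("".join(bg[prev:pos]))
            pieces.append(array_str)
            arr_start = pos + offset
            cursor = arr_start + len(unit)
            for slot in arr_slots:
                sp_len = len(slot["sequence"])
                spacer_rows.append(
                    {
                        "spacer_id": slot["spacer_id"],
                        "source_id": gid,
                        "array_index": slot["array_index"],
                        "ordinal": slot["ordinal"],
                        "start": cursor,
                        "end": cursor + sp_len,
                        "sequence": slot["sequence"],
                        "is_protospacer": int(slot["is_protospacer"]),
                    }
                )
                cursor += sp_len + len(unit)
            offset += len(array_str)
            prev = pos
        pieces.append("".join(bg[prev:]))
        genome_seqs[gid] = "".join(pieces)
        genus, species = ARCHAEAL_TAXA[g % len(ARCHAEAL_TAXA)]
        host_tax_rows.append({"genome_id": gid, "genus": genus, "species": species})
        labels = ["housekeeping"] * (_GENES_PER_CELL_GENOME - 1) + ["transposase"]
        gene_rows.extend(_plant_genes(gid, labels))
    records.extend(
        SequenceRecord(g, s, "archaeal_genome") for g, s in genome_seqs.items()
    )

    # --- bacterial decoy genomes -------------------------------------------
    bacterial: dict[str, str] = {}
    for b in range(config.n_bacterial_decoys):
        bid = f"bact_{b + 1:03d}"
        length = int(rng.integers(*config.genome_length_range, endpoint=True))
        bacterial[bid] = random_seq(rng, length, gc)
        gene_rows.extend(_plant_genes(bid, ["housekeeping"] * _GENES_PER_CELL_GENOME))
    records.extend(SequenceRecord(b, s, "bacterial_genome") for b, s in bacterial.items())

    all_spacer_seqs = [r["sequence"] for r in spacer_rows]

    # --- plasmid decoys: spacer-matched but hallmark-free -------------------
    plasmids: dict[str, str] = {}
    p_lo, p_hi = config.viral_length_range[0] // 2, config.viral_length_range[1] // 2
    for p in range(config.n_plasmid_decoys):
        pid = f"plas_{p + 1:03d}"
        length = int(rng.integers(p_lo, p_hi, endpoint=True))
        seq = random_seq(rng, length, gc)
        if all_spacer_seqs:
            for _ in range(2):
                sp = all_spacer_seqs[int(rng.integers(len(all_spacer_seqs)))]
                at = int(rng.integers(2000, length - 2000))
                seq = seq[:at] + sp + seq[at:]
        plasmids[pid] = seq
        gene_rows.extend(_plant_genes(pid, ["transposase", "housekeeping", "housekeeping"]))
    records.extend(SequenceRecord(p, s, "plasmid_decoy") for p, s in plasmids.items())

    # --- contamination contigs ----------------------------------------------
    expected_removal: dict[str, str] = {}
    for b, (bid, bseq) in enumerate(bacterial.items()):
        cid = f"bfrag_{b + 1:03d}"
        w0 = int(rng.integers(0, max(1, len(bseq) - _FRAGMENT_LEN)))
        frag = bseq[w0 : w0 + _FRAGMENT_LEN]
        if all_spacer_seqs:
            sp = all_spacer_seqs[int(rng.integers(len(all_spacer_seqs)))]
            mid = len(frag) // 2
            frag = frag[:mid] + sp + frag[mid:]
        records.append(SequenceRecord(cid, frag, "bacterial_fragment"))
        expected_removal[cid] = "candidate_ii"
    for g, (gid, gseq) in enumerate(genome_seqs.items()):
        cid = f"afrag_{g + 1:03d}"
        first_arr = next(r for r in spacer_rows if r["source_id"] == gid)
        w0 = max(0, first_arr["start"] - 1000)
        frag = gseq[w0 : w0 + _FRAGMENT_LEN]
        records.append(SequenceRecord(cid, frag, "archaeal_fragment"))
        expected_removal[cid] = "candidate_iii"
    for pid in plasmids:
        expected_removal[pid] = "final"

    # --- tables --------------------------------------------------------------
    gene_table = pd.DataFrame(
        gene_rows, columns=["genome_id", "gene_id", "label", "start", "end"]
    )
    hallmark_placements = gene_table[
        gene_table["label"].isin(HALLMARK_LABELS)
    ].reset_index(drop=True)

    host_taxonomy = pd.DataFrame(host_tax_rows, columns=["genome_id", "genus", "species"])
    taxonomy_hits = _taxonomy_hit_table(
        gene_table, host_taxonomy, set(bacterial), rng, label_noise
    )
    viral_annotations = _annotation_table(gene_table, set(viral), "viral_reference")
    isolate_annotations = _annotation_table(gene_table, set(genome_seqs), "archaeal_isolate")
    candidate_hallmark_hits = _hallmark_hit_table(gene_table, set(viral))

    spacers_df = pd.DataFrame(
        spacer_rows,
        columns=[
            "spacer_id", "source_id", "array_index", "ordinal",
            "start", "end", "sequence", "is_protospacer",
        ],
    )
    proto_df = pd.DataFrame(
        proto_rows, columns=["spacer_id", "viral_id", "start", "end", "strand"]
    )

    links, links_df = _truth_host_links(spacers_df, proto_df, genome_plans, host_taxonomy)

    truth = CommunityTruth(
        spacers=spacers_df,
        protospacer_placements=proto_df,
        hallmark_gene_placements=hallmark_placements,
        host_links_truth=links,
        host_links_by_genome=links_df,
        gene_table=gene_table,
        taxonomy_hits=taxonomy_hits,
        viral_annotations=viral_annotations,
        isolate_annotations=isolate_annotations,
        candidate_hallmark_hits=candidate_hallmark_hits,
        host_taxonomy=host_taxonomy,
        expected_removal=expected_removal,
    )
    return records, truth


def _taxonomy_hit_table(
    gene_table: pd.DataFrame,
    host_taxonomy: pd.DataFrame,
    bacterial_ids: set[str],
    rng: np.random.Generator,
    label_noise: float,
) -> pd.DataFrame:
    tax_of = {r.genome_id: (r.genus, r.species) for r in host_taxonomy.itertuples()}
    rows = []
    cell_genes = gene_table[
        gene_table["genome_id"].isin(bacterial_ids | set(tax_of))
    ]
    for r in cell_genes.itertuples():
        if r.genome_id in bacterial_ids:
            domain, genus, species = "bacterial", "Bacteroides", "Bacteroides sp001"
        else:
            domain = "archaeal"
            genus, species = tax_of[r.genome_id]
        if label_noise > 0 and rng.random() < label_noise:
            domain = "bacterial" if domain == "archaeal" else "archaeal"
        ranks = {rank: "" for rank in RANKS}
        ranks.update(
            phylum="Euryarchaeota" if domain == "archaeal" else "Bacteroidota",
            genus=genus,
            species=species,
        )
        rows.append(
            {
                "protein_id": r.gene_id,
                "contig_id": r.genome_id,
                "domain": domain,
                **ranks,
                "score": 120.0,
                "evalue": 1e-30,
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "contig_id", "domain", *RANKS, "score", "evalue"])


def _annotation_table(
    gene_table: pd.DataFrame, genome_ids: set[str], source_class: str
) -> pd.DataFrame:
    rows = []
    for r in gene_table[gene_table["genome_id"].isin(genome_ids)].itertuples():
        family_id, description = GENE_FAMILIES[r.label]
        rows.append(
            {
                "protein_id": r.gene_id,
                "source_genome_id": r.genome_id,
                "source_class": source_class,
                "family_id": family_id,
                "family_description": description,
                "evalue": 1e-20,
                "score": 80.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "source_genome_id", "source_class",
            "family_id", "family_description", "evalue", "score",
        ],
    )


def _hallmark_hit_table(gene_table: pd.DataFrame, viral_ids: set[str]) -> pd.DataFrame:
    """Ideal best-hit table of candidate proteins against the hallmark set.

    The planted viral genomes double as the reference genomes, so each
    hallmark-labeled candidate protein best-hits its own hallmark entry.
    """
    rows = [
        {
            "contig_id": r.genome_id,
            "protein_id": r.gene_id,
            "hallmark_id": r.gene_id,
            "evalue": 1e-30,
        }
        for r in gene_table[
            gene_table["genome_id"].isin(viral_ids)
            & gene_table["label"].isin(HALLMARK_LABELS)
        ].itertuples()
    ]
    return pd.DataFrame(rows, columns=["contig_id", "protein_id", "hallmark_id", "evalue"])


def _truth_host_links(
    spacers_df: pd.DataFrame,
    proto_df: pd.DataFrame,
    genome_plans: list,
    host_taxonomy: pd.DataFrame,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Host links expected after the host-prediction spacer criteria.

    A planted protospacer supports a link when its source genome is longer
    than 10 kb (always true here), its array holds at least three spacers,
    and the spacer is longer than 25 bp.
    """
    tax_of = {r.genome_id: (r.genus, r.species) for r in host_taxonomy.itertuples()}
    arr_sizes = spacers_df.groupby(["source_id", "array_index"]).size()
    virus_of = dict(zip(proto_df["spacer_id"], proto_df["viral_id"]))
    links: dict[str, set[str]] = {}
    rows = []
    seen = set()
    for r in spacers_df.itertuples():
        vid = virus_of.get(r.spacer_id)
        if vid is None:
            continue
        if len(r.sequence) <= 25:
            continue
        if arr_sizes[(r.source_id, r.array_index)] < 3:
            continue
        genus, species = tax_of[r.source_id]
        links.setdefault(vid, set()).add(species)
        key = (vid, r.source_id)
        if key not in seen:
            seen.add(key)
            rows.append(
                {
                    "virus_id": vid,
                    "host_genome_id": r.source_id,
                    "host_genus": genus,
                    "host_species": species,
                }
            )
    links_df = pd.DataFrame(
        sorted(rows, key=lambda d: (d["virus_id"], d["host_genome_id"])),
        columns=["virus_id", "host_genome_id", "host_genus", "host_species"],
    )
    return links, links_df


# ---------------------------------------------------------------------------
# Reads


def generate_reads(
    sequences: Iterable[SequenceRecord],
    truth: CommunityTruth,
    config: CommunityConfig,
    n_samples: int = 4,
    presence_prob: float = 0.8,
) -> pd.DataFrame:
    """Sample per-sample shotgun reads uniformly along each replicon.

    Each replicon is present in a sample with probability ``presence_prob``;
    a present replicon contributes Poisson(coverage * length / read length)
    reads with uniform start positions. Returns a read table (read_id,
    sample_id, replicon_id, start) and fills ``truth.sample_compositions``
    with the realized per-sample read fractions.
    """
    import warnings as _warnings

    rng = np.random.default_rng(config.seed + 1_000_003)
    replicons = [r for r in sequences if len(r.seq) >= config.read_length]
    rows = []
    comp_rows = []
    for j in range(n_samples):
        sample = f"sample_{j + 1:02d}"
        counts: dict[str, int] = {}
        for rec in replicons:
            if rng.random() >= presence_prob:
                continue
            lam = config.coverage_per_genome * len(rec.seq) / config.read_length
            n = int(rng.poisson(lam))
            if n == 0:
                _warnings.warn(
                    f"replicon {rec.id} present in {sample} but drew zero reads"
                )
                continue
            starts = rng.integers(0, len(rec.seq) - config.read_length + 1, size=n)
            counts[rec.id] = n
            rows.extend(
                {
                    "read_id": f"{sample}:{rec.id}:{i}",
                    "sample_id": sample,
                    "replicon_id": rec.id,
                    "start": int(s),
                }
                for i, s in enumerate(starts)
            )
        total = sum(counts.values())
        for rid, n in counts.items():
            comp_rows.append(
                {"sample_id": sample, "replicon_id": rid, "fraction": n / total if total else 0.0}
            )
    reads = pd.DataFrame(rows, columns=["read_id", "sample_id", "replicon_id", "start"])
    truth.sample_compositions = pd.DataFrame(
        comp_rows, columns=["sample_id", "replicon_id", "fraction"]
    )
    return reads


def mapping_summaries_from_reads(
    reads: pd.DataFrame,
    lengths: Mapping[str, int],
    read_length: int,
) -> list[MappingSummary]:
    """Collapse a read table into per-sample per-contig mapping summaries."""
    summaries = []
    totals = reads.groupby("sample_id").size().to_dict()
    for (sample, rid), group in reads.groupby(["sample_id", "replicon_id"]):
        length = lengths[rid]
        starts = np.sort(group["start"].to_numpy())
        covered = 0
        cur_start = cur_end = -1
        for s in starts:
            e = min(int(s) + read_length, length)
            if s > cur_end:
                covered += cur_end - cur_start if cur_end > cur_start else 0
                cur_start, cur_end = int(s), e
            else:
                cur_end = max(cur_end, e)
        covered += cur_end - cur_start if cur_end > cur_start else 0
        summaries.append(
            MappingSummary(
                sample_id=sample,
                contig_id=rid,
                mapped_read_count=len(group),
                covered_positions=covered,
                contig_length=length,
                sample_total_reads=totals[sample],
            )
        )
    return summaries


def simulate_virome_mixture(
    archaeal_fraction: float,
    n_samples: int,
    reads_per_sample: int,
    rng: np.random.Generator,
    n_archaeal_contigs: int = 3,
    n_other_contigs: int = 20,
    contig_length: int = 10_000,
    read_length: int = 100,
) -> tuple[list[MappingSummary], list[MappingSummary]]:
    """Plant a known archaeal fraction of the virome and emit summaries.

    Per sample, Binomial(reads, fraction) reads go to archaeal viral
    contigs, the rest to other (bacteriophage) contigs; reads spread over
    the contigs multinomially. Breadth follows the Lander-Waterman
    expectation 1 - exp(-coverage). Contig count and length are chosen so
    that a planted contig's expected breadth sits well above the 30%
    filter; otherwise the breadth cutoff, not sampling noise, would govern
    the recovered fraction. Returns (archaeal, total) summary lists; the
    total includes the archaeal contigs.
    """
    arch_ids = [f"avir_{i + 1:03d}" for i in range(n_archaeal_contigs)]
    other_ids = [f"bvir_{i + 1:03d}" for i in range(n_other_contigs)]
    archaeal: list[MappingSummary] = []
    total: list[MappingSummary] = []

    def summaries(sample: str, ids: list[str], n_reads: int) -> list[MappingSummary]:
        if not ids:
            return []
        split = rng.multinomial(n_reads, np.full(len(ids), 1 / len(ids)))
        out = []
        for cid, n in zip(ids, split):
            cov = n * read_length / contig_length
            covered = int(round(contig_length * (1 - np.exp(-cov))))
            out.append(
                MappingSummary(
                    sample_id=sample,
                    contig_id=cid,
                    mapped_read_count=int(n),
                    covered_positions=min(covered, contig_length),
                    contig_length=contig_length,
                    sample_total_reads=reads_per_sample,
                )
            )
        return out

    for j in range(n_samples):
        sample = f"sample_{j + 1:02d}"
        n_arch = int(rng.binomial(reads_per_sample, archaeal_fraction))
        arch = summaries(sample, arch_ids, n_arch)
        other = summaries(sample, other_ids, reads_per_sample - n_arch)
        archaeal.extend(arch)
        total.extend(arch + other)
    return archaeal, total


# ---------------------------------------------------------------------------
# Fixture round-tripping


_TRUTH_TABLES = {
    "truth_spacers.tsv": "spacers",
    "truth_protospacers.tsv": "protospacer_placements",
    "truth_hallmark_genes.tsv": "hallmark_gene_placements",
    "truth_host_links.tsv": "host_links_by_genome",
    "genes.tsv": "gene_table",
    "taxonomy_hits.tsv": "taxonomy_hits",
    "viral_annotations.tsv": "viral_annotations",
    "isolate_annotations.tsv": "isolate_annotations",
    "hallmark_hits.tsv": "candidate_hallmark_hits",
    "host_taxonomy.tsv": "host_taxonomy",
}


def write_fixture(
    sequences: Iterable[SequenceRecord],
    truth: CommunityTruth,
    directory: str | Path,
    config: CommunityConfig | None = None,
) -> None:
    """Write the community as FASTA + TSV truth tables (lossless round-trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(sequences, directory / "sequences.fasta")
    for fname, attr in _TRUTH_TABLES.items():
        getattr(truth, attr).to_csv(directory / fname, sep="\t", index=False)
    if truth.sample_compositions is not None:
        truth.sample_compositions.to_csv(
            directory / "sample_compositions.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        [{"contig_id": k, "stage": v} for k, v in sorted(truth.expected_removal.items())],
        columns=["contig_id", "stage"],
    ).to_csv(directory / "expected_removal.tsv", sep="\t", index=False)
    if config is not None:
        (directory / "config.yaml").write_text(yaml.safe_dump(config.__dict__))


def read_fixture(directory: str | Path) -> tuple[list[SequenceRecord], CommunityTruth]:
    directory = Path(directory)
    sequences = read_fasta(directory / "sequences.fasta")
    tables = {
        attr: pd.read_csv(directory / fname, sep="\t", keep_default_na=False)
        for fname, attr in _TRUTH_TABLES.items()
    }
    links_df = tables["host_links_by_genome"]
    links: dict[str, set[str]] = {}
    for r in links_df.itertuples():
        links.setdefault(r.virus_id, set()).add(r.host_species)
    removal_df = pd.read_csv(directory / "expected_removal.tsv", sep="\t")
    comp_path = directory / "sample_compositions.tsv"
    truth = CommunityTruth(
        spacers=tables["spacers"],
        protospacer_placements=tables["protospacer_placements"],
        hallmark_gene_placements=tables["hallmark_gene_placements"],
        host_links_truth=links,
        host_links_by_genome=links_df,
        gene_table=tables["gene_table"],
        taxonomy_hits=tables["taxonomy_hits"],
        viral_annotations=tables["viral_annotations"],
        isolate_annotations=tables["isolate_annotations"],
        candidate_hallmark_hits=tables["candidate_hallmark_hits"],
        host_taxonomy=tables["host_taxonomy"],
        expected_removal=dict(zip(removal_df["contig_id"], removal_df["stage"])),
        sample_compositions=(
            pd.read_csv(comp_path, sep="\t") if comp_path.exists() else None
        ),
    )
    return sequences, truth
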