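"""Construction guarantees of the synthetic community generator."""

import numpy as np
import pandas as pd
import pytest

from archvirome.seqs import revcomp
from archvirome.synthetic_community import (
    HALLMARK_LABELS,
    CommunityConfig,
    generate_community,
    generate_reads,
    mapping_summaries_from_reads,
    read_fixture,
    write_fixture,
)


def test_infeasible_configs_rejected():
    with pytest.raises(ValueError, match="no viral genomes"):
        generate_community(CommunityConfig(n_viral_genomes=0, protospacer_fraction=1.0))
    with pytest.raises(ValueError, match="longer than the shortest viral genome"):
        generate_community(
            CommunityConfig(viral_length_range=(30, 40), spacer_length_range=(25, 45),
                            genome_length_range=(20_000, 20_500))
        )
    with pytest.raises(ValueError, match="protospacer_fraction"):
        CommunityConfig(protospacer_fraction=1.5)


def test_same_seed_gives_byte_identical_fixture(tmp_path):
    config = CommunityConfig(seed=7, n_archaeal_genomes=3, n_viral_genomes=4,
                             n_bacterial_decoys=1, n_plasmid_decoys=1)
    for name in ("a", "b"):
        seqs, truth = generate_community(config)
        write_fixture(seqs, truth, tmp_path / name, config=config)
    a, b = (tmp_path / "a"), (tmp_path / "b")
    for f in sorted(p.name for p in a.iterdir()):
        assert (a / f).read_bytes() == (b / f).read_bytes(), f


def test_protospacers_are_verbatim_viral_substrings(community):
    """Exhaustive substring oracle over both strands of the source virus."""
    _, sequences, truth = community
    viral = {s.id: s.seq for s in sequences if s.role == "viral_genome"}
    spacer_seq = dict(zip(truth.spacers["spacer_id"], truth.spacers["sequence"]))
    assert len(truth.protospacer_placements) > 0
    for r in truth.protospacer_placements.itertuples():
        seq = spacer_seq[r.spacer_id]
        genome = viral[r.viral_id]
        assert seq in genome or revcomp(seq) in genome
        planted = genome[r.start : r.end]
        assert seq == (revcomp(planted) if r.strand == "-" else planted)


def test_truth_spacers_match_their_source_coordinates(community):
    _, sequences, truth = community
    genomes = {s.id: s.seq for s in sequences}
    for r in truth.spacers.itertuples():
        assert genomes[r.source_id][r.start : r.end] == r.sequence


def test_hallmark_labels_partition_viruses_from_decoys(community):
    """Every viral genome carries >=1 hallmark gene; no plasmid decoy does."""
    _, sequences, truth = community
    genes = truth.gene_table
    hallmark_carriers = set(genes[genes["label"].isin(HALLMARK_LABELS)]["genome_id"])
    for s in sequences:
        if s.role == "viral_genome":
            assert s.id in hallmark_carriers
        if s.role == "plasmid_decoy":
            assert s.id not in hallmark_carriers


def test_every_virus_receives_a_protospacer(community):
    _, sequences, truth = community
    targeted = set(truth.protospacer_placements["viral_id"])
    assert targeted == {s.id for s in sequences if s.role == "viral_genome"}


def test_fixture_round_trip(tmp_path, community):
    config, sequences, truth = community
    reads = generate_reads(sequences, truth, config, n_samples=2)
    write_fixture(sequences, truth, tmp_path, config=config)
    seqs2, truth2 = read_fixture(tmp_path)
    assert seqs2 == sequences
    pd.testing.assert_frame_equal(truth2.spacers, truth.spacers)
    pd.testing.assert_frame_equal(truth2.gene_table, truth.gene_table)
    pd.testing.assert_frame_equal(truth2.taxonomy_hits, truth.taxonomy_hits)
    assert truth2.host_links_truth == truth.host_links_truth
    assert truth2.expected_removal == truth.expected_removal


def test_read_counts_follow_poisson_coverage():
    """10x coverage of a 10 kb replicon with 100 bp reads gives ~1000 reads."""
    config = CommunityConfig(
        seed=3, n_archaeal_genomes=1, n_viral_genomes=1, n_bacterial_decoys=0,
        n_plasmid_decoys=0, coverage_per_genome=10.0, read_length=100,
        genome_length_range=(20_000, 20_001), viral_length_range=(10_000, 10_001),
    )
    seqs, truth = generate_community(config)
    virus = [s for s in seqs if s.role == "viral_genome"]
    reads = generate_reads(virus, truth, config, n_samples=3, presence_prob=1.0)
    lam = 10.0 * 10_000 / 100  # = 1000 expected reads
    for _, group in reads.groupby("sample_id"):
        assert abs(len(group) - lam) <= 3 * np.sqrt(lam)


def test_absent_replicon_contributes_no_reads(community):
    config, sequences, truth = community
    reads = generate_reads(sequences, truth, config, n_samples=2, presence_prob=0.0)
    assert reads.empty
    assert truth.sample_compositions.empty


def test_mapping_summary_coverage_matches_position_union():
    """Covered positions equal an explicit per-base union oracle."""
    reads = pd.DataFrame(
        [
            {"read_id": "r1", "sample_id": "s1", "replicon_id": "c", "start": 0},
            {"read_id": "r2", "sample_id": "s1", "replicon_id": "c", "start": 50},
            {"read_id": "r3", "sample_id": "s1", "replicon_id": "c", "start": 300},
            {"read_id": "r4", "sample_id": "s1", "replicon_id": "c", "start": 950},
        ]
    )
    summaries = mapping_summaries_from_reads(reads, {"c": 1000}, read_length=100)
    covered = set()
    for s in (0, 50, 300, 950):
        covered.update(range(s, min(s + 100, 1000)))
    assert summaries[0].covered_positions == len(covered)
    assert summaries[0].mapped_read_count == 4
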