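"""Spacer matching against the Hamming oracle, filters, clustering, ledger."""

import numpy as np
import pytest

from archvirome.crispr_mine import Spacer
from archvirome.seqs import SequenceRecord, revcomp
from archvirome.synthetic_community import random_seq
from archvirome.viral_discover import (
    StageLedger,
    cluster_species,
    filter_archaeal,
    filter_bacterial,
    match_spacers,
    run_workflow,
)


def spacer(seq, sid="sp1"):
    return Spacer(spacer_id=sid, sequence=seq, source_id="g", array_id="a",
                  ordinal=0, start=0, end=len(seq))


def hamming_oracle(spacer_seq, target_seq, tolerance):
    """Exhaustive sliding-window Hamming scan over both strands (pure python)."""
    hits = []
    m = len(spacer_seq)
    for strand, probe in (("+", spacer_seq), ("-", revcomp(spacer_seq))):
        for i in range(len(target_seq) - m + 1):
            mism = sum(a != b for a, b in zip(probe, target_seq[i : i + m]))
            if mism <= tolerance:
                hits.append((i, strand, mism))
    return sorted(hits)


def as_tuples(matches):
    return sorted((m.start, m.strand, m.mismatches) for m in matches)


def test_verbatim_and_reverse_complement_matches():
    rng = np.random.default_rng(30)
    target = random_seq(rng, 2000)
    fwd = target[300:335]
    rc_only = revcomp(target[900:940])
    contig = SequenceRecord("c", target)
    m_fwd = match_spacers([spacer(fwd)], [contig], mode="host")
    assert as_tuples(m_fwd) == [(300, "+", 0)]
    m_rev = match_spacers([spacer(rc_only)], [contig], mode="host")
    assert as_tuples(m_rev) == [(900, "-", 0)]


def test_mode_mismatch_contracts():
    """A 30 bp spacer with 2 substitutions: host mode misses, discovery hits."""
    rng = np.random.default_rng(31)
    target = random_seq(rng, 1000)
    sub = list(target[500:530])
    sub[5] = "A" if sub[5] != "A" else "C"
    sub[20] = "A" if sub[20] != "A" else "C"
    sp = spacer("".join(sub))
    contig = SequenceRecord("c", target)
    assert match_spacers([sp], [contig], mode="host") == []
    discovery = match_spacers([sp], [contig], mode="discovery")
    assert (500, "+", 2) in as_tuples(discovery)
    assert as_tuples(discovery) == hamming_oracle(sp.sequence, target, 3)


def test_non_acgt_spacer_skipped_with_warning():
    contig = SequenceRecord("c", "ACGT" * 100)
    with pytest.warns(UserWarning, match="non-ACGT"):
        assert match_spacers([spacer("ACGTNACGTANCGTACGTACGTACGT")], [contig]) == []


@pytest.mark.parametrize("seed", range(3))
def test_match_spacers_equals_oracle_on_random_instances(seed):
    rng = np.random.default_rng(100 + seed)
    for _ in range(25):
        target = random_seq(rng, int(rng.integers(100, 600)))
        length = int(rng.integers(25, 46))
        if rng.random() < 0.7 and len(target) > length:
            pos = int(rng.integers(0, len(target) - length))
            probe = list(target[pos : pos + length])
            for _ in range(int(rng.integers(0, 5))):
                i = int(rng.integers(0, length))
                probe[i] = "ACGT"[int(rng.integers(4))]
            seq = "".join(probe)
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = random_seq(rng, length)
        sp = spacer(seq)
        for mode, tol in (("host", 0), ("discovery", length // 10)):
            got = as_tuples(match_spacers([sp], [SequenceRecord("t", target)], mode=mode))
            assert got == hamming_oracle(seq, target, tol), (mode, seq)


def test_bacterial_filter_thresholds():
    rng = np.random.default_rng(32)
    genome = SequenceRecord("bact", random_seq(rng, 30_000))
    # 85% of the candidate is an exact genome fragment -> removed
    removed_cand = SequenceRecord("rm", genome.seq[1000:9500] + random_seq(rng, 1500))
    # only 70% of the candidate aligns -> coverage below 0.80, retained
    kept_cand = SequenceRecord("kp", genome.seq[1000:8000] + random_seq(rng, 3000))
    unrelated = SequenceRecord("un", random_seq(rng, 10_000))
    retained, removed = filter_bacterial([removed_cand, kept_cand, unrelated], [genome])
    assert [r.id for r in retained] == ["kp", "un"]
    assert [(r.id, reason) for r, reason in removed] == [("rm", "bacterial:bact")]
    # empty decoy set retains everything
    retained2, removed2 = filter_bacterial([removed_cand], [])
    assert retained2 == [removed_cand] and removed2 == []


def test_archaeal_filter_requires_full_containment():
    rng = np.random.default_rng(33)
    genome = SequenceRecord("arch", random_seq(rng, 30_000))
    contained = SequenceRecord("in", genome.seq[2000:12_000])
    almost = SequenceRecord("out", genome.seq[2000:11_900] + random_seq(rng, 100))
    retained, removed = filter_archaeal([contained, almost], [genome])
    assert [r.id for r in retained] == ["out"]
    assert [(r.id, reason) for r, reason in removed] == [("in", "archaeal:arch")]


def test_species_clustering_semantics():
    rng = np.random.default_rng(34)
    a = random_seq(rng, 10_000)
    dup = SequenceRecord("dup", a)
    distinct = [SequenceRecord(f"d{i}", random_seq(rng, 9000)) for i in range(2)]
    species = cluster_species([SequenceRecord("a", a), dup, *distinct])
    assert len(species) == 3
    by_rep = {s.representative.id: s for s in species}
    assert sorted(by_rep["a"].member_ids) == ["a", "dup"]
    for s in species:
        assert all(len(m.seq) <= len(s.representative.seq) for m in s.members)


def test_ledger_invariants_enforced():
    ledger = StageLedger.from_counts(100, 40, 5, 10, 5)
    assert ledger.counts == {
        "spacer_matched": 100, "candidate_i_species": 40,
        "candidate_ii": 35, "candidate_iii": 25, "final": 20,
    }
    with pytest.raises(ValueError, match="negative"):
        StageLedger.from_counts(10, 5, 6, 0, 0)
    with pytest.raises(ValueError, match="non-increasing"):
        StageLedger(counts={
            "spacer_matched": 10, "candidate_i_species": 5,
            "candidate_ii": 7, "candidate_iii": 7, "final": 7,
        }).validate()


def test_empty_spacer_set_yields_empty_workflow():
    rng = np.random.default_rng(35)
    contigs = [SequenceRecord("c", random_seq(rng, 5000))]
    species, ledger = run_workflow([], contigs)
    assert species == []
    assert all(v == 0 for v in ledger.counts.values())


def test_workflow_ledger_matches_truth_bookkeeping(pipeline):
    """Stage counts and removal reasons equal the generator's own records."""
    truth = pipeline.truth
    ledger = pipeline.ledger
    expected_by_stage = {"candidate_ii": 0, "candidate_iii": 0, "final": 0}
    for stage in truth.expected_removal.values():
        expected_by_stage[stage] += 1
    n_candidates = len(pipeline.candidates)
    assert ledger.counts["spacer_matched"] == n_candidates
    assert ledger.counts["candidate_i_species"] == n_candidates  # all distinct
    assert len(ledger.removed["candidate_ii"]) == expected_by_stage["candidate_ii"]
    assert len(ledger.removed["candidate_iii"]) == expected_by_stage["candidate_iii"]
    assert len(ledger.removed["final"]) == expected_by_stage["final"]
    for contig_id, stage in truth.expected_removal.items():
        assert contig_id in {cid for cid, _ in ledger.removed[stage]}
    # conservation: retained + removed = input at every stage
    assert ledger.counts["final"] + sum(
        len(v) for v in ledger.removed.values()
    ) == ledger.counts["candidate_i_species"]
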