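"""Hallmark gene set construction and hallmark-based filtering."""

import pandas as pd
import pytest

from archvirome.hallmark_build import (
    HALLMARK_KEYWORDS,
    AnnotationHit,
    build_hallmark_set,
    filter_by_hallmarks,
    keyword_matches,
    select_exclusive_families,
    select_keyword_families,
)


def hit(pid, family, desc="", source="viral_reference", genome="v1", evalue=1e-20):
    return AnnotationHit(
        protein_id=pid, source_genome_id=genome, source_class=source,
        family_id=family, family_description=desc, evalue=evalue, score=80,
    )


def test_exclusive_families_rule():
    viral = [hit("vp1", "F1"), hit("vp2", "F1"), hit("vp3", "F2")]
    isolates = [hit("ip1", "F2", source="archaeal_isolate")]
    # F1 only on viral genomes -> its proteins included; F2 shared -> excluded
    assert select_exclusive_families(viral, isolates) == {"vp1", "vp2"}
    # vacuous exclusivity with an empty isolate table
    assert select_exclusive_families(viral, []) == {"vp1", "vp2", "vp3"}


@pytest.mark.parametrize(
    "description,expected",
    [
        ("Phage terminase large subunit", True),
        ("integrase", False),                 # not in the keyword list
        ("Tailless complex polypeptide", False),  # whole-token: tailless != tail
        ("tape measure protein", True),       # two-token form of tapemeasure
        ("Tail fiber assembly", True),
        ("", False),
    ],
)
def test_keyword_whole_token_matching(description, expected):
    assert keyword_matches(description, HALLMARK_KEYWORDS) is expected


def test_keyword_selection_spans_viral_and_isolate_proteins():
    anns = [
        hit("vp1", "F1", "Portal protein"),
        hit("ip1", "F9", "Minor capsid protein", source="archaeal_isolate"),
        hit("ip2", "F8", "ABC transporter", source="archaeal_isolate"),
    ]
    assert select_keyword_families(anns) == {"vp1", "ip1"}


def test_keyword_monotonicity():
    """Enlarging the keyword list never shrinks the selected set."""
    anns = [hit(f"p{i}", f"F{i}", d) for i, d in enumerate(
        ["Portal protein", "integrase", "tail fiber", "transposase", "holin family"]
    )]
    small = select_keyword_families(anns, ("portal",))
    larger = select_keyword_families(anns, ("portal", "tail", "holin"))
    assert small <= larger
    assert larger <= select_keyword_families(anns, HALLMARK_KEYWORDS + ("integrase",))


def test_build_set_union_and_reasons():
    assert len(build_hallmark_set()) == 0
    hallmark = build_hallmark_set(
        exclusive={"p1", "p2"},
        keyword={"p2", "p3"},
        provirus_proteins={"p4"},
        orthology_hits=[hit("p5", "VOG1", evalue=1e-8), hit("p6", "VOG2", evalue=1e-3)],
    )
    # p6 fails the e-value threshold; p2 carries two reasons
    assert hallmark.protein_ids == {"p1", "p2", "p3", "p4", "p5"}
    assert hallmark.members["p2"] == {"exclusive_family", "keyword_family"}
    # brute-force set-union oracle on the cardinality
    assert len(hallmark) == len({"p1", "p2"} | {"p2", "p3"} | {"p4"} | {"p5"})


def test_build_set_deduplicates_by_protein_sequence():
    seqs = {"p1": "MAAA", "p2": "MAAA", "p3": "MCCC"}
    hallmark = build_hallmark_set(
        exclusive={"p1"}, keyword={"p2"}, provirus_proteins={"p3"}, protein_seqs=seqs
    )
    assert hallmark.protein_ids == {"p1", "p3"}
    assert hallmark.members["p1"] == {"exclusive_family", "keyword_family"}


def test_filter_retains_hallmark_bearing_contigs_only():
    hallmark = build_hallmark_set(exclusive={"hm1"})
    hits = pd.DataFrame(
        [
            {"contig_id": "viral", "protein_id": "g1", "hallmark_id": "hm1", "evalue": 1e-30},
            {"contig_id": "weak", "protein_id": "g2", "hallmark_id": "hm1", "evalue": 1e-3},
            {"contig_id": "plasmid", "protein_id": "g3", "hallmark_id": "tnp1", "evalue": 1e-30},
        ]
    )
    retained, removed = filter_by_hallmarks(["viral", "weak", "plasmid", "empty"], hallmark, hits)
    assert retained == ["viral"]
    assert removed == ["weak", "plasmid", "empty"]


def test_community_hallmark_filter_separates_viruses_from_decoys(community):
    """All planted viruses pass; spacer-matched plasmid decoys do not."""
    _, sequences, truth = community

    def from_table(df):
        return [
            AnnotationHit(
                protein_id=r.protein_id, source_genome_id=r.source_genome_id,
                source_class=r.source_class, family_id=r.family_id,
                family_description=r.family_description,
                evalue=float(r.evalue), score=float(r.score),
            )
            for r in df.itertuples()
        ]

    viral_ann = from_table(truth.viral_annotations)
    isolate_ann = from_table(truth.isolate_annotations)
    hallmark = build_hallmark_set(
        exclusive=select_exclusive_families(viral_ann, isolate_ann),
        keyword=select_keyword_families(viral_ann + isolate_ann),
    )
    candidates = [s.id for s in sequences if s.role in ("viral_genome", "plasmid_decoy")]
    retained, removed = filter_by_hallmarks(candidates, hallmark, truth.candidate_hallmark_hits)
    assert set(retained) == {s.id for s in sequences if s.role == "viral_genome"}
    assert set(removed) == {s.id for s in sequences if s.role == "plasmid_decoy"}
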