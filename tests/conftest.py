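"""Shared fixtures: one seeded synthetic community and one full pipeline run."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from archvirome.crispr_mine import MineConfig, dereplicate_spacers, mine_spacers
from archvirome.hallmark_build import (
    AnnotationHit,
    build_hallmark_set,
    select_exclusive_families,
    select_keyword_families,
)
from archvirome.host_taxa import predict_hosts
from archvirome.synthetic_community import CommunityConfig, generate_community
from archvirome.viral_discover import match_spacers, run_workflow

CANDIDATE_ROLES = ("viral_genome", "plasmid_decoy", "bacterial_fragment", "archaeal_fragment")


def annotation_hits(df):
    return [
        AnnotationHit(
            protein_id=r.protein_id,
            source_genome_id=r.source_genome_id,
            source_class=r.source_class,
            family_id=r.family_id,
            family_description=r.family_description,
            evalue=float(r.evalue),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


@pytest.fixture(scope="session")
def community():
    """The default seeded community: 10 archaea, 5 bacteria, 20 viruses, 5 plasmids."""
    config = CommunityConfig(seed=42)
    sequences, truth = generate_community(config)
    return config, sequences, truth


@dataclass
class PipelineRun:
    config: CommunityConfig
    sequences: list
    truth: object
    candidates: list
    species: list
    ledger: object
    host_links: list
    recovered_links: dict[str, set[str]]


@pytest.fixture(scope="session")
def pipeline(community) -> PipelineRun:
    """Full cascade + host prediction on the seeded community, run once."""
    config, sequences, truth = community
    archaea = [s for s in sequences if s.role == "archaeal_genome"]
    bacteria = [s for s in sequences if s.role == "bacterial_genome"]
    candidates = [s for s in sequences if s.role in CANDIDATE_ROLES]

    spacers, _ = mine_spacers(archaea, MineConfig(), "database")
    spacer_reps, _ = dereplicate_spacers(spacers)

    viral_ann = annotation_hits(truth.viral_annotations)
    isolate_ann = annotation_hits(truth.isolate_annotations)
    hallmark = build_hallmark_set(
        exclusive=select_exclusive_families(viral_ann, isolate_ann),
        keyword=select_keyword_families(viral_ann + isolate_ann),
    )

    species, ledger = run_workflow(
        spacer_reps,
        candidates,
        bacteria,
        archaea,
        hallmark,
        truth.candidate_hallmark_hits,
    )

    host_spacers, _ = mine_spacers(archaea, MineConfig(), "host_prediction")
    host_reps, host_membership = dereplicate_spacers(host_spacers)
    matches = match_spacers(host_reps, [s.representative for s in species], mode="host")
    by_id = {sp.spacer_id: sp for sp in host_spacers}
    sources = {
        rep_id: sorted({by_id[m].source_id for m in members})
        for rep_id, members in host_membership.items()
    }
    taxonomy = {
        r.genome_id: (r.genus, r.species) for r in truth.host_taxonomy.itertuples()
    }
    links = predict_hosts(matches, sources, taxonomy)
    recovered: dict[str, set[str]] = {}
    for link in links:
        recovered.setdefault(link.species_id, set()).add(link.host_species)

    return PipelineRun(
        config=config,
        sequences=sequences,
        truth=truth,
        candidates=candidates,
        species=species,
        ledger=ledger,
        host_links=links,
        recovered_links=recovered,
    )
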