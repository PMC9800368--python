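"""Virus-host prediction and taxonomy assignment.

Hosts are predicted by strict CRISPR evidence: a virus is linked to an
archaeal genome only when a spacer from that genome matches the viral
sequence at 100% identity over the spacer's full length. Host-range breadth
is the number of distinct host species so linked to one virus.

Taxonomy uses two complementary rules. Within a viral cluster (VC, a
genus-level grouping by shared protein content, supplied as input), the
reference members' class label is propagated to unlabeled members; outliers
and singletons never receive a propagated label. Independently, a contig is
assigned to the tailed-virus class (*Caudoviricetes*) when at least one of
its proteins has a qualifying orthology hit whose description carries a
tailed-virus keyword.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hallmark_build import keyword_matches
from .viral_discover import SpacerMatch

UNASSIGNED = "unassigned"

#: Keywords marking tailed-virus (Caudoviricetes) functions in orthology
#: annotations.
CLASS_KEYWORDS: tuple[str, ...] = (
    "portal", "terminase", "spike", "capsid", "sheath", "tail",
    "base plate", "fiber", "tape measure",
)

TAILED_CLASS = "Caudoviricetes"


@dataclass(frozen=True)
class HostLink:
    """A spacer-supported link between a viral species and a host genome."""

    species_id: str
    host_genome_id: str
    host_genus: str
    host_species: str
    match_spacer_ids: tuple[str, ...]


@dataclass(frozen=True)
class VcAssignment:
    species_id: str
    vc_id: str  # a VC id, or "outlier"/"singleton"
    taxonomy: str  # propagated or own label, or "unassigned"


def predict_hosts(
    host_mode_matches: Sequence[SpacerMatch],
    spacer_sources: Mapping[str, Iterable[str]],
    host_taxonomy: Mapping[str, tuple[str, str]],
    contig_to_species: Mapping[str, str] | None = None,
) -> list[HostLink]:
    """Aggregate 100%-identity spacer matches into virus-host links.

    ``spacer_sources`` maps a (dereplicated) spacer id to every source
    genome carrying it; ``host_taxonomy`` maps genome id to (genus,
    species). One link per (viral species, host genome) pair, with the
    supporting spacer ids collected. Matches from spacers with unknown
    provenance are excluded with a warning.
    """
    support: dict[tuple[str, str], set[str]] = defaultdict(set)
    for m in host_mode_matches:
        sources = spacer_sources.get(m.spacer_id)
        if sources is None:
            warnings.warn(f"spacer {m.spacer_id} has no recorded provenance; match excluded")
            continue
        species = (contig_to_species or {}).get(m.target_id, m.target_id)
        for genome in sources:
            support[(species, genome)].add(m.spacer_id)

    links = []
    for (species, genome), spacer_ids in sorted(support.items()):
        genus, host_sp = host_taxonomy.get(genome, (UNASSIGNED, UNASSIGNED))
        links.append(
            HostLink(
                species_id=species,
                host_genome_id=genome,
                host_genus=genus,
                host_species=host_sp,
                match_spacer_ids=tuple(sorted(spacer_ids)),
            )
        )
    return links


def propagate_vc_taxonomy(
    vc_membership: Mapping[str, str],
    reference_labels: Mapping[str, str],
) -> list[VcAssignment]:
    """Propagate reference class labels within each VC.

    A reference member always keeps its own label. An unlabeled member of a
    real VC receives the strict-majority label of the VC's reference
    members (tie or no reference → unassigned). Outliers and singletons are
    never assigned by propagation.
    """
    by_vc: dict[str, list[str]] = defaultdict(list)
    for member, vc in vc_membership.items():
        by_vc[vc].append(member)

    vc_label: dict[str, str] = {}
    for vc, members in by_vc.items():
        if vc in ("outlier", "singleton"):
            continue
        labels = [reference_labels[m] for m in members if m in reference_labels]
        if not labels:
            vc_label[vc] = UNASSIGNED
            continue
        counts = Counter(labels).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            vc_label[vc] = UNASSIGNED
        else:
            vc_label[vc] = counts[0][0]

    assignments = []
    for member, vc in sorted(vc_membership.items()):
        if member in reference_labels:
            label = reference_labels[member]
        elif vc in ("outlier", "singleton"):
            label = UNASSIGNED
        else:
            label = vc_label.get(vc, UNASSIGNED)
        assignments.append(VcAssignment(species_id=member, vc_id=vc, taxonomy=label))
    return assignments


def keyword_class_assign(
    hits: pd.DataFrame,
    keywords: Sequence[str] = CLASS_KEYWORDS,
    score_min: float = 40.0,
    evalue_max: float = 1e-5,
) -> dict[str, str]:
    """Assign the tailed-virus class from keyword-bearing orthology hits.

    ``hits`` columns: contig_id, description, score, evalue. A contig is
    assigned iff it has at least one hit passing the score/e-value
    thresholds whose description matches a keyword.
    """
    result: dict[str, str] = {c: UNASSIGNED for c in hits["contig_id"].unique()}
    ok = hits[(hits["score"] >= score_min) & (hits["evalue"] <= evalue_max)]
    for row in ok.itertuples():
        if keyword_matches(str(row.description), keywords):
            result[row.contig_id] = TAILED_CLASS
    return result


def summarize_networks(
    links: Sequence[HostLink],
    vc_assignments: Sequence[VcAssignment] | Mapping[str, str] = (),
) -> dict[str, pd.DataFrame]:
    """Deterministic host-range summaries.

    Returns four tables: viruses per host genus, VCs per host genus, the
    host-range breadth histogram (distinct host species per virus), and the
    bipartite virus-host-species edge list.
    """
    if isinstance(vc_assignments, Mapping):
        vc_of = dict(vc_assignments)
    else:
        vc_of = {a.species_id: a.vc_id for a in vc_assignments}

    edges = sorted({(l.species_id, l.host_species) for l in links})
    edge_df = pd.DataFrame(edges, columns=["virus", "host_species"])

    genus_viruses: dict[str, set[str]] = defaultdict(set)
    genus_vcs: dict[str, set[str]] = defaultdict(set)
    for l in links:
        genus_viruses[l.host_genus].add(l.species_id)
        vc = vc_of.get(l.species_id)
        if vc and vc not in ("outlier", "singleton"):
            genus_vcs[l.host_genus].add(vc)

    per_genus = pd.DataFrame(
        sorted((g, len(v)) for g, v in genus_viruses.items()),
        columns=["host_genus", "n_viruses"],
    )
    vcs_per_genus = pd.DataFrame(
        sorted((g, len(v)) for g, v in genus_vcs.items()),
        columns=["host_genus", "n_vcs"],
    )

    breadth = Counter(
        len({l.host_species for l in links if l.species_id == sp})
        for sp in {l.species_id for l in links}
    )
    breadth_df = pd.DataFrame(
        sorted(breadth.items()), columns=["host_range_breadth", "n_viruses"]
    )
    return {
        "viruses_per_genus": per_genus,
        "vcs_per_genus": vcs_per_genus,
        "breadth_histogram": breadth_df,
        "edges": edge_df,
    }


def shared_family_vcs(
    protein_families: Mapping[str, set[str]], min_shared: int = 2
) -> dict[str, str]:
    """Simplified VC builder: connected components by shared protein families.

    This is a deliberately simple stand-in for gene-sharing network
    clustering, intended for synthetic tests only; it is **not** equivalent
    to the published viral-cluster methodology. Members sharing at least
    ``min_shared`` families join one component; components of size one are
    labeled "singleton".
    """
    ids = sorted(protein_families)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if len(protein_families[a] & protein_families[b]) >= min_shared:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = defaultdict(list)
    for i in ids:
        components[find(i)].append(i)

    membership: dict[str, str] = {}
    for n, (_, members) in enumerate(sorted(components.items()), start=1):
        label = "singleton" if len(members) == 1 else f"VC_{n:03d}"
        for m in members:
            membership[m] = label
    return membership
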