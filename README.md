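# archvirome

Discovery and characterization of **archaeal viruses in gut metagenomes**
from CRISPR spacers and viral signature genes.

Archaeal viruses are nearly invisible to conventional virome tools: they
lack universal marker genes, and reference databases hold only a few
hundred genomes. What archaea do have is CRISPR immunity — most archaeal
genomes carry CRISPR arrays whose spacers are verbatim copies of past
invaders. `archvirome` implements the spacer-anchored discovery strategy
built on that fact, as a tested, reusable library plus CLI for
bioinformaticians studying the non-bacterial fraction of the microbiome.

## The method

1. **Archaeal screening.** A metagenome contig is called archaeal when its
   per-protein taxonomy hits satisfy `n_archaeal > n_bacterial` and
   `n_archaeal ≥ 5`; per-rank taxonomy is the strict plurality over protein
   hits; contigs >3 kb are dereplicated at ≥95% identity over ≥85% of the
   shorter sequence (greedy, longest-first).
2. **Spacer mining.** CRISPR arrays (exact direct repeats 19–38 bp,
   spacers 19–48 bp, ≥2 repeat copies) are detected by a seed-and-extend
   repeat finder; spacers are pooled into a nonredundant database (exact
   duplicates collapsed, strand preserved). For host prediction, a
   stringent subset is used: source >10 kb, ≥3 spacers per array, spacer
   length >25 bp.
3. **Hallmark genes.** An archaeal-virus hallmark protein set is the
   deduplicated union of (i) annotation families exclusive to reference
   archaeal viruses, (ii) keyword families (portal, terminase, capsid,
   tail, holin, …), (iii) provirus proteins, (iv) viral-orthology best
   hits at e ≤ 1e-5.
4. **Discovery cascade.** Contigs matched by any spacer (≤10%
   substitutions, full spacer length) are clustered into species (95%/85%,
   longest representative; *candidate I*), then filtered: bacterial
   contamination (≥50% identity over ≥80% of the candidate; *candidate
   II*), archaeal contamination (≥50% identity over 100%; *candidate
   III*), and finally any candidate without a hallmark best hit at
   e ≤ 1e-5 — which is what removes spacer-matched plasmids and
   transposons. A stage ledger records every count and removal.
5. **Hosts, taxonomy, abundance.** Hosts are assigned from 100%-identity
   full-length spacer matches; class labels propagate within viral
   clusters (VCs) and via tailed-virus keywords (score ≥40, e ≤ 1e-5);
   relative abundance is mapped reads over sample total, counted only at
   breadth of coverage >30%, with prevalence and the archaeal fraction of
   the virome derived from the abundance matrix.

A first-class synthetic-community generator plants archaeal genomes with
CRISPR arrays, viral genomes containing the protospacers, spacer-matched
plasmid decoys without hallmark genes, bacterial/archaeal contamination
fragments, and ideal hit tables — so every stage is testable against known
truth without external databases.

## Worked example

```python
from archvirome import (
    CommunityConfig, generate_community, mine_spacers, dereplicate_spacers,
    build_hallmark_set, select_exclusive_families, select_keyword_families,
    run_workflow, MineConfig, AnnotationHit,
)

config = CommunityConfig(seed=42)          # 10 archaea, 5 bacteria, 20 viruses, 5 plasmids
sequences, truth = generate_community(config)
archaea = [s for s in sequences if s.role == "archaeal_genome"]
candidates = [s for s in sequences if s.role in
              ("viral_genome", "plasmid_decoy", "bacterial_fragment", "archaeal_fragment")]

spacers, arrays = mine_spacers(archaea, MineConfig(), "database")
spacer_reps, _ = dereplicate_spacers(spacers)
print(f"{len(arrays)} CRISPR arrays -> {len(spacer_reps)} nonredundant spacers")

def hits(df):
    return [AnnotationHit(r.protein_id, r.source_genome_id, r.source_class,
                          r.family_id, r.family_description, r.evalue, r.score)
            for r in df.itertuples()]
viral_ann, iso_ann = hits(truth.viral_annotations), hits(truth.isolate_annotations)
hallmark = build_hallmark_set(
    exclusive=select_exclusive_families(viral_ann, iso_ann),
    keyword=select_keyword_families(viral_ann + iso_ann))
print(f"{len(hallmark)} hallmark proteins")

species, ledger = run_workflow(
    spacer_reps, candidates,
    [s for s in sequences if s.role == "bacterial_genome"], archaea,
    hallmark, truth.candidate_hallmark_hits)
print("stage counts:", ledger.counts)
```

prints

```
20 CRISPR arrays -> 116 nonredundant spacers
68 hallmark proteins
stage counts: {'spacer_matched': 40, 'candidate_i_species': 40, 'candidate_ii': 35,
               'candidate_iii': 25, 'final': 20}
```

Forty candidate contigs enter the cascade; the bacterial filter removes the
5 bacterial fragments, the archaeal filter the 10 excised CRISPR loci, and
the hallmark filter the 5 plasmid decoys, leaving exactly the 20 planted
viral genomes as final species. The same pipeline is exposed as a CLI:

```sh
archvirome simulate --seed 11 --out-dir fixture
archvirome mine-spacers archaea.fasta --purpose database --out spacers.tsv
archvirome discover --spacers spacers.tsv --contigs candidates.fasta \
    --bacterial bacteria.fasta --archaeal archaea.fasta \
    --hallmarks hallmarks.tsv --hallmark-hits hits.tsv --out-dir discovery
archvirome assign-hosts --spacers host_spacers.tsv \
    --species discovery/species.fasta --host-taxonomy host_taxonomy.tsv --out links.tsv
```

## Layout

- `src/archvirome/synthetic_community.py` — planted-truth community generator
- `src/archvirome/archaeal_screen.py` — archaeal contig classification and dereplication
- `src/archvirome/crispr_mine.py` — CRISPR array detection and spacer database
- `src/archvirome/hallmark_build.py` — hallmark gene set construction and filtering
- `src/archvirome/viral_discover.py` — matching, contamination filters, species, ledger
- `src/archvirome/host_taxa.py` — host prediction, VC taxonomy, network summaries
- `src/archvirome/abundance_profile.py` — breadth-filtered abundance, prevalence, virome fraction
- `src/archvirome/alignment.py` — shared k-mer-seeded identity/coverage engine
- `docs/methods.md` — model, parameters, numerical choices, limitations
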