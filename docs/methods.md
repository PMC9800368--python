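# Methods

## Model and assumptions

The pipeline rests on one biological premise: CRISPR spacers are verbatim
records of past infection, so a nucleotide match between an archaeal
spacer and an assembled contig is evidence that the contig derives from a
mobile element that infected (or invaded) that archaeon. Discovery
therefore proceeds spacer-first, and three confounders are handled
explicitly downstream:

- **bacterial contamination** — chimeric or misbinned contigs of bacterial
  origin can match spacers by chance or via shared mobile DNA; they are
  recognized by alignment to bacterial genomes (≥50% identity over ≥80%
  of the candidate);
- **archaeal (host) contamination** — an excised fragment of the host
  chromosome, in particular the CRISPR locus itself, matches many spacers
  trivially; it is recognized by full containment in an archaeal genome
  (≥50% identity over 100% of the candidate);
- **non-viral mobile elements** — plasmids and transposons are genuine
  spacer targets but not viruses; they are excluded because they encode no
  protein homologous to the archaeal-virus hallmark set.

A contig surviving all three filters and carrying a hallmark homolog is
treated as viral. Host assignment uses a stricter evidence standard than
discovery: the spacer must match at 100% identity over its full length,
and only spacers from confident arrays count (source sequence >10 kb, ≥3
spacers per array, spacer >25 bp; the length criteria are read strictly,
so a 25 bp spacer and a 10 kb source are excluded).

## Key parameters

| parameter | default | role |
| --- | --- | --- |
| archaeal call | >bacterial hits and ≥5 archaeal hits | contig screening |
| hit thresholds | e ≤ 1e-3, score ≥ 50 | protein taxonomy hits |
| dereplication / species | ≥95% identity over ≥85% of shorter | greedy longest-first clustering |
| contig length floor | >3000 bp | screening output |
| repeat / spacer detection | 19–38 bp / 19–48 bp, k_seed = 8 | array detector |
| discovery match | ≤ floor(0.10·len) substitutions, no indels, full length | stand-in for short-query blastn at e < 1e-5 |
| host match | 0 mismatches, full length | host prediction |
| bacterial filter | id ≥ 0.50, candidate coverage ≥ 0.80 | contamination |
| archaeal filter | id ≥ 0.50, candidate coverage = 1.00 | contamination |
| hallmark filter | best hit at e ≤ 1e-5 | viral confirmation |
| class keywords | score ≥ 40, e ≤ 1e-5 | tailed-virus assignment |
| breadth filter | abundance counted only when breadth > 0.30 | profiling |

## Alignment engine

Identity/coverage between nucleotide sequences is computed by a banded
local alignment seeded by shared 16-mers: seeds are anchored on the
dominant diagonal (±64 bp band), the chained query span is aligned
globally with edlib, and identity is matched columns over alignment
columns of the extended CIGAR. Coverage is the chained span divided by the
query length; in clustering the query is always the shorter sequence
(processing is longest-first), mirroring the `-aS` convention of classic
dereplicators. Both strands are examined by reverse-complementing the
query. Like any word-seeded aligner, the engine cannot detect homology
so diverged that no exact 16-mer survives (roughly below 60–70% identity);
the 50%-identity contamination thresholds are therefore conservative
contracts, exercised in tests with near-exact and fully random cases on
either side of the coverage boundary.

Greedy clustering processes sequences by descending length (ties broken
lexicographically by id) and joins each sequence to the first matching
representative, so representatives are always the longest member and the
operation is idempotent on its own output.

## CRISPR detection

The detector finds exact direct repeats: every 8-mer whose occurrences
recur at spacings within [min repeat + min spacer, max repeat + max
spacer] anchors a candidate run of repeat copies; the repeat unit is then
the maximal string on which *all* anchored copies agree, which pins the
repeat/spacer boundary using every copy rather than a single pair.
Overlapping candidates are resolved by most repeat copies, then longest
span, then leftmost start. Exact-repeat semantics are a deliberate
simplification: the synthetic generator plants exact repeat copies, and
on i.i.d. background the chance that a ≥19 bp exact repeat recurs at
array-like spacing is negligible, which the tests assert empirically.
Spacer dereplication collapses byte-identical sequences only — no strand
canonicalization — keeping first-seen provenance as representative and a
full membership map.

## Synthetic communities

The generator's defaults are the study conditions of the test-bed: 10
archaeal genomes (20–30 kb) each carrying 2 arrays of 4–8 spacers
(repeats 28–37 bp, spacers 25–45 bp), 20 viral genomes (15–25 kb), 5
bacterial genomes, 5 plasmid decoys, protospacer fraction 0.6, GC 0.45.
Protospacers are copied verbatim from viral genomes (reverse complement
with probability 0.5) and assigned by cycling a shuffled virus list, so
every virus is targeted by at least one spacer whenever spacer slots are
plentiful. Contamination candidates are constructed per decoy: a bacterial
fragment with one inserted spacer copy, and an excised archaeal window
containing a CRISPR array. Repeat boundaries are made unambiguous by
construction (a uniform flanking base across all copies would make the
repeat unit ill-defined; the generator perturbs the adjacent background
base in that case).

Hit tables are ideal by default: taxonomy hits carry the source genome's
labels, annotation families follow the planted gene labels (terminase,
portal, capsid, integrase, peiW, mazE on viruses; housekeeping and
transposase on cellular genomes and plasmids), and the candidate-vs-
hallmark table contains exactly the hallmark-labeled viral proteins. A
label-noise rate can corrupt taxonomy domains to separate logic errors
from noise effects. What passing tests show is therefore that the *logic*
of every stage is correct under its stated contracts; they do not show
robustness to assembly chimerism, repeat degeneracy, sequencing error, or
divergent real-world homology, none of which the generator emulates.

Reads are sampled uniformly per replicon at Poisson(coverage ×
length / read length) per sample; the virome-fraction simulator plants a
known archaeal share (0.5% by default, the scale reported for gut
viromes) as a per-sample binomial split and uses the Lander–Waterman
breadth expectation 1 − exp(−coverage). Its contig count and length are
chosen so planted contigs sit well above the 30% breadth cutoff —
otherwise the filter, not sampling noise, would govern the recovered
fraction.

## Numerical and design choices

- Coordinates are 0-based half-open internally, 1-based inclusive in
  exported tables.
- Taxonomy plurality and VC label propagation are strict: ties yield
  `unassigned`; reference members always keep their own label, and
  outliers/singletons are never assigned by propagation.
- Keyword matching is case-insensitive and whole-token; a keyword also
  matches the concatenation of two adjacent tokens, so "tapemeasure"
  matches "tape measure" but "tail" never matches "tailless".
- The breadth threshold is strict (>30%), as is the spacer length
  criterion (>25 bp) and the host-source length (>10 kb).
- Discovery-mode matching is full-spacer-length with ≤10% substitutions
  and no indels — a deterministic contract standing in for engine-specific
  e-value thresholds on 25–45 bp queries; partial-length spacer hits are
  not accepted.
- The per-stage ledger counts species after the initial clustering;
  retained + removed equals the input at every stage and counts are
  validated as non-increasing.
- Multi-mapped reads, when a mapping table is provided, are counted once
  toward the best-covered contig with lexicographic tie-break; the
  synthetic read simulator emits unique-source reads.
- VC membership is consumed as input; the built-in shared-family
  connected-components builder is a labeled simplification for synthetic
  tests, not a substitute for gene-sharing network clustering.

## Problem sizes

The test suite and the acceptance script run the complete cascade on the
default 40-candidate community (one CPU, well under two minutes), check
the spacer matcher against an exhaustive Hamming oracle on 1,000
randomized instances, and recover the planted virome fraction over
replicated simulations of 4–8 samples × 50–100k reads. These sizes fully
exercise every code path while keeping the whole suite fast enough to run
routinely.

## Known limitations

- Exact-repeat CRISPR detection will fragment real arrays with degenerate
  repeat copies; real-data use would substitute a dedicated detector's
  output via the spacer-table input path.
- The alignment engine is insensitive below the 16-mer seeding horizon
  (see above) and reports coverage from the chained span, which can
  slightly understate coverage at heavily mutated ends.
- Hallmark construction depends entirely on the supplied annotation
  tables; the package does not attempt profile-HMM scoring.
- The abundance model assumes per-position breadth with no depth floor
  and error-free read assignment.
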