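# Methods

## Model and procedure

`cdsortho` identifies orthologs between two annotated genomes without
aligning sequences, using two signals in sequence:

**Exon-structure matching.** A gene is represented by the ordered nucleotide
lengths of its CDS regions (coding exons), 5'→3' in coding orientation.
Under the *close* setting two genes match only if their length lists are
identical. Under the *distant* setting an in-order scan pairs equal lengths
1:1 and may, up to `max_diff_regions` times (default 2), merge a run of
consecutive regions in one gene whose summed length equals a single region
of the other — the signature of an exon fusion or splitting event. The scan
is greedy but complete for this event model: when the heads are equal a 1:1
pairing is forced (a merge would require additional regions of length zero),
and when they differ the merge direction and run length are forced by the
sum constraint, so there is never a branching choice. The test suite still
cross-checks the greedy scan against an exhaustive recursive matcher.

Because gene sets are kept sorted by CDS-region count (ties by gene id), the
candidates for a query are a contiguous window of subjects whose count
differs by at most the event budget; the engine locates it by binary search
and never touches genes outside it. This pruning is sound — a gene outside
the window cannot satisfy the matcher — and the suite asserts that disabling
it never changes any output pair.

**Dinucleotide-percentage distance.** Each exon is summarized by the
proportions of its 16 overlapping nucleotide bigrams (positions *i*, *i*+1
for *i* = 0…L−2). Bigram proportions are compared by total-variation
distance, d(p,q) = ½‖p−q‖₁ ∈ [0,1]; a gene pair's distance is the mean of d
over its pairing units, where a merge unit compares the profile of the
concatenated run against the single region. A subject is reported for a
query when its distance is minimal among the query's candidates (ties to the
smallest gene id) and at most the setting's threshold. Each query yields at
most one pair; a reciprocal-best filter is available but off by default.

The aggregation choices — overlapping bigram counting, total variation as
the norm, and the mean over exon units with a per-gene (not per-exon)
threshold — are this package's own: overlapping counting maximizes signal
from short exons, total variation is bounded in [0,1] so the conventional
thresholds (0.05 close / 0.1 distant) are dimensionally sensible, and the
mean keeps multi-exon gene distances on the same scale as single-exon ones.
Both the norm and the aggregation are isolated in `profile_distance` /
`gene_distance` so an alternative (non-overlapping counting, sum instead of
mean, per-exon thresholds) is a local change.

**Settings and thresholds.** *close*: exact length lists, θ = 0.05, for
closely related species. *distant*: up to two fusion/split events, θ = 0.1.
*combined*: both runs (about twice the cost), union of pairs with the close
pair winning on conflict. Thresholds are adjustable per call.

**Parallelism contract.** Work is partitioned by query gene across worker
processes; results are merged and re-sorted by query id, so output is
byte-identical for any worker count. The CLI defaults to all available
cores; the library API defaults to one process.

## Degenerate inputs

- Bigrams containing N are excluded from both numerator and denominator of a
  profile. An exon shorter than 2 nt, or all of whose bigrams contain N,
  gets the all-zero profile.
- Pairing units where either profile is all-zero are skipped from the mean
  with a warning; if every unit is skipped the genes are incomparable and
  the distance is +∞ (never reported).
- Genes whose CDS contain characters outside {A,C,G,T,N} after uppercasing
  are dropped at extraction time with a warning, since bigram proportions
  are undefined for ambiguity codes.
- Empty gene sets yield an empty result with a warning; 0/0 precision or
  recall is reported as NA, never as 0.

## Annotation pipeline

GFF3 parsing is strict where it matters (nine tab-separated columns, start ≤
end, known strand) and tolerant elsewhere (directives skipped, `##FASTA`
terminates parsing, attributes percent-unescaped). Genes carrying
annotation-error notes — by default any attribute value containing
"translational error", "suspected error" or "transcription discrepancy",
case-insensitively — are removed entirely; the flag list is configurable
because annotation dialects differ in which attribute carries such notes.
Per gene, the transcript with the largest summed CDS length is kept (ties to
the lexicographically smallest transcript id). Minus-strand CDS regions are
reverse-complemented and order-reversed so index 0 is always the 5'-most
coding region. The interchange format ("CDS-FASTA") stores one record per
gene, header `species|gene_id|transcript_id|n_cds`, CDS regions joined by
`*`, records sorted by (CDS count, gene id); read ∘ write is the identity.

## Group combination

Pairwise outputs are undirected edges between (species, gene) nodes; groups
are the connected components of that graph, sorted by descending size then
smallest member. One-to-one enforcement removes any group in which a species
contributes two or more genes — whole-group removal is the default because
splitting such a group would require an arbitrary choice among paralogs; a
prune mode (drop only the duplicated species' genes) is available.

## Benchmark construction and scoring

Shared case-folded gene names define true pairs. *original* sets chunk the
name-sorted pair list; *mismatch* sets draw a per-chunk TP fraction
uniformly from [0.5, 0.9] (seeded) and pad with partnerless genes from both
species symmetrically; *error* sets chunk only partnerless genes. Every set
holds at most `chunk_size` (default 1000) genes per species, and a new set
starts where the previous one ended. Scoring excludes reported items that
lack a gene from each of the two species, requires exactly one gene per
species plus truth membership for a TP, and reports precision TP/(TP+FP) and
recall TP/(TP+FN).

## Synthetic data generator

The generator emulates exactly the regime the matcher assumes: multi-exon
genes (exon count 3–12 with geometric-decay weights, decay 0.8; exon lengths
uniform on 60–300 nt; uniform base composition at GC 0.5), orthologs derived
by i.i.d. per-site substitution (uniform over the three alternatives,
Jukes–Cantor-like — only the amount of divergence matters to the
thresholds), optional structural events (a split cuts one region at a random
interior point, a fusion joins two adjacent regions; one event per gene by
default so the two-event budget is comfortably sufficient), decoy genes with
no ortholog, and optional error-flagged genes and shorter extra isoforms to
exercise the annotation filters. Genomes are emitted as FASTA + GFF3 with
random intronic (50–400 nt) and intergenic (100–500 nt) spacers, ~25 genes
per contig, random strand per gene, and correct CDS phases; extraction from
the emitted files reproduces the input genes exactly.

Defaults (500 ortholog pairs, 1% substitution, 50 decoys) are the study
conditions used throughout the tests and the acceptance script. What the
generator does **not** model: indels inside exons (they would break the
length-conservation premise by design), codon structure and selection,
realistic GC heterogeneity, repeats, overlapping or nested genes, and
annotation coordinate errors. Passing tests therefore demonstrate
correctness of the algorithms under their own assumptions, not performance
on real genomes, where exon-length conservation decays with divergence time.

## Problem sizes

The test suite uses gene sets of 40–500 genes per species (oracle
equivalence against a naive all-pairs reference runs on twenty 40–60-gene
fixtures; planted-recovery checks use the full 500-pair study condition),
and the acceptance script re-runs the pipeline at 500 ortholog pairs per
species comparison. These sizes exercise every code path, including the
sorted-window pruning, at a scale where the exhaustive oracle remains
feasible.

## Known limitations

- Requires annotated CDS coordinates; protein-only inputs are out of scope.
- No within-species paralog search, and no alignment-based verification of
  reported pairs (a downstream aligner can be applied to the pair TSV).
- Recall falls with evolutionary distance as exon lengths diverge;
  precision is deliberately favored over recall.
- The distant setting's event model covers adjacent fusion/splitting only;
  exon gain/loss that changes total coding length is not matched.
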