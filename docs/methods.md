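# Methods

This note documents the models, defaults, and numerical choices behind
`cobakit`, and what its synthetic validation does and does not show.

## Marker evidence

Cobamide biosynthesis is detected through profile searches of predicted
proteins against a marker catalog. The catalog is *data*
(`src/cobakit/data/scp_markers.tsv`, TSV with columns `marker_id,
gene_symbol, profile_accessions, module, branch, required, weight`): the
shipped file is a curated default keyed to cobalamin-pathway KO/TIGRFAM
accessions, organized into the pathway modules *precursor*, *ring*
(oxygen-dependent aerobic vs oxygen-independent anaerobic), *chelation*,
*adenosylation*, *nucleotide loop*, and *salvage*. Any catalog with the
same columns can be dropped in without code change; the catalog validator
enforces unique marker ids, positive weights, at least one required ring
marker per oxygen branch, and at least one required loop marker.

Evidence handling:

- **Input dialect.** HMMER3 `--domtblout` tables are parsed directly
  (≥ 23 whitespace-separated columns; malformed lines are reported with
  their line number). The *full-sequence* E-value and bit score are used,
  matching default `hmmsearch` reporting, rather than per-domain
  conditional E-values. A live `pyhmmer` backend is available behind the
  same contract, but no backend is required: the entire pipeline runs from
  precomputed tables.
- **E-value gate.** Hits with E > 1e−6 are discarded; the boundary E =
  1e−6 passes.
- **One protein, one marker.** Each protein is assigned to its single
  best-scoring marker (bit score, then lower E-value, then lexicographic
  marker id). This prevents one promiscuous protein from inflating
  completeness across several paralogous families.

## Contig-level screening

False positives in MAGs arise mainly from binning contamination and
assembly fragments. Screening applies three independent guards, each
logged as a flag:

a. support on a contig shorter than 2 kb (`min_contig_len`) carrying no
   other marker is dropped — an isolated gene on a scrap contig is weak
   evidence, whereas co-located markers are kept even on short contigs
   (cobamide genes frequently cluster);
b. when per-contig taxonomy is available, support on contigs whose phylum
   conflicts with the genome's majority phylum is dropped;
c. if *all* surviving markers sit on one contig comprising < 5% of the
   genome (`single_contig_fraction`), the genome is flagged
   `single_contig_suspect`, which the classifier converts into a
   one-class downgrade rather than a rejection.

Hits whose contig cannot be determined (non-prodigal protein headers) are
exempt from the guards — their provenance cannot be checked — and a
warning notes how many such proteins exist. Screening never adds markers.

## Completeness scoring and the four-class rubric

Per branch, completeness is the weighted fraction of required markers
detected (branch-exclusive plus shared); module completeness is the same
fraction restricted per module and is reported for diagnosis. The
classification rubric defaults are:

| parameter | default | meaning |
|---|---|---|
| `t_very` | 0.75 | inclusive lower bound for *very likely* |
| `t_likely` | 0.50 | inclusive lower bound for *likely* |
| `t_possible` | 0.25 | inclusive lower bound for *possible* |
| `require_chelation_for_very` | true | no *very likely* call without cobalt-chelatase evidence |
| `adjust_for_genome_completeness` | true | divide by max(CheckM completeness/100, `q_floor`) |
| `q_floor` | 0.5 | floor for the adjustment divisor |

The thresholds and the chelation requirement are this package's defaults
for the four-class contract; they are deliberately config-exposed (TOML
`[rubric]` table on the CLI) so an authoritative rubric can replace them
without code change. The completeness adjustment exists so fragmentary
MAGs are not systematically under-called: a genome estimated 60% complete
with 45% of the pathway observed scores 0.45/0.60 = 0.75. The divisor is
floored at 0.5 because below that the extrapolation is unreliable; the
adjusted score is capped at 1.

The oxygen-route call uses branch-exclusive diagnostic markers only
(strictly greater count wins; equal nonzero counts are ambiguous; no
diagnostics at all is ambiguous when shared markers exist, else none), so
shared early-pathway genes never decide the route. Whether a *possible*
call reflects a partial de novo pathway or salvage-only capability is not
distinguished at the phenotype level; the per-module completeness columns
in the report make the distinction inspectable.

Genome quality gating retains completeness ≥ 50% (inclusive) and
contamination < 10% (strict), the medium-quality MAG convention for CheckM
estimates; no upper completeness bound is applied.

## 16S reference and exact-match annotation

16S genes are sliced from genomes using rRNA GFF3 coordinates (1-based
inclusive; minus-strand features reverse-complemented; U→T normalized).
Curation drops sequences shorter than 1000 nt — an invented quantification
of "high quality", config-exposed — and collapses exact duplicates and
exact substrings onto the longest representative (ties to the smallest
sequence id). Sequence strings occurring in both the producer and
nonproducer sets are quarantined as *conflicted* and excluded from both,
because a single 16S cannot separate the two phenotypes.

OTU annotation is exact: a query matches a reference iff the query or its
reverse complement is a gap-free substring of (or equal to) the reference —
100% identity over 100% of the query. Full-query coverage is required
because partial-coverage identity would make calls length-dependent. Calls
are producer / nonproducer / ambiguous (both sets match) / unassigned, and
the reported producer phenotype is the best class among matched references
(very likely > likely > possible). An external aligner could be swapped in
behind the same contract; the shipped implementation is a direct substring
search, which at reference-set scales of thousands of sequences is fast
and exactly auditable.

## Co-occurrence networks

Counts are converted to per-sample relative abundances before correlation
(sequencing depth varies across samples; `--on-counts` restores raw-count
behaviour). Rare OTUs (< 100 reads total; a total of exactly 100 is kept)
are excluded first. For every OTU pair, Pearson r and a two-sided p-value
from the t transform with n−2 df are computed; an edge requires p < 0.05
and |r| > 0 by default. Uncorrected thresholds match common practice in
amplicon network studies, but all-pairs testing is anticonservative, so
Benjamini–Hochberg correction is available (`--correction bh`).
Zero-variance OTU vectors are skipped with a note.

Centralities: degree; closeness as *harmonic* centrality normalized by
(n−1), chosen because it stays finite and comparable on disconnected
graphs (the classic variant is undefined there; the harmonic sum is
accumulated in sorted node order so outputs are bit-identical across
processes); betweenness on unweighted shortest paths, normalized. Group
comparisons (default: very-likely producers vs nonproducers) use two-sided
Mann–Whitney U tests per metric.

## Synthetic fixtures: what they emulate, and what they don't

All generators draw from one explicit seed; identical seeds give
byte-identical fixtures.

- **Planted genomes** sample a marker subset whose completeness sits at
  least 0.05 inside the target class band (so recovery is well-posed),
  write genuine hits at E ∈ [1e−30, 1e−7] and decoys at E ∈ (1e−6, 1e−3]
  to straddle the gate, and can stage each screening guard: an extra
  marker alone on an 800 nt contig, an extra marker on a
  foreign-phylum contig, or the whole marker complement on one contig
  covering < 5% of the genome.
- **16S communities** draw OTU representatives as 250 nt exact substrings
  of random references (or single-substitution mutants, which must come
  back unassigned), with log-normal–Poisson counts.
- **Correlated count tables** put half the OTUs into equal blocks with
  within-block latent correlation `block_rho` (Gaussian copula,
  exponentiated, Poisson-sampled) and leave half independent. The first
  block is labelled *very likely* and the independent background
  *nonproducer*: the hub property is planted in the correlated block, and
  the independent taxa are the natural null group for the comparison.
  With `block_rho = 0` every pair is null, which calibrates the
  false-edge rate against the nominal alpha.

These fixtures validate the *machinery* — boundary semantics, assignment
resolution, screening, exact matching, edge calling — under known truth.
They do not emulate real data's phylogenetic correlation among 16S
sequences, compositional depth artifacts, chimeras, sequencing error, or
realistic marker co-occurrence structure, so perfect recovery on fixtures
bounds software correctness, not real-world classifier accuracy.

Validation problem sizes (200 planted genomes; 60-OTU communities; 40-OTU
× 50-sample networks, 780 pairs) were chosen as the smallest scales at
which every planted property is statistically unambiguous; the whole
validation runs in seconds.

## Known limitations

- The shipped marker catalog is a reasonable default, not an authoritative
  profile list; per-profile score cutoffs (as in trusted-cutoff-style
  curation) are not implemented — the gate is a global E-value.
- Phenotype classes are completeness bands; no attempt is made to predict
  which cobamide variant (lower ligand) is produced.
- Exact-match annotation is strict by design: a single sequencing error
  makes an OTU unassigned. That is the intended trade-off (precision over
  recall) for trait attribution from amplicons.
- Pearson networks on relative abundances inherit compositional biases;
  SparCC-style compositionality-aware estimators are out of scope.
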