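# Methods

## Coordinates, chromosome labels and the overlap predicate

All coordinates are 1-based inclusive, the native convention of both GTF and
GFF; candidate `BP` values are interpreted on the same scale, so no silent
half-open shifts occur anywhere. Chromosome labels are normalized before any
join: a leading `chr`/`Chr`/`Chr.` prefix is stripped (the Animal-QTLdb
dialect writes `Chr.5`, candidate tables usually write `5`), numeric labels
are canonicalized (`05` → `5`) and non-numeric labels upper-cased, with sex
chromosomes kept as strings.

A feature overlaps a candidate when they share at least one base on closed
intervals after the candidate is expanded by the window `w` on both sides
(clipped at position 1): `feature.start ≤ candidate.end + w` and
`feature.end ≥ candidate.start − w`. There is no partial-overlap threshold
and strand is ignored — QTL records and candidate SNPs are strandless.
The window has **no default**: 100 kb and 200 kb are both defensible flanks
for the same data, so the choice is forced to be explicit.

The indexed join (per-chromosome interval trees; closed intervals stored as
`[start, end+1)`) is verified against an exhaustive O(candidates × features)
scan, which ships as `brute_force_overlap` and serves as the permanent
oracle in the test suite.

## Input parsing

GTF gene lines (feature type configurable, default `gene`) and QTLdb-dialect
GFF lines are parsed directly from their 9-column form. Attribute values are
percent-decoded once and surrounding quotes stripped. The QTL class is taken
from the feature-type column when it encodes one (`Milk_QTL` → `Milk`,
`Reproduction_Association` → `Reproduction`, underscores → spaces), falling
back to a `trait_type` attribute; the source of the class is not fixed by
any published schema, so the rule covers both observed dialect variants.
Records with missing or inverted coordinates are dropped, never imputed —
unplaced database records must not inflate the enrichment background — and
every drop is counted by reason in the database's provenance, so
`records_kept + records_dropped` always equals the number of data lines. A
file with data lines but no usable record is an error; a file with no data
lines loads as a legitimate empty database.

Candidate tables are auto-detected: `(CHR, BP1, BP2)` takes precedence over
`(CHR, BP)` because the interval schema is strictly more informative; all
other columns pass through unmodified to every output row.

## The enrichment test

One test per observed trait (or QTL class) per scope. Scope is either the
whole genome or one chromosome; in chromosome scope all four counts
(k: annotated records of the trait, K: database records of the trait,
n: total annotated records, N: total database records) are restricted to
that chromosome. Counting semantics that matter:

* records are deduplicated by database identifier within scope before
  counting — without this, several markers hitting one record could push
  k above K and break the model;
* traits with k = 0 in scope are not tested, so the correction family
  contains only observed traits; the number of emitted tests m is recorded
  in the result's metadata;
* an annotated trait absent from the database (K = 0) is a hard error:
  it means the annotation was not made against the supplied database.

The p-value is the upper tail P(X ≥ k) of the hypergeometric distribution.
For populations N ≤ 100,000 the tail is computed as a ratio of exact
big-integer binomial sums, converted to a correctly rounded double only at
the end; this is exact to the last ulp, never underflows prematurely (the
strongest real-data enrichments reach ~1e-171, and doubles carry subnormals
down to ~5e-324), and makes the point masses sum to 1 to within 1e-12 by
construction. For larger populations the tail switches to log-gamma point
masses combined with `logsumexp`, which bounds the cost at huge N at a small
accuracy price. A seeded Monte-Carlo cross-check (`permutation_pvalue`) is
provided for sanity checking; the analytic tail is always the default. The
test is deliberately one-sided: depletion is not flagged.

Multiple-testing correction delegates to
`statsmodels.stats.multitest.multipletests` (BH by default — the natural
choice when results are reported as FDR — with Bonferroni, Holm and none
available). Adjusted values are capped at 1 and returned in input order.

## Overlap matrices

Sharing between grouping factors uses unique-ID set semantics: IDs are
deduplicated within each group, the count matrix holds intersection sizes
(symmetric, diagonal = group sizes), and the percentage cell (A, B) is
100·|A∩B|/|A| — a deliberately asymmetric quantity, since 5 shared records
mean something different to a group of 10 than to a group of 5 (50% vs
100%). Percentages are reported to 2 decimals in files, full precision
internally.

## Composition summaries

Pie/bar compositions count unique database records, not join rows, so a QTL
hit by many markers cannot dominate the picture; the row-level alternative
is available via `unique_records=False`. Bars sort by descending frequency
with an optional top-N cut.

## The synthetic-data generator

`FixtureSpec` draws chromosomes of fixed length, genes of 2–200 kb, QTL
records with the heterogeneous spans seen in real QTL databases (30% point
records, 50% of 1–100 kb, 20% of 0.1–2 Mb), and interval candidates with a
grouping column. Trait labels come from a catalog of (name, class, relative
abundance) triples — the default catalog spans the six coarse classes used
for cattle (Milk, Reproduction, Meat and Carcass, Health, Production,
Exterior). With `planted_enrichment=(trait, d)`, records overlapping a
candidate window receive that trait with its abundance multiplied by `d`
(renormalized), creating a known signal. All randomness flows through one
`numpy.random.default_rng(seed)`; the same spec yields byte-identical files,
and the generator returns ground-truth hit lists and count quadruples
computed independently of the annotation code path.

What the generator does **not** emulate: linkage disequilibrium, realistic
marker density, clustering of QTL records around well-studied genes,
correlated trait labels between overlapping records, or real genome
coordinates. Passing tests therefore demonstrate correctness of the
counting, joining and testing machinery — not robustness to the spatial
correlation structure of real databases, where the independence assumptions
of the hypergeometric null are knowingly optimistic.

## Validation settings

The suite validates at sizes chosen to make the statistics informative while
keeping runs quick:

* join equivalence (index vs scan): 100 random datasets of 80 QTLs × 8
  candidates, plus 1,000 random window queries against one 400-record
  database;
* tail correctness: exhaustive subset enumeration for every parameter set
  with N ≤ 12, agreement with an independent library tail at random larger
  parameters, exact pmf normalization at N up to 2,000;
* null calibration: 200 datasets of 2,000 records over 8 equally abundant
  traits, 60 candidate windows of 20–80 kb with a 20 kb flank on two 10 Mb
  chromosomes; the fraction of genome-wide trait tests with p < 0.05 must
  fall in [0.02, 0.09]. The counts are sized so each trait draws enough
  records (K ≈ 250, n ≈ 400) that the discreteness of the hypergeometric
  tail does not push the attained level far below the nominal 5%;
* signal recovery: one trait planted at 10× in-window density must rank
  first by p-value in at least 95 of 100 seeded datasets (observed:
  100/100).

## Known limitations

* The enrichment null treats annotated records as exchangeable draws;
  spatial clustering of records for intensively studied traits violates
  this, and p-values for such traits should be read as upper bounds on
  surprise, not calibrated probabilities.
* No LD-aware or covariate-adjusted null is offered.
* GFF3 niceties (FASTA sections, ontology terms) are out of scope; the
  parser targets the Ensembl GTF and Animal-QTLdb dialects.
* Nearest-feature distances for zero-hit candidates are not reported; such
  candidates appear only in the summary table with a hit count of 0.
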