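# Methods

This note records the models, conventions and numerical choices behind
`circpipe`, and what its synthetic fixtures do and do not demonstrate.

## Coordinates

All internal coordinates are 0-based half-open (BED convention). Every
reader declares its source convention (`one_closed` for GTF/GFF and
DCC-style tables, `zero_half_open` for BED-like files) and converts on
ingestion. This matters because the conservation classifier works at ±2 nt
resolution: a single off-by-one introduced by mixing conventions would
silently shift circRNAs between categories. Strand `"."` means unknown and
is never coerced to `"+"`; operations that need an orientation (5′/3′ end
resolution) assume plus-strand for unknown and flag it in their output.

## Two-caller consensus

Junctions match across callers only on identical `(chrom, start, end)`
after normalization, with *compatible* strands (equal, or at least one
unknown — one common caller dialect omits strand; `strict_strand=True`
demands equality). No tolerance window is applied: backsplice coordinates
are read-level exact in both supported callers, and a window would
re-introduce the ambiguity the consensus is meant to remove.

The expression rule is read literally as "the same samples in both tools":
a sample counts only when it has ≥ `min_count` (default 2) reads in *both*
callers, and ≥ `min_samples` (default 3) such samples are required —
either over all samples (`all_samples`) or inside a single treatment group
(`within_group`, for designs where expression is group-specific). The
looser reading — three qualifying samples per tool, not necessarily the
same ones — is available as `samples_shared=False`. The 2-read minimum is
applied to each tool's own counts. Survivors take the reference caller's
counts (DCC-style caller by convention, configurable) and sequential IDs
assigned after sorting by `(chrom, start, end)`, which makes numbering
deterministic regardless of input order.

## Boundary concordance

A circRNA end is concordant when it coincides with an exon boundary (circ
start with an exon start, circ end with an exon end) of *any* overlapping
gene, at tolerance 0 by default — exact matching is the appropriate
default when discrepancies are attributed to incomplete gene annotation
rather than measurement error. Raising the tolerance can only promote a
classification (`neither → one_end → both_ends`). The exon count is the
number of distinct host-gene exons fully inside the circRNA interval.

## Chain liftover

`lift_interval` maps a query through the gapless aligned blocks of the
best-scoring chain whose source range covers it (ties broken toward the
lowest chain id, logged). The interval maps iff the fraction of its bases
inside blocks is ≥ `min_ratio` (default 0.95, inclusive); the target
interval spans the mapped bases, with strand flipped under minus-strand
chains. Splice sites are lifted as 1-base intervals, which makes the ratio
test all-or-none per site; a config option lifts the full circRNA interval
instead and applies the ratio to it. The implementation walks blocks
arithmetically; the test suite checks it base-by-base against an
independent per-base mapper on ≥1000 random chains including inversions.

## Conservation categories

For each circRNA both splice-site flanks (strand-resolved into 5′ and 3′)
are lifted; a lifted site *matches* a database record when it lies on the
same target chromosome within ±`tolerance_nt` (default 2, inclusive on
both sides — 5 positions per site) of either of the record's two splice
positions. Categories: `not_aligned` (a flank failed to lift),
`homologous` (one record matched at both flanks, at opposite sites),
`both_sites_utilized` (both flanks matched, but by different records
only), `five_prime_utilized` / `three_prime_utilized` (exactly one flank
matched), `no_homologous` (neither). DB positions are compared
strand-blind because public circRNA databases annotate strand
inconsistently; a strict-strand mode exists. Summary percentages always
use all detected circRNAs as denominator, including `not_aligned` — e.g.
1606 homologous out of 2510 detected is reported as 63.98%, not as a
fraction of the 2458 liftable ones.

## Sponge screen

Cluster intersection reports a (circRNA, cluster) pair when the circRNA
covers ≥ `min_frac` (default 0.75, inclusive) of the *cluster* — the
screen asks whether the circRNA contains the reported sponge region; the
fraction-of-circ alternative is a flag. The orthology filter keeps miRNAs
flagged confident, or whose precursor hairpin aligns at identity ≥ 0.90
over coverage ≥ 0.95 (both inclusive).

The binding-site scanner is deliberately not a thermodynamic model. It
slides the miRNA antiparallel along the (transcribed) circRNA sequence and
reports a site when (a) ≥ `min_seed_pairs` (default 6) of the seed
positions (miRNA bases 1–8) pair — Watson–Crick or G:U wobble — and
(b) the ungapped duplex over min(miRNA length, 20) target bases scores
≤ −10 under integer scores WC −2, wobble −1, mismatch +1 (a gap penalty
of +3 is defined but the default scan is ungapped). The downstream
quantities of interest — site presence, clustering, per-base ratio, seed
pairing counts — depend on where sites are, not on free energies, which is
what this model preserves. Overlapping sites are removed greedily,
strongest (most negative) score first, ties to the leftmost then shortest
site; the greedy rule is this package's documented choice where the
literature procedure is underspecified. `duplex_profile` aligns the miRNA
end-to-end without gaps and counts Watson–Crick ("canonical") pairs in the
seed separately from wobbles, which pair but are not canonical.
`orientation="reverse"` scans the reverse complement and mirrors
coordinates back, which keeps minus-strand workflows consistent.

## Differential expression

SRPBM = count / per-sample mapped-read total × 10⁹. The definition of the
denominator (uniquely vs. all aligned reads) is left to the caller, since
it is a property of the upstream alignment, not of the normalization.
Group differences are tested per circRNA with the Kruskal–Wallis rank test
(tie-corrected H, χ² approximation with k−1 df; an exact permutation
p-value is available for tiny n). A circRNA constant across all samples
returns H = 0, p = 1 rather than an error. P-values are BH-adjusted;
significance is adjusted p < α (default 0.05). At n = 4 per group the rank
test is conservative — raw p-values cannot go below ~1/35 per pairwise
arrangement — so null calibration is asserted as "at or below nominal",
not "equal to nominal". Batch adjustment, off by default, is a simple
per-batch median-centering of log1p SRPBM: it removes additive batch
shifts only and makes no claim to match PCA-based batch-correction
methods.

## Enrichment

One-sided (over-representation) Fisher's exact test per term, equal to the
hypergeometric upper tail; the test suite verifies the identity against a
closed-form binomial-coefficient sum on random tables. Term sets are
intersected with the expressed-gene background *before* the size filter
(5 ≤ size ≤ 400), so "term size" always means background-expressed term
genes; applying the filter before intersection would let unexpressed genes
keep oversized terms in play. BH correction runs across the tested terms
only.

## Synthetic data: what it emulates

All generators are pure functions of (seed, parameters); fixtures are
byte-reproducible. Defaults encode the study conditions the pipeline
targets:

- **Design** — 12 samples in 3 treatment groups of 4 (repeated-vaccination
  cortex design), or 2 groups × 2 timepoints × 3 animals (PBMC design).
- **Counts** — negative binomial with mean 4 and NB2 dispersion 0.5
  (variance = μ + 0.5 μ²): circRNA backsplice counts are low and
  overdispersed relative to mRNA. Library sizes ~30–40 M mapped reads.
- **Caller noise** — each caller reports every true circRNA (minus
  dropout, default 5% per caller) plus caller-private false junctions
  (default 50% of the true count), mimicking the large non-concordant
  fractions real caller pairs produce.
- **Conservation** — the chain generator buries one flank of each planted
  `not_aligned` circRNA inside a source gap and keeps all other planted
  flanks inside blocks; the database generator lifts each remaining
  circRNA with the package's own (independently oracle-tested) lifter and
  plants records at offsets cycling through −2…+2 for matching sites and
  at exactly ±3 for non-matching ones, so both sides of the tolerance
  boundary are exercised. Planted circRNA flanks are kept ≥300 bp apart so
  records cannot cross-match neighbouring circRNAs. The generator verifies
  the planted category of every circRNA and refuses impossible requests.
- **Sponge fixtures** — planted sites are exact reverse complements of the
  full miRNA; the background is rejection-sampled so that *no* 8-base
  window passes the scanner's seed criterion, which guarantees exactly
  zero off-site hits (every reported site must pass that criterion), and a
  repair loop resamples windows straddling embed boundaries.

What passing these fixtures does **not** show: robustness to small
coordinate disagreements between real callers (real pipelines sometimes
need tolerance windows), to chain files with overlapping same-score chains
(resolved here by a deterministic tie-break), to thermodynamically weak
but biologically real miRNA sites, or to count distributions with
sample-specific dispersion. The fixtures establish correctness of the
implemented rules, not generalization to every real dataset.

## Problem sizes in the test suite

The default suite runs consensus recovery on a 200-circRNA noiseless
fixture, lift-oracle agreement on 1000+ random chains, conservation
recovery on a 100-circRNA fixture covering all six categories, sponge
recall on 2–3 kb sequences with up to 8 planted sites, Kruskal–Wallis
type-I calibration on a 1000-circRNA null matrix, and 50 seeded null
replicates of the full SRPBM → KW → BH pipeline (1000 circRNAs each),
asserting zero significant calls in ≥96% of replicates. These sizes keep
the whole suite around five minutes on one CPU while leaving the
statistical assertions well-powered.
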