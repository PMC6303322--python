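# Methods

## Read deconvolution

A screen read is assigned in two steps. The sample barcode (8 nt, from a
parallel index read or a fixed in-read offset) is resolved first: exact
match by default, optionally tolerating one mismatch when the match is
unique — an ambiguous rescue is rejected, and rejected reads increment a
single global `n_unassigned_barcode` tally because no per-condition
attribution is defensible. The sgRNA insert is then the 20 nt following the
**first** occurrence of the `CACCG` anchor in the read; inserts are matched
by exact string equality against the library reference. Exact matching is
deliberate: the protospacer is synthesized, not biological, so mismatches
indicate sequencing error, and exact lookup keeps counting unambiguous and
fast. Reads lacking the anchor (`n_no_anchor`) and anchored reads whose
insert is truncated or unknown (`n_unmapped_insert`) are tallied per
condition. The identity

    n_assigned + n_no_anchor + n_unmapped_insert + n_unassigned_barcode
      = reads processed

holds for every run and is asserted in tests. Anything fancier
(mismatch-tolerant insert assignment, UMIs, dual indices) is out of scope.

## Normalization

Counts are scaled to reads-per-million within each condition and
log2-transformed after adding one: `log2(c/T · 10⁶ + 1)`. The pseudocount is
added to the RPM value, not the raw count, so a zero count maps exactly to
0 regardless of depth, and scaling all counts in a condition by a constant
leaves the transform unchanged. A condition with zero total reads fails
loudly rather than propagating NaNs. Log-fold-changes are differences of
these values — against the plasmid pool for dropout screens and against the
untreated arm for drug screens — and replicates are combined by averaging
LFCs (not counts), so each replicate contributes equally regardless of
sequencing depth.

## Gene scoring

### The rank-order hypergeometric statistic

All N scored sgRNAs are ranked by LFC (ascending for depletion, descending
for enrichment; ties broken lexicographically by sgRNA id so results are
reproducible). For a gene with s guides at sorted ranks r₁ < … < r_s, each
rank yields the tail probability P[X ≥ k] with
X ~ Hypergeometric(N, s, r_k) — exactly the one-sided Fisher's exact test on
the 2×2 table {top-r_k vs rest} × {gene vs rest}. The gene's canonical
`pvalue` is the minimum tail over k = 1..s, **uncorrected** for taking the
minimum. This is the variant that uses every guide of a gene while staying
a pure rank statistic; it is documented here as this package's canonical
definition rather than an inferred reconstruction of any particular
published pipeline.

### Calibration

The uncorrected minimum is *not* uniform under a random ranking: it is
super-uniform only in the Bonferroni sense P[p ≤ α] ≤ s·α, and measurably
sub-uniform in distribution (KS distance ≈ 0.3 at 1,000 genes × 4 guides).
Where a calibrated quantity is needed — null-uniformity checks, direct
threshold interpretation — the package computes `calibrated_pvalue`: the
exact probability, under a uniformly random placement of s ranks among N,
that the min-tail statistic falls at or below the observed value. Because
each event {tailₖ ≤ t} is {r_k ≤ q_k(t)} for a computable threshold, this is
an order-statistic boundary-crossing probability evaluated by a cumulative-
sum dynamic program over ranks — exact, deterministic, no resampling; cost
O(N·s) per evaluated value, which is negligible at screen scale for the
set sizes that occur (s ≤ ~15). The calibrated p-value is uniform under the
null by construction (measured KS p ≈ 0.4–0.9 across seeds) and always ≥
the raw minimum. Hit counts quoted at a p-value threshold use the canonical
uncorrected p; calibration checks use the calibrated one.

### Dummy genes and empirical FDR

Non-targeting controls are grouped, uniformly at random given a seed, into
dummy genes of the library's per-gene set size (floor(n_controls/s) genes;
leftovers unused). Scored alongside targeting genes, they provide an
in-library null. The empirical FDR walks genes from the most extreme
average LFC (deterministic tie-break by gene name): raw(i) = #negatives
among the top i divided by i, monotonized from the bottom
(FDR(i) = min_{j≥i} raw(j)) so the estimate never decreases as the ranking
worsens. Negatives are the declared negative-control genes plus all dummy
genes. The default reports the *unscaled* fraction of negatives — in the
secondary-pool geometry negatives vastly outnumber candidates, so density
rescaling changes little; the rescaled variant
((#neg ≤ rank)/N_neg · N_total/i) is available behind a flag. The default
hit call is FDR < 5%, and dummy genes are excluded from hit counts. Genes
are scored in one direction per run; two-sided questions get two runs
rather than a two-sided p-value.

## Benchmarking metrics

The depletion AUC sorts every scored sgRNA ascending by LFC (ties by id)
and integrates the curve through (i/N, cᵢ/|S|) by trapezoid. The x-axis is
the fraction of **all** scored sgRNAs, non-targeting controls included, not
just the union of the gene sets — this is what makes the metric comparable
across libraries of different sizes, since no pre-filtering of guides
occurs. dAUC = AUC(essential) − AUC(non-essential); ddAUC is the change in
dAUC after keeping the library-wide (not per-gene) top fraction, default
10%, of sgRNAs under a scoring scheme. The gene-level ROC-AUC scores each
gene by −mean(LFC) and equals the normalized Mann–Whitney U with ties
counted ½ (computed via scikit-learn; tests verify it against all-pairs
concordance counting). A PR-AUC companion is provided as an auxiliary
output. Subsampling draws min(n, available) guides per gene without
replacement per iteration (default 100 iterations; the s.d. over iterations
is reported, 0 for a single iteration, and an exhaustive draw reproduces
the full-library ROC-AUC exactly). STOP gene sets are built from three
per-cell-line ORF proliferation tables: a gene qualifies when present
(non-missing) in all three and showing a negative log2 effect with
p strictly below 10⁻⁴ in both non-held-out lines.

## Library design

TSS resolution prefers CAGE peak annotations (the representative p1
promoter position), then Ensembl's principal transcript, then NCBI; the
source is recorded per gene and genes found nowhere are reported as
undesignable rather than dropped. The p1 read fraction — reads at the
top-ranked promoter over all promoter reads of the gene — is exposed as a
TSS-confidence proxy.

Candidate enumeration scans both strands for NGG PAMs within −300..+300 nt
of the TSS (inclusive). The offset convention is explicit because no single
convention is universal: the signed distance from the TSS to the
**PAM-proximal protospacer base**, positive in the direction of
transcription, measured on the gene's strand. Interfaces use 1-based
inclusive genomic coordinates; internal string arithmetic is 0-based.

Picking runs ordered rounds, each a predicate (window, max perfect-match
sites, min on-target score) that must be no stricter than its predecessor
in every criterion — validated at construction. The shipped defaults are:
round 1 = preferred window (+25..+75 CRISPRi, −150..−75 CRISPRa) with ≤ 1
perfect-match site and score ≥ 0.5; round 2 relaxes the window to
−300..+300; round 3 relaxes off-targets to ≤ 5; round 4 drops the score
floor. These defaults reconstruct the *shape* of the published heuristic;
the exact published per-round thresholds live in supplementary material not
reproduced here, so the policy is a config object and the defaults make no
claim to reproduce any published library guide-for-guide. Within a round,
candidates rank by on-target score descending with ties broken by sequence.
Ranks 1–3 form Set A, 4–6 Set B. Genes that exhaust all rounds below quota
emit what they have with a shortfall flag — shortfalls are data, not
errors. `assign_rounds` labels any annotated external library with the
earliest satisfied round (or `none`/`unassignable`), giving per-round
fractions that partition to 1.

Off-target annotation counts **perfect-match** protospacer+NGG genome
occurrences only (both strands); mismatch-tolerant search is out of scope,
matching how the input annotations are defined. Non-targeting controls are
random 20-mers accepted only at zero perfect-match sites, drawn
deterministically from a seed with an attempt budget.

Synthesis oligos are
`[forward primer] CGTCTCACACCG [protospacer] GTTTCGAGACG [revcomp(reverse primer)]`
— BsmBI sites flanking the CACC/GTTT Golden Gate overhangs, 83 nt with the
six shipped 20-nt subpool primer pairs. The reverse primer is appended as
the reverse complement of its printed 5′→3′ sequence, the standard
synthesis convention. Extracting the 20 nt after the first `CACCG` of an
oligo recovers the protospacer, the same rule the deconvoluter applies to
reads.

## The simulator

`simulate_screen` generates: log-normal plasmid abundances (σ = 0.5 in
natural log, a typical cloning skew); per-guide efficacy ~ Beta(5, 1)
(median ≈ 0.87, a well-designed library); deterministic guide effect =
gene effect × efficacy, so an inactive guide shows no phenotype; a cutting
penalty (default −0.5 log2 units) added to every targeting guide in
knockout mode only, which reproduces the non-targeting-vs-non-essential AUC
gap of real knockout screens; per-replicate Gaussian LFC noise (σ = 0.25);
and counts drawn multinomially at depth (default 500 reads per guide) from
proportions ∝ plasmid × 2^LFC. Overdispersion is Dirichlet-multinomial with
a single scalar: `dispersion` is the squared coefficient of variation of
the extra-multinomial abundance noise for an equi-abundant guide
(concentration n/dispersion; default 0.01 ⇒ ~10% abundance CV; multinomial
limit at 0). Positive-selection screens plant resistance genes whose
enrichment acts in the treatment arm on top of the dropout effects. The
default study conditions (1,000 genes × 4 guides, 992 controls, 20%
essential at effect −3, two or three replicates) were chosen once to mirror
a compact genome-wide screen and are exercised as-is by the tests and the
acceptance script.

What the simulator does **not** model: sequencing error and quality scores,
PCR amplification bias, copy-number-scaled cutting toxicity, guide-level
off-target phenotypes, and cell-to-cell infection bottlenecks. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis* under the stated generative model, not robustness to every
artifact of real screens.

`simulate_fastq` renders counts into reads with a 0–7 nt stagger drawn from
{A, C, T} — excluding G so no anchor can form upstream of the vector
prefix, whose first `CACCG` occurrence is required to terminate it; this
makes the FASTQ → count round trip exact by construction, which the tests
and acceptance script verify on a 10,000-guide matrix. `make_design_fixture`
plants TGG PAMs into A/T-only loci (which cannot otherwise host a PAM on
either strand), so the enumerated candidate set equals the planted set and
the expected pick table — derived from the planted metadata alone, sorted
by (round, score descending, sequence) — is the unique correct picker
output.

## Problem sizes

The test suite and acceptance script run simulations at 200–2,375 genes,
10,000 guides for round trips, 20 seeds for FDR calibration and 1,000 genes
for null uniformity — sizes chosen so the full suite completes in about a
minute on one core while keeping every statistical check at meaningful
power. Published-screen reproductions load the externally distributed count
tables from `data/external/` when present.

## Known limitations

- The canonical p-value's aggregation (uncorrected min over per-rank
  tails) is one of several defensible readings of a rank-order
  hypergeometric test; hit counts at fixed thresholds shift by a small
  factor under other aggregations. The calibrated variant removes that
  ambiguity at the cost of departing from the simplest definition.
- Empirical FDR accuracy depends on the negative set's representativeness;
  the unscaled default mildly overestimates FDR when candidates are
  enriched for true positives.
- The picking defaults cannot reproduce published libraries
  sgRNA-for-sgRNA (exact published thresholds unavailable); `assign_rounds`
  self-consistency and planted fixtures are the verifiable claims.
- Insert matching is exact-only; heavily error-prone sequencing will
  inflate `n_unmapped_insert` rather than rescue reads.
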