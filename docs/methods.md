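# Methods

This note records the models, conventions, and design choices behind the two
analysis arms, what the synthetic generators do and do not emulate, and the
numerical details a user re-deriving results will need.

## Label-free enrichment arm

### Model and assumptions

Protein-level MS1 intensity is treated as log-normally distributed across
proteins, with multiplicative replicate noise. After log2 transformation and
per-sample mean-centering (which aligns sample locations without touching
variances), two-condition comparisons assume approximately equal variances
across samples — the assumption behind the pooled-variance (Student) t-test
used by default. Per-sample mean/variance diagnostics with all-pairs t- and
F-tests (`sample_diagnostics`) let a user check this before trusting the
pooled test; Welch's test is available via `VolcanoConfig(welch=True)`.

Missingness is treated as missing-not-at-random: a protein is absent from a
sample because its abundance sits near the detection limit, so missing cells
are imputed from a per-sample normal down-shifted by 1.8 observed standard
deviations. The `width` parameter scales the imputation spread in units of
the observed standard deviation; the default is 3, following the convention
this pipeline descends from, even though the common Perseus parameterization
uses 0.3 — the config makes the value explicit rather than silently
"correcting" either way. Calibration tests pass `width=0.3` explicitly so
the Monte-Carlo target (sd = 0.3·sigma) is unambiguous.

Observed cells are never modified by imputation, and the pre-imputation
observation mask travels with the matrix: significance flags are only
granted to proteins observed in **every** replicate of the specific-IP
condition, so an enrichment call can never rest purely on imputed values.

### Permutation FDR and s0

The moderated statistic d = diff/(se_pooled + s0) is calibrated by
relabeling the pooled samples into groups of the original sizes. For 3 vs 3
only 20 ordered assignments exist; the observed assignment and its
group-swap mirror produce |d| identical to the observed statistics and are
excluded, leaving 18. Including them would floor the FDR estimate at 2/20 at
every cutoff and no protein could ever be called at 0.05 with triplicates —
the exclusion is what makes the stated procedure usable at this design size.
When the requested permutation count is below the number of distinct
relabelings, a seeded subset is drawn; above it, enumeration is exhaustive.

FDR_est(c) is evaluated at every observed |d| as a candidate cutoff and the
smallest qualifying c is used; proteins tied with the cutoff are significant
(≥ comparison). No π0 correction is applied, making the estimate mildly
conservative when many true positives inflate the permutation null.

`s0="auto"` scans {0, 0.1, …, 2.0} and picks the value minimizing the
number of significant proteins on the mock (negative) side. That objective
alone is degenerate — an s0 whose cutoff calls *nothing* trivially has zero
mock-side hits — so ties are broken by retaining the most specific-side
hits, then by the smaller s0. Even so, on data where some intermediate s0
admits a single mock-side call while s0 = 0 calls a handful of proteins
cleanly, the rule can prefer the very conservative curve; analyses that care
about power at a known operating point should fix s0 explicitly (0.2–0.5 is
typical), which is what the power-oriented tests here do.

Sub-streams for imputation draws and permutation subsets are spawned
independently from the stage seeds, so each stage is reproducible in
isolation.

### Diagnostics

Pairwise Pearson correlations use pairwise-complete observations (pairs with
fewer than 3 co-observed proteins are undefined); correlations on the
imputed matrix can be computed by passing it instead. PCA uses proteins
observed in every sample as centered features. Complete-linkage clustering
runs on 1 − r distances, with undefined pairs assigned the maximum distance
2 so the dendrogram stays defined.

## NET-seq occupancy arm

### Conventions

All coordinates are 0-based half-open internally; BED input is native and
1-based prose conventions exist only at parse boundaries. A gene is a
(TSS, polyA) pair of inclusive single-base anchors; transcript offset k
means k bases downstream of the anchor in the direction of transcription.
Score windows are half-open in transcript coordinates: 5′ window
[TSS, TSS+250), 3′ window [polyA−250, polyA), pausing numerator
[polyA−50, polyA+100) vs denominator [polyA−200, polyA−50) (150 nt each).
An alternative pausing preset ([polyA, +100) vs [−50, polyA)) is provided as
`FIG5C_LEGEND_PRESET` for the variant window definition that appears in
figure legends of the literature this implements; the Methods-style windows
are the default.

### Mispriming filter

A reverse-transcription mispriming event is a read whose random-hexamer
barcode annealed to the RNA body instead of the ligated linker; its
signature is a barcode exactly matching the 6 genomic bases that would
extend the nascent RNA past its recorded 3′ end. The comparison is made in
read orientation — for a + alignment the forward bases at [start−6, start),
for a − alignment the reverse complement of [end, end+6) — because that is
the orientation in which a misprimed hexamer appears in the sequenced read.
The side checked is configurable (`downstream` | `upstream` | `either` in
transcript orientation) since "adjacent" is ambiguous in principle; reads
whose comparison window runs off the chromosome are retained, and barcodes
containing N never match. The false-removal background for random barcodes
is 4⁻⁶ per read, verified by simulation.

### Occupancy, selection, scores

Each uniquely mapped, filtered read contributes +1 at its 5′-aligned end
(start for +, end−1 for −) on the transcription strand opposite the
alignment strand. Spliced alignments contribute the first aligned block, so
intron gaps do not shift the recorded position. Duplicate reads are kept —
no UMI collapse beyond mispriming removal is modeled. CPM normalization
multiplies by 1e6 / uniquely-mapped-total.

Gene selection computes RPKM from raw counts against the uniquely mapped
library total (RPKM > 10, length ≥ 500 bp, strictly), and excludes genes
whose body — extended by the overlap-exclusion distance (0 by default, 350
for the stricter variant) — intersects any other gene's body on either
strand. The all-pairs overlap check is quadratic but annotation sizes here
(thousands) keep it cheap.

Per-gene normalization divides each gene's anchored rows by its mean density
over the combined 1,650-bp analyzed region (1,100 around the TSS, 550 around
the polyA site), making profiles comparable across expression levels. The
window split around each anchor is not uniquely determined by the combined
widths; the defaults TSS [−100, +1000) and polyA [−450, +100) were chosen to
match the visible ranges of published profile figures and are fully
configurable.

Metagene profiles smooth each gene's row with a centered 25-bp moving
average (truncated at edges — no padding, so no signal is fabricated outside
the window), then average across genes; the CI is the normal approximation
mean ± 1.96·sd/√n, appropriate at n in the thousands (and exercised at
n = 2,000 in the coverage tests). Smoothing before averaging and averaging
before smoothing commute for the mean but not the CI; per-gene smoothing is
implemented because the band should reflect the across-gene variability of
the *smoothed* signal being plotted.

Genes with a zero numerator or denominator window have undefined scores and
are excluded from score distributions (no pseudocount by default; a
`pseudocount` option exists). "Fraction increased" uses strict inequality on
the per-gene difference.

## Synthetic generators

The occupancy generator lays non-overlapping genes with a minimum intergenic
gap on an i.i.d. random genome, assigns a per-base expected rate (uniform
body, rectangular TSS-proximal peak and polyA-proximal pause bumps
multiplying the local base rate by 1+amplitude, optional readthrough beyond
the polyA site), and draws Poisson counts. Rectangular bumps are the default
because their expected window sums are exactly integrable, so the truth
record can carry closed-form expected scores; with the default pause
(amplitude 3, width 150, centered to cover the pausing numerator window) the
expected pausing score is exactly log2(4) = 2. The read simulator inverts
occupancy extraction one read per count and plants misprimed barcodes at a
controlled rate using the same window rule the filter checks.

The MS generator draws per-protein baselines from Normal(20, 2) in log2
units, adds condition-specific enrichments for disjoint protein subsets,
replicate noise of sd 0.65, and MNAR dropout via a decreasing logistic in
true abundance (midpoint 17, slope 1.5 per log2 unit — about 25% missing
cells overall, concentrated in the low-abundance tail). These defaults were
chosen as representative of triplicate AP-MS interactome data: they imply a
within-condition replicate correlation near 4/(4+0.65²) ≈ 0.9 from the
variance ratio alone, and with ~8% of proteins specific per IP condition at
~8-fold, cross-condition correlations fall in the mid-0.7s — the regime the
diagnostics are designed to flag as "reproducible but distinct". Optional
peptide-level splitting distributes each protein intensity over 1–5 peptides
with symmetric-Dirichlet(1) proportions.

What the generators do **not** emulate: realistic sequence composition or
mappability, nucleosome-driven occupancy structure, protein complex
covariance in IPs, peptide-level detectability differences, and
heteroscedastic per-protein noise. Passing tests therefore demonstrate the
correctness and calibration of the statistics under their stated model, not
robustness to every pathology of real libraries.

## Problem sizes

Tests and the acceptance script run at deliberately modest scales chosen to
keep Monte-Carlo error well inside the asserted tolerances: 1,000-protein
matrices with 8–20 replicate simulations for volcano operating
characteristics, 10,000 imputed cells for imputation calibration, ~50,000
reads for the mispriming background, 25-gene annotations for score recovery,
and 2,000-row matrices for CI coverage. At these sizes the whole suite
completes in seconds.

## Known limitations

* With triplicates the permutation null has only 18 usable relabelings, so
  achievable FDR estimates are coarse (granularity 1/18 per observed-count
  unit); reported FDR control is validated empirically in the tests.
* The s0 auto-selection heuristic can prefer very conservative curves (see
  above); fix s0 for power-critical analyses.
* Mean-centering couples samples through their observed protein sets: under
  heavy MNAR dropout the centered fold changes of well-observed proteins
  acquire a small bias (a few percent of the effect size in the planted-fold
  recovery runs).
* SAM/BAM input expects the molecular barcode in a tag (``BC`` by default)
  or as the last ``:``-separated field of the read name; pipelines storing
  it elsewhere need a converter or the simplified TSV.
* `profile_ratio` divides mean profiles without propagating the CI band.
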