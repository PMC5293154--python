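# subpolii

Statistics for **region-specific RNA polymerase II elongation complexes** in
budding yeast: which proteins travel with Pol II near the 5′ end of a gene
versus near the polyA site, and how Pol II occupancy redistributes along genes
when those factors are deleted.

The package implements the two computational arms such a study needs:

1. **Label-free AP-MS enrichment** (`subpolii.ms_quant`) — from peptide-level
   MS1 intensity tables of sequential-IP experiments (specific IPs vs a mock
   control, in biological triplicate) to a volcano analysis of specifically
   enriched interactors.
2. **NET-seq occupancy statistics** (`subpolii.netseq_core`,
   `subpolii.metagene_scores`) — from aligned NET-seq reads carrying 6-nt
   molecular barcodes to strand-aware single-nucleotide Pol II occupancy,
   anchored metagene profiles, and per-gene pausing scores.

A truth-known synthetic-data generator (`subpolii.synthetic_data`) emulates
both data types so every stage is testable without any download, and
`subpolii.io_cli` supplies text-format I/O (FASTA, BED, bedGraph, TSV), a
pipeline driver, and the `subpolii` command-line interface.

## The statistics

**Enrichment arm.** Peptide MS1 intensities are summed per protein, log2
transformed, and mean-centered per sample. Proteins observed in every
replicate of at least one condition are kept; remaining missing values —
which are missing *not* at random, because low-abundance proteins drop below
the detection limit — are imputed from a down-shifted normal per sample,

    x_miss ~ Normal(mu_s − 1.8·sigma_s, (w·sigma_s)²),

with `mu_s`, `sigma_s` the observed mean and standard deviation of sample
*s* (down-shift 1.8, width `w = 3` by default). Condition A vs B enrichment
uses the moderated statistic

    d = (mean_A − mean_B) / (se_pooled + s0),

where `s0 ≥ 0` bends the volcano significance curve away from small, noisy
fold changes. Significance cutoffs on |d| come from a permutation null
(relabeling samples across the two groups; exhaustive for 3 vs 3), with

    FDR_est(c) = mean_perm #{|d_perm| ≥ c} / #{|d_obs| ≥ c},

and a protein is significant at level f iff |d| ≥ the smallest c with
FDR_est(c) ≤ f (defaults f = 0.05 strict, 0.10 lenient). With `s0="auto"`
a grid of s0 values is scanned and the one minimizing the number of
mock-side hits (ties: retaining the most specific-side hits) is chosen.

**Occupancy arm.** In an fr-firststrand NET-seq library the read aligns
antisense to the transcript, so the read's 5′-aligned end marks the nascent
RNA 3′ end — the exact position of the transcribing polymerase — on the
opposite strand. Reads whose 6-nt barcode exactly matches the genomic
sequence adjacent to the alignment are reverse-transcription mispriming
artifacts and are removed (random-barcode background: 4⁻⁶ ≈ 2.4×10⁻⁴).
Tracks are normalized to counts per million; profile genes are
non-overlapping, ≥ 500 bp, RPKM > 10. Each gene is then normalized by its
own mean density over the 1,650 bp analyzed around its TSS (1,100 bp) and
polyA site (550 bp), and metagene profiles are averaged across genes with a
25-bp sliding window and a 95% CI. Per-gene summary scores:

* **5′:3′ ratio** = log2( Σ occupancy [TSS, TSS+250) / Σ [polyA−250, polyA) )
* **polyA pausing score** = log2( Σ [polyA−50, polyA+100) / Σ [polyA−200, polyA−50) )

Genotype comparisons report box-plot summaries, a two-sided t-test across
gene score distributions, and the fraction of genes with increased pausing.

## Worked example

Simulate a NET-seq experiment (30 genes with a 3-fold polyA-proximal pause
bump), filter mispriming, build occupancy, and score pausing:

```sh
$ subpolii simulate --what reads --out sim --seed 3
simulated 30 genes, 66136 reads -> sim
$ subpolii occupancy --reads sim/reads.tsv --genome sim/genome.fa --out occ
66136 reads in, 17 misprimed removed
$ subpolii scores --kind pausing --wt occ --mut occ \
    --genes sim/genes.bed --genome sim/genome.fa --out cmp.json
n=30 p=1 fraction_increased=0.000
```

The 17 removed reads match the 4⁻⁶ random-barcode background for a 66k-read
library (expected ≈ 16). `cmp.json` reports a wild-type median pausing score
of 1.99 — the generative pause amplitude of 3 predicts log2(1+3) = 2 — and,
since the "mutant" here is the same library, p = 1 with no genes increased.

The MS arm, end to end on simulated triplicate IPs:

```sh
$ subpolii simulate --what ms --out sim_ms --seed 4
wrote 8178 records for 1000 proteins to sim_ms
$ subpolii msquant --intensities sim_ms/intensities.tsv --samples sim_ms/samples.tsv \
    --a five_prime --b mock --s0 0.2 --seed 4 --out out_ms
s0=0.20; 69 proteins significant at FDR 0.05
```

`out_ms/enrichment.tsv` holds per-protein log2 fold change, t, p, the
moderated d, and significance flags at both FDR levels.

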