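"""Truth-known synthetic inputs with the statistical structure the analyses assume.

Two generators:

* **Occupancy side** — a random genome plus non-overlapping gene annotation;
  per-base Poisson occupancy with a rectangular 5' (TSS-proximal) peak, a
  polyA-proximal pause bump, and optional readthrough past the polyA site;
  and simulated aligned reads with 6-nt molecular barcodes, a controlled
  fraction of which are reverse-transcription mispriming events (barcode
  copied from the genomic window the mispriming filter checks).

* **MS side** — MS1 intensity tables over conditions x replicates with
  condition-specific log2 enrichments, log-normal baseline abundances,
  replicate noise, and abundance-dependent (missing-not-at-random)
  missingness following a logistic in the true log2 abundance.

Every generator is a pure function of its config + seed, and each returns a
truth record so downstream estimates can be checked against the generative
parameters (expected window sums, true pausing fold, enrichment labels).

Rectangular bumps are the default because their expected window sums are
exactly integrable; bump windows are half-open intervals
[center - width//2, center - width//2 + width) in transcript coordinates
relative to their anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metagene_scores import GeneModel, ScoreConfig
from .netseq_core import AlignedReadRecord, OccupancyTrack, _adjacent_window, revcomp

__all__ = [
    "OccupancySimConfig",
    "MsSimConfig",
    "simulate_annotation",
    "simulate_occupancy",
    "simulate_reads",
    "simulate_ms_dataset",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupancySimConfig:
    """Generative parameters for synthetic Pol II occupancy.

    Rates are mean reads per nucleotide; bump amplitudes are fold increases
    over the local base rate (amplitude a puts the rate at base*(1+a) inside
    the bump window).  ``readthrough_fraction`` scales the body rate over
    ``readthrough_length`` nt beyond the polyA site.
    """

    n_genes: int = 30
    chrom_length: int = 100_000
    chrom: str = "chrSim"
    gene_length_range: tuple[int, int] = (800, 2000)
    min_intergenic_gap: int = 400
    body_rate: float = 1.0
    tss_peak: tuple[float, int, int] = (2.0, 150, 0)  # (amplitude fold, width, center offset)
    polya_pause: tuple[float, int, int] = (3.0, 150, 25)  # center +25 covers [-50, +100)
    readthrough_fraction: float = 1.0
    readthrough_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_rate < 0 or self.readthrough_fraction < 0:
            raise ValueError("rates must be >= 0")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene length range")


@dataclass(frozen=True)
class MsSimConfig:
    """Generative parameters for synthetic sequential-IP MS1 intensity data.

    Emulates the study design: three conditions in biological triplicate
    (two specific IPs plus a mock), a log-normal protein abundance baseline,
    condition-specific log2 enrichments for disjoint subsets of proteins, and
    MNAR missingness — the probability a cell is missing follows a decreasing
    logistic in its true log2 abundance, so low-abundance proteins drop out
    preferentially.
    """

    n_proteins: int = 1000
    conditions: tuple[str, ...] = ("five_prime", "three_prime", "mock")
    n_replicates: int = 3
    n_enriched: dict = field(
        default_factory=lambda: {"five_prime": 80, "three_prime": 80, "mock": 0}
    )
    effect_size: float = 3.0  # log2 enrichment of condition-specific proteins
    noise_sd: float = 0.65  # replicate noise, log2 units
    baseline_mean: float = 20.0  # log2 abundance location
    baseline_sd: float = 2.0  # log2 abundance spread
    missing_midpoint: float = 17.0  # log2 abundance of 50% dropout
    missing_slope: float = 1.5  # logistic steepness (per log2 unit)
    peptides_per_protein: tuple[int, int] = (1, 1)  # (min, max); >1 splits intensities
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.n_enriched.values()) > self.n_proteins:
            raise ValueError("n_enriched exceeds n_proteins")
        if self.noise_sd < 0 or self.baseline_sd <= 0:
            raise ValueError("invalid noise parameters")


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------


def simulate_annotation(cfg: OccupancySimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome and non-overlapping gene placement.

    Genes are laid left to right with intergenic gaps of at least
    ``min_intergenic_gap`` and random strands; the layout leaves
    ``min_intergenic_gap`` of margin at the chromosome ends so anchored
    windows near gene edges stay on-chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    genome = {
        cfg.chrom: "".join(rng.choice(list("ACGT"), size=cfg.chrom_length))
    }
    worst = cfg.n_genes * (cfg.gene_length_range[1] + cfg.min_intergenic_gap) + cfg.min_intergenic_gap
    if worst > cfg.chrom_length:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes into {cfg.chrom_length} nt; "
            f"need at least {worst}"
        )
    genes = []
    cursor = cfg.min_intergenic_gap
    for i in range(cfg.n_genes):
        length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        start = cursor
        end = start + length  # half-open body
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            g = GeneModel(f"g{i:04d}", cfg.chrom, "+", tss=start, polya=end - 1)
        else:
            g = GeneModel(f"g{i:04d}", cfg.chrom, "-", tss=end - 1, polya=start)
        genes.append(g)
        cursor = end + cfg.min_intergenic_gap
    return genome, genes


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def _bump_window(anchor_offset: int, width: int, center: int) -> tuple[int, int]:
    lo = center - width // 2
    return lo, lo + width


def _expected_rate_profile(gene: GeneModel, cfg: OccupancySimConfig) -> np.ndarray:
    """Expected reads/nt in transcript coordinates over body + readthrough."""
    L = gene.length
    rate = np.full(L + cfg.readthrough_length, 0.0)
    rate[:L] = cfg.body_rate
    rate[L:] = cfg.body_rate * cfg.readthrough_fraction
    for (amp, width, center), anchor in ((cfg.tss_peak, 0), (cfg.polya_pause, L - 1)):
        if amp <= 0 or width <= 0:
            continue
        lo, hi = _bump_window(anchor, width, center)
        lo, hi = max(0, anchor + lo), min(len(rate), anchor + hi)
        rate[lo:hi] *= 1.0 + amp
    return rate


def simulate_occupancy(
    genes: list[GeneModel], cfg: OccupancySimConfig
) -> tuple[OccupancyTrack, dict]:
    """Poisson occupancy over an annotation, plus a per-gene truth record.

    The truth record stores, per gene, the exact expected sums over every
    ScoreConfig window and the generative pausing/5':3' folds implied by the
    rate profile, so estimators can be validated without re-deriving them.
    """
    chrom_lengths: dict[str, int] = {}
    for g in genes:
        chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), max(g.tss, g.polya) + cfg.readthrough_length + 1)
    chrom_lengths = {c: max(n, cfg.chrom_length) for c, n in chrom_lengths.items()}
    if not genes:
        chrom_lengths = {cfg.chrom: cfg.chrom_length}
    track = OccupancyTrack.zeros(chrom_lengths)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    score_cfg = ScoreConfig()
    truth: dict = {"genes": {}, "total_expected_reads": 0.0}
    for g in genes:
        rate = _expected_rate_profile(g, cfg)
        counts = rng.poisson(rate)
        vec = track.get(g.chrom, g.strand)
        if g.strand == "+":
            vec[g.tss : g.tss + len(rate)] += counts
        else:
            vec[g.tss - len(rate) + 1 : g.tss + 1] += counts[::-1]
        L = g.length

        def wsum(anchor_pos: int, window: tuple[int, int]) -> float:
            lo, hi = anchor_pos + window[0], anchor_pos + window[1]
            lo, hi = max(0, lo), min(len(rate), hi)
            return float(rate[lo:hi].sum()) if hi > lo else 0.0

        exp_num = wsum(L - 1, score_cfg.pausing_numerator)
        exp_den = wsum(L - 1, score_cfg.pausing_denominator)
        exp_5 = wsum(0, score_cfg.five_prime_window)
        exp_3 = wsum(L - 1, score_cfg.three_prime_window)
        truth["genes"][g.gene_id] = {
            "expected_reads": float(rate.sum()),
            "expected_pausing_numerator": exp_num,
            "expected_pausing_denominator": exp_den,
            "expected_pausing_score": float(np.log2(exp_num / exp_den))
            if exp_num > 0 and exp_den > 0 else None,
            "expected_five_prime_sum": exp_5,
            "expected_three_prime_sum": exp_3,
            "expected_five_three_score": float(np.log2(exp_5 / exp_3))
            if exp_5 > 0 and exp_3 > 0 else None,
        }
        truth["total_expected_reads"] += float(rate.sum())
    track.total_reads = int(track.total_signal())
    return track, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_reads(
    track: OccupancyTrack,
    genome: dict[str, str],
    mispriming_rate: float = 0.0,
    read_length: int = 50,
    seed: int = 0,
) -> list[AlignedReadRecord]:
    """One read per occupancy unit, inverting the occupancy extraction.

    Each count at base ``p`` on transcription strand ``s`` yields a read whose
    5'-aligned end is ``p`` on the opposite (alignment) strand, truncated at
    chromosome edges.  With probability ``mispriming_rate`` the barcode is
    copied from the genomic window the mispriming filter checks (so the
    filter will remove it); otherwise it is drawn uniformly over 4^6
    hexamers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[2])
    reads: list[AlignedReadRecord] = []
    for (chrom, strand), vec in sorted(track.data.items()):
        if not np.issubdtype(vec.dtype, np.integer):
            raise ValueError("simulate_reads needs an integer count track")
        chrom_len = len(genome[chrom])
        positions = np.repeat(np.nonzero(vec)[0], vec[np.nonzero(vec)[0]])
        for p in positions:
            p = int(p)
            if strand == "+":  # transcription +, alignment -
                start, end = max(0, p - read_length + 1), p + 1
                aln = "-"
            else:  # transcription -, alignment +
                start, end = p, min(chrom_len, p + read_length)
                aln = "+"
            probe = AlignedReadRecord(chrom, start, end, aln, "NNNNNN")
            if rng.random() < mispriming_rate:
                window = _adjacent_window(probe, genome, "downstream")
                barcode = window if window is not None else "".join(rng.choice(_BASES, 6))
            else:
                barcode = "".join(rng.choice(_BASES, 6))
            reads.append(AlignedReadRecord(chrom, start, end, aln, barcode))
    return reads


# ---------------------------------------------------------------------------
# MS intensities
# ---------------------------------------------------------------------------


def simulate_ms_dataset(cfg: MsSimConfig):
    """Synthetic peptide-level MS1 intensity records with truth labels.

    Returns ``(records, truth)`` where ``records`` is a DataFrame with
    columns ``protein_id, peptide_id, sample_id, intensity`` plus a
    ``condition_of_sample`` entry in the truth dict.  Truth also carries the
    per-protein enrichment condition ("" for background) and the pre-dropout
    true log2 abundance per cell.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng = np.random.default_rng(ss[3])
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)

    enriched_in = np.array([""] * cfg.n_proteins, dtype=object)
    cursor = 0
    for cond in cfg.conditions:
        k = cfg.n_enriched.get(cond, 0)
        enriched_in[cursor : cursor + k] = cond
        cursor += k

    samples = [
        (f"{cond}_r{r + 1}", cond)
        for cond in cfg.conditions
        for r in range(cfg.n_replicates)
    ]
    condition_of_sample = dict(samples)

    rows = []
    true_abundance: dict[tuple[str, str], float] = {}
    for sample_id, cond in samples:
        truth_log2 = baseline + cfg.effect_size * (enriched_in == cond)
        observed_log2 = truth_log2 + rng.normal(0, cfg.noise_sd, size=cfg.n_proteins)
        p_missing = 1.0 / (1.0 + np.exp(cfg.missing_slope * (truth_log2 - cfg.missing_midpoint)))
        missing = rng.random(cfg.n_proteins) < p_missing
        for i, prot in enumerate(proteins):
            true_abundance[(prot, sample_id)] = float(truth_log2[i])
            if missing[i]:
                continue
            intensity = float(2.0 ** observed_log2[i])
            n_pep = int(rng.integers(cfg.peptides_per_protein[0], cfg.peptides_per_protein[1] + 1))
            if n_pep == 1:
                rows.append((prot, f"{prot}_pep1", sample_id, intensity))
            else:
                shares = rng.dirichlet(np.ones(n_pep))
                for j, w in enumerate(shares):
                    rows.append((prot, f"{prot}_pep{j + 1}", sample_id, intensity * float(w)))

    records = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "sample_id", "intensity"])
    truth = {
        "condition_of_sample": condition_of_sample,
        "enriched_in": dict(zip(proteins, enriched_in)),
        "baseline_log2": dict(zip(proteins, baseline.tolist())),
        "true_abundance_log2": true_abundance,
        "effect_size": cfg.effect_size,
    }
    return records, truth
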