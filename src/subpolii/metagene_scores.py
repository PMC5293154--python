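"""Anchored metagene profiles and per-gene Pol II occupancy statistics.

Applies equally to NET-seq occupancy, MNase-seq, and ChIP-style coverage:
build genes x positions matrices anchored at the TSS or polyA site (always in
transcript orientation), normalize each gene by its own density over the
analyzed windows, average across genes with a sliding-window smooth and a 95%
confidence band, and compute per-gene summary scores — the 5':3' density
ratio, the polyA pausing score, cumulative read-fraction curves — plus the
between-genotype comparison report (box-plot summaries, two-sided t-test,
fraction of genes with increased pausing).

Transcript coordinates: offset ``k`` relative to an anchor means ``k`` bases
downstream of the anchor in the direction of transcription (genomic
``anchor + k`` on the + strand, ``anchor - k`` on the - strand); negative
offsets are upstream.  Windows are half-open in these coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netseq_core import OccupancyTrack

__all__ = [
    "GeneModel",
    "AnchoredMatrix",
    "MetageneProfile",
    "ScoreConfig",
    "FIG5C_LEGEND_PRESET",
    "GeneScoreTable",
    "anchored_matrix",
    "per_gene_normalize",
    "metagene_profile",
    "profile_ratio",
    "cumulative_read_fraction",
    "five_three_ratio",
    "polya_pausing_score",
    "score_table",
    "compare_gene_scores",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene as a (TSS, polyA) pair of 0-based genomic coordinates.

    On the + strand ``tss < polya``; on the - strand ``tss > polya``.  Both
    positions are inclusive single bases (the major-isoform TSS and cleavage
    site).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    polya: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.strand == "+" and not self.tss < self.polya:
            raise ValueError(f"{self.gene_id}: + strand needs tss < polya")
        if self.strand == "-" and not self.tss > self.polya:
            raise ValueError(f"{self.gene_id}: - strand needs tss > polya")

    @property
    def length(self) -> int:
        return abs(self.polya - self.tss) + 1

    def genomic_position(self, anchor_coord: int, offset: int) -> int:
        return anchor_coord + offset if self.strand == "+" else anchor_coord - offset

    def anchor_coord(self, anchor: str) -> int:
        if anchor == "TSS":
            return self.tss
        if anchor == "polyA":
            return self.polya
        raise ValueError(f"unknown anchor {anchor!r}")


@dataclass
class AnchoredMatrix:
    """Genes x transcript-relative positions matrix of track values."""

    gene_ids: list[str]
    anchor: str  # "TSS" | "polyA"
    offsets: np.ndarray  # contiguous, step 1
    values: np.ndarray  # shape (n_genes, n_offsets)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class MetageneProfile:
    offsets: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_genes: int
    smoothing_window: int


@dataclass(frozen=True)
class ScoreConfig:
    """Transcript-coordinate windows for the per-gene summary scores.

    Defaults: 5' window [TSS, TSS+250), 3' window [polyA-250, polyA);
    pausing numerator [polyA-50, polyA+100) vs denominator
    [polyA-200, polyA-50).  ``FIG5C_LEGEND_PRESET`` carries the alternative
    pausing windows [polyA, polyA+100) vs [polyA-50, polyA).
    """

    five_prime_window: tuple[int, int] = (0, 250)  # relative to TSS
    three_prime_window: tuple[int, int] = (-250, 0)  # relative to polyA
    pausing_numerator: tuple[int, int] = (-50, 100)  # relative to polyA
    pausing_denominator: tuple[int, int] = (-200, -50)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.five_prime_window,
            self.three_prime_window,
            self.pausing_numerator,
            self.pausing_denominator,
        ):
            if hi <= lo:
                raise ValueError("empty score window")
        n, d = self.pausing_numerator, self.pausing_denominator
        if n[0] < d[1] and d[0] < n[1]:
            raise ValueError("pausing numerator and denominator overlap")


FIG5C_LEGEND_PRESET = ScoreConfig(pausing_numerator=(0, 100), pausing_denominator=(-50, 0))


@dataclass
class GeneScoreTable:
    """Per-gene log2-ratio scores; NaN marks genes with an empty window."""

    scores: pd.Series  # indexed by gene_id
    kind: str  # "five_three" | "polya_pausing"
    config: ScoreConfig

    def defined(self) -> pd.Series:
        return self.scores.dropna()


# ---------------------------------------------------------------------------
# anchored matrices and profiles
# ---------------------------------------------------------------------------


def _window_values(track: OccupancyTrack, gene: GeneModel, anchor_coord: int,
                   lo: int, hi: int) -> np.ndarray | None:
    """Track values at transcript offsets [lo, hi); None if off-chromosome."""
    vec = track.get(gene.chrom, gene.strand)
    if gene.strand == "+":
        glo, ghi = anchor_coord + lo, anchor_coord + hi
        if glo < 0 or ghi > len(vec):
            return None
        return vec[glo:ghi].astype(float)
    glo, ghi = anchor_coord - hi + 1, anchor_coord - lo + 1
    if glo < 0 or ghi > len(vec):
        return None
    return vec[glo:ghi][::-1].astype(float)


def anchored_matrix(
    track: OccupancyTrack,
    genes: list[GeneModel],
    anchor: str,
    upstream: int,
    downstream: int,
) -> AnchoredMatrix:
    """Collect track values around an anchor, in transcript orientation.

    Offsets run from ``-upstream`` to ``downstream - 1`` in 1-bp bins; minus-
    strand genes are coordinate-mirrored so offsets always increase in the
    direction of transcription.  Genes whose window leaves the chromosome are
    dropped with a warning.
    """
    offsets = np.arange(-upstream, downstream)
    rows, kept = [], []
    for g in genes:
        vals = _window_values(track, g, g.anchor_coord(anchor), -upstream, downstream)
        if vals is None:
            warnings.warn(f"gene {g.gene_id} window leaves chromosome; dropped")
            continue
        rows.append(vals)
        kept.append(g.gene_id)
    values = np.array(rows) if rows else np.empty((0, len(offsets)))
    return AnchoredMatrix(gene_ids=kept, anchor=anchor, offsets=offsets, values=values)


def per_gene_normalize(
    tss_matrix: AnchoredMatrix, polya_matrix: AnchoredMatrix
) -> tuple[AnchoredMatrix, AnchoredMatrix]:
    """Normalize each gene by its own mean density over both windows.

    Each gene's rows are divided by (sum over the TSS window + sum over the
    polyA window) / total width, so a gene of constant density c maps to a
    constant 1 and overall expression level cancels.  Genes with zero
    combined signal are dropped from both matrices.
    """
    if tss_matrix.gene_ids != polya_matrix.gene_ids:
        raise ValueError("matrices are not row-aligned")
    total_width = len(tss_matrix.offsets) + len(polya_matrix.offsets)
    sums = tss_matrix.values.sum(axis=1) + polya_matrix.values.sum(axis=1)
    keep = sums > 0
    factors = sums[keep] / total_width
    kept_ids = [g for g, k in zip(tss_matrix.gene_ids, keep) if k]
    out = []
    for m in (tss_matrix, polya_matrix):
        vals = m.values[keep] / factors[:, None]
        out.append(AnchoredMatrix(kept_ids, m.anchor, m.offsets, vals))
    return out[0], out[1]


def _sliding_mean(rows: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average per row; edges truncated to the available span."""
    if window <= 1:
        return rows
    kernel = np.ones(window)
    counts = np.convolve(np.ones(rows.shape[1]), kernel, mode="same")
    return np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same") / counts, 1, rows
    )


def metagene_profile(
    matrix: AnchoredMatrix, smoothing: int = 25, ci: float = 0.95
) -> MetageneProfile:
    """Across-gene average profile with a normal-approximation CI band.

    Each gene's row is smoothed with a centered ``smoothing``-bp moving
    average (truncated at the edges), then the per-offset mean and
    ``ci``-level confidence interval (z * sd / sqrt(n)) are taken across
    genes.
    """
    n = matrix.values.shape[0]
    if n < 2:
        raise ValueError("metagene profile needs >= 2 genes")
    smoothed = _sliding_mean(matrix.values, smoothing)
    mean = smoothed.mean(axis=0)
    sd = smoothed.std(axis=0, ddof=1)
    z = stats.norm.ppf(0.5 + ci / 2)
    half = z * sd / np.sqrt(n)
    return MetageneProfile(
        offsets=matrix.offsets,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_genes=n,
        smoothing_window=smoothing,
    )


def profile_ratio(profile_a: MetageneProfile, profile_b: MetageneProfile) -> MetageneProfile:
    """Element-wise ratio of two mean profiles (e.g. H2Bub over H2B).

    Offsets where the denominator mean is 0 are NaN.  The CI band is not
    propagated (set to the ratio itself).
    """
    if not np.array_equal(profile_a.offsets, profile_b.offsets):
        raise ValueError("profiles have different offsets")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(profile_b.mean != 0, profile_a.mean / profile_b.mean, np.nan)
    return MetageneProfile(
        offsets=profile_a.offsets,
        mean=ratio,
        ci_low=ratio,
        ci_high=ratio,
        n_genes=min(profile_a.n_genes, profile_b.n_genes),
        smoothing_window=profile_a.smoothing_window,
    )


# ---------------------------------------------------------------------------
# per-gene scores
# ---------------------------------------------------------------------------


def cumulative_read_fraction(track: OccupancyTrack, gene: GeneModel) -> np.ndarray:
    """Cumulative fraction of the gene's reads vs distance from the TSS.

    Entry ``k`` is the fraction of the gene-body signal located within the
    first ``k + 1`` bases downstream of the TSS; monotone from >0 to 1.
    """
    vals = _window_values(track, gene, gene.tss, 0, gene.length)
    if vals is None:
        raise ValueError(f"gene {gene.gene_id} leaves the chromosome")
    total = vals.sum()
    if total <= 0:
        raise ValueError(f"gene {gene.gene_id} has no reads")
    return np.cumsum(vals) / total


def _window_sum(track: OccupancyTrack, gene: GeneModel, anchor: str,
                window: tuple[int, int]) -> float | None:
    vals = _window_values(track, gene, gene.anchor_coord(anchor), *window)
    return None if vals is None else float(vals.sum())


def _log2_window_ratio(track, gene, anchor_num, win_num, anchor_den, win_den,
                       pseudocount: float) -> float:
    num = _window_sum(track, gene, anchor_num, win_num)
    den = _window_sum(track, gene, anchor_den, win_den)
    if num is None or den is None:
        return np.nan
    num += pseudocount
    den += pseudocount
    if num <= 0 or den <= 0:
        return np.nan
    return float(np.log2(num / den))


def five_three_ratio(track: OccupancyTrack, gene: GeneModel,
                     cfg: ScoreConfig | None = None) -> float:
    """log2 of promoter-proximal over terminal-window occupancy.

    NaN when either window sum is zero (the gene is then excluded from
    downstream distributions).
    """
    cfg = cfg or ScoreConfig()
    return _log2_window_ratio(
        track, gene, "TSS", cfg.five_prime_window, "polyA", cfg.three_prime_window,
        cfg.pseudocount,
    )


def polya_pausing_score(track: OccupancyTrack, gene: GeneModel,
                        cfg: ScoreConfig | None = None) -> float:
    """log2 of occupancy around/just past the polyA site over just upstream.

    Measures Pol II accumulation during 3'-end processing; NaN when either
    window sum is zero.
    """
    cfg = cfg or ScoreConfig()
    return _log2_window_ratio(
        track, gene, "polyA", cfg.pausing_numerator, "polyA", cfg.pausing_denominator,
        cfg.pseudocount,
    )


def score_table(track: OccupancyTrack, genes: list[GeneModel], kind: str,
                cfg: ScoreConfig | None = None) -> GeneScoreTable:
    """Per-gene score table of the requested kind over a gene set."""
    cfg = cfg or ScoreConfig()
    fn = {"five_three": five_three_ratio, "polya_pausing": polya_pausing_score}[kind]
    scores = pd.Series(
        {g.gene_id: fn(track, g, cfg) for g in genes}, dtype=float, name=kind
    )
    return GeneScoreTable(scores=scores, kind=kind, config=cfg)


def compare_gene_scores(scores_wt: GeneScoreTable, scores_mut: GeneScoreTable) -> dict:
    """Between-genotype comparison of per-gene score distributions.

    Restricted to genes with a defined score in both tables.  Reports box-plot
    summaries, a two-sided two-sample t-test across the score distributions,
    the per-gene difference (mut - wt) with its cumulative distribution, and
    the fraction of genes with a strictly increased score.
    """
    wt = scores_wt.defined()
    mut = scores_mut.defined()
    shared = wt.index.intersection(mut.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes with defined scores in both tables")
    wt, mut = wt.loc[shared], mut.loc[shared]
    diff = (mut - wt).sort_values()
    if np.allclose(wt, mut):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(mut, wt, equal_var=True)

    def box(x: pd.Series) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "n_genes": int(len(shared)),
        "wt": box(wt),
        "mut": box(mut),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "difference": diff,
        "difference_cdf": pd.DataFrame(
            {"difference": diff.to_numpy(),
             "cumulative_fraction": np.arange(1, len(diff) + 1) / len(diff)}
        ),
        "fraction_increased": float((diff > 0).mean()),
    }
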