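"""Label-free quantitative enrichment analysis of sequential-IP mass spectrometry.

Implements the interactome arm of the pipeline: peptide-to-protein MS1
aggregation, log2 mean-centering, completeness filtering, missing-not-at-random
imputation from a down-shifted normal, and a permutation-FDR volcano analysis
with an s0-moderated test statistic (the SAM-style "fudge factor" that bends
the significance curve), plus sample-level diagnostics (pairwise Pearson, PCA,
complete-linkage clustering, mean/variance tests).

Conventions
-----------
A protein is *present* in a sample iff its summed intensity is recorded and
strictly positive; absence is carried as NaN and survives log2/normalization
untouched.  Imputation is the only operation allowed to fill it, and it
remembers the pre-imputation observation mask so that significance flags can be
restricted to proteins observed in every replicate of the specific IP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

__all__ = [
    "ProteinMatrix",
    "ImputeConfig",
    "VolcanoConfig",
    "EnrichmentTable",
    "aggregate_peptides",
    "log2_mean_normalize",
    "filter_complete",
    "impute_mnar",
    "volcano_enrichment",
    "sample_diagnostics",
]

# default s0 grid scanned when VolcanoConfig.s0 == "auto"; covers the range
# label-free tools typically explore
S0_AUTO_GRID = tuple(np.round(np.arange(0.0, 2.01, 0.1), 10))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProteinMatrix:
    """Proteins x samples matrix of (possibly missing) MS1 intensities.

    Parameters
    ----------
    values
        DataFrame indexed by protein_id with one column per sample; NaN marks
        a protein absent from a sample.
    condition_of_sample
        Mapping sample_id -> condition label (e.g. ``five_prime``, ``mock``).
    scale
        One of ``raw``, ``log2``, ``normalized``.
    observed
        Boolean mask with the same shape as ``values`` recording which cells
        were measured (as opposed to imputed).  ``None`` means "equal to
        ``values.notna()``".
    """

    values: pd.DataFrame
    condition_of_sample: dict[str, str]
    scale: str = "raw"
    observed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.condition_of_sample)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.condition_of_sample[s] == condition]
        if not out:
            raise ValueError(f"unknown condition label: {condition!r}")
        return out

    def observed_mask(self) -> pd.DataFrame:
        if self.observed is not None:
            return self.observed
        return self.values.notna()


@dataclass(frozen=True)
class ImputeConfig:
    """Down-shifted-normal imputation parameters.

    ``down_shift`` and ``width`` are in units of the per-sample standard
    deviation of the observed log2 intensity distribution: missing cells in
    sample *s* draw from Normal(mu_s - down_shift * sd_s, (width * sd_s)^2).
    """

    down_shift: float = 1.8
    width: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.down_shift < 0:
            raise ValueError("down_shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass(frozen=True)
class VolcanoConfig:
    fdr_strict: float = 0.05
    fdr_lenient: float = 0.10
    s0: float | str = "auto"
    n_permutations: int = 250
    seed: int = 0
    welch: bool = False
    s0_grid: tuple[float, ...] = S0_AUTO_GRID

    def __post_init__(self) -> None:
        for f in (self.fdr_strict, self.fdr_lenient):
            if not 0 < f < 1:
                raise ValueError("FDR levels must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not isinstance(self.s0, str) and self.s0 < 0:
            raise ValueError("s0 must be >= 0 or 'auto'")


@dataclass
class EnrichmentTable:
    """Per-protein volcano results plus table-level metadata."""

    table: pd.DataFrame  # log2_fold_change, t_statistic, p_value, d_statistic,
    #                      significant_strict, significant_lenient
    s0_used: float
    fdr_thresholds: tuple[float, float]
    n_permutations_used: int
    condition_a: str = ""
    condition_b: str = ""
    d_cutoffs: tuple[float, float] = (np.inf, np.inf)


# ---------------------------------------------------------------------------
# aggregation and normalization
# ---------------------------------------------------------------------------


def aggregate_peptides(records: pd.DataFrame, condition_of_sample: dict[str, str]) -> ProteinMatrix:
    """Sum peptide MS1 intensities to protein level.

    ``records`` needs columns ``protein_id``, ``sample_id``, ``intensity`` and
    optionally ``peptide_id``.  A protein with no records (or a summed
    intensity of zero) in a sample is marked missing.
    """
    if len(records) == 0:
        raise ValueError("no peptide records supplied")
    bad = records[records["intensity"] < 0]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"negative intensity for protein {r['protein_id']!r} sample {r['sample_id']!r}"
        )
    if not np.isfinite(records["intensity"]).all():
        raise ValueError("non-finite intensity in peptide records")
    wide = (
        records.groupby(["protein_id", "sample_id"])["intensity"]
        .sum()
        .unstack("sample_id")
    )
    wide = wide.mask(wide <= 0)  # zero total = not present
    # keep every labelled sample as a column even if it has no records
    for s in condition_of_sample:
        if s not in wide.columns:
            wide[s] = np.nan
    wide = wide[[s for s in condition_of_sample if s in wide.columns]]
    return ProteinMatrix(wide, dict(condition_of_sample), scale="raw")


def log2_mean_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """log2-transform and mean-center each sample over its observed values.

    Centering makes samples directly comparable without touching their
    variances; missing cells stay missing.
    """
    if matrix.scale != "raw":
        raise ValueError(f"expected a raw-scale matrix, got {matrix.scale!r}")
    vals = matrix.values
    if (vals <= 0).any().any():
        raise ValueError("non-positive observed intensity; cannot log2 transform")
    logged = np.log2(vals)
    centered = logged - logged.mean(axis=0, skipna=True)
    return ProteinMatrix(centered, dict(matrix.condition_of_sample), scale="normalized")


def filter_complete(matrix: ProteinMatrix, conditions: tuple[str, str]) -> ProteinMatrix:
    """Keep proteins observed in *every* replicate of at least one condition."""
    cond_a, cond_b = conditions
    obs = matrix.observed_mask()
    keep = pd.Series(False, index=matrix.values.index)
    for cond in (cond_a, cond_b):
        cols = matrix.samples_of(cond)
        keep |= obs[cols].all(axis=1)
    out = replace(matrix)
    out.values = matrix.values.loc[keep]
    if matrix.observed is not None:
        out.observed = matrix.observed.loc[keep]
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_mnar(matrix: ProteinMatrix, cfg: ImputeConfig) -> ProteinMatrix:
    """Fill missing cells from a per-sample down-shifted normal distribution.

    Models the fact that absent proteins sit near the detection limit: each
    missing cell in sample *s* draws from
    ``Normal(mu_s - down_shift * sd_s, (width * sd_s)^2)`` with ``mu_s`` and
    ``sd_s`` estimated from that sample's observed values.  Observed cells are
    copied bit-identically; the pre-imputation mask is stored on the result.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    vals = matrix.values.copy()
    observed = matrix.values.notna()
    for s in vals.columns:
        col = vals[s]
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observed values")
        n_miss = int(col.isna().sum())
        if n_miss == 0:
            continue
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(mu - cfg.down_shift * sd, cfg.width * sd, size=n_miss)
        vals.loc[col.isna(), s] = draws
    return ProteinMatrix(
        vals, dict(matrix.condition_of_sample), scale=matrix.scale, observed=observed
    )


# ---------------------------------------------------------------------------
# volcano analysis
# ---------------------------------------------------------------------------


def _group_stats(x: np.ndarray, y: np.ndarray, s0: float, welch: bool):
    """Fold change, t, two-sided p, and s0-moderated d for rows of x vs y."""
    na, nb = x.shape[1], y.shape[1]
    ma, mb = x.mean(axis=1), y.mean(axis=1)
    va, vb = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    diff = ma - mb
    if welch:
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = np.where(np.isfinite(df), df, na + nb - 2)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = np.full(x.shape[0], na + nb - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    d = diff / (se + s0) if s0 > 0 else t
    return diff, t, p, d


def _null_splits(samples_a: list[str], samples_b: list[str], n_permutations: int, rng):
    """Relabelings of the pooled samples into groups of the original sizes.

    The observed assignment (and, for equal group sizes, its mirror — which
    yields the identical |d|) is excluded so that the null is not contaminated
    by the observed statistic itself.
    """
    pooled = list(samples_a) + list(samples_b)
    na = len(samples_a)
    observed = frozenset(samples_a)
    splits = []
    for combo in itertools.combinations(pooled, na):
        grp = frozenset(combo)
        if grp == observed:
            continue
        if na == len(samples_b) and grp == frozenset(samples_b):
            continue
        splits.append(list(combo))
    if len(splits) > n_permutations:
        idx = rng.choice(len(splits), size=n_permutations, replace=False)
        splits = [splits[i] for i in sorted(idx)]
    return splits


def _significant_at(abs_d_obs: np.ndarray, null_abs_d: np.ndarray, fdr: float):
    """Permutation-FDR cutoff: smallest c with FDR_est(c) <= fdr.

    FDR_est(c) = mean over permutations of #{|d_perm| >= c} / #{|d_obs| >= c},
    evaluated at every observed |d| as candidate cutoff; proteins with
    |d| >= c (ties inclusive) are called significant.
    """
    n_perm = null_abs_d.shape[0]
    candidates = np.unique(abs_d_obs)
    flat_null = np.sort(null_abs_d.ravel())
    sorted_obs = np.sort(abs_d_obs)
    n_obs = len(sorted_obs) - np.searchsorted(sorted_obs, candidates, side="left")
    n_null = len(flat_null) - np.searchsorted(flat_null, candidates, side="left")
    fdr_est = (n_null / n_perm) / n_obs
    ok = np.flatnonzero(fdr_est <= fdr)
    cutoff = float(candidates[ok[0]]) if len(ok) else np.inf
    return abs_d_obs >= cutoff, cutoff


def volcano_enrichment(
    matrix: ProteinMatrix,
    condition_a: str,
    condition_b: str,
    cfg: VolcanoConfig | None = None,
) -> EnrichmentTable:
    """Permutation-FDR volcano analysis of condition A vs condition B.

    Per protein: log2 fold change (mean A - mean B), pooled-variance two-sided
    t-test, and the s0-moderated statistic d = diff / (se + s0).  Significance
    cutoffs on |d| are calibrated by relabeling samples across the two groups;
    with ``s0='auto'`` a grid is scanned and the value minimizing the number
    of significant proteins enriched on the B (mock/negative) side is chosen.
    Significance flags are only granted to proteins observed in every
    replicate of condition A (the specific IP) before imputation.
    """
    cfg = cfg or VolcanoConfig()
    samples_a = matrix.samples_of(condition_a)
    samples_b = matrix.samples_of(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >= 2 samples")
    sub = matrix.values[samples_a + samples_b]
    if sub.isna().any().any():
        raise ValueError("missing values remain; impute before volcano analysis")

    x = sub[samples_a].to_numpy(float)
    y = sub[samples_b].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    splits = _null_splits(samples_a, samples_b, cfg.n_permutations, rng)
    pooled = sub.to_numpy(float)
    col_of = {s: i for i, s in enumerate(samples_a + samples_b)}
    all_cols = set(range(len(col_of)))

    def null_abs_d(s0: float) -> np.ndarray:
        rows = []
        for grp in splits:
            ia = [col_of[s] for s in grp]
            ib = sorted(all_cols - set(ia))
            _, _, _, d = _group_stats(pooled[:, ia], pooled[:, ib], s0, cfg.welch)
            rows.append(np.abs(d))
        return np.asarray(rows)

    def run(s0: float):
        diff, t, p, d = _group_stats(x, y, s0, cfg.welch)
        null = null_abs_d(s0)
        sig_s, cut_s = _significant_at(np.abs(d), null, cfg.fdr_strict)
        sig_l, cut_l = _significant_at(np.abs(d), null, cfg.fdr_lenient)
        return diff, t, p, d, sig_s, sig_l, (cut_s, cut_l)

    if isinstance(cfg.s0, str):
        # auto: minimize mock-side (negative) hits; among ties keep the s0
        # retaining the most specific-side hits, then the smallest s0
        best = None
        for s0 in cfg.s0_grid:
            diff, t, p, d, sig_s, sig_l, cuts = run(float(s0))
            n_mock = int(np.sum(sig_s & (diff < 0)))
            n_specific = int(np.sum(sig_s & (diff > 0)))
            key = (n_mock, -n_specific)
            if best is None or key < best[0]:
                best = (key, float(s0), (diff, t, p, d, sig_s, sig_l, cuts))
        s0_used = best[1]
        diff, t, p, d, sig_s, sig_l, cuts = best[2]
    else:
        s0_used = float(cfg.s0)
        diff, t, p, d, sig_s, sig_l, cuts = run(s0_used)

    # flags require presence in all replicates of the specific condition
    obs = matrix.observed_mask().loc[sub.index, samples_a].all(axis=1).to_numpy()
    table = pd.DataFrame(
        {
            "log2_fold_change": diff,
            "t_statistic": t,
            "p_value": p,
            "d_statistic": d,
            "significant_strict": sig_s & obs,
            "significant_lenient": sig_l & obs,
        },
        index=sub.index,
    )
    return EnrichmentTable(
        table=table,
        s0_used=s0_used,
        fdr_thresholds=(cfg.fdr_strict, cfg.fdr_lenient),
        n_permutations_used=len(splits),
        condition_a=condition_a,
        condition_b=condition_b,
        d_cutoffs=cuts,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def sample_diagnostics(matrix: ProteinMatrix) -> dict:
    """Reproducibility diagnostics across samples.

    Returns pairwise Pearson correlations over proteins co-observed in each
    sample pair, PCA scores of the samples (complete proteins as centered
    features), a complete-linkage dendrogram on 1 - Pearson distance, and
    per-sample mean/variance with all-pairs t- and F-tests.
    """
    vals = matrix.values
    samples = list(vals.columns)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples for diagnostics")

    n = len(samples)
    corr = pd.DataFrame(np.eye(n), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for j in range(i + 1, n):
            b = samples[j]
            both = vals[[a, b]].dropna()
            if len(both) < 3 or both[a].std() == 0 or both[b].std() == 0:
                r = np.nan
            else:
                r = float(both[a].corr(both[b]))
            corr.iloc[i, j] = corr.iloc[j, i] = r

    complete = vals.dropna()
    n_comp = min(n - 1, len(complete), 2)
    if n_comp >= 1:
        feats = complete.T.to_numpy(float)
        feats = feats - feats.mean(axis=0)
        pca = PCA(n_components=n_comp)
        scores = pd.DataFrame(
            pca.fit_transform(feats),
            index=samples,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        explained = pca.explained_variance_ratio_
    else:  # no protein observed in every sample
        scores = pd.DataFrame(np.nan, index=samples, columns=["PC1"])
        explained = np.array([np.nan])

    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    condensed = np.nan_to_num(condensed, nan=2.0)  # undefined pairs: max distance
    linkage = hierarchy.linkage(np.clip(condensed, 0, None), method="complete")

    means = vals.mean(axis=0, skipna=True)
    variances = vals.var(axis=0, ddof=1, skipna=True)
    rows = []
    for a, b in itertools.combinations(samples, 2):
        xa, xb = vals[a].dropna(), vals[b].dropna()
        t_stat, t_p = stats.ttest_ind(xa, xb, equal_var=True)
        f_stat = xa.var(ddof=1) / xb.var(ddof=1)
        dfa, dfb = len(xa) - 1, len(xb) - 1
        f_p = 2 * min(stats.f.cdf(f_stat, dfa, dfb), stats.f.sf(f_stat, dfa, dfb))
        rows.append(
            {"sample_a": a, "sample_b": b, "t": float(t_stat), "t_p": float(t_p),
             "F": float(f_stat), "F_p": float(min(f_p, 1.0))}
        )
    return {
        "pearson": corr,
        "pca_scores": scores,
        "pca_explained_variance_ratio": explained,
        "linkage": linkage,
        "sample_means": means,
        "sample_variances": variances,
        "mean_variance_tests": pd.DataFrame(rows),
    }


def mean_within_between_correlation(
    diag_pearson: pd.DataFrame, condition_of_sample: dict[str, str]
) -> tuple[float, float]:
    """Average Pearson r within conditions and between different conditions."""
    samples = list(diag_pearson.columns)
    within, between = [], []
    for a, b in itertools.combinations(samples, 2):
        r = diag_pearson.loc[a, b]
        if np.isnan(r):
            continue
        (within if condition_of_sample[a] == condition_of_sample[b] else between).append(r)
    return float(np.mean(within)), float(np.mean(between))
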