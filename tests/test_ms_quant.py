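"""Unit and property tests for the label-free MS enrichment pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from subpolii.ms_quant import (
    ImputeConfig,
    ProteinMatrix,
    VolcanoConfig,
    aggregate_peptides,
    filter_complete,
    impute_mnar,
    log2_mean_normalize,
    mean_within_between_correlation,
    sample_diagnostics,
    volcano_enrichment,
)


def records_df(rows):
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id", "sample_id", "intensity"])


class TestAggregatePeptides:
    def test_single_and_multi_peptide_sums(self):
        rec = records_df([("P1", "pepA", "S1", 100.0), ("P1", "pepB", "S1", 200.0),
                          ("P2", "pepC", "S1", 7.0)])
        m = aggregate_peptides(rec, {"S1": "a"})
        assert m.values.loc["P1", "S1"] == 300.0
        assert m.values.loc["P2", "S1"] == 7.0

    def test_matches_groupby_oracle(self, rng):
        prots = [f"P{i}" for i in range(50)]
        samples = ["S1", "S2", "S3"]
        rows = [
            (rng.choice(prots), f"pep{i}", rng.choice(samples), float(rng.uniform(1, 1000)))
            for i in range(500)
        ]
        rec = records_df(rows)
        m = aggregate_peptides(rec, {s: "c" for s in samples})
        oracle: dict = {}
        for p, _pep, s, x in rows:
            oracle[(p, s)] = oracle.get((p, s), 0.0) + x
        for (p, s), v in oracle.items():
            assert m.values.loc[p, s] == pytest.approx(v)
        n_cells = m.values.notna().sum().sum()
        assert n_cells == len(oracle)

    def test_absent_and_zero_are_missing(self):
        rec = records_df([("P1", "x", "S1", 5.0), ("P2", "y", "S2", 0.0)])
        m = aggregate_peptides(rec, {"S1": "a", "S2": "a"})
        assert np.isnan(m.values.loc["P1", "S2"])
        assert np.isnan(m.values.loc["P2", "S2"])  # zero sum = not present

    def test_negative_intensity_rejected(self):
        rec = records_df([("P1", "x", "S1", -1.0)])
        with pytest.raises(ValueError, match="P1"):
            aggregate_peptides(rec, {"S1": "a"})


class TestLog2MeanNormalize:
    def test_forced_arithmetic(self):
        vals = pd.DataFrame({"S1": [2.0, 8.0, 32.0]}, index=list("abc"))
        m = log2_mean_normalize(ProteinMatrix(vals, {"S1": "c"}))
        assert np.allclose(m.values["S1"], [-2.0, 0.0, 2.0])
        assert m.scale == "normalized"

    def test_constant_sample_becomes_zero(self):
        vals = pd.DataFrame({"S1": [4.0, 4.0, 4.0]}, index=list("abc"))
        m = log2_mean_normalize(ProteinMatrix(vals, {"S1": "c"}))
        assert np.allclose(m.values["S1"], 0.0)

    def test_mean_zero_variance_preserved_missing_untouched(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 1e6, (200, 4)),
                            columns=list("wxyz"), index=range(200))
        vals.iloc[rng.choice(200, 40, replace=False), 2] = np.nan
        m = log2_mean_normalize(ProteinMatrix(vals, {c: "c" for c in "wxyz"}))
        assert np.allclose(m.values.mean(axis=0, skipna=True), 0.0, atol=1e-9)
        assert np.allclose(
            m.values.var(axis=0, skipna=True), np.log2(vals).var(axis=0, skipna=True)
        )
        assert m.values[m.values.columns[2]].isna().sum() == 40
        # idempotence: re-centering an already centered matrix is a no-op
        recentered = m.values - m.values.mean(axis=0, skipna=True)
        assert np.nanmax(np.abs((recentered - m.values).to_numpy())) < 1e-9

    def test_nonpositive_rejected(self):
        vals = pd.DataFrame({"S1": [2.0, 0.0]}, index=list("ab"))
        with pytest.raises(ValueError):
            log2_mean_normalize(ProteinMatrix(vals, {"S1": "c"}))


class TestFilterComplete:
    def test_complete_in_one_condition_kept(self, toy_matrix):
        out = filter_complete(toy_matrix, ("a", "b"))
        # P1: 3/3 in a, 0/3 in b -> kept; P2: complete in both -> kept;
        # P3: 3/3 in a -> kept
        assert list(out.values.index) == ["P1", "P2", "P3"]
        assert list(out.values.columns) == list(toy_matrix.values.columns)

    def test_incomplete_in_both_dropped(self):
        vals = pd.DataFrame(
            {"a1": [1.0], "a2": [np.nan], "a3": [1.0], "b1": [1.0], "b2": [1.0], "b3": [np.nan]},
            index=["P"],
        )
        m = ProteinMatrix(vals, {s: s[0] for s in vals.columns})
        assert len(filter_complete(m, ("a", "b")).values) == 0

    def test_matches_bruteforce_over_random_patterns(self, rng):
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        vals = pd.DataFrame(rng.uniform(1, 10, (200, 6)), columns=cols,
                            index=[f"P{i}" for i in range(200)])
        mask = rng.random((200, 6)) < 0.4
        vals = vals.mask(mask)
        m = ProteinMatrix(vals, {s: s[0] for s in cols})
        kept = set(filter_complete(m, ("a", "b")).values.index)
        expected = {
            p for p in vals.index
            if vals.loc[p, ["a1", "a2", "a3"]].notna().all()
            or vals.loc[p, ["b1", "b2", "b3"]].notna().all()
        }
        assert kept == expected

    def test_unknown_condition_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown condition"):
            filter_complete(toy_matrix, ("a", "zz"))


class TestImputeMnar:
    def test_no_missing_is_identity(self, rng):
        vals = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        m = ProteinMatrix(vals, {c: "c" for c in "abc"}, scale="normalized")
        out = impute_mnar(m, ImputeConfig(seed=1))
        assert out.values.equals(vals)

    def test_monte_carlo_mean_and_sd(self, rng):
        # one column whose observed part has exactly mean 0, sd 1
        obs = rng.normal(0, 1, 2000)
        obs = (obs - obs.mean()) / obs.std(ddof=1)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        vals = pd.DataFrame({"S1": col, "S2": np.ones(len(col))})
        m = ProteinMatrix(vals, {"S1": "c", "S2": "c"}, scale="normalized")
        out = impute_mnar(m, ImputeConfig(down_shift=1.8, width=0.3, seed=7))
        imputed = out.values["S1"].to_numpy()[2000:]
        assert imputed.mean() == pytest.approx(-1.8, abs=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.02)

    def test_locality_and_determinism(self, rng):
        vals = pd.DataFrame(rng.normal(5, 2, (100, 3)), columns=list("abc"))
        vals = vals.mask(rng.random((100, 3)) < 0.3)
        m = ProteinMatrix(vals, {c: "c" for c in "abc"}, scale="normalized")
        out1 = impute_mnar(m, ImputeConfig(seed=3))
        out2 = impute_mnar(m, ImputeConfig(seed=3))
        assert out1.values.equals(out2.values)  # determinism
        # changed cells are exactly the missing cells; observed bit-identical
        changed = out1.values.to_numpy() != vals.to_numpy()
        assert (changed == vals.isna().to_numpy()).all()
        assert out1.observed.equals(vals.notna())

    def test_underobserved_sample_rejected(self):
        vals = pd.DataFrame({"S1": [1.0, np.nan, np.nan]})
        m = ProteinMatrix(vals, {"S1": "c"}, scale="normalized")
        with pytest.raises(ValueError, match="S1"):
            impute_mnar(m, ImputeConfig())


def make_pm(x, y, cond=("a", "b")):
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    cols = [f"{cond[0]}{i}" for i in range(x.shape[1])] + [
        f"{cond[1]}{i}" for i in range(y.shape[1])
    ]
    vals = pd.DataFrame(np.hstack([x, y]), columns=cols,
                        index=[f"P{i}" for i in range(x.shape[0])])
    c_of_s = {c: (cond[0] if c.startswith(cond[0]) else cond[1]) for c in cols}
    return ProteinMatrix(vals, c_of_s, scale="normalized")


class TestVolcano:
    def test_textbook_pooled_t(self):
        m = make_pm([[1.0, 2.0, 3.0]], [[3.0, 4.0, 5.0]])
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.0, seed=0))
        row = res.table.iloc[0]
        assert row.log2_fold_change == pytest.approx(-2.0)
        assert abs(row.t_statistic) == pytest.approx(2.449, abs=5e-4)
        assert row.p_value == pytest.approx(0.0705, abs=2e-3)

    def test_identical_groups_null(self):
        m = make_pm([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.0, seed=0))
        row = res.table.iloc[0]
        assert row.log2_fold_change == 0.0
        assert row.d_statistic == 0.0
        assert not row.significant_strict and not row.significant_lenient

    def test_s0_zero_equals_t_ranking(self, rng):
        m = make_pm(rng.normal(0, 1, (100, 3)), rng.normal(0, 1, (100, 3)))
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.0, seed=0))
        assert np.allclose(res.table.d_statistic, res.table.t_statistic)

    def test_exhaustive_enumeration_for_3v3(self, rng):
        m = make_pm(rng.normal(0, 1, (20, 3)), rng.normal(0, 1, (20, 3)))
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.1, n_permutations=250, seed=0))
        # 20 label assignments minus the observed one and its mirror
        assert res.n_permutations_used == 18

    def test_fdr_monotonicity_strict_subset_of_lenient(self, rng):
        x = rng.normal(0, 0.5, (300, 3))
        x[:25] += 2.0
        m = make_pm(x, rng.normal(0, 0.5, (300, 3)))
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.3, seed=1))
        t = res.table
        assert (t.significant_strict <= t.significant_lenient).all()
        assert t.significant_strict.sum() > 0

    def test_global_null_fdr_control(self):
        # fraction of flagged proteins under the global null stays near zero
        fracs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            m = make_pm(g.normal(0, 1, (500, 3)), g.normal(0, 1, (500, 3)))
            res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.1, seed=seed))
            fracs.append(res.table.significant_strict.mean())
        assert np.mean(fracs) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (10 * 500))

    def test_spike_in_power(self):
        # 30 spikes at log2FC 2, sd 0.5, 3v3: strict set recovers >= 80%
        # of spikes with <= 5% null contamination on average
        recov, fp = [], []
        for seed in range(10):
            g = np.random.default_rng(100 + seed)
            x = g.normal(0, 0.5, (1000, 3))
            y = g.normal(0, 0.5, (1000, 3))
            x[:30] += 2.0
            m = make_pm(x, y)
            res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.5, seed=seed))
            sig = res.table.significant_strict.to_numpy()
            recov.append(sig[:30].mean())
            fp.append(sig[30:].mean())
        assert np.mean(recov) >= 0.8
        assert np.mean(fp) <= 0.05

    def test_flags_require_full_observation_in_specific_condition(self, rng):
        x = rng.normal(0, 0.3, (50, 3))
        x[:10] += 3.0
        m = make_pm(x, rng.normal(0, 0.3, (50, 3)))
        observed = pd.DataFrame(True, index=m.values.index, columns=m.values.columns)
        observed.iloc[0, 0] = False  # P0 not observed in one "a" replicate
        m.observed = observed
        res = volcano_enrichment(m, "a", "b", VolcanoConfig(s0=0.3, seed=0))
        assert not res.table.loc["P0", "significant_strict"]
        assert res.table.loc["P1", "significant_strict"]

    def test_single_sample_condition_rejected(self):
        m = make_pm([[1.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            volcano_enrichment(m, "a", "b")


class TestDiagnostics:
    def test_self_correlation_is_one(self, rng):
        vals = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        d = sample_diagnostics(ProteinMatrix(vals, {c: "c" for c in "abc"}))
        assert np.allclose(np.diag(d["pearson"]), 1.0)

    def test_duplicated_samples_cluster_first_at_zero(self, rng):
        base = rng.normal(0, 1, 60)
        vals = pd.DataFrame(
            {"dup1": base, "dup2": base, "other": rng.normal(0, 1, 60)}
        )
        d = sample_diagnostics(ProteinMatrix(vals, {c: "c" for c in vals.columns}))
        first = d["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_cluster_design_separated(self, rng):
        offset = np.where(rng.random(80) < 0.5, 4.0, -4.0)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = offset + rng.normal(0, 0.2, 80)
        for i in range(3):
            cols[f"b{i}"] = -offset + rng.normal(0, 0.2, 80)
        vals = pd.DataFrame(cols)
        m = ProteinMatrix(vals, {c: c[0] for c in cols})
        d = sample_diagnostics(m)
        pc1 = d["pca_scores"]["PC1"].to_numpy()
        assert (np.sign(pc1[:3]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[3:]) == -np.sign(pc1[0])).all()
        # dendrogram splits 3 | 3
        labels = hierarchy.fcluster(d["linkage"], t=2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        w, b = mean_within_between_correlation(d["pearson"], m.condition_of_sample)
        assert w > b

    def test_pair_with_too_few_coobserved_is_nan(self):
        vals = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, np.nan, 1.0, 2.0],
             "z": [1.0, 2.0, 3.0, 4.0]}
        )
        d = sample_diagnostics(ProteinMatrix(vals, {c: "c" for c in "xyz"}))
        assert np.isnan(d["pearson"].loc["x", "y"])
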