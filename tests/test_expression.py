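"""Differential-test calibration, standardization contract, binning."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldclock import expression


def nb_counts(rng, mean, dispersion, size):
    lam = rng.gamma(1.0 / dispersion, dispersion * np.broadcast_to(mean, size))
    return rng.poisson(lam)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, rng, nb_table):
        counts = nb_table(rng, 50, 1)
        counts["s1"] = counts["s0"]
        sf = expression.size_factors(counts)
        np.testing.assert_allclose(sf, 1.0)

    def test_doubled_sample_gets_double_factor(self, rng, nb_table):
        counts = nb_table(rng, 100, 1)
        counts["s1"] = counts["s0"] * 2
        sf = expression.size_factors(counts)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_matches_direct_median_of_ratios(self, rng, nb_table):
        counts = nb_table(rng, 200, 5)
        sf = expression.size_factors(counts)
        mat = counts.to_numpy(float)
        keep = (mat > 0).all(axis=1)
        geo = np.exp(np.log(mat[keep]).mean(axis=1))
        expected = np.median(mat[keep] / geo[:, None], axis=0)
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)

    def test_no_universally_expressed_gene_rejected(self):
        counts = pd.DataFrame({"s0": [0, 5], "s1": [5, 0]})
        with pytest.raises(ValueError):
            expression.size_factors(counts)


class TestNbWaldDe:
    groups = ([f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)])

    def test_identical_groups_give_null_result(self):
        counts = pd.DataFrame(
            np.tile(np.arange(10, 60, 10)[:, None], (1, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(12)],
        )
        res = expression.nb_wald_de(counts, *self.groups)
        np.testing.assert_allclose(res.table["log2fc"], 0.0)
        assert (res.table["p"] > 0.99).all()

    def test_single_replicate_rejected(self, rng, nb_table):
        counts = nb_table(rng, 20, 3)
        with pytest.raises(ValueError):
            expression.nb_wald_de(counts, ["s0"], ["s1", "s2"])

    def test_all_zero_gene_reported_untested(self, rng, nb_table):
        counts = nb_table(rng, 20, 12)
        counts.iloc[0] = 0
        res = expression.nb_wald_de(counts, *self.groups)
        assert np.isnan(res.table["p"].iloc[0])
        assert np.isnan(res.table["padj"].iloc[0])

    def test_null_calibration(self, rng, nb_table):
        counts = nb_table(rng, 1000, 12, dispersion=0.1)
        res = expression.nb_wald_de(counts, *self.groups)
        p = res.table["p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert (res.table["padj"] < 0.05).mean() <= 0.05

    def test_nuclear_restricted_effect_recovered(self, rng):
        n_genes, n_inj = 1000, 100
        means = rng.uniform(20, 2000, n_genes)
        eff = np.ones(n_genes)
        eff[:n_inj] = 4.0
        idx = [f"g{i}" for i in range(n_genes)]
        cols = [f"s{j}" for j in range(12)]
        cyt = pd.DataFrame(nb_counts(rng, means[:, None], 0.1, (n_genes, 12)),
                           index=idx, columns=cols)
        nuc = pd.DataFrame(
            np.hstack([
                nb_counts(rng, means[:, None], 0.1, (n_genes, 6)),
                nb_counts(rng, (means * eff)[:, None], 0.1, (n_genes, 6)),
            ]),
            index=idx, columns=cols,
        )
        rn = expression.nb_wald_de(nuc, *self.groups)
        rc = expression.nb_wald_de(cyt, *self.groups)
        injected = idx[:n_inj]
        assert (rn.table.loc[injected, "padj"] < 0.05).mean() >= 0.90
        assert (rc.table.loc[injected, "padj"] < 0.05).mean() <= 0.05


class TestAgainstIndependentDeImplementation:
    def test_fold_changes_and_calls_track_pydeseq2(self, rng):
        """Cross-check the NB Wald stand-in against an independent DE tool."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        n, n_eff = 200, 20
        means = rng.uniform(50, 1000, n)
        eff = np.ones(n)
        eff[:n_eff] = 3.0
        counts = pd.DataFrame(
            np.hstack([nb_counts(rng, means[:, None], 0.1, (n, 6)),
                       nb_counts(rng, (means * eff)[:, None], 0.1, (n, 6))]),
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(12)],
        )
        meta = pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        ref = ds.results_df

        mine = expression.nb_wald_de(
            counts, [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)]
        ).table
        r = np.corrcoef(ref["log2FoldChange"], mine["log2fc"])[0, 1]
        assert r > 0.99
        # calls agree on the injected genes; the stand-in (no dispersion
        # shrinkage) may be somewhat more conservative overall
        injected = counts.index[:n_eff]
        agree = ((ref.loc[injected, "padj"] < 0.05)
                 & (mine.loc[injected, "padj"] < 0.05)).mean()
        assert agree >= 0.8


class TestStandardizeSeries:
    def _counts(self, rng, trajectories, reps=2, base=(50, 500)):
        """Genes x samples table with per-timepoint mean shapes."""
        n_genes, n_tp = trajectories.shape
        base = rng.uniform(*base, n_genes)
        cols, tps = [], []
        mat = []
        for t in range(n_tp):
            for r in range(reps):
                cols.append(f"t{t}r{r}")
                tps.append(f"t{t}")
                mat.append(base * trajectories[:, t] * rng.lognormal(0, 0.05, n_genes))
        counts = pd.DataFrame(np.array(mat).T.astype(int),
                              index=[f"g{i}" for i in range(n_genes)], columns=cols)
        return counts, pd.Series(tps, index=cols)

    def test_mean_zero_sd_one_contract(self, rng):
        traj = rng.uniform(0.5, 2.0, (100, 4))
        counts, tps = self._counts(rng, traj)
        ss = expression.standardize_series(counts, tps)
        assert np.abs(ss.values.mean(axis=1)).max() < 1e-9
        assert np.abs(ss.values.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_scale_invariance_per_gene(self, rng):
        # approximate at the pseudocount level: use large counts
        traj = rng.uniform(0.5, 2.0, (50, 3))
        counts, tps = self._counts(rng, traj, base=(500, 5000))
        scaled = counts.copy()
        scaled.iloc[0] *= 64
        a = expression.standardize_series(counts, tps)
        b = expression.standardize_series(scaled, tps)
        np.testing.assert_allclose(a.values.iloc[0], b.values.iloc[0], atol=0.02)

    def test_constant_gene_dropped_with_record(self, rng):
        # majority of constant genes pins every size factor at 1, so a
        # raw-constant gene stays constant after normalization
        counts = pd.DataFrame(
            np.tile(np.arange(1, 21)[:, None] * 10, (1, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"t{t}r{r}" for t in range(3) for r in range(2)],
        )
        counts.iloc[19, 0] += 40  # one varying gene survives
        tps = pd.Series([f"t{t}" for t in range(3) for _ in range(2)],
                        index=counts.columns)
        ss = expression.standardize_series(counts, tps)
        assert "g0" in ss.dropped
        assert "g19" in ss.values.index

    def test_cohort_peaking_at_injected_timepoint(self, rng):
        # 800 stable background genes anchor the depth normalization;
        # the 200-gene cohort rises at t2 and returns at t3
        n_bg, n_coh, n_tp = 800, 200, 4
        traj = np.ones((n_bg + n_coh, n_tp))
        traj[n_bg:, 2] = 3.0
        counts, tps = self._counts(rng, traj)
        ss = expression.standardize_series(counts, tps)
        cohort = [f"g{i}" for i in range(n_bg, n_bg + n_coh) if f"g{i}" in ss.values.index]
        med = ss.values.loc[cohort].median(axis=0)
        assert med.idxmax() == "t2"

    def test_single_timepoint_rejected(self, rng):
        counts, tps = self._counts(rng, np.ones((10, 1)))
        with pytest.raises(ValueError):
            expression.standardize_series(counts, tps)


class TestHalfLifeBinning:
    def test_equal_bins_of_ten(self, rng):
        # uniform log half-lives: nothing beyond 2 SD, so all 100 genes bin
        s = expression.half_life_binning(
            pd.Series(rng.normal(size=100)), pd.Series(2 ** rng.uniform(1, 4, 100))
        )
        assert s.bins["n"].tolist() == [10] * 10

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            expression.half_life_binning(
                pd.Series(rng.normal(size=5)), pd.Series(rng.lognormal(2, 0.5, 5))
            )

    def test_extreme_half_lives_excluded(self, rng):
        lfc = pd.Series(rng.normal(size=101))
        hl = pd.Series(np.r_[rng.lognormal(2, 0.3, 100), 1e9])
        s = expression.half_life_binning(lfc, hl)
        assert s.n_excluded >= 1
        assert s.n_genes <= 100

    def test_null_rarely_rejects(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            lfc = pd.Series(rng.normal(size=100))
            hl = pd.Series(rng.lognormal(2, 0.5, 100))
            s = expression.half_life_binning(lfc, hl)
            rejections += s.p < 0.05
        assert rejections / n_rep <= 0.10

    def test_positive_dependence_detected(self, rng):
        hl = rng.lognormal(2, 0.8, 300)
        lfc = 0.5 * np.log2(hl) + rng.normal(0, 0.3, 300)
        s = expression.half_life_binning(pd.Series(lfc), pd.Series(hl))
        assert s.r > 0
        assert s.p < 0.05


class TestNkScatterClasses:
    def test_identical_results_give_r_one_no_exclusive_classes(self, rng, nb_table):
        counts = nb_table(rng, 100, 12)
        de = expression.nb_wald_de(counts, [f"s{j}" for j in range(6)],
                                   [f"s{j}" for j in range(6, 12)])
        _, summary = expression.nk_scatter_classes(de, de)
        assert summary["pearson_r"] == pytest.approx(1.0)
        assert summary["counts"].get("nucleus_only", 0) == 0
        assert summary["counts"].get("cytoplasm_only", 0) == 0

    def test_base_mean_filter_applied(self, rng, nb_table):
        counts = nb_table(rng, 100, 12, mean_range=(5, 20))
        de = expression.nb_wald_de(counts, [f"s{j}" for j in range(6)],
                                   [f"s{j}" for j in range(6, 12)])
        table, summary = expression.nk_scatter_classes(de, de, base_mean_min=30)
        assert (de.table.loc[table.index, "base_mean"] >= 30).all()

    def test_independent_nulls_give_small_correlation(self, rng, nb_table):
        hits = 0
        for _ in range(10):
            groups = ([f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)])
            d1 = expression.nb_wald_de(nb_table(rng, 1000, 12), *groups)
            d2 = expression.nb_wald_de(nb_table(rng, 1000, 12), *groups)
            _, summary = expression.nk_scatter_classes(d1, d2)
            hits += abs(summary["pearson_r"]) < 0.1
        assert hits >= 9
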