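"""Normalization, filtering, and QC."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribolens import preprocess
from ribolens.preprocess import (
    batch_adjust,
    compute_cpm,
    detect_outliers,
    filter_low_abundance,
    log2_cpm,
    pca,
    tmm_factors,
)


def _random_counts(rng, n_genes=60, n_samples=6, mean=200):
    cols = [f"s{i}" for i in range(n_samples)]
    return pd.DataFrame(
        rng.negative_binomial(5, 5 / (5 + mean), size=(n_genes, n_samples)),
        columns=cols,
        index=[f"g{i}" for i in range(n_genes)],
    )


class TestCpm:
    def test_simple_value(self):
        counts = pd.DataFrame({"a": [10, 10**6 - 10]})
        assert compute_cpm(counts).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_is_zero(self, rng):
        counts = _random_counts(rng)
        counts.iloc[0, 0] = 0
        assert compute_cpm(counts).iloc[0, 0] == 0.0

    def test_matches_elementwise_oracle(self, rng):
        counts = _random_counts(rng, 50, 6)
        cpm = compute_cpm(counts)
        lib = counts.sum(axis=0)
        for g in range(0, 50, 7):
            for s in range(6):
                assert cpm.iloc[g, s] == pytest.approx(
                    counts.iloc[g, s] / lib.iloc[s] * 1e6
                )

    def test_column_sums_to_million(self, rng):
        cpm = compute_cpm(_random_counts(rng))
        assert np.allclose(cpm.sum(axis=0), 1e6, atol=1e-6)

    def test_all_zero_sample_rejected(self, rng):
        counts = _random_counts(rng)
        counts["s0"] = 0
        with pytest.raises(ValueError, match="all-zero"):
            compute_cpm(counts)


class TestFilter:
    def _pair(self, rng, lib=8_000_000, n_genes=40):
        def mat(tag):
            cols = [f"{tag}{i}" for i in range(5)]
            x = rng.multinomial(lib, np.ones(n_genes) / n_genes, size=5).T
            return pd.DataFrame(x, columns=cols, index=[f"g{i}" for i in range(n_genes)])

        return mat("t"), mat("p")

    def test_threshold_collapses_at_nominal_depth(self):
        # every library exactly 8e6 reads -> N = 1 CPM
        genes = [f"g{i}" for i in range(4)]
        t = pd.DataFrame(2_000_000, index=genes, columns=[f"t{i}" for i in range(4)])
        p = pd.DataFrame(2_000_000, index=genes, columns=[f"p{i}" for i in range(4)])
        _, n_thr = filter_low_abundance(t, p)
        assert n_thr == pytest.approx(1.0)

    def test_boundary_is_inclusive(self):
        genes = ["g0", "g1"]
        lib = 8_000_000
        # g0 sits exactly at CPM = N = 1 in 4 total samples; g1 below
        t = pd.DataFrame(
            {f"t{i}": [8, lib - 8] for i in range(4)}, index=genes
        )
        p = pd.DataFrame({f"p{i}": [0, lib] for i in range(4)}, index=genes)
        kept, n_thr = filter_low_abundance(t, p)
        assert n_thr == pytest.approx(1.0)
        assert "g0" in kept and "g1" in kept  # g1 carries whole library

    def test_matches_brute_force(self, rng):
        t, p = self._pair(rng)
        kept, n_thr = filter_low_abundance(t, p, min_samples=4)
        cpm_t, cpm_p = compute_cpm(t), compute_cpm(p)
        for g in t.index:
            expected = ((cpm_t.loc[g] >= n_thr).sum() >= 4) or (
                (cpm_p.loc[g] >= n_thr).sum() >= 4
            )
            assert (g in kept) == expected

    @given(st.integers(0, 39), st.integers(1, 500))
    @settings(max_examples=20)
    def test_monotone_in_counts(self, gene_idx, extra):
        rng = np.random.default_rng(7)
        t, p = self._pair(rng)
        kept, _ = filter_low_abundance(t, p)
        gene = t.index[gene_idx]
        if gene in kept:
            t2 = t.copy()
            t2.loc[gene] += extra
            kept2, _ = filter_low_abundance(t2, p)
            assert gene in kept2


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_absorbed(self, rng):
        a = rng.integers(10, 1000, size=300)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_depth_rescaling_invariance(self, rng):
        counts = _random_counts(rng, 300, 4)
        f1 = tmm_factors(counts)
        scaled = counts.copy()
        scaled["s1"] = counts["s1"] * 5
        f2 = tmm_factors(scaled)
        # M values are depth-free; only precision weights see the depth
        assert np.allclose(f1, f2, atol=0.02)

    def test_composition_shift_matches_edger(self, rng):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        counts = _random_counts(rng, 400, 5, mean=500)
        counts.iloc[:40, 2] *= 8  # composition shift in one sample
        path = "/tmp/ribolens_tmm_test.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            "suppressMessages(library(edgeR));"
            'cat(paste(calcNormFactors(x, method="TMM"), collapse=","))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.allclose(tmm_factors(counts).to_numpy(), reference, atol=1e-10)

    def test_geometric_mean_is_one(self, rng):
        f = tmm_factors(_random_counts(rng, 200, 6))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)


class TestOutliers:
    def _labels(self, cols):
        return pd.Series("total", index=cols)

    def test_planted_outlier_flagged(self, rng):
        base = rng.normal(5, 1, size=400)
        cols = {f"s{i}": base + rng.normal(0, 0.05, 400) for i in range(7)}
        cols["bad"] = rng.normal(5, 1, size=400)  # unrelated sample
        x = pd.DataFrame(cols)
        assert detect_outliers(x, self._labels(x.columns)) == ["bad"]

    def test_identical_samples_no_flags(self, rng):
        # 4 byte-identical samples: IQR = 0 and nothing falls below Q1
        v = rng.normal(0, 1, 50)
        x = pd.DataFrame({f"s{i}": v for i in range(4)})
        assert detect_outliers(x, self._labels(x.columns)) == []

    def test_scale_free(self, rng):
        x = pd.DataFrame(rng.normal(size=(200, 8)), columns=[f"s{i}" for i in range(8)])
        f1 = detect_outliers(x, self._labels(x.columns))
        f2 = detect_outliers(x + 100.0, self._labels(x.columns))
        assert f1 == f2

    def test_constant_sample_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        x["a"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            detect_outliers(x, self._labels(x.columns))

    def test_false_positive_rate_under_null(self):
        """Clean simulated replicates: flags are rare (1.5 IQR normal
        reference rate ~0.35%/sample; allow generous Monte-Carlo slack)."""
        from ribolens.synthetic import StudyDesign, simulate_experiment

        total_flags = total_samples = 0
        for rep in range(10):
            expt, _ = simulate_experiment(
                StudyDesign(), n_genes=300, batch_effect_sd=0.0, seed=100 + rep
            )
            lc = log2_cpm(expt.counts)
            total_flags += len(detect_outliers(lc, expt.samples["fraction"]))
            total_samples += expt.counts.shape[1]
        assert total_flags / total_samples <= 0.03

    def test_planted_outlier_in_simulation(self):
        from ribolens.synthetic import StudyDesign, simulate_experiment

        expt, _ = simulate_experiment(
            StudyDesign(), n_genes=400, outlier_samples=("m03_T",), seed=5
        )
        lc = log2_cpm(expt.counts)
        assert "m03_T" in detect_outliers(lc, expt.samples["fraction"])


class TestBatchAdjust:
    def _frame(self, rng, n=2000, delta=0.0):
        cols = [f"s{i}" for i in range(12)]
        age = pd.Series([3] * 6 + [20] * 6, index=cols)
        batch = pd.Series(["b0", "b1"] * 6, index=cols)
        y = pd.DataFrame(rng.normal(5, 1, size=(n, 12)), columns=cols)
        y.loc[:, (batch == "b1").to_numpy()] += delta
        return y, batch, age

    def test_null_is_near_identity(self, rng):
        y, batch, age = self._frame(rng)
        adj = batch_adjust(y, batch, age)
        assert (adj - y).abs().to_numpy().max() < 0.1

    def test_planted_offset_removed(self, rng):
        y, batch, age = self._frame(rng, delta=2.0)
        adj = batch_adjust(y, batch, age)
        diff = (
            adj.loc[:, (batch == "b1").to_numpy()].mean(axis=1)
            - adj.loc[:, (batch == "b0").to_numpy()].mean(axis=1)
        )
        assert abs(diff.mean()) < 0.05

    def test_single_batch_identity(self, rng):
        y, _, age = self._frame(rng)
        batch = pd.Series("b0", index=y.columns)
        assert batch_adjust(y, batch, age).equals(y)

    def test_confounded_design_refused(self, rng):
        y, _, age = self._frame(rng)
        batch = pd.Series(["b0"] * 6 + ["b1"] * 6, index=y.columns)  # == age
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust(y, batch, age)


class TestPca:
    def test_variance_fractions_sum_to_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(100, 8)))
        _, var_frac = pca(x)
        assert var_frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_clusters_separate_on_pc1(self, rng):
        cols = [f"s{i}" for i in range(8)]
        x = pd.DataFrame(rng.normal(size=(300, 8)), columns=cols)
        x.iloc[:, 4:] += 5.0
        scores, _ = pca(x)
        pc1 = scores["PC1"]
        assert set(np.sign(pc1[:4])) != set(np.sign(pc1[4:])) or (
            pc1[:4].mean() * pc1[4:].mean() < 0
        )

    def test_duplicated_sample_identical_scores(self, rng):
        cols = [f"s{i}" for i in range(5)]
        x = pd.DataFrame(rng.normal(size=(50, 5)), columns=cols)
        x["s1"] = x["s0"]
        scores, _ = pca(x)
        assert np.allclose(scores.loc["s0"], scores.loc["s1"], atol=1e-9)
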