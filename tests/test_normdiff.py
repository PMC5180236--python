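"""Normalization and moderated differential model."""

import math
import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from eubflow import (AbundanceTable, DataError, call_differential,
                     compute_tmm_factors, fit_moderated, normalize, to_log_cpm,
                     voom_weights)
from eubflow.normdiff import fit_scaled_f_prior


def tmm_oracle_pair(obs, ref, logratio_trim=0.3, sum_trim=0.05):
    """Straight-line trimmed weighted mean of M-values for one library pair."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep0 = (obs > 0) & (ref > 0)
    o, r = obs[keep0], ref[keep0]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m, hi_m = math.floor(n * logratio_trim) + 1, n - math.floor(n * logratio_trim)
    lo_a, hi_a = math.floor(n * sum_trim) + 1, n - math.floor(n * sum_trim)
    order_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    order_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    sel = (order_m >= lo_m) & (order_m <= hi_m) & (order_a >= lo_a) & (order_a <= hi_a)
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return 2.0 ** f


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 15, 2], "b": [5, 10, 15, 2]})
        f = compute_tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_proportional_samples_absorbed_by_library_size(self):
        counts = pd.DataFrame({"a": [5, 10, 15, 2, 7], "b": [15, 30, 45, 6, 21]})
        f = compute_tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-8)

    def test_matches_straight_line_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(5, 2)) + np.array([[0, 0]] * 4 + [[5000, 100]]),
            columns=["a", "b"],
        )
        f = compute_tmm_factors(counts, reference="a")
        raw = np.array([
            tmm_oracle_pair(counts["a"].to_numpy(float), counts["a"].to_numpy(float)),
            tmm_oracle_pair(counts["b"].to_numpy(float), counts["a"].to_numpy(float)),
        ])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-10)

    def test_matches_oracle_on_larger_random_matrix(self, rng):
        counts = pd.DataFrame(rng.integers(0, 300, size=(40, 4)),
                              columns=list("abcd"))
        counts += 1  # avoid all-zero rows dominating the trim edge cases
        f = compute_tmm_factors(counts, reference="c")
        raw = np.array([
            tmm_oracle_pair(counts[s].to_numpy(float), counts["c"].to_numpy(float))
            for s in counts.columns
        ])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-10)

    @given(st.integers(1, 50), st.integers(0, 3))
    def test_scale_invariance_unweighted(self, c, col):
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(rng.integers(1, 200, size=(30, 4)), columns=list("abcd"))
        base = compute_tmm_factors(counts, do_weighting=False)
        scaled = counts.copy()
        scaled.iloc[:, col] *= c
        f = compute_tmm_factors(scaled, do_weighting=False)
        assert np.allclose(f, base, atol=1e-8)

    def test_global_scaling_invariance_weighted(self, rng):
        counts = pd.DataFrame(rng.integers(1, 200, size=(30, 4)), columns=list("abcd"))
        base = compute_tmm_factors(counts)
        f = compute_tmm_factors(counts * 3)
        assert np.allclose(f, base, atol=1e-8)

    def test_all_zero_sample_is_an_error_naming_it(self):
        counts = pd.DataFrame({"ok": [1, 2], "dead": [0, 0]})
        with pytest.raises(DataError, match="dead"):
            compute_tmm_factors(counts)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, size=(50, 6)))
        f = compute_tmm_factors(counts + 1)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_matches_edger_reference_implementation(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the edgeR cross-check")
        counts = pd.DataFrame(rng.integers(0, 400, size=(60, 5)) + 1,
                              columns=[f"s{i}" for i in range(5)])
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'f <- calcNormFactors(DGEList(counts=x), method="TMM")$samples$norm.factors;'
            'cat(sprintf("%.12f", f), sep="\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        f = compute_tmm_factors(counts)
        assert np.allclose(f.to_numpy(), ref, atol=1e-6)


class TestLogCpm:
    def test_zero_count_closed_form(self):
        # zero count, prior 0.5, library 1e6, factor 1 -> log2(0.5) up to
        # the prior's library adjustment, which is O(prior/L)
        counts = pd.DataFrame({"s": [0, 10 ** 6]})
        out = to_log_cpm(counts, prior_count=0.5)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-5)

    def test_monotone_in_count(self):
        counts = pd.DataFrame({"s": [3, 100, 50], "t": [3, 100, 50]})
        bumped = counts.copy()
        bumped.loc[0, "s"] = 6
        lo = to_log_cpm(counts).iloc[0, 0]
        hi = to_log_cpm(bumped).iloc[0, 0]
        assert hi > lo

    def test_equal_counts_equal_logcpm(self):
        counts = pd.DataFrame({"a": [7, 7, 7], "b": [7, 7, 7]})
        out = to_log_cpm(counts)
        assert np.allclose(out.to_numpy(), out.iloc[0, 0])


class TestModeratedFit:
    def _matrix(self, rng, n_feat=50, n1=4, n2=4, delta=0.0):
        y = rng.normal(5.0, 1.0, size=(n_feat, n1 + n2))
        y[:, :n1] += delta
        cols = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
        labels = pd.Series(["g1"] * n1 + ["g2"] * n2, index=cols)
        return pd.DataFrame(y, columns=cols), labels

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        y, labels = self._matrix(rng)
        res = fit_moderated(y, labels, groups=("g1", "g2"), prior_df=0)
        t_ref, p_ref = stats.ttest_ind(y.iloc[:, :4], y.iloc[:, 4:], axis=1)
        assert np.allclose(res.table["t"], t_ref, atol=1e-10)
        assert np.allclose(res.table["p"], p_ref, atol=1e-10)

    def test_logfc_is_difference_of_group_means(self):
        y = pd.DataFrame([[5.0, 5.0, 3.0, 3.0]] * 3 + [[4.0, 6.0, 2.0, 4.0]],
                         columns=["a1", "a2", "b1", "b2"])
        labels = pd.Series(["A", "A", "B", "B"], index=y.columns)
        res = fit_moderated(y, labels, groups=("A", "B"))
        assert res.table["logFC"].iloc[0] == pytest.approx(2.0)
        assert res.table["logFC"].iloc[3] == pytest.approx(2.0)

    def test_label_swap_flips_logfc_keeps_p(self, rng):
        y, labels = self._matrix(rng, delta=1.0)
        a = fit_moderated(y, labels, groups=("g1", "g2"))
        b = fit_moderated(y, labels, groups=("g2", "g1"))
        assert np.allclose(a.table["logFC"], -b.table["logFC"])
        assert np.allclose(a.table["p"], b.table["p"])

    def test_shared_variance_moderation_approaches_ordinary_t(self, rng):
        # all features share one true variance -> estimated prior df is large
        # and the moderated t tracks the ordinary t closely once per-feature
        # variance estimates are themselves stable
        y, labels = self._matrix(rng, n_feat=500, n1=16, n2=16)
        res = fit_moderated(y, labels)
        t_ref = stats.ttest_ind(y.iloc[:, :16], y.iloc[:, 16:], axis=1).statistic
        assert res.prior_df > 10
        corr = np.corrcoef(res.table["t"], t_ref)[0, 1]
        assert corr > 0.98
        ratio = np.median(np.abs(res.table["t"].to_numpy() / t_ref))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_constant_feature_handled_by_moderation(self, rng):
        y, labels = self._matrix(rng, n_feat=20)
        y.iloc[0] = 3.14
        res = fit_moderated(y, labels)
        assert np.isfinite(res.table["t"].iloc[0])
        assert res.table["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_too_small_group_is_an_error(self, rng):
        y, _ = self._matrix(rng, n1=1, n2=4)
        labels = pd.Series(["g1"] + ["g2"] * 4, index=y.columns)
        with pytest.raises(DataError, match="2 samples"):
            fit_moderated(y, labels, groups=("g1", "g2"))

    def test_matches_limma_reference_implementation(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        y, labels = self._matrix(rng, n_feat=80, delta=0.5)
        path = tmp_path / "y.tsv"
        y.to_csv(path, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma));'
            f'y <- as.matrix(read.delim("{path}", row.names=1));'
            'design <- cbind(1, c(rep(1,4), rep(0,4)));'
            'fit <- eBayes(lmFit(y, design));'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior);'
            f'write.table(format(out, digits=15), "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
        )
        run = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert run.returncode == 0, run.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = fit_moderated(y, labels, groups=("g1", "g2"))
        assert res.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.prior_var == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        assert np.allclose(res.table["t"], ref["t"], rtol=1e-4)
        assert np.allclose(res.table["p"], ref["p"], rtol=1e-4)

    def test_prior_estimator_on_known_f_distribution(self, rng):
        # variances drawn from s0^2 * F(df, d0) should recover (d0, s0^2)
        d0_true, s20_true, df = 8.0, 2.0, 6.0
        s2 = s20_true * rng.f(df, d0_true, size=20000)
        d0, s20 = fit_scaled_f_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s20 == pytest.approx(s20_true, rel=0.05)


class TestCalling:
    def _result(self, logfc, p):
        from eubflow.normdiff import DiffResult

        table = pd.DataFrame({"logFC": logfc, "AveExpr": 0.0, "t": 0.0, "p": p,
                              "p_adj": p, "flag": False},
                             index=[f"f{i}" for i in range(len(logfc))])
        return DiffResult(table, ("a", "b"), 0, 0, 1)

    def test_flag_definition(self):
        res = self._result([np.log2(2.5), np.log2(2.5), np.log2(1.5)],
                           [0.01, 0.2, 0.01])
        flagged = call_differential(res)
        assert list(flagged) == ["f0"]

    def test_boundary_is_strict(self):
        res = self._result([1.0, 1.0 + 1e-9], [0.05, 0.049])
        assert list(call_differential(res)) == ["f1"]

    def test_voom_weights_positive_and_fit_runs(self, sim_config):
        from eubflow import simulate_microbiome

        table, _ = simulate_microbiome(sim_config)
        sub = table.filter(arms=["T"])
        norm = normalize(sub)
        w = voom_weights(sub.counts, norm.factors, sub.metadata["timepoint"])
        assert (w.to_numpy() > 0).all()
        res = fit_moderated(norm.log_cpm, sub.metadata["timepoint"],
                            groups=("A", "B"), weights=w)
        assert np.isfinite(res.table["t"]).all()


class TestAbundanceTableValidation:
    def test_duplicate_feature_ids_rejected(self, small_table):
        counts = small_table.counts.copy()
        counts.index = ["g"] * len(counts)
        with pytest.raises(DataError, match="duplicate feature"):
            AbundanceTable(counts, small_table.metadata)

    def test_missing_metadata_rejected(self, small_table):
        with pytest.raises(DataError, match="without metadata"):
            AbundanceTable(small_table.counts, small_table.metadata.iloc[:3])

    def test_permutation_invariance_of_normalization(self, small_table, rng):
        norm = normalize(small_table)
        perm = rng.permutation(len(small_table.features))
        shuffled = AbundanceTable(small_table.counts.iloc[perm],
                                  small_table.metadata)
        norm2 = normalize(shuffled)
        assert np.allclose(norm.factors, norm2.factors)
        assert np.allclose(norm.log_cpm.iloc[perm].to_numpy(),
                           norm2.log_cpm.to_numpy())
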