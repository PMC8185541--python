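"""Proteomics preprocessing chain and moderated differential abundance,
checked against brute-force oracles and limma's eBayes."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assert_within_3se
from ehtphysio import (AbundanceMatrix, FilterRule, ProteomicsSimParams,
                       bh_adjust, differential_abundance_pipeline,
                       filter_missing, knn_impute, log2_transform,
                       moderated_ttest, normalize_abundance, pca_retain,
                       simulate_proteomics)
from oracles import (bh_stepup, filter_rule_oracle, knn_impute_oracle,
                     pca_retained_oracle, pooled_t_oracle)


def make_matrix(X, n1=12, n2=10, log_scale=False):
    n, m = X.shape
    assert m == n1 + n2
    cols = [f"s{i:02d}" for i in range(m)]
    return AbundanceMatrix(
        pd.DataFrame(X, index=[f"P{i:04d}" for i in range(n)], columns=cols),
        pd.Series(["g1"] * n1 + ["g2"] * n2, index=cols, name="group"),
        log_scale=log_scale,
    )


class TestNormalize:
    def test_equal_totals_and_grand_mean_100(self):
        X = np.array([[50.0, 100.0], [150.0, 300.0]])
        am = make_matrix(X, n1=1, n2=1)
        # two samples, two proteins each; totals 200 and 400
        out = normalize_abundance(am)
        v = out.data.to_numpy()
        assert np.allclose(v.sum(axis=0)[0], v.sum(axis=0)[1])
        assert np.nanmean(v) == pytest.approx(100.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(3, 1, (50, 22))
        X[rng.random((50, 22)) < 0.1] = np.nan
        once = normalize_abundance(make_matrix(X))
        twice = normalize_abundance(once)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(),
                           equal_nan=True)

    def test_random_matrix_grand_mean(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(2, 2, (50, 22))
        out = normalize_abundance(make_matrix(X))
        assert np.nanmean(out.data.to_numpy()) == pytest.approx(100.0,
                                                                abs=1e-9)

    def test_all_missing_sample_named_in_error(self):
        X = np.ones((5, 22))
        X[:, 3] = np.nan
        with pytest.raises(ValueError, match="s03"):
            normalize_abundance(make_matrix(X))


class TestFilterMissing:
    def test_exhaustive_truth_table_12_10(self):
        """Every per-group missingness pattern (m1, m2) in 0..12 x 0..10
        agrees with a literal transcription of the filtering rule."""
        patterns = [(m1, m2) for m1 in range(13) for m2 in range(11)
                    if (m1, m2) != (12, 10)]
        rows = []
        for m1, m2 in patterns:
            row = np.ones(22)
            row[:m1] = np.nan
            row[12:12 + m2] = np.nan
            rows.append(row)
        am = make_matrix(np.array(rows))
        out, status = filter_missing(am, FilterRule())
        for (m1, m2), pid in zip(patterns, am.data.index):
            assert status[pid] == filter_rule_oracle(m1, m2), (m1, m2)

    def test_presence_absence_protein_zero_imputed(self):
        """Missing 10/10 in group 2, 0/12 in group 1 (overall 45 % > 30 %):
        kept with zeros imputed in group 2."""
        row = np.ones(22)
        row[12:] = np.nan
        am = make_matrix(row[None, :])
        out, status = filter_missing(am)
        assert status.iloc[0] == "kept_zero_imputed"
        v = out.data.iloc[0].to_numpy()
        assert np.all(v[:12] == 1.0) and np.all(v[12:] == 0.0)

    def test_moderate_missingness_dropped(self):
        row = np.ones(22)
        row[:5] = np.nan          # 5/12 missing in group 1
        row[12:16] = np.nan       # 4/10 missing in group 2
        _, status = filter_missing(make_matrix(row[None, :]))
        assert status.iloc[0] == "dropped"

    def test_complete_protein_kept_unchanged(self):
        am = make_matrix(np.ones((1, 22)))
        out, status = filter_missing(am)
        assert status.iloc[0] == "kept"
        assert out.data.equals(am.data)


class TestKNNImpute:
    def test_identical_neighbours_supply_their_value(self):
        X = np.tile(np.linspace(1, 6, 6), (5, 1))
        X[0, 2] = np.nan
        out = knn_impute(make_matrix(X, n1=3, n2=3), k=3)
        assert out.data.iloc[0, 2] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(10, 2, (10, 6))
        X[rng.random((10, 6)) < 0.1] = np.nan
        X[np.isnan(X).all(axis=1)] = 1.0  # keep every row imputable
        got = knn_impute(make_matrix(X, n1=3, n2=3), k=3).data.to_numpy()
        want = knn_impute_oracle(X, 3)
        assert np.allclose(got, want)

    def test_no_missing_returned_unchanged(self):
        X = np.arange(60.0).reshape(10, 6)
        am = make_matrix(X, n1=3, n2=3)
        assert knn_impute(am, k=3).data.equals(am.data)

    @pytest.mark.parametrize("k", [0, 10])
    def test_bad_k_errors(self, k):
        X = np.ones((10, 6))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="k must"):
            knn_impute(make_matrix(X, n1=3, n2=3), k=k)


class TestLog2Transform:
    def test_zero_maps_to_zero_at_unit_pseudocount(self):
        out = log2_transform(make_matrix(np.zeros((2, 22))), pseudocount=1.0)
        assert np.all(out.data.to_numpy() == 0.0)

    def test_closed_form(self):
        out = log2_transform(make_matrix(np.full((1, 22), 99.0)))
        assert out.data.iloc[0, 0] == pytest.approx(np.log2(100.0))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(1e-6, 10))
    def test_monotone_for_any_pseudocount(self, a, b, pc):
        fa = np.log2(a + pc)
        fb = np.log2(b + pc)
        assert (a <= b) == (fa <= fb)

    def test_negative_value_errors(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(
                make_matrix(-np.ones((1, 22)), log_scale=True))


class TestBHAdjust:
    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_stepup_oracle_and_bounds(self, p):
        got = bh_adjust(p)
        assert np.allclose(got, bh_stepup(p), atol=1e-12)
        assert np.all(got >= np.asarray(p) - 1e-12)
        assert np.all(got <= 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeratedTTest:
    def _simulate_log2(self, seed, n=500, sd_spread=True):
        rng = np.random.default_rng(seed)
        if sd_spread:
            sd = np.sqrt(0.2 * 8 / rng.chisquare(8, n))
        else:
            sd = np.full(n, 0.5)
        X = rng.normal(8, 1, (n, 1)) + rng.normal(0, 1, (n, 22)) * sd[:, None]
        return make_matrix(X, log_scale=True)

    def test_matches_limma_ebayes(self, tmp_path):
        """The shrinkage prior, moderated t and p-values agree with
        Bioconductor limma's eBayes on the same matrix."""
        am = self._simulate_log2(123)
        mat = tmp_path / "mat.tsv"
        am.data.to_csv(mat, sep="\t")
        out = tmp_path / "limma.tsv"
        rscript = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{mat}", row.names=1))
        design <- cbind(Intercept=1, grp=c(rep(0,12), rep(1,10)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
        out$df_prior <- fit$df.prior; out$s2_prior <- fit$s2.prior
        write.table(out, "{out}", sep="\\t", quote=FALSE)
        """
        script = tmp_path / "cmp.R"
        script.write_text(rscript)
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        lm = pd.read_csv(out, sep="\t")
        res = moderated_ttest(am)
        assert res.df_prior == pytest.approx(lm["df_prior"].iloc[0],
                                             rel=1e-5)
        assert res.s2_prior == pytest.approx(lm["s2_prior"].iloc[0],
                                             rel=1e-5)
        assert np.allclose(res.table["moderated_t"], lm["t"], rtol=1e-8)
        assert np.allclose(res.table["p_value"], lm["p"], rtol=1e-6,
                           atol=1e-12)

    def test_shrinkage_fixed_point(self):
        """For the protein whose sample variance equals the prior, the
        moderated t coincides with the ordinary pooled t."""
        am = self._simulate_log2(7)
        res = moderated_ttest(am)
        X = am.data.to_numpy()
        s2 = (X[:, :12].var(axis=1, ddof=1) * 11
              + X[:, 12:].var(axis=1, ddof=1) * 9) / 20
        i = int(np.argmin(np.abs(s2 - res.s2_prior)))
        t_ord = pooled_t_oracle(X[i, :12], X[i, 12:])
        assert res.table["moderated_t"].iloc[i] == pytest.approx(t_ord,
                                                                 rel=5e-3)

    def test_null_type_I_error_small(self):
        """Null matrices: fraction of p < 0.05 within 3 SE of 0.05."""
        fracs = [ (moderated_ttest(self._simulate_log2(seed, n=800))
                   .table["p_value"] < 0.05).mean() for seed in range(30) ]
        assert_within_3se(fracs, 0.05, "type-I error")

    def test_planted_effect_recovery(self):
        """Planted |log2FC| = 1 at residual sd 0.5: mean signed estimate
        within 3 SE of 1 and near-perfect ranking (AUC > 0.9)."""
        means, aucs = [], []
        for seed in range(10):
            am, gt = simulate_proteomics(ProteomicsSimParams(
                n_proteins=1000, dropout_intercept=-50.0,
                group_dropout_fraction=0.0, seed=seed))
            logged = make_matrix(gt.latent_log2, log_scale=True)
            res = moderated_ttest(logged)
            fc = res.table["log2_fc"].to_numpy()
            sign = np.sign(gt.true_log2fc)
            means.append((fc[gt.de_mask] * sign[gt.de_mask]).mean())
            p = res.table["p_value"].to_numpy()
            from sklearn.metrics import roc_auc_score
            aucs.append(roc_auc_score(gt.de_mask, -np.log10(p)))
        assert_within_3se(means, 1.0, "planted log2 FC")
        assert np.mean(aucs) > 0.9

    def test_all_zero_variance_errors(self):
        am = make_matrix(np.ones((5, 22)), log_scale=True)
        with pytest.raises(ValueError, match="zero variance"):
            moderated_ttest(am)

    def test_missing_values_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 22))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            moderated_ttest(make_matrix(X, log_scale=True))


class TestPCARetain:
    def test_exact_2d_subspace(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 22))
        X = rng.normal(size=(100, 2)) @ basis
        res = pca_retain(make_matrix(X, log_scale=True).data, 0.90)
        assert res.n_retained == 2
        assert np.cumsum(res.variance_fractions)[1] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        res = pca_retain(pd.DataFrame(rng.normal(size=(200, 22))), 0.90)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 22))
        res = pca_retain(pd.DataFrame(X), 0.90)
        assert res.n_retained == pca_retained_oracle(X, 0.90)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_retain(pd.DataFrame(np.ones((5, 2))), 0.9)


class TestEndToEnd:
    def test_pipeline_statuses_and_columns(self):
        am, gt = simulate_proteomics(ProteomicsSimParams(n_proteins=600,
                                                         seed=1))
        res = differential_abundance_pipeline(am)
        tab = res.table
        assert set(tab["filter_status"].unique()) <= {
            "kept", "dropped", "kept_zero_imputed"}
        dropped = tab["filter_status"] == "dropped"
        assert tab.loc[dropped, "p_value"].isna().all()
        kept = tab.dropna(subset=["p_value"])
        assert ((kept["bh_adjusted_p"] >= kept["p_value"] - 1e-12).all())

    def test_empirical_fdr_controlled(self):
        """Realized FDR of BH at 0.05 stays below 0.10 on average across
        simulated matrices (planted shifts and presence/absence proteins
        both count as true positives)."""
        fdrs = []
        for seed in range(25):
            am, gt = simulate_proteomics(ProteomicsSimParams(seed=seed))
            res = differential_abundance_pipeline(am)
            kept = res.table.dropna(subset=["p_value"])
            idx = np.array([int(i[1:]) for i in kept.index])
            truth = gt.de_mask[idx] | gt.group_dropout_mask[idx]
            sig = (kept["bh_adjusted_p"] < 0.05).to_numpy()
            fdrs.append((sig & ~truth).sum() / max(sig.sum(), 1))
        assert np.mean(fdrs) <= 0.10
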