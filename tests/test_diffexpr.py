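import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ftx import diffexpr, simulate
from ftx.errors import DomainError


def frame(rows, genes=None, samples=None):
    rows = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestCountMatrix:
    def test_rejects_negative(self):
        with pytest.raises(DomainError, match="negative count"):
            diffexpr.CountMatrix(frame([[1, -2]]))

    def test_rejects_non_integer(self):
        with pytest.raises(DomainError, match="non-integer"):
            diffexpr.CountMatrix(frame([[1.5, 2.0]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(DomainError, match="duplicate gene"):
            diffexpr.CountMatrix(frame([[1, 2], [3, 4]], genes=["g1", "g1"]))


class TestSizeFactors:
    def test_hand_example(self):
        sf = diffexpr.size_factors(frame([[2, 4], [6, 12], [10, 20]]))
        assert sf.iloc[0] == pytest.approx(0.7071, abs=1e-4)
        assert sf.iloc[1] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_samples(self):
        sf = diffexpr.size_factors(frame([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(sf, 1.0)

    def test_homogeneity(self, rng):
        """Scaling one sample by c multiplies its factor by c, relative to the rest."""
        counts = rng.poisson(30, size=(50, 4)) + 1
        base = diffexpr.size_factors(frame(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 3
        out = diffexpr.size_factors(frame(scaled))
        assert out.iloc[2] / out.iloc[0] == pytest.approx(3 * base.iloc[2] / base.iloc[0], rel=1e-10)
        assert out.iloc[1] / out.iloc[0] == pytest.approx(base.iloc[1] / base.iloc[0], rel=1e-10)

    def test_no_all_positive_gene(self):
        with pytest.raises(DomainError):
            diffexpr.size_factors(frame([[0, 1], [1, 0]]))


class TestBhAdjust:
    def test_hand_step_up(self):
        out = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single(self):
        assert diffexpr.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_monotone_on_sorted(self, rng):
        p = np.sort(rng.random(50))
        out = diffexpr.bh_adjust(p)
        assert (np.diff(out) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            diffexpr.bh_adjust([0.5, 1.2])

    @staticmethod
    def brute_force(p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        out_sorted = [min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)]
        out = np.empty(m)
        out[order] = out_sorted
        return out

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_brute_force(self, pvals):
        assert np.allclose(diffexpr.bh_adjust(pvals), self.brute_force(pvals), atol=1e-12)


class TestDispersions:
    def test_poisson_gene_hits_floor(self, rng):
        counts = frame(rng.poisson(200, size=(300, 60)))
        sf = pd.Series(1.0, index=counts.columns)
        disp = diffexpr.estimate_dispersions(counts, sf)
        assert np.median(disp.alpha_mom) < 1e-2

    def test_constant_counts_floor(self):
        counts = frame(np.full((5, 6), 7))
        sf = pd.Series(1.0, index=counts.columns)
        disp = diffexpr.estimate_dispersions(counts, sf)
        assert (disp.alpha_mom == diffexpr.ALPHA_FLOOR).all()

    def test_parameter_recovery(self, rng):
        mu, alpha, n = 100.0, 0.1, 100
        size = 1 / alpha
        counts = frame(rng.negative_binomial(size, size / (size + mu), size=(400, n)))
        sf = pd.Series(1.0, index=counts.columns)
        groups = np.array(["a"] * 50 + ["b"] * 50)
        disp = diffexpr.estimate_dispersions(counts, sf, groups)
        assert 0.05 <= np.median(disp.alpha) <= 0.2

    def test_all_zero_gene_nan(self):
        counts = frame([[0, 0, 0, 0], [5, 6, 7, 8]])
        sf = pd.Series(1.0, index=counts.columns)
        disp = diffexpr.estimate_dispersions(counts, sf)
        assert np.isnan(disp.alpha.iloc[0])
        assert np.isfinite(disp.alpha.iloc[1])


class TestWald:
    def test_p_formula(self):
        # wald of 2.0 (e.g. log2fc 1.0, se 0.5) -> p = 2(1 - Phi(2)) = 0.0455
        assert 2 * stats.norm.sf(2.0) == pytest.approx(0.0455, abs=5e-5)

    def test_pvalues_match_wald_stat(self, contrast_28m):
        de = contrast_28m["de"].dropna(subset=["pval"])
        expected = 2 * stats.norm.sf(np.abs(de["wald"]))
        assert np.allclose(de["pval"], expected)

    def test_identical_groups_zero_lfc(self, rng):
        half = rng.poisson(80, size=(100, 4))
        counts = frame(np.hstack([half, half]))
        sf = pd.Series(1.0, index=counts.columns)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        disp = diffexpr.estimate_dispersions(counts, sf, groups)
        de = diffexpr.wald_test(counts, sf, disp, groups)
        assert np.allclose(de["log2fc"], 0.0, atol=1e-7)

    def test_padj_ge_pval(self, contrast_28m):
        de = contrast_28m["de"].dropna(subset=["pval"])
        assert (de["padj"] >= de["pval"] - 1e-12).all()

    def test_deg_flag_definition(self, contrast_28m):
        de = contrast_28m["de"]
        expected = (de["padj"] < 0.05) & (de["log2fc"].abs() >= 1.0) & np.isfinite(de["pval"])
        assert (de["is_deg"] == expected).all()

    def test_null_permutation_calibration(self, rng):
        cfg = simulate.SimulationConfig(seed=42, n_genes=1000, frac_de_24m=0.0, frac_de_28m=0.0,
                                        n_coupled=0, n_per_group=(8, 2, 8))
        fn, counts, meta, _ = simulate.simulate_study(cfg)
        sel = meta[meta["run"] == 2]
        labels = rng.permutation(sel["age_group"].to_numpy())
        c = diffexpr.CountMatrix(counts[sel.index])
        sf = diffexpr.size_factors(c)
        disp = diffexpr.estimate_dispersions(c, sf, labels)
        de = diffexpr.wald_test(c, sf, disp, labels)
        p = de["pval"].dropna()
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_scale_invariance(self, contrast_28m):
        counts = contrast_28m["counts"].frame.copy()
        counts.iloc[:, 0] *= 4
        c = diffexpr.CountMatrix(counts)
        sf = diffexpr.size_factors(c)
        groups = contrast_28m["meta"]["age_group"].to_numpy()
        disp = diffexpr.estimate_dispersions(c, sf, groups)
        de = diffexpr.wald_test(c, sf, disp, groups, reference="6m")
        base = contrast_28m["de"]
        both = np.isfinite(de["log2fc"]) & np.isfinite(base["log2fc"])
        diff = (de.loc[both, "log2fc"] - base.loc[both, "log2fc"]).abs()
        # normalization absorbs the constant exactly; the NB likelihood
        # re-weighting leaves only small count-level wobble
        assert diff.median() < 0.02
        assert diff[base.loc[both, "baseMean"] >= 20].max() < 0.1

    def test_requires_two_groups(self, contrast_28m):
        counts = contrast_28m["counts"]
        sf = contrast_28m["factors"]
        with pytest.raises(DomainError):
            diffexpr.wald_test(counts, sf, contrast_28m["disp"], np.repeat("a", counts.frame.shape[1]))


class TestNormalizedLog2:
    def test_values(self):
        counts = frame([[0, 7]])
        sf = pd.Series(1.0, index=counts.columns)
        norm = diffexpr.normalized_log2(counts, sf)
        assert norm.iloc[0, 0] == 0.0
        assert norm.iloc[0, 1] == pytest.approx(3.0)

    def test_monotone(self, rng):
        a = rng.integers(0, 100, size=(20, 3))
        counts = frame(a)
        sf = pd.Series([0.8, 1.0, 1.3], index=counts.columns)
        norm = diffexpr.normalized_log2(counts, sf)
        bumped = diffexpr.normalized_log2(frame(a + 1), sf)
        assert (bumped.to_numpy() > norm.to_numpy()).all()

    def test_rejects_nonpositive_factor(self):
        counts = frame([[1, 2]])
        with pytest.raises(DomainError):
            diffexpr.normalized_log2(counts, pd.Series([1.0, 0.0], index=counts.columns))


class TestPca:
    def test_identical_samples_zero_scores(self):
        counts = frame(np.tile([[10], [20], [5]], (1, 2)))
        sf = pd.Series(1.0, index=counts.columns)
        norm = diffexpr.normalized_log2(counts, sf)
        scores, pct = diffexpr.pca_scores(norm, n_components=1)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_group_separation(self, contrast_28m):
        scores, pct = diffexpr.pca_scores(contrast_28m["norm"])
        groups = contrast_28m["meta"]["age_group"]
        pc1 = scores["PC1"]
        mean_6m = pc1[groups == "6m"].mean()
        mean_28m = pc1[groups == "28m"].mean()
        spread = pc1.std()
        assert abs(mean_6m - mean_28m) > spread

    def test_percent_variance_bounded(self, contrast_28m):
        _, pct = diffexpr.pca_scores(contrast_28m["norm"], n_components=5)
        assert pct.sum() <= 100.0 + 1e-9
        assert (pct >= 0).all()

    def test_too_many_components(self, contrast_28m):
        with pytest.raises(DomainError):
            diffexpr.pca_scores(contrast_28m["norm"], n_components=1000)


class TestHeatmap:
    def test_z_rows_standardized_and_clipped(self, contrast_28m):
        z = diffexpr.top_z_heatmap_data(contrast_28m["norm"], contrast_28m["de"], k=10)
        assert (z.to_numpy() >= -3).all() and (z.to_numpy() <= 3).all()
        raw = contrast_28m["norm"].loc[z.index]
        recomputed = raw.sub(raw.mean(axis=1), axis=0).div(raw.std(axis=1, ddof=1), axis=0)
        unclipped = recomputed.abs() < 3
        assert np.allclose(z.to_numpy()[unclipped], recomputed.to_numpy()[unclipped])
        assert np.allclose(recomputed.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(recomputed.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_warns_when_k_exceeds_degs(self, contrast_28m):
        n_degs = int(contrast_28m["de"]["is_deg"].sum())
        with pytest.warns(UserWarning, match="DEGs"):
            z = diffexpr.top_z_heatmap_data(contrast_28m["norm"], contrast_28m["de"], k=n_degs + 50)
        assert len(z) <= n_degs


class TestFoldChange:
    def test_percent_of_baseline(self):
        assert diffexpr.truncate(diffexpr.fold_change_percent(3.599)) == 1211
        assert diffexpr.fold_change_percent(0.0) == pytest.approx(100.0)

    def test_fold_decline(self):
        assert diffexpr.truncate(diffexpr.fold_change(2.51), 2) == pytest.approx(5.69)

    def test_truncation_toward_zero(self):
        assert diffexpr.truncate(1.99) == 1
        assert diffexpr.truncate(-1.99) == -1
        assert diffexpr.truncate(5.699, 2) == 5.69

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            diffexpr.fold_change_percent(float("inf"))
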