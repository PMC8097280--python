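import numpy as np
import pandas as pd
import pytest

from paralogdissect.preprocess import (
    filter_genes,
    flag_outlier_samples,
    getmm_normalize,
    NormFactors,
    rpk,
    tmm_factors,
)


def _counts(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestFilterGenes:
    def test_rule_examples(self):
        counts = _counts(
            {
                "all_zero": [0] * 8,
                "sparse_low_median": [0, 0, 0, 0, 0, 0, 5, 5],  # 25% nonzero, median 0
                "all_twos": [2] * 8,
            }
        )
        kept = filter_genes(counts)
        assert list(kept.index) == ["all_twos"]

    def test_idempotent(self, null_experiment):
        counts, _, _ = null_experiment
        once = filter_genes(counts)
        twice = filter_genes(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_gene_order_irrelevant(self, null_experiment):
        counts, _, _ = null_experiment
        shuffled = counts.sample(frac=1, random_state=1)
        assert set(filter_genes(counts).index) == set(filter_genes(shuffled).index)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_genes(pd.DataFrame())


class TestRpk:
    @pytest.mark.parametrize(
        "count,length,expected", [(100, 2000, 50.0), (0, 1000, 0.0), (7, 500, 14.0)]
    )
    def test_arithmetic(self, count, length, expected):
        counts = pd.DataFrame({"s1": [count]}, index=["g"])
        lengths = pd.Series([length], index=["g"], dtype=float)
        assert rpk(counts, lengths).iloc[0, 0] == pytest.approx(expected)

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(ValueError, match="missing gene lengths"):
            rpk(counts, pd.Series([100.0], index=["other"]))


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=200).astype(float)
        mat = pd.DataFrame({f"s{i}": col for i in range(4)})
        nf = tmm_factors(mat)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_scaling_absorbed(self):
        # sample B = 4 x sample A: constant M, factor ratio 1 after
        # renormalization, and effective expression of B equals A
        rng = np.random.default_rng(1)
        a = rng.poisson(100, size=300).astype(float) + 1
        mat = pd.DataFrame({"A": a, "B": 4 * a})
        nf = tmm_factors(mat)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)
        eff = mat / (nf.lib_sizes * nf.factors)
        assert np.allclose(eff["A"], eff["B"])

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            rng.poisson(80, size=(250, 5)).astype(float) + 1,
            columns=list("ABCDE"),
        )
        nf1 = tmm_factors(mat)
        nf2 = tmm_factors(mat * 4.0)
        assert np.allclose(nf1.factors, nf2.factors)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.poisson(60, size=(200, 3)).astype(float) + 1, columns=list("ABC")
        )
        perm = rng.permutation(len(mat))
        assert np.allclose(tmm_factors(mat).factors, tmm_factors(mat.iloc[perm]).factors)

    def test_spike_genes_trimmed(self):
        # 1000 equal genes plus 10 strongly up in one sample: trimming
        # removes the spikes, so the factor stays within 1% of the
        # all-equal case; checked against an unweighted brute-force
        # trimmed mean computed here
        base = np.full(1010, 100.0)
        spiked = base.copy()
        spiked[:10] *= 50
        mat = pd.DataFrame({"A": base, "B": spiked, "C": base})
        nf = tmm_factors(mat, reference="A", weighted=False)
        # after TMM the base genes' effective expression is equalized:
        # the spike no longer deflates sample B's other genes
        eff = mat / (nf.lib_sizes * nf.factors)
        ratio = eff["B"].iloc[10:] / eff["A"].iloc[10:]
        assert np.allclose(ratio, ratio.iloc[0])
        assert abs(ratio.iloc[0] - 1.0) < 0.01

        # brute-force oracle for sample B vs A: double trim on M and A
        fo = spiked / spiked.sum()
        fr = base / base.sum()
        m = np.log2(fo / fr)
        a = 0.5 * np.log2(fo * fr)
        n = len(m)
        keep = np.ones(n, bool)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep &= (rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
        keep &= (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05))
        oracle_log_factor = m[keep].mean()
        got = np.log2(nf.factors["B"] / nf.factors["A"])
        assert got == pytest.approx(oracle_log_factor, abs=1e-9)

    def test_matches_edger_reference_values(self):
        # frozen oracle: Bioconductor edgeR::calcNormFactors on this exact
        # matrix (regenerated deterministically) returned these factors
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 5 / 205, size=(150, 4))
        counts[:10, 0] = counts[:10, 0] * 8
        mat = pd.DataFrame(counts.astype(float), columns=list("ABCD"))
        nf = tmm_factors(mat)
        expected = [0.8179571648, 1.0795411308, 1.0729717639, 1.0554604206]
        assert np.allclose(nf.factors.to_numpy(), expected, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        mat = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(ValueError, match="B"):
            tmm_factors(mat)


class TestGetmmNormalize:
    def test_single_gene_single_sample_is_per_million(self):
        counts = pd.DataFrame({"s1": [123]}, index=["g"])
        lengths = pd.Series([700.0], index=["g"])
        factors = NormFactors(
            factors=pd.Series([1.0], index=["s1"]),
            lib_sizes=pd.Series([123 / 0.7], index=["s1"]),
            reference_sample="s1",
        )
        out = getmm_normalize(counts, lengths, factors=factors, log2=False)
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million_with_unit_factors(self, null_experiment):
        counts, lengths, _ = null_experiment
        filtered = filter_genes(counts)
        r = rpk(filtered, lengths)
        factors = NormFactors(
            factors=pd.Series(1.0, index=filtered.columns),
            lib_sizes=r.sum(axis=0),
            reference_sample=filtered.columns[0],
        )
        out = getmm_normalize(filtered, lengths, factors=factors, log2=False)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_poisson_no_effect_matrix_is_stable_across_samples(self):
        # phi=0, no effects, high expression: per-gene CoV of normalized
        # values across samples stays under 5% at a million-read depth
        from paralogdissect.design import DesignConfig, simulate_design
        from paralogdissect.simulate import CountTruthConfig, simulate_counts

        meta = simulate_design(DesignConfig())
        cfg = CountTruthConfig(
            n_genes=500, baseline_log2_mean=10.0, dispersion=0.0, line_sd=0.0,
            seed=12,
        )
        counts, lengths, _ = simulate_counts(meta, cfg)
        out = getmm_normalize(filter_genes(counts), lengths, log2=False)
        cov = out.std(axis=1, ddof=1) / out.mean(axis=1)
        assert (cov < 0.05).all()

    def test_doubling_one_sample_changes_nothing(self, null_experiment):
        # depth is absorbed by the RPK library size; exact with the
        # unweighted trimmed mean (precision weights depend on depth, so
        # the weighted default is invariant only to ~1%)
        counts, lengths, _ = null_experiment
        filtered = filter_genes(counts)
        doubled = filtered.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        r_a, r_b = rpk(filtered, lengths), rpk(doubled, lengths)
        a = getmm_normalize(
            filtered, lengths, factors=tmm_factors(r_a, weighted=False), log2=False
        )
        b = getmm_normalize(
            doubled, lengths, factors=tmm_factors(r_b, weighted=False), log2=False
        )
        # tiny residual: floating-point rank ties at the trim boundary
        assert np.allclose(a.iloc[:, 0], b.iloc[:, 0], rtol=1e-3)
        b_w = getmm_normalize(doubled, lengths, log2=False)
        assert np.allclose(a.iloc[:, 0], b_w.iloc[:, 0], rtol=0.01)


class TestOutlierQc:
    def test_clean_samples_not_flagged(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(8, 2, size=300)
        expr = pd.DataFrame(
            {f"s{i}": profile + rng.normal(0, 0.05, 300) for i in range(8)}
        )
        assert flag_outlier_samples(expr) == []

    def test_alien_profile_flagged(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(8, 2, size=300)
        cols = {f"s{i}": profile + rng.normal(0, 0.1, 300) for i in range(7)}
        cols["alien"] = rng.normal(8, 2, size=300)  # unrelated profile
        expr = pd.DataFrame(cols)
        assert flag_outlier_samples(expr) == ["alien"]

    def test_groups_analyzed_separately(self):
        rng = np.random.default_rng(6)
        pf = rng.normal(8, 2, 300)
        pm = rng.normal(8, 2, 300)
        cols = {f"f{i}": pf + rng.normal(0, 0.1, 300) for i in range(5)}
        cols.update({f"m{i}": pm + rng.normal(0, 0.1, 300) for i in range(5)})
        expr = pd.DataFrame(cols)
        groups = pd.Series(["F"] * 5 + ["M"] * 5, index=expr.columns)
        # males and females differ, but within-group everything is clean
        assert flag_outlier_samples(expr, groups) == []

    def test_two_samples_warns_and_returns_empty(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.1]})
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert flag_outlier_samples(expr) == []
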