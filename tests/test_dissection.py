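import numpy as np
import pandas as pd
import pytest

from paralogdissect.anova import fit_gene_models
from paralogdissect.design import DesignConfig, simulate_design
from paralogdissect.dissection import (
    classify,
    cov_of_lsmeans,
    dissect_phenotype,
    dissect_transcripts,
    diversification_test,
    epistasis_test,
    epistasis_weights,
)
from paralogdissect.simulate import CountTruthConfig, simulate_counts
from tests.conftest import make_exact_expression


def _cells(values_by_genotype, sexes=("F", "M")):
    return {(g, s): v for g, v in values_by_genotype.items() for s in sexes}


ALL_GENOTYPES = ["++++", "----", "+---", "-+--", "--+-", "---+"]


def exact_bundle(values_by_genotype, lines=2, reps=2):
    meta = simulate_design(
        DesignConfig(genotypes=tuple(values_by_genotype),
                     lines_per_genotype=lines, replicates_per_cell=reps)
    )
    expr = make_exact_expression(meta, _cells(values_by_genotype))
    return fit_gene_models(expr, meta), meta, expr


class TestCov:
    def test_equal_means_give_zero(self):
        assert cov_of_lsmeans([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_worked_example(self):
        # sd([1,2,3,4], n-1) = 1.2910, mean = 2.5 -> 0.5164
        assert cov_of_lsmeans([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.5164, abs=5e-5)

    def test_scale_invariance_over_random_vectors(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            x = rng.uniform(0.5, 10.0, size=4)
            c = rng.uniform(0.1, 50.0)
            assert cov_of_lsmeans(c * x) == pytest.approx(cov_of_lsmeans(x), rel=1e-10)

    def test_nonpositive_mean_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(cov_of_lsmeans([-1.0, -2.0, 1.0, 0.0]))


class TestEpistasisContrast:
    def test_weights_are_full_plus_three_ko_minus_singles(self):
        w = epistasis_weights("M")
        assert w[("++++", "M")] == 1.0
        assert w[("----", "M")] == 3.0
        assert all(w[(g, "M")] == -1.0 for g in ["+---", "-+--", "--+-", "---+"])

    @pytest.mark.parametrize(
        "full,single,expected",
        [(5.0, 1.0, 1.0), (4.0, 1.0, 0.0)],
        ids=["enhancing_by_one", "additive"],
    )
    def test_arithmetic_on_exact_cell_means(self, full, single, expected):
        values = {"++++": full, "----": 0.0, "+---": single, "-+--": single,
                  "--+-": single, "---+": single}
        bundle, _, _ = exact_bundle(values)
        est = epistasis_test(bundle, "M")["estimate"].iloc[0]
        assert est == pytest.approx(expected, abs=1e-10)

    def test_linearity_identity(self):
        # the weighted contrast equals the LS-mean arithmetic exactly
        rng = np.random.default_rng(32)
        values = dict(zip(ALL_GENOTYPES, rng.normal(5, 2, 6)))
        bundle, _, _ = exact_bundle(values)
        est = epistasis_test(bundle, "F")["estimate"].iloc[0]
        lsm = bundle.lsmean_frame().iloc[0]
        by_hand = (lsm[("++++", "F")] - lsm[("----", "F")]) - sum(
            lsm[(g, "F")] - lsm[("----", "F")]
            for g in ["+---", "-+--", "--+-", "---+"]
        )
        assert est == pytest.approx(by_hand, abs=1e-12)

    def test_missing_genotype_rejected(self):
        values = {g: 1.0 for g in ALL_GENOTYPES if g != "+---"}
        bundle, _, _ = exact_bundle(values)
        with pytest.raises(ValueError, match="absent"):
            epistasis_test(bundle, "M")


class TestDiversification:
    def test_missing_single_genotype_rejected(self, default_meta):
        sub = default_meta[default_meta["genotype"] != "--+-"]
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, len(sub))),
            columns=sub["sample_id"], index=["g1", "g2", "g3"],
        )
        with pytest.raises(ValueError, match="missing single-reinsertion"):
            diversification_test(expr, sub, "M")

    def test_constant_response_gives_nan_p(self, default_meta):
        expr = pd.DataFrame(
            np.ones((2, len(default_meta))),
            columns=default_meta["sample_id"], index=["g1", "g2"],
        )
        tab, _ = diversification_test(expr, default_meta, "M")
        assert tab["p"].isna().all()

    def test_strong_divergence_detected(self, default_meta):
        # beta = (2,0,0,0) yields a large genotype F among the singles
        n = 60
        beta = np.zeros((n, 4))
        beta[:30, 0] = 2.0
        cfg = CountTruthConfig(n_genes=n, paralog_effects=beta, seed=33,
                               library_sizes=np.full(len(default_meta), 1e6))
        counts, _, _ = simulate_counts(default_meta, cfg)
        expr = np.log2(counts + 0.5)
        tab, _ = diversification_test(expr, default_meta, "M")
        assert (tab["p"][:30] < 0.05).mean() >= 0.8
        assert (tab["p"][30:] < 0.05).mean() <= 0.2


class TestClassify:
    @pytest.mark.parametrize(
        "div_fdr,epi_fdr,est,quadrant,direction",
        [
            (0.4, 0.6, 1.0, "redundant-additive", "none"),
            (0.01, 0.6, 1.0, "diverse-additive", "none"),
            (0.4, 0.01, -1.0, "redundant-epistatic", "suppressing"),
            (0.01, 0.01, 2.0, "diverse-epistatic", "enhancing"),
        ],
    )
    def test_quadrant_rules(self, div_fdr, epi_fdr, est, quadrant, direction):
        assert classify(div_fdr, epi_fdr, est) == (quadrant, direction)

    def test_nan_inputs_propagate(self):
        assert classify(float("nan"), 0.01, 1.0) == ("NA", "none")


class TestDissectTranscripts:
    def test_suppressing_epistasis_recovered_and_labeled(self, default_meta):
        n = 300
        delta = np.zeros(n)
        delta[:40] = -2.0
        delta[40:80] = 2.0
        cfg = CountTruthConfig(
            n_genes=n, epistasis_delta=delta, seed=34,
            library_sizes=np.full(len(default_meta), 1e6),
        )
        counts, _, _ = simulate_counts(default_meta, cfg)
        expr = np.log2(counts + 0.5)
        out = dissect_transcripts(expr, default_meta, sexes=("M",))
        sup = out[out["gene"].isin([f"gene{i + 1:04d}" for i in range(40)])]
        mc_se = sup["epi_estimate"].std() / np.sqrt(len(sup))
        assert abs(sup["epi_estimate"].mean() + 2.0) < 3 * mc_se
        called = sup[sup["epi_fdr"] < 0.05]
        assert len(called) > 0
        assert (called["epistasis_direction"] == "suppressing").all()
        # redundant quadrant for delta-only genes (all beta equal)
        assert (called["quadrant"] == "redundant-epistatic").mean() > 0.8

    def test_cov_linear_scale_is_positive(self, default_meta):
        cfg = CountTruthConfig(
            n_genes=50, seed=35, library_sizes=np.full(len(default_meta), 1e6)
        )
        counts, _, _ = simulate_counts(default_meta, cfg)
        expr = np.log2(counts + 0.5)
        out = dissect_transcripts(expr, default_meta, sexes=("F",))
        assert (out["cov"] >= 0).all()
        assert out["cov"].notna().all()


class TestDissectPhenotype:
    def _cov(self, genotypes, var=0.01):
        return pd.DataFrame(np.eye(len(genotypes)) * var, index=genotypes,
                            columns=genotypes)

    def test_additive_survival_scenario(self):
        # full effect 4.6 = 4 x 1.15 single effects: no epistasis
        lsm = pd.Series(
            {"++++": 44.6, "----": 40.0, "+---": 41.15, "-+--": 41.15,
             "--+-": 41.15, "---+": 41.15}
        )
        out = dissect_phenotype(lsm, self._cov(lsm.index), df_resid=100)
        assert out["epi_estimate"] == pytest.approx(0.0, abs=1e-10)
        assert out["quadrant"] == "redundant-additive"

    def test_identical_genotypes_are_null(self):
        lsm = pd.Series({g: 42.0 for g in ALL_GENOTYPES})
        out = dissect_phenotype(lsm, self._cov(lsm.index), df_resid=50)
        assert out["epi_estimate"] == pytest.approx(0.0)
        assert out["divers_p"] > 0.99
        assert out["cov"] == 0.0

    def test_sex_ratio_epistasis_sign_matches_construction(self):
        from scipy.special import logit

        lsm = pd.Series(
            {
                "++++": logit(0.46), "----": logit(0.32), "+---": logit(0.42),
                "-+--": logit(0.32), "--+-": logit(0.32), "---+": logit(0.32),
            }
        )
        expected = (lsm["++++"] - lsm["----"]) - (lsm["+---"] - lsm["----"])
        out = dissect_phenotype(lsm, self._cov(lsm.index, var=1e-4), df_resid=100)
        assert out["epi_estimate"] == pytest.approx(expected, abs=1e-10)
        assert out["epistasis_direction"] == (
            "enhancing" if expected > 0 else "suppressing"
        )

    def test_missing_genotype_rejected(self):
        lsm = pd.Series({"++++": 1.0, "----": 0.0})
        with pytest.raises(ValueError, match="lacks genotypes"):
            dissect_phenotype(lsm, self._cov(lsm.index), df_resid=10)
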