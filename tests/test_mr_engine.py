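"""Wald ratios, IVW pooling, heterogeneity statistics and subset analyses."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from igfmr.harmonize import HarmonizedPair
from igfmr.mr import (
    MREngineError,
    ivw_meta,
    or_ci,
    standardized_residuals,
    subset_analysis,
    wald_ratio,
)


def pair(beta_gx=0.1, se_gx=0.02, beta_gy=0.02, se_gy=0.01):
    return HarmonizedPair(
        rsid="rs1", coded_allele="A", other_allele="G",
        beta_gx=beta_gx, se_gx=se_gx, beta_gy=beta_gy, se_gy=se_gy,
    )


class TestWaldRatio:
    @pytest.mark.parametrize(
        "beta_gy, beta_gx, expected",
        [(0.02, 0.1, 0.2), (0.0, 0.1, 0.0), (-0.05, 0.25, -0.2)],
    )
    def test_ratio_is_direct_division(self, beta_gy, beta_gx, expected):
        est = wald_ratio(pair(beta_gx=beta_gx, beta_gy=beta_gy))
        assert est.beta_iv == pytest.approx(expected)

    def test_delta_method_se_both_terms(self):
        # sqrt(se_gy^2/gx^2 + gy^2 se_gx^2 / gx^4) = sqrt(0.0001/0.01 + 0.0004*0.0004/0.0001)
        est = wald_ratio(pair(beta_gx=0.1, se_gx=0.02, beta_gy=0.02, se_gy=0.01))
        assert est.se_iv == pytest.approx(math.sqrt(0.0116), rel=1e-12)
        assert est.se_iv == pytest.approx(0.10770, abs=5e-6)

    def test_one_term_simplification_option(self):
        est = wald_ratio(pair(beta_gx=-0.1, se_gx=0.02, beta_gy=0.02, se_gy=0.01), method="delta1")
        assert est.se_iv == pytest.approx(0.1)

    def test_zero_exposure_beta_is_degenerate(self):
        with pytest.raises(MREngineError, match="beta_gx = 0"):
            wald_ratio(pair(beta_gx=0.0))

    def test_weight_is_inverse_squared_se(self):
        est = wald_ratio(pair())
        assert est.weight == est.se_iv ** -2

    def test_delta_se_matches_parametric_bootstrap(self):
        """With a strong instrument the delta SE tracks the simulated ratio SD."""
        rng = np.random.default_rng(42)
        p = pair(beta_gx=0.3, se_gx=0.01, beta_gy=0.06, se_gy=0.02)
        gx = rng.normal(p.beta_gx, p.se_gx, 200_000)
        gy = rng.normal(p.beta_gy, p.se_gy, 200_000)
        boot_sd = np.std(gy / gx, ddof=1)
        est = wald_ratio(p)
        assert est.se_iv == pytest.approx(boot_sd, rel=0.03)


class TestIVWMeta:
    def test_hand_worked_two_study_case(self):
        res = ivw_meta([0.1, 0.3], [0.1, 0.1])
        assert res.beta_pooled == pytest.approx(0.2)
        assert res.se_pooled == pytest.approx(1 / math.sqrt(200), rel=1e-12)
        assert res.se_pooled == pytest.approx(0.07071, abs=5e-6)
        assert res.q_stat == pytest.approx(2.0)
        assert res.q_df == 1
        assert res.i2 == pytest.approx(50.0)
        assert res.q_pvalue == pytest.approx(0.157, abs=5e-4)

    def test_homogeneous_studies(self):
        res = ivw_meta([0.05] * 4, [0.1] * 4)
        assert res.beta_pooled == pytest.approx(0.05)
        assert res.se_pooled == pytest.approx(0.05)
        assert res.q_stat == pytest.approx(0.0, abs=1e-25)
        assert res.i2 == 0.0

    def test_single_study_identity(self):
        res = ivw_meta([0.04], [0.02])
        assert res.beta_pooled == pytest.approx(0.04)
        assert res.se_pooled == pytest.approx(0.02)
        assert res.q_stat == 0.0
        assert res.q_df == 0
        assert res.q_pvalue == 1.0
        assert res.i2 == 0.0

    def test_empty_and_nonpositive_se_rejected(self):
        with pytest.raises(MREngineError):
            ivw_meta([], [])
        with pytest.raises(MREngineError):
            ivw_meta([0.1, 0.2], [0.1, 0.0])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-2, 2, allow_nan=False),
                st.floats(0.01, 1.0, allow_nan=False),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_weighted_least_squares_oracle(self, data):
        """Fixed-effects IVW equals intercept-only WLS with known weights."""
        import statsmodels.api as sm
        from hypothesis import assume

        betas = [b for b, _ in data]
        ses = [s for _, s in data]
        assume(max(betas) - min(betas) > 1e-9)  # WLS scale must be nonzero
        res = ivw_meta(betas, ses)
        w = np.asarray(ses, dtype=float) ** -2
        fit = sm.WLS(np.asarray(betas), np.ones((len(betas), 1)), weights=w).fit()
        oracle_beta = fit.params[0]
        oracle_se = fit.bse[0] / np.sqrt(fit.scale)
        assert res.beta_pooled == pytest.approx(oracle_beta, rel=1e-10, abs=1e-12)
        assert res.se_pooled == pytest.approx(oracle_se, rel=1e-10)

    @given(c=st.floats(0.1, 10, allow_nan=False))
    def test_q_invariant_under_common_rescaling(self, c):
        """Q is unchanged under beta_i -> c*beta_i, se_i -> c*se_i."""
        betas, ses = [0.1, 0.25, -0.05], [0.05, 0.1, 0.2]
        base = ivw_meta(betas, ses)
        scaled = ivw_meta([c * b for b in betas], [c * s for s in ses])
        assert scaled.q_stat == pytest.approx(base.q_stat, rel=1e-9)
        assert scaled.z == pytest.approx(base.z, rel=1e-9)

    def test_standardized_residuals_square_to_q(self):
        betas, ses = [0.1, 0.25, -0.05, 0.4], [0.05, 0.1, 0.2, 0.1]
        res = ivw_meta(betas, ses)
        r = standardized_residuals(betas, ses, res)
        assert float(np.sum(r**2)) == pytest.approx(res.q_stat, rel=1e-12)


class TestOrCi:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [
            (0.0, 0.0, (1.0, 1.0, 1.0)),
            (math.log(2), 0.0, (2.0, 2.0, 2.0)),
        ],
    )
    def test_point_mass_cases(self, beta, se, expected):
        assert or_ci(beta, se) == pytest.approx(expected)

    def test_normal_interval(self):
        o, lo, hi = or_ci(0.0, 0.1)
        assert o == 1.0
        assert lo == pytest.approx(0.8220, abs=5e-4)
        assert hi == pytest.approx(1.2165, abs=5e-4)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            or_ci(0.0, 0.1, level=1.5)


class TestScaleEquivariance:
    @given(c=st.floats(0.2, 5, allow_nan=False))
    def test_exposure_rescaling_rescales_wald_but_not_z(self, c):
        """beta_gx -> c*beta_gx (with se_gx) scales Wald by 1/c; z is unchanged."""
        p = pair(beta_gx=0.2, se_gx=0.01, beta_gy=0.05, se_gy=0.02)
        scaled = pair(beta_gx=c * 0.2, se_gx=c * 0.01, beta_gy=0.05, se_gy=0.02)
        e1, e2 = wald_ratio(p), wald_ratio(scaled)
        assert e2.beta_iv == pytest.approx(e1.beta_iv / c, rel=1e-12)
        assert e2.beta_iv / e2.se_iv == pytest.approx(e1.beta_iv / e1.se_iv, rel=1e-12)


class TestSubsetAnalysis:
    def test_subset_counts_match_study_configuration(self, harmonized):
        iset, _ = harmonized
        assert subset_analysis(iset, "main9").k == 9
        assert subset_analysis(iset, "igf1_only5").k == 5
        assert subset_analysis(iset, "igfbp3_only2").k == 2

    def test_magnitude_mode_pools_wald_ratios(self, harmonized):
        iset, _ = harmonized
        causal = subset_analysis(iset, "igf1_only5", mode="causal")
        magnitude = subset_analysis(iset, "igf1_only5", mode="magnitude")
        assert causal.k == magnitude.k == 5
        assert magnitude.beta_pooled != causal.beta_pooled

    def test_unknown_selector_listed(self, harmonized):
        iset, _ = harmonized
        with pytest.raises(MREngineError, match="unknown subset"):
            subset_analysis(iset, "all_the_snps")
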