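"""KLD closed forms, the interpretation index, thresholds, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from nmasplit import (
    Conclusiveness,
    Extent,
    KLDTriple,
    classify_network,
    classify_node,
    half_normal_median_multiplier,
    heterogeneity_band,
    interpretation_index,
    kld_normal,
    low_inconsistency_threshold,
    threshold_from_clinical_delta,
    threshold_sensitivity_grid,
)
from nmasplit.model import NodeSplitResult, PosteriorSummary
from nmasplit.geometry import SplitNode


def kld_quadrature(mu_p, var_p, mu_q, var_q):
    """Independent oracle: numerically integrate p(x) log(p(x)/q(x))."""
    p = norm(mu_p, math.sqrt(var_p))
    q = norm(mu_q, math.sqrt(var_q))

    def integrand(x):
        return p.pdf(x) * (p.logpdf(x) - q.logpdf(x))

    lo = mu_p - 12 * math.sqrt(var_p)
    hi = mu_p + 12 * math.sqrt(var_p)
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


def summary(mean, sd):
    return PosteriorSummary(
        mean=mean, sd=sd, median=mean, q025=mean - 2 * sd, q975=mean + 2 * sd,
        rhat=1.0,
    )


def make_result(index, cri):
    node = SplitNode(("A", "B"), 1, True)
    if_summ = PosteriorSummary(
        mean=sum(cri) / 2, sd=1.0, median=sum(cri) / 2,
        q025=cri[0], q975=cri[1], rhat=1.0,
    )
    d = summary(0.0, 1.0)
    return NodeSplitResult(
        node=node, direct=d, indirect=d, inconsistency_factor=if_summ,
        tau=summary(0.2, 0.1),
        kld=KLDTriple(index, index, index),
    )


class TestKldNormal:
    def test_identical_distributions_are_zero(self):
        assert kld_normal(0, 1, 0, 1) == 0.0
        assert kld_normal(-2.5, 0.3, -2.5, 0.3) == 0.0

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1.17, 1, 0, 2), 0.4388),
            ((0, 2, 1.17, 1), 0.8379),
            ((0.3, 0.16, -0.1, 0.25), 0.3631),
        ],
    )
    def test_directed_divergences(self, args, expected):
        assert kld_normal(*args) == pytest.approx(expected, abs=5e-5)
        assert kld_normal(*args) == pytest.approx(
            kld_quadrature(*args), abs=1e-8
        )

    @pytest.mark.parametrize("bad", [(0, 0, 0, 1), (0, 1, 0, -2)])
    def test_nonpositive_variance_rejected(self, bad):
        with pytest.raises(ValueError):
            kld_normal(*bad)

    def test_matches_quadrature_on_grid(self):
        mus = [-1.5, -0.3, 0.0, 0.8, 2.0]
        sds = [0.2, 0.7, 1.3]
        for mu_p in mus:
            for sd_p in sds:
                for sd_q in sds:
                    closed = kld_normal(mu_p, sd_p**2, 0.4, sd_q**2)
                    numeric = kld_quadrature(mu_p, sd_p**2, 0.4, sd_q**2)
                    assert closed == pytest.approx(numeric, abs=1e-6)

    @given(
        mu=st.floats(-3, 3),
        sd_p=st.floats(0.1, 3),
        sd_q=st.floats(0.1, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_zero_iff_equal(self, mu, sd_p, sd_q):
        val = kld_normal(mu, sd_p**2, 0.0, sd_q**2)
        assert val >= 0.0
        if mu == 0.0 and sd_p == sd_q:
            assert val == 0.0


class TestInterpretationIndex:
    def test_equal_posteriors_give_zero(self):
        s = summary(0.4, 0.3)
        triple = interpretation_index(s, s)
        assert triple.index == 0.0 and triple.d_di == 0.0 and triple.d_id == 0.0

    def test_threshold_configuration_reproduced(self):
        # mu_D - mu_I = 1.17 with variances 1 and 2 is the threshold setup
        triple = interpretation_index(summary(1.17, 1.0), summary(0.0, math.sqrt(2)))
        assert round(triple.index, 2) == 0.64
        assert triple.index == pytest.approx(0.6383, abs=5e-4)

    def test_average_of_directed_divergences(self):
        triple = interpretation_index(summary(0.3, 0.4), summary(-0.1, 0.5))
        assert triple.index == pytest.approx(0.461, abs=1e-3)
        assert triple.index == 0.5 * (triple.d_di + triple.d_id)
        oracle = 0.5 * (
            kld_quadrature(0.3, 0.16, -0.1, 0.25)
            + kld_quadrature(-0.1, 0.25, 0.3, 0.16)
        )
        assert triple.index == pytest.approx(oracle, abs=1e-8)

    @given(
        mu_d=st.floats(-2, 2), mu_i=st.floats(-2, 2),
        sd_d=st.floats(0.1, 2), sd_i=st.floats(0.1, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_under_role_swap_with_negated_means(
        self, mu_d, mu_i, sd_d, sd_i
    ):
        a = interpretation_index(summary(mu_d, sd_d), summary(mu_i, sd_i))
        b = interpretation_index(summary(-mu_i, sd_i), summary(-mu_d, sd_d))
        assert a.index == pytest.approx(b.index, rel=1e-12, abs=1e-12)

    def test_monotone_in_mean_difference(self):
        vals = [
            interpretation_index(summary(d, 0.7), summary(0.0, 0.9)).index
            for d in np.linspace(0, 3, 13)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestParabola:
    @pytest.mark.parametrize("var_d, var_i", [(1.0, 2.0), (0.16, 0.25), (0.5, 0.5)])
    def test_exact_quadratic_with_zero_linear_term(self, var_d, var_i):
        deltas = np.array([-1.5, -0.5, 0.0, 0.7, 2.0])
        vals = [
            interpretation_index(
                summary(d, math.sqrt(var_d)), summary(0.0, math.sqrt(var_i))
            ).index
            for d in deltas
        ]
        a, b, c = np.polyfit(deltas, vals, 2)
        assert abs(b) < 1e-10
        assert a == pytest.approx((1 / var_d + 1 / var_i) / 4, rel=1e-10)
        # the fit is exact: residuals vanish
        assert np.allclose(np.polyval([a, b, c], deltas), vals, atol=1e-10)


class TestThresholds:
    def test_half_normal_median_multiplier(self):
        assert half_normal_median_multiplier() == pytest.approx(1.17, abs=5e-3)
        full = half_normal_median_multiplier(rounded=False)
        assert full == pytest.approx(norm.ppf(0.75) * math.sqrt(3), rel=1e-12)
        # independent check: median of |N(0, 3)| by its CDF
        assert norm.cdf(full / math.sqrt(3)) - norm.cdf(-full / math.sqrt(3)) == (
            pytest.approx(0.5, abs=1e-12)
        )

    def test_threshold_value(self):
        thr = low_inconsistency_threshold()
        assert round(thr, 2) == 0.64
        assert thr == pytest.approx(0.6383, abs=5e-4)
        assert low_inconsistency_threshold(rounded_multiplier=False) == (
            pytest.approx(0.6368, abs=5e-4)
        )

    def test_threshold_is_tau_free(self):
        m = half_normal_median_multiplier()
        vals = {
            round(threshold_from_clinical_delta(m * tau, tau), 12)
            for tau in (0.05, 0.3, 1.0, 4.0)
        }
        assert vals == {round(low_inconsistency_threshold(), 12)}

    def test_parabola_intercept_at_zero_delta(self):
        # c = threshold - a * 1.17^2 with a = (1/tau^2 + 1/(2 tau^2))/4 = 0.375/tau^2
        c = threshold_from_clinical_delta(0.0, 1.0)
        assert c == pytest.approx(0.125, abs=1e-12)
        assert c == pytest.approx(
            low_inconsistency_threshold() - 0.375 * 1.17**2, abs=1e-12
        )

    def test_monotone_in_abs_delta(self):
        taus = threshold_sensitivity_grid(np.linspace(0, 2, 9), [0.3, 0.7])
        for _, grp in taus.groupby("tau"):
            vals = grp.sort_values("delta")["threshold"].to_numpy()
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_clinical_delta(0.5, 0.0)


class TestHeterogeneityBand:
    @pytest.mark.parametrize(
        "tau, band",
        [
            (0.0, "low"), (0.05, "low"), (0.1, "low"),
            (0.11, "reasonable"), (0.3, "reasonable"), (0.49, "reasonable"),
            (0.5, "fairly_high"), (0.8, "fairly_high"), (1.0, "fairly_high"),
            (1.01, "fairly_extreme"), (1.2, "fairly_extreme"),
        ],
    )
    def test_bands(self, tau, band):
        assert heterogeneity_band(tau) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_band(-0.1)


class TestClassification:
    @pytest.mark.parametrize(
        "index, cri, extent, concl",
        [
            (0.5, (-0.2, 0.3), Extent.ACCEPTABLY_LOW, Conclusiveness.INCONCLUSIVE),
            (0.8, (0.1, 0.9), Extent.MATERIAL, Conclusiveness.CONCLUSIVE),
            (0.9, (-0.5, 1.4), Extent.MATERIAL, Conclusiveness.INCONCLUSIVE),
            (0.2, (-0.9, -0.1), Extent.ACCEPTABLY_LOW, Conclusiveness.CONCLUSIVE),
        ],
    )
    def test_node_rules(self, index, cri, extent, concl):
        verdict = classify_node(make_result(index, cri), threshold=0.64)
        assert verdict.extent is extent
        assert verdict.conclusiveness is concl

    def test_tie_at_threshold_is_material(self):
        verdict = classify_node(make_result(0.64, (-1, 1)), threshold=0.64)
        assert verdict.extent is Extent.MATERIAL

    def test_default_threshold_is_full_precision(self):
        verdict = classify_node(make_result(0.64, (-1, 1)))
        assert verdict.threshold_used == pytest.approx(0.6383, abs=5e-4)

    def test_network_rules(self):
        low_inc = classify_node(make_result(0.3, (-1, 1)), 0.64)
        mat_inc = classify_node(make_result(0.9, (-1, 1)), 0.64)
        low_con = classify_node(make_result(0.3, (0.2, 0.9)), 0.64)
        v = classify_network([low_inc, low_inc, low_inc])
        assert (v.index_based, v.cri_based) == ("consistent", "inconclusive")
        v = classify_network([low_inc, mat_inc])
        assert v.index_based == "potentially_inconsistent"
        v = classify_network([low_inc, low_con])
        assert (v.index_based, v.cri_based) == (
            "potentially_inconsistent", "conclusive",
        )

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no split nodes"):
            classify_network([])
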