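"""Closed-form decay model: worked values, limits, and oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import rifdecay as rd
from rifdecay.kinetic_model import SEC_PER_MIN


def quadrature_posttranscriptional(x, t, kin):
    """Independent numerical oracle for the post-transcriptional model.

    Integrates molecule survival over stationary initiation times: with
    u = t - x/(60v) - t0, a molecule's position x is present iff
    u >= 0 and the RNase (bound only after completion, offset
    E' ~ Exp(d)) has not yet cleared it, i.e. u < S + E'.  The relative
    abundance is the ratio of the survival integral at time t to its value
    at t = 0.
    """
    a = x / (SEC_PER_MIN * kin.v)
    S = kin.L / (SEC_PER_MIN * kin.v)
    m = max(t - a, 0.0)

    def survival(u):
        return 1.0 if u <= S else math.exp(-kin.d * (u - S))

    upper = S + 60.0 / kin.d  # exp(-60): tail beyond is < 1e-26
    def piece(lo):
        pts = [p for p in (S,) if lo < p < upper]
        val, _ = integrate.quad(survival, lo, upper, points=pts or None,
                                limit=200, epsabs=1e-12, epsrel=1e-12)
        return val

    return piece(m) / piece(0.0)


class TestWorkedValues:
    def test_steady_state_at_time_zero(self, kin):
        for x in (0.0, 1500.0, 3000.0):
            assert rd.cotranscriptional_abundance(x, 0.0, kin) == 1.0
            assert rd.posttranscriptional_abundance(x, 0.0, kin) == 1.0

    def test_delay_boundary_is_passage_time(self):
        # x/v = 300 nt / 25 nt/s = 12 s = 0.2 min: still at steady state
        kin = rd.TranscriptKinetics("t", k=1, v=25.0, d=1.7, L=3000)
        assert rd.cotranscriptional_abundance(300.0, 0.2, kin) == 1.0
        assert rd.cotranscriptional_abundance(300.0, 0.2001, kin) < 1.0

    def test_one_lifetime_elapsed_at_5prime_end(self):
        kin = rd.TranscriptKinetics("t", k=1, v=25.0, d=1 / 2.5, L=3000)
        assert rd.cotranscriptional_abundance(0.0, 2.5, kin) == \
            pytest.approx(math.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("L,v,expected", [
        (12000, 25.0, 8.0),
        (1500, 25.0, 1.0),
        (3371, 25.0, 3371 / 1500),  # a 3,371-nt tricistronic unit: 2.247 min
    ])
    def test_synthesis_time(self, L, v, expected):
        kin = rd.TranscriptKinetics("t", k=1, v=v, d=0.1, L=L)
        assert rd.synthesis_time(kin) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k,d,expected", [(1.0, 0.4, 2.5), (0.0, 0.5, 0.0),
                                              (2.0, 0.5, 4.0)])
    def test_steady_state_abundance(self, k, d, expected):
        kin = rd.TranscriptKinetics("t", k=k, v=25.0, d=d, L=1000)
        assert rd.steady_state_abundance(kin) == pytest.approx(expected)

    def test_steady_state_undefined_without_degradation(self):
        kin = rd.TranscriptKinetics("t", k=1.0, v=25.0, d=0.0, L=1000)
        with pytest.raises(ValueError, match="d = 0"):
            rd.steady_state_abundance(kin)


class TestCotranscriptionalProbability:
    def test_ratio_half_gives_about_forty_percent(self):
        # synthesis time / lifetime = 0.5: ~40% of molecules are degraded
        # before their synthesis completes
        p = rd.p_from_ratio(0.5)
        assert p == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        assert round(100 * p, -1) == 40.0

    def test_ratio_one_exceeds_sixty_percent(self):
        assert rd.p_from_ratio(1.0) > 0.60

    def test_no_degradation_never_cotranscriptional(self):
        kin = rd.TranscriptKinetics("t", k=1, v=25.0, d=0.0, L=9000)
        assert rd.p_cotranscriptional(kin) == 0.0

    def test_kinetics_and_ratio_forms_agree(self, kin):
        r = kin.d * kin.L / (60.0 * kin.v)
        assert rd.p_cotranscriptional(kin) == pytest.approx(
            rd.p_from_ratio(r), rel=1e-14)

    @given(st.floats(min_value=1e-6, max_value=8.0),
           st.floats(min_value=1.01, max_value=4.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ratio_with_limits(self, r, fac):
        assert rd.p_from_ratio(r * fac) > rd.p_from_ratio(r)
        assert 0.0 < rd.p_from_ratio(r) < 1.0
        assert rd.p_from_ratio(0.0) == 0.0
        assert rd.p_from_ratio(1e6) == pytest.approx(1.0, abs=1e-12)


@st.composite
def model_points(draw):
    L = draw(st.integers(min_value=300, max_value=15000))
    v = draw(st.floats(min_value=5.0, max_value=80.0))
    d = draw(st.floats(min_value=0.05, max_value=5.0))
    x = draw(st.floats(min_value=0.0, max_value=1.0)) * L
    t = draw(st.floats(min_value=0.0, max_value=15.0))
    return rd.TranscriptKinetics("h", k=1.0, v=v, d=d, L=L), x, t


class TestModelProperties:
    @given(model_points())
    @settings(max_examples=200, deadline=None)
    def test_post_dominates_co(self, point):
        kin, x, t = point
        co = rd.cotranscriptional_abundance(x, t, kin)
        post = rd.posttranscriptional_abundance(x, t, kin)
        assert post >= co - 1e-12
        if t <= x / (60.0 * kin.v):
            assert post == pytest.approx(1.0) and co == pytest.approx(1.0)

    @given(model_points())
    @settings(max_examples=100, deadline=None)
    def test_cotx_is_delayed_single_exponential(self, point):
        kin, x, _ = point
        delay = x / (60.0 * kin.v)
        ts = delay + np.linspace(0.1, 5.0, 7)
        ys = rd.cotranscriptional_abundance(x, ts, kin)
        slopes = np.diff(np.log(ys)) / np.diff(ts)
        assert np.allclose(slopes, -kin.d, rtol=1e-9, atol=1e-12)

    @given(model_points())
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_time_and_position(self, point):
        kin, x, t = point
        assert rd.cotranscriptional_abundance(x, t + 0.5, kin) <= \
            rd.cotranscriptional_abundance(x, t, kin) + 1e-15
        x2 = min(x + 200.0, float(kin.L))
        assert rd.cotranscriptional_abundance(x2, t, kin) >= \
            rd.cotranscriptional_abundance(x, t, kin) - 1e-15

    def test_posttranscriptional_matches_quadrature_on_grid(self):
        # closed form vs numerical integration over initiation times
        for d in (0.1, 0.4, 2.0):
            for v in (10.0, 25.0, 60.0):
                for L in (900, 3000, 12000):
                    kin = rd.TranscriptKinetics("t", k=1, v=v, d=d, L=L)
                    for xfrac in (0.0, 0.4, 1.0):
                        x = xfrac * L
                        for t in (0.0, 0.5, 2.0, 5.0, 12.0):
                            closed = rd.posttranscriptional_abundance(x, t, kin)
                            oracle = quadrature_posttranscriptional(x, t, kin)
                            assert closed == pytest.approx(oracle, abs=1e-6)

    def test_specific_quadrature_point(self):
        # frozen spot check: x=0, d=0.4/min, L=3000 nt, v=25 nt/s, t=5 min
        kin = rd.TranscriptKinetics("t", k=1, v=25.0, d=0.4, L=3000)
        oracle = quadrature_posttranscriptional(0.0, 5.0, kin)
        assert rd.posttranscriptional_abundance(0.0, 5.0, kin) == \
            pytest.approx(oracle, abs=1e-9)

    def test_instantaneous_binding_limit_is_linear_ramp(self):
        # d -> inf: 5'-end abundance falls exactly linearly over the
        # synthesis time L/(60 v), here 6000/(60*25) = 4 min
        kin = rd.TranscriptKinetics("t", k=1, v=25.0, d=math.inf, L=6000)
        for t in (0.0, 1.0, 2.0, 3.3, 4.0, 7.0):
            expected = max(0.0, 1.0 - t / 4.0)
            assert rd.posttranscriptional_abundance(0.0, t, kin) == \
                pytest.approx(expected, abs=1e-12)
        # large finite d converges to the same ramp
        kin_big = rd.TranscriptKinetics("t", k=1, v=25.0, d=1e7, L=6000)
        assert rd.posttranscriptional_abundance(0.0, 2.0, kin_big) == \
            pytest.approx(0.5, abs=1e-5)


class TestValidation:
    def test_rejects_bad_domain(self, kin):
        with pytest.raises(ValueError):
            rd.cotranscriptional_abundance(-1.0, 1.0, kin)
        with pytest.raises(ValueError):
            rd.cotranscriptional_abundance(kin.L + 1, 1.0, kin)
        with pytest.raises(ValueError):
            rd.posttranscriptional_abundance(0.0, -0.1, kin)

    def test_rejects_bad_kinetics(self):
        with pytest.raises(ValueError):
            rd.TranscriptKinetics("t", k=-1, v=25, d=0.4, L=100)
        with pytest.raises(ValueError):
            rd.TranscriptKinetics("t", k=1, v=0.0, d=0.4, L=100)
        with pytest.raises(ValueError):
            rd.TranscriptKinetics("t", k=1, v=25, d=0.4, L=0)
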