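import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edflow.config import DEFAULT_SERVICE_TIMES
from edflow.distributions import (
    DistributionDomainError,
    DistributionParseError,
    DistributionSpec,
    DistributionWarning,
    RandomStream,
    format_distribution,
    moments,
    parse_distribution,
    sample,
)


class TestParsing:
    def test_plain_triangular(self):
        spec = parse_distribution("TRI (2, 3, 5)")
        assert spec.family == "triangular"
        assert spec.params == (2.0, 3.0, 5.0)
        assert spec.scale == 1.0 and spec.shift == 0.0

    def test_affine_gamma_prefix_offset(self):
        spec = parse_distribution("1 + 2 ∗ Gamma (0.1, 2.5, 2.5)")
        assert spec.family == "gamma"
        assert spec.params == (0.1, 2.5, 2.5)
        assert spec.scale == 2.0
        assert spec.shift == 1.0

    def test_affine_suffix_offset(self):
        spec = parse_distribution("2 * Gamma(0.1, 2.5) + 1")
        assert spec.scale == 2.0 and spec.shift == 1.0
        assert spec.params == (0.1, 2.5, 0.0)

    def test_degenerate_triangular_is_constant(self):
        spec = parse_distribution("TRI (4, 4, 4)")
        assert spec.family == "constant"
        assert spec.params == (4.0,)

    def test_ill_ordered_triangular_sorted_with_warning(self):
        with pytest.warns(DistributionWarning):
            spec = parse_distribution("1.7 ∗ TRIA (1, 0.3, 10.1)")
        assert spec.params == (0.3, 1.0, 10.1)
        assert spec.scale == 1.7

    def test_lognormal_three_param(self):
        spec = parse_distribution("LogNORM (1.3, 2, 1)")
        assert spec.family == "lognormal"
        assert spec.params == (1.3, 2.0, 1.0)

    @pytest.mark.parametrize(
        "bad",
        ["", "TRI", "TRI(2, 3)", "FOO(1, 2)", "TRI(2, x, 5)", "TRI(1 2 3)"],
    )
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(DistributionParseError):
            parse_distribution(bad)

    @pytest.mark.parametrize("bad", ["Gamma(-1, 2)", "Gamma(1, 0)", "LogNORM(0, -1)", "EXPO(0)"])
    def test_domain_errors(self, bad):
        with pytest.raises(DistributionDomainError):
            parse_distribution(bad)

    def test_every_stock_law_parses(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DistributionWarning)
            for text in DEFAULT_SERVICE_TIMES.values():
                spec = parse_distribution(text)
                assert moments(spec)[0] > 0

    def test_parse_format_roundtrip_on_stock_laws(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DistributionWarning)
            for text in DEFAULT_SERVICE_TIMES.values():
                spec = parse_distribution(text)
                assert parse_distribution(format_distribution(spec)) == spec


@st.composite
def specs(draw):
    family = draw(st.sampled_from(["triangular", "gamma", "lognormal", "exponential", "constant"]))
    pos = st.floats(0.01, 50, allow_nan=False)
    if family == "triangular":
        vals = sorted(draw(st.lists(pos, min_size=3, max_size=3)))
        if vals[0] == vals[2]:
            vals[2] += 1.0
        params = tuple(vals)
    elif family == "gamma":
        params = (draw(pos), draw(pos), draw(st.floats(0, 10)))
    elif family == "lognormal":
        params = (draw(st.floats(-2, 2)), draw(st.floats(0.05, 2)), draw(st.floats(0, 10)))
    elif family == "exponential":
        params = (draw(pos), draw(st.floats(0, 10)))
    else:
        params = (draw(pos),)
    return DistributionSpec(
        family=family,
        params=params,
        scale=draw(st.floats(0.1, 5)),
        shift=draw(st.floats(0, 20)),
    )


@settings(max_examples=50, deadline=None)
@given(specs())
def test_format_parse_is_identity(spec):
    text = format_distribution(spec)
    spec2 = parse_distribution(text)
    assert spec2.family == spec.family
    assert np.allclose(spec2.params, spec.params, rtol=1e-5)
    assert math.isclose(spec2.scale, spec.scale, rel_tol=1e-5)
    assert math.isclose(spec2.shift, spec.shift, rel_tol=1e-5, abs_tol=1e-9)


class TestSampling:
    def test_constant_is_constant(self):
        spec = DistributionSpec("constant", (4.0,))
        stream = RandomStream(1, "c")
        assert all(sample(spec, stream) == 4.0 for _ in range(10))

    def test_determinism_identical_streams(self):
        spec = parse_distribution("Gamma(0.77, 0.4667, 13.24)")
        a = RandomStream(42, "x").draw(spec, size=1000)
        b = RandomStream(42, "x").draw(spec, size=1000)
        assert a.tobytes() == b.tobytes()

    def test_distinct_stream_ids_differ(self):
        spec = parse_distribution("EXPO(5)")
        a = RandomStream(42, "x").draw(spec, size=100)
        b = RandomStream(42, "y").draw(spec, size=100)
        assert not np.allclose(a, b)

    def test_copy_restarts_sequence(self):
        spec = parse_distribution("TRIA(2, 3, 5)")
        s = RandomStream(9, "t")
        first = s.draw(spec, size=50)
        again = s.copy().draw(spec, size=50)
        np.testing.assert_array_equal(first, again)

    def test_triangular_empirical_mean(self):
        # closed-form triangular mean (2+3+5)/3 as oracle
        spec = parse_distribution("TRI(2, 3, 5)")
        x = RandomStream(0, "tri").draw(spec, size=10**6)
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - 10.0 / 3.0) < 3 * se

    def test_shifted_gamma_empirical_mean(self):
        # closed-form k*theta + shift as oracle
        spec = parse_distribution("3 + Gamma(2, 1.5)")
        x = RandomStream(0, "g").draw(spec, size=10**6)
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - (2 * 1.5 + 3)) < 3 * se

    def test_nonnegative_and_truncation_counted(self):
        spec = parse_distribution("EXPO(1) + -5")  # mass below zero
        stream = RandomStream(0, "neg")
        x = stream.draw(spec, size=10000)
        assert (x >= 0).all()
        assert stream.truncated > 0

    def test_samples_finite(self):
        for text in DEFAULT_SERVICE_TIMES.values():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DistributionWarning)
                spec = parse_distribution(text)
            x = RandomStream(5, text).draw(spec, size=1000)
            assert np.isfinite(x).all() and (x >= 0).all()


class TestMoments:
    def test_constant(self):
        assert moments(DistributionSpec("constant", (4.0,))) == (4.0, 0.0)

    def test_symmetric_triangular_midpoint(self):
        mean, var = moments(parse_distribution("TRI(5, 10, 15)"))
        assert mean == pytest.approx(10.0)
        assert var == pytest.approx((25 + 100 + 225 - 50 - 75 - 150) / 18)

    def test_lognormal_closed_form_vs_monte_carlo(self):
        spec = parse_distribution("LogNORM(0.5, 1, 5.5)")
        mean, var = moments(spec)
        assert mean == pytest.approx(math.exp(0.5 + 0.5) + 5.5)
        x = RandomStream(1, "ln").draw(spec, size=10**6)
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - mean) < 4 * se

    def test_every_stock_law_mean_and_variance_vs_monte_carlo(self):
        # 10^6 draws per law; 4-standard-error agreement for mean and variance
        rtol_free = {"consult_notes", "discharge_delay"}  # sigma=2 lognormals: wild kurtosis
        for task, text in DEFAULT_SERVICE_TIMES.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DistributionWarning)
                spec = parse_distribution(text)
            mean, var = moments(spec)
            x = RandomStream(11, task).draw(spec, size=10**6)
            n = len(x)
            se_mean = x.std(ddof=1) / math.sqrt(n)
            assert abs(x.mean() - mean) < max(4 * se_mean, 1e-12), task
            if var == 0:
                assert x.var() == 0
                continue
            centered = x - x.mean()
            m4 = np.mean(centered**4)
            se_var = math.sqrt(max(m4 - x.var(ddof=1) ** 2, 0.0) / n)
            assert abs(x.var(ddof=1) - var) < max(4 * se_var, 1e-12), task

    def test_affine_transform_of_moments(self):
        base = parse_distribution("Gamma(2, 3)")
        scaled = parse_distribution("5 + 2 * Gamma(2, 3)")
        m0, v0 = moments(base)
        m1, v1 = moments(scaled)
        assert m1 == pytest.approx(2 * m0 + 5)
        assert v1 == pytest.approx(4 * v0)
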