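"""Tunable Q-factor wavelet transform: reconstruction, structure, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olfeeg import (
    TQWTParams,
    forward,
    inverse,
    max_levels,
    scaling_factors,
    subband_center_frequencies,
    subband_lengths,
)
from olfeeg.errors import DataError, LevelError, ParameterError

GRID = [(q, j) for q in (1, 2, 3, 4) for j in (5, 9)]


def brute_force_max_levels(q, r, n):
    """Independent oracle: multiply the nominal high-pass length by alpha
    until it would drop below the 8-sample support."""
    alpha, beta = scaling_factors(TQWTParams(q_factor=q, redundancy=r, levels=1))
    length = beta * n
    j = 0
    while length * alpha >= 8.0:
        length *= alpha
        j += 1
    return j


class TestScalingFactors:
    def test_closed_forms(self):
        alpha, beta = scaling_factors(TQWTParams(q_factor=1, redundancy=3, levels=1))
        assert beta == 1.0 and alpha == pytest.approx(2.0 / 3.0)
        alpha, beta = scaling_factors(TQWTParams(q_factor=4, redundancy=3, levels=1))
        assert beta == pytest.approx(0.4) and alpha == pytest.approx(1 - 0.4 / 3)

    def test_alpha_plus_beta_over_r_is_one(self):
        for q in (1.0, 2.5, 4.0):
            for r in (2.0, 3.0, 5.0):
                p = TQWTParams(q_factor=q, redundancy=r, levels=1)
                alpha, beta = scaling_factors(p)
                assert alpha + beta / r == pytest.approx(1.0, abs=1e-15)
                assert 0 < alpha < 1 and 0 < beta <= 1

    @pytest.mark.parametrize("bad", [{"q_factor": 0.5}, {"redundancy": 1.0},
                                     {"redundancy": 0.5}, {"levels": 0}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            TQWTParams(**{"q_factor": 1, "redundancy": 3, "levels": 5, **bad})


class TestMaxLevels:
    @pytest.mark.parametrize("q,r,n,expected", [(1, 3, 400, 9), (4, 3, 400, 20)])
    def test_known_values(self, q, r, n, expected):
        assert max_levels(TQWTParams(q_factor=q, redundancy=r, levels=1), n) == expected

    def test_matches_brute_force_iteration(self):
        for q in (1, 2, 3, 4):
            for r in (2, 3, 4):
                for n in (256, 400, 512, 1024):
                    p = TQWTParams(q_factor=q, redundancy=r, levels=1)
                    assert max_levels(p, n) == brute_force_max_levels(q, r, n)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            max_levels(TQWTParams(q_factor=1, redundancy=3, levels=1), 8)

    def test_forward_rejects_excess_levels(self, rng):
        p = TQWTParams(q_factor=1, redundancy=3, levels=10)
        with pytest.raises(LevelError, match="max_levels"):
            forward(rng.standard_normal(400), p)


class TestPerfectReconstruction:
    @pytest.mark.parametrize("q,j", GRID)
    def test_round_trip_on_grid(self, q, j, rng):
        p = TQWTParams(q_factor=q, redundancy=3, levels=j)
        x = rng.standard_normal(400)
        err = np.max(np.abs(inverse(forward(x, p)) - x))
        assert err <= 1e-10

    def test_round_trip_impulse(self):
        x = np.zeros(512)
        x[100] = 1.0
        p = TQWTParams(q_factor=2, redundancy=3, levels=6)
        assert np.max(np.abs(inverse(forward(x, p)) - x)) <= 1e-10

    def test_round_trip_odd_length(self, rng):
        x = rng.standard_normal(401)
        p = TQWTParams(q_factor=1, redundancy=3, levels=5)
        xr = inverse(forward(x, p))
        assert xr.shape == x.shape
        assert np.max(np.abs(xr - x)) <= 1e-10

    def test_zero_signal_gives_zero_bands(self):
        sb = forward(np.zeros(256), TQWTParams(q_factor=1, redundancy=3, levels=4))
        for band in sb.coeffs:
            assert np.all(band == 0.0)

    def test_linearity(self, rng):
        p = TQWTParams(q_factor=2, redundancy=3, levels=5)
        x, y = rng.standard_normal((2, 512))
        a, b = 2.5, -1.25
        combined = forward(a * x + b * y, p)
        fx, fy = forward(x, p), forward(y, p)
        for cb, cx, cy in zip(combined.coeffs, fx.coeffs, fy.coeffs):
            np.testing.assert_allclose(cb, a * cx + b * cy, atol=1e-10)

    def test_energy_preserved_by_analysis(self, rng):
        # the unitary scaling makes the analysis a Parseval frame
        x = rng.standard_normal(400)
        sb = forward(x, TQWTParams(q_factor=3, redundancy=3, levels=7))
        assert sum(np.sum(c ** 2) for c in sb.coeffs) == pytest.approx(np.sum(x ** 2))

    def test_nan_input_rejected(self):
        x = np.zeros(256)
        x[3] = np.nan
        with pytest.raises(DataError):
            forward(x, TQWTParams(q_factor=1, redundancy=3, levels=3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(q=st.floats(1.0, 4.0), r=st.floats(2.0, 4.0), j=st.integers(1, 6),
           seed=st.integers(0, 2 ** 16))
    def test_round_trip_property(self, q, r, j, seed):
        p = TQWTParams(q_factor=q, redundancy=r, levels=j)
        x = np.random.default_rng(seed).standard_normal(256)
        assert np.max(np.abs(inverse(forward(x, p)) - x)) <= 1e-10


class TestSubbandStructure:
    def test_lengths_formula_single_level(self):
        p = TQWTParams(q_factor=1, redundancy=3, levels=1)
        alpha, beta = scaling_factors(p)
        lengths = subband_lengths(p, 512)
        assert lengths[0] == 2 * round(beta * 512 / 2)
        assert lengths[1] == 2 * round(alpha * 256)

    @pytest.mark.parametrize("q,j", GRID)
    def test_band_count_and_length_consistency(self, q, j, rng):
        p = TQWTParams(q_factor=q, redundancy=3, levels=j)
        sb = forward(rng.standard_normal(400), p)
        assert len(sb.coeffs) == j + 1
        assert [len(c) for c in sb.coeffs] == subband_lengths(p, 400)

    @pytest.mark.parametrize("q,j", GRID)
    def test_total_length_bounded_by_redundancy(self, q, j):
        p = TQWTParams(q_factor=q, redundancy=3, levels=j)
        total = sum(subband_lengths(p, 400))
        assert total <= 3 * 400 + 2 * (j + 1)

    def test_redundancy_at_max_depth(self):
        # coefficient count / N approaches r at the deepest decomposition
        for q in (1, 2, 3, 4):
            jmax = max_levels(TQWTParams(q_factor=q, redundancy=3, levels=1), 400)
            p = TQWTParams(q_factor=q, redundancy=3, levels=jmax)
            ratio = sum(subband_lengths(p, 400)) / 400
            assert abs(ratio - 3.0) / 3.0 <= 0.10

    def test_min_band_length_at_max_depth(self):
        p0 = TQWTParams(q_factor=2, redundancy=3, levels=1)
        jmax = max_levels(p0, 400)
        lengths = subband_lengths(TQWTParams(q_factor=2, redundancy=3, levels=jmax), 400)
        assert min(lengths) >= 2


class TestCenterFrequencies:
    def test_strictly_decreasing(self):
        p = TQWTParams(q_factor=2, redundancy=3, levels=8)
        f = subband_center_frequencies(p, 200.0)
        assert np.all(np.diff(f) < 0)
        assert f[-1] > 0

    def test_deeper_decomposition_reaches_lower(self):
        shallow = subband_center_frequencies(
            TQWTParams(q_factor=2, redundancy=3, levels=4), 200.0)
        deep = subband_center_frequencies(
            TQWTParams(q_factor=2, redundancy=3, levels=8), 200.0)
        assert deep[-2] < shallow[-2]

    @pytest.mark.parametrize("level", [2, 4, 6])
    def test_sinusoid_energy_localizes(self, level):
        # a tone at band j's center should put its energy in band j (+/- 1)
        p = TQWTParams(q_factor=2, redundancy=3, levels=8)
        fs, n = 200.0, 1024
        freqs = subband_center_frequencies(p, fs)
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freqs[level - 1] * t)
        sb = forward(x, p)
        energies = [np.mean(c ** 2) for c in sb.coeffs]
        assert abs(int(np.argmax(energies)) - (level - 1)) <= 1
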