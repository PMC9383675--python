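import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomewaves.wave import (
    alternating_sum,
    amplitude,
    endpoint_form,
    increments,
    lambda_n,
    normalization_check,
    series_table,
    wavefunction,
)

binary_vectors = st.lists(st.integers(0, 1), min_size=1, max_size=400).map(np.array)


class TestAlternatingSum:
    @pytest.mark.parametrize(
        "x,phi",
        [
            ([0, 0, 0, 0], [0, 0, 0, 0]),
            ([1, 1, 1, 1], [1, 0, 1, 0]),
            ([1, 0, 1, 1], [1, 1, 2, 1]),
        ],
    )
    def test_cumulative_signed_sums(self, x, phi):
        assert alternating_sum(x).tolist() == phi

    def test_rejects_nonbinary_entries(self):
        with pytest.raises(ValueError):
            alternating_sum([0, 2, 1])
        with pytest.raises(ValueError):
            alternating_sum([])

    @given(binary_vectors)
    @settings(derandomize=True, max_examples=100)
    def test_bounded_integer_walk(self, x):
        phi = alternating_sum(x)
        k = np.arange(1, x.size + 1)
        assert (np.abs(phi) <= np.ceil(k / 2)).all()


class TestIncrements:
    @pytest.mark.parametrize("phi,x", [([1, 1, 2, 1], [1, 0, 1, 1]), ([0, 0, 0], [0, 0, 0])])
    def test_recovers_indicators(self, phi, x):
        assert increments(phi).tolist() == x

    def test_rejects_jump_larger_than_one(self):
        with pytest.raises(ValueError, match="adjacent difference"):
            increments([1, 3])

    def test_roundtrip_exhaustive_short_strings(self):
        for n in range(1, 9):
            for bits in itertools.product((0, 1), repeat=n):
                x = np.array(bits)
                assert (increments(alternating_sum(x)) == x).all()

    def test_roundtrip_long_random_string(self, rng):
        x = (rng.random(5000) < 0.4).astype(np.int8)
        assert (increments(alternating_sum(x)) == x).all()


class TestScalars:
    @pytest.mark.parametrize("x,lam", [([1, 0, 1, 1], 1), ([1, 1], 0), ([1], 1)])
    def test_lambda_is_series_endpoint(self, x, lam):
        assert lambda_n(x) == lam

    @pytest.mark.parametrize("n_one,a", [(4, 0.5), (1, 1.0), (8843, 1 / np.sqrt(8843))])
    def test_amplitude_inverse_root(self, n_one, a):
        assert amplitude(n_one) == pytest.approx(a, rel=1e-15)

    def test_all_zero_projection_is_degenerate(self):
        with pytest.raises(ValueError, match="unnormalizable"):
            amplitude(0)


class TestWavefunction:
    def test_hand_derived_example_mode_one(self):
        ws = wavefunction([1, 0, 1, 1], mode=1)
        a = 1 / np.sqrt(3)
        assert ws.phi.tolist() == [1, 1, 2, 1]
        assert ws.lam == 1
        assert ws.amplitude == pytest.approx(a)
        np.testing.assert_allclose(ws.psi, [-a, 0, a, a], atol=1e-15)

    def test_hand_derived_example_mode_two(self):
        a = 1 / np.sqrt(3)
        np.testing.assert_allclose(
            wavefunction([1, 0, 1, 1], mode=2).psi, [a, 0, a, -a], atol=1e-15
        )

    def test_single_one(self):
        np.testing.assert_allclose(wavefunction([1], mode=1).psi, [-1.0], atol=1e-15)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="lambda_N"):
            wavefunction([1, 1])  # balanced: Phi_N = 0
        with pytest.raises(ValueError, match="unnormalizable"):
            wavefunction([0, 0, 0])
        with pytest.raises(ValueError, match="mode"):
            wavefunction([1], mode=0)

    def test_support_matches_indicators(self, rng):
        x = (rng.random(2000) < 0.3).astype(np.int8)
        ws = wavefunction(x, mode=3)
        assert ((ws.psi == 0) == (x == 0)).all()
        np.testing.assert_allclose(
            np.abs(ws.psi) ** 2, ws.amplitude**2 * x, atol=1e-15
        )

    def test_modulus_independent_of_mode(self, rng):
        x = (rng.random(1000) < 0.5).astype(np.int8)
        if lambda_n(x) == 0:
            x[-1] = 1 - x[-1]
        mods = [np.abs(wavefunction(x, mode=n).psi) for n in range(1, 9)]
        for m in mods[1:]:
            np.testing.assert_allclose(m, mods[0], rtol=1e-15, atol=0)

    def test_translation_non_symmetry(self, rng):
        x = (rng.random(500) < 0.4).astype(np.int8)
        if lambda_n(x) == 0:
            x[-1] = 1 - x[-1]
        ws = wavefunction(x)
        dens = np.abs(ws.psi) ** 2 * ws.n_one
        np.testing.assert_allclose(dens, x, atol=1e-12)
        for k_a in (1, 7, 50):
            diff = x[:-k_a] != x[k_a:]
            assert diff.any()
            assert (np.abs(dens[k_a:][diff] - dens[:-k_a][diff]) > 0.5 / ws.n_one).all()

    @given(binary_vectors, st.integers(1, 8))
    @settings(derandomize=True, max_examples=150)
    def test_normalization_property(self, x, mode):
        if x.sum() == 0 or lambda_n(x) == 0:
            return
        assert normalization_check(wavefunction(x, mode)) == pytest.approx(1.0, rel=1e-9)


class TestEndpointForm:
    @pytest.mark.parametrize(
        "x,mode,expected",
        [
            ([1, 0, 1, 1], 1, 1 / np.sqrt(3)),
            ([1, 0, 1, 0], 1, 0.0),
            ([1], 2, 1.0),
        ],
    )
    def test_closed_form_values(self, x, mode, expected):
        assert endpoint_form(x, mode) == pytest.approx(expected, abs=1e-15)

    @given(binary_vectors, st.integers(1, 6))
    @settings(derandomize=True, max_examples=150)
    def test_matches_final_wavefunction_value(self, x, mode):
        if x.sum() == 0 or lambda_n(x) == 0:
            return
        ws = wavefunction(x, mode)
        assert abs(ws.psi[-1] - endpoint_form(x, mode)) < 1e-12


class TestSeriesTable:
    def test_single_row(self):
        df = series_table(wavefunction([1]))
        assert df.values.tolist() == [[1, 1, 1, -1.0, 0.0]]
        assert list(df.columns) == ["k", "X", "Phi", "Re_psi", "Im_psi"]

    def test_window_restriction_and_empty_window(self, rng):
        x = (rng.random(300) < 0.3).astype(np.int8)
        if lambda_n(x) == 0 or x.sum() == 0:
            x[0] = 1
        ws = wavefunction(x)
        win = series_table(ws, k_min=100, k_max=200)
        assert win["k"].min() == 100 and win["k"].max() == 200 and len(win) == 101
        assert len(series_table(ws, k_min=5, k_max=4)) == 0
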