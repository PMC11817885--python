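import numpy as np
import pytest

from melpat.tqwt import (SubBandSet, TqwtDepthError, TqwtParams, max_levels,
                         reconstruct_single_band, tqwt_decompose,
                         tqwt_reconstruct)


@pytest.mark.parametrize("n", [512, 1000, 7500])
@pytest.mark.parametrize("Q,r,J", [(1, 3, 4), (2, 4, 12), (3, 5, 8)])
def test_perfect_reconstruction(n, Q, r, J):
    """decompose -> reconstruct is the identity to ~1e-8 relative error."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(n)
    params = TqwtParams(Q, r, J)
    if J > max_levels(n, params):
        pytest.skip("length does not support this depth")
    xr = tqwt_reconstruct(tqwt_decompose(x, params))
    assert np.max(np.abs(x - xr)) < 1e-8 * np.max(np.abs(x))


def test_band_count_and_lengths_at_defaults():
    """The default parameterisation (2, 4, 12) yields 13 non-empty bands."""
    sb = tqwt_decompose(np.random.default_rng(0).standard_normal(7500))
    assert len(sb) == 13
    assert all(len(b) > 0 for b in sb)
    # every band long enough for the 169-sample texture blocks
    assert min(len(b) for b in sb) >= 169


def test_zero_signal_gives_zero_bands():
    sb = tqwt_decompose(np.zeros(7500), TqwtParams(2, 4, 12))
    assert len(sb) == 13
    for band in sb:
        assert np.all(band == 0.0)


def test_energy_conservation_tight_frame():
    """Sum of band energies equals signal energy (Parseval, tight frame)."""
    rng = np.random.default_rng(8)
    x = rng.standard_normal(4096)
    sb = tqwt_decompose(x, TqwtParams(2, 4, 8))
    ratio = sb.energies().sum() / np.sum(x * x)
    assert 1 - 1e-8 < ratio < 1 + 1e-8


def test_linearity():
    rng = np.random.default_rng(5)
    x, y = rng.standard_normal((2, 1000))
    a, b = 2.5, -1.25
    sb_mix = tqwt_decompose(a * x + b * y, TqwtParams(2, 4, 6))
    sb_x = tqwt_decompose(x, TqwtParams(2, 4, 6))
    sb_y = tqwt_decompose(y, TqwtParams(2, 4, 6))
    for mix, bx, by in zip(sb_mix, sb_x, sb_y):
        assert np.allclose(mix, a * bx + b * by, atol=1e-10)


def test_circular_shift_leaves_band_energies_stable():
    """Band energies barely move under a one-sample shift of noise."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal(2048)
    e0 = tqwt_decompose(x, TqwtParams(2, 4, 6)).energies()
    e1 = tqwt_decompose(np.roll(x, 1), TqwtParams(2, 4, 6)).energies()
    assert np.all(np.abs(e1 - e0) <= 0.01 * e0 + 1e-12)


def test_depth_error_reports_max_feasible_levels():
    n = 64
    feasible = max_levels(n, TqwtParams(2, 4, 1))
    with pytest.raises(TqwtDepthError, match=r"at most J=\d+"):
        tqwt_decompose(np.ones(n), TqwtParams(2, 4, feasible + 1))
    tqwt_decompose(np.ones(n), TqwtParams(2, 4, feasible))  # must not raise


def test_reconstruct_rejects_inconsistent_bands():
    sb = tqwt_decompose(np.random.default_rng(1).standard_normal(1000),
                        TqwtParams(2, 4, 4))
    bad = SubBandSet(bands=[b[:-1] for b in sb.bands], params=sb.params,
                     source_length=sb.source_length)
    with pytest.raises(ValueError, match="length"):
        tqwt_reconstruct(bad)


def test_all_zero_bands_reconstruct_to_zero():
    sb = tqwt_decompose(np.random.default_rng(4).standard_normal(1000),
                        TqwtParams(2, 4, 4))
    zeroed = SubBandSet(bands=[np.zeros_like(b) for b in sb.bands],
                        params=sb.params, source_length=sb.source_length)
    assert np.allclose(tqwt_reconstruct(zeroed), 0.0)


def test_lowpass_band_reconstruction_is_low_frequency():
    """Content of the final low-pass band sits below its passband edge."""
    rng = np.random.default_rng(6)
    params = TqwtParams(2, 4, 12)
    sb = tqwt_decompose(rng.standard_normal(7500), params)
    x_low = reconstruct_single_band(sb, params.J)  # low-pass only
    spec = np.abs(np.fft.rfft(x_low)) ** 2
    freqs = np.fft.rfftfreq(len(x_low), d=1.0)  # cycles/sample
    centroid = np.sum(freqs * spec) / np.sum(spec)
    edge = 0.5 * params.alpha ** params.J  # low-pass edge after J levels
    assert centroid < edge


def test_parameter_validation():
    with pytest.raises(ValueError):
        TqwtParams(Q=0.5)
    with pytest.raises(ValueError):
        TqwtParams(r=1.0)
    with pytest.raises(ValueError):
        TqwtParams(J=0)
    with pytest.raises(ValueError):
        tqwt_decompose(np.array([1.0, np.nan, 0.0] * 300), TqwtParams(2, 4, 2))
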