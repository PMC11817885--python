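import numpy as np
import pytest

from melpat.features import (AblationFlags, FULL_LENGTH,
                             extract_segment_features, feature_names,
                             source_names)
from melpat.moments import moments_extract
from melpat.pattern import melpat_extract
from melpat.tqwt import TqwtParams, tqwt_decompose


@pytest.fixture(scope="module")
def segment():
    return np.random.default_rng(42).standard_normal(7500) * 15.0


def test_full_vector_length(segment):
    fv = extract_segment_features(segment)
    assert fv.shape == (FULL_LENGTH,) == (8624,)
    assert np.all(np.isfinite(fv))


def test_manifest_matches_vector(segment):
    names = feature_names()
    assert len(names) == 8624
    assert names[0] == "raw/melpat/sgn_g1_b00"
    assert names[576] == "raw/moments/sig_min"
    assert len(set(names)) == 8624  # round-trippable layout
    assert source_names() == (["raw"] + [f"band{j:02d}" for j in range(1, 13)]
                              + ["lowpass"])


def test_vector_is_concatenation_of_per_source_blocks(segment):
    """Compositionality: the vector equals independently computed blocks."""
    fv = extract_segment_features(segment)
    sb = tqwt_decompose(segment, TqwtParams())
    sources = [segment] + list(sb.bands)
    offset = 0
    for src in sources:
        mel = melpat_extract(src).values
        mom = moments_extract(src).values
        assert np.array_equal(fv[offset:offset + 576], mel)
        assert np.allclose(fv[offset + 576:offset + 616], mom)
        offset += 616
    assert offset == 8624


def test_determinism(segment):
    assert np.array_equal(extract_segment_features(segment),
                          extract_segment_features(segment.copy()))


@pytest.mark.parametrize("flags,expected", [
    (AblationFlags(include_moments=False), 576 * 14),
    (AblationFlags(include_melpat=False), 40 * 14),
    (AblationFlags(include_melpat=False, include_entropy=False), 30 * 14),
])
def test_ablation_lengths(segment, flags, expected):
    fv = extract_segment_features(segment, ablation=flags)
    assert fv.shape == (expected,)
    assert len(feature_names(ablation=flags)) == expected


def test_ablation_manifest_content():
    names = feature_names(ablation=AblationFlags(include_moments=False))
    assert all("/melpat/" in n for n in names)
    assert sum(n.startswith("raw/") for n in names) == 576
    names = feature_names(ablation=AblationFlags(include_entropy=False))
    assert not any("entropy" in n for n in names)


def test_all_blocks_disabled_rejected():
    with pytest.raises(ValueError):
        AblationFlags(include_melpat=False, include_moments=False)


def test_short_subband_names_offending_band():
    """A configuration whose deepest band is shorter than a block fails
    with the band named in the error."""
    short = np.random.default_rng(1).standard_normal(1000)
    with pytest.raises(ValueError, match="band|lowpass"):
        extract_segment_features(short, params=TqwtParams(2, 4, 12))


def test_reconstruction_mode(segment):
    """Band reconstructions give the same layout with different values."""
    fv = extract_segment_features(segment[:2000], params=TqwtParams(2, 4, 4))
    fv_rec = extract_segment_features(segment[:2000],
                                      params=TqwtParams(2, 4, 4),
                                      tqwt_mode="reconstruction")
    assert fv.shape == fv_rec.shape == ((576 + 40) * 6,)  # raw + 5 bands
    assert not np.array_equal(fv, fv_rec)
    # raw-source block identical in both modes
    assert np.allclose(fv[:616], fv_rec[:616])
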