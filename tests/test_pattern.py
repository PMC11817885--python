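"""Tests of the melatonin-graph texture extractor, including a literal
brute-force transcription used as an independent oracle."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melpat.pattern import (BLOCK_LENGTH, FEATURE_LENGTH,
                            MELATONIN_EDGE_TABLE, EdgeTable, bits_to_codes,
                            block_to_matrix, compute_threshold, extract_bits,
                            kernel_lower_ternary, kernel_signum,
                            kernel_upper_ternary, load_edge_table,
                            melpat_extract, save_edge_table)

# ---------------------------------------------------------------------------
# Independent oracle: a literal, scalar transcription of the algorithm.
# ---------------------------------------------------------------------------


def naive_melpat(signal, edges):
    """Double-loop reference: block -> matrix -> 18 bits -> 3 codes -> hists."""
    s = np.asarray(signal, dtype=float)
    thr = float(np.std(s, ddof=1)) / 2.0
    hists = {(k, g): [0] * 64 for k in ("sgn", "ut", "lt") for g in range(3)}
    for i in range(len(s) - BLOCK_LENGTH + 1):
        block = s[i:i + BLOCK_LENGTH]
        # column-major 13x13 fill, 1-based coordinates
        mx = {}
        for col in range(1, 14):
            for row in range(1, 14):
                mx[(row, col)] = block[(col - 1) * 13 + (row - 1)]
        for kernel in ("sgn", "ut", "lt"):
            bits = []
            for (sr, sc), (er, ec) in edges.edges:
                d = mx[(sr, sc)] - mx[(er, ec)]
                if kernel == "sgn":
                    bits.append(1 if d >= 0 else 0)
                elif kernel == "ut":
                    bits.append(1 if d > thr else 0)
                else:
                    bits.append(1 if d < -thr else 0)
            for g in range(3):
                code = 0
                for j, bit in enumerate(bits[g * 6:(g + 1) * 6]):
                    code += bit * 2 ** (5 - j)
                hists[(kernel, g)][code] += 1
    out = []
    for kernel in ("sgn", "ut", "lt"):
        for g in range(3):
            out.extend(hists[(kernel, g)])
    return np.array(out)


# ---------------------------------------------------------------------------
# Kernels and threshold
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a,b,expected", [(5, 3, 1), (3, 5, 0), (2, 2, 1)])
def test_kernel_signum(a, b, expected):
    assert kernel_signum(a, b) == expected


@pytest.mark.parametrize("a,b,thr,expected",
                         [(5, 3, 1, 1), (5, 3, 2, 0), (3, 5, 1, 0)])
def test_kernel_upper_ternary(a, b, thr, expected):
    assert kernel_upper_ternary(a, b, thr) == expected


@pytest.mark.parametrize("a,b,thr,expected",
                         [(3, 5, 1, 1), (4, 5, 1, 0), (5, 3, 1, 0)])
def test_kernel_lower_ternary(a, b, thr, expected):
    assert kernel_lower_ternary(a, b, thr) == expected


def test_threshold_is_half_sample_sd():
    rng = np.random.default_rng(1)
    s = rng.standard_normal(100) * 8.0
    assert compute_threshold(s) == pytest.approx(np.std(s, ddof=1) / 2)
    assert compute_threshold([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)
    assert compute_threshold(np.full(10, 4.2)) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Block/matrix/bits/codes
# ---------------------------------------------------------------------------


def test_block_to_matrix_column_major_coordinates():
    block = np.arange(1, 170, dtype=float)
    mx = block_to_matrix(block)
    assert mx[0, 0] == 1            # (1,1)
    assert mx[12, 9] == 130         # (13,10) = (10-1)*13 + 13
    assert mx[10, 11] == 154        # (11,12) = (12-1)*13 + 11
    assert np.array_equal(mx.reshape(-1, order="F"), block)  # bijection


def test_block_to_matrix_row_major_option():
    block = np.arange(1, 170, dtype=float)
    mx = block_to_matrix(block, order="row_major")
    assert mx[0, 1] == 2
    with pytest.raises(ValueError):
        block_to_matrix(block[:-1])


def test_extract_bits_constant_matrix():
    mx = np.full((13, 13), 3.0)
    assert np.all(extract_bits(mx, MELATONIN_EDGE_TABLE, "sgn") == 1)
    assert np.all(extract_bits(mx, MELATONIN_EDGE_TABLE, "ut", 0.5) == 0)
    assert np.all(extract_bits(mx, MELATONIN_EDGE_TABLE, "lt", 0.5) == 0)


def test_extract_bits_edge3_matches_printed_coordinates():
    """Edge 3 compares matrix (13,10) against (11,12)."""
    mx = block_to_matrix(np.arange(1, 170, dtype=float))
    bits = extract_bits(mx, MELATONIN_EDGE_TABLE, "sgn")
    assert bits[2] == kernel_signum(130, 154) == 0


def test_bits_to_codes():
    assert bits_to_codes([1, 0, 1, 0, 1, 0] + [0] * 12) == (42, 0, 0)
    assert bits_to_codes([0] * 18) == (0, 0, 0)
    assert bits_to_codes([1] * 18) == (63, 63, 63)


# ---------------------------------------------------------------------------
# Edge table
# ---------------------------------------------------------------------------


def test_default_edge_table_structure():
    table = MELATONIN_EDGE_TABLE
    assert len(table.edges) == 18
    assert table.edges[2] == ((13, 10), (11, 12))  # printed edge 3
    nodes = {pt for edge in table.edges for pt in edge}
    assert len(nodes) == 17  # heavy atoms of melatonin


def test_edge_table_json_round_trip(tmp_path):
    path = tmp_path / "edges.json"
    save_edge_table(MELATONIN_EDGE_TABLE, path)
    loaded = load_edge_table(path)
    assert loaded.edges == MELATONIN_EDGE_TABLE.edges


def test_edge_table_validation(tmp_path):
    with pytest.raises(ValueError, match="18 edges"):
        EdgeTable(edges=(((1, 1), (2, 2)),) * 17)
    with pytest.raises(ValueError, match="outside"):
        EdgeTable(edges=(((0, 1), (2, 2)),) + MELATONIN_EDGE_TABLE.edges[1:])
    with pytest.raises(ValueError, match="start equals end"):
        EdgeTable(edges=(((2, 2), (2, 2)),) + MELATONIN_EDGE_TABLE.edges[1:])
    bad = tmp_path / "bad.json"
    bad.write_text(json.dumps({"edges": []}))
    with pytest.raises(ValueError, match="groups"):
        load_edge_table(bad)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def test_feature_length_and_conservation(rng):
    s = rng.standard_normal(500)
    f = melpat_extract(s)
    assert f.values.shape == (FEATURE_LENGTH,)
    assert f.n_blocks == 500 - 168
    for kernel in ("sgn", "ut", "lt"):
        for group in (1, 2, 3):
            assert f.histogram(kernel, group).sum() == f.n_blocks


def test_constant_signal_forces_boundary_bins():
    """Constant input: all sgn mass in bin 63, all ternary mass in bin 0."""
    f = melpat_extract(np.full(500, 7.0))
    assert f.n_blocks == 332
    for group in (1, 2, 3):
        assert f.histogram("sgn", group)[63] == 332
        assert f.histogram("ut", group)[0] == 332
        assert f.histogram("lt", group)[0] == 332


def test_matches_naive_oracle_across_lengths():
    """Vectorised extraction equals the literal transcription bit-for-bit."""
    rng = np.random.default_rng(11)
    lengths = rng.integers(169, 1001, size=12)
    for n in lengths:
        s = rng.standard_normal(int(n))
        fast = melpat_extract(s).values
        assert np.array_equal(fast, naive_melpat(s, MELATONIN_EDGE_TABLE))


def test_scale_invariance_of_histograms(rng):
    """Positive scaling leaves all histograms unchanged (thr scales with sd)."""
    s = rng.standard_normal(400)
    assert np.array_equal(melpat_extract(s).values,
                          melpat_extract(3.7 * s).values)


def test_short_signal_rejected():
    with pytest.raises(ValueError, match="169"):
        melpat_extract(np.zeros(168))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=169, max_value=600),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_histograms_always_conserve_blocks(n, seed):
    """Property: every histogram sums to n - 168 and codes stay in 0..63."""
    s = np.random.default_rng(seed).standard_normal(n)
    f = melpat_extract(s)
    assert np.all(f.values >= 0)
    for kernel in ("sgn", "ut", "lt"):
        for group in (1, 2, 3):
            assert f.histogram(kernel, group).sum() == n - 168
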