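import numpy as np
import pytest

from melpat.selection import (chi2_rank, nca_rank, select_union,
                              selection_report)


@pytest.fixture(scope="module")
def planted():
    """Two informative features among 50 noise columns, n = 300."""
    rng = np.random.default_rng(9)
    n = 300
    y = np.array(["NS"] * (n // 2) + ["SD"] * (n // 2))
    F = rng.standard_normal((n, 52))
    F[y == "SD", 0] += 2.0
    F[y == "SD", 1] += 2.0
    return F, y


# -- Chi2 -------------------------------------------------------------------

def test_chi2_label_identical_feature_is_maximal(rng):
    n = 400
    y = rng.integers(0, 2, n).astype(str)
    F = rng.standard_normal((n, 20))
    F[:, 7] = (y == "1").astype(float)
    scores = chi2_rank(F, y)
    assert np.argmax(scores) == 7


def test_chi2_constant_feature_scores_zero(rng):
    y = np.array(["NS", "SD"] * 100)
    F = rng.standard_normal((200, 5))
    F[:, 2] = 3.14
    assert chi2_rank(F, y)[2] == 0.0


def test_chi2_independent_feature_below_permutation_null():
    """An unrelated feature's score is not extreme against its own
    permutation null (200 permutations, 99th percentile)."""
    rng = np.random.default_rng(5)
    n = 400
    y = np.array(["NS"] * 200 + ["SD"] * 200)
    x = rng.permutation(np.linspace(-1, 1, n))
    observed = chi2_rank(x[:, None], y)[0]
    null = np.array([chi2_rank(rng.permutation(x)[:, None], y)[0]
                     for _ in range(200)])
    assert observed < np.percentile(null, 99)


def test_chi2_affine_invariance(planted):
    F, y = planted
    base = chi2_rank(F, y)
    mapped = chi2_rank(2.5 * F + 7.0, y)
    assert np.allclose(base, mapped)


# -- NCA --------------------------------------------------------------------

def test_nca_recovers_planted_features(planted):
    F, y = planted
    w = nca_rank(F, y, seed=9)
    assert set(np.argsort(-w)[:2]) == {0, 1}


def test_nca_duplicated_feature_gets_equal_weight(rng):
    y = np.array(["NS", "SD"] * 100)
    F = rng.standard_normal((200, 20))
    F[y == "SD", 0] += 1.5
    F[:, 1] = F[:, 0]
    w = nca_rank(F, y, seed=0)
    assert abs(w[0] - w[1]) <= 0.1 * max(w[0], w[1])


def test_nca_all_noise_weights_collapse():
    """On pure noise with an adequate penalty all weights vanish: the
    leave-one-out term carries no signal, so the L2 term drives w to 0."""
    rng = np.random.default_rng(1)
    y = np.array(["NS", "SD"] * 25)
    for draw in range(3):
        w = nca_rank(rng.standard_normal((50, 20)), y, lam=0.05, seed=1)
        assert w.max() < 0.1


def test_nca_deterministic(planted):
    F, y = planted
    assert np.array_equal(nca_rank(F, y, seed=3), nca_rank(F, y, seed=3))


def test_nca_convergence_warning(planted):
    F, y = planted
    with pytest.warns(RuntimeWarning, match="did not converge"):
        nca_rank(F, y, max_iter=2, tol=1e-12)


# -- union ------------------------------------------------------------------

def test_union_bounds_and_tie_breaks():
    scores = np.arange(100, dtype=float)
    # identical rankings -> union size k
    sel = select_union(scores, scores.copy(), k=10)
    assert sel.n_selected == 10
    # disjoint top-k -> union size 2k
    sel2 = select_union(scores, -scores, k=10)
    assert sel2.n_selected == 20
    assert np.array_equal(sel2.union_indices, np.sort(sel2.union_indices))
    # ties broken towards the lower feature index, stably
    tied = np.zeros(100)
    sel3 = select_union(tied, tied, k=10)
    assert np.array_equal(sel3.union_indices, np.arange(10))
    with pytest.raises(ValueError):
        select_union(scores, scores, k=101)


def test_planted_union_recovery():
    """10 informative + 490 noise features, n = 400: at least 9 of the 10
    informative columns appear in the union of the two top-256 sets."""
    rng = np.random.default_rng(17)
    n = 400
    y = np.array(["NS", "SD"] * (n // 2))
    F = rng.standard_normal((n, 500))
    F[y == "SD", :10] += 1.5
    sel = select_union(chi2_rank(F, y), nca_rank(F, y, seed=2), k=256)
    assert 256 <= sel.n_selected <= 512
    recovered = sum(i in sel.union_indices for i in range(10))
    assert recovered >= 9


def test_selection_report_table(planted):
    F, y = planted
    sel = select_union(chi2_rank(F, y), nca_rank(F, y, seed=9), k=5)
    report = selection_report(sel, [f"f{i}" for i in range(F.shape[1])])
    assert len(report) == F.shape[1]
    assert report["selected"].sum() == sel.n_selected
    assert report.loc[0, "name"] == "f0"


def test_input_validation(planted):
    F, y = planted
    with pytest.raises(ValueError, match="two classes"):
        chi2_rank(F, np.array(["NS"] * F.shape[0]))
    with pytest.raises(ValueError, match="non-finite"):
        chi2_rank(np.full((10, 2), np.nan), np.array(["a", "b"] * 5))
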