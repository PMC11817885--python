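"""Dual feature selection: Chi2 ranking and NCA weighting, combined by union.

Both selectors rank all features against the class labels; the top 256
of each ranking are taken and the two index sets are united, giving
between 256 and 512 selected columns.

Chi2 here is the classic filter for continuous features: each feature is
min-max scaled to [0, 1], discretised into equal-width bins (10 by
default) and the chi-square statistic of the bin x class contingency
table is computed (expected counts from the marginals, empty bins
dropped).  Constant features score 0.

NCA is the feature-weighting variant of neighbourhood component
analysis: per-feature weights ``w`` parameterise the distance
``d(x_i, x_j) = sum_l w_l^2 |x_il - x_jl|`` and are fitted by gradient
ascent on the leave-one-out soft-neighbour classification objective

    F(w) = (1/n) sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_l w_l^2,
    p_ij = softmax_j(-d(x_i, x_j)),

so informative features keep large weights and noise features shrink
towards zero.  Features are z-scored internally before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["SelectedFeatures", "chi2_rank", "nca_rank", "select_union",
           "selection_report"]


@dataclass
class SelectedFeatures:
    """Outcome of the dual selection step."""

    chi2_indices: np.ndarray
    nca_indices: np.ndarray
    union_indices: np.ndarray
    chi2_scores: np.ndarray
    nca_weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.chi2_indices) != len(self.nca_indices):
            raise ValueError("selector index sets must have equal size")
        k = len(self.chi2_indices)
        if not k <= len(self.union_indices) <= 2 * k:
            raise ValueError("union size outside [k, 2k]")

    @property
    def n_selected(self) -> int:
        return int(len(self.union_indices))


def _check_inputs(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    F = np.asarray(F, dtype=float)
    y = np.asarray(y)
    if F.ndim != 2:
        raise ValueError("F must be a segments x features matrix")
    if y.shape[0] != F.shape[0]:
        raise ValueError("y length must match the number of rows of F")
    if not np.all(np.isfinite(F)):
        raise ValueError("F contains non-finite entries")
    if np.unique(y).shape[0] < 2:
        raise ValueError("at least two classes required")
    return F, y


def chi2_rank(F, y, n_bins: int = 10) -> np.ndarray:
    """Per-feature chi-square score of the binned feature vs the class."""
    F, y = _check_inputs(F, y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, d = F.shape
    n_classes = classes.shape[0]

    lo = F.min(axis=0)
    span = F.max(axis=0) - lo
    constant = span <= 0
    span = np.where(constant, 1.0, span)
    scaled = (F - lo) / span
    bins = np.minimum((scaled * n_bins).astype(np.intp), n_bins - 1)

    # counts[c, b, f] via one bincount per class over flattened (bin, feature)
    scores = np.zeros(d)
    counts = np.empty((n_classes, n_bins, d), dtype=float)
    offsets = bins + n_bins * np.arange(d)[None, :]
    for c in range(n_classes):
        flat = offsets[y_idx == c].ravel()
        counts[c] = np.bincount(flat, minlength=n_bins * d).reshape(d, n_bins).T

    class_tot = counts.sum(axis=1)               # (classes, features)
    bin_tot = counts.sum(axis=0)                 # (bins, features)
    expected = class_tot[:, None, :] * bin_tot[None, :, :] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (counts - expected) ** 2 / expected
    contrib[expected == 0] = 0.0                 # empty bins dropped
    scores = contrib.sum(axis=(0, 1))
    scores[constant] = 0.0
    return scores


def _pair_abs_diff(X: np.ndarray, start: int, stop: int) -> np.ndarray:
    """|x_i - x_j| for rows i in [start, stop) against all j, as
    ((stop-start)*n, d) float32."""
    n, d = X.shape
    Dc = np.abs(X[start:stop, None, :] - X[None, :, :])
    return Dc.reshape((stop - start) * n, d)


def _nca_objective_grad(X: np.ndarray, same: np.ndarray, w: np.ndarray,
                        lam: float, chunk: int,
                        cached: np.ndarray | None) -> tuple[float, np.ndarray]:
    n, d = X.shape
    w2 = (w * w).astype(np.float32)
    obj = 0.0
    grad = np.zeros(d, dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rows = stop - start
        if cached is not None:
            D = cached[start * n:stop * n]               # (rows*n, d)
        else:
            D = _pair_abs_diff(X, start, stop)
        dist = (D @ w2).reshape(rows, n)
        diag = (np.arange(rows), np.arange(start, stop))
        dist[diag] = np.inf                              # exclude j = i
        dist -= dist.min(axis=1, keepdims=True)          # softmax shift
        K = np.exp(-dist)
        K[diag] = 0.0
        P = K / K.sum(axis=1, keepdims=True)
        p_i = (P * same[start:stop]).sum(axis=1)
        obj += float(p_i.sum())
        A = (p_i[:, None] * P - P * same[start:stop]).astype(np.float32)
        grad += A.reshape(rows * n) @ D
    grad = (2.0 / n) * w * grad - 2.0 * lam * w
    obj = obj / n - lam * float(np.sum(w * w))
    return obj, grad


def nca_rank(F, y, lam: float | None = None, max_iter: int = 200,
             tol: float = 1e-6, seed: int = 0, standardize: bool = True,
             chunk_rows: int = 64, max_cache_bytes: float = 2e9) -> np.ndarray:
    """Fit NCA feature weights; returns one non-negative weight per feature.

    Parameters
    ----------
    lam : float or None
        L2 penalty; None uses 1 / n_segments.
    max_iter, tol
        Iteration cap and relative objective tolerance of the L-BFGS
        ascent.  The top-k ranking stabilises long before full
        convergence, so pipeline configurations may cap iterations well
        below the default.
    seed : int
        Kept for interface stability; the solver itself is deterministic
        (fixed initialisation).
    standardize : bool
        z-score features before fitting (recommended for mixed scales).
    max_cache_bytes : float
        If the n^2 x d pairwise-difference tensor fits in this many
        bytes (float32) it is precomputed once; otherwise it is rebuilt
        chunk-wise per objective evaluation.

    A convergence warning is issued (and the best iterate returned) if
    the objective has not stabilised within ``max_iter`` iterations.
    """
    F, y = _check_inputs(F, y)
    n, d = F.shape
    X = F.astype(np.float32)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    same = (y[:, None] == y[None, :]).astype(np.float32)
    np.fill_diagonal(same, 0.0)
    lam = 1.0 / n if lam is None else float(lam)
    chunk = max(1, min(chunk_rows, int(2e8 // max(1, n * d))))
    cached = None
    if 4.0 * n * n * d <= max_cache_bytes:
        cached = np.empty((n * n, d), dtype=np.float32)
        for s in range(0, n, chunk):
            e = min(s + chunk, n)
            cached[s * n:e * n] = _pair_abs_diff(X, s, e)
        chunk = n  # a single pass over the cached tensor per evaluation

    def negated(w: np.ndarray):
        obj, grad = _nca_objective_grad(X, same, w, lam, chunk, cached)
        return -obj, -grad

    result = minimize(negated, np.ones(d), jac=True, method="L-BFGS-B",
                      options={"maxiter": max_iter, "ftol": tol,
                               "gtol": 1e-12, "maxls": 20})
    if not result.success and result.nit >= max_iter:
        warnings.warn("NCA weight fit did not converge within "
                      f"{max_iter} iterations; returning the best iterate",
                      RuntimeWarning, stacklevel=2)
    return np.abs(result.x)


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    # stable: ties at the k-th rank broken by the lower feature index
    order = np.argsort(-scores, kind="stable")
    return order[:k]


def select_union(chi2_scores, nca_weights, k: int = 256) -> SelectedFeatures:
    """Union of the top-k features of each ranking (sorted, deduplicated)."""
    chi2_scores = np.asarray(chi2_scores, dtype=float)
    nca_weights = np.asarray(nca_weights, dtype=float)
    if chi2_scores.shape != nca_weights.shape:
        raise ValueError("score vectors must have equal length")
    d = chi2_scores.shape[0]
    if k > d:
        raise ValueError(f"k={k} exceeds the feature count {d}")
    alpha = _top_k(chi2_scores, k)
    beta = _top_k(nca_weights, k)
    union = np.union1d(alpha, beta)
    return SelectedFeatures(
        chi2_indices=np.sort(alpha), nca_indices=np.sort(beta),
        union_indices=union, chi2_scores=chi2_scores,
        nca_weights=nca_weights)


def selection_report(selected: SelectedFeatures,
                     feature_names: list[str] | None = None) -> pd.DataFrame:
    """Per-feature table of scores and selected-by flags."""
    d = selected.chi2_scores.shape[0]
    in_chi2 = np.zeros(d, dtype=bool)
    in_chi2[selected.chi2_indices] = True
    in_nca = np.zeros(d, dtype=bool)
    in_nca[selected.nca_indices] = True
    frame = pd.DataFrame({
        "index": np.arange(d),
        "name": feature_names if feature_names is not None else [""] * d,
        "chi2_score": selected.chi2_scores,
        "nca_weight": selected.nca_weights,
        "selected_chi2": in_chi2,
        "selected_nca": in_nca,
        "selected": in_chi2 | in_nca,
    })
    return frame
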