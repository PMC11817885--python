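"""Tunable Q-factor wavelet transform (TQWT).

The TQWT is an iterated two-channel filter bank defined directly in the
frequency domain.  Its three parameters are the Q-factor ``Q`` (number of
oscillations of the wavelet), the redundancy ``r`` and the number of
levels ``J``.  They fix the filter-bank scaling factors

    beta  = 2 / (Q + 1)          (high-pass band fraction)
    alpha = 1 - beta / r         (low-pass band fraction)

At every level the signal spectrum is split into a low-pass child of
~``alpha * n`` samples and a high-pass child of ~``beta * n`` samples; the
low-pass branch is split again ``J`` times, giving ``J + 1`` sub-bands
(detail 1 = highest frequency, ..., detail ``J``, then the final low-pass).
The transition band between the two children uses the Daubechies
frequency response

    theta(w) = 0.5 * (1 + cos w) * sqrt(2 - cos w),   w in [0, pi],

which satisfies ``theta(w)**2 + theta(pi - w)**2 == 1``, so the filter
bank is an exactly tight frame: energy is conserved and the inverse
transform reconstructs the input to machine precision.

This implementation operates on the real FFT of the signal and preserves
length parity between parent and children, so arbitrary input lengths
(odd or even) are admissible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TqwtParams",
    "SubBandSet",
    "TqwtDepthError",
    "tqwt_decompose",
    "tqwt_reconstruct",
    "max_levels",
]


class TqwtDepthError(ValueError):
    """Signal too short for the requested number of decomposition levels."""


@dataclass(frozen=True)
class TqwtParams:
    """Parameters of the tunable Q-factor wavelet transform.

    Attributes
    ----------
    Q : float
        Oscillation (quality) factor, >= 1.  Low Q gives good time
        localisation; the default Q=2 suits non-oscillatory EEG texture.
    r : float
        Redundancy factor, > 1.  Controls transition-band overlap.
    J : int
        Number of decomposition levels; the transform yields J+1 bands.
    """

    Q: float = 2.0
    r: float = 4.0
    J: int = 12

    def __post_init__(self) -> None:
        if not self.Q >= 1:
            raise ValueError(f"Q must be >= 1, got {self.Q}")
        if not self.r > 1:
            raise ValueError(f"r must be > 1, got {self.r}")
        if not (isinstance(self.J, (int, np.integer)) and self.J >= 1):
            raise ValueError(f"J must be a positive integer, got {self.J}")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


@dataclass
class SubBandSet:
    """Ordered TQWT sub-band coefficient sequences of one signal.

    ``bands[0]`` is the highest-frequency detail band, ``bands[J-1]`` the
    lowest detail band and ``bands[J]`` the final low-pass band.
    """

    bands: list[np.ndarray]
    params: TqwtParams
    source_length: int

    def __post_init__(self) -> None:
        if len(self.bands) != self.params.J + 1:
            raise ValueError(
                f"expected {self.params.J + 1} bands, got {len(self.bands)}"
            )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def energies(self) -> np.ndarray:
        """Per-band sum of squared coefficients."""
        return np.array([float(np.sum(b * b)) for b in self.bands])


def _child_lengths(n: int, alpha: float, beta: float) -> tuple[int, int]:
    # Children keep the parent's parity so every spectrum either has a
    # Nyquist bin at both ends of the mapping or at neither.
    if n % 2 == 0:
        n0 = 2 * int(round(alpha * n / 2.0))
        n1 = 2 * int(round(beta * n / 2.0))
    else:
        n0 = 2 * int(round(alpha * (n - 1) / 2.0)) + 1
        n1 = 2 * int(round(beta * (n - 1) / 2.0)) + 1
    return n0, n1


def _level_geometry(n: int, n0: int, n1: int):
    """Bin bookkeeping for one analysis/synthesis level.

    Returns (P, kmax_low, T, h0, h1): pass-band edge P, top low-pass bin,
    transition width T and the filter weights over parent rfft bins
    0..n//2.  Weights satisfy h0**2 + h1**2 == 1 exactly on every bin.
    """
    P = (n - n1) // 2
    kmax_low = n0 // 2
    T = kmax_low - P
    nbins = n // 2 + 1
    h0 = np.zeros(nbins)
    h1 = np.zeros(nbins)
    h0[: P + 1] = 1.0
    h1[kmax_low:] = 1.0
    if T > 0:
        w = np.arange(1, T + 1) * (np.pi / T)
        h0[P + 1 : P + T + 1] = 0.5 * (1 + np.cos(w)) * np.sqrt(2 - np.cos(w))
        wr = np.pi - w
        h1[P + 1 : P + T + 1] = 0.5 * (1 + np.cos(wr)) * np.sqrt(2 - np.cos(wr))
    return P, kmax_low, T, h0, h1


def _level_valid(n: int, n0: int, n1: int) -> bool:
    P = (n - n1) // 2
    T = n0 // 2 - P
    return n0 < n and n0 >= 4 and n1 >= 2 and P >= 0 and T >= 1


def max_levels(n: int, params: TqwtParams) -> int:
    """Maximum feasible number of decomposition levels for a length-n signal."""
    alpha, beta = params.alpha, params.beta
    j = 0
    while True:
        n0, n1 = _child_lengths(n, alpha, beta)
        if not _level_valid(n, n0, n1):
            return j
        n = n0
        j += 1
        if j > 200:  # alpha < 1 guarantees termination long before this
            return j


def _analysis_step(x: np.ndarray, alpha: float, beta: float):
    n = x.shape[0]
    n0, n1 = _child_lengths(n, alpha, beta)
    P, kmax_low, _T, h0, h1 = _level_geometry(n, n0, n1)
    X = np.fft.rfft(x)

    V0 = X[: kmax_low + 1] * h0[: kmax_low + 1] * np.sqrt(n0 / n)
    v0 = np.fft.irfft(V0, n0)

    nb1 = n1 // 2
    V1 = np.empty(nb1 + 1, dtype=complex)
    V1[0] = 0.0
    idx = P + np.arange(1, nb1 + 1)
    V1[1:] = X[idx] * h1[idx] * np.sqrt(n1 / n)
    v1 = np.fft.irfft(V1, n1)
    return v0, v1


def _synthesis_step(v0: np.ndarray, v1: np.ndarray, n: int,
                    alpha: float, beta: float) -> np.ndarray:
    n0, n1 = _child_lengths(n, alpha, beta)
    if v0.shape[0] != n0 or v1.shape[0] != n1:
        raise ValueError(
            f"band lengths ({v0.shape[0]}, {v1.shape[0]}) inconsistent with "
            f"parent length {n} (expected {n0}, {n1})"
        )
    P, kmax_low, _T, h0, h1 = _level_geometry(n, n0, n1)
    X = np.zeros(n // 2 + 1, dtype=complex)
    V0 = np.fft.rfft(v0)
    X[: kmax_low + 1] += V0 * h0[: kmax_low + 1] * np.sqrt(n / n0)
    V1 = np.fft.rfft(v1)
    idx = P + np.arange(1, n1 // 2 + 1)
    X[idx] += V1[1:] * h1[idx] * np.sqrt(n / n1)
    return np.fft.irfft(X, n)


def tqwt_decompose(s, params: TqwtParams = TqwtParams()) -> SubBandSet:
    """Decompose a 1-D signal into ``J + 1`` TQWT sub-bands.

    Parameters
    ----------
    s : array-like, 1-D
        Finite real signal.
    params : TqwtParams
        Transform parameters; the defaults (Q=2, r=4, J=12) give 13 bands.

    Returns
    -------
    SubBandSet
        ``params.J`` detail bands ordered high frequency to low, followed
        by the final low-pass band.

    Raises
    ------
    TqwtDepthError
        If the signal is too short for ``J`` levels; the message reports
        the maximum feasible depth.
    """
    x = np.asarray(s, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    feasible = max_levels(x.shape[0], params)
    if params.J > feasible:
        raise TqwtDepthError(
            f"signal of length {x.shape[0]} supports at most J={feasible} "
            f"levels at (Q={params.Q}, r={params.r}); requested J={params.J}"
        )
    bands: list[np.ndarray] = []
    cur = x
    for _ in range(params.J):
        cur, detail = _analysis_step(cur, params.alpha, params.beta)
        bands.append(detail)
    bands.append(cur)
    return SubBandSet(bands=bands, params=params, source_length=x.shape[0])


def tqwt_reconstruct(subbands: SubBandSet) -> np.ndarray:
    """Invert :func:`tqwt_decompose`; exact up to floating-point rounding."""
    params = subbands.params
    # Recompute the length cascade from source_length and check consistency.
    lengths = [subbands.source_length]
    for _ in range(params.J):
        n0, _n1 = _child_lengths(lengths[-1], params.alpha, params.beta)
        lengths.append(n0)
    for j in range(params.J):
        _n0, n1 = _child_lengths(lengths[j], params.alpha, params.beta)
        if subbands.bands[j].shape[0] != n1:
            raise ValueError(
                f"detail band {j + 1} has length {subbands.bands[j].shape[0]}, "
                f"expected {n1} for source length {subbands.source_length}"
            )
    if subbands.bands[params.J].shape[0] != lengths[params.J]:
        raise ValueError(
            f"low-pass band has length {subbands.bands[params.J].shape[0]}, "
            f"expected {lengths[params.J]}"
        )
    cur = np.asarray(subbands.bands[params.J], dtype=float)
    for j in range(params.J - 1, -1, -1):
        cur = _synthesis_step(
            cur, np.asarray(subbands.bands[j], dtype=float), lengths[j],
            params.alpha, params.beta,
        )
    return cur


def reconstruct_single_band(subbands: SubBandSet, band_index: int) -> np.ndarray:
    """Full-length reconstruction of one sub-band with all others zeroed.

    ``band_index`` is 0-based into ``subbands.bands``.  Used when features
    are computed on band reconstructions instead of raw coefficients.
    """
    zeroed = [np.zeros_like(b) if i != band_index else b
              for i, b in enumerate(subbands.bands)]
    return tqwt_reconstruct(
        SubBandSet(bands=zeroed, params=subbands.params,
                   source_length=subbands.source_length)
    )
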