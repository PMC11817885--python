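"""Statistical descriptor features (20 per signal version, 40 total).

Twenty descriptors are computed on the signal and again on its absolute
value.  Sixteen are the classic set (min, max, mean, median, sd,
variance, RMS, energy, five wavelet-style entropies, skewness, kurtosis,
MAD); the remaining four (range, interquartile range, mean absolute
deviation, crest factor) round the block out to twenty and are swappable
without affecting any downstream stage.

Entropy conventions follow the wavelet-entropy family:

* Shannon:     -sum(s_i^2 * ln s_i^2), with 0*ln 0 = 0
* SURE:        n - #{|s_i| <= eps} + sum(min(s_i^2, eps^2))
* log-energy:  sum(ln s_i^2), zero samples contributing 0
* threshold:   #{|s_i| > eps}
* norm:        sum(|s_i|^p), 1 <= p < 2

``eps`` defaults to half the sample standard deviation of the input
(the same convention as the ternary-kernel threshold) and ``p`` to 1.5;
both are configurable since no canonical value exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MomentFeatures", "moments_extract", "DESCRIPTOR_NAMES",
           "ENTROPY_DESCRIPTORS", "N_DESCRIPTORS", "FEATURE_LENGTH"]

DESCRIPTOR_NAMES = (
    "min", "max", "mean", "median", "std", "variance", "rms", "energy",
    "shannon_entropy", "sure_entropy", "log_energy_entropy",
    "threshold_entropy", "norm_entropy",
    "skewness", "kurtosis", "mad",
    "range", "iqr", "mean_abs_dev", "crest_factor",
)
ENTROPY_DESCRIPTORS = frozenset((
    "shannon_entropy", "sure_entropy", "log_energy_entropy",
    "threshold_entropy", "norm_entropy",
))
N_DESCRIPTORS = len(DESCRIPTOR_NAMES)          # 20
FEATURE_LENGTH = 2 * N_DESCRIPTORS             # 40


@dataclass
class MomentFeatures:
    """40 descriptor values: 20 on the signal, then 20 on |signal|."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FEATURE_LENGTH,):
            raise ValueError(f"expected {FEATURE_LENGTH} values, "
                             f"got {self.values.shape}")

    def descriptor(self, name: str, absolute: bool = False) -> float:
        i = DESCRIPTOR_NAMES.index(name) + (N_DESCRIPTORS if absolute else 0)
        return float(self.values[i])


def _describe(x: np.ndarray, eps, p: float) -> np.ndarray:
    n = x.size
    if eps is None:
        eps = float(np.std(x, ddof=1) / 2.0)
    sq = x * x
    energy = float(np.sum(sq))
    rms = float(np.sqrt(energy / n))
    mean = float(np.mean(x))
    med = float(np.median(x))
    sd = float(np.std(x, ddof=1))

    nz = sq > 0.0
    log_sq = np.log(sq[nz])
    shannon = float(-np.sum(sq[nz] * log_sq))
    log_energy = float(np.sum(log_sq))
    sure = float(n - np.count_nonzero(np.abs(x) <= eps)
                 + np.sum(np.minimum(sq, eps * eps)))
    threshold_ent = float(np.count_nonzero(np.abs(x) > eps))
    norm_ent = float(np.sum(np.abs(x) ** p))

    centred = x - mean
    if sd > 0.0:
        z = centred / np.sqrt(np.mean(centred * centred))
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))  # raw 4th standardised moment
    else:
        skew = 0.0
        kurt = 0.0

    mad = float(np.median(np.abs(x - med)))
    rng = float(np.max(x) - np.min(x))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    crest = float(np.max(np.abs(x)) / rms) if rms > 0.0 else 0.0

    return np.array([
        np.min(x), np.max(x), mean, med, sd, sd * sd, rms, energy,
        shannon, sure, log_energy, threshold_ent, norm_ent,
        skew, kurt, mad,
        rng, float(q75 - q25), float(np.mean(np.abs(centred))), crest,
    ])


def moments_extract(s, entropy_eps: float | None = None,
                    norm_p: float = 1.5) -> MomentFeatures:
    """Compute the 40 statistical descriptors of a 1-D signal.

    Parameters
    ----------
    s : array-like, 1-D, length >= 2
    entropy_eps : float or None
        Threshold for the SURE/threshold entropies.  None (default)
        uses half the sample standard deviation of each signal version.
    norm_p : float
        Norm-entropy exponent, 1 <= p < 2.

    The 20 descriptors are evaluated on ``s`` and then on ``|s|``; when
    ``entropy_eps`` is None, eps is recomputed from each version.
    """
    x = np.asarray(s, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if not 1.0 <= norm_p < 2.0:
        raise ValueError(f"norm_p must be in [1, 2), got {norm_p}")
    if entropy_eps is not None and entropy_eps < 0:
        raise ValueError("entropy_eps must be >= 0")
    values = np.concatenate([
        _describe(x, entropy_eps, norm_p),
        _describe(np.abs(x), entropy_eps, norm_p),
    ])
    return MomentFeatures(values=values)
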