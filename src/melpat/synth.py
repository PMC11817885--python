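"""Synthetic two-class resting-state EEG.

The generator emulates the study conditions of the sleep-deprivation
problem: multi-channel recordings sampled at 500 Hz, 5 minutes long,
segmentable into 15 s windows, with a class-dependent spectral contrast.
Each channel is

    x_ch = w_ch * common + pink_ch + theta_ch + alpha_ch      [microvolts]

where ``common`` is a 1/f (pink) source shared by all channels (spatial
correlation), ``pink_ch`` is independent pink noise, and the slow
(1-8 Hz, "delta/theta") and alpha (8-13 Hz) oscillations are
band-filtered noise with fixed RMS amplitudes.  The sleep-deprived (SD)
class multiplies the slow-band *power* by ``theta_power_ratio``
(amplitude x sqrt(ratio)); a ratio of 1 makes the two classes draw from
the same distribution.  Given the same seed the output is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .io import EegRecording

__all__ = ["BandPowerEffect", "generate_synthetic_dataset", "band_power"]


@dataclass(frozen=True)
class BandPowerEffect:
    """Class contrast of the generator, as band-power parameters.

    ``theta_power_ratio`` is the SD/NS power ratio of the slow band
    (must be > 0; 1.0 means no class difference).  RMS amplitudes are in
    microvolts and apply to the NS class.
    """

    theta_power_ratio: float = 3.0
    theta_band: tuple[float, float] = (1.0, 8.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    theta_rms: float = 3.0
    alpha_rms: float = 5.0
    background_rms: float = 10.0
    common_rms: float = 6.0

    def __post_init__(self) -> None:
        if not self.theta_power_ratio > 0:
            raise ValueError("theta_power_ratio must be positive "
                             f"(1.0 = no effect), got {self.theta_power_ratio}")
        for name in ("theta_rms", "alpha_rms", "background_rms", "common_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f-power-shaped Gaussian noise with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.sqrt(np.mean(x * x)))


def _band_noise(rng: np.random.Generator, n: int, srate: float,
                band: tuple[float, float], rms: float) -> np.ndarray:
    """Zero-phase band-filtered Gaussian noise with the requested RMS."""
    lo, hi = band
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=srate, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    return x * (rms / np.sqrt(np.mean(x * x)))


def generate_synthetic_dataset(n_subjects_per_class: int = 5,
                               n_channels: int = 4,
                               duration_seconds: float = 300.0,
                               srate: float = 500.0,
                               effect: BandPowerEffect = BandPowerEffect(),
                               seed: int = 0,
                               channel_labels: list[str] | None = None
                               ) -> list[EegRecording]:
    """Generate paired NS/SD recordings for synthetic subjects.

    Returns one NS and one SD recording per subject (within-subject
    design), ``2 * n_subjects_per_class`` recordings in total.  The
    default sizes mirror the study conditions per recording (500 Hz,
    5 min) at a desk-scale channel count.
    """
    if n_subjects_per_class <= 0 or n_channels <= 0:
        raise ValueError("counts must be positive")
    if duration_seconds <= 0 or srate <= 0:
        raise ValueError("duration and srate must be positive")
    n = int(round(duration_seconds * srate))
    labels = channel_labels or [f"CH{i + 1:02d}" for i in range(n_channels)]
    if len(labels) != n_channels:
        raise ValueError("channel_labels length must equal n_channels")

    root = np.random.SeedSequence(seed)
    recordings: list[EegRecording] = []
    for subj in range(n_subjects_per_class):
        subj_seq = root.spawn(1)[0]
        for condition in ("NS", "SD"):
            rng = np.random.default_rng(subj_seq.spawn(1)[0])
            theta_rms = effect.theta_rms
            if condition == "SD":
                theta_rms = theta_rms * np.sqrt(effect.theta_power_ratio)
            common = _pink_noise(rng, n, effect.common_rms)
            weights = rng.uniform(0.5, 1.0, size=n_channels)
            data = np.empty((n_channels, n))
            for ch in range(n_channels):
                data[ch] = (
                    weights[ch] * common
                    + _pink_noise(rng, n, effect.background_rms)
                    + _band_noise(rng, n, srate, effect.theta_band, theta_rms)
                    + _band_noise(rng, n, srate, effect.alpha_band,
                                  effect.alpha_rms)
                )
            recordings.append(EegRecording(
                data=data, srate=float(srate), channel_labels=list(labels),
                subject_id=f"sub-{subj + 1:03d}", condition_label=condition))
    return recordings


def band_power(x, srate: float, lo: float, hi: float) -> float:
    """Average power of ``x`` in the [lo, hi] Hz band (Welch estimate)."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.shape[0], 1024)
    freqs, psd = _sig.welch(x, fs=srate, nperseg=nperseg)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[mask], freqs[mask]))
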