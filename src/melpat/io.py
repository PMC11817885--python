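"""EEG recording I/O, segmentation and dataset containers.

Recordings are read through MNE (BrainVision ``.vhdr``, EDF/EDF+ and
EEGLAB ``.set``) into a light :class:`EegRecording` holding the data in
microvolts.  Recordings are cut into non-overlapping, left-aligned
windows (15 s by default; trailing remainders are discarded) and stacked
into a :class:`SegmentedDataset`, the unit the classification pipeline
consumes: per-channel segment matrices with one label vector aligned
across channels.

Small writers for EDF (16-bit), BrainVision (IEEE float32) and EEGLAB
``.set`` are included so synthetic recordings can be round-tripped
through the standard readers in tests; they cover only the plain
continuous-EEG subset of each format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EegRecording", "SegmentedDataset",
    "FormatError", "UnsupportedFormatError", "EmptySegmentationError",
    "read_recording", "segment_recording", "build_dataset",
    "read_bids_dataset", "write_edf", "write_brainvision", "write_eeglab_set",
]

CLASS_LABELS = ("NS", "SD")


class FormatError(ValueError):
    """A file could not be parsed under its declared standard."""


class UnsupportedFormatError(ValueError):
    """The requested file format is not one of the supported readers."""


class EmptySegmentationError(ValueError):
    """Recording shorter than a single window."""


@dataclass
class EegRecording:
    """A multi-channel EEG recording.

    ``data`` is channels x samples in microvolts; ``condition_label`` is
    one of {"NS", "SD"} (or None when unknown at read time).
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    subject_id: str = "unknown"
    condition_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels")
        if not self.srate > 0:
            raise ValueError(f"srate must be positive, got {self.srate}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.condition_label is not None and \
                self.condition_label not in CLASS_LABELS:
            raise ValueError(f"condition_label must be one of {CLASS_LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentedDataset:
    """Segments grouped by channel with one aligned label vector.

    ``data[ch]`` is an (n_segments, window_length) array; ``y`` holds the
    class tag of every segment in the same order for every channel, and
    ``origins`` the (subject_id, window_index) provenance.
    """

    channels: list[str]
    data: dict[str, np.ndarray]
    y: np.ndarray
    srate: float
    origins: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        n = self.y.shape[0]
        for ch in self.channels:
            if ch not in self.data:
                raise ValueError(f"missing data for channel {ch!r}")
            if self.data[ch].shape[0] != n:
                raise ValueError(
                    f"channel {ch!r} holds {self.data[ch].shape[0]} segments "
                    f"but y has {n}")

    @property
    def n_segments(self) -> int:
        return int(self.y.shape[0])

    @property
    def window_length(self) -> int:
        return int(self.data[self.channels[0]].shape[1])

    def save(self, directory) -> None:
        """Write the index as CSV and the arrays as an ``.npz`` container."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = pd.DataFrame({
            "segment": np.arange(self.n_segments),
            "subject": [s for s, _ in self.origins] or [""] * self.n_segments,
            "window": [w for _, w in self.origins] or [-1] * self.n_segments,
            "label": self.y,
        })
        index.to_csv(directory / "segments.csv", index=False)
        meta = {"srate": np.array([self.srate]),
                "channels": np.array(self.channels)}
        arrays = {f"ch_{i}": self.data[ch]
                  for i, ch in enumerate(self.channels)}
        np.savez(directory / "segments.npz", **meta, **arrays)

    @classmethod
    def load(cls, directory) -> "SegmentedDataset":
        directory = Path(directory)
        index = pd.read_csv(directory / "segments.csv", keep_default_na=False)
        with np.load(directory / "segments.npz", allow_pickle=False) as z:
            channels = [str(c) for c in z["channels"]]
            srate = float(z["srate"][0])
            data = {ch: z[f"ch_{i}"] for i, ch in enumerate(channels)}
        origins = list(zip(index["subject"].astype(str),
                           index["window"].astype(int)))
        return cls(channels=channels, data=data,
                   y=index["label"].to_numpy(), srate=srate, origins=origins)


# ---------------------------------------------------------------------------
# Readers (via MNE)
# ---------------------------------------------------------------------------

_SUFFIX_FORMAT = {".vhdr": "brainvision", ".edf": "edf", ".set": "eeglab_set"}


def read_recording(path, fmt: str | None = None,
                   condition: str | None = None,
                   subject: str | None = None) -> EegRecording:
    """Read one EEG file into an :class:`EegRecording` (data in microvolts).

    Parameters
    ----------
    path : path-like
    fmt : {"brainvision", "edf", "eeglab_set"} or None
        None infers the format from the file suffix.
    condition, subject
        Class tag and subject id to attach (file headers do not carry
        the experimental condition).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
        if fmt is None:
            raise UnsupportedFormatError(
                f"cannot infer format from suffix {path.suffix!r}")

    import mne  # deferred: mne import is slow

    readers = {
        "brainvision": lambda p: mne.io.read_raw_brainvision(
            p, preload=True, verbose="error"),
        "edf": lambda p: mne.io.read_raw_edf(p, preload=True, verbose="error"),
        "eeglab_set": lambda p: mne.io.read_raw_eeglab(
            p, preload=True, verbose="error"),
    }
    if fmt not in readers:
        raise UnsupportedFormatError(f"unsupported format {fmt!r}")
    try:
        raw = readers[fmt](str(path))
    except (UnsupportedFormatError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalise reader failures
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # MNE returns volts for EEG channels
    return EegRecording(
        data=data_uv,
        srate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject or path.stem,
        condition_label=condition,
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_recording(rec: EegRecording,
                      window_seconds: float = 15.0) -> SegmentedDataset:
    """Cut a recording into non-overlapping, left-aligned windows.

    The trailing remainder shorter than one window is discarded; every
    segment inherits the recording's class tag.
    """
    if not window_seconds > 0:
        raise ValueError("window_seconds must be positive")
    win = int(round(window_seconds * rec.srate))
    n_seg = rec.n_samples // win
    if n_seg == 0:
        raise EmptySegmentationError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{win}-sample window")
    y = np.array([rec.condition_label] * n_seg)
    data = {ch: rec.data[i, : n_seg * win].reshape(n_seg, win)
            for i, ch in enumerate(rec.channel_labels)}
    origins = [(rec.subject_id, w) for w in range(n_seg)]
    return SegmentedDataset(channels=list(rec.channel_labels), data=data,
                            y=y, srate=rec.srate, origins=origins)


def build_dataset(recordings, window_seconds: float = 15.0) -> SegmentedDataset:
    """Segment and concatenate recordings into one aligned dataset.

    All recordings must share sampling rate and channel set (order is
    taken from the first recording).
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    channels = list(recordings[0].channel_labels)
    srate = recordings[0].srate
    parts = []
    for rec in recordings:
        if rec.srate != srate:
            raise ValueError("recordings differ in sampling rate")
        if set(rec.channel_labels) != set(channels):
            raise ValueError("recordings differ in channel set")
        seg = segment_recording(rec, window_seconds)
        parts.append(seg)
    y = np.concatenate([p.y for p in parts])
    data = {ch: np.vstack([p.data[ch] for p in parts]) for ch in channels}
    origins = [o for p in parts for o in p.origins]
    return SegmentedDataset(channels=channels, data=data, y=y,
                            srate=srate, origins=origins)


# ---------------------------------------------------------------------------
# BIDS directory walker
# ---------------------------------------------------------------------------

def read_bids_dataset(root, task: str | None = None, run: str | None = None,
                      session: str | None = None,
                      condition_map=None) -> list[EegRecording]:
    """Walk a BIDS EEG layout and read the matching recordings.

    Parameters
    ----------
    root : path-like
        BIDS dataset root (``sub-*/[ses-*/]eeg/*_eeg.<ext>``).
    task, run, session : str or None
        Entity filters; None matches anything.  Selecting the eyes-open
        task is a configuration choice, not hard-coded.
    condition_map : callable or None
        ``condition_map(entities) -> {"NS", "SD", None}`` where
        ``entities`` is the dict of BIDS entities of a file (keys such
        as "sub", "ses", "task", "run").  Required to attach class tags,
        since counterbalanced designs encode the condition outside the
        file name.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(root)
    recordings = []
    exts = sorted(_SUFFIX_FORMAT)
    for path in sorted(p for ext in exts for p in root.rglob(f"*_eeg{ext}")):
        entities = {}
        for token in path.stem.split("_"):
            if "-" in token:
                key, value = token.split("-", 1)
                entities[key] = value
        if task is not None and entities.get("task") != task:
            continue
        if run is not None and entities.get("run") != run:
            continue
        if session is not None and entities.get("ses") != session:
            continue
        condition = condition_map(entities) if condition_map else None
        recordings.append(read_recording(
            path, condition=condition,
            subject=entities.get("sub", path.stem)))
    return recordings


# ---------------------------------------------------------------------------
# Writers (test/round-trip helpers)
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EegRecording) -> None:
    """Write a 16-bit EDF file (1 s data records, physical unit uV).

    Only whole 1 s records are written; amplitudes are quantised to the
    per-channel physical range, so round trips are exact only to the
    16-bit resolution ``(max - min) / 65535``.
    """
    path = Path(path)
    spr = int(round(rec.srate))
    if abs(spr - rec.srate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s EDF record")
    nch = rec.n_channels
    data = rec.data[:, : n_records * spr]

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    header = b"0       "  # version
    header += _ascii_field(rec.subject_id, 80)
    header += _ascii_field("melpat synthetic", 80)
    header += b"01.01.00" + b"00.00.00"
    header += _ascii_field(256 * (1 + nch), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)  # record duration, seconds
    header += _ascii_field(nch, 4)
    for ch in rec.channel_labels:
        header += _ascii_field(ch, 16)
    header += b"".join(_ascii_field("", 80) for _ in range(nch))
    header += b"".join(_ascii_field("uV", 8) for _ in range(nch))
    header += b"".join(_ascii_field(f"{v:.1f}", 8) for v in pmin)
    header += b"".join(_ascii_field(f"{v:.1f}", 8) for v in pmax)
    header += b"".join(_ascii_field(dmin, 8) for _ in range(nch))
    header += b"".join(_ascii_field(dmax, 8) for _ in range(nch))
    header += b"".join(_ascii_field("", 80) for _ in range(nch))
    header += b"".join(_ascii_field(spr, 8) for _ in range(nch))
    header += b"".join(_ascii_field("", 32) for _ in range(nch))

    gain = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = data[:, r * spr:(r + 1) * spr]
            digital = np.rint((chunk - pmin[:, None]) * gain[:, None] + dmin)
            fh.write(digital.astype("<i2").tobytes())


def write_brainvision(basepath, rec: EegRecording) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32, uV).

    ``basepath`` is the path without extension; returns the ``.vhdr``
    path.
    """
    base = Path(basepath)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    sampling_interval_us = 1e6 / rec.srate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8")
    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def write_eeglab_set(path, rec: EegRecording) -> None:
    """Write a minimal continuous EEGLAB ``.set`` file (scipy MAT v5)."""
    from scipy.io import savemat

    n = rec.n_samples
    chanlocs = np.zeros((rec.n_channels,),
                        dtype=[("labels", object), ("type", object),
                               ("theta", object), ("radius", object),
                               ("X", object), ("Y", object), ("Z", object),
                               ("sph_theta", object), ("sph_phi", object),
                               ("sph_radius", object), ("urchan", object),
                               ("ref", object)])
    for i, ch in enumerate(rec.channel_labels):
        chanlocs["labels"][i] = ch
        for key in ("theta", "radius", "X", "Y", "Z",
                    "sph_theta", "sph_phi", "sph_radius", "urchan"):
            chanlocs[key][i] = np.array([])
        chanlocs["type"][i] = "EEG"
        chanlocs["ref"][i] = ""
    eeg = {
        "setname": "melpat synthetic", "filename": Path(path).name,
        "filepath": "", "subject": rec.subject_id, "group": "",
        "condition": rec.condition_label or "", "session": 1, "comments": "",
        "nbchan": float(rec.n_channels), "trials": 1.0, "pnts": float(n),
        "srate": float(rec.srate), "xmin": 0.0,
        "xmax": (n - 1) / rec.srate,
        "times": np.arange(n) / rec.srate * 1000.0,
        "data": rec.data.astype(np.float32),
        "icaact": np.array([]), "icawinv": np.array([]),
        "icasphere": np.array([]), "icaweights": np.array([]),
        "icachansind": np.array([]),
        "chanlocs": chanlocs, "urchanlocs": np.array([]),
        "chaninfo": {"nosedir": "+X"}, "ref": "common",
        "event": np.array([]), "urevent": np.array([]),
        "eventdescription": np.array([], dtype=object),
        "epoch": np.array([]), "epochdescription": np.array([], dtype=object),
        "reject": {}, "stats": {}, "specdata": np.array([]),
        "specicaact": np.array([]), "splinefile": "", "icasplinefile": "",
        "dipfit": np.array([]), "history": "", "saved": "yes",
        "etc": np.array([]),
    }
    savemat(str(path), {"EEG": eeg}, appendmat=False)
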