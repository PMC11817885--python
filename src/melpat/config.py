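"""Pipeline configuration.

All tunable keys of the pipeline live in one dataclass tree that
round-trips through YAML for the command line.  Defaults are the study
protocol: 15 s windows, TQWT (Q=2, r=4, J=12), 256 features per
selector, Gaussian SVM (kernel scale 20, box constraint 1) under
stratified 10-fold CV with SD as the positive class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import AblationFlags
from .tqwt import TqwtParams

__all__ = ["SelectionConfig", "SvmConfig", "PipelineConfig", "CHANNELS_61"]

# Canonical 61-channel order of the study montage, used for reporting.
CHANNELS_61 = [
    "Fp1", "AF3", "AF7", "Fz", "F1", "F3", "F5", "F7", "FC1", "FC3",
    "FC5", "FT7", "Cz", "C1", "C3", "C5", "T7", "CP1", "CP3", "CP5",
    "TP7", "TP9", "Pz", "P1", "P3", "P5", "P7", "PO3", "PO7", "Oz",
    "O1", "Fpz", "Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8", "FC2",
    "FC4", "FC6", "FT8", "C2", "C4", "C6", "T8", "CPz", "CP2", "CP4",
    "CP6", "TP8", "TP10", "P2", "P4", "P6", "P8", "POz", "PO4", "PO8",
    "O2",
]


@dataclass(frozen=True)
class SelectionConfig:
    k: int = 256
    chi2_bins: int = 10
    nca_lambda: float | None = None      # None -> 1 / n_segments
    nca_max_iter: int = 60               # ranking stabilises early; see docs
    nca_tol: float = 1e-6
    nca_standardize: bool = True


@dataclass(frozen=True)
class SvmConfig:
    kernel_scale: float = 20.0
    box_constraint: float = 1.0
    folds: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    window_seconds: float = 15.0
    tqwt: TqwtParams = field(default_factory=TqwtParams)
    tqwt_mode: str = "coefficients"      # or "reconstruction"
    matrix_order: str = "column_major"
    edge_table_path: str | None = None   # None -> melatonin default
    moments_entropy_eps: float | None = None
    moments_norm_p: float = 1.5
    ablation: AblationFlags = field(default_factory=AblationFlags)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    positive_class: str = "SD"
    bids_task: str | None = "eyesopen"   # eyes-open runs by default
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "tqwt" in kwargs:
            kwargs["tqwt"] = TqwtParams(**kwargs["tqwt"])
        if "ablation" in kwargs:
            kwargs["ablation"] = AblationFlags(**kwargs["ablation"])
        if "selection" in kwargs:
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "svm" in kwargs:
            kwargs["svm"] = SvmConfig(**kwargs["svm"])
        return cls(**kwargs)
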