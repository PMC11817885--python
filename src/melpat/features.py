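"""Per-segment multi-level feature vectors.

One EEG segment yields 14 feature sources: the raw segment plus the 13
TQWT sub-bands (Q=2, r=4, J=12 by default).  Each source contributes the
576 MelPat histogram counts followed by the 40 statistical descriptors,
giving (576 + 40) x 14 = 8624 features at the defaults.  Ablation flags
can drop the MelPat block, the moments block, or only the entropy
descriptors; the layout manifest (one name per column) always reflects
the active configuration.

Features are computed on the sub-band coefficient sequences directly;
``tqwt_mode="reconstruction"`` substitutes full-length single-band
reconstructions instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import moments as _moments
from . import pattern as _pattern
from .moments import moments_extract
from .pattern import EdgeTable, MELATONIN_EDGE_TABLE, melpat_extract
from .tqwt import TqwtParams, reconstruct_single_band, tqwt_decompose

__all__ = ["AblationFlags", "extract_segment_features", "feature_names",
           "source_names", "FULL_LENGTH"]

FULL_LENGTH = (_pattern.FEATURE_LENGTH + _moments.FEATURE_LENGTH) * 14  # 8624


@dataclass(frozen=True)
class AblationFlags:
    """Feature-block switches for ablation studies.

    ``include_entropy`` only matters while ``include_moments`` is True;
    switching it off drops the five entropy descriptors from both signal
    versions (40 -> 30 moments per source).
    """

    include_melpat: bool = True
    include_moments: bool = True
    include_entropy: bool = True

    def __post_init__(self) -> None:
        if not (self.include_melpat or self.include_moments):
            raise ValueError("at least one feature block must be enabled")


def source_names(params: TqwtParams = TqwtParams()) -> list[str]:
    """Frozen source order: raw, detail bands high->low, final low-pass."""
    return (["raw"]
            + [f"band{j:02d}" for j in range(1, params.J + 1)]
            + ["lowpass"])


def _moment_indices(ablation: AblationFlags) -> list[int]:
    keep = [i for i, name in enumerate(_moments.DESCRIPTOR_NAMES)
            if ablation.include_entropy or name not in _moments.ENTROPY_DESCRIPTORS]
    return keep + [i + _moments.N_DESCRIPTORS for i in keep]


def feature_names(params: TqwtParams = TqwtParams(),
                  ablation: AblationFlags = AblationFlags()) -> list[str]:
    """Layout manifest: one ``source/extractor/descriptor`` name per column."""
    names: list[str] = []
    moment_cols = _moment_indices(ablation)
    half = _moments.N_DESCRIPTORS
    for src in source_names(params):
        if ablation.include_melpat:
            for kernel in _pattern.KERNEL_NAMES:
                for group in range(1, _pattern.N_GROUPS + 1):
                    for code in range(_pattern.CODES_PER_GROUP):
                        names.append(f"{src}/melpat/{kernel}_g{group}_b{code:02d}")
        if ablation.include_moments:
            for i in moment_cols:
                version = "abs" if i >= half else "sig"
                names.append(
                    f"{src}/moments/{version}_{_moments.DESCRIPTOR_NAMES[i % half]}")
    return names


def extract_segment_features(samples,
                             params: TqwtParams = TqwtParams(),
                             edges: EdgeTable = MELATONIN_EDGE_TABLE,
                             ablation: AblationFlags = AblationFlags(),
                             tqwt_mode: str = "coefficients",
                             matrix_order: str = "column_major",
                             entropy_eps: float | None = None,
                             norm_p: float = 1.5) -> np.ndarray:
    """Compute the multi-level feature vector of one segment.

    Returns a 1-D float array of length 8624 at the default
    configuration; ablation flags shrink it consistently with
    :func:`feature_names`.

    Raises
    ------
    ValueError
        If a sub-band coefficient sequence is shorter than the
        169-sample MelPat block (the error names the band); use
        ``tqwt_mode="reconstruction"`` for such configurations.
    """
    if tqwt_mode not in ("coefficients", "reconstruction"):
        raise ValueError(f"unknown tqwt_mode {tqwt_mode!r}")
    x = np.asarray(samples, dtype=float)
    subbands = tqwt_decompose(x, params)
    if tqwt_mode == "coefficients":
        sources = [x] + list(subbands.bands)
    else:
        sources = [x] + [reconstruct_single_band(subbands, j)
                         for j in range(len(subbands.bands))]

    names = source_names(params)
    moment_cols = _moment_indices(ablation)
    blocks: list[np.ndarray] = []
    for name, src in zip(names, sources):
        if ablation.include_melpat:
            if src.shape[0] < _pattern.BLOCK_LENGTH:
                raise ValueError(
                    f"source {name!r} has {src.shape[0]} samples, fewer than "
                    f"the {_pattern.BLOCK_LENGTH}-sample MelPat block; use "
                    f"tqwt_mode='reconstruction' or a shallower J")
            blocks.append(melpat_extract(src, edges=edges,
                                         order=matrix_order).values.astype(float))
        if ablation.include_moments:
            mom = moments_extract(src, entropy_eps=entropy_eps, norm_p=norm_p)
            blocks.append(mom.values[moment_cols])
    return np.concatenate(blocks)
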