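"""Melatonin-graph local texture features (MelPat) for 1-D signals.

The extractor slides a 169-sample window (stride 1) over the signal,
arranges each window as a 13x13 matrix and compares the matrix values at
the two endpoints of 18 directed edges.  The edge layout is a planar
embedding of the melatonin molecule's heavy-atom skeleton (17 atoms, 18
bonds, including both indole rings) on the 13x13 grid.  Each comparison
is run through three kernels:

* signum:        1 if sp - ep >= 0
* upper ternary: 1 if sp - ep >  thr
* lower ternary: 1 if sp - ep < -thr

with ``thr`` equal to half the sample standard deviation of the whole
input signal.  The 18 bits of a kernel are split into three groups of 6
and read as 6-bit codes (first bit most significant), and a 64-bin code
histogram is accumulated per kernel and group over all windows.  The
result is 3 kernels x 3 groups x 64 bins = 576 counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EdgeTable",
    "MELATONIN_EDGE_TABLE",
    "MelPatFeatures",
    "load_edge_table",
    "save_edge_table",
    "kernel_signum",
    "kernel_upper_ternary",
    "kernel_lower_ternary",
    "compute_threshold",
    "block_to_matrix",
    "extract_bits",
    "bits_to_codes",
    "melpat_extract",
]

GRID_SIZE = 13
BLOCK_LENGTH = GRID_SIZE * GRID_SIZE  # 169
N_EDGES = 18
GROUP_SIZE = 6
N_GROUPS = 3
CODES_PER_GROUP = 2 ** GROUP_SIZE  # 64
KERNEL_NAMES = ("sgn", "ut", "lt")
FEATURE_LENGTH = len(KERNEL_NAMES) * N_GROUPS * CODES_PER_GROUP  # 576


@dataclass(frozen=True)
class EdgeTable:
    """18 directed edges on the 13x13 grid, in three groups of six.

    ``edges`` holds ``((sp_row, sp_col), (ep_row, ep_col))`` pairs with
    1-based coordinates.  Edge i (0-based) belongs to group ``i // 6``.
    """

    edges: tuple
    name: str = "custom"
    version: str = "1"

    def __post_init__(self) -> None:
        if len(self.edges) != N_EDGES:
            raise ValueError(f"edge table must have {N_EDGES} edges, "
                             f"got {len(self.edges)}")
        for i, (sp, ep) in enumerate(self.edges):
            for r, c in (sp, ep):
                if not (1 <= r <= GRID_SIZE and 1 <= c <= GRID_SIZE):
                    raise ValueError(
                        f"edge {i + 1}: coordinate ({r},{c}) outside the "
                        f"{GRID_SIZE}x{GRID_SIZE} grid")
            if tuple(sp) == tuple(ep):
                raise ValueError(f"edge {i + 1}: start equals end {sp}")

    def flat_indices(self, order: str = "column_major"):
        """0-based flat block indices of (sp, ep) per edge for a fill order."""
        sp = np.empty(N_EDGES, dtype=np.intp)
        ep = np.empty(N_EDGES, dtype=np.intp)
        for i, ((sr, sc), (er, ec)) in enumerate(self.edges):
            sp[i] = _flat_index(sr, sc, order)
            ep[i] = _flat_index(er, ec, order)
        return sp, ep


def _flat_index(row: int, col: int, order: str) -> int:
    if order == "column_major":
        return (col - 1) * GRID_SIZE + (row - 1)
    if order == "row_major":
        return (row - 1) * GRID_SIZE + (col - 1)
    raise ValueError(f"unknown fill order {order!r}")


# Heavy-atom skeleton of melatonin (N-acetyl-5-methoxytryptamine) laid out
# on the 13x13 grid: indole ring pair (N1, C2, C3, C3a, C4-C7, C7a), the
# N-acetyl side chain at C3 and the 5-methoxy group.  Edge 3 is pinned at
# (13,10) -> (11,12).  Groups of six follow edge order.
_ATOMS = {
    "N1": (12, 13), "C2": (13, 12), "C3": (13, 10), "C3a": (11, 12),
    "C4": (10, 10), "C5": (8, 10), "C6": (7, 12), "C7": (8, 13),
    "C7a": (10, 13),
    # N-acetyl side chain
    "CB": (12, 8), "CA": (11, 6), "N10": (9, 5), "C11": (7, 4),
    "O11": (6, 2), "C12": (5, 5),
    # 5-methoxy group
    "O13": (6, 8), "C14": (4, 7),
}
_BONDS = [
    ("N1", "C2"), ("C2", "C3"), ("C3", "C3a"), ("C3a", "C4"),
    ("C4", "C5"), ("C5", "C6"),
    ("C6", "C7"), ("C7", "C7a"), ("C7a", "N1"), ("C3a", "C7a"),
    ("C3", "CB"), ("CB", "CA"),
    ("CA", "N10"), ("N10", "C11"), ("C11", "O11"), ("C11", "C12"),
    ("C5", "O13"), ("O13", "C14"),
]

MELATONIN_EDGE_TABLE = EdgeTable(
    edges=tuple((_ATOMS[a], _ATOMS[b]) for a, b in _BONDS),
    name="melatonin-skeleton",
    version="1",
)


def save_edge_table(table: EdgeTable, path) -> None:
    payload = {
        "edges": [[sr, sc, er, ec] for (sr, sc), (er, ec) in table.edges],
        "groups": [GROUP_SIZE] * N_GROUPS,
        "name": table.name,
        "version": table.version,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_edge_table(path) -> EdgeTable:
    """Load and validate an edge-table JSON file."""
    payload = json.loads(Path(path).read_text())
    for key in ("edges", "groups"):
        if key not in payload:
            raise ValueError(f"edge-table file {path} missing field {key!r}")
    if list(payload["groups"]) != [GROUP_SIZE] * N_GROUPS:
        raise ValueError(f"edge-table groups must be {[GROUP_SIZE] * N_GROUPS}")
    edges = tuple(((sr, sc), (er, ec)) for sr, sc, er, ec in payload["edges"])
    return EdgeTable(edges=edges, name=payload.get("name", "custom"),
                     version=str(payload.get("version", "1")))


@dataclass
class MelPatFeatures:
    """576 histogram counts: kernel-major (sgn, ut, lt), then group, then bin."""

    values: np.ndarray
    n_blocks: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (FEATURE_LENGTH,):
            raise ValueError(f"expected {FEATURE_LENGTH} features, "
                             f"got {self.values.shape}")

    def histogram(self, kernel: str, group: int) -> np.ndarray:
        """One 64-bin histogram; ``group`` is 1-based (1..3)."""
        k = KERNEL_NAMES.index(kernel)
        start = (k * N_GROUPS + (group - 1)) * CODES_PER_GROUP
        return self.values[start:start + CODES_PER_GROUP]


def kernel_signum(a: float, b: float) -> int:
    """1 if a - b >= 0 else 0."""
    return 1 if a - b >= 0 else 0


def kernel_upper_ternary(a: float, b: float, thr: float) -> int:
    """1 if a - b > thr else 0."""
    return 1 if a - b > thr else 0


def kernel_lower_ternary(a: float, b: float, thr: float) -> int:
    """1 if a - b < -thr else 0."""
    return 1 if a - b < -thr else 0


def compute_threshold(s) -> float:
    """Ternary-kernel threshold: half the sample (n-1) standard deviation."""
    x = np.asarray(s, dtype=float)
    if x.size < 2:
        raise ValueError("threshold needs at least 2 samples")
    return float(np.std(x, ddof=1) / 2.0)


def block_to_matrix(block, order: str = "column_major") -> np.ndarray:
    """Arrange a 169-sample block as a 13x13 matrix.

    Column-major (the default) puts ``block[(col-1)*13 + row - 1]`` at
    1-based ``(row, col)``.
    """
    b = np.asarray(block, dtype=float)
    if b.shape != (BLOCK_LENGTH,):
        raise ValueError(f"block must have exactly {BLOCK_LENGTH} values, "
                         f"got shape {b.shape}")
    np_order = "F" if order == "column_major" else "C"
    if order not in ("column_major", "row_major"):
        raise ValueError(f"unknown fill order {order!r}")
    return b.reshape(GRID_SIZE, GRID_SIZE, order=np_order)


def extract_bits(mx: np.ndarray, edges: EdgeTable, kernel: str,
                 thr: float = 0.0) -> np.ndarray:
    """18 comparison bits of one matrix under one kernel, in edge order."""
    mx = np.asarray(mx, dtype=float)
    if mx.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"matrix must be {GRID_SIZE}x{GRID_SIZE}")
    bits = np.empty(N_EDGES, dtype=np.uint8)
    for i, ((sr, sc), (er, ec)) in enumerate(edges.edges):
        a = mx[sr - 1, sc - 1]
        b = mx[er - 1, ec - 1]
        if kernel == "sgn":
            bits[i] = kernel_signum(a, b)
        elif kernel == "ut":
            bits[i] = kernel_upper_ternary(a, b, thr)
        elif kernel == "lt":
            bits[i] = kernel_lower_ternary(a, b, thr)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    return bits


_WEIGHTS = 2 ** (GROUP_SIZE - 1 - np.arange(GROUP_SIZE))  # 32, 16, ..., 1


def bits_to_codes(bits) -> tuple[int, int, int]:
    """Read three 6-bit codes (first bit most significant) from 18 bits."""
    b = np.asarray(bits, dtype=np.int64)
    if b.shape != (N_EDGES,):
        raise ValueError(f"expected {N_EDGES} bits, got shape {b.shape}")
    return tuple(int(b[g * GROUP_SIZE:(g + 1) * GROUP_SIZE] @ _WEIGHTS)
                 for g in range(N_GROUPS))


def melpat_extract(s, edges: EdgeTable = MELATONIN_EDGE_TABLE,
                   order: str = "column_major",
                   normalize: bool = False) -> MelPatFeatures:
    """Extract the 576 MelPat histogram features of a 1-D signal.

    Parameters
    ----------
    s : array-like, 1-D, length >= 169
    edges : EdgeTable
        Directed-edge table; defaults to the melatonin-skeleton layout.
    order : {"column_major", "row_major"}
        How each 169-block fills its 13x13 matrix.
    normalize : bool
        If True, divide each histogram by the number of blocks (useful
        when comparing signals of different length).

    Notes
    -----
    The ternary threshold is computed once from the whole input signal
    (half its sample standard deviation), not per block.
    """
    x = np.asarray(s, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.shape[0] < BLOCK_LENGTH:
        raise ValueError(f"signal length {x.shape[0]} is shorter than the "
                         f"{BLOCK_LENGTH}-sample block")
    thr = compute_threshold(x)
    sp_idx, ep_idx = edges.flat_indices(order)

    blocks = sliding_window_view(x, BLOCK_LENGTH)  # (n_blocks, 169)
    n_blocks = blocks.shape[0]
    diff = blocks[:, sp_idx] - blocks[:, ep_idx]   # (n_blocks, 18)

    hists = []
    for kernel in KERNEL_NAMES:
        if kernel == "sgn":
            bits = diff >= 0
        elif kernel == "ut":
            bits = diff > thr
        else:
            bits = diff < -thr
        bits = bits.astype(np.int64)
        for g in range(N_GROUPS):
            codes = bits[:, g * GROUP_SIZE:(g + 1) * GROUP_SIZE] @ _WEIGHTS
            hists.append(np.bincount(codes, minlength=CODES_PER_GROUP))
    values = np.concatenate(hists)
    if normalize:
        values = values / float(n_blocks)
    return MelPatFeatures(values=values, n_blocks=n_blocks)
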