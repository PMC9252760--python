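"""Per-residue input encodings and long-sequence windowing.

Residues are encoded either as a one-hot baseline (20 columns, all-zero row
for unknown 'X') or as precomputed embedding matrices loaded from an HDF5
archive — e.g. evolutionary profiles (50 columns) or protein language-model
embeddings (1280 columns) produced externally.

Encoders with a bounded context window (notably language models capped at
1024 residues) cannot consume arbitrarily long sequences in one pass.
:func:`plan_windows` decomposes a long sequence into overlapping windows of
size ``W`` moved with stride ``S``, assigns every position to exactly one
window ("keep intervals"), and :func:`stitch` reassembles per-window outputs
into a single full-length matrix.  Interior window edges are trimmed by
``T`` positions to discard context-starved predictions; the residual overlap
between consecutive trimmed intervals is split at its midpoint so each
position is owned by the window whose centre it is closest to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, ProteinRecord, UNKNOWN_RESIDUE, ValidationError

#: Default window size, stride and edge trim for long-sequence processing.
WINDOW_SIZE = 1024
WINDOW_STRIDE = 824
WINDOW_TRIM = 50


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An L×D numeric encoding of one sequence."""

    values: np.ndarray
    source_tag: str = "custom"  # one_hot | profile | lm | custom

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError(f"embedding must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def one_hot_encode(record: ProteinRecord) -> EmbeddingMatrix:
    """One-hot sparse encoding: L×20, all-zero row for an unknown residue."""
    L = len(record.sequence)
    mat = np.zeros((L, len(AMINO_ACIDS)), dtype=np.float64)
    for i, ch in enumerate(record.sequence):
        if ch == UNKNOWN_RESIDUE:
            continue
        try:
            mat[i, AA_INDEX[ch]] = 1.0
        except KeyError:
            raise ValidationError(
                f"sequence {record.id!r} has unvalidated character {ch!r} "
                f"at position {i + 1}; run validate_record first"
            ) from None
    return EmbeddingMatrix(mat, source_tag="one_hot")


def save_embedding_archive(
    path, matrices: Mapping[str, np.ndarray] | Mapping[str, EmbeddingMatrix]
) -> None:
    """Write one float32 L×D dataset per sequence id into an HDF5 file."""
    with h5py.File(path, "w") as fh:
        for seq_id, mat in matrices.items():
            values = mat.values if isinstance(mat, EmbeddingMatrix) else mat
            fh.create_dataset(seq_id, data=np.asarray(values, dtype=np.float32))


def load_embedding_archive(
    path,
    ids: Sequence[str],
    records: Iterable[ProteinRecord] | None = None,
) -> dict[str, EmbeddingMatrix]:
    """Load per-sequence embedding matrices for the requested ids.

    All matrices in one archive must share the feature dimension D.  When
    ``records`` is given, each matrix's row count is checked against the
    corresponding sequence length.

    Raises
    ------
    ValidationError
        Listing any missing ids, on inconsistent D, or naming a record whose
        length disagrees with its matrix.
    """
    lengths = {r.id: len(r) for r in records} if records is not None else {}
    out: dict[str, EmbeddingMatrix] = {}
    with h5py.File(path, "r") as fh:
        missing = [i for i in ids if i not in fh]
        if missing:
            raise ValidationError(
                f"embedding archive {path} is missing ids: {missing}"
            )
        dim = None
        for seq_id in ids:
            values = np.asarray(fh[seq_id], dtype=np.float64)
            if values.ndim != 2:
                raise ValidationError(
                    f"dataset {seq_id!r} in {path} is not a 2-D matrix"
                )
            if dim is None:
                dim = values.shape[1]
            elif values.shape[1] != dim:
                raise ValidationError(
                    f"dataset {seq_id!r} has {values.shape[1]} columns; "
                    f"archive dimension is {dim}"
                )
            if seq_id in lengths and values.shape[0] != lengths[seq_id]:
                raise ValidationError(
                    f"embedding for {seq_id!r} has {values.shape[0]} rows "
                    f"but the sequence has {lengths[seq_id]} residues"
                )
            out[seq_id] = EmbeddingMatrix(values)
    return out


@dataclass(frozen=True)
class Window:
    """One window over residue positions (0-based, half-open intervals)."""

    start: int
    end: int
    keep_start: int
    keep_end: int


@dataclass(frozen=True)
class WindowPlan:
    """Exact-coverage decomposition of ``[0, L)`` into windows."""

    windows: tuple[Window, ...]
    length: int
    window_size: int = WINDOW_SIZE
    stride: int = WINDOW_STRIDE
    trim: int = WINDOW_TRIM


def plan_windows(
    L: int,
    window_size: int = WINDOW_SIZE,
    stride: int = WINDOW_STRIDE,
    trim: int = WINDOW_TRIM,
) -> WindowPlan:
    """Plan overlapping windows whose keep intervals partition ``[0, L)``.

    A sequence no longer than ``window_size`` gets a single full window.
    Otherwise windows start at 0, S, 2S, ...; the last window is the first
    one whose end reaches L (its end clipped to L, never shifted).  Interior
    keep boundaries sit at the midpoint of the residual overlap left after
    trimming ``trim`` positions from each interior window edge; the first
    window keeps from 0 and the last keeps to L, since sequence termini have
    no artificial context edge to trim away.
    """
    W, S, T = window_size, stride, trim
    if L < 1:
        raise ValidationError(f"sequence length must be >= 1, got {L}")
    if W <= 2 * T:
        raise ValidationError(f"window size {W} must exceed twice the trim {T}")
    if not 1 <= S < W:
        raise ValidationError(f"stride {S} must satisfy 1 <= stride < window {W}")

    if L <= W:
        return WindowPlan((Window(0, L, 0, L),), L, W, S, T)

    starts = [0]
    while starts[-1] + W < L:
        starts.append(starts[-1] + S)
    ends = [min(s + W, L) for s in starts]

    # Interior keep boundary between window i and i+1: midpoint of the
    # residual overlap [starts[i+1]+T, ends[i]-T] (independent of T when the
    # overlap is symmetric).
    bounds = [0]
    for i in range(len(starts) - 1):
        bounds.append((starts[i + 1] + T + ends[i] - T) // 2)
    bounds.append(L)

    windows = tuple(
        Window(s, e, bounds[i], bounds[i + 1])
        for i, (s, e) in enumerate(zip(starts, ends))
    )
    plan = WindowPlan(windows, L, W, S, T)
    _check_plan(plan)
    return plan


def _check_plan(plan: WindowPlan) -> None:
    prev_end = 0
    for w in plan.windows:
        if not (w.start <= w.keep_start <= w.keep_end <= w.end):
            raise ValidationError(f"keep interval escapes its window: {w}")
        if w.keep_start != prev_end:
            raise ValidationError(f"keep intervals do not tile [0, L): {w}")
        prev_end = w.keep_end
    if prev_end != plan.length:
        raise ValidationError("keep intervals do not reach sequence end")


def split_by_plan(matrix: np.ndarray, plan: WindowPlan) -> list[np.ndarray]:
    """Slice an L×D matrix into per-window row blocks (copies)."""
    if matrix.shape[0] != plan.length:
        raise ValidationError(
            f"matrix has {matrix.shape[0]} rows, plan covers {plan.length}"
        )
    return [matrix[w.start:w.end].copy() for w in plan.windows]


def stitch(window_outputs: Sequence[np.ndarray], plan: WindowPlan) -> np.ndarray:
    """Reassemble per-window outputs into one full-length matrix.

    Row ``p`` of the result is taken from the unique window whose keep
    interval contains ``p``.
    """
    if len(window_outputs) != len(plan.windows):
        raise ValidationError(
            f"got {len(window_outputs)} window outputs for "
            f"{len(plan.windows)} planned windows"
        )
    ncol = None
    for i, (w, out) in enumerate(zip(plan.windows, window_outputs)):
        out = np.asarray(out)
        if out.shape[0] != w.end - w.start:
            raise ValidationError(
                f"window {i}: output has {out.shape[0]} rows, "
                f"window extent is {w.end - w.start}"
            )
        if ncol is None:
            ncol = out.shape[1:]
        elif out.shape[1:] != ncol:
            raise ValidationError(f"window {i}: trailing dimensions differ")
    result = np.empty((plan.length, *ncol), dtype=np.asarray(window_outputs[0]).dtype)
    for w, out in zip(plan.windows, window_outputs):
        result[w.keep_start:w.keep_end] = np.asarray(out)[
            w.keep_start - w.start : w.keep_end - w.start
        ]
    return result
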