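"""Sliding-window spectral features of adjacency-matrix series.

A segment's adjacency tensor is cut into overlapping windows (default 50
frames with a 25-frame hop at 25 fps, i.e. 2 s windows overlapping by
1 s).  Each window is decomposed with Graph DMD; modes faster than the
frequency cutoff (default 2 Hz) are discarded, each surviving mode is
scored by the variability accounted for (VAF) of its single-mode
reconstruction, and a window is valid only if its best mode reaches the
VAF threshold (default 0.01).  Valid windows' modes are normalised
(max-abs 1), symmetrised, reduced to element-wise moduli and averaged —
first within a window over modes with non-negative eigenvalue imaginary
part (so conjugate pairs are not double counted), then across windows —
into one symmetric matrix per segment with entries in [0, 1].

Task-specific feature vectors pick named node-pair elements from that
matrix (defence: defender-defender, attacker-defender and defender-ring
pairs; offence: attacker-attacker and attacker-defender pairs).  Two
baseline feature families operate on the same windows: graph-Laplacian
eigenvalues of the averaged matrix, and plain summary statistics
(mean/max/min over time per node pair) of the raw adjacency series.  The
exact-DMD spectrum variant runs the identical pipeline with exact DMD on
the vectorised slices in place of Graph DMD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adjacency import SLOT_NAMES
from .errors import ConfigError, SegmentInvalidError, ValidationError
from . import spectral
from .spectral import GraphDMDResult, SnapshotTensor, exact_dmd, graph_dmd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in frames."""

    size: int = 50
    hop: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.size):
            raise ValidationError("window spec requires 0 < hop <= size")


@dataclass(frozen=True)
class ModeFilterSpec:
    """Mode retention and window-validity thresholds."""

    freq_cutoff_hz: float = 2.0
    vaf_window_threshold: float = 0.01
    eps: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.freq_cutoff_hz > 0 and self.vaf_window_threshold > 0 and self.eps > 0):
            raise ValidationError("mode filter thresholds must be positive")


@dataclass(frozen=True)
class WindowDecomposition:
    """One window's (cutoff-filtered) decomposition and validity verdict."""

    start: int
    end: int
    result: Optional[GraphDMDResult]
    mode_vaf: np.ndarray
    valid: bool

    @property
    def max_vaf(self) -> float:
        return float(np.max(self.mode_vaf)) if self.mode_vaf.size else float("-inf")


def sliding_windows(T: int, spec: WindowSpec = WindowSpec()) -> List[Tuple[int, int]]:
    """Half-open frame ranges ``[k*hop, k*hop + size)`` fully inside ``[0, T)``.

    Trailing partial windows are dropped; a segment shorter than one window
    yields an empty list.
    """
    if T < 1:
        raise ValidationError("T must be at least 1")
    windows = []
    start = 0
    while start + spec.size <= T:
        windows.append((start, start + spec.size))
        start += spec.hop
    return windows


def _exact_dmd_as_graph_result(window: SnapshotTensor, eps: float) -> GraphDMDResult:
    """Exact DMD on the vectorised slices, packaged with matrix-shaped modes."""
    m, _, T = window.values.shape
    D = window.values.reshape(m * m, T, order="F")
    res = exact_dmd(D, eps)
    nonzero = np.abs(res.eigenvalues) > spectral.ZERO_EIGENVALUE_TOL
    eigvals = res.eigenvalues[nonzero]
    if eigvals.size == 0:
        raise spectral.DegenerateInputError("no nonzero eigenvalues in window")
    modes = res.modes[:, nonzero].reshape(m, m, eigvals.size, order="F")
    amplitudes = res.amplitudes[nonzero]
    freqs, growth = spectral.eigenvalue_to_frequency(eigvals, window.dt)
    order = np.lexsort((-np.abs(amplitudes), freqs))
    return GraphDMDResult(
        eigenvalues=eigvals[order],
        modes=modes[:, :, order],
        amplitudes=amplitudes[order],
        frequencies_hz=freqs[order],
        growth_per_s=growth[order],
        dt=window.dt,
        r1=res.rank,
        r2=res.rank,
        eps=eps,
    )


def decompose_windows(
    snapshots: SnapshotTensor,
    wspec: WindowSpec = WindowSpec(),
    fspec: ModeFilterSpec = ModeFilterSpec(),
    method: str = "graph",
) -> List[WindowDecomposition]:
    """Windowed decomposition with frequency cutoff and VAF-based validity.

    The cutoff is applied before validity scoring, so a window is judged
    only on the modes that survive into the features.  ``method`` selects
    Graph DMD (``'graph'``) or the exact-DMD baseline (``'exact'``).
    """
    if method not in ("graph", "exact"):
        raise ConfigError(f"unknown decomposition method {method!r}")
    out: List[WindowDecomposition] = []
    for start, end in sliding_windows(snapshots.n_frames, wspec):
        window = snapshots.window(start, end)
        try:
            if method == "graph":
                res = graph_dmd(window, fspec.eps)
            else:
                res = _exact_dmd_as_graph_result(window, fspec.eps)
        except spectral.DegenerateInputError:
            out.append(
                WindowDecomposition(start, end, None, np.empty(0), valid=False)
            )
            continue
        res = res.subset(res.frequencies_hz <= fspec.freq_cutoff_hz)
        t_idx = np.arange(window.n_frames)
        vafs = np.array(
            [
                spectral.vaf(window.values, spectral.reconstruct(res, t_idx, [j]))
                for j in range(res.n_modes)
            ]
        )
        valid = vafs.size > 0 and float(np.max(vafs)) >= fspec.vaf_window_threshold
        logger.debug(
            "window [%d,%d): r2=%d retained=%d max_vaf=%s valid=%s",
            start, end, res.r2, res.n_modes,
            f"{np.max(vafs):.4f}" if vafs.size else "n/a", valid,
        )
        out.append(WindowDecomposition(start, end, res, vafs, valid))
    if not out:
        logger.warning("segment of %d frames shorter than one window; skipped",
                       snapshots.n_frames)
    return out


def postprocess_mode(Z: np.ndarray) -> np.ndarray:
    """Normalise, symmetrise and take the modulus of one matrix mode.

    The mode is scaled so its largest entry modulus is 1 (mode amplitude is
    carried by the time dynamics, not the spatial pattern), averaged with
    its transpose (ideal modes of an undirected graph are symmetric), and
    reduced to element-wise absolute values, giving a symmetric real matrix
    with entries in [0, 1].
    """
    Z = np.asarray(Z)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValidationError("mode must be a square matrix")
    peak = np.max(np.abs(Z))
    if peak == 0.0:
        raise ValidationError("all-zero mode cannot be normalised")
    Zn = Z / peak
    return np.abs(0.5 * (Zn + Zn.T))


def aggregate_modes(windows: Sequence[WindowDecomposition]) -> np.ndarray:
    """Average the post-processed modes of all valid windows.

    Within a window, the unweighted mean over retained modes with
    ``Im(lambda) >= 0`` (one representative per conjugate pair); across
    windows, the unweighted mean of the window means.
    """
    window_means = []
    for w in windows:
        if not w.valid or w.result is None:
            continue
        keep = np.where(w.result.eigenvalues.imag >= 0)[0]
        mats = [postprocess_mode(w.result.modes[:, :, j]) for j in keep]
        if mats:
            window_means.append(np.mean(mats, axis=0))
    if not window_means:
        raise SegmentInvalidError("no valid sliding window in segment")
    return np.mean(window_means, axis=0)


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

_ATTACKERS = tuple(range(0, 5))
_DEFENDERS = tuple(range(5, 10))
_RING = 10


def _pair_name(i: int, j: int) -> str:
    # ring-involving pairs are conventionally written ring-first ("R-D1")
    if j == _RING:
        return f"{SLOT_NAMES[_RING]}-{SLOT_NAMES[i]}"
    return f"{SLOT_NAMES[i]}-{SLOT_NAMES[j]}"


def mask_pairs(name: str) -> List[Tuple[int, int]]:
    """Slot-index pairs of a named task mask.

    ``'defence'``: the 10 defender-defender, 25 attacker-defender and 5
    defender-ring pairs (40 features).  ``'offence'``: the 10
    attacker-attacker and 25 attacker-defender pairs (35 features, no
    ring).
    """
    if name == "defence":
        pairs = [(i, j) for k, i in enumerate(_DEFENDERS) for j in _DEFENDERS[k + 1:]]
        pairs += [(i, j) for i in _ATTACKERS for j in _DEFENDERS]
        pairs += [(i, _RING) for i in _DEFENDERS]
        return pairs
    if name == "offence":
        pairs = [(i, j) for k, i in enumerate(_ATTACKERS) for j in _ATTACKERS[k + 1:]]
        pairs += [(i, j) for i in _ATTACKERS for j in _DEFENDERS]
        return pairs
    raise ConfigError(f"unknown task mask {name!r}")


def _resolve_mask(task_mask) -> List[Tuple[int, int]]:
    if isinstance(task_mask, str):
        return mask_pairs(task_mask)
    slot_index = {s: k for k, s in enumerate(SLOT_NAMES)}
    pairs = []
    for pair in task_mask:
        if isinstance(pair, str):
            a, b = pair.split("-")
            i, j = slot_index[a], slot_index[b]
        else:
            i, j = pair
        pairs.append((min(i, j), max(i, j)))
    return pairs


def select_features(aggregated: np.ndarray, task_mask="defence") -> pd.Series:
    """Named node-pair elements of an aggregated mode matrix.

    ``task_mask`` is ``'defence'``, ``'offence'`` or an explicit iterable
    of slot pairs (``'A1-A2'`` strings or index tuples).  Only
    upper-triangle elements are used; the diagonal is excluded.
    """
    A = np.asarray(aggregated)
    if A.shape != (11, 11):
        raise ValidationError("aggregated mode matrix must be 11 x 11")
    pairs = _resolve_mask(task_mask)
    return pd.Series(
        {_pair_name(i, j): float(A[i, j]) for (i, j) in pairs},
        dtype=float,
    )


def laplacian_features(W: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of the graph Laplacian ``L = D - W``.

    The diagonal of ``W`` (self-loops) is ignored; ``D`` holds the
    off-diagonal row sums, so the constant vector is always a null vector
    and the smallest eigenvalue is 0.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("weight matrix must be square")
    if np.max(np.abs(W - W.T)) > 1e-8:
        raise ValidationError("weight matrix must be symmetric")
    if np.any(W < -1e-12):
        raise ValidationError("weights must be non-negative")
    Wo = W.copy()
    np.fill_diagonal(Wo, 0.0)
    L = np.diag(Wo.sum(axis=1)) - Wo
    return np.linalg.eigvalsh(L)


def handcrafted_features(snapshots: SnapshotTensor) -> pd.Series:
    """Temporal mean, max and min per upper-triangle adjacency element."""
    A = snapshots.values
    m = snapshots.m
    names = (
        [f"n{i+1}" for i in range(m)] if m != 11 else list(SLOT_NAMES)
    )
    out = {}
    for i in range(m):
        for j in range(i + 1, m):
            series = A[i, j, :]
            key = f"{names[i]}-{names[j]}"
            out[f"mean_{key}"] = float(series.mean())
            out[f"max_{key}"] = float(series.max())
            out[f"min_{key}"] = float(series.min())
    return pd.Series(out, dtype=float)


def gdmd_spectrum_features(
    snapshots: SnapshotTensor,
    wspec: WindowSpec = WindowSpec(),
    fspec: ModeFilterSpec = ModeFilterSpec(),
    task_mask="defence",
) -> pd.Series:
    """Graph-DMD mode-element feature vector of one segment."""
    windows = decompose_windows(snapshots, wspec, fspec, method="graph")
    return select_features(aggregate_modes(windows), task_mask)


def dmd_spectrum_features(
    snapshots: SnapshotTensor,
    wspec: WindowSpec = WindowSpec(),
    fspec: ModeFilterSpec = ModeFilterSpec(),
    task_mask="defence",
) -> pd.Series:
    """Exact-DMD baseline run through the identical windowing pipeline."""
    windows = decompose_windows(snapshots, wspec, fspec, method="exact")
    return select_features(aggregate_modes(windows), task_mask)


def gdmd_laplacian_features(
    snapshots: SnapshotTensor,
    wspec: WindowSpec = WindowSpec(),
    fspec: ModeFilterSpec = ModeFilterSpec(),
) -> pd.Series:
    """Laplacian eigenvalues of the aggregated Graph-DMD mode matrix."""
    windows = decompose_windows(snapshots, wspec, fspec, method="graph")
    ev = laplacian_features(aggregate_modes(windows))
    return pd.Series({f"lap_ev_{k+1}": float(v) for k, v in enumerate(ev)})


def build_feature_table(
    tensors: dict,
    labels: dict,
    method: str = "gdmd_spectrum",
    wspec: WindowSpec = WindowSpec(),
    fspec: ModeFilterSpec = ModeFilterSpec(),
    task_mask="defence",
) -> pd.DataFrame:
    """Per-segment feature table with a trailing ``label`` column.

    ``tensors`` maps segment id to :class:`SnapshotTensor`; segments with
    no valid window are excluded (logged).  ``method`` is one of
    ``gdmd_spectrum``, ``dmd_spectrum``, ``gdmd_laplacian``,
    ``handcrafted``.
    """
    extractors = {
        "gdmd_spectrum": lambda t: gdmd_spectrum_features(t, wspec, fspec, task_mask),
        "dmd_spectrum": lambda t: dmd_spectrum_features(t, wspec, fspec, task_mask),
        "gdmd_laplacian": lambda t: gdmd_laplacian_features(t, wspec, fspec),
        "handcrafted": handcrafted_features,
    }
    if method not in extractors:
        raise ConfigError(f"unknown feature method {method!r}")
    rows = {}
    dropped = []
    for seg_id, tensor in tensors.items():
        try:
            rows[seg_id] = extractors[method](tensor)
        except SegmentInvalidError:
            dropped.append(seg_id)
            logger.warning("segment %s has no valid window; excluded", seg_id)
    if not rows:
        raise SegmentInvalidError("no segment produced a valid feature vector")
    logger.info("feature extraction kept %d/%d segments", len(rows), len(tensors))
    table = pd.DataFrame(rows).T
    table.index.name = "segment_id"
    table["label"] = pd.Series({k: labels[k] for k in rows}).astype(int)
    return table
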