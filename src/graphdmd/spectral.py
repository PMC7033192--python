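"""Spectral decomposition of adjacency-matrix time series.

This module implements graph dynamic mode decomposition (Graph DMD): a
Koopman-style spectral analysis of a sequence of weighted adjacency
matrices ``A_0, ..., A_tau`` of a graph dynamical system.  Instead of
flattening each snapshot and running a plain SVD-based DMD, the order-3
snapshot tensor (node x node x time) is factorised with a tensor-train
decomposition, so the reduced linear operator is built in an orthonormal
basis that respects the node-pair structure of the data.  The output is a
set of complex eigenvalues ``lambda_j`` (frequency and growth/decay rate)
paired with matrix-valued spatial modes ``Z_j`` such that

    A_t  ~=  sum_j  Z_j * lambda_j**t * b_j0,

where ``b_j0`` is the scalar amplitude of mode ``j`` fitted to the initial
snapshot.  Exact DMD on the vectorised snapshots is provided as a
baseline; with negligible truncation the two produce the same nonzero
eigenvalues because both compress ``Y X^+`` onto the column space of the
matricised data in an orthonormal basis.

Vectorisation is column-major throughout (``vec(A)`` stacks columns), and
matricisations of the order-3 tensor follow the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError

#: eigenvalues with modulus at or below this are treated as zero modes and
#: dropped before mode computation (the 1/lambda factor is undefined at 0)
ZERO_EIGENVALUE_TOL = 1e-10

_SYMMETRY_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnapshotTensor:
    """A sequence of symmetric weighted adjacency matrices.

    Parameters
    ----------
    values
        Real array of shape ``(m, m, T)``; slice ``values[:, :, t]`` is the
        adjacency matrix of the graph at frame ``t``.  Every slice must be
        symmetric and finite.
    dt
        Frame interval in seconds.
    """

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3 or values.shape[0] != values.shape[1]:
            raise ValidationError(
                f"snapshot tensor must have shape (m, m, T), got {values.shape}"
            )
        if values.shape[2] < 3:
            raise ValidationError(
                f"need at least 3 frames (two snapshot pairs), got {values.shape[2]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("snapshot tensor contains non-finite entries")
        asym = np.max(np.abs(values - values.transpose(1, 0, 2)))
        if asym > _SYMMETRY_TOL:
            raise ValidationError(
                f"snapshot slices must be symmetric; max asymmetry {asym:.3e}"
            )
        if not self.dt > 0:
            raise ValidationError("dt must be positive")

    @property
    def m(self) -> int:
        """Number of graph nodes."""
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def tau(self) -> int:
        """Number of snapshot pairs (frames minus one)."""
        return self.values.shape[2] - 1

    def window(self, start: int, end: int) -> "SnapshotTensor":
        """Sub-series over the half-open frame range ``[start, end)``."""
        return SnapshotTensor(self.values[:, :, start:end], self.dt)


@dataclass(frozen=True)
class TTFactorization:
    """Matricised tensor-train factors of an order-3 tensor.

    The matricisation ``X_mat`` of the source tensor (shape ``m*m x T``,
    column-major node-pair index) factorises as ``M @ diag(sigma) @ N``
    with ``M`` column-orthonormal, ``N`` row-orthonormal and ``sigma``
    positive non-increasing.  Unlike a plain SVD of ``X_mat``, ``M`` is
    assembled from two successive unfolding SVDs and therefore carries the
    tensor-train structure of the node x node x time data.
    """

    M: np.ndarray
    sigma: np.ndarray
    N: np.ndarray
    r1: int
    r2: int
    eps: float

    @property
    def Sigma(self) -> np.ndarray:
        """Retained singular values as a diagonal matrix."""
        return np.diag(self.sigma)

    def matricized(self) -> np.ndarray:
        """Reassemble ``M @ diag(sigma) @ N``."""
        return (self.M * self.sigma) @ self.N


@dataclass(frozen=True)
class GraphDMDResult:
    """Eigenvalues, matrix-valued modes and amplitudes of a Graph DMD fit."""

    eigenvalues: np.ndarray
    modes: np.ndarray  # complex, shape (m, m, p)
    amplitudes: np.ndarray
    frequencies_hz: np.ndarray
    growth_per_s: np.ndarray
    dt: float
    r1: int
    r2: int
    eps: float

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def m(self) -> int:
        return self.modes.shape[0]

    def subset(self, keep: np.ndarray) -> "GraphDMDResult":
        """Restrict the result to the modes selected by ``keep``."""
        keep = np.asarray(keep)
        return GraphDMDResult(
            eigenvalues=self.eigenvalues[keep],
            modes=self.modes[:, :, keep],
            amplitudes=self.amplitudes[keep],
            frequencies_hz=self.frequencies_hz[keep],
            growth_per_s=self.growth_per_s[keep],
            dt=self.dt,
            r1=self.r1,
            r2=self.r2,
            eps=self.eps,
        )


@dataclass(frozen=True)
class ExactDMDResult:
    """Eigenvalues, vector modes and amplitudes of an exact DMD fit.

    Zero eigenvalues are kept in ``eigenvalues`` but their mode and
    amplitude columns are zero (the ``1/lambda`` mode formula is undefined
    there); nonzero modes are stored column-wise in ``modes``.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray  # complex, shape (d, p)
    amplitudes: np.ndarray
    rank: int


# ---------------------------------------------------------------------------
# tensor-train decomposition
# ---------------------------------------------------------------------------


def _retained_rank(singular_values: np.ndarray, eps: float) -> int:
    """Number of singular values with sigma_k / sigma_1 > eps (at least 1)."""
    s0 = singular_values[0]
    if s0 <= 0.0:
        return 0
    return max(1, int(np.sum(singular_values / s0 > eps)))


def tt_svd_order3(tensor: np.ndarray, eps: float) -> TTFactorization:
    """Tensor-train decomposition of an order-3 tensor via two unfolding SVDs.

    The first SVD acts on the ``m1 x (m2*T)`` unfolding and is truncated at
    relative threshold ``eps`` (drop ``sigma_k`` with ``sigma_k/sigma_1 <=
    eps``), giving rank ``r1``; the second acts on the ``(r1*m2) x T``
    reshaping of the remainder, giving rank ``r2``.  The reconstruction
    error of the matricisation is bounded by ``sqrt(2) * eps * ||X_mat||_F``
    (each truncation discards at most ``eps * sigma_1 <= eps * ||X||_F`` per
    retained direction, summed in quadrature over the two SVDs).

    Raises
    ------
    DegenerateInputError
        If the tensor is identically zero (rank 0 — no factorisation).
    ValidationError
        For wrong dimensionality or non-finite entries.
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 3 or min(X.shape) == 0:
        raise ValidationError(f"expected a non-empty order-3 tensor, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("tensor contains non-finite entries")
    if not eps > 0:
        raise ValidationError("eps must be positive")
    m1, m2, T = X.shape
    if not np.any(X):
        raise DegenerateInputError("all-zero tensor has tensor-train rank 0")

    U1, s1, V1t = np.linalg.svd(X.reshape(m1, m2 * T, order="F"), full_matrices=False)
    r1 = _retained_rank(s1, eps)
    U1 = U1[:, :r1]
    remainder = (s1[:r1, None] * V1t[:r1]).reshape(r1 * m2, T, order="F")

    U2, s2, V2t = np.linalg.svd(remainder, full_matrices=False)
    r2 = _retained_rank(s2, eps)
    U2 = U2[:, :r2]

    # M[(i + m1*j), b] = sum_a U1[i, a] * U2[(a + r1*j), b]; column-orthonormal
    # because U1 and U2 both are.
    core = U2.reshape(r1, m2, r2, order="F")
    M = np.einsum("ia,ajb->ijb", U1, core).reshape(m1 * m2, r2, order="F")
    return TTFactorization(M=M, sigma=s2[:r2], N=V2t[:r2], r1=r1, r2=r2, eps=eps)


# ---------------------------------------------------------------------------
# DMD algorithms
# ---------------------------------------------------------------------------


def _row_orthonormal_pinv(N: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    # N from tt_svd_order3 has orthonormal rows, so pinv(N) = N.T; fall back
    # to the true pseudo-inverse if orthonormality has degraded numerically.
    gram = N @ N.T
    if np.max(np.abs(gram - np.eye(N.shape[0]))) <= tol:
        return N.T
    return np.linalg.pinv(N)


def graph_dmd(snapshots: SnapshotTensor, eps: float = 1e-5) -> GraphDMDResult:
    """Graph DMD of an adjacency-matrix series.

    Builds the forward/shifted sub-tensors (frames ``0..tau-1`` and
    ``1..tau``), tensor-train factorises both with the same tolerance, forms
    the reduced operator ``F_hat = (M^T P)(Q N^+) Sigma^-1`` and
    eigendecomposes it.  Each eigenpair ``(lambda_j, w_j)`` with
    ``|lambda_j|`` above :data:`ZERO_EIGENVALUE_TOL` yields a matrix mode
    ``Z_j = unvec((1/lambda_j) P Q N^+ Sigma^-1 w_j)``.  Amplitudes are the
    least-squares fit of the modes to the first frame; modes are ordered by
    ascending frequency, then descending ``|b_j0|``.
    """
    if snapshots.tau < 2:
        raise ValidationError("need at least two snapshot pairs (T >= 3)")
    A = snapshots.values
    m, _, T = A.shape
    tau = T - 1
    if not np.any(A):
        raise DegenerateInputError("all-zero snapshot tensor")

    ttX = tt_svd_order3(A[:, :, :tau], eps)
    ttY = tt_svd_order3(A[:, :, 1:], eps)
    M, sigma, N = ttX.M, ttX.sigma, ttX.N
    P = ttY.M
    Q = ttY.sigma[:, None] * ttY.N  # absorb the shifted tensor's singular values

    # K = P Q N^+ Sigma^-1 (m^2 x r2); F_hat = M^T K is the compression of
    # Y_mat X_mat^+ onto the tensor-train basis M.
    K = (P @ (Q @ _row_orthonormal_pinv(N))) / sigma[None, :]
    F_hat = M.T @ K

    eigvals, W = np.linalg.eig(F_hat)
    keep = np.abs(eigvals) > ZERO_EIGENVALUE_TOL
    eigvals = eigvals[keep]
    W = W[:, keep]
    if eigvals.size == 0:
        raise DegenerateInputError("all eigenvalues numerically zero")

    mode_vectors = (K @ W) / eigvals[None, :]
    modes = mode_vectors.reshape(m, m, eigvals.size, order="F")
    amplitudes = compute_amplitudes(modes, A[:, :, 0])
    freqs, growth = eigenvalue_to_frequency(eigvals, snapshots.dt)

    order = np.lexsort((-np.abs(amplitudes), freqs))
    return GraphDMDResult(
        eigenvalues=eigvals[order],
        modes=modes[:, :, order],
        amplitudes=amplitudes[order],
        frequencies_hz=freqs[order],
        growth_per_s=growth[order],
        dt=snapshots.dt,
        r1=ttX.r1,
        r2=ttX.r2,
        eps=eps,
    )


def exact_dmd(snapshot_matrix: np.ndarray, eps_or_rank: float | int = 1e-12) -> ExactDMDResult:
    """Exact DMD of a snapshot matrix whose columns are successive states.

    ``X`` is columns ``0..tau-1`` and ``Y`` columns ``1..tau``; ``X`` is
    SVD-truncated either at relative singular-value threshold (float) or at
    a fixed rank (int), and the reduced operator ``F_hat = U^* Y V
    Sigma^-1`` is eigendecomposed.  Modes are ``psi_j = (1/lambda_j) Y V
    Sigma^-1 w_j`` and amplitudes the least-squares fit to the first column.
    """
    D = np.asarray(snapshot_matrix)
    if D.ndim != 2 or D.shape[1] < 2:
        raise ValidationError("need a 2-D snapshot matrix with at least two columns")
    if not np.all(np.isfinite(D)):
        raise ValidationError("snapshot matrix contains non-finite entries")
    X, Y = D[:, :-1], D[:, 1:]
    if not np.any(X):
        raise DegenerateInputError("X block is identically zero")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if isinstance(eps_or_rank, (int, np.integer)) and not isinstance(eps_or_rank, bool):
        r = min(int(eps_or_rank), int(np.sum(s > 0)))
        if r < 1:
            raise ValidationError("requested rank < 1")
    else:
        r = _retained_rank(s, float(eps_or_rank))
    U, s, Vt = U[:, :r], s[:r], Vt[:r]

    YVs = (Y @ Vt.conj().T) / s[None, :]
    F_hat = U.conj().T @ YVs
    eigvals, W = np.linalg.eig(F_hat)

    nonzero = np.abs(eigvals) > ZERO_EIGENVALUE_TOL
    modes = np.zeros((D.shape[0], eigvals.size), dtype=complex)
    if np.any(nonzero):
        modes[:, nonzero] = (YVs @ W[:, nonzero]) / eigvals[None, nonzero]
    amplitudes = np.zeros(eigvals.size, dtype=complex)
    if np.any(nonzero):
        amplitudes[nonzero] = np.linalg.lstsq(
            modes[:, nonzero], D[:, 0].astype(complex), rcond=None
        )[0]
    return ExactDMDResult(eigenvalues=eigvals, modes=modes, amplitudes=amplitudes, rank=r)


def eigenvalue_to_frequency(lam: np.ndarray | complex, dt: float):
    """Map discrete-time eigenvalues to (frequency [Hz], growth rate [1/s]).

    Uses the principal branch of the complex logarithm: frequency is
    ``|arg(lambda)| / (2 pi dt)`` (non-negative, so a conjugate pair maps to
    one physical frequency) and growth is ``ln|lambda| / dt``.
    """
    if not dt > 0:
        raise ValidationError("dt must be positive")
    lam_arr = np.asarray(lam, dtype=complex)
    if np.any(lam_arr == 0):
        raise ValidationError("zero eigenvalue has no finite logarithm")
    freq = np.abs(np.angle(lam_arr)) / (2.0 * np.pi * dt)
    growth = np.log(np.abs(lam_arr)) / dt
    if np.isscalar(lam) or lam_arr.ndim == 0:
        return float(freq), float(growth)
    return freq, growth


def compute_amplitudes(modes: np.ndarray, A0: np.ndarray) -> np.ndarray:
    """Least-squares amplitudes ``b_0 = Psi^+ vec(A0)``.

    ``Psi`` stacks the vectorised matrix modes as columns; the returned
    vector makes ``sum_j Z_j b_j0`` the best approximation of the initial
    snapshot in the mode span.
    """
    modes = np.asarray(modes)
    if modes.ndim != 3 or modes.shape[2] < 1:
        raise ValidationError("modes must have shape (m, m, p) with p >= 1")
    m = modes.shape[0]
    Psi = modes.reshape(m * m, modes.shape[2], order="F")
    b0 = np.asarray(A0).reshape(m * m, order="F").astype(complex)
    return np.linalg.lstsq(Psi, b0, rcond=None)[0]


def reconstruct(
    result: GraphDMDResult,
    t_indices,
    mode_subset=None,
) -> np.ndarray:
    """Real part of ``sum_{j in subset} Z_j lambda_j^t b_j0`` at the given frames.

    An empty ``mode_subset`` returns the zero tensor (a reconstruction from
    no modes), not an error.  ``mode_subset=None`` uses all modes.
    """
    t = np.asarray(t_indices)
    if mode_subset is None:
        subset = np.arange(result.n_modes)
    else:
        subset = np.asarray(list(mode_subset), dtype=int)
    out = np.zeros((result.m, result.m, t.size))
    if subset.size == 0:
        return out
    # (p, T) temporal dynamics
    dynamics = result.eigenvalues[subset, None] ** t[None, :] * result.amplitudes[subset, None]
    out = np.einsum("ijp,pt->ijt", result.modes[:, :, subset], dynamics).real
    return out


def vaf(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Variability accounted for: ``1 - ||A - A_hat||_F^2 / ||A||_F^2``.

    Equals 1 for a perfect reconstruction, 0 for the zero reconstruction,
    and can be negative when the reconstruction is worse than predicting
    zero.
    """
    A = np.asarray(original, dtype=float)
    A_hat = np.asarray(reconstructed, dtype=float)
    if A.shape != A_hat.shape:
        raise ValidationError(f"shape mismatch: {A.shape} vs {A_hat.shape}")
    denom = np.sum(A**2)
    if denom == 0.0:
        raise ValidationError("VAF undefined for an all-zero original")
    return float(1.0 - np.sum((A - A_hat) ** 2) / denom)
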