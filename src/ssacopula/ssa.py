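"""Singular spectrum analysis (SSA) of a univariate series.

SSA decomposes a series through the SVD of its lag-embedded (Hankel)
trajectory matrix, splits the singular triples into a leading "trend"
group and a residual group, and maps matrices back to series by
anti-diagonal (Hankel) averaging.  Forecasting uses the recurrent
linear-formula method: the linear recurrence implied by the leading left
singular vectors is iterated past the end of the reconstructed series.

All functions accept plain 1-D sequences (or anything with a ``.values``
attribute, e.g. :class:`ssacopula.series.TimeSeries`) and return numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

__all__ = [
    "DegenerateRecurrenceError",
    "SSADecomposition",
    "embed",
    "decompose",
    "group",
    "diagonal_average",
    "reconstruct",
    "recurrence_coefficients",
    "forecast",
]

#: singular values below this fraction of the largest are treated as zero
#: when determining the effective rank d (floating-point rank cutoff).
RANK_TOL = 1e-12

#: verticality coefficient this close to 1 makes the forecasting
#: recurrence numerically meaningless.
VERTICALITY_TOL = 1e-10


class DegenerateRecurrenceError(ArithmeticError):
    """The SSA forecasting recurrence is degenerate (verticality ~ 1)."""


def _as_values(series) -> np.ndarray:
    values = getattr(series, "values", series)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"series must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"series must have length >= 2, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def embed(series, window_length: int) -> np.ndarray:
    """Lag-embed a series into its L x K Hankel trajectory matrix.

    Column ``j`` holds the window ``f[j], ..., f[j+L-1]``; entry ``(i, j)``
    is ``f[i+j]`` (0-based), so every anti-diagonal is constant and
    ``K = N - L + 1``.
    """
    f = _as_values(series)
    n = f.size
    L = int(window_length)
    k = n - L + 1
    if not (1 < L <= k):
        raise ValueError(
            f"window_length must satisfy 1 < L <= K = N - L + 1; "
            f"got L={L} with N={n} (valid range: 2..{(n + 1) // 2})"
        )
    return hankel(f[:L], f[L - 1 :])


@dataclass(frozen=True)
class SSADecomposition:
    """Singular triples ``(sqrt(lambda_i), U_i, V_i)`` of a trajectory matrix.

    ``singular_values`` is non-increasing and strictly positive (values below
    ``RANK_TOL`` times the largest are dropped); ``left_vectors`` is L x d and
    ``right_vectors`` K x d, both with orthonormal columns.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray

    @property
    def rank(self) -> int:
        return int(self.singular_values.size)

    @property
    def window_length(self) -> int:
        return int(self.left_vectors.shape[0])

    @property
    def series_length(self) -> int:
        return int(self.left_vectors.shape[0] + self.right_vectors.shape[0] - 1)

    def elementary(self, i: int) -> np.ndarray:
        """Rank-one elementary matrix ``X_i = sqrt(lambda_i) U_i V_i^T``."""
        return self.singular_values[i] * np.outer(
            self.left_vectors[:, i], self.right_vectors[:, i]
        )

    def partial(self, indices) -> np.ndarray:
        """Sum of the elementary matrices over ``indices`` (0-based)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            return np.zeros((self.left_vectors.shape[0], self.right_vectors.shape[0]))
        U = self.left_vectors[:, idx]
        V = self.right_vectors[:, idx]
        return (U * self.singular_values[idx]) @ V.T


def decompose(trajectory_matrix: np.ndarray, rank_tol: float = RANK_TOL) -> SSADecomposition:
    """SVD of the trajectory matrix, truncated to its effective rank d."""
    X = np.asarray(trajectory_matrix, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("trajectory matrix must be a non-empty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("trajectory matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        d = 0
    else:
        d = int(np.sum(s > rank_tol * s[0]))
    return SSADecomposition(
        singular_values=s[:d].copy(),
        left_vectors=U[:, :d].copy(),
        right_vectors=Vt[:d].T.copy(),
    )


def group(decomposition: SSADecomposition, num_components: int):
    """Split the decomposition into trend (first I triples) and residual sums.

    Returns ``(trend_matrix, residual_matrix)`` whose sum reproduces the
    decomposed matrix to floating tolerance.
    """
    d = decomposition.rank
    I = int(num_components)
    if not (1 <= I <= d):
        raise ValueError(f"num_components must be in 1..d={d}, got {I}")
    trend = decomposition.partial(np.arange(I))
    residual = decomposition.partial(np.arange(I, d))
    return trend, residual


def diagonal_average(matrix: np.ndarray) -> np.ndarray:
    """Hankelize an L x K matrix into a length ``L + K - 1`` series.

    Each output element is the mean of the matrix entries on the
    corresponding anti-diagonal ``{(m, i - m)}``, which is the three-branch
    averaging formula written out for the head (short diagonals), body
    (full-length diagonals) and tail.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("matrix must be a non-empty 2-D array")
    L, K = M.shape
    n = L + K - 1
    idx = np.add.outer(np.arange(L), np.arange(K)).ravel()
    sums = np.bincount(idx, weights=M.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return sums / counts


def reconstruct(series, window_length: int, num_components: int) -> np.ndarray:
    """Reconstruct the I-component trend of a series (embed -> SVD -> group
    -> diagonal averaging).  With ``num_components = d`` this returns the
    original series to floating tolerance."""
    X = embed(series, window_length)
    decomposition = decompose(X)
    trend_matrix, _ = group(decomposition, num_components)
    return diagonal_average(trend_matrix)


def recurrence_coefficients(left_vectors: np.ndarray):
    """Linear-recurrence coefficients of the space spanned by ``left_vectors``.

    For the L x I matrix of leading left singular vectors with last-row
    components ``pi`` and verticality ``nu^2 = |pi|^2``, the recurrence is

        y_t = sum_{j=1}^{L-1} R[L-1-j] * y_{t-j},

    i.e. ``R`` is ordered oldest-lag first so the next value is ``R @ tail``
    with ``tail`` the last L-1 values in time order.

    Raises
    ------
    DegenerateRecurrenceError
        If the verticality coefficient is within ``VERTICALITY_TOL`` of 1
        (the trend space contains a vector concentrated on the last
        coordinate and the recurrence blows up).
    """
    P = np.asarray(left_vectors, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("left_vectors must be an L x I matrix with L >= 2")
    pi = P[-1, :]
    nu2 = float(pi @ pi)
    if nu2 >= 1.0 - VERTICALITY_TOL:
        raise DegenerateRecurrenceError(
            f"degenerate SSA recurrence: verticality coefficient nu^2 = {nu2:.12g} "
            "is too close to 1; reduce the number of trend components"
        )
    R = (P[:-1, :] @ pi) / (1.0 - nu2)
    return R, nu2


def forecast(series, window_length: int, num_components: int, steps: int) -> np.ndarray:
    """Continue the I-component SSA trend ``steps`` epochs past the series end.

    Uses recurrent SSA forecasting: the linear recurrence derived from the
    leading I left singular vectors is iterated on the reconstructed trend.
    Deterministic given its inputs; ``steps = 0`` returns an empty array.
    """
    steps = int(steps)
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    X = embed(series, window_length)
    decomposition = decompose(X)
    trend_matrix, _ = group(decomposition, num_components)
    recon = diagonal_average(trend_matrix)
    if steps == 0:
        return np.empty(0)
    R, _ = recurrence_coefficients(decomposition.left_vectors[:, :num_components])
    L = int(window_length)
    buf = np.concatenate([recon[-(L - 1) :], np.empty(steps)])
    for t in range(steps):
        buf[L - 1 + t] = R @ buf[t : L - 1 + t]
    return buf[L - 1 :].copy()
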