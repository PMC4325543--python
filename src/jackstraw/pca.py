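"""Row-centering and singular value decomposition of an expression matrix.

The data model is a labeled m x n matrix Y of variables (genes, probe sets,
loci) by observations (samples, time points), with m typically much larger
than n.  Principal components are taken from the SVD of the row-centered
matrix, Y = U D V^T: the rows of V^T are the right singular vectors, and the
top r of them serve as the estimate of the latent-variable row basis the
downstream association tests work against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "PCADecomposition",
    "PCBasis",
    "center_rows",
    "svd_decompose",
    "top_pcs",
    "variance_explained",
]

#: singular values below RANK_TOL * D[0] are treated as numerically zero
RANK_TOL = 1e-12


@dataclass(frozen=True)
class ExpressionMatrix:
    """Labeled m x n numeric matrix of variables by observations."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))
        object.__setattr__(self, "col_ids", tuple(str(c) for c in self.col_ids))
        if values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        m, n = values.shape
        if m < 2 or n < 3:
            raise ValueError(f"matrix too small: need m >= 2 and n >= 3, got {m} x {n}")
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.row_ids)) != m:
            raise ValueError("row labels are not unique")
        if len(set(self.col_ids)) != n:
            raise ValueError("column labels are not unique")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite entry at row {self.row_ids[i]!r}, column {self.col_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        row_ids: Sequence[str] | None = None,
        col_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        m, n = values.shape
        if row_ids is None:
            row_ids = [f"var{i}" for i in range(m)]
        if col_ids is None:
            col_ids = [f"obs{j}" for j in range(n)]
        return cls(values, tuple(row_ids), tuple(col_ids))


@dataclass(frozen=True)
class PCADecomposition:
    """Economy SVD factors of a (row-centered) expression matrix.

    ``U`` has orthonormal columns, ``D`` holds singular values in
    non-increasing order and ``V`` is column-orthonormal; the decomposed
    matrix is recovered as ``U @ diag(D) @ V.T``.  ``centered`` records
    whether row means were removed before the decomposition.
    """

    U: np.ndarray
    D: np.ndarray
    V: np.ndarray
    centered: bool = True

    @property
    def n_components(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class PCBasis:
    """Top-r right singular vectors: an r x n orthonormal row basis."""

    basis: np.ndarray
    r: int
    singular_values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.basis.shape[1]


def center_rows(M: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the mean of each row (variable), leaving labels intact.

    Idempotent; constant rows become exactly zero.
    """
    centered = M.values - M.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(centered, M.row_ids, M.col_ids)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> None:
    """Flip each right singular vector so its largest-|entry| is positive.

    Resolves the sign indeterminacy of the SVD in place, making the
    decomposition a deterministic function of its input.
    """
    idx = np.argmax(np.abs(Vt), axis=1)
    flip = Vt[np.arange(Vt.shape[0]), idx] < 0
    Vt[flip, :] *= -1.0
    U[:, flip] *= -1.0


def svd_decompose(M: ExpressionMatrix, center: bool = True) -> PCADecomposition:
    """Economy SVD of ``M`` (after row-centering unless ``center=False``).

    Parameters
    ----------
    M
        Input matrix; all entries must be finite and the (centered) matrix
        must not be identically zero.
    center
        Remove row means first.  Pass ``False`` only for data already
        centered (e.g. a permuted copy of a centered matrix, whose row
        means are unchanged by construction).

    Returns
    -------
    PCADecomposition
        Deterministic for fixed input: each column of ``V`` is flipped so
        that its entry of largest magnitude is positive, with ``U`` flipped
        to match.
    """
    A = M.values
    if center:
        A = A - A.mean(axis=1, keepdims=True)
    if not np.any(A):
        raise ValueError("matrix is identically zero after centering; nothing to decompose")
    m, n = A.shape
    if m < n:
        warnings.warn(
            f"fewer variables than observations (m={m} < n={n}); "
            "the decomposition is valid but thin directions may swap order",
            stacklevel=2,
        )
    U, D, Vt = np.linalg.svd(A, full_matrices=False)
    _fix_signs(U, Vt)
    return PCADecomposition(U=U, D=D, V=Vt.T, centered=center)


def top_pcs(dec: PCADecomposition, r: int) -> PCBasis:
    """Extract the top-r right singular vectors as an r x n row basis.

    Requires ``1 <= r <= n - 2`` so that the full regression model retains
    at least one residual degree of freedom.  Requested components must be
    numerically nonzero (singular value above ``RANK_TOL`` relative to the
    largest) — near-degenerate trailing components are unstable and are
    refused rather than silently returned.
    """
    n = dec.V.shape[0]
    if not 1 <= r <= n - 2:
        raise ValueError(f"r must satisfy 1 <= r <= n - 2 = {n - 2}, got {r}")
    if dec.D[r - 1] <= RANK_TOL * dec.D[0]:
        raise ValueError(
            f"component {r} has a numerically zero singular value; "
            "the requested PCs are not sufficiently distinguished"
        )
    return PCBasis(basis=dec.V.T[:r].copy(), r=r, singular_values=dec.D[:r].copy())


def variance_explained(dec: PCADecomposition) -> np.ndarray:
    """Proportion of total variance captured by each component, D_k^2 / sum D_j^2."""
    total = float(np.sum(dec.D**2))
    if total == 0.0:
        raise ValueError("all singular values are zero")
    return dec.D**2 / total
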