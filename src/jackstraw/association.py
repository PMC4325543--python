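"""Per-variable F-statistics of association between data rows and PCs.

Each variable's row y_i is regressed on the top-r PC basis under the model
y_i = gamma_i V_r^T + e_i, and the F-statistic compares the full model with
a reduced model containing only the adjustment PCs.  Testing a subset of
the r PCs while adjusting for the rest (optionally after an orthogonal
rotation of the basis, e.g. toward independent components) is the partial
test; the default tests all r PCs jointly against the zero-mean null.

Degrees of freedom are (r1, n - r) with no intercept term: both the data
rows and the PC rows are exactly mean-zero after row-centering, so an
intercept column would carry zero weight while altering the denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pca import ExpressionMatrix, PCBasis

__all__ = ["AssociationSpec", "RowFit", "build_design", "fstat_row", "fstats_all"]

_ORTH_TOL = 1e-10


@dataclass(frozen=True)
class AssociationSpec:
    """Which PCs are tested versus adjusted for.

    Parameters
    ----------
    r
        Total number of PCs in the model.
    subset
        1-based indices (within ``1..r``) of the r1 PCs under test; the
        remaining r0 = r - r1 PCs are adjustment covariates.  Defaults to
        all r PCs.
    rotation
        Optional r x r orthogonal matrix applied to the basis rows before
        partitioning, so the subset refers to rotated components.
    """

    r: int
    subset: tuple[int, ...] | None = None
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")
        subset = self.subset
        if subset is None:
            subset = tuple(range(1, self.r + 1))
        else:
            subset = tuple(int(k) for k in subset)
        if len(subset) == 0:
            raise ValueError("subset must be nonempty")
        if len(set(subset)) != len(subset):
            raise ValueError(f"subset has duplicate indices: {subset}")
        if any(k < 1 or k > self.r for k in subset):
            raise ValueError(f"subset indices must lie in 1..{self.r}, got {subset}")
        object.__setattr__(self, "subset", subset)
        if self.rotation is not None:
            R = np.asarray(self.rotation, dtype=float)
            if R.shape != (self.r, self.r):
                raise ValueError(f"rotation must be {self.r} x {self.r}, got {R.shape}")
            if not np.allclose(R.T @ R, np.eye(self.r), atol=_ORTH_TOL):
                raise ValueError("rotation matrix is not orthogonal")
            object.__setattr__(self, "rotation", R)

    @property
    def r1(self) -> int:
        return len(self.subset)

    @property
    def r0(self) -> int:
        return self.r - self.r1


@dataclass(frozen=True)
class RowFit:
    """Regression result for a single variable."""

    gamma_hat: np.ndarray
    rss_full: float
    rss_reduced: float
    fstat: float


def build_design(basis: PCBasis, spec: AssociationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Full (n x r) and reduced (n x r0) design matrices for the partial test.

    Columns of the full design are the (optionally rotated) basis rows
    transposed; the reduced design keeps only the adjustment columns.  With
    r0 = 0 the reduced model is the zero-mean null (fitted values are
    identically zero), valid because both data rows and PC rows are
    centered.
    """
    if spec.r != basis.r:
        raise ValueError(f"spec.r = {spec.r} does not match basis.r = {basis.r}")
    rows = basis.basis
    if spec.rotation is not None:
        rows = spec.rotation @ rows
        if not np.allclose(rows @ rows.T, np.eye(spec.r), atol=1e-8):
            raise ValueError("rotated basis rows are not orthonormal")
    full = rows.T
    test_idx = np.array([k - 1 for k in spec.subset], dtype=int)
    keep = np.setdiff1d(np.arange(spec.r), test_idx)
    reduced = full[:, keep]
    return full, reduced


def _fstats(Y: np.ndarray, full: np.ndarray, reduced: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized F-statistics for the rows of ``Y``.

    Exploits orthonormality of the design columns: least-squares
    coefficients are inner products and each model's RSS is the total sum
    of squares minus the squared projections.  Returns (gamma, rss_full,
    rss_reduced, F).
    """
    n, r = full.shape
    r1 = r - reduced.shape[1]
    # broadcast multiply-and-sum instead of BLAS matmul: each row reduces
    # independently, so batched and row-at-a-time calls agree bit for bit
    tss = (Y * Y).sum(axis=1)
    gamma = (Y[:, :, None] * full[None, :, :]).sum(axis=1)
    rss_full = np.maximum(tss - (gamma * gamma).sum(axis=1), 0.0)
    if reduced.shape[1]:
        coef_red = (Y[:, :, None] * reduced[None, :, :]).sum(axis=1)
        rss_red = np.maximum(tss - (coef_red * coef_red).sum(axis=1), 0.0)
    else:
        rss_red = tss
    num = np.maximum(rss_red - rss_full, 0.0) / r1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / (rss_full / (n - r))
    # perfect full-model fit (up to rounding): +inf when the reduced model
    # leaves variance, 0 when both fit perfectly (e.g. an all-zero row)
    exact = rss_full <= 1e-12 * tss
    f[exact] = np.where(num[exact] > 1e-12 * tss[exact], np.inf, 0.0)
    return gamma, rss_full, rss_red, f


def fstat_row(y: np.ndarray, full_design: np.ndarray, reduced_design: np.ndarray) -> RowFit:
    """F-statistic for one centered data row against the designs.

    Shares its arithmetic with :func:`fstats_all`, so looping this function
    over rows reproduces the vectorized result bit for bit.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != full_design.shape[0]:
        raise ValueError(
            f"y has shape {y.shape}; expected length {full_design.shape[0]}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n, r = full_design.shape
    if n - r < 1:
        raise ValueError(f"no residual degrees of freedom: n = {n}, r = {r}")
    gamma, rss_full, rss_red, f = _fstats(y[None, :], full_design, reduced_design)
    return RowFit(
        gamma_hat=gamma[0],
        rss_full=float(rss_full[0]),
        rss_reduced=float(rss_red[0]),
        fstat=float(f[0]),
    )


def fstats_all(Y: ExpressionMatrix | np.ndarray, basis: PCBasis, spec: AssociationSpec) -> np.ndarray:
    """F-statistics for every row of a centered matrix against the PC basis."""
    A = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    full, reduced = build_design(basis, spec)
    n, r = full.shape
    if A.shape[1] != n:
        raise ValueError(f"matrix has {A.shape[1]} columns; design expects {n}")
    if n - r < 1:
        raise ValueError(f"no residual degrees of freedom: n = {n}, r = {r}")
    if not np.all(np.isfinite(A)):
        bad = int(np.argwhere(~np.all(np.isfinite(A), axis=1))[0, 0])
        raise ValueError(f"non-finite values in row {bad}")
    return _fstats(A, full, reduced)[3]
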