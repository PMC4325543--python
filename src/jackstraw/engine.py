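"""The jackstraw resampling engine.

PCs are estimated from the very variables being tested, so parametric
p-values for variable-PC association are anti-conservative.  The jackstraw
builds an empirical null that absorbs this over-fitting: in each of B
iterations a small number s of rows is replaced by independently permuted
("synthetic null") copies, the PCs are recomputed from the perturbed
matrix, and the permuted rows' F-statistics against the recomputed basis
are collected.  Because s << m the systematic variation — and hence the
over-fitting behavior of the PCA — is preserved, while the permuted rows
are null by construction.  The pooled s x B null statistics convert the
observed statistics into empirical p-values.

The s/B trade-off: for a fixed pool size s x B, smaller s is more accurate
but needs more SVDs; larger s is cheaper but mildly conservative (the
perturbed matrix contains more null rows than the original, so the PCs
over-fit the noise slightly more).  The trade-off is one-sided — it never
becomes anti-conservative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import AssociationSpec, _fstats, build_design, fstats_all
from .pca import ExpressionMatrix, center_rows, svd_decompose, top_pcs

__all__ = [
    "JackstrawConfig",
    "JackstrawResult",
    "default_s",
    "default_B",
    "permute_rows",
    "jackstraw_iteration",
    "empirical_pvalues",
    "run_jackstraw",
    "exhaustive_jackstraw",
]

_CENTER_ATOL = 1e-8


def default_s(m: int) -> int:
    """Default number of synthetic nulls per iteration: ceil(0.10 m)."""
    return max(1, math.ceil(0.10 * m))


def default_B(m: int, s: int) -> int:
    """Default iteration count: the smallest B with s*B >= 10*m null statistics."""
    return max(1, math.ceil(10 * m / s))


@dataclass(frozen=True)
class JackstrawConfig:
    """Resampling parameters.

    ``s`` rows are permuted per iteration and ``B`` iterations are run,
    pooling s x B null statistics.  ``pseudo_count`` switches the p-value
    formula from k/(sB) to (k+1)/(sB+1), guaranteeing strictly positive
    p-values for downstream software that dislikes exact zeros.
    """

    s: int
    B: int
    seed: int = 0
    pseudo_count: bool = False

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError(f"s must be >= 1, got {self.s}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.s * self.B < 1000:
            warnings.warn(
                f"s*B = {self.s * self.B} null statistics is a coarse empirical "
                "null; s*B >= 1000 is recommended",
                stacklevel=2,
            )

    @classmethod
    def for_matrix(cls, m: int, seed: int = 0, **kwargs) -> "JackstrawConfig":
        s = kwargs.pop("s", None) or default_s(m)
        B = kwargs.pop("B", None) or default_B(m, s)
        return cls(s=s, B=B, seed=seed, **kwargs)


@dataclass(frozen=True)
class JackstrawResult:
    """Observed statistics, pooled null pool and empirical p-values."""

    observed_f: np.ndarray
    null_f: np.ndarray  # flat, iteration-major: s values per iteration
    pvalues: np.ndarray
    config: JackstrawConfig
    spec: AssociationSpec
    pi0_hat: float | None = field(default=None, compare=False)

    @property
    def m(self) -> int:
        return self.observed_f.shape[0]


def permute_rows(Y: ExpressionMatrix, rows: Sequence[int], rng: np.random.Generator) -> ExpressionMatrix:
    """Replace the selected rows by independently permuted copies.

    Each selected row receives a fresh uniform permutation of its n
    entries; unselected rows are untouched.  Row means are preserved, so a
    centered matrix stays centered.
    """
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("no rows selected for permutation")
    if np.unique(rows).size != rows.size:
        raise ValueError("duplicate row indices in permutation set")
    A = Y.values.copy()
    n = A.shape[1]
    for i in rows:
        A[i] = A[i, rng.permutation(n)]
    return ExpressionMatrix(A, Y.row_ids, Y.col_ids)


def _iteration(
    A: np.ndarray, full_shape_spec: AssociationSpec, s: int, rng: np.random.Generator
) -> np.ndarray:
    """One resampling pass on a centered array; returns s null F-statistics."""
    m, n = A.shape
    rows = rng.choice(m, size=s, replace=False)
    Astar = A.copy()
    for i in rows:
        Astar[i] = Astar[i, rng.permutation(n)]
    # permutation preserves row means; the centered input stays centered
    U, D, Vt = np.linalg.svd(Astar, full_matrices=False)
    idx = np.argmax(np.abs(Vt), axis=1)
    flip = Vt[np.arange(Vt.shape[0]), idx] < 0
    Vt[flip, :] *= -1.0
    basis = Vt[: full_shape_spec.r]
    if full_shape_spec.rotation is not None:
        basis = full_shape_spec.rotation @ basis
    test_idx = np.array([k - 1 for k in full_shape_spec.subset], dtype=int)
    keep = np.setdiff1d(np.arange(full_shape_spec.r), test_idx)
    full = basis.T
    return _fstats(Astar[rows], full, full[:, keep])[3]


def jackstraw_iteration(
    Y: ExpressionMatrix, spec: AssociationSpec, s: int, rng: np.random.Generator
) -> np.ndarray:
    """One jackstraw iteration on a centered matrix.

    Selects s distinct rows uniformly without replacement, permutes each
    independently, recomputes the SVD and the top-r basis of the perturbed
    matrix, and returns the permuted rows' F-statistics against it.
    """
    A = Y.values
    m, n = A.shape
    if s > m:
        raise ValueError(f"s = {s} exceeds the number of rows m = {m}")
    if np.max(np.abs(A.mean(axis=1))) > _CENTER_ATOL * max(1.0, np.max(np.abs(A))):
        raise ValueError("matrix is not row-centered; center it before resampling")
    return _iteration(A, spec, s, rng)


def empirical_pvalues(
    observed: np.ndarray, null_pool: np.ndarray, pseudo_count: bool = False
) -> np.ndarray:
    """Empirical p-values p_i = #{null >= F_i} / (s*B).

    Ties count toward the numerator.  Implemented by sorting the pool once
    and binary-searching each observed statistic, which agrees exactly with
    the naive double loop.  With ``pseudo_count`` the formula becomes
    (# + 1)/(s*B + 1).
    """
    observed = np.asarray(observed, dtype=float)
    pool = np.asarray(null_pool, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("null pool is empty")
    if np.any(np.isnan(pool)) or np.any(np.isnan(observed)):
        raise ValueError("NaN statistics are not allowed")
    pool = np.sort(pool)
    n_ge = pool.size - np.searchsorted(pool, observed, side="left")
    if pseudo_count:
        return (n_ge + 1.0) / (pool.size + 1.0)
    return n_ge / float(pool.size)


def run_jackstraw(
    Y: ExpressionMatrix, spec: AssociationSpec, config: JackstrawConfig
) -> JackstrawResult:
    """Full jackstraw: observed F, pooled empirical null, p-values.

    The observed statistics are computed once against the top-r basis of
    the original (row-centered) data; B independent iterations then build
    the pooled s x B null.  Fully reproducible from ``config.seed``.
    """
    m, n = Y.shape
    if n < spec.r + 2:
        raise ValueError(f"need n >= r + 2; got n = {n}, r = {spec.r}")
    if config.s > m:
        raise ValueError(f"s = {config.s} exceeds m = {m}")
    Yc = center_rows(Y)
    dec = svd_decompose(Yc, center=False)
    basis = top_pcs(dec, spec.r)
    observed = fstats_all(Yc, basis, spec)

    rng = np.random.default_rng(config.seed)
    A = Yc.values
    null_f = np.empty(config.s * config.B)
    for b in range(config.B):
        null_f[b * config.s : (b + 1) * config.s] = _iteration(A, spec, config.s, rng)
    pvals = empirical_pvalues(observed, null_f, config.pseudo_count)
    return JackstrawResult(
        observed_f=observed, null_f=null_f, pvalues=pvals, config=config, spec=spec
    )


def exhaustive_jackstraw(
    Y: ExpressionMatrix, spec: AssociationSpec, B: int, seed: int = 0
) -> np.ndarray:
    """Within-variable jackstraw: s = 1, null statistics per variable.

    For each variable i, runs B iterations in which only row i is permuted
    and p_i is computed from row i's own B null statistics — the
    assumption-light gold standard the pooled method is checked against.
    Costs m x B SVD computations.
    """
    m, n = Y.shape
    if n < spec.r + 2:
        raise ValueError(f"need n >= r + 2; got n = {n}, r = {spec.r}")
    if m * B > 10**6:
        warnings.warn(
            f"exhaustive jackstraw needs {m * B:,} SVD computations; "
            "this may take a long time",
            stacklevel=2,
        )
    Yc = center_rows(Y)
    dec = svd_decompose(Yc, center=False)
    basis = top_pcs(dec, spec.r)
    observed = fstats_all(Yc, basis, spec)

    full0, reduced_cols = build_design(basis, spec)
    test_idx = np.array([k - 1 for k in spec.subset], dtype=int)
    keep = np.setdiff1d(np.arange(spec.r), test_idx)

    rng = np.random.default_rng(seed)
    A = Yc.values
    pvals = np.empty(m)
    Astar = A.copy()
    for i in range(m):
        count = 0
        orig_row = A[i].copy()
        for _ in range(B):
            Astar[i] = orig_row[rng.permutation(n)]
            U, D, Vt = np.linalg.svd(Astar, full_matrices=False)
            basis_star = Vt[: spec.r]
            if spec.rotation is not None:
                basis_star = spec.rotation @ basis_star
            full = basis_star.T
            f0 = _fstats(Astar[i][None, :], full, full[:, keep])[3][0]
            if f0 >= observed[i]:
                count += 1
        Astar[i] = orig_row
        pvals[i] = count / B
    return pvals
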