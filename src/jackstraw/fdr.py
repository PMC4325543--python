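"""pi0 estimation and q-values for calling significant variables.

Once the jackstraw has produced jointly valid p-values, standard false
discovery rate machinery applies.  The proportion of truly null variables
pi0 is estimated by Storey's lambda-grid method with a cubic smoother, and
q-values follow the usual step-up transform q_(i) = min_{j>=i} pi0*m*p_(j)/j.
Setting pi0 = 1 recovers Benjamini-Hochberg adjusted p-values for users who
want guaranteed-conservative calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FDRResult", "estimate_pi0", "qvalues", "call_significant", "fdr_analysis"]

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass(frozen=True)
class FDRResult:
    pi0_hat: float
    qvalues: np.ndarray
    significant: np.ndarray
    fdr_level: float


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Storey estimate of the proportion of true nulls.

    Computes pi0(lambda) = #{p_i > lambda} / (m (1 - lambda)) over the
    grid, fits a cubic polynomial smoother and evaluates it at the largest
    lambda (extrapolating toward lambda -> 1, where the estimate is least
    biased but most variable).  The result is truncated into (0, 1].
    """
    p = _check_pvalues(p)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("lambda grid must lie strictly inside (0, 1)")
    grid = np.sort(grid)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size < 4:
        est = pi0_lambda[-1]
    else:
        coeffs = np.polynomial.polynomial.polyfit(grid, pi0_lambda, deg=3)
        est = float(np.polynomial.polynomial.polyval(grid[-1], coeffs))
    return float(np.clip(est, 1.0 / m, 1.0))


def qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """q-value transform: with p sorted ascending, q_(i) = min_{j>=i} pi0*m*p_(j)/j.

    Order-preserving; with pi0 = 1 this is exactly the Benjamini-Hochberg
    adjustment.  Zero p-values map to zero q-values unchanged.
    """
    p = _check_pvalues(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(q: np.ndarray, fdr_level: float) -> np.ndarray:
    """Boolean mask of calls at the stated FDR level (q <= level)."""
    q = np.asarray(q, dtype=float)
    if not 0.0 < fdr_level < 1.0:
        raise ValueError(f"FDR level must lie strictly in (0, 1), got {fdr_level}")
    return q <= fdr_level


def fdr_analysis(
    p: np.ndarray,
    fdr_level: float = 0.01,
    method: str = "storey",
    lambda_grid: np.ndarray | None = None,
) -> FDRResult:
    """Estimate pi0 (or fix it at 1 for plain BH), compute q-values and calls."""
    if method == "storey":
        pi0 = estimate_pi0(p, lambda_grid)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown method {method!r}; use 'storey' or 'bh'")
    q = qvalues(p, pi0)
    return FDRResult(
        pi0_hat=pi0, qvalues=q, significant=call_significant(q, fdr_level), fdr_level=fdr_level
    )
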