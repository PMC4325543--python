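import numpy as np
import pytest

from jackstraw import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """Random 10 x 5 labeled matrix."""
    return ExpressionMatrix.from_array(rng.standard_normal((10, 5)))


def brute_force_fstat(y, full_design, reduced_design, clip=True):
    """Independent F-statistic oracle: both models fit by explicit normal equations.

    Solves (X'X)^{-1} X'y by matrix inversion, never reusing the package's
    projection shortcut.
    """
    y = np.asarray(y, dtype=float)
    n, r = full_design.shape
    r1 = r - reduced_design.shape[1]

    def rss(X):
        if X.shape[1] == 0:
            return float(y @ y)
        beta = np.linalg.inv(X.T @ X) @ (X.T @ y)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_full = rss(full_design)
    rss_red = rss(reduced_design)
    num = max(rss_red - rss_full, 0.0) / r1 if clip else (rss_red - rss_full) / r1
    if rss_full == 0.0:
        return np.inf if num > 0 else 0.0
    return num / (rss_full / (n - r))
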