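"""Synthetic gene-expression generator under the factor model Y = B L + E.

L is an r x n latent row basis (each row centered and scaled to unit sample
variance), B an m x r coefficient matrix in which a pi0 fraction of rows is
exactly zero — those rows are the true null variables — and E is i.i.d.
Gaussian noise.  The generator covers the standard 16-scenario grid
(dichotomous/sinusoidal latent x Uniform(0,1)/Bernoulli{-1,+1} coefficients
x m in {1000, 5000} x pi0 in {0.75, 0.95}, n = 20 throughout) and two
multi-latent designs used for subset-testing and rank-misspecification
studies.  Ground-truth masks make these studies usable for calibration
testing of any association method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pca import ExpressionMatrix

__all__ = [
    "SimulationScenario",
    "SimulatedStudy",
    "make_latent_dichotomous",
    "make_latent_sinusoidal",
    "simulate_coefficients",
    "simulate_study",
    "scenario_grid",
    "subset_design_study",
    "five_latent_study",
]

LATENT_KINDS = ("dichotomous", "sinusoidal", "custom")
COEFF_DISTS = ("uniform01", "bernoulli_pm1")


def _unit_scale(x: np.ndarray) -> np.ndarray:
    """Center and scale to zero sample mean, unit sample variance (ddof=1)."""
    x = x - x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("latent pattern is constant; cannot scale to unit variance")
    return x / sd


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated study."""

    m: int
    n: int
    latent_kind: str = "dichotomous"
    coeff_dist: str = "uniform01"
    pi0: float = 0.95
    noise_sd: float = 1.0
    r: int = 1
    custom_latents: np.ndarray | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.latent_kind not in LATENT_KINDS:
            raise ValueError(f"unknown latent kind {self.latent_kind!r}")
        if self.coeff_dist not in COEFF_DISTS:
            raise ValueError(f"unknown coefficient distribution {self.coeff_dist!r}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.latent_kind == "custom":
            if self.custom_latents is None:
                raise ValueError("latent_kind='custom' requires custom_latents")
            L = np.asarray(self.custom_latents, dtype=float)
            if L.shape != (self.r, self.n):
                raise ValueError(
                    f"custom_latents must be {self.r} x {self.n}, got {L.shape}"
                )
            object.__setattr__(self, "custom_latents", L)


@dataclass(frozen=True)
class SimulatedStudy:
    """Generated data plus the ground truth that produced it."""

    Y: ExpressionMatrix
    L: np.ndarray
    coeffs: np.ndarray
    noise: np.ndarray = field(repr=False)
    null_mask: np.ndarray
    scenario: SimulationScenario | None = None

    def null_mask_for(self, latents: Sequence[int]) -> np.ndarray:
        """Null mask for a test restricted to the given latent rows (0-based).

        A variable is null for such a test iff its coefficients on *those*
        latents are all zero, regardless of its loading on the others.
        """
        idx = np.asarray(latents, dtype=int)
        return np.all(self.coeffs[:, idx] == 0.0, axis=1)


def make_latent_dichotomous(n: int) -> np.ndarray:
    """Two-group mean-shift pattern: +c for the first n/2 observations, -c after.

    c = sqrt((n-1)/n) gives exactly unit sample variance (and zero mean).
    """
    if n % 2 != 0:
        raise ValueError(f"dichotomous latent needs even n, got {n}")
    c = math.sqrt((n - 1) / n)
    return np.concatenate([np.full(n // 2, c), np.full(n // 2, -c)])


def make_latent_sinusoidal(n: int) -> np.ndarray:
    """One full sine period over the n observations, centered and unit-variance."""
    if n < 4:
        raise ValueError(f"sinusoidal latent needs n >= 4, got {n}")
    return _unit_scale(np.sin(2.0 * np.pi * np.arange(n) / n))


def simulate_coefficients(
    m: int, pi0: float, dist: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient vector with exactly round(pi0*m) zeros at uniformly chosen positions.

    Nonzero entries are i.i.d. Uniform(0,1) or {-1,+1} signs with equal
    probability.  Returns (coefficients, null_mask).
    """
    if dist not in COEFF_DISTS:
        raise ValueError(f"unknown coefficient distribution {dist!r}")
    n_null = round(pi0 * m)
    b = np.zeros(m)
    nonnull = rng.choice(m, size=m - n_null, replace=False)
    if dist == "uniform01":
        b[nonnull] = rng.uniform(0.0, 1.0, size=nonnull.size)
    else:
        b[nonnull] = rng.choice([-1.0, 1.0], size=nonnull.size)
    mask = np.ones(m, dtype=bool)
    mask[nonnull] = False
    return b, mask


def _build_latents(sc: SimulationScenario) -> np.ndarray:
    if sc.latent_kind == "custom":
        return np.vstack([_unit_scale(row) for row in sc.custom_latents])
    maker = make_latent_dichotomous if sc.latent_kind == "dichotomous" else make_latent_sinusoidal
    return np.vstack([maker(sc.n) for _ in range(sc.r)])


def simulate_study(sc: SimulationScenario) -> SimulatedStudy:
    """Draw one study Y = B L + E from the scenario; deterministic from its seed.

    For r > 1 the non-null support (size m - round(pi0*m)) is shared across
    latents and coefficient values are drawn independently per (row,
    latent), so the number of all-zero coefficient rows is exactly
    round(pi0*m).
    """
    rng = np.random.default_rng(sc.seed)
    L = _build_latents(sc)
    m, n = sc.m, sc.n
    n_null = round(sc.pi0 * m)
    nonnull = rng.choice(m, size=m - n_null, replace=False)
    B = np.zeros((m, sc.r))
    k = nonnull.size
    if k:
        if sc.coeff_dist == "uniform01":
            B[nonnull] = rng.uniform(0.0, 1.0, size=(k, sc.r))
        else:
            B[nonnull] = rng.choice([-1.0, 1.0], size=(k, sc.r))
    E = rng.normal(0.0, sc.noise_sd, size=(m, n)) if sc.noise_sd > 0 else np.zeros((m, n))
    Y = ExpressionMatrix.from_array(B @ L + E)
    return SimulatedStudy(
        Y=Y, L=L, coeffs=B, noise=E, null_mask=np.all(B == 0.0, axis=1), scenario=sc
    )


def scenario_grid(noise_sd: float = 1.0, seed: int = 0) -> list[SimulationScenario]:
    """The 16-scenario factorial: latent kind x coefficient law x m x pi0, n = 20."""
    grid = []
    for latent in ("dichotomous", "sinusoidal"):
        for dist in ("uniform01", "bernoulli_pm1"):
            for m in (1000, 5000):
                for pi0 in (0.75, 0.95):
                    grid.append(
                        SimulationScenario(
                            m=m,
                            n=20,
                            latent_kind=latent,
                            coeff_dist=dist,
                            pi0=pi0,
                            noise_sd=noise_sd,
                            seed=seed,
                            name=f"{latent}-{dist}-m{m}-pi0{pi0:g}",
                        )
                    )
    return grid


def subset_design_study(seed: int = 0) -> SimulatedStudy:
    """Two-latent design for partial (subset-of-PCs) testing.

    m = 1000, n = 20, r = 2.  L1 is the 10/10 dichotomous split; L2
    alternates sign in blocks of five, orthogonal to L1; both carry the
    sqrt((n-1)/n) unit-variance scaling.  100 variables load on L1 and 60
    on L2, with an overlap of 40 loading on both (120 non-null overall);
    nonzero coefficients are Uniform(0,1) and noise is standard normal.
    For the test of PC1 adjusting for PC2 the nulls are the 900 rows with
    zero L1-coefficient — obtain them as ``study.null_mask_for([0])``.
    """
    m, n = 1000, 20
    rng = np.random.default_rng(seed)
    c = math.sqrt((n - 1) / n)
    L1 = c * np.concatenate([np.ones(10), -np.ones(10)])
    L2 = c * np.concatenate([np.ones(5), -np.ones(5), np.ones(5), -np.ones(5)])
    L = np.vstack([L1, L2])
    chosen = rng.choice(m, size=120, replace=False)
    both, l1_only, l2_only = chosen[:40], chosen[40:100], chosen[100:120]
    B = np.zeros((m, 2))
    B[np.concatenate([both, l1_only]), 0] = rng.uniform(0.0, 1.0, size=100)
    B[np.concatenate([both, l2_only]), 1] = rng.uniform(0.0, 1.0, size=60)
    E = rng.normal(size=(m, n))
    Y = ExpressionMatrix.from_array(B @ L + E)
    return SimulatedStudy(Y=Y, L=L, coeffs=B, noise=E, null_mask=np.all(B == 0.0, axis=1))


def five_latent_study(seed: int = 0, pi0: float = 0.75) -> SimulatedStudy:
    """Five heterogeneous latent variables for rank-misspecification studies.

    m = 1000, n = 20.  The five latent rows are drawn from: a randomized
    dichotomous variable, Normal(0,1), Uniform(0,1), Binomial(2, 0.5), and
    Normal(0, 0.25); each is centered and scaled to unit sample variance.
    Non-null rows (shared support of size m - round(pi0*m)) carry
    Uniform(0,1) coefficients on all five latents; noise is standard
    normal.
    """
    m, n, r = 1000, 20, 5
    rng = np.random.default_rng(seed)
    rows = [
        make_latent_dichotomous(n)[rng.permutation(n)],
        rng.normal(0.0, 1.0, n),
        rng.uniform(0.0, 1.0, n),
        rng.binomial(2, 0.5, n).astype(float),
        rng.normal(0.0, math.sqrt(0.25), n),
    ]
    L = np.vstack([_unit_scale(row) for row in rows])
    n_null = round(pi0 * m)
    nonnull = rng.choice(m, size=m - n_null, replace=False)
    B = np.zeros((m, r))
    B[nonnull] = rng.uniform(0.0, 1.0, size=(nonnull.size, r))
    E = rng.normal(size=(m, n))
    Y = ExpressionMatrix.from_array(B @ L + E)
    return SimulatedStudy(Y=Y, L=L, coeffs=B, noise=E, null_mask=np.all(B == 0.0, axis=1))
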