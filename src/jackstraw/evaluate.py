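"""Joint-null-criterion evaluation harness.

A multiple-testing method is jointly valid when the p-values of the true
null variables behave like an i.i.d. Uniform(0,1) sample — the joint null
criterion.  The harness simulates many independent studies, runs either
the jackstraw or the conventional parametric F-test on each, applies a
Kolmogorov-Smirnov test to each study's null p-values (two-sided for any
deviation, one-sided for anti-conservative skew toward zero), and then
aggregates the per-study KS p-values with a second, one-sided KS test —
the "double KS test".  A small double-KS p-value indicates systematic
mis-calibration that no single simulated dataset could establish on its
own.  True-null status always comes from the generator's coefficient
matrix, never from fitted loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .association import AssociationSpec, fstats_all
from .engine import JackstrawConfig, run_jackstraw
from .fdr import fdr_analysis
from .pca import ExpressionMatrix, center_rows, svd_decompose, top_pcs
from .simulate import SimulatedStudy, SimulationScenario, simulate_study

__all__ = [
    "EvaluationReport",
    "conventional_f_pvalues",
    "ks_uniform",
    "double_ks",
    "joint_null_evaluation",
    "fdr_calibration",
]

METHODS = ("jackstraw", "conventional_f")


@dataclass(frozen=True)
class EvaluationReport:
    method: str
    n_studies: int
    ks_pvalues_onesided: np.ndarray
    ks_pvalues_twosided: np.ndarray
    double_ks_p_onesided: float
    double_ks_p_twosided: float
    scenario: object = None


def conventional_f_pvalues(
    Y: ExpressionMatrix, spec: AssociationSpec
) -> np.ndarray:
    """Parametric upper-tail F(r1, n-r) p-values against the data's own PCs.

    This is the comparator the jackstraw exists to replace: because the PC
    basis is estimated from the same variables being tested, these
    p-values are anti-conservative.  Provided for evaluation only, never
    as a shipped default.
    """
    Yc = center_rows(Y)
    basis = top_pcs(svd_decompose(Yc, center=False), spec.r)
    f = fstats_all(Yc, basis, spec)
    n = Y.shape[1]
    return stats.f.sf(f, spec.r1, n - spec.r)


def ks_uniform(p: np.ndarray, sided: str = "two_sided") -> float:
    """KS test of the p-values against Uniform(0,1); returns the KS p-value.

    ``sided='anticonservative'`` uses the one-sided statistic for the
    empirical CDF exceeding the uniform CDF, i.e. p-values skewed toward
    zero.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if sided == "two_sided":
        alternative = "two-sided"
    elif sided == "anticonservative":
        alternative = "greater"
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(stats.ks_1samp(p, stats.uniform.cdf, alternative=alternative).pvalue)


def double_ks(ks_pvals: np.ndarray) -> float:
    """One-sided (anti-conservative) KS test applied to per-study KS p-values."""
    return ks_uniform(np.asarray(ks_pvals, dtype=float), "anticonservative")


def _study_seeds(seed: int, n_studies: int) -> list[tuple[int, int]]:
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_studies):
        a, b = child.generate_state(2, dtype=np.uint32)
        out.append((int(a), int(b)))
    return out


def joint_null_evaluation(
    scenario: SimulationScenario | Callable[[int], SimulatedStudy],
    n_studies: int,
    method: str,
    spec: AssociationSpec | None = None,
    engine_config: dict | None = None,
    seed: int = 0,
    null_latents: Sequence[int] | None = None,
) -> EvaluationReport:
    """Run the double-KS evaluation pipeline for one method on one design.

    Parameters
    ----------
    scenario
        Either a :class:`SimulationScenario` or a callable mapping a seed
        to a :class:`SimulatedStudy` (for the multi-latent designs).
    n_studies
        Number of independently simulated studies.
    method
        ``'jackstraw'`` or ``'conventional_f'``.
    spec
        Association test specification; defaults to testing all r PCs with
        r taken from the study's latent dimension.
    engine_config
        Extra :class:`JackstrawConfig` keywords (``s``, ``B``,
        ``pseudo_count``); sizes default from the matrix dimension.
    null_latents
        0-based latent rows defining null status for partial tests (a row
        is null iff its coefficients on these latents are all zero);
        defaults to all latents.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    engine_config = dict(engine_config or {})
    ks1 = np.empty(n_studies)
    ks2 = np.empty(n_studies)
    for k, (sim_seed, engine_seed) in enumerate(_study_seeds(seed, n_studies)):
        if callable(scenario):
            study = scenario(sim_seed)
        else:
            study = simulate_study(replace(scenario, seed=sim_seed))
        r = study.L.shape[0]
        study_spec = spec if spec is not None else AssociationSpec(r=r)
        if null_latents is None:
            mask = study.null_mask_for(range(study.coeffs.shape[1]))
        else:
            mask = study.null_mask_for(null_latents)
        if method == "jackstraw":
            cfg = JackstrawConfig.for_matrix(
                study.Y.shape[0], seed=engine_seed, **engine_config
            )
            p = run_jackstraw(study.Y, study_spec, cfg).pvalues
        else:
            p = conventional_f_pvalues(study.Y, study_spec)
        null_p = p[mask]
        ks1[k] = ks_uniform(null_p, "anticonservative")
        ks2[k] = ks_uniform(null_p, "two_sided")
    return EvaluationReport(
        method=method,
        n_studies=n_studies,
        ks_pvalues_onesided=ks1,
        ks_pvalues_twosided=ks2,
        double_ks_p_onesided=double_ks(ks1),
        double_ks_p_twosided=float(
            stats.ks_1samp(ks2, stats.uniform.cdf, alternative="greater").pvalue
        ),
        scenario=scenario if not callable(scenario) else getattr(scenario, "__name__", "factory"),
    )


def fdr_calibration(
    scenario: SimulationScenario,
    n_studies: int,
    engine_config: dict | None = None,
    thresholds: Sequence[float] = (0.01, 0.05, 0.10),
    seed: int = 0,
    method: str = "storey",
) -> list[dict]:
    """Mean estimated vs. true FDR of jackstraw + q-value calls across studies.

    For each study, jackstraw p-values are converted to q-values; at each
    threshold t the call set is {q <= t}.  The estimated FDR claimed for
    such a call set is t itself (reporting "significant at FDR <= t"), or
    0 when nothing is called; the true FDR is the fraction of calls that
    are truly null (0 when nothing is called).  Returns one dict per
    threshold with means across studies.
    """
    thresholds = [float(t) for t in thresholds]
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    engine_config = dict(engine_config or {})
    est = np.zeros((n_studies, len(thresholds)))
    true = np.zeros_like(est)
    for k, (sim_seed, engine_seed) in enumerate(_study_seeds(seed, n_studies)):
        study = simulate_study(replace(scenario, seed=sim_seed))
        cfg = JackstrawConfig.for_matrix(study.Y.shape[0], seed=engine_seed, **engine_config)
        res = run_jackstraw(study.Y, AssociationSpec(r=study.L.shape[0]), cfg)
        fdr = fdr_analysis(res.pvalues, fdr_level=max(thresholds), method=method)
        for j, t in enumerate(thresholds):
            calls = fdr.qvalues <= t
            if calls.any():
                est[k, j] = t
                true[k, j] = (calls & study.null_mask).sum() / calls.sum()
    return [
        {
            "threshold": t,
            "mean_estimated_fdr": float(est[:, j].mean()),
            "mean_true_fdr": float(true[:, j].mean()),
        }
        for j, t in enumerate(thresholds)
    ]
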