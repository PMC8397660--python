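"""Model validation against clinical-format ANC snapshots and Monte Carlo
global sensitivity analysis.

Validation compares the distribution of simulated ANC against a clinical
sample at matched days with the two-sample Kolmogorov-Smirnov test.  The
sensitivity analysis ranks parameters by partial rank correlation (PRCC)
between Latin-hypercube parameter draws and a scalar output metric (by
default the cycle-1 ANC nadir under a reference regimen) — a Monte Carlo
method that captures monotone, nonlinear input-output dependence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, qmc, rankdata

__all__ = [
    "KSReport",
    "GSAReport",
    "ks_validate",
    "validate_cohort",
    "gsa_rank",
    "nadir_metric",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSReport:
    """Two-sample K-S comparison at one day."""

    day: int | None
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    n_sim: int
    n_clinical: int


def _ks_asymp_pvalue(stat: float, n1: int, n2: int) -> float:
    """Asymptotic two-sample K-S p-value with the Stephens correction.

    ``lambda = (sqrt(en) + 0.12 + 0.11/sqrt(en)) * D`` with
    ``en = n1*n2/(n1+n2)``, then the Kolmogorov series
    ``p = 2 * sum_j (-1)^(j-1) exp(-2 j^2 lambda^2)``.  This is the classic
    *kstest2* computation; the correction makes the test mildly conservative
    at clinical sample sizes.
    """
    en = math.sqrt(n1 * n2 / (n1 + n2))
    lam = max((en + 0.12 + 0.11 / en) * stat, 0.0)
    j = np.arange(1, 102)
    p = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j**2 * lam**2))
    return float(min(max(p, 0.0), 1.0))


def ks_validate(sim_values, clin_values, alpha: float = 0.05,
                day: int | None = None, method: str = "asymp") -> KSReport:
    """Two-sample Kolmogorov-Smirnov test between simulated and clinical ANC.

    The default p-value is the classic asymptotic *kstest2*-style
    approximation with the Stephens small-sample correction (the computation
    the validation workflow is modeled on); pass ``method='exact'`` or
    ``'auto'`` for scipy's exact small-sample evaluation instead.
    """
    sim_values = np.asarray(sim_values, dtype=float)
    clin_values = np.asarray(clin_values, dtype=float)
    if sim_values.size < 5 or clin_values.size < 5:
        raise ValueError("need at least 5 values per sample")
    if method == "asymp":
        stat = float(ks_2samp(sim_values, clin_values, method="asymp").statistic)
        pvalue = _ks_asymp_pvalue(stat, sim_values.size, clin_values.size)
    else:
        res = ks_2samp(sim_values, clin_values, method=method)
        stat, pvalue = float(res.statistic), float(res.pvalue)
    return KSReport(
        day=day,
        statistic=stat,
        p_value=pvalue,
        alpha=alpha,
        reject=bool(pvalue < alpha),
        n_sim=sim_values.size,
        n_clinical=clin_values.size,
    )


def validate_cohort(
    virtual_series,
    clinical: pd.DataFrame,
    days=(1, 8, 16, 22, 28),
    alpha: float = 0.05,
    measurement_sigma: float = 0.0,
    seed: int | None = None,
    familywise: bool = True,
) -> list[KSReport]:
    """K-S comparison of virtual vs clinical ANC snapshots at selected days.

    ``clinical`` is a long-format table (patient_id, day, anc_cells_per_l);
    the virtual snapshot is read off the simulated trajectories at hour
    24*(day-1).  Days with fewer than 5 clinical patients are skipped with a
    warning.

    Clinical ANC carries measurement error while model output does not; for a
    like-with-like (predictive) comparison, pass the measurement model's
    log-scale sd as ``measurement_sigma`` to smear the virtual snapshots with
    the same multiplicative lognormal noise (seeded for reproducibility).

    ``alpha`` is the familywise level of the joint validation decision: the
    per-day tests run at the Sidak-adjusted level ``1-(1-alpha)**(1/m)`` over
    the ``m`` usable days, so a valid cohort passes *all* days with
    probability ``>= 1-alpha``.  Set ``familywise=False`` for unadjusted
    per-day decisions at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    usable = []
    for day in days:
        clin = clinical.loc[clinical["day"] == day, "anc_cells_per_l"].to_numpy()
        if clin.size < 5:
            logger.warning("day %s: only %d clinical values, skipped", day, clin.size)
            continue
        usable.append((int(day), clin))
    if not usable:
        return []
    alpha_day = (
        1.0 - (1.0 - alpha) ** (1.0 / len(usable)) if familywise else alpha
    )
    reports = []
    for day, clin in usable:
        t = 24.0 * (day - 1)
        sim = np.array([s.at_times(t) for s in virtual_series], dtype=float)
        if measurement_sigma > 0:
            sim = sim * np.exp(rng.normal(0.0, measurement_sigma, sim.size))
        reports.append(ks_validate(sim, clin, alpha=alpha_day, day=day))
    return reports


@dataclass
class GSAReport:
    """PRCC sensitivity scores and the induced importance ranking."""

    parameters: list[str]
    scores: dict[str, float]
    ranking: list[str]  # most to least influential by |score|
    n_samples: int
    metric_name: str = "anc_nadir_cycle1"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.ranking,
                "prcc": [self.scores[p] for p in self.ranking],
            }
        )


def _prcc(x_mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each column of x with y.

    Rank-transform everything, then correlate the residuals of parameter j
    and output after regressing both on the remaining parameters.
    """
    n, k = x_mat.shape
    xr = np.column_stack([rankdata(x_mat[:, j]) for j in range(k)])
    yr = rankdata(y)
    out = np.empty(k)
    for j in range(k):
        others = np.delete(xr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(design, xr[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, yr, rcond=None)
        rx = xr[:, j] - design @ beta_x
        ry = yr - design @ beta_y
        denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        out[j] = float(rx @ ry / denom) if denom > 0 else 0.0
    return out


def gsa_rank(
    parameter_ranges: dict[str, tuple[float, float]],
    n_samples: int,
    seed: int,
    output_metric,
    metric_name: str = "anc_nadir_cycle1",
) -> GSAReport:
    """Monte Carlo global sensitivity ranking by PRCC on Latin-hypercube draws.

    ``output_metric`` maps a ``{name: value}`` parameter dict to a scalar.
    Constant output yields zero scores and a warning rather than an error.
    """
    names = list(parameter_ranges)
    if len(names) < 2:
        raise ValueError("need at least 2 parameters")
    if n_samples < 100:
        raise ValueError("need at least 100 samples for a stable ranking")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_samples)
    lo = np.array([parameter_ranges[n][0] for n in names])
    hi = np.array([parameter_ranges[n][1] for n in names])
    x_mat = qmc.scale(unit, lo, hi)
    y = np.array([
        output_metric(dict(zip(names, row))) for row in x_mat
    ], dtype=float)
    if np.ptp(y) == 0:
        logger.warning("output metric constant across samples; scores set to 0")
        scores = dict.fromkeys(names, 0.0)
    else:
        scores = dict(zip(names, _prcc(x_mat, y)))
    ranking = sorted(names, key=lambda p: abs(scores[p]), reverse=True)
    return GSAReport(
        parameters=names,
        scores=scores,
        ranking=ranking,
        n_samples=n_samples,
        metric_name=metric_name,
    )


def nadir_metric(base_traits, pk, pd_params, regimen, **sim_kwargs):
    """Factory: cycle-1 ANC nadir as a function of overridden trait values.

    Returns a callable suitable as ``output_metric`` for :func:`gsa_rank`;
    parameter names must be PatientTraits fields.
    """
    from .simulate import simulate_patient

    sim_kwargs.setdefault("rtol", 1e-6)
    sim_kwargs.setdefault("atol", 1e3)

    def metric(values: dict[str, float]) -> float:
        traits = base_traits.replace(**values)
        res = simulate_patient(traits, pk, pd_params, regimen, **sim_kwargs)
        return float(res.series.anc.min())

    return metric
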