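"""Parameter regression from longitudinal ANC data.

The objective is the weighted sum of absolute normalized differences between
simulated and observed ANC, minimized by Nelder-Mead direct search (the
classic *fminsearch* workflow of pharmacometric model fitting).  Positivity
of all fitted parameters is enforced by optimizing in log space; declared
bounds are enforced by a quadratic penalty outside the box, with the final
estimate clipped to the box.

Free parameters are any subset of the patient traits ``gamma``,
``ratio_reserv0_circ0`` and ``km_fraction`` plus the PD parameters ``ec50``
and ``n_hill``; the usual workflow fits the two PD parameters once on a
reference (treatment-naive) cohort, freezes them, and then refits the three
marrow traits per disease cohort and per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .lifecycle import PatientTraits
from .pkpd import PDParams, PKParams, Regimen
from .simulate import ANCSeries, simulate_patient

__all__ = [
    "FitSpec",
    "FitResult",
    "FITTABLE_PARAMETERS",
    "objective",
    "fit_patient",
    "fit_cohort_median",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Names accepted in FitSpec.free: three marrow traits and two PD parameters.
FITTABLE_PARAMETERS = ("gamma", "ratio_reserv0_circ0", "km_fraction", "ec50", "n_hill")

#: Default search boxes; generous around the physiological/reported ranges.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (1e-4, 1.0),
    "ratio_reserv0_circ0": (0.2, 20.0),
    "km_fraction": (0.005, 5.0),
    "ec50": (0.5, 500.0),
    "n_hill": (0.2, 8.0),
}

# solver tolerances used inside fitting loops: ~3e-4 relative accuracy,
# far below the objective's sensitivity, at a fraction of the cost
_FIT_RTOL = 1e-6
_FIT_ATOL = 1e3


@dataclass
class FitSpec:
    """What to fit and from where to start.

    free : subset of :data:`FITTABLE_PARAMETERS` (non-empty)
    bounds : per-parameter (lo, hi) boxes; defaults from DEFAULT_BOUNDS
    x0 : initial guesses; defaults to the fixed context values
    weights : optional per-observation weights (default all 1)
    """

    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    x0: dict[str, float] = field(default_factory=dict)
    weights: np.ndarray | None = None
    max_iter: int = 400
    n_restarts: int = 1

    def __post_init__(self) -> None:
        self.free = tuple(self.free)
        if not self.free:
            raise ValueError("FitSpec.free must name at least one parameter")
        unknown = set(self.free) - set(FITTABLE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown fit parameters: {sorted(unknown)}")
        for name in self.free:
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name} must be finite and positive")
            self.bounds[name] = (lo, hi)
            if name in self.x0 and not (lo <= self.x0[name] <= hi):
                raise ValueError(f"initial guess for {name} outside bounds")


@dataclass
class FitResult:
    """Outcome of a direct-search fit."""

    params: dict[str, float]
    objective: float
    converged: bool
    n_iter: int
    n_fev: int
    residuals: np.ndarray
    message: str = ""


def objective(sim: ANCSeries, obs: ANCSeries, weights=None) -> float:
    """Weighted sum of absolute normalized differences.

    ``sum_i w_i * |sim(t_i) - obs_i| / obs_i`` over the uncensored
    observations; zero iff the simulation matches every observation exactly.
    Observations equal to zero cannot be normalized and are skipped with a
    warning.
    """
    obs_u = obs.uncensored()
    resid = residuals(sim, obs_u)
    if weights is None:
        weights = np.ones_like(resid)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != resid.shape:
        raise ValueError("weights must match the number of usable observations")
    return float(np.sum(weights * np.abs(resid)))


def residuals(sim: ANCSeries, obs: ANCSeries) -> np.ndarray:
    """Normalized residuals (sim - obs)/obs at the uncensored observation times."""
    obs = obs.uncensored()
    keep = obs.anc != 0
    if not keep.all():
        logger.warning(
            "skipping %d zero-valued ANC observation(s): normalization undefined",
            int((~keep).sum()),
        )
    t = obs.times[keep]
    o = obs.anc[keep]
    s = sim.at_times(t)
    return (s - o) / o


def _split_params(values: dict[str, float], base_traits: PatientTraits,
                  base_pd: PDParams) -> tuple[PatientTraits, PDParams]:
    trait_updates = {k: v for k, v in values.items()
                     if k in ("gamma", "ratio_reserv0_circ0", "km_fraction")}
    pd_updates = {k: v for k, v in values.items() if k in ("ec50", "n_hill")}
    traits = base_traits.replace(**trait_updates) if trait_updates else base_traits
    pdp = base_pd.replace(**pd_updates) if pd_updates else base_pd
    return traits, pdp


def _default_x0(name: str, traits: PatientTraits, pdp: PDParams) -> float:
    return {
        "gamma": traits.gamma,
        "ratio_reserv0_circ0": traits.ratio_reserv0_circ0,
        "km_fraction": traits.km_fraction,
        "ec50": pdp.ec50,
        "n_hill": pdp.n_hill,
    }[name]


def _run_nelder_mead(cost, x0_log, spec: FitSpec):
    """Nelder-Mead with a fresh-simplex restart.

    Direct search on this objective crawls once the simplex degenerates along
    the weakly identified directions (notably gamma); restarting from the
    incumbent with a fresh simplex is the standard *fminsearch* remedy and is
    still fully deterministic.
    """
    best = None
    x = np.asarray(x0_log, dtype=float)
    total_nit = total_nfev = 0
    stagnated = False
    for _ in range(1 + spec.n_restarts):
        res = minimize(
            cost,
            x,
            method="Nelder-Mead",
            options={
                "maxiter": spec.max_iter,
                "xatol": 1e-5,
                "fatol": 1e-10,
                "adaptive": len(x) > 2,
            },
        )
        total_nit += int(res.nit)
        total_nfev += int(res.nfev)
        if best is not None:
            stagnated = best.fun - res.fun <= max(1e-10, 1e-4 * abs(best.fun))
        if best is None or res.fun < best.fun:
            best = res
        x = res.x
    best.nit, best.nfev = total_nit, total_nfev
    # a restart that cannot improve the incumbent is a converged direct search
    # even when the iteration cap was hit
    best.success = bool(best.success or stagnated)
    return best


def fit_patient(
    obs: ANCSeries,
    spec: FitSpec,
    pk: PKParams,
    pd_params: PDParams,
    regimen: Regimen,
    base_traits: PatientTraits,
    *,
    t_half: float = 30.0,
    k_d: float = 0.001,
    beta: float = 20.0,
) -> FitResult:
    """Fit one ANC profile by Nelder-Mead on the normalized-difference objective.

    ``base_traits`` supplies every fixed trait (typically cohort medians with
    ``circ0`` set from the patient's baseline); free parameters start from
    ``spec.x0`` or, failing that, from the fixed context values.
    """
    obs_u = obs.uncensored()
    usable = obs_u.anc != 0
    if int(usable.sum()) < 3:
        raise ValueError("need at least 3 uncensored, nonzero observations")
    return fit_cohort_median(
        [(obs, regimen)], spec, pk, pd_params, base_traits,
        t_half=t_half, k_d=k_d, beta=beta,
    )


def fit_cohort_median(
    groups,
    spec: FitSpec,
    pk: PKParams,
    pd_params: PDParams,
    base_traits: PatientTraits,
    *,
    t_half: float = 30.0,
    k_d: float = 0.001,
    beta: float = 20.0,
) -> FitResult:
    """Fit one parameter set jointly to several dose groups.

    ``groups`` is a list of ``(ANCSeries, Regimen)`` pairs; each group is
    simulated under its own regimen and the per-group objectives are summed.
    With a single group this reduces exactly to :func:`fit_patient`.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one observation group")

    names = spec.free
    x0 = np.array([
        spec.x0.get(n, _default_x0(n, base_traits, pd_params)) for n in names
    ])
    bounds = [spec.bounds.get(n, DEFAULT_BOUNDS[n]) for n in names]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    lo_log = np.log([b[0] for b in bounds])
    hi_log = np.log([b[1] for b in bounds])

    horizon = max(
        28, int(np.ceil(max(g[0].uncensored().times.max() for g in groups) / 24.0))
    )

    def simulate_group(values: dict, regimen: Regimen) -> ANCSeries:
        traits, pdp = _split_params(values, base_traits, pd_params)
        res = simulate_patient(
            traits, pk, pdp, regimen, horizon,
            t_half=t_half, k_d=k_d, beta=beta,
            rtol=_FIT_RTOL, atol=_FIT_ATOL,
        )
        return res.series

    def cost(x_log: np.ndarray) -> float:
        # quadratic penalty outside the (log-space) box keeps the simplex in
        # the declared range without breaking Nelder-Mead's smooth descent
        penalty = float(
            np.sum(np.maximum(x_log - hi_log, 0.0) ** 2)
            + np.sum(np.maximum(lo_log - x_log, 0.0) ** 2)
        ) * 1e3
        x = np.exp(np.clip(x_log, lo_log, hi_log))
        values = dict(zip(names, x))
        total = 0.0
        for obs, regimen in groups:
            sim = simulate_group(values, regimen)
            total += objective(sim, obs, spec.weights)
        return total + penalty

    res = _run_nelder_mead(cost, np.log(x0), spec)

    x_fit = np.exp(np.clip(res.x, lo_log, hi_log))
    fitted = dict(zip(names, (float(v) for v in x_fit)))
    all_resid = []
    for obs, regimen in groups:
        sim = simulate_group(fitted, regimen)
        all_resid.append(residuals(sim, obs))
    if not res.success:
        logger.warning("Nelder-Mead did not converge: %s", res.message)
    return FitResult(
        params=fitted,
        objective=float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_fev=int(res.nfev),
        residuals=np.concatenate(all_resid),
        message=str(res.message),
    )
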