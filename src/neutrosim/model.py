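"""Model/Results API over the neutropenia QSP machinery.

``NeutropeniaModel`` binds observed ANC data (one patient profile or several
dose groups) to the mechanistic context — PK set, PD parameters, fixed
life-cycle constants — and ``fit()`` returns a ``NeutropeniaResults`` object
carrying estimates, residual diagnostics and a text summary, in the spirit
of the classic statistical-modeling packages:

>>> model = NeutropeniaModel.from_dataframe(obs, regimen="3mg 5/7")
>>> res = model.fit(free=("gamma", "ratio_reserv0_circ0", "km_fraction"))
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as nio
from .fitting import FITTABLE_PARAMETERS, FitResult, FitSpec, fit_cohort_median
from .lifecycle import PatientTraits
from .pkpd import PDParams, PKParams, Regimen
from .simulate import ANCSeries, simulate_patient

__all__ = ["NeutropeniaModel", "NeutropeniaResults"]


def _series_from_frame(df: pd.DataFrame, patient_id=None) -> ANCSeries:
    if patient_id is not None:
        df = df[df["patient_id"] == patient_id]
    if "gcsf_flag" in df.columns:
        flagged = df[df["gcsf_flag"].astype(bool)]
        if not flagged.empty:
            first = flagged["day"].min()
            df = df[df["day"] < first]
    df = df.sort_values("day")
    times = (df["day"].to_numpy(dtype=float) - 1.0) * 24.0
    return ANCSeries(times, df["anc_cells_per_l"].to_numpy(dtype=float))


class NeutropeniaModel:
    """A neutrophil life-cycle model bound to longitudinal ANC observations.

    Parameters
    ----------
    endog : list of (ANCSeries, Regimen)
        Observation groups; each is fitted under its own regimen and the
        objectives are summed (a single-patient fit is one group).
    base_traits : PatientTraits, optional
        Fixed-trait context; defaults to the bundled DLBCL medians with
        ``circ0`` replaced by the first observation of the first group.
    pk, pd_params : optional
        PK set (bundled default if omitted) and PD parameters.
    """

    def __init__(
        self,
        endog,
        base_traits: PatientTraits | None = None,
        pk: PKParams | None = None,
        pd_params: PDParams | None = None,
        *,
        t_half: float = 30.0,
        k_d: float = 0.001,
        beta: float = 20.0,
    ):
        self.groups = [
            (obs, Regimen.parse(reg) if isinstance(reg, str) else reg)
            for obs, reg in endog
        ]
        if not self.groups:
            raise ValueError("need at least one observation group")
        disease = nio.load_disease_set("DLBCL")
        if base_traits is None:
            baseline = float(self.groups[0][0].uncensored().anc[0])
            base_traits = disease.traits.replace(circ0=baseline)
        self.base_traits = base_traits
        self.pk = pk if pk is not None else nio.default_pk()
        self.pd_params = pd_params if pd_params is not None else disease.pd_params
        self.t_half = t_half
        self.k_d = k_d
        self.beta = beta

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        regimen,
        patient_id=None,
        **kwargs,
    ) -> "NeutropeniaModel":
        """Build from a long-format table (patient_id, day, anc_cells_per_l).

        Rows at and after a patient's first G-CSF flag are excluded, matching
        the clinical preprocessing rule.
        """
        series = _series_from_frame(data, patient_id)
        return cls([(series, regimen)], **kwargs)

    @classmethod
    def from_csv(cls, path, regimen, patient_id=None, **kwargs) -> "NeutropeniaModel":
        return cls.from_dataframe(nio.read_anc_table(path), regimen,
                                  patient_id=patient_id, **kwargs)

    def fit(
        self,
        free=("gamma", "ratio_reserv0_circ0", "km_fraction"),
        start: dict | None = None,
        bounds: dict | None = None,
        max_iter: int = 400,
        n_restarts: int = 1,
    ) -> "NeutropeniaResults":
        """Nelder-Mead fit of the free parameters; returns a results object."""
        spec = FitSpec(
            free=tuple(free),
            x0=dict(start or {}),
            bounds=dict(bounds or {}),
            max_iter=max_iter,
            n_restarts=n_restarts,
        )
        fit = fit_cohort_median(
            self.groups, spec, self.pk, self.pd_params, self.base_traits,
            t_half=self.t_half, k_d=self.k_d, beta=self.beta,
        )
        return NeutropeniaResults(self, spec, fit)

    def simulate(self, traits: PatientTraits | None = None, regimen=None,
                 horizon_days: int = 28, **kwargs):
        """Simulate the bound context (or overridden traits/regimen)."""
        reg = self.groups[0][1] if regimen is None else (
            Regimen.parse(regimen) if isinstance(regimen, str) else regimen
        )
        return simulate_patient(
            traits or self.base_traits, self.pk, self.pd_params, reg,
            horizon_days, t_half=self.t_half, k_d=self.k_d, beta=self.beta,
            **kwargs,
        )


class NeutropeniaResults:
    """Estimates, diagnostics and reporting for a fitted NeutropeniaModel."""

    def __init__(self, model: NeutropeniaModel, spec: FitSpec, fit: FitResult):
        self.model = model
        self.spec = spec
        self._fit = fit
        self.params = pd.Series(fit.params, name="estimate")
        self.objective = fit.objective
        self.converged = fit.converged
        self.n_iter = fit.n_iter
        self.resid = fit.residuals
        self.nobs = int(fit.residuals.size)

    @property
    def fitted_traits(self) -> PatientTraits:
        updates = {k: v for k, v in self._fit.params.items()
                   if k in ("gamma", "ratio_reserv0_circ0", "km_fraction")}
        return self.model.base_traits.replace(**updates)

    @property
    def fitted_pd(self) -> PDParams:
        updates = {k: v for k, v in self._fit.params.items()
                   if k in ("ec50", "n_hill")}
        return self.model.pd_params.replace(**updates) if updates else self.model.pd_params

    def predict(self, group: int = 0, times=None) -> np.ndarray:
        """Model ANC at the observation times (or supplied times, hours)."""
        obs, regimen = self.model.groups[group]
        res = simulate_patient(
            self.fitted_traits, self.model.pk, self.fitted_pd, regimen,
            t_half=self.model.t_half, k_d=self.model.k_d, beta=self.model.beta,
        )
        t = obs.uncensored().times if times is None else np.asarray(times, float)
        return res.series.at_times(t)

    def summary(self) -> str:
        lines = [
            "Neutrophil life-cycle model fit (Nelder-Mead, weighted |normalized diff|)",
            "=" * 74,
            f"groups: {len(self.model.groups)}   observations: {self.nobs}   "
            f"objective: {self.objective:.6g}",
            f"converged: {self.converged}   iterations: {self.n_iter}   "
            f"function evals: {self._fit.n_fev}",
            "-" * 74,
            f"{'parameter':<24}{'estimate':>14}  {'bounds':>24}",
        ]
        for name in self.spec.free:
            lo, hi = self.spec.bounds[name]
            lines.append(f"{name:<24}{self.params[name]:>14.6g}  "
                         f"[{lo:.3g}, {hi:.3g}]")
        fixed = {
            "circ0": self.model.base_traits.circ0,
            "t_half_h": self.model.t_half,
            "k_d_per_h": self.model.k_d,
            "beta": self.model.beta,
        }
        for name in FITTABLE_PARAMETERS:
            if name not in self.spec.free:
                if name in ("ec50", "n_hill"):
                    fixed[name] = getattr(self.model.pd_params, name)
                else:
                    fixed[name] = getattr(self.model.base_traits, name)
        lines.append("-" * 74)
        lines.append("fixed: " + ", ".join(f"{k}={v:.4g}" for k, v in fixed.items()))
        lines.append(
            "residuals (sim-obs)/obs: "
            f"mean {self.resid.mean():+.4f}, max|.| {np.abs(self.resid).max():.4f}"
        )
        return "\n".join(lines)

    def plot_fit(self, group: int = 0, ax=None):
        """Observed points and the fitted trajectory for one group."""
        import matplotlib.pyplot as plt

        obs, regimen = self.model.groups[group]
        sim = simulate_patient(
            self.fitted_traits, self.model.pk, self.fitted_pd, regimen,
            t_half=self.model.t_half, k_d=self.model.k_d, beta=self.model.beta,
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(sim.series.times / 24.0 + 1, sim.series.anc, "-", label="model")
        u = obs.uncensored()
        ax.plot(u.times / 24.0 + 1, u.anc, "o", label="observed")
        ax.set_xlabel("day")
        ax.set_ylabel("ANC (cells/L)")
        ax.set_yscale("log")
        ax.legend()
        return ax
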