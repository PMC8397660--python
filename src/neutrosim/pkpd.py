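"""Drug exposure and effect: two-compartment oral PK, inhibitory-Emax PD,
and dosing-schedule expansion.

Concentrations are ng/mL, doses mg, times hours.  Avadomide-like kinetics
are linear, so multiple dosing is handled by superposition of identical
single-dose responses, for which the standard bi/tri-exponential closed form
of the two-compartment oral model is used.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PKParams",
    "PDParams",
    "Regimen",
    "InvalidRegimenError",
    "dosing_times",
    "single_dose_concentration",
    "pk_concentration",
    "ExposureMetrics",
    "exposure_metrics",
    "effect_cc122",
    "CYCLE_HOURS",
]

CYCLE_HOURS = 672.0  # one 28-day treatment cycle


class InvalidRegimenError(ValueError):
    """Raised for dosing schedules that cannot be expanded."""


@dataclass(frozen=True)
class PKParams:
    """Apparent (oral) two-compartment PK parameters.

    ka : absorption rate, 1/h
    cl_over_f : apparent clearance CL/F, L/h
    vc_over_f : apparent central volume Vc/F, L
    q : inter-compartmental clearance, L/h
    vp : peripheral volume, L
    """

    ka: float
    cl_over_f: float
    vc_over_f: float
    q: float
    vp: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl_over_f", "vc_over_f", "q", "vp"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"PK parameter {name} must be > 0")

    def hybrid_rates(self) -> tuple[float, float]:
        """Distribution/elimination hybrid rate constants (alpha, beta)."""
        k10 = self.cl_over_f / self.vc_over_f
        k12 = self.q / self.vc_over_f
        k21 = self.q / self.vp
        s = k10 + k12 + k21
        disc = math.sqrt(s * s - 4.0 * k10 * k21)
        return (s + disc) / 2.0, (s - disc) / 2.0


@dataclass(frozen=True)
class PDParams:
    """Inhibitory sigmoid-Emax parameters for the maturation block.

    emax : maximal fractional block in [0, 1)
    ec50 : concentration of half-maximal block, ng/mL
    n_hill : Hill coefficient (> 0)
    """

    emax: float = 0.9
    ec50: float = 15.0
    n_hill: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.emax < 1.0):
            raise ValueError(f"emax must be in [0, 1), got {self.emax}")
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.n_hill > 0):
            raise ValueError(f"n_hill must be > 0, got {self.n_hill}")

    def replace(self, **kwargs) -> "PDParams":
        return replace(self, **kwargs)


_REGIMEN_RE = re.compile(
    r"^\s*(?P<dose>\d+(?:\.\d+)?)\s*mg\s+(?P<on>\d+)\s*/\s*(?P<period>\d+)\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class Regimen:
    """A dose amount plus a days-on/days-off repeating schedule.

    The schedule string convention is days-on / pattern-length: ``5/7`` means
    5 days of daily dosing followed by 2 days off, repeating weekly; ``21/28``
    means 21 days on then 7 off, anchored to the 28-day cycle.
    """

    dose_mg: float
    days_on: int
    days_off: int
    cycle_days: int = 28
    n_cycles: int = 1
    dose_hour: float = 0.0

    def __post_init__(self) -> None:
        if self.days_on < 1:
            raise InvalidRegimenError(
                f"days_on must be >= 1, got {self.days_on}"
            )
        if self.days_off < 0:
            raise InvalidRegimenError(
                f"days_off must be >= 0, got {self.days_off}"
            )
        if self.dose_mg < 0:
            raise InvalidRegimenError(
                f"dose_mg must be >= 0, got {self.dose_mg}"
            )
        if self.n_cycles < 1:
            raise InvalidRegimenError(
                f"n_cycles must be >= 1, got {self.n_cycles}"
            )
        if self.period > self.cycle_days:
            raise InvalidRegimenError(
                f"pattern length {self.period} exceeds cycle of "
                f"{self.cycle_days} days"
            )

    @property
    def period(self) -> int:
        return self.days_on + self.days_off

    @property
    def schedule_label(self) -> str:
        return f"{self.days_on}/{self.period}"

    @classmethod
    def parse(cls, text: str, **kwargs) -> "Regimen":
        """Parse a ``'6mg 5/7'``-style regimen string."""
        m = _REGIMEN_RE.match(text)
        if m is None:
            raise InvalidRegimenError(
                f"cannot parse regimen {text!r}; expected e.g. '6mg 5/7'"
            )
        days_on = int(m.group("on"))
        period = int(m.group("period"))
        if days_on > period:
            raise InvalidRegimenError(
                f"days on ({days_on}) exceeds pattern length ({period})"
            )
        return cls(
            dose_mg=float(m.group("dose")),
            days_on=days_on,
            days_off=period - days_on,
            **kwargs,
        )

    def replace(self, **kwargs) -> "Regimen":
        return replace(self, **kwargs)


def dosing_times(regimen: Regimen, horizon_days: int) -> np.ndarray:
    """Expand a regimen into strictly increasing dose times (hours).

    One dose is given on each 'on' day at ``dose_hour``; the on/off pattern
    repeats every ``days_on + days_off`` days from treatment start, so weekly
    patterns (x/7) tile the week and x/14, x/28 patterns are anchored to the
    cycle start.
    """
    if horizon_days < 1:
        raise InvalidRegimenError(f"horizon_days must be >= 1, got {horizon_days}")
    period = regimen.period
    days = [d for d in range(horizon_days) if d % period < regimen.days_on]
    return np.array([24.0 * d + regimen.dose_hour for d in days], dtype=float)


def single_dose_concentration(pk: PKParams, dose_mg: float, t) -> np.ndarray:
    """Central concentration (ng/mL) after one oral dose given at t = 0.

    Tri-exponential closed-form solution of the two-compartment model with
    first-order absorption; zero before the dose.
    """
    alpha, beta = pk.hybrid_rates()
    ka = pk.ka
    for rate in (alpha, beta):
        if abs(ka - rate) < 1e-12:
            ka *= 1.0 + 1e-9  # avoid the removable singularity at ka == alpha/beta
    k21 = pk.q / pk.vp
    dose_ng = dose_mg * 1e6
    v_ml = pk.vc_over_f * 1e3
    scale = ka * dose_ng / v_ml
    coef_a = scale * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = scale * (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_k = scale * (k21 - ka) / ((alpha - ka) * (beta - ka))

    t = np.asarray(t, dtype=float)
    tt = np.where(t >= 0.0, t, 0.0)
    conc = (
        coef_a * np.exp(-alpha * tt)
        + coef_b * np.exp(-beta * tt)
        + coef_k * np.exp(-ka * tt)
    )
    return np.where(t >= 0.0, np.maximum(conc, 0.0), 0.0)


def pk_concentration(
    pk: PKParams,
    doses: np.ndarray,
    dose_mg: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Multi-dose central concentration by superposition (linear PK)."""
    t_grid = np.asarray(t_grid, dtype=float)
    conc = np.zeros_like(t_grid)
    for td in np.asarray(doses, dtype=float):
        conc += single_dose_concentration(pk, dose_mg, t_grid - td)
    return conc


@dataclass(frozen=True)
class ExposureMetrics:
    """Cycle-1 exposure summary: AUC (ng/mL*h) and Cmax (ng/mL)."""

    auc_cycle1: float
    cmax: float


def exposure_metrics(t_grid, conc) -> ExposureMetrics:
    """Trapezoidal cycle-1 AUC and grid Cmax of a concentration series."""
    t_grid = np.asarray(t_grid, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty concentration series")
    mask = t_grid <= CYCLE_HOURS
    if not mask.any():
        raise ValueError("series does not cover cycle 1")
    return ExposureMetrics(
        auc_cycle1=float(np.trapezoid(conc[mask], t_grid[mask])),
        cmax=float(conc[mask].max()),
    )


def effect_cc122(conc, pd: PDParams):
    """Fractional maturation capacity remaining at concentration ``conc``.

    ``1 - emax * C**n / (ec50**n + C**n)``: equals 1 with no drug, decreases
    monotonically with concentration, and approaches ``1 - emax`` at
    saturating exposure.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative drug concentration")
    cn = c ** pd.n_hill
    out = 1.0 - pd.emax * cn / (pd.ec50 ** pd.n_hill + cn)
    if np.ndim(conc) == 0:
        return float(out)
    return out
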