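"""Neutrophil life-cycle model: states, homeostatic parameter cascade, and ODE
right-hand side.

The model tracks six pools of cells, all expressed as concentrations in
cells/L so that the circulation pool is directly comparable to a clinical
absolute neutrophil count (ANC):

``prol``
    committed proliferative neutrophil precursors in bone marrow,
``transit1..transit3``
    sequential maturation stages introducing a maturation time delay,
``reserv``
    mature neutrophils stored in the bone marrow reservoir awaiting egress,
``circ``
    circulating neutrophils in peripheral blood (the ANC).

A CELMoD-class drug blocks late maturation: the transit-2 -> transit-3 flux
is a Michaelis-Menten term ``v_max * effect * T2 / (k_m + T2)`` whose capacity
is scaled by the pharmacodynamic effect in (0, 1].  Two feedbacks regulate
the system: proliferation speeds up when transit 2 drops below its
homeostatic level (exponent ``gamma``), and reservoir egress speeds up when
circulating counts drop below baseline (exponent ``beta``).

All rate constants are per hour and all times are hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "FEEDBACK_CAP",
    "LifeCycleState",
    "PatientTraits",
    "LifeCycleParams",
    "InvalidParameterError",
    "derive_homeostatic_parameters",
    "feedback_proliferation",
    "feedback_egress",
    "rhs",
    "STATE_FLOOR",
]

logger = logging.getLogger(__name__)

#: Floor (cells/L) applied to state variables inside feedback evaluation only.
#: With beta = 20 the egress feedback diverges as circ -> 0; one cell per
#: litre is far below any physiological scale, so clamping there leaves the
#: dynamics of interest untouched.
STATE_FLOOR = 1.0

#: Upper cap on either feedback multiplier.  At 1e3 the effective egress rate
#: constant is ~1000 * k_out (about 9/h, a timescale of minutes), far faster
#: than every other process in the model, so the quasi-steady-state ANC is
#: unaffected; without a cap the beta = 20 power overflows once circulating
#: counts fall well below baseline and the integrator stalls.
FEEDBACK_CAP = 1e3


class InvalidParameterError(ValueError):
    """Raised when a physiological parameter is outside its valid domain."""


@dataclass(frozen=True)
class LifeCycleState:
    """Cell concentrations (cells/L) of the six model pools."""

    prol: float
    transit1: float
    transit2: float
    transit3: float
    reserv: float
    circ: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prol, self.transit1, self.transit2, self.transit3,
             self.reserv, self.circ],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LifeCycleState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class PatientTraits:
    """The four quantities that individualize a (virtual) patient.

    Parameters
    ----------
    circ0 : float
        Baseline ANC, cells/L.
    ratio_reserv0_circ0 : float
        Initial reservoir size expressed as a multiple of baseline ANC.
    km_fraction : float
        Michaelis constant of the maturation flux as a fraction of the
        homeostatic transit-2 level.
    gamma : float
        Exponent of the proliferation feedback (>= 0); larger values mean a
        stronger proliferative response to maturation block.
    """

    circ0: float
    ratio_reserv0_circ0: float
    km_fraction: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.circ0 > 0):
            raise InvalidParameterError(f"circ0 must be > 0, got {self.circ0}")
        if not (self.ratio_reserv0_circ0 > 0):
            raise InvalidParameterError(
                f"ratio_reserv0_circ0 must be > 0, got {self.ratio_reserv0_circ0}"
            )
        if not (self.km_fraction > 0):
            raise InvalidParameterError(
                f"km_fraction must be > 0, got {self.km_fraction}"
            )
        if self.gamma < 0:
            raise InvalidParameterError(f"gamma must be >= 0, got {self.gamma}")

    def replace(self, **kwargs) -> "PatientTraits":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return PatientTraits(**vals)


@dataclass(frozen=True)
class LifeCycleParams:
    """Complete, cascade-consistent parameterization of the life-cycle ODEs.

    Built by :func:`derive_homeostatic_parameters`; fields mirror the model
    rate constants (1/h), the Michaelis-Menten maturation flux (``v_max`` in
    cells/L/h, ``k_m`` in cells/L), the feedback exponents, and the
    homeostatic reference levels (cells/L).
    """

    k_prol: float
    k_tr1: float
    k_tr2: float
    k_tr3_nominal: float
    k_tr4: float
    k_out: float
    k_elim: float
    k_d: float
    v_max: float
    k_m: float
    gamma: float
    beta: float
    transit2_homeostatic: float
    circ_homeostatic: float
    reserv0: float
    tran0: float
    prol0: float
    t_half_neutrophil: float

    def initial_state(self) -> LifeCycleState:
        """Homeostatic initial condition used at treatment start."""
        return LifeCycleState(
            prol=self.prol0,
            transit1=self.tran0,
            transit2=self.transit2_homeostatic,
            transit3=self.tran0,
            reserv=self.reserv0,
            circ=self.circ_homeostatic,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def derive_homeostatic_parameters(
    traits: PatientTraits,
    t_half: float = 30.0,
    k_d: float = 0.001,
    beta: float = 20.0,
) -> LifeCycleParams:
    """Back-calculate all transit/egress rates from the steady-state condition.

    Under homeostasis every pool is constant, so the whole rate cascade is
    determined by the circulating half-life, the apoptosis rate of maturing
    cells, and the patient traits:

    * ``k_elim = ln(2) / t_half``
    * ``k_out  = k_elim * circ0 / reserv0``       (circulation balance)
    * ``k_tr4  = (k_d + k_out) * reserv0 / tran0``  (reservoir balance)
    * ``k_tr3  = k_tr4 + k_d``, ``k_tr2 = k_tr3 + k_d``,
      ``k_tr1 = k_tr2 + k_d``, ``k_prol = k_tr1``   (transit balances)
    * ``k_m    = km_fraction * tran0``
    * ``v_max  = k_tr3 * (k_m + tran0)``  so the Michaelis-Menten flux equals
      the nominal first-order flux at the homeostatic transit-2 level.

    Initial levels in all compartments except the reservoir are set to the
    baseline ANC; the reservoir starts at ``ratio_reserv0_circ0 * circ0``.

    Parameters
    ----------
    traits : PatientTraits
    t_half : float
        Circulating-neutrophil half-life in hours (> 0).
    k_d : float
        Apoptosis rate of maturing cells, 1/h (>= 0).
    beta : float
        Egress feedback exponent (>= 0).
    """
    if not (t_half > 0):
        raise InvalidParameterError(f"t_half must be > 0, got {t_half}")
    if k_d < 0:
        raise InvalidParameterError(f"k_d must be >= 0, got {k_d}")
    if beta < 0:
        raise InvalidParameterError(f"beta must be >= 0, got {beta}")

    circ0 = traits.circ0
    tran0 = circ0  # all non-reservoir pools start at the baseline ANC
    reserv0 = traits.ratio_reserv0_circ0 * circ0

    k_elim = math.log(2.0) / t_half
    k_out = k_elim * circ0 / reserv0
    k_tr4 = (k_d + k_out) * reserv0 / tran0
    k_tr3 = k_tr4 + k_d
    k_tr2 = k_tr3 + k_d
    k_tr1 = k_tr2 + k_d
    k_prol = k_tr1

    k_m = traits.km_fraction * tran0
    v_max = k_tr3 * (k_m + tran0)

    return LifeCycleParams(
        k_prol=k_prol,
        k_tr1=k_tr1,
        k_tr2=k_tr2,
        k_tr3_nominal=k_tr3,
        k_tr4=k_tr4,
        k_out=k_out,
        k_elim=k_elim,
        k_d=k_d,
        v_max=v_max,
        k_m=k_m,
        gamma=traits.gamma,
        beta=beta,
        transit2_homeostatic=tran0,
        circ_homeostatic=circ0,
        reserv0=reserv0,
        tran0=tran0,
        prol0=tran0,
        t_half_neutrophil=t_half,
    )


def _clamped(value, name: str):
    """Clamp a state variable to the feedback floor, logging on activation."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= STATE_FLOOR):
        logger.warning(
            "%s fell to or below the %g cells/L floor; clamping inside "
            "feedback evaluation", name, STATE_FLOOR,
        )
        arr = np.maximum(arr, STATE_FLOOR)
        return arr
    return value


def feedback_proliferation(transit2, transit2_homeostatic: float, gamma: float):
    """Proliferation feedback multiplier ``(T2_homeo / T2) ** gamma``.

    Equals 1 at homeostasis and exceeds 1 when the transit-2 pool is
    depleted, accelerating precursor proliferation.
    """
    t2 = _clamped(transit2, "transit2")
    return np.minimum((transit2_homeostatic / t2) ** gamma, FEEDBACK_CAP)


def feedback_egress(circ, circ_homeostatic: float, beta: float):
    """Egress feedback multiplier ``(circ_homeo / circ) ** beta``.

    With a large exponent this feedback keeps the ANC pinned near baseline
    for as long as the reservoir can sustain the required egress flux.
    """
    c = _clamped(circ, "circ")
    return np.minimum((circ_homeostatic / c) ** beta, FEEDBACK_CAP)


def rhs(state, params: LifeCycleParams, effect: float = 1.0) -> np.ndarray:
    """Time derivatives (cells/L/h) of the six pools.

    ``effect`` is the pharmacodynamic multiplier in (0, 1] applied to the
    Michaelis-Menten maturation capacity ``v_max`` — i.e. to the transit-2
    outflow and the identical transit-3 inflow — and to no other rate.
    """
    if isinstance(state, LifeCycleState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    prol, t1, t2, t3, res, circ = y

    fb_prol = feedback_proliferation(t2, params.transit2_homeostatic, params.gamma)
    fb_egr = feedback_egress(circ, params.circ_homeostatic, params.beta)
    mm_flux = params.v_max * effect * t2 / (params.k_m + t2)
    egress = params.k_out * fb_egr * res

    return np.array([
        params.k_prol * fb_prol * prol - params.k_tr1 * prol,
        params.k_tr1 * prol - (params.k_tr2 + params.k_d) * t1,
        params.k_tr2 * t1 - mm_flux - params.k_d * t2,
        mm_flux - (params.k_tr4 + params.k_d) * t3,
        params.k_tr4 * t3 - params.k_d * res - egress,
        egress - params.k_elim * circ,
    ])
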