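"""Virtual patient cohorts from empirical parameter distributions.

Individual-patient fits give a sample of values per trait.  Those samples
are screened for normality (Anderson-Darling), smoothed with a Gaussian
kernel density estimate (Silverman bandwidth, the common *ksdensity*
default), and virtual patients are created by independent draws from each
trait's estimated density — the traits are assumed independent, so no
copula or joint model is involved.  Physically positive traits use
rejection resampling of non-positive draws, which preserves the KDE shape
away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.stats.diagnostic import normal_ad

from .lifecycle import PatientTraits

__all__ = [
    "TRAIT_NAMES",
    "ParameterDistribution",
    "VirtualCohort",
    "screen_normality",
    "estimate_density",
    "sample_cohort",
    "distributions_from_frame",
]

TRAIT_NAMES = ("circ0", "ratio_reserv0_circ0", "km_fraction", "gamma")

MIN_SAMPLES = 8


def screen_normality(samples, alpha: float = 0.05) -> tuple[float, bool]:
    """Anderson-Darling test of normality with estimated mean and variance.

    Returns ``(p_value, reject)`` with ``reject`` True when normality is
    rejected at ``alpha``.  Requires at least 8 samples; constant samples are
    degenerate for the test.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant samples: normality test undefined")
    stat, pval = normal_ad(x)
    return float(pval), bool(pval < alpha)


@dataclass
class ParameterDistribution:
    """Empirical distribution of one fitted parameter plus its KDE smooth."""

    name: str
    samples: np.ndarray
    kde: gaussian_kde = field(repr=False)
    bandwidth: float
    ad_pvalue: float
    normality_rejected: bool
    positive_only: bool = True

    def pdf(self, x) -> np.ndarray:
        return self.kde(np.asarray(x, dtype=float))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample from the KDE; non-positive draws are rejected and redrawn."""
        out = np.empty(0)
        while out.size < n:
            batch = self.kde.resample(max(n - out.size, 16), seed=rng)[0]
            if self.positive_only:
                batch = batch[batch > 0]
            out = np.concatenate([out, batch])
        return out[:n]


def estimate_density(
    name: str,
    samples,
    positive_only: bool = True,
    alpha: float = 0.05,
) -> ParameterDistribution:
    """Gaussian KDE with Silverman bandwidth over a fitted-parameter sample."""
    x = np.asarray(samples, dtype=float)
    pval, reject = screen_normality(x, alpha)  # also validates the sample
    if positive_only and np.any(x <= 0):
        raise ValueError(f"{name}: positive-only distribution with non-positive samples")
    kde = gaussian_kde(x, bw_method="silverman")
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    return ParameterDistribution(
        name=name,
        samples=x,
        kde=kde,
        bandwidth=bandwidth,
        ad_pvalue=pval,
        normality_rejected=reject,
        positive_only=positive_only,
    )


def distributions_from_frame(frame: pd.DataFrame) -> dict[str, ParameterDistribution]:
    """Build the four trait distributions from a (patient x trait) table."""
    missing = [c for c in TRAIT_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    return {name: estimate_density(name, frame[name].to_numpy()) for name in TRAIT_NAMES}


@dataclass
class VirtualCohort:
    """A sampled cohort of virtual patients, reproducible from its seed."""

    traits: list[PatientTraits]
    seed: int
    source: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [f"VP{i:04d}" for i in range(len(self.traits))],
                "circ0": [t.circ0 for t in self.traits],
                "ratio_reserv0_circ0": [t.ratio_reserv0_circ0 for t in self.traits],
                "km_fraction": [t.km_fraction for t in self.traits],
                "gamma": [t.gamma for t in self.traits],
            }
        )


def sample_cohort(
    distributions: dict[str, ParameterDistribution],
    n: int,
    seed: int,
) -> VirtualCohort:
    """Create ``n`` virtual patients by independent draws per trait."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    missing = [t for t in TRAIT_NAMES if t not in distributions]
    if missing:
        raise ValueError(f"missing trait distributions: {missing}")
    rng = np.random.default_rng(seed)
    draws = {name: distributions[name].draw(n, rng) for name in TRAIT_NAMES}
    traits = [
        PatientTraits(
            circ0=draws["circ0"][i],
            ratio_reserv0_circ0=draws["ratio_reserv0_circ0"][i],
            km_fraction=draws["km_fraction"][i],
            gamma=draws["gamma"][i],
        )
        for i in range(n)
    ]
    source = {name: f"kde(n={distributions[name].samples.size})" for name in TRAIT_NAMES}
    return VirtualCohort(traits=traits, seed=seed, source=source)
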