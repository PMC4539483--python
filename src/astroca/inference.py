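"""Inferring the SERCA-activity/temperature relation from spike-width fits.

Spike width decays exponentially with temperature in experiments,
g(T) = a exp(-b T), and with pump strength in simulations,
f(P_p) = alpha exp(-beta P_p). Setting g(T) proportional to f(P_p) maps
temperature onto pump strength linearly:

    P_p(T) = (b / beta) T + ln(alpha / a) / beta.

An unknown proportionality constant between g and f shifts only the
intercept term, never the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import ExpFit


@dataclass(frozen=True)
class InferredRelation:
    """Linear pump-strength/temperature relation P_p(T) = slope * T + intercept."""

    slope: float  # pump rate per degC
    intercept: float  # pump rate
    valid_range: tuple[float, float] = (20.0, 37.0)

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def predict(self, temperature):
        return self.slope * np.asarray(temperature, dtype=float) + self.intercept


def infer_relation(
    exp_fit: ExpFit,
    sim_fit: ExpFit,
    valid_range: tuple[float, float] = (20.0, 37.0),
) -> InferredRelation:
    """Combine the experimental and simulated exponential spike-width fits.

    ``exp_fit`` holds (a, b) of width-vs-temperature, ``sim_fit`` holds
    (alpha, beta) of width-vs-pump-strength.
    """
    a, b = exp_fit.prefactor, exp_fit.decay
    alpha, beta = sim_fit.prefactor, sim_fit.decay
    if beta == 0:
        raise ValueError("beta = 0: the simulated fit carries no pump dependence")
    if a <= 0 or alpha <= 0:
        raise ValueError("prefactors must be positive")
    return InferredRelation(
        slope=b / beta,
        intercept=float(np.log(alpha / a) / beta),
        valid_range=valid_range,
    )


def relative_activity(
    relation: InferredRelation,
    t_ref: float = 30.0,
    temperatures=(20.0, 24.0, 28.0, 30.0, 31.0, 37.0),
) -> list[tuple[float, float]]:
    """Pump activity as a percentage of its value at ``t_ref``."""
    ref = float(relation.predict(t_ref))
    if ref <= 0:
        raise ValueError(
            f"P_p({t_ref}) = {ref:.3g} <= 0: relation not interpretable as "
            "an activity at the reference temperature"
        )
    return [(float(T), 100.0 * float(relation.predict(T)) / ref) for T in temperatures]


def report(
    exp_fit: ExpFit,
    sim_fit: ExpFit,
    relation: InferredRelation,
    t_ref: float = 30.0,
    temperatures=(20.0, 24.0, 28.0, 30.0, 31.0, 37.0),
) -> dict:
    """Structured inference report (JSON-serializable)."""
    return {
        "experimental_fit": {
            "a_s": exp_fit.prefactor,
            "b_per_degC": exp_fit.decay,
            "a_se": exp_fit.prefactor_se,
            "b_se": exp_fit.decay_se,
        },
        "simulated_fit": {
            "alpha_s": sim_fit.prefactor,
            "beta_s": sim_fit.decay,
            "alpha_se": sim_fit.prefactor_se,
            "beta_se": sim_fit.decay_se,
        },
        "relation": {
            "slope_per_degC": relation.slope,
            "intercept": relation.intercept,
            "valid_range_degC": list(relation.valid_range),
        },
        "relative_activity_pct": {
            f"{T:g}": pct
            for T, pct in relative_activity(relation, t_ref, temperatures)
        },
    }
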