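"""Synthetic fluorescence-like Ca2+ traces and in-text reference tables.

Spontaneous astrocyte spiking behaves as a renewal process whose inter-spike
intervals are a deterministic refractory time plus an exponential waiting
time. That construction realizes exactly the linear sigma-T_av relation with
slope one and intercept T_det that characterizes spontaneous activity, which
makes it the natural ground-truth generator for testing the spike-train
statistics. It is a modeling stand-in for the real ISI law, not a claim
about it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spikes import Trace


@dataclass(frozen=True)
class TraceRecipe:
    """Everything needed to generate one synthetic recording.

    Times in seconds, amplitudes in arbitrary fluorescence units.
    """

    t_det: float = 20.0
    waiting_mean: float = 30.0
    shape: str = "gaussian"  # or "double_exponential"
    fwhm: float = 30.0
    amplitude: float = 1.0
    baseline: float = 0.1
    drift_per_s: float = 0.0
    noise_sd: float = 0.0
    sampling_dt: float = 0.5
    duration: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if self.t_det < 0 or self.waiting_mean < 0:
            raise ValueError("t_det and waiting_mean must be non-negative")
        if self.fwhm <= 0 or self.amplitude <= 0:
            raise ValueError("fwhm and amplitude must be positive")
        typical_isi = self.t_det + self.waiting_mean
        if typical_isi > 0 and self.fwhm >= typical_isi:
            raise ValueError("fwhm must be below the typical inter-spike interval")
        if self.sampling_dt * 10 > self.fwhm:
            raise ValueError("sampling interval must resolve the width "
                             "(>= 10 samples per FWHM)")
        if self.shape not in ("gaussian", "double_exponential"):
            raise ValueError(f"unknown shape {self.shape!r}")


def generate_spike_train(recipe: TraceRecipe) -> np.ndarray:
    """Spike times with ISIs = T_det + Exponential(waiting_mean)."""
    rng = np.random.default_rng(recipe.seed)
    times = []
    t = 0.0
    while True:
        wait = rng.exponential(recipe.waiting_mean) if recipe.waiting_mean > 0 else 0.0
        t += recipe.t_det + wait
        if t >= recipe.duration:
            break
        times.append(t)
    return np.asarray(times)


def _gaussian_template(tau: np.ndarray, fwhm: float) -> np.ndarray:
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (tau / sd) ** 2)


def _double_exp_template(tau: np.ndarray, fwhm: float) -> np.ndarray:
    """Fast-rise/slow-decay pulse, numerically scaled to the requested FWHM.

    Shape exp(-t/tau_d) - exp(-t/tau_r) with tau_r = tau_d / 5; the decay
    constant is chosen so the half-maximum width equals ``fwhm``.
    """
    ratio = 5.0
    # width of the unit-tau_d template, found once on a fine grid
    s = np.linspace(0, 20, 20_001)
    base = np.exp(-s) - np.exp(-ratio * s)
    base /= base.max()
    above = np.nonzero(base >= 0.5)[0]
    unit_width = s[above[-1]] - s[above[0]]
    tau_d = fwhm / unit_width
    out = np.zeros_like(tau)
    pos = tau >= 0
    out[pos] = np.exp(-tau[pos] / tau_d) - np.exp(-ratio * tau[pos] / tau_d)
    peak = out.max()
    return out / peak if peak > 0 else out


def render_trace(spike_times: np.ndarray, recipe: TraceRecipe) -> Trace:
    """Superimpose shape templates on a drifting baseline plus noise."""
    rng = np.random.default_rng(recipe.seed + 1)
    t = np.arange(0.0, recipe.duration, recipe.sampling_dt)
    y = recipe.baseline + recipe.drift_per_s * t
    for ts in np.asarray(spike_times, dtype=float):
        tau = t - ts
        if recipe.shape == "gaussian":
            y += recipe.amplitude * _gaussian_template(tau, recipe.fwhm)
        else:
            y += recipe.amplitude * _double_exp_template(tau, recipe.fwhm)
    if recipe.noise_sd > 0:
        y = y + rng.normal(0.0, recipe.noise_sd, size=t.size)
    overlap_warning = bool(
        spike_times.size >= 2 and np.min(np.diff(np.sort(spike_times))) < 2 * recipe.fwhm
    )
    return Trace(
        time=t,
        values=y,
        meta={
            "recipe": recipe,
            "n_spikes_true": int(np.asarray(spike_times).size),
            "overlap_warning": overlap_warning,
        },
    )


def synthesize(recipe: TraceRecipe) -> Trace:
    """Convenience wrapper: train + rendering in one call."""
    return render_trace(generate_spike_train(recipe), recipe)


def fixture_spike_width_table() -> pd.DataFrame:
    """Measured mean spike widths (FWHM) per temperature condition.

    Columns: preparation, condition, temperature (degC), mean spike width and
    its spread (s), and the number of pooled spikes (pd.NA where the count
    was not reported). ``recovery`` marks recordings taken after returning to
    the lower temperature.
    """
    rows = [
        ("slice", "baseline", 24.0, 45.0, 17.0, 70),
        ("slice", "heated", 37.0, 13.0, 4.0, 53),
        ("slice", "recovery", 24.0, 45.0, 18.0, 71),
        ("slice", "heated", 31.0, 22.0, 5.0, 43),
        ("culture", "baseline", 20.0, 63.0, 18.0, pd.NA),
        ("culture", "heated", 30.0, 21.0, 5.0, 26),
        ("culture", "recovery", 20.0, 72.0, 20.0, 56),
        ("culture", "heated", 28.0, 27.0, 6.0, 103),
        ("culture", "baseline", 20.0, 75.0, 16.0, 105),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "preparation",
            "condition",
            "temperature_C",
            "mean_width_s",
            "sd_width_s",
            "n_spikes",
        ],
    )
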