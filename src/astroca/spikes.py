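"""Spike detection and quantification for Ca2+ traces.

Shared by fluorescence-like recordings, the spatial cell simulator, and the
rate-equation model: FWHM spike widths, amplitudes, inter-spike-interval
statistics (T_av, sigma), the population sigma-T_av regression, and
exponential y = a exp(-b x) fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import curve_fit


@dataclass
class Trace:
    """Uniformly sampled time series with optional labels."""

    time: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise ValueError("time and values must be 1-D arrays of equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class SpikeEvent:
    peak_time: float
    peak_value: float
    baseline: float
    fwhm: float

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.baseline

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.peak_value <= self.baseline:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class TrainStats:
    """Inter-spike-interval statistics of one spike train."""

    n_spikes: int
    t_av: float
    sigma: float | None  # undefined (None) below 3 spikes

    @property
    def sigma_defined(self) -> bool:
        return self.sigma is not None


@dataclass(frozen=True)
class ExpFit:
    """Parameters of y = prefactor * exp(-decay * x)."""

    prefactor: float
    decay: float
    prefactor_se: float
    decay_se: float
    residual: float

    def predict(self, x):
        return self.prefactor * np.exp(-self.decay * np.asarray(x, dtype=float))


def _running_baseline(values: np.ndarray, window: int, percentile: float) -> np.ndarray:
    """Running low-percentile over a centered window (edge-padded)."""
    n = values.size
    half = max(window // 2, 1)
    padded = np.pad(values, half, mode="edge")
    sw = np.lib.stride_tricks.sliding_window_view(padded, 2 * half + 1)[:n]
    return np.percentile(sw, percentile, axis=1)


def detect_spikes(
    trace: Trace,
    baseline_window: float = 60.0,
    prominence_fraction: float = 0.2,
    min_separation: float = 5.0,
    baseline_percentile: float = 10.0,
    min_snr: float = 6.0,
) -> list[SpikeEvent]:
    """Detect Ca2+ spikes and measure their FWHM.

    The baseline is a running low percentile of the signal, refined per spike
    by the low percentile of the stretch between the neighboring peaks (so an
    isolated wide transient does not drag its own baseline up). Candidate
    peaks are local maxima exceeding ``prominence_fraction`` of the global
    signal range above baseline and ``min_snr`` times the robust noise level,
    separated by at least ``min_separation``. The width is measured at
    baseline + amplitude/2 with linear interpolation between samples; spikes
    whose half-height crossings leave the recording are discarded.
    """
    t, y = trace.time, trace.values
    if trace.duration <= baseline_window:
        raise ValueError("trace must be longer than the baseline window")
    dt = trace.dt
    win = max(int(round(baseline_window / dt)), 2)
    baseline = _running_baseline(y, win, baseline_percentile)
    above = y - baseline
    global_range = float(np.ptp(y))
    if global_range == 0.0:
        return []
    # robust noise scale from first differences (spikes occupy few samples)
    dy = np.diff(y)
    noise_sd = 1.4826 * float(np.median(np.abs(dy - np.median(dy)))) / np.sqrt(2.0)
    min_amp = max(prominence_fraction * global_range, min_snr * noise_sd)
    distance = max(int(round(min_separation / dt)), 1)
    peaks, _ = signal.find_peaks(
        above, height=min_amp, prominence=min_amp, distance=distance
    )
    events: list[SpikeEvent] = []
    n = y.size
    for i, p in enumerate(peaks):
        seg_lo = peaks[i - 1] if i > 0 else 0
        seg_hi = peaks[i + 1] if i + 1 < len(peaks) else n - 1
        segment_base = float(np.percentile(y[seg_lo : seg_hi + 1],
                                           baseline_percentile))
        base = min(baseline[p], segment_base)
        if y[p] - base < min_amp:
            continue
        half = base + (y[p] - base) / 2.0
        # bound the spike by the troughs towards the neighboring peaks
        lo = seg_lo + int(np.argmin(y[seg_lo : p + 1]))
        hi = p + int(np.argmin(y[p : seg_hi + 1]))
        if y[lo] > half or y[hi] > half:
            continue  # merged with a neighbor or leaves the recording
        if (i == 0 and y[0] > half) or (i == len(peaks) - 1 and y[-1] > half):
            continue
        # occupancy width: time above the half level between the troughs;
        # counting samples is unbiased under symmetric noise, unlike walking
        # to the first crossing
        fwhm = float(np.count_nonzero(y[lo : hi + 1] > half)) * dt
        if fwhm <= 0:
            continue
        events.append(
            SpikeEvent(peak_time=float(t[p]), peak_value=float(y[p]),
                       baseline=float(base), fwhm=float(fwhm))
        )
    return events


def isi_stats(spikes: list[SpikeEvent]) -> TrainStats:
    """Mean and unbiased standard deviation of the inter-spike intervals."""
    if len(spikes) < 2:
        raise ValueError("at least two spikes are required for an ISI")
    times = np.sort([s.peak_time for s in spikes])
    isis = np.diff(times)
    sigma = float(np.std(isis, ddof=1)) if len(spikes) >= 3 else None
    return TrainStats(n_spikes=len(spikes), t_av=float(isis.mean()), sigma=sigma)


@dataclass(frozen=True)
class SigmaTavFit:
    slope: float
    intercept: float
    t_det: float
    slope_se: float
    intercept_se: float


def fit_sigma_tav(stats_list: list[TrainStats]) -> SigmaTavFit:
    """Population OLS of sigma against T_av; T_det is the sigma = 0 intercept."""
    pts = [(s.t_av, s.sigma) for s in stats_list if s.sigma is not None]
    if len(pts) < 3:
        raise ValueError("need at least three trains with defined sigma")
    x, y = map(np.asarray, zip(*pts))
    if np.ptp(x) == 0:
        raise ValueError("degenerate spread: all T_av equal")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("zero slope: deterministic time undefined")
    return SigmaTavFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_det=float(-res.intercept / res.slope),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def fit_exponential(x, y) -> ExpFit:
    """Nonlinear least squares of y = a exp(-b x), log-linear initialized.

    All points are weighted equally. Standard errors are
    heteroscedasticity-robust (HC3 sandwich), since spike-width spreads
    typically scale with the width itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.any(y <= 0):
        raise ValueError("y must be positive for the exponential model")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(-b * t), x, y, p0=p0, maxfev=10_000
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit did not converge; log-linear fallback "
            f"a={p0[0]:.6g}, b={p0[1]:.6g}"
        ) from err
    a, b = popt
    model = a * np.exp(-b * x)
    resid_vec = y - model
    jac = np.stack([np.exp(-b * x), -a * x * np.exp(-b * x)], axis=1)
    jtj_inv = np.linalg.inv(jac.T @ jac)
    leverage = np.einsum("ij,jk,ik->i", jac, jtj_inv, jac)
    wres = (resid_vec / np.clip(1.0 - leverage, 1e-8, None)) ** 2
    cov = jtj_inv @ (jac.T @ (jac * wres[:, None])) @ jtj_inv
    se = np.sqrt(np.diag(cov))
    return ExpFit(
        prefactor=float(a),
        decay=float(b),
        prefactor_se=float(se[0]),
        decay_se=float(se[1]),
        residual=float(np.sqrt(np.mean(resid_vec**2))),
    )


def spike_table(traces_and_spikes) -> pd.DataFrame:
    """Long-format spike table (trace_id, t_peak, amplitude, fwhm)."""
    rows = []
    for trace_id, spikes in traces_and_spikes:
        for s in spikes:
            rows.append(
                {
                    "trace_id": trace_id,
                    "t_peak": s.peak_time,
                    "amplitude": s.amplitude,
                    "fwhm": s.fwhm,
                }
            )
    return pd.DataFrame(rows, columns=["trace_id", "t_peak", "amplitude", "fwhm"])
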