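"""Well-stirred rate-equation counter-model of cellular Ca2+ cycling.

Three compartments — cytosol, ER, and mitochondria — exchange Ca2+ through
IP3R release, SERCA uptake, an ER leak, mitochondrial uniporter and Na/Ca
exchanger fluxes, plasma-membrane influx, and PMCA extrusion. The model has
no spatial structure by construction; it exists to ask whether a homogeneous
cell can reproduce the measured dependence of spike shape on pump strength.

Internal units are uM and ms (the natural units of the parameter set);
periods and widths are reported in seconds.

Two printed ambiguities are kept explicit and configurable:

* ``K_serca``: the half-saturation constant of the SERCA flux collides
  symbolically with the Na/Ca exchanger prefactor in the source tables. It
  is therefore a separate, mandatory parameter (reference value 0.2 uM, a
  typical sub-micromolar SERCA affinity).
* ``inhibition``: the Ca inhibition factor of the release flux as printed,
  ``p3^4/(p4^4+Ca^4)``, is >> 1 at rest; the variants ``p4^4/(p4^4+Ca^4)``
  and ``p3^4/(p3^4+Ca^4)`` are selectable. The printed form is the default.

With every printed default the model is non-oscillatory for all pump
strengths (the plasma-membrane flux balance pins the cytosolic fixed point
at ~0.51 uM, outside the release term's positive-feedback region, making the
fixed point stable); see docs/methods.md. ``oscillatory_reference_params``
returns the corrected configuration in which a genuine oscillatory window
in P_p exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .config import default_config
from .spikes import Trace, detect_spikes, isi_stats

INHIBITION_FORMS = ("printed", "p4", "p3")


@dataclass(frozen=True)
class OdeParams:
    """Rate-equation parameters (uM, ms)."""

    P_r: float = 0.03  # 1/ms
    p1: float = 0.5
    p2: float = 0.9
    p3: float = 1.3
    p4: float = 0.2
    P_p: float = 0.06  # uM/ms
    p5: float = 10.0
    p6: float = 0.6
    p7: float = 1.0
    p8: float = 10.0
    p9: float = 0.2
    p10: float = 1.0
    p11: float = 1.0e-3
    p12: float = 3.0e-6
    p13: float = 15.0e-6
    p14: float = 0.01
    p15: float = 0.7
    IP3: float = 0.4
    f_cyt: float = 0.015
    f_er: float = 0.5
    J_ext_bas: float = 3.5e-3
    Delta: float = 0.07
    gamma_inv: float = 30.0
    K_serca: float = 0.2
    inhibition: str = "printed"

    def __post_init__(self):
        if self.inhibition not in INHIBITION_FORMS:
            raise ValueError(f"inhibition must be one of {INHIBITION_FORMS}")
        if self.K_serca <= 0:
            raise ValueError("K_serca must be positive")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "OdeParams":
        if cfg is None:
            cfg = default_config()["ode"]
        return cls(**{k: cfg[k] for k in cfg})


def oscillatory_reference_params(**overrides) -> OdeParams:
    """Corrected configuration with a genuine oscillatory window in P_p."""
    cfg = default_config()
    params = OdeParams.from_config(cfg["ode"])
    return replace(params, **{**cfg["ode_oscillatory"], **overrides})


@dataclass(frozen=True)
class OdeState:
    ca_c: float
    ca_er: float
    ca_m: float

    def __post_init__(self):
        if min(self.ca_c, self.ca_er, self.ca_m) < 0:
            raise ValueError("concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_c, self.ca_er, self.ca_m])


def fluxes(state: OdeState | np.ndarray, params: OdeParams) -> dict:
    """All named fluxes (uM/ms) at the given state."""
    if isinstance(state, OdeState):
        cc, cer, cm = state.ca_c, state.ca_er, state.ca_m
    else:
        cc, cer, cm = state
    p = params
    if p.inhibition == "printed":
        inh = p.p3**4 / (p.p4**4 + cc**4)
    elif p.inhibition == "p4":
        inh = p.p4**4 / (p.p4**4 + cc**4)
    else:
        inh = p.p3**4 / (p.p3**4 + cc**4)
    j_release = (
        p.P_r
        * (p.IP3**2 / (p.p1**2 + p.IP3**2))
        * (cc**2 / (p.p2**2 + cc**2))
        * inh
        * (cer - cc)
    )
    j_serca = p.P_p * cc**2 / (p.K_serca**2 + cc**2)
    j_naca = p.p5 * cm / (cm + p.p6) * p.p7**2 / (p.p8**2 + cc**2)
    j_uni = p.p9 * cc**2 / (p.p10**2 + cc**2)
    j_leak = p.p11 * (cer - cc)
    j_ext = p.J_ext_bas - (p.p12 * cer + p.p13 * cc)
    j_pmca = p.p14 * cc**2 / (p.p15**2 + cc**2)
    return {
        "J_release": j_release,
        "J_serca": j_serca,
        "J_NaCa": j_naca,
        "J_uni": j_uni,
        "J_mito": j_naca - j_uni,
        "J_leak": j_leak,
        "J_ext": j_ext,
        "J_pmca": j_pmca,
    }


def rhs(state: OdeState | np.ndarray, params: OdeParams) -> np.ndarray:
    """Time derivatives (uM/ms) of (Ca_c, Ca_er, Ca_m).

    The mitochondrial pool is closed with dCa_m/dt = J_uni - J_NaCa, the
    minimal closure consistent with the Delta * J_mito term in the cytosolic
    balance (no mitochondrial equation is part of the printed model).
    """
    j = fluxes(state, params)
    p = params
    dca_c = p.f_cyt * (
        j["J_ext"]
        + p.Delta * j["J_mito"]
        + j["J_release"]
        + j["J_leak"]
        - j["J_serca"]
        - j["J_pmca"]
    )
    dca_er = p.f_er * p.gamma_inv * (j["J_serca"] - j["J_release"] - j["J_leak"])
    dca_m = j["J_uni"] - j["J_NaCa"]
    return np.array([dca_c, dca_er, dca_m])


def resting_state(
    params: OdeParams, guess: OdeState | None = None, zero_release: bool = False
) -> OdeState:
    """Fixed point of the rate equations, found by root-finding."""
    p = replace(params, P_r=0.0) if zero_release else params
    x0 = guess.as_array() if guess is not None else np.array([0.1, 10.0, 0.1])
    sol, info, ier, msg = fsolve(
        lambda x: rhs(np.maximum(x, 0.0), p), x0, full_output=True, xtol=1e-13
    )
    if ier != 1:
        # relax towards the attractor first, then polish
        relaxed = integrate(p, OdeState(*np.maximum(x0, 0.0)), 500.0)
        x1 = relaxed.meta["state"][-1]
        sol, info, ier, msg = fsolve(
            lambda x: rhs(np.maximum(x, 0.0), p), x1, full_output=True, xtol=1e-13
        )
    if ier != 1:
        raise RuntimeError(f"fixed-point search failed: {msg}")
    sol = np.maximum(sol, 0.0)
    return OdeState(*sol)


def integrate(
    params: OdeParams,
    initial: OdeState,
    duration_s: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt_s: float = 0.25,
    max_step_ms: float = 500.0,
) -> Trace:
    """Stiff-capable integration with dense uniform output for spike analysis.

    Returns the cytosolic trace (seconds, uM); the full state is available in
    the trace metadata.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    t_s = np.arange(0.0, duration_s + sample_dt_s / 2, sample_dt_s)
    if duration_s == 0.0 or t_s.size < 2:
        return Trace(
            time=np.array([0.0]),
            values=np.array([initial.ca_c]),
            meta={"state": np.array([initial.as_array()]), "params": params},
        )
    sol = solve_ivp(
        lambda t, x: rhs(x, params),
        (0.0, duration_s * 1000.0),
        initial.as_array(),
        method="LSODA",
        t_eval=t_s * 1000.0,
        rtol=rtol,
        atol=atol,
        max_step=max_step_ms,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    return Trace(
        time=t_s,
        values=sol.y[0],
        meta={"state": sol.y.T.copy(), "params": params},
    )


def measure_oscillation(
    trace: Trace,
    transient_fraction: float = 0.25,
    prominence_fraction: float = 0.2,
    min_separation_s: float = 2.0,
    min_amplitude: float = 1e-3,
) -> dict:
    """Period, amplitude and FWHM of the post-transient oscillation.

    Non-oscillating runs (< 3 surviving peaks, or sub-nanomolar ripple from
    integrator noise below ``min_amplitude``) are flagged with NaN metrics.
    """
    keep = trace.time >= transient_fraction * trace.time[-1]
    tail = Trace(time=trace.time[keep], values=trace.values[keep])
    window = min(60.0, 0.45 * tail.duration)
    if float(np.ptp(tail.values)) < min_amplitude:
        return {
            "oscillating": False,
            "period_s": np.nan,
            "amplitude_uM": np.nan,
            "width_s": np.nan,
            "n_spikes": 0,
        }
    spikes = detect_spikes(
        tail,
        baseline_window=window,
        prominence_fraction=prominence_fraction,
        min_separation=min_separation_s,
    )
    if len(spikes) < 3:
        return {
            "oscillating": False,
            "period_s": np.nan,
            "amplitude_uM": np.nan,
            "width_s": np.nan,
            "n_spikes": len(spikes),
        }
    st = isi_stats(spikes)
    return {
        "oscillating": True,
        "period_s": st.t_av,
        "amplitude_uM": float(np.mean([s.amplitude for s in spikes])),
        "width_s": float(np.mean([s.fwhm for s in spikes])),
        "n_spikes": len(spikes),
    }


def scan_pp(
    params: OdeParams,
    pp_grid,
    pr_values=(0.015, 0.03, 0.06),
    duration_s: float = 400.0,
    transient_fraction: float = 0.25,
    initial: OdeState | None = None,
) -> pd.DataFrame:
    """Pump-strength scan for several release rates.

    Each cell of the (P_p, P_r) grid is integrated past a transient and the
    spike characteristics are measured; rows are flagged non-oscillating
    when fewer than three peaks survive the transient.
    """
    pp_grid = list(pp_grid)
    pr_values = list(pr_values)
    if not pp_grid or not pr_values:
        raise ValueError("scan grids must be non-empty")
    x0 = initial if initial is not None else OdeState(0.1, 10.0, 0.1)
    rows = []
    for pr in pr_values:
        for pp in pp_grid:
            p = replace(params, P_p=pp, P_r=pr)
            trace = integrate(p, x0, duration_s)
            m = measure_oscillation(trace, transient_fraction)
            rows.append(
                {
                    "P_p": pp,
                    "P_r": pr,
                    "period_s": m["period_s"],
                    "amplitude_uM": m["amplitude_uM"],
                    "width_s": m["width_s"],
                    "oscillating": m["oscillating"],
                }
            )
    return pd.DataFrame(rows)
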