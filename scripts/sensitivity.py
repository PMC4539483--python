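#!/usr/bin/env python
"""Sensitivity reports for the two documented analysis choices.

1. Rate-equation model: how the qualitative oscillation structure depends
   on the SERCA half-saturation constant K_serca in [0.1, 1] uM (the symbol
   is ambiguous in the printed model; 0.2 uM is the reference value).
2. Spike-width/temperature fit: the fitted (a, b) with and without the
   recovery recordings (the conditions re-measured after returning to the
   lower temperature).

Usage: python scripts/sensitivity.py [--out report.json]
"""

from __future__ import annotations

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np

from astroca.ode import OdeParams, oscillatory_reference_params, scan_pp
from astroca.spikes import fit_exponential
from astroca.synth import fixture_spike_width_table


def kserca_sensitivity() -> dict:
    out = {}
    for label, base in [
        ("printed", OdeParams()),
        ("oscillatory_reference", oscillatory_reference_params()),
    ]:
        rows = {}
        for ks in (0.1, 0.2, 0.5, 1.0):
            params = dataclasses.replace(base, K_serca=ks)
            if label == "printed":
                grid = np.geomspace(0.01, 1.0, 6)
            else:
                grid = np.linspace(1.2, 3.2, 9)
            table = scan_pp(params, grid, pr_values=[0.03], duration_s=350.0)
            osc = table[table["oscillating"]]
            rows[f"K_serca_{ks}"] = {
                "n_oscillating": int(len(osc)),
                "pp_window": (
                    [float(osc["P_p"].min()), float(osc["P_p"].max())]
                    if len(osc)
                    else None
                ),
                "amplitude_increasing": (
                    bool(np.all(np.diff(osc["amplitude_uM"]) > 0))
                    if len(osc) >= 2
                    else None
                ),
            }
        out[label] = rows
    return out


def recovery_point_sensitivity() -> dict:
    table = fixture_spike_width_table()
    full = fit_exponential(table["temperature_C"], table["mean_width_s"])
    no_rec = table[table["condition"] != "recovery"]
    reduced = fit_exponential(no_rec["temperature_C"], no_rec["mean_width_s"])
    return {
        "all_nine_conditions": {"a_s": full.prefactor, "b_per_degC": full.decay},
        "without_recovery": {
            "a_s": reduced.prefactor,
            "b_per_degC": reduced.decay,
            "n_points": int(len(no_rec)),
        },
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()
    report = {
        "kserca": kserca_sensitivity(),
        "recovery_points": recovery_point_sensitivity(),
    }
    text = json.dumps(report, indent=2)
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(text)
    print(text)


if __name__ == "__main__":
    main()
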