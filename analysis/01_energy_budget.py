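#!/usr/bin/env python
"""Resting and per-event ATP budget of an excitable neuroendocrine cell.

Recomputes the closed-form energy accounting: the pump-leak resting cost for
a typical cell (V = -70 mV, g_in = 1 nS), the sodium-charge cost of one
action potential, the vesicle count and packaging cost behind an
activity-evoked capacitance step, and the per-cell ATP production ceiling
these demands must be compared against.

Writes results/energy_budget.csv.
"""

from pathlib import Path

import pandas as pd

from necell.energetics import (
    IonEnvironment,
    RestingMeasurement,
    ap_charge_cost,
    cells_per_ug_protein,
    production_rate_per_cell,
    resting_atp_rate,
    round_to_sig_figs,
    vesicle_count_from_capacitance,
    vesicle_release_cost,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    env = IonEnvironment()
    typical = RestingMeasurement(V=-70.0, g_in=1.0, cell_id="typical")
    rest = resting_atp_rate(typical, env)
    ap = ap_charge_cost()
    n_ves = vesicle_count_from_capacitance()
    ves_cost = vesicle_release_cost(n_ves)
    ceiling = production_rate_per_cell()

    rows = [
        ("resting ATP rate (V=-70 mV, g_in=1 nS)", rest.atp_rate_molecules,
         "molecules/s/cell"),
        ("  of which g_Na", rest.g_Na, "nS"),
        ("  of which g_K", rest.g_K, "nS"),
        ("  pump current", rest.I_pump, "pA"),
        ("AP sodium-charge cost (20 pF, 60 mV)", ap, "ATP/AP"),
        ("vesicles per 20 fF capacitance step", n_ves, "vesicles"),
        ("vesicle packaging cost (23,400 ATP each)", ves_cost, "ATP/AP"),
        ("cells per ug protein (1 pl, 25% dry)", cells_per_ug_protein(),
         "cells/ug"),
        ("production ceiling (20 pmol/ug/min)", ceiling,
         "molecules/s/cell"),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value", "units"])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "energy_budget.csv", index=False)

    print(df.to_string(index=False))
    print()
    print(f"Resting maintenance alone consumes ~{rest.atp_rate_molecules:.2g}"
          f" ATP/s, i.e. {rest.atp_rate_molecules / ceiling:.0%} of the"
          f" ~{ceiling:.1g} ATP/s production ceiling.")
    print(f"Each action potential adds ~{round_to_sig_figs(ap, 2):.2g} ATP of"
          f" pumping cost plus ~{ves_cost:.2g} ATP of vesicle packaging"
          f" (~{round_to_sig_figs(n_ves, 1):.0f} vesicles).")


if __name__ == "__main__":
    main()
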