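#!/usr/bin/env python
"""Preferential-vulnerability filter on a synthetic CRISPR-screen table.

Simulates a 4,915-gene x 8-cell-line log2-fold-change table with 8 planted
SCLC-preferential vulnerabilities, applies the two-threshold filter
(median SCLC L2FC < -2 and SCLC-minus-other difference < -1.5), and reports
recovery and false positives.

Writes results/screen_hits.csv.
"""

from pathlib import Path

import pandas as pd

from necell.screen import plant_and_recover, select_preferential
from necell.simulate import ScreenSimParams, simulate_screen

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tab, truth = simulate_screen(ScreenSimParams(seed=0))
    call = select_preferential(tab)
    report = plant_and_recover(tab, truth["planted"])

    hits = call.per_gene[call.per_gene["pass"]].sort_values("median_sclc")
    OUT.mkdir(exist_ok=True)
    hits.to_csv(OUT / "screen_hits.csv")

    print(f"Library: {report['n_genes']} genes, planted "
          f"{report['n_planted']} preferential vulnerabilities.")
    print(f"Filter (median SCLC < {call.t_abs}, difference < {call.t_diff}) "
          f"called {report['n_hits']} hits; exact recovery: "
          f"{report['exact_recovery']}; false positives: "
          f"{report['false_positives']}.")
    print("\nHit table:")
    print(hits.to_string())


if __name__ == "__main__":
    main()
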