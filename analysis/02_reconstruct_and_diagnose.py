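"""Pseudo-IPD reconstruction check and empirical hazard diagnostics.

Digitizes each simulated arm, reconstructs individual records with the
interval algorithm, reports the round-trip fidelity (KM discrepancy at the
digitization grid, event-count error), and writes piecewise-exponential and
B-spline-smoothed hazard tables used to judge hazard shapes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from survhta.km import km_estimate, piecewise_hazard, reconstruct_ipd, smoothed_hazard
from survhta.synthetic import digitize, make_reference_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/diagnostics"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ref = make_reference_scenario(args.seed)
    rows = []
    for (arm, ep), data in sorted(ref.datasets.items()):
        curve = digitize(data, grid_points=60, risk_table_interval=0.5)
        rec = reconstruct_ipd(curve)
        km_o, km_r = km_estimate(data), km_estimate(rec)
        disc = float(np.max(np.abs(km_o.sf(curve.times) - km_r.sf(curve.times))))
        rows.append(dict(arm=arm, endpoint=ep, n=data.n,
                         events_true=data.n_events, events_rec=rec.n_events,
                         km_discrepancy=disc))
        piecewise_hazard(data, 0.25).to_frame().to_csv(
            args.out / f"hazard_piecewise_{arm}_{ep}.csv", index=False)
        smoothed_hazard(data, knot_count=4).to_frame().to_csv(
            args.out / f"hazard_smoothed_{arm}_{ep}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "round_trip.csv", index=False)
    print(table.to_string(index=False))
    worst = table["km_discrepancy"].max()
    print(f"\nworst round-trip KM discrepancy at the grid: {worst:.4f} "
          f"(all event counts recovered within "
          f"{(abs(table.events_rec - table.events_true) / table.events_true).max():.1%})")


if __name__ == "__main__":
    main()
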