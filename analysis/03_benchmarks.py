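#!/usr/bin/env python
"""Characterize the numerical core: field solver vs the analytic
monopole, and the axon model's strength-duration/distance behavior.

Writes results/benchmarks.json and prints the table.
"""
import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent.parent / "src"))

from tamflow.axonsim import PointSourceField, build_axon, find_threshold
from tamflow.efield import monopole_benchmark

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = monopole_benchmark()
    print(f"field solver vs -a/r: max relative error "
          f"{100 * res['max_rel_err']:.2f}% over r in [2a, 10a] "
          f"({res['n_cells']} cells, residual {res['residual']:.1e})")

    n = 81
    pts = np.column_stack([np.linspace(0, 40.0, n), np.zeros(n), np.zeros(n)])
    axon = build_axon(pts)
    period = 1000.0 / 135.0

    def pulse(w_us):
        w = w_us / 1000.0
        return lambda t: ((np.asarray(t) % period) < w) * 0.58

    src = PointSourceField([20.0, 1.5, 0.0])
    sd = {w: find_threshold(axon, src, pulse(w))
          for w in (60.0, 90.0, 150.0, 210.0)}
    print("strength-duration (threshold V at 1.5 mm):",
          {w: round(t, 3) for w, t in sd.items()})
    dist = {d: find_threshold(axon, PointSourceField([20.0, d, 0.0]),
                              pulse(90.0)) for d in (1.0, 2.0, 4.0)}
    print("distance-threshold (90 us):",
          {d: round(t, 3) for d, t in dist.items()})

    with open(OUT / "benchmarks.json", "w") as fh:
        json.dump({
            "field_solver_max_rel_err_pct": 100 * res["max_rel_err"],
            "strength_duration_thresholds_V": {str(k): v for k, v in sd.items()},
            "distance_thresholds_V": {str(k): v for k, v in dist.items()},
        }, fh, indent=1)


if __name__ == "__main__":
    main()
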