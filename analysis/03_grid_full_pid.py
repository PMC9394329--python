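"""Full AP-count-grid decomposition.

Generates the deterministic spike-count surface (31 basal x 21 apical input
levels), converts it to the uniform 31 x 21 x 3 distribution over the 651
observed combinations (output categories 0 / 1-2 / 3-4 APs), reports the
classical information measures, and decomposes with all five methods.

Writes results/ap_grid.csv, results/grid_classical_measures.csv and
results/grid_full_pids.csv.
"""

from pathlib import Path

import pandas as pd

from pyrpid import (METHODS, GridGenParams, classical_measures, decompose,
                    gen_ap_grid, grid_to_distribution, normalize_pid)
from pyrpid.io import write_ap_grid

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = gen_ap_grid(GridGenParams())
    write_ap_grid(grid, OUT / "ap_grid.csv")

    dist = grid_to_distribution(grid, (0, 300), (0, 200))
    s = classical_measures(dist)
    measures = pd.DataFrame([{
        "mi_b": s.mi_b, "mi_a": s.mi_a, "cmi_b": s.cmi_b, "cmi_a": s.cmi_a,
        "jmi": s.jmi, "ii": s.ii, "h_y": s.h_y,
    }]).round(4)
    measures.to_csv(OUT / "grid_classical_measures.csv", index=False)

    rows = []
    for method in METHODS:
        r = normalize_pid(decompose(dist, method))
        rows.append({"method": method,
                     "unq_b_pct": round(100 * r.unq_b, 1),
                     "unq_a_pct": round(100 * r.unq_a, 1),
                     "shd_pct": round(100 * r.shd, 1),
                     "syn_pct": round(100 * r.syn, 1)})
    pids = pd.DataFrame(rows)
    pids.to_csv(OUT / "grid_full_pids.csv", index=False)

    print(f"grid: {len(grid.observed)} observed combinations; "
          f"JMI {s.jmi:.2f} bit, I(Y;B)-I(Y;A) = {s.mi_b - s.mi_a:.2f} bit, "
          f"interaction information {s.ii:.2f} bit "
          f"({100 * s.ii / s.jmi:.0f}% of JMI)")
    print(pids.to_string(index=False))
    print(f"wrote ap_grid, grid_classical_measures, grid_full_pids to {OUT}")


if __name__ == "__main__":
    main()
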