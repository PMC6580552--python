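"""Simulate the metabolism of every cell line in the panel.

Seeds the network's gene components from each of the 479 synthetic expression
profiles, propagates to the fixed point, and reports convergence behaviour.
The component x cell-line matrix goes to scratch/ for the screening stages.
"""

import sys
import time
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MODEL_JSON, RESULTS, SIM_MATRIX_TSV, STUDY_SPEC

from metscreen.network import load_model
from metscreen.simulate import simulate_cohort, write_simulation
from metscreen.synth import generate_cohort


def main():
    model = load_model(MODEL_JSON)
    profiles = generate_cohort(model, STUDY_SPEC)
    t0 = time.perf_counter()
    matrix, records = simulate_cohort(model, profiles)
    wall = time.perf_counter() - t0
    n_conv = sum(r.converged for r in records)
    iters = [r.iterations for r in records]
    print(f"simulated {matrix.shape[1]} cell lines x {matrix.shape[0]} components "
          f"in {wall:.1f} s; {n_conv}/{len(records)} converged "
          f"(iterations: min {min(iters)}, max {max(iters)})")

    out = RESULTS / "02_simulation"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "n_cell_lines": len(records),
        "n_converged": n_conv,
        "min_iterations": min(iters),
        "max_iterations": max(iters),
        "wall_time_s": round(wall, 2),
    }]).to_csv(out / "convergence_summary.tsv", sep="\t", index=False)

    write_simulation(matrix, records, SIM_MATRIX_TSV)
    print(f"wrote convergence summary to {out}; matrix to scratch/")


if __name__ == "__main__":
    main()
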