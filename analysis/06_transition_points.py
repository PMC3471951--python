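"""Transition points: the junction of folded/unfolded neighbor fractions.

For each variant, the d at which the fractions of more-folded and more-
unfolded structural neighbors (pairwise Cα RMSD < 3 Å) cross marks the main
unfolding transition. A planted two-basin control with a known crossover at
d* = 0.65 validates the estimator, and the data-driven cutoff calibration
(mean native RMSD at d ≈ 0.5) is reported alongside.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import SEED, VARIANTS, banner, load_summary, results_dir

from unfoldmap import dcoord, metrics, synth, transition


def main() -> None:
    rows = []
    for name in VARIANTS:
        s = load_summary(name)
        rows.append([name, "pipeline", s["d_star"], s["rmsd_cutoff"]])
        banner(name)
        print(f"junction crossing reported at d* = {s['d_star']:.3f} "
              f"(cutoff {s['rmsd_cutoff']} Å)")
    print("\nnote: these variants dwell in discrete state blocks, so the d "
          "density has gaps and the neighbor-fraction curves cross once per "
          "basin — the 'main' junction is under-determined there. The "
          "estimator's intended regime is a continuously populated coordinate "
          "with two overlapping basins; the control below validates it.")

    banner("planted two-basin control (d* = 0.65)")
    native = synth.make_toy_polymer(40, seed=SEED)
    traj, _ = synth.simulate_two_basin_trajectory(
        native, n_frames=1500, d_star=0.65, seed=SEED
    )
    pm = metrics.property_matrix(
        traj, metrics.PropertyConfig(properties=["RMSD", "dRMS", "Rgyr"])
    )
    ds = dcoord.compute_d(dcoord.normalize_properties(pm))
    est = transition.junction_transition(traj, ds, rmsd_cutoff=3.0, grid_size=400)
    calib = transition.rmsd_cutoff_calibration(traj, ds)
    rows.append(["two_basin_control", "planted 0.65", est.d_star, est.rmsd_cutoff])
    print(f"recovered d* = {est.d_star:.3f}; data-driven cutoff calibration "
          f"(mean native RMSD at d ≈ 0.5) = {calib:.2f} Å")

    out = results_dir() / "06_transitions.tsv"
    pd.DataFrame(
        rows, columns=["run", "kind", "d_star", "rmsd_cutoff"]
    ).to_csv(out, sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
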