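"""The d reaction coordinate and its density for each variant.

d is 0 at the native ensemble and 1 at the most unfolded frame; the density
of d along the trajectory shows which regions of the unfolding coordinate are
populated. Different planted state ladders should show up as differently
placed density peaks.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import VARIANTS, banner, ensure_run, results_dir
from scipy.signal import argrelmax


def main() -> None:
    rows = []
    for name in VARIANTS:
        run = ensure_run(name)
        d = pd.read_csv(run / "d.tsv", sep="\t")["d"].to_numpy()
        dens = pd.read_csv(run / "d_density.tsv", sep="\t")
        peaks = dens["d"].to_numpy()[argrelmax(dens["density"].to_numpy(), order=8)[0]]
        rows.append([
            name, d.min(), d.max(), float(np.median(d)), len(peaks),
            ";".join(f"{p:.2f}" for p in peaks),
        ])
        banner(name)
        print(f"d ∈ [{d.min():.3f}, {d.max():.3f}], median {np.median(d):.3f}; "
              f"{len(peaks)} density peaks at d = "
              + ", ".join(f"{p:.2f}" for p in peaks))
    out = results_dir() / "03_d_summary.tsv"
    pd.DataFrame(
        rows,
        columns=["variant", "d_min", "d_max", "d_median", "n_peaks", "peak_positions"],
    ).to_csv(out, sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
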