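"""Information content: which properties discriminate the unfolding states.

Per variant, each property's per-state mean unfolding fractions are scored by
I = log2(k) − H(f_oU); comparing I across variants shows which structural
signals are most re-shaped by the different unfolding pathways (the percent-
contribution table).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import VARIANTS, banner, ensure_run, results_dir

from unfoldmap import info


def main() -> None:
    tables = {}
    for name in VARIANTS:
        run = ensure_run(name)
        df = pd.read_csv(run / "information.tsv", sep="\t")
        tables[name] = df
        top = df.sort_values("I", ascending=False).head(5)
        banner(name)
        print("top-5 properties by information (bits): "
              + ", ".join(f"{r.property}={r.I:.3f}" for r in top.itertuples()))

    names = list(tables)
    merged = tables[names[0]][["property"]].copy()
    for name in names:
        merged[name] = tables[name]["I"].to_numpy()
    out = results_dir() / "05_information.tsv"
    merged.to_csv(out, sep="\t", index=False, float_format="%.6g")

    ics = [
        info.InformationContent(
            property_names=list(t["property"]), information=t["I"].to_numpy(),
            observed_fractions=np.zeros((1, len(t))), n_states=1,
        )
        for t in tables.values()
    ]
    contrib = info.species_contribution(ics, names)
    out2 = results_dir() / "05_contributions.tsv"
    contrib.to_csv(out2, sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {out} and {out2}")


if __name__ == "__main__":
    main()
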