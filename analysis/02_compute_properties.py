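"""Per-frame property matrices: how far each variant's structures swell.

Reads the cached pipeline intermediates and contrasts the native-pool mean of
each raw property with its trajectory extreme — the raw material of the d
coordinate. The unfolded ensembles should show larger surface areas and
radius of gyration and a collapsed native-contact fraction.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import VARIANTS, banner, ensure_run, results_dir


def main() -> None:
    rows = []
    for name in VARIANTS:
        run = ensure_run(name)
        df = pd.read_csv(run / "properties.tsv", sep="\t")
        pool = df.iloc[:10]
        for prop in ("Rgyr", "Qsh", "t.ASA", "dRMS"):
            rows.append([
                name, prop, pool[prop].mean(), df[prop].min(), df[prop].max()
            ])
        banner(name)
        print(f"Rg: native {pool['Rgyr'].mean():.2f} Å → max {df['Rgyr'].max():.2f} Å; "
              f"Qsh: native {pool['Qsh'].mean():.2f} → min {df['Qsh'].min():.2f}; "
              f"t.ASA: native {pool['t.ASA'].mean():.0f} Å² → max {df['t.ASA'].max():.0f} Å²")
    out = results_dir() / "02_property_ranges.tsv"
    pd.DataFrame(
        rows, columns=["variant", "property", "native_pool_mean", "min", "max"]
    ).to_csv(out, sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
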