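"""Shared setup for the numbered analysis scripts.

Three synthetic unfolding runs ("variants") emulate the study design of
comparing one protein prepared in different chemical states: identical native
topology, different unfolding-state ladders. Each variant is analysed by the
full pipeline; intermediates are cached under scratch/analysis/<name> and the
narrative tables of each script go to results/.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

# One native topology (seed below), three unfolding pathways:
#  - apo:   many metastable states, broad ladder
#  - bound: stabilised — dwells long near native, then two unfolded states
#  - acid:  fast, almost two-state unfolding
VARIANTS: dict[str, dict] = {
    "apo": {
        "n_residues": 30,
        "n_frames": 240,
        "states": [(0.15, 1.0, 0.04), (0.25, 1.35, 0.08),
                   (0.30, 1.8, 0.10), (0.30, 2.3, 0.12)],
    },
    "bound": {
        "n_residues": 30,
        "n_frames": 240,
        "states": [(0.40, 1.0, 0.04), (0.30, 1.6, 0.08), (0.30, 2.3, 0.12)],
    },
    "acid": {
        "n_residues": 30,
        "n_frames": 240,
        "states": [(0.25, 1.0, 0.04), (0.75, 2.3, 0.12)],
    },
}

SEED = 2026


def ensure_run(name: str) -> Path:
    """Run the pipeline for a variant unless its summary already exists."""
    from unfoldmap.pipeline import RunConfig, run_pipeline

    outdir = SCRATCH / name
    if not (outdir / "summary.json").exists():
        cfg = RunConfig(synthetic=VARIANTS[name], seed=SEED, outdir=str(outdir))
        run_pipeline(cfg)
    return outdir


def load_summary(name: str) -> dict:
    return json.loads((ensure_run(name) / "summary.json").read_text())


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def banner(text: str) -> None:
    print(f"\n== {text} ==")
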