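"""End-to-end orchestration: simulate → properties → d → states → info → transition.

:func:`run_pipeline` executes every stage on a validated :class:`RunConfig`,
writes all intermediate tables under the output directory and produces a
machine-readable ``summary.json``. The bundle is a pure function of
(config, seed): running the same config twice yields byte-identical output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import dcoord, info, metrics, states, synth, transition
from .errors import ConfigError, PipelineStageError
from .io import (
    SelectionConfig,
    Trajectory,
    read_ss_table,
    read_trajectory,
    write_labels,
    write_table,
    write_trajectory,
)

log = logging.getLogger("unfoldmap")


class SyntheticInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_residues: int = 40
    n_frames: int = 400
    states: list[tuple[float, float, float]] = Field(
        default=[(0.15, 1.0, 0.05), (0.25, 1.3, 0.10), (0.30, 1.7, 0.12), (0.30, 2.2, 0.15)]
    )
    transition_sharpness: float | None = None  # None = hard state blocks


class FileInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paths: list[str]
    native_pool: str | list[int] = "first:10"
    ss_table: Optional[str] = None


class MetricsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    properties: Optional[list[str]] = None  # None = full default list
    min_seq_sep: int = 7
    contact_cutoff: float = 10.0
    qsh_mode: Literal["hard", "soft"] = "hard"
    qsh_beta: float = 5.0
    qsh_lambda: float = 1.2
    probe: float = 1.4
    sasa_points: int = 960
    rg_weighting: Literal["mass", "uniform"] = "mass"
    selections_file: Optional[str] = None


class StatesParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pca_components: int = 2
    rt: float = states.RT_500K
    kde_bandwidth: Optional[float] = None
    nmds_restarts: int = 4
    nmds_max_iter: int = 300
    ap_preference: Optional[float] = None  # None = median similarity
    ap_damping: float = 0.9
    cluster_on: Literal["embedding", "properties"] = "embedding"
    stride: int = 1


class TransitionParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rmsd_cutoff: float = 3.0
    grid_size: Optional[int] = None
    stride: int = 1
    smooth_window: int = 11


class RunConfig(BaseModel):
    """Fully validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    synthetic: Optional[SyntheticInput] = SyntheticInput()
    input: Optional[FileInput] = None
    seed: int = 0
    outdir: str = "unfoldmap_run"
    metrics: MetricsParams = MetricsParams()
    states: StatesParams = StatesParams()
    transition: TransitionParams = TransitionParams()
    d_renormalize: bool = True
    d_bandwidth: Optional[float] = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _round_floats(obj, ndigits: int = 10):
    """Round every float for stable, byte-identical JSON output."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _load_trajectory(config: RunConfig) -> tuple[Trajectory, np.ndarray | None]:
    if config.input is not None:
        ss = read_ss_table(config.input.ss_table) if config.input.ss_table else None
        traj = read_trajectory(
            [Path(p) for p in config.input.paths],
            native_pool=config.input.native_pool,
            ss=ss,
        )
        return traj, None
    syn = config.synthetic or SyntheticInput()
    spec = synth.SyntheticTrajectorySpec(
        n_residues=syn.n_residues,
        n_frames=syn.n_frames,
        states=[tuple(s) for s in syn.states],
        seed=config.seed,
        transition_sharpness=(
            np.inf if syn.transition_sharpness is None else syn.transition_sharpness
        ),
    )
    native = synth.make_toy_polymer(syn.n_residues, seed=config.seed)
    traj, labels = synth.simulate_unfolding_trajectory(native, spec)
    return traj, labels


def run_pipeline(config: RunConfig, write_trajectory_pdb: bool = False) -> dict:
    """Execute all stages; write intermediates + summary.json under ``outdir``.

    Returns the summary dict. A stage failure raises
    :class:`PipelineStageError` naming the stage; outputs written so far are
    preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    stage = "input"
    try:
        traj, planted = _load_trajectory(config)
        if planted is not None:
            write_labels(planted, outdir / "planted_labels.tsv")
        if write_trajectory_pdb:
            write_trajectory(traj, outdir / "trajectory.pdb")
        log.info("input: %d frames, %d atoms, pool=%s",
                 len(traj), traj.frames[0].n_atoms, traj.pool_indices)

        stage = "properties"
        mp = config.metrics
        sel = (
            SelectionConfig.from_json(mp.selections_file)
            if mp.selections_file
            else None
        )
        pconf = metrics.PropertyConfig(
            properties=mp.properties or list(metrics.DEFAULT_PROPERTIES),
            min_seq_sep=mp.min_seq_sep,
            contact_cutoff=mp.contact_cutoff,
            qsh_mode=mp.qsh_mode,
            qsh_beta=mp.qsh_beta,
            qsh_lambda=mp.qsh_lambda,
            probe=mp.probe,
            sasa_points=mp.sasa_points,
            rg_weighting=mp.rg_weighting,
            selections=sel,
        )
        pm = metrics.property_matrix(traj, pconf)
        pm.to_dataframe().to_csv(
            outdir / "properties.tsv", sep="\t", index=False, float_format="%.6g"
        )
        log.info("properties: %d columns", len(pm.property_names))

        stage = "dcoord"
        norm = dcoord.normalize_properties(pm)
        norm.to_dataframe().to_csv(
            outdir / "normalized.tsv", sep="\t", index=False, float_format="%.6g"
        )
        ds = dcoord.compute_d(norm, renormalize=config.d_renormalize)
        write_table(
            [[i, float(a), float(b)] for i, (a, b) in enumerate(zip(ds.d, ds.d_raw))],
            ["frame", "d", "d_raw"],
            outdir / "d.tsv",
        )
        grid, dens = dcoord.d_density(ds, bandwidth=config.d_bandwidth)
        write_table(
            list(zip(grid.tolist(), dens.tolist())),
            ["d", "density"],
            outdir / "d_density.tsv",
        )

        stage = "states"
        sp = config.states
        stride = max(1, sp.stride)
        sub = slice(None, None, stride)
        scores, evr = states.pca(norm, k=sp.pca_components)
        write_table(
            [[i] + list(map(float, row)) for i, row in enumerate(scores)],
            ["frame"] + [f"PC{j+1}" for j in range(scores.shape[1])],
            outdir / "pc_scores.tsv",
        )
        pmf = states.kde2d_pmf(scores[:, :2], bandwidth=sp.kde_bandwidth, rt=sp.rt)
        pd.DataFrame(pmf["pmf"]).to_csv(
            outdir / "pmf.tsv", sep="\t", index=False, header=False,
            float_format="%.6g",
        )
        from scipy.spatial.distance import pdist, squareform

        X = norm.values[sub]
        D = squareform(pdist(X))
        emb, stress = states.nmds(
            D,
            seed=config.seed,
            n_init=sp.nmds_restarts,
            max_iter=sp.nmds_max_iter,
        )
        write_table(
            [[i * stride, float(a), float(b)] for i, (a, b) in enumerate(emb)],
            ["frame", "mds1", "mds2"],
            outdir / "embedding.tsv",
        )
        points = emb if sp.cluster_on == "embedding" else X
        ap = states.affinity_propagation(
            points, preference=sp.ap_preference, damping=sp.ap_damping
        )
        # map strided labels back to the strided frame set only
        d_sub = ds.d[sub]
        norm_sub = dcoord.NormalizedMatrix(
            property_names=norm.property_names,
            values=norm.values[sub],
            native_means=norm.native_means,
            orientation=norm.orientation,
            native_pool=[0],
            dropped=norm.dropped,
            enforce_range=False,
        )
        summary = states.state_summary(ap.labels, norm_sub, d_sub, ap.exemplars)
        exemplar_frames = (
            [int(e) * stride for e in summary.exemplars]
            if summary.exemplars is not None
            else []
        )
        write_labels(summary.labels, outdir / "labels.tsv")
        summary.to_dataframe().to_csv(
            outdir / "state_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        log.info("states: %d clusters, nmds stress=%.4f", summary.n_states, stress)

        stage = "info"
        ic = info.information_content(summary)
        ic.to_dataframe().to_csv(
            outdir / "information.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "transition"
        tp = config.transition
        try:
            est = transition.junction_transition(
                traj,
                ds,
                rmsd_cutoff=tp.rmsd_cutoff,
                grid_size=tp.grid_size,
                stride=tp.stride,
                smooth_window=tp.smooth_window,
            )
            write_table(
                [
                    [float(g), float(f), float(u)]
                    for g, f, u in zip(est.grid, est.folded_curve, est.unfolded_curve)
                ],
                ["d", "folded_fraction", "unfolded_fraction"],
                outdir / "junction_curves.tsv",
            )
            d_star = est.d_star
            n_skipped = est.n_skipped
        except transition.NoTransitionError:
            log.warning("no transition crossing found")
            d_star = None
            n_skipped = None

        stage = "summary"
        top = ic.rank()[:5]
        report = {
            "n_frames": len(traj),
            "n_properties": ds.n_properties,
            "n_states": int(summary.n_states),
            "exemplar_frames": exemplar_frames,
            "state_frame_counts": [int(c) for c in summary.frame_counts],
            "state_mean_d": [float(x) for x in summary.mean_d],
            "pca_explained_variance": [float(x) for x in evr],
            "nmds_stress": float(stress),
            "top_properties_by_information": top,
            "top_information_bits": [
                float(ic.information[ic.property_names.index(t)]) for t in top
            ],
            "d_star": None if d_star is None else float(d_star),
            "rmsd_cutoff": tp.rmsd_cutoff,
            "n_skipped": n_skipped,
            "seed": config.seed,
        }
        (outdir / "summary.json").write_text(
            json.dumps(_round_floats(report), indent=2, sort_keys=True,
                       default=_json_default)
            + "\n"
        )
        return report
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc


def compare_runs(reports: list[dict | str | Path], run_names: list[str] | None = None) -> dict:
    """Side-by-side comparison of ≥2 pipeline reports.

    Accepts summary dicts or paths to ``summary.json`` files whose directories
    also contain ``information.tsv`` and ``d_density.tsv``. Returns a dict
    with a per-run overview table, aligned d-density curves, and per-property
    information-content percentage contributions.
    """
    if len(reports) < 2:
        raise ConfigError("need at least 2 runs to compare")
    loaded = []
    for r in reports:
        if isinstance(r, (str, Path)):
            p = Path(r)
            report = json.loads(p.read_text())
            base = p.parent
        else:
            report = dict(r)
            base = Path(report.get("outdir", "."))
        loaded.append((report, base))
    if run_names is None:
        run_names = [f"run{i}" for i in range(len(loaded))]

    overview = pd.DataFrame(
        {
            "run": run_names,
            "n_states": [r["n_states"] for r, _ in loaded],
            "d_star": [r.get("d_star") for r, _ in loaded],
            "nmds_stress": [r.get("nmds_stress") for r, _ in loaded],
        }
    )
    ics = []
    densities = {}
    for (report, base), name in zip(loaded, run_names):
        info_path = base / "information.tsv"
        if info_path.exists():
            df = pd.read_csv(info_path, sep="\t")
            ics.append((name, df))
        dens_path = base / "d_density.tsv"
        if dens_path.exists():
            densities[name] = pd.read_csv(dens_path, sep="\t")
    out: dict = {"overview": overview, "d_densities": densities}
    if len(ics) == len(loaded):
        names0 = list(ics[0][1]["property"])
        for _, df in ics[1:]:
            if list(df["property"]) != names0:
                raise ConfigError("runs have mismatched property lists")
        ic_objs = []
        for name, df in ics:
            ic_objs.append(
                info.InformationContent(
                    property_names=list(df["property"]),
                    information=df["I"].to_numpy(),
                    observed_fractions=np.zeros((1, len(df))),
                    n_states=1,
                )
            )
        out["contributions"] = info.species_contribution(
            ic_objs, [name for name, _ in ics]
        )
    return out
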