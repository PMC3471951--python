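"""Single-trajectory transition-point estimation (junction criterion).

For a structure x at d_x, consider its structural neighbors — frames within a
pairwise Cα RMSD cutoff (default 3 Å). The fraction of neighbors more folded
(d < d_x) and more unfolded (d > d_x) are complementary curves along d; the d
where they cross is the main transition point of the trajectory, the
single-temperature analogue of the folded/unfolded population balance at the
melting temperature. The 3 Å default can be replaced by a data-driven value:
the mean native-reference RMSD of frames near d = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dcoord import DSeries
from .errors import CalibrationError, ConfigError, NoTransitionError
from .io import Structure, Trajectory
from .metrics import pairwise_rmsd, rmsd_ca


@dataclass
class TransitionEstimate:
    d_star: float  # junction of the smoothed curves
    d_star_raw: float | None  # junction of the unsmoothed curves
    grid: np.ndarray  # evaluated d values (sorted)
    folded_curve: np.ndarray  # smoothed fraction of more-folded neighbors
    unfolded_curve: np.ndarray
    folded_raw: np.ndarray
    unfolded_raw: np.ndarray
    crossings: list[float]  # all smoothed-curve crossings
    rmsd_cutoff: float
    n_skipped: int  # evaluation frames with empty neighborhoods
    interpolated: bool = True


def _coords(trajectory) -> np.ndarray:
    if isinstance(trajectory, Trajectory):
        return trajectory.ca_array()
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigError("expected a Trajectory or an (n, L, 3) coordinate stack")
    return arr


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    window = min(window if window % 2 == 1 else window + 1, 2 * (len(x) // 2) - 1)
    if window <= 1:
        return x.copy()
    half = window // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _find_crossings(grid: np.ndarray, diff: np.ndarray) -> list[tuple[float, int]]:
    """(interpolated d, surrounding sign-run length) for each sign change."""
    sign = np.sign(diff)
    out = []
    nz = np.nonzero(sign)[0]
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            # linear interpolation between the bracketing grid points
            x0, x1 = grid[a], grid[b]
            y0, y1 = diff[a], diff[b]
            d_c = float(x0 - y0 * (x1 - x0) / (y1 - y0))
            run = 0
            i = a
            while i >= 0 and sign[i] in (0, sign[a]):
                run += 1
                i -= 1
            i = b
            while i < len(sign) and sign[i] in (0, sign[b]):
                run += 1
                i += 1
            out.append((d_c, run))
    return out


def junction_transition(
    trajectory,
    dseries: DSeries | np.ndarray,
    rmsd_cutoff: float = 3.0,
    grid_size: int | None = None,
    stride: int = 1,
    smooth_window: int = 11,
    min_unfolded_d: float = 0.5,
) -> TransitionEstimate:
    """Locate the d where folded- and unfolded-neighbor fractions cross.

    Every (strided) frame is an evaluation point x; its neighborhood is all
    other strided frames within ``rmsd_cutoff`` Å pairwise Cα RMSD. Ties
    (d_y = d_x) split evenly between the folded and unfolded counts. The
    fraction-difference curve over the d-sorted evaluation grid is smoothed by
    a running mean of ``smooth_window`` points and the junction located by
    linear interpolation; all crossings are reported, the one with the longest
    surrounding sign-consistent run as the main transition.

    A folded/unfolded transition requires that the unfolded side of the
    coordinate is actually sampled: if the whole trajectory stays below
    ``min_unfolded_d`` (one compact basin), a no-transition error is raised
    rather than reporting the basin's internal median.
    """
    coords = _coords(trajectory)[::stride]
    d = (dseries.d if isinstance(dseries, DSeries) else np.asarray(dseries, float))[
        ::stride
    ]
    n = len(coords)
    if len(d) != n:
        raise ConfigError("d series length must match frame count")
    if n < 50:
        raise ConfigError(f"need at least 50 frames after stride, got {n}")
    if d.max() < min_unfolded_d:
        raise NoTransitionError(
            f"all frames stay below d = {min_unfolded_d} (one compact basin); "
            "no folded/unfolded transition to locate"
        )

    order = np.argsort(d, kind="stable")
    if grid_size is not None and grid_size < n:
        pick = order[np.linspace(0, n - 1, grid_size).round().astype(int)]
    else:
        pick = order

    R = pairwise_rmsd(coords[pick], coords)  # (n_eval, n)
    grid_d = d[pick]

    folded = np.full(len(pick), np.nan)
    unfolded = np.full(len(pick), np.nan)
    n_skipped = 0
    for k, (x, dx) in enumerate(zip(pick, grid_d)):
        mask = R[k] < rmsd_cutoff
        mask[x] = False  # exclude self
        n_nb = int(mask.sum())
        if n_nb == 0:
            n_skipped += 1
            continue
        dn = d[mask]
        below = float(np.sum(dn < dx))
        above = float(np.sum(dn > dx))
        ties = n_nb - below - above
        folded[k] = (below + 0.5 * ties) / n_nb
        unfolded[k] = (above + 0.5 * ties) / n_nb
    if n_skipped:
        warnings.warn(f"{n_skipped} evaluation frames had empty neighborhoods")

    ok = ~np.isnan(folded)
    if ok.sum() < 2:
        raise NoTransitionError("too few frames with non-empty neighborhoods")
    grid_ok = grid_d[ok]
    f_raw = folded[ok]
    u_raw = unfolded[ok]
    diff_raw = f_raw - u_raw
    f_s = _running_mean(f_raw, smooth_window)
    u_s = _running_mean(u_raw, smooth_window)
    diff_s = f_s - u_s

    crossings = _find_crossings(grid_ok, diff_s)
    if not crossings:
        raise NoTransitionError(
            "folded/unfolded neighbor fractions never cross; no transition found"
        )
    crossings.sort(key=lambda c: -c[1])
    d_star = crossings[0][0]
    raw_crossings = _find_crossings(grid_ok, diff_raw)
    d_star_raw = (
        max(raw_crossings, key=lambda c: c[1])[0] if raw_crossings else None
    )
    return TransitionEstimate(
        d_star=d_star,
        d_star_raw=d_star_raw,
        grid=grid_ok,
        folded_curve=f_s,
        unfolded_curve=u_s,
        folded_raw=f_raw,
        unfolded_raw=u_raw,
        crossings=[c[0] for c in crossings],
        rmsd_cutoff=rmsd_cutoff,
        n_skipped=n_skipped,
    )


def rmsd_cutoff_calibration(
    trajectory: Trajectory,
    dseries: DSeries | np.ndarray,
    reference: Structure | None = None,
    window: float = 0.05,
) -> float:
    """Data-driven RMSD cutoff: mean native-reference RMSD at d ≈ 0.5.

    Averages the Cα RMSD to ``reference`` (default: first native-pool frame)
    over frames with |d − 0.5| ≤ ``window``; errors if the window is empty.
    """
    d = dseries.d if isinstance(dseries, DSeries) else np.asarray(dseries, float)
    if reference is None:
        reference = trajectory.frames[trajectory.pool_indices[0]]
    idx = np.nonzero(np.abs(d - 0.5) <= window)[0]
    if len(idx) == 0:
        raise CalibrationError(f"no frames with |d − 0.5| ≤ {window}")
    return float(np.mean([rmsd_ca(trajectory.frames[i], reference) for i in idx]))
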