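"""Synthetic unfolding trajectories with planted ground truth.

Two levels of synthesis are provided, matching the two entry points of the
analysis:

* coordinate level — :func:`make_toy_polymer` builds a compact self-avoiding
  Cα (+ pseudo side chain) chain and :func:`simulate_unfolding_trajectory`
  expands it about its centroid through a sequence of metastable states.
  Expansion breaks long-range contacts, grows the radius of gyration and ASA,
  and melts the planted secondary structure — exactly the signals the property
  metrics consume. No physical dynamics are simulated.

* property level — :func:`simulate_property_trajectory` draws frames directly
  in the normalized [0, 1] property space around planted per-state means, for
  testing the clustering / information-content stages in isolation.

All randomness flows from the spec seed through per-frame
``np.random.default_rng([seed, tag, frame])`` streams, so generating more
frames never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import Structure, Trajectory

CA_CA_DISTANCE = 3.8  # Å, consecutive Cα spacing
MIN_NONLOCAL_DISTANCE = 3.4  # Å, self-avoidance threshold
SIDECHAIN_OFFSET = 1.5  # Å, pseudo side-chain atom distance from Cα

# Residue palette cycled along the toy chain. Chosen so polar and non-polar
# classes and tryptophans all occur; every 10th residue is a TRP.
_PALETTE = ["ALA", "SER", "LEU", "LYS", "VAL", "ASP", "PHE", "THR", "GLY", "TRP"]


@dataclass
class SyntheticTrajectorySpec:
    """Plan for a coordinate-level toy unfolding run.

    ``states`` is an ordered list of (dwell_fraction, expansion_factor,
    noise_sd) tuples: each state occupies ``dwell_fraction`` of the frames,
    scales coordinates about the centroid by ``expansion_factor`` and adds
    isotropic Gaussian noise of ``noise_sd`` Å. ``transition_sharpness``
    controls how abruptly the expansion factor switches between consecutive
    states (larger = sharper; np.inf = hard blocks). ``ss_melt_fractions``
    optionally fixes, per state, the fraction of native helix/strand residues
    converted to coil; by default it scales with the expansion factor.
    """

    n_residues: int = 40
    n_frames: int = 400
    states: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (0.15, 1.00, 0.05),
            (0.25, 1.30, 0.10),
            (0.30, 1.70, 0.12),
            (0.30, 2.20, 0.15),
        ]
    )
    seed: int = 0
    transition_sharpness: float = np.inf
    ss_melt_fractions: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ConfigError("at least one state required")
        dwell = np.array([s[0] for s in self.states], dtype=float)
        if np.any(dwell <= 0) or not np.isclose(dwell.sum(), 1.0):
            raise ConfigError("state dwell fractions must be positive and sum to 1")
        exp = np.array([s[1] for s in self.states], dtype=float)
        if np.any(exp < 1.0) or np.any(np.diff(exp) < 0):
            raise ConfigError("expansion factors must be ≥1 and non-decreasing")
        if np.any(np.array([s[2] for s in self.states]) < 0):
            raise ConfigError("noise sd must be non-negative")
        if self.ss_melt_fractions is not None and len(self.ss_melt_fractions) != len(
            self.states
        ):
            raise ConfigError("ss_melt_fractions length must match states")


@dataclass
class SyntheticPropertySpec:
    """Plan for a property-level run: per-state means in normalized space."""

    state_means: np.ndarray  # (n_states, n_properties), values in [0, 1]
    frames_per_state: int = 150
    noise_sd: float | np.ndarray = 0.05
    seed: int = 0
    property_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.state_means = np.atleast_2d(np.asarray(self.state_means, dtype=float))
        if self.state_means.min() < 0 or self.state_means.max() > 1:
            raise ConfigError("state means must lie in [0, 1]")
        if self.frames_per_state < 2:
            raise ConfigError("need at least 2 frames per state")
        if self.property_names is None:
            self.property_names = [
                f"p{i}" for i in range(self.state_means.shape[1])
            ]
        elif len(self.property_names) != self.state_means.shape[1]:
            raise ConfigError("property_names length must match state_means columns")

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]


def _rng(seed: int, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag), int(index)])


def _has_long_range_contact(ca: np.ndarray, min_sep: int = 7, cutoff: float = 10.0) -> bool:
    n = len(ca)
    for i in range(n):
        d = np.linalg.norm(ca[i + min_sep :] - ca[i], axis=1)
        if np.any(d < cutoff):
            return True
    return False


def _grow_chain(n_residues: int, rng: np.random.Generator) -> np.ndarray | None:
    """Self-avoiding walk biased back toward the origin to stay compact."""
    radius = 2.8 * n_residues ** (1 / 3) + 2.0
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        placed = False
        for _ in range(60):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            # pull toward origin when drifting out of the compact sphere
            pos = coords[i - 1]
            if np.linalg.norm(pos) > 0.7 * radius:
                inward = -pos / np.linalg.norm(pos)
                step = step + 1.5 * inward
                step /= np.linalg.norm(step)
            cand = pos + CA_CA_DISTANCE * step
            if np.linalg.norm(cand) > radius:
                continue
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if d.min() < MIN_NONLOCAL_DISTANCE:
                    continue
            coords[i] = cand
            placed = True
            break
        if not placed:
            return None
    return coords


def _planted_ss(n_residues: int) -> str:
    """Planted native secondary structure: a helix block, a strand block, coil."""
    n_h = n_residues // 3
    n_e = n_residues // 3
    return "H" * n_h + "E" * n_e + "C" * (n_residues - n_h - n_e)


def make_toy_polymer(n_residues: int, seed: int = 0) -> Structure:
    """Build a compact self-avoiding Cα + pseudo-side-chain chain.

    Guarantees at least one long-range contact (sequence separation ≥ 7,
    distance < 10 Å); generation is bit-reproducible for a given seed.
    """
    if n_residues < 8:
        raise ConfigError(
            f"n_residues={n_residues} cannot admit a long-range (sep ≥ 7) contact"
        )
    ca = None
    for attempt in range(200):
        rng = _rng(seed, 1, attempt)
        cand = _grow_chain(n_residues, rng)
        if cand is not None and _has_long_range_contact(cand):
            ca = cand
            break
    if ca is None:
        raise ConfigError(
            f"could not grow a compact chain with a long-range contact "
            f"(n_residues={n_residues}, seed={seed})"
        )
    ca = ca - ca.mean(axis=0)

    # pseudo side-chain atom: radially outward from the chain centroid
    out = ca.copy()
    norms = np.linalg.norm(out, axis=1)
    norms[norms < 1e-9] = 1.0
    cb = ca + SIDECHAIN_OFFSET * out / norms[:, None]

    coords = np.empty((2 * n_residues, 3))
    coords[0::2] = ca
    coords[1::2] = cb
    res_names = [_PALETTE[i % len(_PALETTE)] for i in range(n_residues)]
    # alternating small formal charges on side chains; net neutral for even n
    charges = np.zeros(2 * n_residues)
    charges[1::2] = np.where(np.arange(n_residues) % 2 == 0, 0.25, -0.25)
    return Structure(
        atom_name=np.array(["CA", "CB"] * n_residues),
        element=np.array(["C", "C"] * n_residues),
        res_id=np.repeat(np.arange(1, n_residues + 1), 2),
        res_name=np.repeat(res_names, 2),
        chain_id=np.array(["A"] * (2 * n_residues)),
        coord=coords,
        hetero=np.zeros(2 * n_residues, dtype=bool),
        charge=charges,
        ss=_planted_ss(n_residues),
    )


def _melt_ss(native_ss: str, fraction: float) -> str:
    """Convert the first ``fraction`` of native H and of native E positions to C."""
    ss = list(native_ss)
    for letter in "HE":
        idx = [i for i, c in enumerate(native_ss) if c == letter]
        n_melt = int(round(fraction * len(idx)))
        for i in idx[:n_melt]:
            ss[i] = "C"
    return "".join(ss)


def _expansion_profile(spec: SyntheticTrajectorySpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame expansion factor and planted state labels."""
    dwell = np.array([s[0] for s in spec.states])
    counts = np.floor(dwell * spec.n_frames).astype(int)
    counts[-1] += spec.n_frames - counts.sum()
    if np.any(counts < 1):
        raise ConfigError("a state received zero frames; increase n_frames")
    labels = np.repeat(np.arange(len(spec.states)), counts)
    factors = np.array([s[1] for s in spec.states])
    s = factors[labels].astype(float)
    if np.isfinite(spec.transition_sharpness) and len(spec.states) > 1:
        # logistic blending across each boundary
        t = np.arange(spec.n_frames, dtype=float)
        s = np.full(spec.n_frames, factors[0], dtype=float)
        bounds = np.cumsum(counts)[:-1]
        width = spec.n_frames / (spec.transition_sharpness * len(spec.states))
        for b, (f0, f1) in zip(bounds, zip(factors[:-1], factors[1:])):
            s = s + (f1 - f0) / (1.0 + np.exp(-(t - b) / max(width, 1e-9)))
    return s, labels


def simulate_unfolding_trajectory(
    native: Structure, spec: SyntheticTrajectorySpec
) -> tuple[Trajectory, np.ndarray]:
    """Expand ``native`` about its centroid through the spec's states.

    Returns the trajectory (native pool = first frames of the first state)
    and the planted per-frame state labels.
    """
    s, labels = _expansion_profile(spec)
    centroid = native.coord.mean(axis=0)
    factors = np.array([st[1] for st in spec.states])
    max_exp = factors.max()
    if spec.ss_melt_fractions is not None:
        melt = np.asarray(spec.ss_melt_fractions, dtype=float)
    elif max_exp > 1.0:
        melt = (factors - 1.0) / (max_exp - 1.0)
    else:
        melt = np.zeros(len(spec.states))
    state_ss = [_melt_ss(native.ss, m) if native.ss else None for m in melt]

    frames = []
    for i in range(spec.n_frames):
        noise_sd = spec.states[labels[i]][2]
        if s[i] == 1.0:
            coord = native.coord.copy()
        else:
            coord = centroid + s[i] * (native.coord - centroid)
        if noise_sd > 0:
            coord = coord + _rng(spec.seed, 2, i).normal(
                scale=noise_sd, size=coord.shape
            )
        frames.append(native.with_coords(coord, ss=state_ss[labels[i]]))
    n_first = int(np.sum(labels == 0))
    pool = set(range(min(10, n_first)))
    times = np.linspace(0.0, 25.0, spec.n_frames)
    return Trajectory(frames=frames, native_pool=pool, times=times), labels


def simulate_property_trajectory(
    spec: SyntheticPropertySpec,
) -> tuple["NormalizedMatrix", np.ndarray]:
    """Draw frames in normalized property space around planted state means.

    Frames are ordered by state (contiguous blocks); values are state mean +
    Gaussian noise truncated to [0, 1]. The first state acts as native pool.
    """
    from .dcoord import NormalizedMatrix  # local import: avoid cycle

    k, p = spec.state_means.shape
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (p,))
    rows = []
    for state in range(k):
        rng = _rng(spec.seed, 3, state)
        block = spec.state_means[state] + rng.normal(size=(spec.frames_per_state, p)) * sd
        rows.append(np.clip(block, 0.0, 1.0))
    values = np.vstack(rows)
    labels = np.repeat(np.arange(k), spec.frames_per_state)
    pool = list(range(spec.frames_per_state))
    native_means = values[pool].mean(axis=0)
    norm = NormalizedMatrix(
        property_names=list(spec.property_names),
        values=values,
        native_means=native_means,
        orientation=["increase"] * p,
        native_pool=pool,
        enforce_range=False,
    )
    return norm, labels


def simulate_two_basin_trajectory(
    native: Structure,
    n_frames: int = 2000,
    d_star: float = 0.65,
    basin_offset: float = 0.20,
    basin_sd: float = 0.15,
    noise_sd: float = 0.03,
    rmsd_at_half: float = 3.0,
    n_native_frames: int = 10,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Two-basin trajectory whose folded/unfolded populations cross at ``d_star``.

    Planted per-frame unfolding coordinates are drawn from an equal-weight
    two-Gaussian mixture symmetric about ``d_star`` (components at
    d_star ± basin_offset, sd ``basin_sd``), perturbed by ``noise_sd`` and
    clipped to [0, 1], then realised geometrically as centroid-anchored
    expansion. The expansion range is set so that the Cα RMSD from the native
    structure grows to ``rmsd_at_half`` Å at d = 0.5 — the same calibration
    that motivates the default 3 Å neighbor cutoff of the junction criterion.
    A pool of ``n_native_frames`` native frames is prepended as the reference
    ensemble.

    Returns the trajectory and the planted d values (pool frames have d = 0).
    """
    ca = native.ca_coords
    rms_ca = float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))
    max_expansion = 1.0 + 2.0 * rmsd_at_half / rms_ca
    rng = _rng(seed, 4)
    comp = rng.integers(0, 2, size=n_frames)
    centers = np.where(comp == 0, d_star - basin_offset, d_star + basin_offset)
    d = centers + rng.normal(scale=basin_sd, size=n_frames)
    d = d + rng.normal(scale=noise_sd, size=n_frames)
    d = np.clip(d, 0.0, 1.0)
    d = np.concatenate([np.zeros(n_native_frames), d])

    centroid = native.coord.mean(axis=0)
    frames = []
    for i, di in enumerate(d):
        s = 1.0 + di * (max_expansion - 1.0)
        coord = centroid + s * (native.coord - centroid)
        coord = coord + _rng(seed, 5, i).normal(scale=0.05, size=coord.shape)
        frames.append(native.with_coords(coord))
    traj = Trajectory(frames=frames, native_pool=set(range(n_native_frames)))
    return traj, d
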