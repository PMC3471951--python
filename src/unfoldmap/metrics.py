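"""Per-frame structural properties feeding the composite reaction coordinate.

Implements the full property vector: the long-range native-contact fraction
Qsh, optimal-superposition Cα RMSD, the superposition-free distance-matrix
deviation dRMS, radius of gyration, Shrake–Rupley solvent-accessible surface
area with total/side-chain and polar/non-polar splits, secondary-structure
melting percentages, dipole moment, and the ASA-based heat-capacity change
ΔCp. :func:`property_matrix` assembles the frames × properties table.

Cα-based metrics (Qsh, RMSD, dRMS) are protein-only; hetero atoms participate
in ASA and mass-weighted Rg as generic spheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .errors import ConfigError, ShapeError, TopologyError, UndefinedMetricError
from .io import BACKBONE_ATOMS, SelectionConfig, Structure, Trajectory

E_ANGSTROM_TO_DEBYE = 4.80320  # 1 e·Å in Debye

#: Bondi-like van der Waals radii (Å); FE is a generic ion sphere.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73,
}

DEFAULT_ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}

#: Default polar residue classes; everything else (incl. hetero residues)
#: counts as non-polar. Overridable wherever it is consumed.
DEFAULT_POLAR_RESIDUES = frozenset({
    "ASP", "GLU", "LYS", "ARG", "HIS", "ASN", "GLN",
    "SER", "THR", "TYR", "CYS", "TRP",
})

#: ΔCp regression coefficients on buried-area changes, cal mol⁻¹ K⁻¹ Å⁻²
#: (Myers, Pace & Scholtz 1995): ΔCp = 0.28·ΔASA_np − 0.09·ΔASA_p.
DEFAULT_DCP_COEFFS = (0.28, -0.09)  # (a_np, a_p)


# ---------------------------------------------------------------------------
# Native contacts / Qsh
# ---------------------------------------------------------------------------

@dataclass
class ContactSet:
    """Long-range native Cα contacts: residue pairs and native distances."""

    pairs: np.ndarray  # (n, 2) indices into the Cα ordering, i < j
    native_distances: np.ndarray  # Å
    min_seq_sep: int
    cutoff: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.native_distances = np.asarray(self.native_distances, dtype=float)
        if len(self.pairs) != len(self.native_distances):
            raise ShapeError("pairs and native_distances length mismatch")
        if len(self.pairs) and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ShapeError("contact pairs must have i < j")

    @property
    def n_native(self) -> int:
        return len(self.pairs)


def native_contacts(
    native: Structure, min_seq_sep: int = 7, cutoff: float = 10.0
) -> ContactSet:
    """All Cα pairs with sequence separation ≥ ``min_seq_sep`` and native
    distance < ``cutoff`` Å."""
    ca = native.ca_coords
    n = len(ca)
    if n < min_seq_sep + 1:
        warnings.warn(
            f"only {n} residues: no pair can reach separation {min_seq_sep}; "
            "contact set is empty"
        )
        return ContactSet(np.empty((0, 2), int), np.empty(0), min_seq_sep, cutoff)
    ii, jj = np.triu_indices(n, k=min_seq_sep)
    d = np.linalg.norm(ca[ii] - ca[jj], axis=1)
    keep = d < cutoff
    return ContactSet(
        pairs=np.column_stack([ii[keep], jj[keep]]),
        native_distances=d[keep],
        min_seq_sep=min_seq_sep,
        cutoff=cutoff,
    )


def compute_qsh(
    frame: Structure,
    contacts: ContactSet,
    mode: str = "hard",
    beta: float = 5.0,
    lam: float = 1.2,
) -> float:
    """Fraction of long-range native contacts retained in ``frame``.

    ``mode="hard"`` counts native pairs closer than the contact cutoff;
    ``mode="soft"`` averages the logistic 1/(1+exp(β(d_ij − λ·d_ij^native))).
    """
    if contacts.n_native == 0:
        raise UndefinedMetricError("empty contact set: Qsh undefined")
    ca = frame.ca_coords
    d = np.linalg.norm(ca[contacts.pairs[:, 0]] - ca[contacts.pairs[:, 1]], axis=1)
    if mode == "hard":
        return float(np.mean(d < contacts.cutoff))
    if mode == "soft":
        x = np.clip(beta * (d - lam * contacts.native_distances), -500, 500)
        return float(np.mean(1.0 / (1.0 + np.exp(x))))
    raise ConfigError(f"unknown Qsh mode {mode!r}")


# ---------------------------------------------------------------------------
# RMSD / dRMS / Rg
# ---------------------------------------------------------------------------

def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares proper-rotation RMSD of two centered point sets."""
    rot, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def rmsd_ca(frame: Structure, reference: Structure) -> float:
    """Optimal-superposition (proper rotation + translation) Cα RMSD in Å."""
    a = frame.ca_coords
    b = reference.ca_coords
    if a.shape != b.shape:
        raise TopologyError(f"Cα count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return _kabsch_rmsd(a - a.mean(axis=0), b - b.mean(axis=0))


def pairwise_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, chunk: int = 64
) -> np.ndarray:
    """Pairwise optimal-superposition RMSD between two stacks of Cα frames.

    ``coords_a``: (m, L, 3), ``coords_b``: (n, L, 3); returns (m, n) Å.
    Batched Kabsch via 3×3 SVDs with proper-rotation sign correction.
    """
    A = coords_a - coords_a.mean(axis=1, keepdims=True)
    B = coords_b - coords_b.mean(axis=1, keepdims=True)
    L = A.shape[1]
    ssq_a = np.einsum("ilk,ilk->i", A, A)
    ssq_b = np.einsum("jlk,jlk->j", B, B)
    out = np.empty((A.shape[0], B.shape[0]))
    for start in range(0, A.shape[0], chunk):
        Ac = A[start : start + chunk]
        # cross-covariance matrices for every (a, b) pair in the chunk
        C = np.einsum("ilk,jlm->ijkm", Ac, B)
        U, S, Vt = np.linalg.svd(C)
        sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
        S[..., -1] *= sign
        tr = S.sum(axis=-1)
        msd = (ssq_a[start : start + chunk, None] + ssq_b[None, :] - 2.0 * tr) / L
        out[start : start + chunk] = np.sqrt(np.maximum(msd, 0.0))
    return out


def drms(frame: Structure, reference: Structure) -> float:
    """RMS deviation between the Cα–Cα distance matrices (superposition-free)."""
    a = frame.ca_coords
    b = reference.ca_coords
    if a.shape != b.shape:
        raise TopologyError(f"Cα count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if len(a) < 2:
        raise UndefinedMetricError("dRMS undefined for fewer than 2 residues")
    return float(np.sqrt(np.mean((pdist(a) - pdist(b)) ** 2)))


def radius_of_gyration(structure: Structure, weighting: str = "mass") -> float:
    """Radius of gyration about the center of mass (or geometric center)."""
    coord = structure.coord
    if weighting == "mass":
        w = np.array(
            [DEFAULT_ATOMIC_MASSES.get(e.upper(), 12.011) for e in structure.element]
        )
    elif weighting == "uniform":
        w = np.ones(len(coord))
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")
    center = np.average(coord, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coord - center) ** 2, axis=1), weights=w)))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def atom_radii(
    structure: Structure,
    radii_table: Mapping[str, float] | None = None,
    default_radius: float | None = None,
) -> np.ndarray:
    """Per-atom van der Waals radii: explicit column, then table, then default."""
    table = dict(DEFAULT_VDW_RADII)
    if radii_table:
        table.update({k.upper(): float(v) for k, v in radii_table.items()})
    if structure.radius is not None:
        return np.asarray(structure.radius, dtype=float)
    radii = np.empty(structure.n_atoms)
    for i, el in enumerate(structure.element):
        r = table.get(str(el).upper())
        if r is None:
            if default_radius is None:
                raise ConfigError(
                    f"no van der Waals radius for element {el!r} and no default"
                )
            r = default_radius
        radii[i] = r
    return radii


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
    default_radius: float | None = None,
) -> np.ndarray:
    """Shrake–Rupley per-atom solvent-accessible surface areas (Å²).

    Deterministic for fixed ``n_points``: test points come from a fixed
    golden-spiral construction, not random sampling.
    """
    radii = atom_radii(structure, radii_table, default_radius) + probe
    coord = structure.coord
    n = len(coord)
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coord)
    max_r = radii.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coord[i] + radii[i] * sphere
        neighbors = tree.query_ball_point(coord[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            d = cdist(pts, coord[neighbors])
            buried = (d < radii[neighbors]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def asa_aggregates(
    per_atom_areas: np.ndarray,
    structure: Structure,
    selections: SelectionConfig | None = None,
    polar_residues: frozenset[str] | set[str] = DEFAULT_POLAR_RESIDUES,
) -> dict[str, float]:
    """Sum per-atom areas into the named ASA properties.

    Returns total (t.ASA), side-chain (s.ASA), polar/non-polar splits of each
    (t.p/t.np/s.p/s.np), all-tryptophan (W.ASA), per-tryptophan side-chain
    columns (s.W<resid>.ASA) and one column per named selection. Splits are
    exact partitions: t.ASA = t.p.ASA + t.np.ASA.
    """
    areas = np.asarray(per_atom_areas, dtype=float)
    if len(areas) != structure.n_atoms:
        raise ShapeError("per-atom areas length != atom count")
    sidechain = ~np.isin(structure.atom_name, list(BACKBONE_ATOMS))
    polar = np.isin(structure.res_name, list(polar_residues))
    trp = structure.res_name == "TRP"

    out: dict[str, float] = {
        "t.ASA": float(areas.sum()),
        "s.ASA": float(areas[sidechain].sum()),
        "t.p.ASA": float(areas[polar].sum()),
        "t.np.ASA": float(areas[~polar].sum()),
        "s.p.ASA": float(areas[sidechain & polar].sum()),
        "s.np.ASA": float(areas[sidechain & ~polar].sum()),
        "W.ASA": float(areas[trp].sum()),
    }
    for rid in np.unique(structure.res_id[trp]):
        mask = trp & (structure.res_id == rid) & sidechain
        out[f"s.W{int(rid)}.ASA"] = float(areas[mask].sum())
    if selections is not None:
        selections.validate_against(structure)
        for name, resids in selections.selections.items():
            mask = np.isin(structure.res_id, list(resids))
            if selections.mode(name) == "sidechain":
                mask = mask & sidechain
            out[name] = float(areas[mask].sum())
    return out


# ---------------------------------------------------------------------------
# Secondary-structure melting, dipole, ΔCp
# ---------------------------------------------------------------------------

def ss_melting(frame_ss: str, native_ss: str) -> tuple[float, float, float]:
    """Percent of native helix melted (l.H), strand melted (l.E), and
    newly appeared coil (l.C); negatives clamp to 0."""
    if len(frame_ss) != len(native_ss):
        raise ShapeError("ss strings differ in length")
    for s in (frame_ss, native_ss):
        if set(s) - set("HEC"):
            raise ConfigError(f"ss string has letters outside H/E/C: {s!r}")
    L = len(native_ss)
    out = []
    for letter in "HE":
        n_nat = native_ss.count(letter)
        n_frm = frame_ss.count(letter)
        if n_nat == 0:
            warnings.warn(f"native has no {letter}; melting percent set to 0")
            out.append(0.0)
        else:
            out.append(100.0 * max(n_nat - n_frm, 0) / n_nat)
    c_nat = native_ss.count("C")
    c_frm = frame_ss.count("C")
    denom = L - c_nat
    if denom == 0:
        warnings.warn("native is all-coil; appeared-coil percent set to 0")
        out.append(0.0)
    else:
        out.append(100.0 * max(c_frm - c_nat, 0) / denom)
    return tuple(out)  # type: ignore[return-value]


def dipole_moment(structure: Structure, charges: np.ndarray | None = None) -> float:
    """|Σ qᵢ rᵢ| in Debye, about the geometric center for net-neutral systems
    and about the |q|-weighted charge center otherwise."""
    q = charges if charges is not None else structure.charge
    if q is None:
        raise ConfigError("dipole moment requires per-atom charges")
    q = np.asarray(q, dtype=float)
    if len(q) != structure.n_atoms:
        raise ShapeError("charge array length != atom count")
    coord = structure.coord
    net = q.sum()
    if abs(net) < 1e-9:
        origin = coord.mean(axis=0)
    else:
        w = np.abs(q)
        origin = np.average(coord, axis=0, weights=w) if w.sum() > 0 else coord.mean(axis=0)
    mu = (q[:, None] * (coord - origin)).sum(axis=0)
    return float(np.linalg.norm(mu) * E_ANGSTROM_TO_DEBYE)


def delta_cp(
    dasa_polar: float,
    dasa_apolar: float,
    coeffs: tuple[float, float] = DEFAULT_DCP_COEFFS,
) -> float:
    """Heat-capacity change from ASA changes: ΔCp = a_np·ΔASA_np + a_p·ΔASA_p.

    Default coefficients are the Myers–Pace–Scholtz regression values in
    cal mol⁻¹ K⁻¹ Å⁻², so the result is in cal mol⁻¹ K⁻¹.
    """
    a_np, a_p = coeffs
    return a_np * dasa_apolar + a_p * dasa_polar


# ---------------------------------------------------------------------------
# Property matrix
# ---------------------------------------------------------------------------

GEOMETRIC_PROPERTIES = ["Qsh", "RMSD", "dRMS", "Rgyr"]
ASA_PROPERTIES = ["t.ASA", "s.ASA", "t.p.ASA", "t.np.ASA", "s.p.ASA", "s.np.ASA", "W.ASA"]
SS_PROPERTIES = ["l.H", "l.E", "l.C"]

DEFAULT_PROPERTIES = ASA_PROPERTIES + ["per_trp"] + GEOMETRIC_PROPERTIES + [
    "Dpm", "dCp"
] + SS_PROPERTIES


@dataclass
class PropertyConfig:
    """What to compute and with which parameters."""

    properties: list[str] = field(default_factory=lambda: list(DEFAULT_PROPERTIES))
    min_seq_sep: int = 7
    contact_cutoff: float = 10.0
    qsh_mode: str = "hard"
    qsh_beta: float = 5.0
    qsh_lambda: float = 1.2
    probe: float = 1.4
    sasa_points: int = 960
    rg_weighting: str = "mass"
    selections: SelectionConfig | None = None
    polar_residues: frozenset[str] = DEFAULT_POLAR_RESIDUES
    dcp_coeffs: tuple[float, float] = DEFAULT_DCP_COEFFS
    radii_table: dict[str, float] | None = None
    default_radius: float | None = None


@dataclass
class PropertyMatrix:
    """Frames × named-properties table of raw values."""

    property_names: list[str]
    values: np.ndarray  # (n_frames, n_properties)
    native_pool: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.property_names):
            raise ShapeError("values shape does not match property_names")
        if np.any(~np.isfinite(self.values)):
            raise ShapeError("property matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.property_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.property_names)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df


def _needs_asa(props: Sequence[str]) -> bool:
    return any(
        p in ASA_PROPERTIES or p == "per_trp" or p == "dCp" or p.startswith("s.W")
        for p in props
    )


def property_matrix(
    trajectory: Trajectory,
    config: PropertyConfig | None = None,
    reference: Structure | None = None,
) -> PropertyMatrix:
    """Compute the configured raw properties for every frame.

    RMSD/dRMS/Qsh are taken against ``reference`` (default: the first
    native-pool frame, standing in for the crystal structure). ΔCp is
    relative to the native-pool mean polar/apolar ASA.
    """
    config = config or PropertyConfig()
    if reference is None:
        reference = trajectory.frames[trajectory.pool_indices[0]]
    props = list(config.properties)

    contacts = None
    if "Qsh" in props:
        contacts = native_contacts(reference, config.min_seq_sep, config.contact_cutoff)
    want_ss = any(p in SS_PROPERTIES for p in props)
    if want_ss:
        if reference.ss is None or any(f.ss is None for f in trajectory.frames):
            raise ConfigError(
                "property l.H/l.E/l.C requested but ss strings are missing"
            )
    want_asa = _needs_asa(props)
    want_dpm = "Dpm" in props
    if want_dpm and trajectory.frames[0].charge is None:
        raise ConfigError("property Dpm requested but per-atom charges are missing")
    if config.selections is not None:
        config.selections.validate_against(trajectory.frames[0])

    rows: list[dict[str, float]] = []
    for idx, frame in enumerate(trajectory.frames):
        row: dict[str, float] = {}
        try:
            if want_asa:
                areas = sasa(
                    frame,
                    probe=config.probe,
                    n_points=config.sasa_points,
                    radii_table=config.radii_table,
                    default_radius=config.default_radius,
                )
                row.update(
                    asa_aggregates(
                        areas, frame, config.selections, config.polar_residues
                    )
                )
            if "Qsh" in props:
                row["Qsh"] = compute_qsh(
                    frame, contacts, config.qsh_mode, config.qsh_beta, config.qsh_lambda
                )
            if "RMSD" in props:
                row["RMSD"] = rmsd_ca(frame, reference)
            if "dRMS" in props:
                row["dRMS"] = drms(frame, reference)
            if "Rgyr" in props:
                row["Rgyr"] = radius_of_gyration(frame, config.rg_weighting)
            if want_dpm:
                row["Dpm"] = dipole_moment(frame)
            if want_ss:
                lh, le, lc = ss_melting(frame.ss, reference.ss)
                row.update({"l.H": lh, "l.E": le, "l.C": lc})
        except Exception as exc:
            raise type(exc)(f"frame {idx}: {exc}") from exc
        rows.append(row)

    # expand 'per_trp' and selection names into the realised column list
    names: list[str] = []
    for p in props:
        if p == "per_trp":
            names.extend(sorted(k for k in rows[0] if k.startswith("s.W")))
        elif p == "dCp":
            names.append("dCp")
        elif p in rows[0] or p == "dCp":
            names.append(p)
        elif config.selections is not None and p in config.selections.selections:
            names.append(p)
        else:
            if p not in rows[0]:
                raise ConfigError(f"property {p!r} was not produced")
    if config.selections is not None:
        for sel in config.selections.selections:
            if sel not in names:
                names.append(sel)

    if "dCp" in names:
        pol = np.array([r["t.p.ASA"] for r in rows])
        apol = np.array([r["t.np.ASA"] for r in rows])
        pool = trajectory.pool_indices
        pol0, apol0 = pol[pool].mean(), apol[pool].mean()
        for r, p_i, a_i in zip(rows, pol, apol):
            r["dCp"] = delta_cp(p_i - pol0, a_i - apol0, config.dcp_coeffs)

    values = np.array([[row[name] for name in names] for row in rows])
    return PropertyMatrix(
        property_names=names, values=values, native_pool=trajectory.pool_indices
    )
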