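"""Structure / trajectory / table I/O.

All downstream modules consume only the domain types defined here:
:class:`Structure` (one conformation), :class:`Trajectory` (an ordered stack
of conformations sharing a topology, with a designated native pool) and
:class:`SelectionConfig` (named residue selections such as binding-site
regions). PDB reading and writing is delegated to biotite; result tables are
tab-separated text written through pandas.

Conventions: residue indices are 1-based (PDB convention), frame indices are
0-based everywhere. Coordinates are in Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, PDBParseError, ShapeError, TopologyError

SS_ALPHABET = frozenset("HEC")

#: Backbone atom names used for total vs side-chain splits.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Structure:
    """A single conformation: parallel per-atom arrays plus optional extras.

    ``res_id`` is 1-based and non-decreasing within each chain. ``charge``
    (elementary charges) and ``radius`` (Å) are optional per-atom columns;
    ``ss`` is an optional per-residue secondary-structure string over
    {H, E, C} covering the protein (non-hetero) residues.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    hetero: np.ndarray
    charge: np.ndarray | None = None
    radius: np.ndarray | None = None
    ss: str | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ShapeError(f"coord must be (n_atoms, 3), got {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise PDBParseError("non-finite coordinates in structure")
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id", "hetero"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.n_atoms:
                raise ShapeError(f"{name} length {arr.shape[0]} != n_atoms {self.n_atoms}")
            setattr(self, name, arr)
        # residue ids non-decreasing within each chain
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            if np.any(np.diff(rid.astype(int)) < 0):
                raise PDBParseError(f"residue indices decrease within chain {ch!r}")
        if self.ss is not None:
            if set(self.ss) - SS_ALPHABET:
                raise PDBParseError(f"ss string has letters outside H/E/C: {self.ss!r}")
            if len(self.ss) != self.n_residues:
                raise ShapeError(
                    f"ss length {len(self.ss)} != residue count {self.n_residues}"
                )

    @property
    def n_atoms(self) -> int:
        return self.coord.shape[0]

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.hetero.astype(bool)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique (chain, res_id) protein residues in order of appearance → res_id."""
        mask = self.protein_mask
        ids = self.res_id[mask]
        # preserve order of first appearance
        _, first = np.unique(ids, return_index=True)
        return ids[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def ca_mask(self) -> np.ndarray:
        """Protein Cα atoms; hetero atoms never qualify."""
        return (self.atom_name == "CA") & self.protein_mask

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coord[self.ca_mask]

    def with_coords(self, coord: np.ndarray, ss: str | None = None) -> "Structure":
        """Copy sharing topology arrays, with new coordinates (and optionally ss)."""
        return Structure(
            atom_name=self.atom_name,
            element=self.element,
            res_id=self.res_id,
            res_name=self.res_name,
            chain_id=self.chain_id,
            coord=np.asarray(coord, dtype=float),
            hetero=self.hetero,
            charge=self.charge,
            radius=self.radius,
            ss=ss if ss is not None else self.ss,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, plus the native reference pool."""

    frames: list[Structure]
    native_pool: set[int]
    times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError("trajectory has no frames")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != ref.n_atoms:
                raise TopologyError(
                    f"frame {i} has {fr.n_atoms} atoms, expected {ref.n_atoms}"
                )
            if not np.array_equal(fr.atom_name, ref.atom_name):
                raise TopologyError(f"frame {i} atom ordering differs from frame 0")
        self.native_pool = set(int(i) for i in self.native_pool)
        if not self.native_pool:
            raise ConfigError("native pool is empty")
        if not self.native_pool <= set(range(len(self.frames))):
            raise ConfigError("native pool contains out-of-range frame indices")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ShapeError("times length != frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pool_indices(self) -> list[int]:
        return sorted(self.native_pool)

    def ca_array(self) -> np.ndarray:
        """(n_frames, n_ca, 3) stack of protein Cα coordinates."""
        return np.stack([f.ca_coords for f in self.frames])


@dataclass
class SelectionConfig:
    """Named residue-index selections with an ASA aggregation mode each.

    ``selections`` maps a name (e.g. ``"active_site_lumen"``) to 1-based
    residue indices; ``modes`` maps the same name to ``"total"`` or
    ``"sidechain"`` (default total).
    """

    selections: dict[str, list[int]] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mode in self.modes.items():
            if mode not in ("total", "sidechain"):
                raise ConfigError(f"selection {name!r}: unknown mode {mode!r}")

    def mode(self, name: str) -> str:
        return self.modes.get(name, "total")

    def validate_against(self, structure: Structure) -> None:
        present = set(int(r) for r in structure.res_id)
        for name, resids in self.selections.items():
            missing = set(int(r) for r in resids) - present
            if missing:
                raise ConfigError(
                    f"selection {name!r} references absent residues {sorted(missing)}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            selections={k: list(map(int, v)) for k, v in raw.get("selections", {}).items()},
            modes=dict(raw.get("modes", {})),
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _check_pdb_coordinates(path: str | Path) -> None:
    """Scan ATOM/HETATM records for unparsable coordinate fields, naming the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: line {lineno}: non-numeric {what} field "
                            f"{fieldtxt!r}"
                        ) from None


def _check_pdb_model_counts(path: str | Path) -> None:
    """Raise TopologyError if MODEL blocks have differing atom counts."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model = True
                current = 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM", "HETATM")) and in_model:
                current += 1
    if counts and len(set(counts)) > 1:
        raise TopologyError(
            f"{path}: models have differing atom counts {sorted(set(counts))}"
        )


def _atom_array_to_structure(arr: bts.AtomArray, ss: str | None = None) -> Structure:
    charge = None
    if "charge" in arr.get_annotation_categories():
        ch = np.asarray(arr.charge, dtype=float)
        if np.any(ch != 0):
            charge = ch
    return Structure(
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=np.asarray(arr.element, dtype="U2"),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype="U5"),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        coord=np.asarray(arr.coord, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        charge=charge,
        ss=ss,
    )


def _structure_to_atom_array(s: Structure) -> bts.AtomArray:
    arr = bts.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.res_id = s.res_id
    arr.res_name = s.res_name
    arr.chain_id = s.chain_id
    arr.hetero = s.hetero.astype(bool)
    return arr


def read_structure(path: str | Path, model_index: int = 1) -> Structure:
    """Read one model of a PDB file (``model_index`` is 1-based).

    Hetero atoms are retained and flagged via ``Structure.hetero``.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(path)
        n_models = pdb.get_model_count()
        if not 1 <= model_index <= n_models:
            raise IndexError(
                f"{path}: model {model_index} requested, file has {n_models}"
            )
        arr = pdb.get_structure(model=model_index)
    except IndexError:
        raise
    except Exception as exc:  # diagnose before re-raising
        _check_pdb_coordinates(path)
        raise PDBParseError(f"{path}: {exc}") from exc
    return _atom_array_to_structure(arr)


def _parse_pool_spec(spec, n_frames: int) -> set[int]:
    if isinstance(spec, str):
        if spec.startswith("first:"):
            m = int(spec.split(":", 1)[1])
            if m < 1:
                raise ConfigError(f"native pool {spec!r} is empty")
            return set(range(min(m, n_frames)))
        raise ConfigError(f"unrecognised native pool spec {spec!r}")
    pool = set(int(i) for i in spec)
    if not pool:
        raise ConfigError("native pool spec is empty")
    return pool


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    native_pool: str | Iterable[int] = "first:10",
    ss: Sequence[str] | None = None,
) -> Trajectory:
    """Read a trajectory from one multi-model PDB or a sequence of PDB files.

    ``native_pool`` is either a list of 0-based frame indices or ``"first:M"``.
    ``ss`` optionally supplies one secondary-structure string per frame.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[Structure] = []
    for p in paths:
        p = Path(p)
        try:
            pdb = PDBFile.read(p)
            n_models = pdb.get_model_count()
            for m in range(1, n_models + 1):
                frames.append(_atom_array_to_structure(pdb.get_structure(model=m)))
        except Exception as exc:
            _check_pdb_coordinates(p)
            _check_pdb_model_counts(p)
            raise PDBParseError(f"{p}: {exc}") from exc
    if ss is not None:
        if len(ss) != len(frames):
            raise ShapeError(f"{len(ss)} ss strings for {len(frames)} frames")
        frames = [f.with_coords(f.coord, ss=s) for f, s in zip(frames, ss)]
    pool = _parse_pool_spec(native_pool, len(frames))
    return Trajectory(frames=frames, native_pool=pool)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB."""
    arrays = [_structure_to_atom_array(f) for f in trajectory.frames]
    stack = bts.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(Path(path))


def write_structure(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(Path(path))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(
    rows: Sequence[Sequence], column_names: Sequence[str], path: str | Path
) -> None:
    """Write rectangular data as a TSV with header; floats at 6 significant digits."""
    rows = list(rows)
    for i, r in enumerate(rows):
        if len(r) != len(column_names):
            raise ShapeError(
                f"row {i} has {len(r)} fields, expected {len(column_names)}"
            )
    df = pd.DataFrame(rows, columns=list(column_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ss_table(ss_strings: Sequence[str], path: str | Path) -> None:
    write_table(
        [[i, s] for i, s in enumerate(ss_strings)], ["frame", "ss"], path
    )


def read_ss_table(path: str | Path) -> list[str]:
    df = read_table(path)
    return [str(s) for s in df["ss"]]


def write_labels(labels: Sequence[int], path: str | Path) -> None:
    write_table([[i, int(l)] for i, l in enumerate(labels)], ["frame", "state"], path)


def read_labels(path: str | Path) -> np.ndarray:
    return read_table(path)["state"].to_numpy()
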