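"""The composite unfolding reaction coordinate d.

Raw per-frame properties are first turned into *unfolding fractions*: each
property is oriented so that unfolding increases it (the native-contact
fraction is flipped; the dipole moment and region-ASA columns enter as
absolute deviation from their native mean), shifted so the native-pool mean
sits at zero, and scaled by the trajectory maximum so the most deviant frame
sits at one. The scalar coordinate d is the root-mean-square of a frame's
normalized deviations from the native-pool mean, optionally renormalized so
the most unfolded frame has d = 1: d is 0 at the native ensemble and 1 at the
most unfolded structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ConfigError, ShapeError
from .metrics import PropertyMatrix

#: How each known property enters the unfolding fraction.
#: "increase": larger raw value = more unfolded. "decrease": flipped.
#: "absdev": absolute deviation from the native-pool mean.
DEFAULT_ORIENTATIONS: dict[str, str] = {
    "Qsh": "decrease",
    "Dpm": "absdev",
}


def _orientation_for(name: str, overrides: dict[str, str] | None) -> str:
    if overrides and name in overrides:
        return overrides[name]
    if name in DEFAULT_ORIENTATIONS:
        return DEFAULT_ORIENTATIONS[name]
    return "increase"


@dataclass
class NormalizedMatrix:
    """Frames × properties unfolding fractions in [0, 1].

    ``native_means`` holds the per-property native-pool mean of the
    normalized values (P_y,native); ``orientation`` records the applied
    per-property transform; ``dropped`` lists constant columns that were
    zeroed and excluded from d.
    """

    property_names: list[str]
    values: np.ndarray
    native_means: np.ndarray
    orientation: list[str]
    native_pool: list[int]
    dropped: list[str] = field(default_factory=list)
    enforce_range: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.native_means = np.asarray(self.native_means, dtype=float)
        if self.values.shape[1] != len(self.property_names):
            raise ShapeError("values shape does not match property_names")
        if self.enforce_range and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ShapeError("normalized values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def active_mask(self) -> np.ndarray:
        return np.array([n not in self.dropped for n in self.property_names])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.property_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.property_names)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df


def normalize_properties(
    matrix: PropertyMatrix,
    orientation_overrides: dict[str, str] | None = None,
) -> NormalizedMatrix:
    """Per-property unfolding-fraction transform of a raw property matrix.

    Each column is oriented (see module docstring), shifted by its
    native-pool mean and scaled by the resulting trajectory maximum, so the
    native pool maps near 0 and the most deviant frame maps to exactly 1.
    Columns with no variation are zeroed, flagged and later excluded from d.
    """
    pool = list(matrix.native_pool)
    if not pool:
        raise ConfigError("empty native pool")
    n, p = matrix.values.shape
    out = np.zeros((n, p))
    orientations: list[str] = []
    dropped: list[str] = []
    for j, name in enumerate(matrix.property_names):
        mode = _orientation_for(name, orientation_overrides)
        if mode not in ("increase", "decrease", "absdev"):
            raise ConfigError(f"property {name!r}: unknown orientation {mode!r}")
        orientations.append(mode)
        x = matrix.values[:, j]
        if mode == "increase":
            oriented = x
        elif mode == "decrease":
            oriented = -x
        else:
            oriented = np.abs(x - x[pool].mean())
        shifted = oriented - oriented[pool].mean()
        peak = shifted.max()
        if peak <= 1e-12:
            warnings.warn(f"property {name!r} does not vary; column zeroed")
            dropped.append(name)
            continue
        out[:, j] = np.clip(shifted / peak, 0.0, 1.0)
    native_means = out[pool].mean(axis=0)
    return NormalizedMatrix(
        property_names=list(matrix.property_names),
        values=out,
        native_means=native_means,
        orientation=orientations,
        native_pool=pool,
        dropped=dropped,
    )


@dataclass
class DSeries:
    """Per-frame reaction-coordinate values."""

    d: np.ndarray
    d_raw: np.ndarray
    renormalized: bool
    n_properties: int

    def __len__(self) -> int:
        return len(self.d)


def compute_d(norm: NormalizedMatrix, renormalize: bool = True) -> DSeries:
    """d(frame) = √( (1/N) Σ_y (P_y − P_y,native)² ) over active properties.

    With ``renormalize`` the series is divided by its maximum so the most
    unfolded frame has d = 1; the native-pool mean property vector has d = 0
    by construction either way.
    """
    active = norm.active_mask
    n_props = int(active.sum())
    if n_props == 0:
        raise ConfigError("no varying properties: d undefined")
    dev = norm.values[:, active] - norm.native_means[active]
    d_raw = np.sqrt(np.mean(dev**2, axis=1))
    d = d_raw.copy()
    if renormalize:
        peak = d_raw.max()
        if peak > 0:
            d = d_raw / peak
        else:
            warnings.warn("all frames at the native mean; d is identically 0")
    return DSeries(d=d, d_raw=d_raw, renormalized=renormalize, n_properties=n_props)


def d_density(
    dseries: DSeries | np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of d on a grid over [0, 1], normalized to unit integral.

    ``bandwidth`` is a KDE factor override (Scott's rule when None).
    Returns (grid, density).
    """
    d = dseries.d if isinstance(dseries, DSeries) else np.asarray(dseries, float)
    if len(d) < 10:
        raise ConfigError("need at least 10 frames for a density estimate")
    grid = np.linspace(0.0, max(1.0, d.max()), max(grid_size, 200))
    if np.ptp(d) < 1e-12:
        warnings.warn("degenerate d series (all equal); density is a single spike")
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - d[0]))] = 1.0
    else:
        kde = gaussian_kde(d, bw_method=bandwidth)
        dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return grid, dens
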