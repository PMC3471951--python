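"""State decomposition of an unfolding trajectory.

Dimensionality reduction (PCA with a 2D kernel-density / potential-of-mean-
force map, and non-metric MDS) followed by exemplar-based affinity-propagation
clustering over the n-MDS embedding, plus per-state summaries ordered along
the unfolding coordinate. PCA, n-MDS and affinity propagation are delegated
to scikit-learn behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

from .dcoord import DSeries, NormalizedMatrix
from .errors import ConfigError, DegenerateDataError, RankError, ShapeError

#: RT at the default analysis temperature of 500 K, kcal/mol
#: (R = 1.987e-3 kcal mol⁻¹ K⁻¹).
RT_500K = 1.987e-3 * 500.0


def pca(
    data: NormalizedMatrix | np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the (internally centered) property matrix.

    Returns (scores (n, k), explained-variance fractions (k,)). Component
    signs follow a deterministic convention: the largest-magnitude loading of
    each component is made positive.
    """
    X = data.values if isinstance(data, NormalizedMatrix) else np.asarray(data, float)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise RankError(f"k={k} exceeds data rank {rank}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Xc)
    # deterministic sign convention
    for j in range(k):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores, model.explained_variance_ratio_.copy()


def kde2d_pmf(
    scores_2d: np.ndarray,
    bandwidth: float | None = None,
    rt: float = RT_500K,
    grid_size: int = 128,
) -> dict[str, np.ndarray]:
    """2D Gaussian KDE of PC scores converted to a potential of mean force.

    PMF = −RT·ln(density), shifted so the global minimum is 0; the grid covers
    the data ± 3 bandwidths in each dimension. Returns a dict with keys
    ``x``, ``y`` (grid axes), ``density`` and ``pmf`` (grid_size × grid_size,
    indexed [iy, ix]).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ShapeError("scores_2d must be (n, 2)")
    if len(pts) < 10:
        raise ConfigError("need at least 10 points")
    if rt <= 0:
        raise ConfigError("RT must be positive")
    std = pts.std(axis=0)
    if np.any(std < 1e-12):
        raise DegenerateDataError("zero variance in a PC dimension")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    h = kde.factor * std
    x = np.linspace(pts[:, 0].min() - 3 * h[0], pts[:, 0].max() + 3 * h[0], grid_size)
    y = np.linspace(pts[:, 1].min() - 3 * h[1], pts[:, 1].max() + 3 * h[1], grid_size)
    XX, YY = np.meshgrid(x, y)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_size, grid_size)
    with np.errstate(divide="ignore"):
        pmf = -rt * np.log(dens)
    pmf = pmf - np.nanmin(pmf[np.isfinite(pmf)])
    return {"x": x, "y": y, "density": dens, "pmf": pmf}


def nmds(
    dissimilarities: np.ndarray,
    dims: int = 2,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 4,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS (Kruskal stress-1 with monotone regression).

    ``dissimilarities`` must be a square symmetric non-negative matrix.
    ``n_init`` random restarts are run and the lowest-stress configuration
    kept; fully deterministic for a given seed. Returns (embedding, stress).
    """
    D = np.asarray(dissimilarities, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ShapeError(f"dissimilarity matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ShapeError("dissimilarity matrix must be symmetric")
    if D.min() < 0:
        raise ShapeError("dissimilarities must be non-negative")
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        emb = model.fit_transform(D)
    return emb, float(model.stress_)


@dataclass
class APResult:
    labels: np.ndarray
    exemplars: np.ndarray  # frame index per cluster
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def affinity_propagation(
    points: np.ndarray | None = None,
    similarity: np.ndarray | None = None,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 500,
    convergence_window: int = 30,
) -> APResult:
    """Exemplar-based affinity propagation.

    Default similarity is negative squared Euclidean distance between rows of
    ``points``; ``preference`` defaults to the median similarity. Exemplars
    are actual frame indices. On non-convergence the best labeling found is
    returned with ``converged=False``; the degenerate all-identical input
    collapses to one cluster with the lowest index as exemplar.
    """
    if (points is None) == (similarity is None):
        raise ConfigError("provide exactly one of points / similarity")
    if similarity is None:
        X = np.atleast_2d(np.asarray(points, dtype=float))
        S = -squareform(pdist(X, "sqeuclidean"))
    else:
        S = np.asarray(similarity, dtype=float)
        if S.shape[0] != S.shape[1]:
            raise ShapeError("similarity matrix must be square")
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    if n == 1 or (np.ptp(off) < 1e-15 and np.allclose(off, off[0])):
        # all points identical: message passing is degenerate
        return APResult(np.zeros(n, dtype=int), np.array([0]), True)
    model = AffinityPropagation(
        affinity="precomputed",
        preference=preference,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_window,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(S)
    centers = model.cluster_centers_indices_
    if centers is None or len(centers) == 0 or np.any(model.labels_ < 0):
        warnings.warn("affinity propagation did not converge; single-cluster fallback")
        return APResult(np.zeros(n, dtype=int), np.array([0]), False)
    converged = model.n_iter_ < max_iter
    return APResult(model.labels_.copy(), np.asarray(centers, dtype=int), converged)


@dataclass
class StateSummary:
    """Per-state means, ordered by mean d along the unfolding pathway."""

    property_names: list[str]
    state_means: np.ndarray  # (n_states, n_properties), normalized fractions
    mean_d: np.ndarray  # (n_states,)
    frame_counts: np.ndarray  # (n_states,)
    labels: np.ndarray  # per-frame state ids after d-ordering (0 = most native)
    exemplars: np.ndarray | None = None  # frame index per ordered state

    @property
    def n_states(self) -> int:
        return len(self.mean_d)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.state_means, columns=self.property_names)
        df.insert(0, "state", np.arange(self.n_states))
        df.insert(1, "n_frames", self.frame_counts)
        df.insert(2, "mean_d", self.mean_d)
        return df


def state_summary(
    labels: np.ndarray,
    norm: NormalizedMatrix,
    dseries: DSeries | np.ndarray,
    exemplars: np.ndarray | None = None,
) -> StateSummary:
    """Per-state mean unfolding fractions and mean d, states ordered by mean d."""
    labels = np.asarray(labels, dtype=int)
    d = dseries.d if isinstance(dseries, DSeries) else np.asarray(dseries, float)
    if len(labels) != norm.n_frames or len(d) != norm.n_frames:
        raise ShapeError("labels/d length must match frame count")
    ids = np.unique(labels)
    mean_d = np.array([d[labels == s].mean() for s in ids])
    order = np.argsort(mean_d)
    ids = ids[order]
    remap = {int(old): new for new, old in enumerate(ids)}
    new_labels = np.array([remap[int(l)] for l in labels])
    means = np.stack([norm.values[labels == s].mean(axis=0) for s in ids])
    counts = np.array([int(np.sum(labels == s)) for s in ids])
    new_exemplars = None
    if exemplars is not None:
        ex = np.asarray(exemplars, dtype=int)
        # exemplar of original cluster id = its position in the AP output
        by_old = {int(labels[e]): int(e) for e in ex}
        new_exemplars = np.array([by_old[int(s)] for s in ids])
    return StateSummary(
        property_names=list(norm.property_names),
        state_means=means,
        mean_d=mean_d[order],
        frame_counts=counts,
        labels=new_labels,
        exemplars=new_exemplars,
    )
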