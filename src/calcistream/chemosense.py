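"""Odour-response analysis: features, distances, Ward trees, Mantel test.

After the stream has been factorised, each response unit contributes one
time series (a column of T).  Per stimulus, the feature is the maximum of
that series between the stimulus onset and the next onset; stacking features
over stimuli gives a stimuli x units matrix whose row geometry encodes odour
identity.  Odour-by-odour Euclidean distance matrices can be clustered
(Ward's minimum-variance linkage) and compared across individuals with a
permutation Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .synthetic import StimulusProtocol


@dataclass
class FeatureMatrix:
    """Stimuli x units response maxima, one row per protocol entry."""

    values: np.ndarray
    stimulus_labels: list[str]
    unit_ids: list[int]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"unit_{u}" for u in self.unit_ids])
        df.insert(0, "stimulus", self.stimulus_labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("stimulus").tolist()
        unit_ids = [int(c.split("_", 1)[1]) if "_" in c else i
                    for i, c in enumerate(df.columns)]
        return cls(values=df.to_numpy(dtype=float),
                   stimulus_labels=[str(x) for x in labels], unit_ids=unit_ids)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def extract_features(
    T: np.ndarray | pd.DataFrame,
    protocol: StimulusProtocol,
    baseline_mode: str = "none",
    baseline_frames: int = 5,
    unit_ids=None,
) -> FeatureMatrix:
    """Per-stimulus maxima of each unit's time series.

    The window for stimulus s runs from its onset to the next onset (the last
    window to the end of the movie).  ``baseline_mode="subtract"`` removes
    the mean of the ``baseline_frames`` frames before onset; the default
    keeps raw maxima.
    """
    if isinstance(T, pd.DataFrame):
        if unit_ids is None:
            unit_ids = list(range(T.shape[1]))
        T = T.to_numpy(dtype=float)
    T = np.atleast_2d(np.asarray(T, dtype=np.float64))
    m, n_units = T.shape
    if unit_ids is None:
        unit_ids = list(range(n_units))
    if baseline_mode not in ("none", "subtract"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    onsets = protocol.onsets
    if len(onsets) == 0:
        raise ValueError("protocol has no stimuli")
    if onsets[-1] >= m:
        raise ValueError("time series does not cover all stimulus onsets")
    ends = np.append(onsets[1:], m)
    rows = []
    for onset, end in zip(onsets, ends):
        if end <= onset:
            raise ValueError(f"empty stimulus window [{onset}, {end})")
        window_max = T[onset:end].max(axis=0)
        if baseline_mode == "subtract":
            b0 = max(onset - baseline_frames, 0)
            base = T[b0:onset].mean(axis=0) if onset > b0 else 0.0
            window_max = window_max - base
        rows.append(window_max)
    return FeatureMatrix(values=np.asarray(rows),
                         stimulus_labels=list(protocol.labels),
                         unit_ids=list(unit_ids))


def euclidean_distances(F: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between stimulus feature vectors."""
    if F.values.shape[0] < 2:
        raise ValueError("need at least two stimuli")
    return DistanceMatrix(labels=list(F.stimulus_labels),
                          d=squareform(pdist(F.values, metric="euclidean")))


@dataclass
class ClusterResult:
    """Ward linkage over stimuli: merge table, labels, leaf order."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in leaves_list(self.linkage)]


def ward_cluster(data: FeatureMatrix | DistanceMatrix) -> ClusterResult:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Feature input uses Euclidean geometry directly; distance input must be a
    Euclidean distance matrix.  Deterministic given input order; merge
    heights are non-decreasing.
    """
    if isinstance(data, FeatureMatrix):
        if data.values.shape[0] < 2:
            raise ValueError("need at least two items to cluster")
        Z = linkage(data.values, method="ward")
        labels = list(data.stimulus_labels)
    elif isinstance(data, DistanceMatrix):
        Z = linkage(data.condensed(), method="ward")
        labels = list(data.labels)
    else:
        raise TypeError("expected a FeatureMatrix or DistanceMatrix")
    return ClusterResult(linkage=Z, labels=labels)


def subtree_leaf_sets(Z: np.ndarray) -> list[set[int]]:
    """Leaf set of every internal node of a linkage tree."""
    n = Z.shape[0] + 1
    sets: list[set[int]] = [{i} for i in range(n)]
    out = []
    for a, b in Z[:, :2].astype(int):
        merged = sets[a] | sets[b]
        sets.append(merged)
        out.append(merged)
    return out


def is_pure_subtree(result: ClusterResult, leaf_indices) -> bool:
    """True if some dendrogram node contains exactly these leaves."""
    target = set(int(i) for i in leaf_indices)
    if len(target) == 1:
        return True
    return target in subtree_leaf_sets(result.linkage)


def to_newick(result: ClusterResult) -> str:
    """Newick string with branch lengths from the Ward merge heights."""
    Z = result.linkage
    n = Z.shape[0] + 1
    heights = np.concatenate([np.zeros(n), Z[:, 2]])

    def node(i: int) -> str:
        if i < n:
            return result.labels[i].replace(" ", "_")
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = heights[i]
        return (f"({node(a)}:{h - heights[a]:.6g},"
                f"{node(b)}:{h - heights[b]:.6g})")

    return node(2 * n - 2) + ";"


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


def mantel_test(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Permutation test for correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; rows/columns of the
    second matrix are permuted jointly and the two-tailed p-value is
    ``(#{|r*| >= |r|} + 1) / (n_permutations + 1)`` (so p can never be 0).
    Deterministic per seed.
    """
    D1 = d1.d if isinstance(d1, DistanceMatrix) else np.asarray(d1, dtype=float)
    D2 = d2.d if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    if D1.shape != D2.shape or D1.shape[0] != D1.shape[1]:
        raise ValueError("distance matrices must be square and equal-sized")
    if (isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix)
            and d1.labels != d2.labels):
        raise ValueError("distance matrices must share label order")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = D1[iu]

    def corr(y: np.ndarray) -> float:
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        return float(xc @ yc / denom) if denom > 0 else 0.0

    r = corr(D2[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Dp = D2[np.ix_(perm, perm)]
        if abs(corr(Dp[iu])) >= abs(r):
            count += 1
    return MantelResult(r=r, p=(count + 1) / (n_permutations + 1),
                        n_permutations=n_permutations)


def save_heatmap(F: FeatureMatrix, path, log_scale: bool = True) -> None:
    """Clustered stimuli-by-units heatmap (rendering aid, linear data kept)."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    vals = F.values
    disp = np.log1p(np.maximum(vals - vals.min(), 0)) if log_scale else vals
    order = ward_cluster(F).leaf_order
    fig = Figure(figsize=(8, 6))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    im = ax.imshow(disp[order], aspect="auto", cmap="coolwarm",
                   interpolation="nearest")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([F.stimulus_labels[i] for i in order], fontsize=5)
    ax.set_xlabel("response unit")
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
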