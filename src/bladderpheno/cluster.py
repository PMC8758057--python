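"""Two-step symptom clustering: Ward dendrogram + elbow, then K-means.

Continuous items are z-standardised (optionally log(1+x)-transformed
first); binary items pass through as 0/1.  Ward's method provides the
dendrogram whose merge heights equal the increase in total within-cluster
sum of squares (so a singleton pair merges at half its squared Euclidean
distance), the elbow of the WSS curve suggests k, and K-means (k-means++
starts, Lloyd iterations, best of ``n_restarts``) produces the final
partition.  Principal coordinate analysis with Bray-Curtis dissimilarity
(on non-negative unit-scaled raw scores, never z-scores) provides the
ordination view.

The statsmodels-style surface is :class:`PhenotypeClustering` (model,
built from a cohort table) whose :meth:`~PhenotypeClustering.fit` returns a
:class:`PhenotypeClusteringResults` carrying labels, centroids, WSS and
the downstream diagnostics (bootstrap stability, variable importance,
phenotype z-matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DegenerateFeatureError, ValidationError
from .instruments import battery

__all__ = [
    "FeatureMatrix",
    "DendrogramTree",
    "ClusterModel",
    "standardize",
    "ward_dendrogram",
    "cut_tree",
    "kmeans_fit",
    "wss_curve",
    "suggest_k",
    "pcoa_bray",
    "unit_scale",
    "PhenotypeClustering",
    "PhenotypeClusteringResults",
]

DEFAULT_N_RESTARTS = 50


# ---------------------------------------------------------------------------
# standardisation


@dataclass
class FeatureMatrix:
    """Standardised feature matrix plus the parameters used to build it."""

    frame: pd.DataFrame                 # standardized values, subjects x features
    feature_kind: dict[str, str]        # column -> "continuous" | "binary"
    log_columns: tuple[str, ...]
    center: dict[str, float]            # per continuous column
    scale: dict[str, float]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.index)

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)

    def apply(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Re-apply the stored transform to new raw data (identical mapping)."""
        out = {}
        for col in self.frame.columns:
            x = raw[col].to_numpy(dtype=float)
            if self.feature_kind[col] == "binary":
                out[col] = x
            else:
                if col in self.log_columns:
                    x = np.log1p(x)
                out[col] = (x - self.center[col]) / self.scale[col]
        return pd.DataFrame(out, index=raw.index)


def standardize(
    raw: pd.DataFrame,
    binary_columns: list[str] | None = None,
    log_columns: tuple[str, ...] = (),
) -> FeatureMatrix:
    """z-score continuous columns (after optional log(1+x)), pass binaries.

    Binary columns default to the battery's binary items.  A zero-variance
    continuous column raises :class:`DegenerateFeatureError` naming it.
    """
    batt = battery()
    cols = [c for c in raw.columns if c in batt or (binary_columns and c in binary_columns)]
    if not cols:
        raise ValidationError("no battery item columns found in input table")
    if raw[cols].isna().any().any():
        bad = [c for c in cols if raw[c].isna().any()]
        raise ValidationError(f"missing values in column(s): {', '.join(bad)}")
    if binary_columns is None:
        binary_columns = [c for c in cols if c in batt and batt[c].kind == "binary"]

    kind, center, scale, out = {}, {}, {}, {}
    degenerate = []
    for col in cols:
        x = raw[col].to_numpy(dtype=float)
        if col in binary_columns:
            if not np.isin(x, (0.0, 1.0)).all():
                raise ValidationError(f"binary column {col} contains non-0/1 values")
            kind[col] = "binary"
            out[col] = x
            continue
        kind[col] = "continuous"
        if col in log_columns:
            if (x < 0).any():
                raise ValidationError(f"log-transform column {col} has negative values")
            x = np.log1p(x)
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0.0:
            degenerate.append(col)
            continue
        center[col], scale[col] = mu, sd
        out[col] = (x - mu) / sd
    if degenerate:
        raise DegenerateFeatureError(f"zero-variance column(s): {', '.join(degenerate)}")

    idx = raw["subject_id"] if "subject_id" in raw.columns else raw.index
    frame = pd.DataFrame(out, index=pd.Index(idx, name="subject_id"))
    return FeatureMatrix(frame=frame, feature_kind=kind,
                         log_columns=tuple(log_columns), center=center, scale=scale)


# ---------------------------------------------------------------------------
# Ward hierarchy


@dataclass
class DendrogramTree:
    """Agglomerative merge history; heights are WSS increases."""

    merges: list[tuple[int, int, float]]  # (node_a, node_b, height); leaves 0..n-1
    n_leaves: int
    _linkage: np.ndarray = field(repr=False, default=None)

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([h for _, _, h in self.merges])


def ward_dendrogram(X: np.ndarray | FeatureMatrix) -> DendrogramTree:
    """Ward agglomeration; merge height = increase in total WSS."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValidationError("ward_dendrogram needs at least 2 subjects")
    Z = hierarchy.linkage(X, method="ward")
    # scipy's ward height h relates to the WSS increase by delta = h^2 / 2
    merges = [(int(a), int(b), float(h) ** 2 / 2.0) for a, b, h, _ in Z]
    return DendrogramTree(merges=merges, n_leaves=n, _linkage=Z)


def cut_tree(tree: DendrogramTree, k: int) -> np.ndarray:
    """Labels (1..k, numbered by first appearance) from undoing the last k-1 merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValidationError(f"k={k} out of range [1, {tree.n_leaves}]")
    raw = hierarchy.cut_tree(tree._linkage, n_clusters=k).ravel()
    return _relabel_first_appearance(raw)


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# K-means


@dataclass
class ClusterModel:
    """A fitted K-means partition in standardized feature space."""

    k: int
    centroids: np.ndarray        # (k, p), row i is cluster i+1
    labels: np.ndarray           # (n,), values 1..k
    wss: float
    seed: int
    n_restarts: int

    def recompute_wss(self, X: np.ndarray) -> float:
        return float(sum(
            ((X[self.labels == c + 1] - self.centroids[c]) ** 2).sum()
            for c in range(self.k)
        ))


def kmeans_fit(
    X: np.ndarray | FeatureMatrix, k: int, seed: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> ClusterModel:
    """Best-of-restarts Lloyd K-means with k-means++ starts.

    Deterministic given (inputs, seed).  Labels are renumbered 1..k by
    order of first appearance; centroids are recomputed as the means of
    their final members (so the stored WSS is exactly the recomputed sum of
    squared distances to member means).
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of subjects n={n}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts,
        max_iter=300, tol=1e-6, algorithm="lloyd",
        random_state=int(seed) % (2**32),
    ).fit(X)
    labels = _relabel_first_appearance(km.labels_)
    centroids = np.vstack([
        X[labels == c].mean(axis=0) if np.any(labels == c) else np.full(X.shape[1], np.nan)
        for c in range(1, k + 1)
    ])
    model = ClusterModel(k=k, centroids=centroids, labels=labels,
                         wss=0.0, seed=int(seed), n_restarts=n_restarts)
    model.wss = model.recompute_wss(X)
    return model


def wss_curve(
    X: np.ndarray | FeatureMatrix, k_max: int, seed: int,
    n_restarts: int = 10,
) -> list[tuple[int, float]]:
    """Within-cluster sum of squares at k = 1..k_max (best of restarts each)."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if k_max > X.shape[0]:
        raise ValidationError("k_max exceeds number of subjects")
    return [
        (k, kmeans_fit(X, k, seed=int(seed) + k, n_restarts=n_restarts).wss)
        for k in range(1, k_max + 1)
    ]


def suggest_k(curve: list[tuple[int, float]]) -> int:
    """Elbow choice: the k after which extra clusters stop paying off.

    Scores each interior k by the ratio of the WSS drop achieved when
    going to k over the drop achieved by going one step further — a
    scale-free curvature of the elbow plot.  The raw second forward
    difference is dominated by the always-large k=1 to k=2 drop and
    systematically under-counts clusters, so the relative form is used.
    """
    if len(curve) < 3:
        raise ValidationError("need a WSS curve with at least 3 points")
    ks = [k for k, _ in curve]
    wss = np.asarray([w for _, w in curve])
    drops = np.maximum(wss[:-1] - wss[1:], 1e-12)
    ratios = drops[:-1] / drops[1:]
    return ks[1 + int(np.argmax(ratios))]


# ---------------------------------------------------------------------------
# ordination


def unit_scale(raw: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Scale item columns to [0, 1] by their theoretical scale bounds."""
    batt = battery()
    columns = columns or [c for c in raw.columns if c in batt]
    out = {}
    for c in columns:
        d = batt[c]
        out[c] = (raw[c].to_numpy(dtype=float) - d.scale_min) / (d.scale_max - d.scale_min)
    idx = raw["subject_id"] if "subject_id" in raw.columns else raw.index
    return pd.DataFrame(out, index=pd.Index(idx, name="subject_id"))


def bray_curtis_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity; a double-zero pair has d = 0."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative features")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def pcoa_bray(raw_nonneg: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Principal coordinates of the Bray-Curtis dissimilarity matrix.

    Expects non-negative (e.g. unit-scaled raw) feature values.  Returns the
    first ``n_dims`` coordinates ordered by eigenvalue.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    batt = battery()
    cols = [c for c in raw_nonneg.columns if c in batt] or list(raw_nonneg.columns)
    numeric = raw_nonneg[cols]
    ids = (raw_nonneg["subject_id"].astype(str).tolist()
           if "subject_id" in raw_nonneg.columns else [str(i) for i in raw_nonneg.index])
    d = bray_curtis_matrix(numeric.to_numpy(dtype=float))
    ord_res = _skbio_pcoa(DistanceMatrix(d, ids=ids), number_of_dimensions=n_dims)
    coords = ord_res.samples.iloc[:, :n_dims].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    coords.index.name = "subject_id"
    return coords


# ---------------------------------------------------------------------------
# model / results surface


class PhenotypeClustering:
    """Two-step clustering model over a standardized symptom feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
        Standardised features (see :func:`standardize`).
    raw : pandas.DataFrame, optional
        The raw cohort table the matrix was built from; kept for
        ordination and z-matrix diagnostics.
    """

    def __init__(self, fm: FeatureMatrix, raw: pd.DataFrame | None = None):
        self.fm = fm
        self.raw = raw

    @classmethod
    def from_dataframe(
        cls, raw: pd.DataFrame, log_columns: tuple[str, ...] = (),
        cases_only: bool = True,
    ) -> "PhenotypeClustering":
        """Build from a cohort table; controls are excluded by default
        (clusters are derived from the symptomatic cohort alone)."""
        if cases_only and "group_label" in raw.columns:
            raw = raw.loc[raw["group_label"] == "case"]
        return cls(standardize(raw, log_columns=log_columns), raw=raw)

    def ward_dendrogram(self) -> DendrogramTree:
        return ward_dendrogram(self.fm)

    def wss_curve(self, k_max: int = 10, seed: int = 0, n_restarts: int = 10):
        return wss_curve(self.fm, k_max=k_max, seed=seed, n_restarts=n_restarts)

    def suggest_k(self, k_max: int = 10, seed: int = 0, n_restarts: int = 10) -> int:
        return suggest_k(self.wss_curve(k_max=k_max, seed=seed, n_restarts=n_restarts))

    def fit(self, k: int = 3, seed: int = 0,
            n_restarts: int = DEFAULT_N_RESTARTS) -> "PhenotypeClusteringResults":
        model = kmeans_fit(self.fm, k=k, seed=seed, n_restarts=n_restarts)
        return PhenotypeClusteringResults(self, model)


class PhenotypeClusteringResults:
    """A fitted K-means partition with its diagnostics."""

    def __init__(self, model: PhenotypeClustering, cluster_model: ClusterModel):
        self.model = model
        self.cluster_model = cluster_model

    @property
    def k(self) -> int:
        return self.cluster_model.k

    @property
    def wss(self) -> float:
        return self.cluster_model.wss

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.cluster_model.labels, index=self.model.fm.frame.index,
                         name="cluster")

    @property
    def centroids(self) -> pd.DataFrame:
        return pd.DataFrame(self.cluster_model.centroids,
                            index=pd.RangeIndex(1, self.k + 1, name="cluster"),
                            columns=self.model.fm.features)

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def bootstrap_stability(self, B: int = 10_000, seed: int = 0, **kwargs):
        from .stability import bootstrap_stability
        return bootstrap_stability(self.model.fm, self.cluster_model, B=B, seed=seed, **kwargs)

    def variable_importance(self, n_trees: int = 500, seed: int = 0, **kwargs):
        from .importance import rf_importance
        return rf_importance(self.model.fm, self.cluster_model.labels,
                             n_trees=n_trees, seed=seed, **kwargs)

    def phenotype_z_matrix(self, raw: pd.DataFrame | None = None,
                           group_names: dict[int, str] | None = None):
        from .importance import phenotype_z_matrix
        raw = raw if raw is not None else self.model.raw
        if raw is None:
            raise ConfigurationError("raw cohort table required for the z-matrix")
        return phenotype_z_matrix(raw, self.cluster_model.labels, group_names=group_names)

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        lines = [
            "Phenotype clustering (K-means after Ward/elbow)",
            "=" * 48,
            f"subjects: {len(self.labels)}    features: {len(self.model.fm.features)}",
            f"k: {self.k}    WSS: {self.wss:.3f}    restarts: {self.cluster_model.n_restarts}"
            f"    seed: {self.cluster_model.seed}",
            "",
            "cluster sizes:",
        ]
        for c, n in sizes.items():
            lines.append(f"  cluster {c}: {n}")
        return "\n".join(lines)
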