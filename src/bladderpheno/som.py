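"""Kohonen self-organizing map over the phenotype measures.

Subjects (cases *and* controls) are binned on a small rectangular grid of
nodes (default 6 x 4 = 24) trained online: at each iteration a random
subject is drawn, its best-matching unit (BMU; nearest codebook by
Euclidean distance) found, and every node pulled toward the subject with a
Gaussian neighborhood weight around the BMU.  Learning rate and
neighborhood radius decay linearly over the run.  Nodes are afterwards
grouped into metaclusters by Ward clustering of codebooks, and each bin is
labelled control / pure phenotype / mixed / global pain from its mean
unit-scaled symptom measures.

The convergence index is the popsom-style composite: half the fraction of
features whose codebook-weight distribution is statistically
indistinguishable from the data (mean and variance two-sample tests at
alpha = 0.05), plus half the fraction of subjects whose best and
second-best matching units are grid neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import cut_tree, ward_dendrogram
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SOMConfig",
    "SOMModel",
    "BinSummaryConfig",
    "BinSummary",
    "train_som",
    "convergence_index",
    "metacluster_nodes",
    "neighbor_distance_map",
    "classify_bins",
    "SelfOrganizingMap",
    "SOMResults",
]

MEASURE_COLUMNS = ("bps_measure", "nupp_measure", "mfp_measure")
_MEASURE_PHENOTYPE = {"bps_measure": "BPS", "nupp_measure": "NUPP", "mfp_measure": "MFP"}


@dataclass
class SOMConfig:
    rows: int = 4
    cols: int = 6
    iterations: int = 1_000_000
    alpha0: float = 0.1          # initial learning rate, linear decay to ~0
    sigma_final: float = 0.5     # final neighborhood radius (grid units)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ConfigurationError("grid must have at least 2 nodes")
        if not 0.0 < self.alpha0 <= 1.0:
            raise ConfigurationError("alpha0 must lie in (0, 1]")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def sigma0(self) -> float:
        return max(self.rows, self.cols) / 2.0


@dataclass
class SOMModel:
    """Trained codebook grid and its training configuration."""

    codebook: np.ndarray         # (n_nodes, p)
    grid: np.ndarray             # (n_nodes, 2) integer (row, col) coordinates
    config: SOMConfig
    feature_names: list[str] = field(default_factory=list)

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Index of the nearest codebook for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def bmu2(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best and second-best matching units per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        order = np.argsort(d, axis=1)
        return order[:, 0], order[:, 1]

    def quantization_error(self, X: np.ndarray) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = self.bmu(X)
        return float(np.sqrt(((X - self.codebook[b]) ** 2).sum(axis=1)).mean())


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([r.ravel(), c.ravel()])


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    return X, [f"x{j}" for j in range(X.shape[1])]


def train_som(data, config: SOMConfig) -> SOMModel:
    """Online SOM training; deterministic given ``config.seed``.

    The codebook is initialised uniformly at random within each feature's
    data range.  At iteration t of T the learning rate is
    alpha0 * (1 - t/T) and the Gaussian neighborhood radius decays linearly
    from max(rows, cols)/2 to ``sigma_final``.
    """
    X, names = _as_matrix(data)
    n, p = X.shape
    if n == 0:
        raise ValidationError("empty training data")
    m = config.n_nodes
    grid = _grid_coords(config.rows, config.cols)
    grid_sq = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2).astype(float)

    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    W = lo + rng.random((m, p)) * (hi - lo)
    T = config.iterations
    draws = rng.integers(0, n, T)
    for t in range(T):
        x = X[draws[t]]
        frac = t / T
        alpha = config.alpha0 * (1.0 - frac)
        sigma = config.sigma0 + (config.sigma_final - config.sigma0) * frac
        b = int(((W - x) ** 2).sum(axis=1).argmin())
        h = np.exp(-grid_sq[b] / (2.0 * sigma * sigma))
        W += (alpha * h)[:, None] * (x - W)
    return SOMModel(codebook=W, grid=grid, config=config, feature_names=names)


def _rook_neighbors(grid: np.ndarray) -> list[np.ndarray]:
    """Indices of the 2-4 rectangular-grid neighbors of each node."""
    out = []
    for i in range(len(grid)):
        d = np.abs(grid - grid[i]).sum(axis=1)
        out.append(np.where(d == 1)[0])
    return out


def convergence_index(model: SOMModel, data) -> float:
    """Composite map-quality index in [0, 1].

    0.5 x embedding accuracy (features whose codebook weights match the
    data distribution in mean and variance at alpha = 0.05) + 0.5 x
    topographic accuracy (subjects whose two best units are grid
    neighbors).
    """
    X, _ = _as_matrix(data)
    W = model.codebook
    alpha = 0.05
    embedded = 0
    for j in range(X.shape[1]):
        _, p_mean = stats.ttest_ind(W[:, j], X[:, j], equal_var=False)
        v1, v2 = W[:, j].var(ddof=1), X[:, j].var(ddof=1)
        if v1 == 0 and v2 == 0:
            p_var = 1.0
        elif v1 == 0 or v2 == 0:
            p_var = 0.0
        else:
            f = v1 / v2
            df1, df2 = len(W) - 1, len(X) - 1
            p_var = 2.0 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
        if (np.isnan(p_mean) or p_mean > alpha) and p_var > alpha:
            embedded += 1
    embed_acc = embedded / X.shape[1]

    b1, b2 = model.bmu2(X)
    grid_dist = np.abs(model.grid[b1] - model.grid[b2]).sum(axis=1)
    topo_acc = float(np.mean(grid_dist == 1))
    return float(0.5 * embed_acc + 0.5 * topo_acc)


def metacluster_nodes(model: SOMModel, n_meta: int) -> np.ndarray:
    """Ward clustering of codebook vectors cut at ``n_meta`` groups."""
    m = len(model.codebook)
    if not 1 <= n_meta <= m:
        raise ValidationError(f"n_meta={n_meta} out of range [1, {m}]")
    if n_meta == m:
        return np.arange(1, m + 1)
    return cut_tree(ward_dendrogram(model.codebook), n_meta)


def neighbor_distance_map(model: SOMModel) -> np.ndarray:
    """Per-node mean Euclidean codebook distance to its grid neighbors,
    returned as a (rows, cols) array."""
    W = model.codebook
    out = np.zeros(len(W))
    for i, nbrs in enumerate(_rook_neighbors(model.grid)):
        out[i] = np.sqrt(((W[nbrs] - W[i]) ** 2).sum(axis=1)).mean()
    return out.reshape(model.config.rows, model.config.cols)


@dataclass
class BinSummaryConfig:
    low_threshold: float = 0.25
    high_threshold: float = 0.6
    dominance_ratio: float = 2.0


@dataclass
class BinSummary:
    """Per-bin subject counts, mean measures (pie-slice sizes) and purity label."""

    table: pd.DataFrame  # index=node; row, col, count, mean measures, label
    config: BinSummaryConfig

    def counts_grid(self, rows: int, cols: int) -> np.ndarray:
        return self.table["count"].to_numpy().reshape(rows, cols)

    def pure_or_control_fraction(self) -> float:
        """Fraction of subjects in bins labelled control or pure-*."""
        t = self.table
        ok = t["label"].isin(["control", "pure-BPS", "pure-NUPP", "pure-MFP"])
        total = t["count"].sum()
        return float(t.loc[ok, "count"].sum() / total) if total else 0.0


def _label_bin(means: dict[str, float], cfg: BinSummaryConfig) -> str:
    vals = np.asarray([means[c] for c in MEASURE_COLUMNS])
    if np.all(vals < cfg.low_threshold):
        return "control"
    if np.all(vals > cfg.high_threshold):
        return "global"
    order = np.argsort(vals)[::-1]
    top, rest = vals[order[0]], vals[order[1:]]
    if top >= cfg.low_threshold and np.all(top >= cfg.dominance_ratio * rest):
        return f"pure-{_MEASURE_PHENOTYPE[MEASURE_COLUMNS[order[0]]]}"
    return "mixed"


def classify_bins(
    model: SOMModel,
    measures: pd.DataFrame,
    cfg: BinSummaryConfig | None = None,
) -> BinSummary:
    """Bin subjects by BMU and label each bin from its mean measures.

    ``measures`` must hold the three unit-scaled phenotype measures
    (columns ``bps_measure``, ``nupp_measure``, ``mfp_measure``) in [0, 1].
    A bin with no subjects is labelled ``empty``.
    """
    cfg = cfg or BinSummaryConfig()
    missing = [c for c in MEASURE_COLUMNS if c not in measures.columns]
    if missing:
        raise ValidationError(f"measures table lacks column(s): {', '.join(missing)}")
    M = measures[list(MEASURE_COLUMNS)].to_numpy(dtype=float)
    if np.any((M < 0) | (M > 1)):
        raise ValidationError("phenotype measures must be unit-scaled to [0, 1]")
    train_cols = model.feature_names or list(MEASURE_COLUMNS)
    bmu = model.bmu(measures[train_cols].to_numpy(dtype=float))

    rows = []
    for i in range(model.config.n_nodes):
        members = bmu == i
        count = int(members.sum())
        if count == 0:
            means = {c: 0.0 for c in MEASURE_COLUMNS}
            label = "empty"
        else:
            means = {c: float(M[members, j].mean()) for j, c in enumerate(MEASURE_COLUMNS)}
            label = _label_bin(means, cfg)
        rows.append({
            "node": i, "row": int(model.grid[i, 0]), "col": int(model.grid[i, 1]),
            "count": count, **{f"mean_{c}": v for c, v in means.items()}, "label": label,
        })
    return BinSummary(table=pd.DataFrame(rows).set_index("node"), config=cfg)


# ---------------------------------------------------------------------------
# model / results surface


class SelfOrganizingMap:
    """SOM model over a subjects x features table (statsmodels-style)."""

    def __init__(self, data, config: SOMConfig | None = None):
        self.data = data
        self.config = config or SOMConfig()

    def fit(self, seed: int | None = None) -> "SOMResults":
        cfg = self.config
        if seed is not None:
            cfg = SOMConfig(rows=cfg.rows, cols=cfg.cols, iterations=cfg.iterations,
                            alpha0=cfg.alpha0, sigma_final=cfg.sigma_final, seed=seed)
        return SOMResults(self, train_som(self.data, cfg))


class SOMResults:
    """A trained SOM with its diagnostics."""

    def __init__(self, model: SelfOrganizingMap, som_model: SOMModel):
        self.model = model
        self.som_model = som_model

    @property
    def codebook(self) -> pd.DataFrame:
        return pd.DataFrame(self.som_model.codebook, columns=self.som_model.feature_names)

    def assignments(self) -> np.ndarray:
        X, _ = _as_matrix(self.model.data)
        return self.som_model.bmu(X)

    def convergence_index(self) -> float:
        return convergence_index(self.som_model, self.model.data)

    def metacluster(self, n_meta: int) -> np.ndarray:
        return metacluster_nodes(self.som_model, n_meta)

    def neighbor_distance_map(self) -> np.ndarray:
        return neighbor_distance_map(self.som_model)

    def classify_bins(self, measures: pd.DataFrame | None = None,
                      cfg: BinSummaryConfig | None = None) -> BinSummary:
        measures = measures if measures is not None else self.model.data
        return classify_bins(self.som_model, measures, cfg)

    def quantization_error(self) -> float:
        X, _ = _as_matrix(self.model.data)
        return self.som_model.quantization_error(X)

    def summary(self) -> str:
        cfg = self.som_model.config
        lines = [
            "Self-organizing map",
            "=" * 48,
            f"grid: {cfg.rows} x {cfg.cols} ({cfg.n_nodes} nodes)    "
            f"iterations: {cfg.iterations}    alpha0: {cfg.alpha0}    seed: {cfg.seed}",
            f"quantization error: {self.quantization_error():.4f}",
            f"convergence index: {self.convergence_index():.3f}",
        ]
        return "\n".join(lines)
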