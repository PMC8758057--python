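"""Which items discriminate the phenotypes.

Two complementary views:

* a random forest classifying subjects into their cluster labels, reporting
  mean decrease in accuracy (out-of-bag accuracy drop under per-feature
  permutation) and mean decrease in Gini impurity;
* a per-item phenotype z-matrix — each group's item mean expressed as a
  z-score relative to the overall cohort, the numeric content of the
  phenotype heat map.

The forest is a bagging loop over scikit-learn decision trees rather than
``RandomForestClassifier`` because the accuracy importance here is defined
on each tree's out-of-bag sample, which the sklearn ensemble does not
expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cluster import FeatureMatrix
from .errors import ValidationError
from .instruments import battery

__all__ = [
    "ImportanceReport",
    "PhenotypeZMatrix",
    "rf_importance",
    "phenotype_z_matrix",
    "select_discriminatory_items",
]


@dataclass
class ImportanceReport:
    """Per-feature forest importances, ranked by accuracy importance."""

    table: pd.DataFrame  # index=feature; mean_decrease_accuracy, mean_decrease_gini
    n_trees: int
    features_per_split: int
    seed: int

    def ranked(self, by: str = "mean_decrease_accuracy") -> pd.DataFrame:
        return self.table.sort_values(by, ascending=False)

    def top_features(self, n: int, by: str = "mean_decrease_accuracy") -> list[str]:
        return list(self.ranked(by).head(n).index)


def rf_importance(
    fm: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    n_trees: int = 500,
    features_per_split: int | None = None,
    seed: int = 0,
) -> ImportanceReport:
    """Random-forest variable importance for the cluster labels.

    Each tree is grown on a bootstrap sample with ``features_per_split``
    (default floor(sqrt(p))) candidate features per split and unlimited
    depth.  Accuracy importance of feature j is the mean, over trees, of
    the tree's out-of-bag accuracy drop when column j is permuted within
    the out-of-bag rows; Gini importance is the mean of the trees'
    normalised impurity decreases.  Deterministic given ``seed``.
    """
    if isinstance(fm, FeatureMatrix):
        feature_names = fm.features
        X = fm.values
    else:
        X = np.asarray(fm, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("importance needs at least two classes of labels")
    n, p = X.shape
    mtry = features_per_split or max(1, int(np.sqrt(p)))
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")

    rng = np.random.default_rng(seed)
    acc_drops = np.zeros((n_trees, p))
    acc_mask = np.zeros(n_trees, dtype=bool)
    gini = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        ).fit(X[boot], y[boot])
        gini += tree.feature_importances_
        if oob.size == 0:
            continue
        acc_mask[t] = True
        base = float(np.mean(tree.predict(X[oob]) == y[oob]))
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            acc_drops[t, j] = base - float(np.mean(tree.predict(Xp) == y[oob]))
    mda = acc_drops[acc_mask].mean(axis=0) if acc_mask.any() else np.zeros(p)
    table = pd.DataFrame(
        {"mean_decrease_accuracy": mda, "mean_decrease_gini": gini / n_trees},
        index=pd.Index(feature_names, name="feature"),
    ).sort_values("mean_decrease_accuracy", ascending=False)
    return ImportanceReport(table=table, n_trees=n_trees, features_per_split=mtry, seed=seed)


@dataclass
class PhenotypeZMatrix:
    """Group item means as z-scores against the overall cohort."""

    table: pd.DataFrame          # rows=items, columns=groups
    group_sizes: dict[str, int]
    degenerate_items: list[str]  # zero-variance items, entries undefined (NaN)

    @property
    def groups(self) -> list[str]:
        return list(self.table.columns)


def phenotype_z_matrix(
    raw: pd.DataFrame,
    labels: np.ndarray,
    group_names: dict[int, str] | None = None,
) -> PhenotypeZMatrix:
    """entry(item, group) = (group mean - overall mean) / overall sd.

    Computed on raw (untransformed) item scores, so entries are invariant
    to affine rescaling of an item.  Zero-variance items are flagged and
    reported as NaN.
    """
    batt = battery()
    items = [c for c in raw.columns if c in batt]
    if not items:
        raise ValidationError("no battery item columns in raw table")
    y = np.asarray(labels)
    if len(y) != len(raw):
        raise ValidationError("labels do not match the raw table")
    groups = sorted(set(y.tolist()))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    names = {g: (group_names or {}).get(g, f"cluster_{g}") if group_names else f"cluster_{g}"
             for g in groups}
    if group_names:
        names = {g: group_names.get(g, f"cluster_{g}") for g in groups}

    X = raw[items].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(ddof=1, axis=0)
    degenerate = [items[j] for j in range(len(items)) if sd[j] == 0]
    entries = {}
    for g in groups:
        gm = X[y == g].mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (gm - mu) / np.where(sd > 0, sd, 1.0), np.nan)
        entries[names[g]] = z
    table = pd.DataFrame(entries, index=pd.Index(items, name="item"))
    sizes = {names[g]: int((y == g).sum()) for g in groups}
    return PhenotypeZMatrix(table=table, group_sizes=sizes, degenerate_items=degenerate)


def select_discriminatory_items(
    report: ImportanceReport,
    zmatrix: PhenotypeZMatrix,
    top_n: int = 20,
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign the top-``top_n`` accuracy-important items to phenotypes.

    Each selected item goes to the group with the largest z-matrix entry;
    exact ties go to the earlier column and the item is flagged.  Returns
    (per-group item lists, tied items).
    """
    if top_n > len(report.table):
        raise ValidationError("top_n exceeds the number of features")
    sets: dict[str, list[str]] = {g: [] for g in zmatrix.groups}
    ties: list[str] = []
    for item in report.top_features(top_n):
        if item not in zmatrix.table.index:
            continue
        row = zmatrix.table.loc[item]
        best = row.idxmax()
        if (row == row.max()).sum() > 1:
            ties.append(item)
        sets[best].append(item)
    return sets, ties
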