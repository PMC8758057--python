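"""Bootstrap assessment of cluster-assignment stability.

Each replicate resamples subjects with replacement, refits K-means with the
same k, aligns the replicate's arbitrary cluster numbering to the reference
partition by maximising Cohen's kappa over all k! label permutations, and
then scores each reference cluster on the subjects present in the
resample:

* per-cluster Rand index — the fraction of common subjects whose binary
  in/out membership for that cluster agrees between the reference and the
  aligned bootstrap clustering (joint absence counts as agreement, which is
  why Rand can stay high for sparsely assigned clusters);
* per-cluster Jaccard coefficient — |intersection| / |union| of the two
  membership sets, conventionally "very good" above 0.7.

Out-of-resample subjects are excluded from the agreement computation by
default (their bootstrap assignment is undefined); an optional
nearest-centroid mode assigns them for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .cluster import ClusterModel, FeatureMatrix, kmeans_fit
from .errors import ValidationError

__all__ = [
    "StabilityReport",
    "align_labels",
    "cluster_rand",
    "cluster_jaccard",
    "bootstrap_stability",
]


def align_labels(
    reference_labels: np.ndarray, candidate_labels: np.ndarray
) -> tuple[dict[int, int], float]:
    """Best relabeling of ``candidate_labels`` onto the reference numbering.

    Searches all k! permutations of the candidate's label values and returns
    the mapping (candidate label -> reference label) with maximal unweighted
    Cohen's kappa, together with that kappa.
    """
    ref = np.asarray(reference_labels)
    cand = np.asarray(candidate_labels)
    if ref.shape != cand.shape:
        raise ValidationError("label vectors must cover the same subjects")
    ref_vals = sorted(set(ref.tolist()))
    cand_vals = sorted(set(cand.tolist()))
    if len(cand_vals) > len(ref_vals):
        raise ValidationError("candidate clustering has more clusters than reference")
    best_perm: dict[int, int] = {}
    best_kappa = -np.inf
    for perm in permutations(ref_vals, len(cand_vals)):
        mapping = dict(zip(cand_vals, perm))
        remapped = np.asarray([mapping[c] for c in cand])
        kappa = cohen_kappa_score(ref, remapped, labels=ref_vals)
        if kappa > best_kappa:
            best_kappa, best_perm = kappa, mapping
    return best_perm, float(best_kappa)


def cluster_rand(
    ref_membership: Iterable, boot_membership: Iterable, common_subjects: Iterable
) -> float:
    """Per-cluster agreement: fraction of common subjects with matching
    in/out status (joint absence agrees)."""
    common = list(common_subjects)
    if not common:
        raise ValidationError("empty common subject set")
    ref, boot = set(ref_membership), set(boot_membership)
    agree = sum((s in ref) == (s in boot) for s in common)
    return agree / len(common)


def cluster_jaccard(
    ref_membership: Iterable, boot_membership: Iterable, common_subjects: Iterable
) -> float:
    """|intersection| / |union| over common subjects; 1 when both are empty."""
    common = set(common_subjects)
    if not common:
        raise ValidationError("empty common subject set")
    ref = set(ref_membership) & common
    boot = set(boot_membership) & common
    union = ref | boot
    if not union:
        return 1.0
    return len(ref & boot) / len(union)


@dataclass
class StabilityReport:
    """Per-cluster point estimates and percentile CIs over B replicates."""

    k: int
    B: int
    seed: int
    rand_point: dict[int, float]
    rand_ci: dict[int, tuple[float, float]]
    jaccard_point: dict[int, float]
    jaccard_ci: dict[int, tuple[float, float]]
    alignment_kappas: list[float] = field(repr=False)
    n_skipped: int = 0
    replicate_rand: np.ndarray | None = field(default=None, repr=False)
    replicate_jaccard: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(1, self.k + 1):
            rows.append({
                "cluster": c,
                "rand": self.rand_point[c],
                "rand_lo": self.rand_ci[c][0], "rand_hi": self.rand_ci[c][1],
                "jaccard": self.jaccard_point[c],
                "jaccard_lo": self.jaccard_ci[c][0], "jaccard_hi": self.jaccard_ci[c][1],
            })
        return pd.DataFrame(rows).set_index("cluster")

    def to_dict(self) -> dict:
        out = self.to_frame().to_dict(orient="index")
        return {
            "k": self.k, "B": self.B, "seed": self.seed,
            "n_skipped": self.n_skipped,
            "mean_alignment_kappa": float(np.mean(self.alignment_kappas))
            if self.alignment_kappas else None,
            "clusters": {int(c): v for c, v in out.items()},
        }

    def summary(self) -> str:
        lines = [
            "Bootstrap cluster stability",
            "=" * 48,
            f"B: {self.B} replicates ({self.n_skipped} skipped)    seed: {self.seed}",
            "",
            self.to_frame().round(3).to_string(),
        ]
        return "\n".join(lines)


def bootstrap_stability(
    fm: FeatureMatrix | np.ndarray,
    reference_model: ClusterModel,
    B: int = 10_000,
    seed: int = 0,
    n_restarts: int = 10,
    assign_out_of_sample: bool = False,
) -> StabilityReport:
    """Resample-with-replacement stability of a reference K-means partition.

    Per replicate: draw n subjects with replacement, refit K-means (same k,
    fresh seeded initialisation), align labels to the reference by maximal
    kappa, and score per-cluster Rand and Jaccard on the unique resampled
    subjects.  Replicates where the refit returns fewer than k non-empty
    clusters are skipped and counted.  Point estimates are replicate means;
    CIs are 2.5/97.5 percentiles.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n = X.shape[0]
    if len(reference_model.labels) != n:
        raise ValidationError("reference model was not fitted on this feature matrix")
    k = reference_model.k
    ref_labels = np.asarray(reference_model.labels)

    rng = np.random.default_rng(seed)
    rand_rows, jacc_rows, kappas = [], [], []
    n_skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        boot = kmeans_fit(X[idx], k=k, seed=rep_seed, n_restarts=n_restarts)
        if len(np.unique(boot.labels)) < k:
            n_skipped += 1
            continue
        unique = np.unique(idx)
        # one label per unique subject: duplicates share a row, hence a label
        first_pos = {int(s): int(np.argmax(idx == s)) for s in unique}
        boot_u = np.asarray([boot.labels[first_pos[int(s)]] for s in unique])
        if assign_out_of_sample:
            out = np.setdiff1d(np.arange(n), unique)
            if out.size:
                d = ((X[out][:, None, :] - boot.centroids[None, :, :]) ** 2).sum(axis=2)
                unique = np.concatenate([unique, out])
                boot_u = np.concatenate([boot_u, d.argmin(axis=1) + 1])
        ref_u = ref_labels[unique]
        mapping, kappa = align_labels(ref_u, boot_u)
        kappas.append(kappa)
        aligned = np.asarray([mapping[c] for c in boot_u])
        rand_rows.append([
            cluster_rand(unique[ref_u == c], unique[aligned == c], unique)
            for c in range(1, k + 1)
        ])
        jacc_rows.append([
            cluster_jaccard(unique[ref_u == c], unique[aligned == c], unique)
            for c in range(1, k + 1)
        ])

    if not rand_rows:
        raise ValidationError("every bootstrap replicate was skipped")
    rand_arr = np.asarray(rand_rows)
    jacc_arr = np.asarray(jacc_rows)
    rand_point = {c + 1: float(rand_arr[:, c].mean()) for c in range(k)}
    jacc_point = {c + 1: float(jacc_arr[:, c].mean()) for c in range(k)}
    rand_ci = {c + 1: tuple(np.percentile(rand_arr[:, c], [2.5, 97.5])) for c in range(k)}
    jacc_ci = {c + 1: tuple(np.percentile(jacc_arr[:, c], [2.5, 97.5])) for c in range(k)}
    return StabilityReport(
        k=k, B=B, seed=seed,
        rand_point=rand_point, rand_ci=rand_ci,
        jaccard_point=jacc_point, jaccard_ci=jacc_ci,
        alignment_kappas=kappas, n_skipped=n_skipped,
        replicate_rand=rand_arr, replicate_jaccard=jacc_arr,
    )
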