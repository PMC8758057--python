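"""Responder analysis by phenotype and thin group-comparison utilities.

Builds the phenotype x therapy contingency of responders over attempts,
the within-group (responders / attempted) and within-cohort (share of all
responders to a therapy) proportion tables, and the two-sample z-test for
comparing proportions, plus Mann-Whitney / chi-square / Fisher wrappers
for baseline group comparisons.  No multiple-testing correction is applied
by default; a Holm adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .calibration import THERAPIES
from .errors import ValidationError
from .simulate import TreatmentRecord

__all__ = [
    "ResponderTable",
    "responder_table",
    "responder_proportions",
    "two_proportion_ztest",
    "compare_groups",
    "pairwise_response_tests",
]


@dataclass
class ResponderTable:
    """Counts of (responders, attempted) per phenotype and therapy."""

    responders: pd.DataFrame   # phenotype x therapy
    attempted: pd.DataFrame
    n_with_followup: pd.Series  # subjects per phenotype with >= 1 assessed therapy

    def __post_init__(self) -> None:
        if (self.responders > self.attempted).any().any():
            raise ValidationError("responders exceed attempts in some cell")

    @property
    def totals(self) -> pd.DataFrame:
        """Totals row: column sums over phenotypes."""
        return pd.DataFrame({
            "responders": self.responders.sum(axis=0),
            "attempted": self.attempted.sum(axis=0),
        }).T

    def to_frame(self) -> pd.DataFrame:
        out = self.responders.astype(str) + " / " + self.attempted.astype(str)
        out["n_with_followup"] = self.n_with_followup
        return out


def responder_table(
    records: list[TreatmentRecord],
    labels: dict[str, str] | pd.Series,
    therapies: tuple[str, ...] = THERAPIES,
) -> ResponderTable:
    """Aggregate treatment records into a phenotype x therapy table.

    ``labels`` maps subject_id to phenotype.  Every subject in the records
    must be labelled; subjects attempting several therapies are counted
    once per therapy and once in the follow-up column.
    """
    if isinstance(labels, pd.Series):
        labels = dict(labels)
    unlabeled = sorted({r.subject_id for r in records} - set(labels))
    if unlabeled:
        raise ValidationError(f"unlabeled subject(s): {', '.join(unlabeled)}")
    phenotypes = sorted({labels[r.subject_id] for r in records}) or ["none"]
    resp = pd.DataFrame(0, index=phenotypes, columns=list(therapies))
    att = pd.DataFrame(0, index=phenotypes, columns=list(therapies))
    followup: dict[str, set] = {p: set() for p in phenotypes}
    for r in records:
        if not r.attempted:
            continue
        p = labels[r.subject_id]
        att.loc[p, r.therapy] += 1
        followup[p].add(r.subject_id)
        if r.responded:
            resp.loc[p, r.therapy] += 1
    n_followup = pd.Series({p: len(s) for p, s in followup.items()}, name="n_with_followup")
    return ResponderTable(responders=resp, attempted=att, n_with_followup=n_followup)


def responder_proportions(table: ResponderTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(within-group, within-cohort) proportion tables.

    within_group[p, t] = responders / attempted for phenotype p (NaN where
    no attempts — flagged undefined, not zero); within_cohort[p, t] =
    phenotype p's responders as a share of all responders to therapy t.
    """
    if table.attempted.to_numpy().sum() == 0:
        raise ValidationError("empty responder table")
    with np.errstate(invalid="ignore", divide="ignore"):
        within_group = table.responders / table.attempted.replace(0, np.nan)
        col_tot = table.responders.sum(axis=0).replace(0, np.nan)
        within_cohort = table.responders / col_tot
    return within_group, within_cohort


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test for proportions (no continuity correction).

    Returns (z, two-sided p).  The sign of z follows x1/n1 - x2/n2.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValidationError("each arm needs n >= 1")
        if not 0 <= x <= n:
            raise ValidationError("need 0 <= x <= n in each arm")
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def compare_groups(values_a, values_b=None, kind: str = "mann_whitney") -> tuple[float, float]:
    """Thin wrappers for the baseline comparisons (two-tailed).

    ``mann_whitney``: two samples, normal approximation with tie
    correction.  ``chi_square``: ``values_a`` is an r x c count table
    (Pearson, no Yates correction).  ``fisher_2x2``: ``values_a`` is a 2x2
    count table, exact hypergeometric p.
    """
    if kind == "mann_whitney":
        if values_b is None:
            raise ValidationError("mann_whitney needs two samples")
        res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided",
                                 method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        table = np.asarray(values_a)
        if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
            raise ValidationError("chi_square needs an r x c table with r, c >= 2")
        res = stats.chi2_contingency(table, correction=False)
        return float(res[0]), float(res[1])
    if kind == "fisher_2x2":
        table = np.asarray(values_a)
        if table.shape != (2, 2):
            raise ValidationError("fisher_2x2 needs a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValidationError(f"unknown comparison kind: {kind}")


def pairwise_response_tests(
    table: ResponderTable, holm: bool = False
) -> pd.DataFrame:
    """Two-proportion z-tests between every phenotype pair, per therapy."""
    phenos = list(table.responders.index)
    rows = []
    for therapy in table.responders.columns:
        for i, a in enumerate(phenos):
            for b in phenos[i + 1:]:
                na, nb = int(table.attempted.loc[a, therapy]), int(table.attempted.loc[b, therapy])
                if na == 0 or nb == 0:
                    continue
                z, p = two_proportion_ztest(
                    int(table.responders.loc[a, therapy]), na,
                    int(table.responders.loc[b, therapy]), nb,
                )
                rows.append({"therapy": therapy, "group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows, columns=["therapy", "group_a", "group_b", "z", "p"])
    if holm and len(out):
        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
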