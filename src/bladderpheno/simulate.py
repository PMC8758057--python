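"""Synthetic cohort generator calibrated to per-phenotype item statistics.

Real item-level questionnaire data for the study cohort are not publicly
deposited, so every downstream stage (clustering, stability, importance,
SOM, treatment analysis) is exercised on synthetic cohorts whose per-item
distributions are moment-matched to the published per-phenotype summary
statistics (see :mod:`bladderpheno.calibration`).

Ordinal items are drawn from a discretised, range-truncated normal whose
location is solved by bisection so the achieved mean matches the target
within 0.01, and whose scale is solved so the achieved SD matches as
closely as the discrete support allows.  Binary items are Bernoulli with
the published endorsement proportion.  Items are independent within
subject by default; an optional Gaussian-copula severity factor
(``correlation``) induces positive dependence while preserving the
marginals exactly.  Mixed-phenotype subjects are drawn from convex blends
of two groups' parameter vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from . import calibration
from .errors import ConfigurationError, ValidationError
from .instruments import QuestionnaireResponse, battery

__all__ = [
    "ItemDistribution",
    "GroupSpec",
    "CohortConfig",
    "TreatmentRecord",
    "moment_match_item",
    "bernoulli_item",
    "generate_cohort",
    "generate_cohort_frame",
    "generate_treatment_records",
    "treatment_frame",
    "default_cohort_config",
    "default_response_rates",
    "default_attempt_rates",
]


@dataclass(frozen=True)
class ItemDistribution:
    """A discrete distribution over an item's integer support."""

    support: tuple[int, ...]
    pmf: tuple[float, ...]

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def sd(self) -> float:
        s = np.asarray(self.support, dtype=float)
        m = self.mean()
        return float(np.sqrt(np.dot(self.pmf, (s - m) ** 2)))

    def quantile(self, u) -> np.ndarray:
        """Inverse CDF for uniforms in [0, 1) (vectorised)."""
        cum = np.cumsum(self.pmf)
        cum[-1] = 1.0
        idx = np.searchsorted(cum, np.asarray(u), side="right")
        return np.asarray(self.support)[np.clip(idx, 0, len(self.support) - 1)]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.quantile(rng.random(n))


def _discretized_pmf(mu: float, sigma: float, support: np.ndarray) -> np.ndarray:
    """Normal(mu, sigma) mass binned at integers and renormalised on support.

    When the whole support sits so far in one tail that the CDF differences
    underflow, the log-density tilt (the analytic limit of the bin masses)
    is used instead, which stays numerically stable for any location.
    """
    za = (support - 0.5 - mu) / sigma
    zb = (support + 0.5 - mu) / sigma
    # log bin masses, using the numerically favourable tail for each bin
    with np.errstate(divide="ignore", invalid="ignore"):
        la, lb = log_ndtr(za), log_ndtr(zb)
        lqa, lqb = log_ndtr(-za), log_ndtr(-zb)
        lower_form = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-15)))
        upper_form = lqa + np.log1p(-np.exp(np.minimum(lqb - lqa, -1e-15)))
    logp = np.where(za + zb <= 0, lower_form, upper_form)
    if not np.isfinite(logp).any():  # degenerate guard: pure exponential tilt
        logp = -((support - mu) ** 2) / (2.0 * sigma * sigma)
    p = np.exp(logp - logp[np.isfinite(logp)].max())
    p[~np.isfinite(p)] = 0.0
    return p / p.sum()


def _solve_location(target_mean: float, sigma: float, support: np.ndarray) -> float:
    """Bisection on mu: the truncated-discretised mean is increasing in mu.

    The bracket must grow with sigma^2: pushing the truncated mean toward a
    scale endpoint requires an exponential tilt of order (mu - mid)/sigma^2.
    """
    span = 8.0 * max(sigma, 1.0) + 60.0 * sigma * sigma
    lo = float(support[0]) - span
    hi = float(support[-1]) + span

    def f(mu):
        return float(np.dot(support, _discretized_pmf(mu, sigma, support))) - target_mean

    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_SIGMA_LO, _SIGMA_HI = 1e-3, 60.0


@lru_cache(maxsize=4096)
def moment_match_item(
    target_mean: float, target_sd: float, scale_min: int, scale_max: int
) -> ItemDistribution:
    """Discretised, range-truncated normal matching a target mean and SD.

    The location is found by bisection so the achieved mean is within 0.01
    of ``target_mean``; the scale is then solved (Brent) so the achieved SD
    matches ``target_sd`` as closely as the discrete support allows.
    Results are cached (the distribution is immutable).
    """
    if not scale_min <= target_mean <= scale_max:
        raise ConfigurationError(
            f"target mean {target_mean} outside item range [{scale_min}, {scale_max}]"
        )
    if target_sd < 0:
        raise ConfigurationError("target sd must be non-negative")
    support = np.arange(scale_min, scale_max + 1)

    def sd_at(sigma: float) -> float:
        mu = _solve_location(target_mean, sigma, support)
        pmf = _discretized_pmf(mu, sigma, support)
        m = float(np.dot(support, pmf))
        return float(np.sqrt(np.dot(pmf, (support - m) ** 2)))

    if sd_at(_SIGMA_LO) >= target_sd:
        sigma = _SIGMA_LO
    elif sd_at(_SIGMA_HI) <= target_sd:
        sigma = _SIGMA_HI
    else:
        sigma = optimize.brentq(lambda s: sd_at(s) - target_sd, _SIGMA_LO, _SIGMA_HI, xtol=1e-6)
    mu = _solve_location(target_mean, sigma, support)
    pmf = _discretized_pmf(mu, sigma, support)
    return ItemDistribution(support=tuple(int(s) for s in support), pmf=tuple(pmf))


def bernoulli_item(p: float) -> ItemDistribution:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"endorsement proportion {p} outside [0, 1]")
    return ItemDistribution(support=(0, 1), pmf=(1.0 - p, p))


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass
class GroupSpec:
    """Target item statistics and size for one generating group."""

    name: str
    n: int
    ordinal_params: dict[str, tuple[float, float]]  # item -> (mean, sd)
    binary_params: dict[str, float]                 # item -> endorsement p
    age_mean: float = 33.0
    age_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"group {self.name}: n must be >= 0")
        batt = battery()
        for item, (m, _) in self.ordinal_params.items():
            d = batt[item]
            if not d.scale_min <= m <= d.scale_max:
                raise ConfigurationError(
                    f"group {self.name}, item {item}: mean {m} outside scale"
                )
        for item, p in self.binary_params.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"group {self.name}, item {item}: p outside [0, 1]")

    def distributions(self) -> dict[str, ItemDistribution]:
        batt = battery()
        out: dict[str, ItemDistribution] = {}
        for item, (m, s) in self.ordinal_params.items():
            d = batt[item]
            out[item] = moment_match_item(m, s, d.scale_min, d.scale_max)
        for item, p in self.binary_params.items():
            out[item] = bernoulli_item(p)
        return out


@dataclass
class CohortConfig:
    """Full generator configuration; ``seed`` is mandatory."""

    groups: list[GroupSpec]
    seed: int
    mixed_fraction: float = 0.0
    blend_weight: float = 0.5
    correlation: float = 0.0  # shared latent severity factor, in [0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixed_fraction <= 1.0:
            raise ConfigurationError("mixed_fraction must lie in [0, 1]")
        if not 0.0 < self.blend_weight < 1.0:
            raise ConfigurationError("blend_weight must lie in (0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigurationError("correlation must lie in [0, 1)")


def default_cohort_config(seed: int, **overrides) -> CohortConfig:
    """The study-sized default: 56 BPS / 31 NUPP / 58 MFP cases + 69 controls."""
    return CohortConfig(groups=calibration.default_group_specs(), seed=seed, **overrides)


def _blend_spec(a: GroupSpec, b: GroupSpec, w: float) -> GroupSpec:
    ordinal = {
        item: (w * a.ordinal_params[item][0] + (1 - w) * b.ordinal_params[item][0],
               w * a.ordinal_params[item][1] + (1 - w) * b.ordinal_params[item][1])
        for item in a.ordinal_params
    }
    binary = {
        item: w * a.binary_params[item] + (1 - w) * b.binary_params[item]
        for item in a.binary_params
    }
    return GroupSpec(
        name=f"{a.name}+{b.name}", n=0, ordinal_params=ordinal, binary_params=binary,
        age_mean=w * a.age_mean + (1 - w) * b.age_mean,
        age_sd=w * a.age_sd + (1 - w) * b.age_sd,
    )


def _draw_subjects(
    spec: GroupSpec, n: int, rng: np.random.Generator, correlation: float,
    dists: dict[str, ItemDistribution] | None = None,
) -> list[dict[str, float]]:
    """Draw n subjects via a Gaussian copula (exact marginals for any rho)."""
    dists = dists or spec.distributions()
    items = list(dists)
    rho = correlation
    z = rng.standard_normal(n)  # shared severity factor per subject
    rows: list[dict[str, float]] = [dict() for _ in range(n)]
    for item in items:
        eps = rng.standard_normal(n)
        u = stats.norm.cdf(np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps)
        vals = dists[item].quantile(u)
        for r, v in zip(rows, vals):
            r[item] = int(v)
    return rows


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[QuestionnaireResponse], list[str]]:
    """Generate a cohort; returns responses and their generating labels.

    Reproducible: the output is a pure function of ``config`` (including its
    seed).  Mixed-phenotype case subjects (``mixed_fraction`` of each case
    group) are drawn from convex blends of that group's parameters with a
    second, randomly chosen phenotype; their label is ``"A+B"``.
    """
    rng = np.random.default_rng(config.seed)
    case_names = [g.name for g in config.groups if g.name != "CONTROL"]
    by_name = {g.name: g for g in config.groups}

    responses: list[QuestionnaireResponse] = []
    labels: list[str] = []
    counter = 0
    for spec in config.groups:
        n_mixed = 0
        if spec.name != "CONTROL" and len(case_names) > 1:
            n_mixed = int(round(config.mixed_fraction * spec.n))
        n_pure = spec.n - n_mixed

        blocks: list[tuple[GroupSpec, int, str]] = [(spec, n_pure, spec.name)]
        for _ in range(n_mixed):
            other = by_name[rng.choice([c for c in case_names if c != spec.name])]
            blended = _blend_spec(spec, other, config.blend_weight)
            blocks.append((blended, 1, blended.name))

        for block_spec, n, label in blocks:
            if n == 0:
                continue
            rows = _draw_subjects(block_spec, n, rng, config.correlation)
            ages = np.clip(rng.normal(block_spec.age_mean, block_spec.age_sd, n), 18.0, 60.0)
            for row, age in zip(rows, ages):
                counter += 1
                responses.append(QuestionnaireResponse(
                    subject_id=f"S{counter:04d}", answers=row, age=round(float(age), 1),
                    group_label="control" if spec.name == "CONTROL" else "case",
                ))
                labels.append(label)
    return responses, labels


def generate_cohort_frame(config: CohortConfig) -> tuple[pd.DataFrame, pd.Series]:
    """As :func:`generate_cohort`, but as a cohort table + label series."""
    responses, labels = generate_cohort(config)
    cols = list(battery())
    rows = []
    for resp in responses:
        row = {"subject_id": resp.subject_id, "age": resp.age, "group_label": resp.group_label}
        row.update({c: resp.answers[c] for c in cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "age", "group_label"] + cols)
    return df, pd.Series(labels, index=df["subject_id"].to_numpy(), name="true_label")


# ---------------------------------------------------------------------------
# treatment records


@dataclass(frozen=True)
class TreatmentRecord:
    subject_id: str
    therapy: str
    attempted: bool
    responded: bool

    def __post_init__(self) -> None:
        if self.responded and not self.attempted:
            raise ValidationError("responded implies attempted")


def default_response_rates() -> dict[str, dict[str, float]]:
    """Per (phenotype, therapy) response probability from the published counts."""
    return {
        ph: {t: r / n for t, (r, n) in cells.items()}
        for ph, cells in calibration.RESPONDER_COUNTS.items()
    }


def default_attempt_rates() -> dict[str, dict[str, float]]:
    """Per (phenotype, therapy) attempt probability (attempted / group size)."""
    return {
        ph: {t: n / calibration.GROUP_SIZES[ph] for t, (_, n) in cells.items()}
        for ph, cells in calibration.RESPONDER_COUNTS.items()
    }


def generate_treatment_records(
    true_labels: dict[str, str] | pd.Series,
    response_rates: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    attempt_rates: dict[str, dict[str, float]] | None = None,
) -> list[TreatmentRecord]:
    """Bernoulli treatment attempts/responses per case subject.

    ``true_labels`` maps subject_id to phenotype; control subjects receive
    no records, mixed subjects (``"A+B"``) use their first component's
    rates.  Reproducible given ``seed``.
    """
    response_rates = response_rates or default_response_rates()
    attempt_rates = attempt_rates or default_attempt_rates()
    for ph, cells in response_rates.items():
        for t, r in cells.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"response rate for ({ph}, {t}) outside [0, 1]")
    if isinstance(true_labels, pd.Series):
        true_labels = dict(true_labels)
    rng = np.random.default_rng(seed)
    records: list[TreatmentRecord] = []
    for subject_id, label in true_labels.items():
        if label == "CONTROL":
            continue
        phenotype = label.split("+")[0]
        if phenotype not in response_rates:
            raise ConfigurationError(f"unknown phenotype {phenotype!r} for {subject_id}")
        for therapy in calibration.THERAPIES:
            if rng.random() < attempt_rates[phenotype].get(therapy, 0.0):
                responded = bool(rng.random() < response_rates[phenotype].get(therapy, 0.0))
                records.append(TreatmentRecord(subject_id, therapy, True, responded))
    return records


def treatment_frame(records: list[TreatmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["subject_id", "therapy", "attempted", "responded"],
    )
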