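"""Item battery and scoring rules for the four symptom questionnaires.

The battery covers the O'Leary-Sant Interstitial Cystitis Symptom and
Problem Indices (ICSI/ICPI, four 0-5 and four 0-4 items), the Overactive
Bladder Questionnaire short form symptom scale (OAB-q SF, six 1-6 items),
the female Genitourinary Pain Index (fGUPI: eight yes/no pain
location/activity items plus seven ordinal severity and bother items) and
the Pelvic Floor Distress Inventory (PFDI-20, twenty 0-4 items scored as
three 0-100 subscales).

Scoring functions accept any real-valued answers inside the declared item
ranges, so they can be applied both to individual subjects (integer
answers) and to per-group mean profiles.  The OAB-q SF is scored as the raw
item sum, not the instrument's official 0-100 transform, so that its totals
remain on the same scale as the per-item entries it is summed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateFeatureError, ScoringError, ValidationError

__all__ = [
    "Instrument",
    "ItemDefinition",
    "QuestionnaireResponse",
    "ScoredProfile",
    "CompositeConfig",
    "PopulationStats",
    "battery",
    "item_ids",
    "binary_item_ids",
    "validate_answers",
    "score_ics_indices",
    "score_oabq_sf",
    "score_fgupi",
    "score_pfdi",
    "compute_bpci",
    "compute_uici",
    "compute_phenotype_measures",
    "score_profile",
    "score_dataframe",
    "add_phenotype_measures",
]


class Instrument(str, Enum):
    ICSI = "ICSI"
    ICPI = "ICPI"
    OABQ = "OABQ"
    FGUPI = "FGUPI"
    PFDI = "PFDI"


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: its instrument, identifier, scale and kind."""

    instrument: Instrument
    item_id: str
    scale_min: int
    scale_max: int
    kind: str = "ordinal"  # "ordinal" | "binary"

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if (self.scale_min, self.scale_max) != (0, 1):
                raise ConfigurationError(f"binary item {self.item_id} must have range {{0,1}}")
        elif self.scale_min >= self.scale_max:
            raise ConfigurationError(f"item {self.item_id}: scale_min must be < scale_max")


def _build_battery() -> dict[str, ItemDefinition]:
    items: list[ItemDefinition] = []
    for i in range(1, 5):
        items.append(ItemDefinition(Instrument.ICSI, f"icsi_{i}", 0, 5))
    for i in range(1, 5):
        items.append(ItemDefinition(Instrument.ICPI, f"icpi_{i}", 0, 4))
    for i in (2, 3, 4, 5, 6, 8):
        items.append(ItemDefinition(Instrument.OABQ, f"oabq_{i}", 1, 6))
    for suffix in ("1a", "1b", "1c", "1d", "2a", "2b", "2c", "2d"):
        items.append(ItemDefinition(Instrument.FGUPI, f"fgupi_{suffix}", 0, 1, "binary"))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_3", 0, 5))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_4", 0, 10))  # pain VAS
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_5", 0, 5))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_6", 0, 5))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_7", 0, 3))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_8", 0, 3))
    items.append(ItemDefinition(Instrument.FGUPI, "fgupi_9", 0, 6))
    for i in range(1, 21):
        items.append(ItemDefinition(Instrument.PFDI, f"pfdi_{i:02d}", 0, 4))
    out = {it.item_id: it for it in items}
    if len(out) != len(items):  # pragma: no cover - battery is static
        raise ConfigurationError("duplicate item_id in battery")
    return out


_BATTERY = _build_battery()


def battery() -> dict[str, ItemDefinition]:
    """Return the full item battery keyed by item_id."""
    return dict(_BATTERY)


def item_ids() -> list[str]:
    """All item ids in canonical (instrument) order."""
    return list(_BATTERY)


def binary_item_ids() -> list[str]:
    return [i for i, d in _BATTERY.items() if d.kind == "binary"]


@dataclass
class QuestionnaireResponse:
    """One subject's item-level answers across the battery."""

    subject_id: str
    answers: dict[str, float]
    age: float | None = None
    group_label: str | None = None  # "case" | "control" | None


@dataclass
class ScoredProfile:
    subject_id: str
    icsi_total: float
    icpi_total: float
    ols_total: float
    oabq_sf_total: float
    fgupi_pain: float
    fgupi_urinary: float
    fgupi_bother: float
    fgupi_total: float
    popdi6: float
    cradi8: float
    udi6: float
    pfdi_total: float
    bpci: float
    bpci_class: str
    uici: float
    bps_measure: float | None = None
    nupp_measure: float | None = None
    mfp_measure: float | None = None


# ---------------------------------------------------------------------------
# composite configuration


def _unit_weights(ids: tuple[str, ...]) -> dict[str, float]:
    return {i: 1.0 for i in ids}


@dataclass
class CompositeConfig:
    """Weights and thresholds of the composite indices.

    The bladder pain composite index (BPCI) gates study inclusion: a score
    above ``bpci_case_threshold`` marks a case and below
    ``bpci_control_threshold`` a control.  Its exact constituent items were
    defined in earlier work and are not fixed here; the shipped default is a
    documented stand-in built from the bladder-pain items (ICSI4, ICPI4 and
    the two voiding-cycle pain binaries) with unit weights.  The urge
    incontinence composite index (UICI) default is likewise a stand-in over
    the urgency-incontinence items.
    """

    bpci_items: dict[str, float] = field(
        default_factory=lambda: _unit_weights(("icsi_4", "icpi_4", "fgupi_2c", "fgupi_2d"))
    )
    bpci_case_threshold: float = 4.0
    bpci_control_threshold: float = 3.0
    uici_items: dict[str, float] = field(
        default_factory=lambda: _unit_weights(("oabq_4", "oabq_8", "pfdi_16"))
    )
    bps_weights: dict[str, float] = field(
        default_factory=lambda: _unit_weights(("icsi_4", "fgupi_2c", "fgupi_6"))
    )
    nupp_items: tuple[str, ...] = ("fgupi_1a", "fgupi_1b", "fgupi_1c", "fgupi_2a", "fgupi_2b")
    mfp_items: tuple[str, ...] = ("fgupi_5", "pfdi_05", "pfdi_01", "pfdi_07")

    def __post_init__(self) -> None:
        for name, weights in (("bpci", self.bpci_items), ("uici", self.uici_items), ("bps", self.bps_weights)):
            for item, w in weights.items():
                if not np.isfinite(w) or w < 0:
                    raise ConfigurationError(f"{name} weight for {item} must be finite and non-negative")
        if self.bpci_control_threshold > self.bpci_case_threshold:
            raise ConfigurationError("control threshold must not exceed case threshold")


@dataclass
class PopulationStats:
    """Per-item mean/sd and min/max of an analysis cohort.

    Used to z-scale items for the bladder-pain measure and unit-scale items
    for the myofascial measure.  ``min``/``max`` default to the theoretical
    item scale bounds so unit-scaled measures always span the full [0, 1]
    interval; observed ranges can be requested instead.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, use_observed_range: bool = False) -> "PopulationStats":
        cols = [c for c in df.columns if c in _BATTERY]
        mean = {c: float(df[c].mean()) for c in cols}
        sd = {c: float(df[c].std(ddof=1)) for c in cols}
        if use_observed_range:
            lo = {c: float(df[c].min()) for c in cols}
            hi = {c: float(df[c].max()) for c in cols}
        else:
            lo = {c: float(_BATTERY[c].scale_min) for c in cols}
            hi = {c: float(_BATTERY[c].scale_max) for c in cols}
        return cls(mean=mean, sd=sd, min=lo, max=hi)


# ---------------------------------------------------------------------------
# helpers


def _answers(resp) -> Mapping[str, float]:
    return resp.answers if isinstance(resp, QuestionnaireResponse) else resp


def _require(answers: Mapping[str, float], ids: list[str]) -> np.ndarray:
    missing = [i for i in ids if i not in answers or answers[i] is None or (
        isinstance(answers[i], float) and np.isnan(answers[i]))]
    if missing:
        raise ScoringError(f"missing item(s): {', '.join(missing)}")
    return np.asarray([float(answers[i]) for i in ids])


def validate_answers(answers: Mapping[str, float], require_complete: bool = True) -> None:
    """Check every answer against its item's declared range.

    With ``require_complete`` the full battery must be present.  Raises
    :class:`ValidationError` naming the offending item.
    """
    answers = _answers(answers)
    if require_complete:
        missing = [i for i in _BATTERY if i not in answers]
        if missing:
            raise ValidationError(f"incomplete battery, missing: {', '.join(missing)}")
    for item, value in answers.items():
        if item not in _BATTERY:
            continue
        d = _BATTERY[item]
        if not (d.scale_min <= value <= d.scale_max):
            raise ValidationError(
                f"item {item}: value {value} outside scale [{d.scale_min}, {d.scale_max}]"
            )


# ---------------------------------------------------------------------------
# subscale scoring


def score_ics_indices(resp) -> tuple[float, float, float]:
    """ICSI total (items 1-4), ICPI total (items 1-4) and their sum (OLS)."""
    a = _answers(resp)
    icsi = _require(a, [f"icsi_{i}" for i in range(1, 5)]).sum()
    icpi = _require(a, [f"icpi_{i}" for i in range(1, 5)]).sum()
    return float(icsi), float(icpi), float(icsi + icpi)


def score_oabq_sf(resp) -> float:
    """OAB-q SF symptom total: raw sum of items 2-6 and 8."""
    a = _answers(resp)
    return float(_require(a, [f"oabq_{i}" for i in (2, 3, 4, 5, 6, 8)]).sum())


_FGUPI_BINARIES = ["fgupi_1a", "fgupi_1b", "fgupi_1c", "fgupi_1d",
                   "fgupi_2a", "fgupi_2b", "fgupi_2c", "fgupi_2d"]


def score_fgupi(resp) -> tuple[float, float, float, float]:
    """fGUPI pain (items 1-4), urinary (5-6), bother (7-9) and total.

    The pain subscale sums the eight binary location/activity endorsements
    with the frequency (item 3) and severity (item 4) scores.
    """
    a = _answers(resp)
    binaries = _require(a, _FGUPI_BINARIES)
    if np.any((binaries < 0) | (binaries > 1)):
        bad = [i for i, v in zip(_FGUPI_BINARIES, binaries) if not 0 <= v <= 1]
        raise ValidationError(f"binary fGUPI item(s) outside [0, 1]: {', '.join(bad)}")
    pain = binaries.sum() + _require(a, ["fgupi_3", "fgupi_4"]).sum()
    urinary = _require(a, ["fgupi_5", "fgupi_6"]).sum()
    bother = _require(a, ["fgupi_7", "fgupi_8", "fgupi_9"]).sum()
    return float(pain), float(urinary), float(bother), float(pain + urinary + bother)


def score_pfdi(resp) -> tuple[float, float, float, float]:
    """POPDI-6, CRADI-8 and UDI-6 subscales (each 25 x mean item, 0-100) and total."""
    a = _answers(resp)
    vals = _require(a, [f"pfdi_{i:02d}" for i in range(1, 21)])
    if np.any((vals < 0) | (vals > 4)):
        bad = [f"pfdi_{i:02d}" for i, v in zip(range(1, 21), vals) if not 0 <= v <= 4]
        raise ValidationError(f"PFDI item(s) outside [0, 4]: {', '.join(bad)}")
    popdi6 = 25.0 * vals[0:6].mean()
    cradi8 = 25.0 * vals[6:14].mean()
    udi6 = 25.0 * vals[14:20].mean()
    return float(popdi6), float(cradi8), float(udi6), float(popdi6 + cradi8 + udi6)


# ---------------------------------------------------------------------------
# composite indices


def _weighted_sum(answers: Mapping[str, float], weights: dict[str, float], name: str) -> float:
    if not weights:
        raise ConfigurationError(f"{name}: empty item list")
    vals = _require(answers, list(weights))
    return float(np.dot(vals, np.asarray(list(weights.values()))))


def compute_bpci(resp, cfg: CompositeConfig | None = None) -> tuple[float, str]:
    """Bladder pain composite index and its case/control/indeterminate call.

    Classification: ``case`` iff score > case threshold (default 4),
    ``control`` iff score < control threshold (default 3), otherwise
    ``indeterminate`` (excluded from both arms).
    """
    cfg = cfg or CompositeConfig()
    score = _weighted_sum(_answers(resp), cfg.bpci_items, "bpci")
    if score > cfg.bpci_case_threshold:
        cls = "case"
    elif score < cfg.bpci_control_threshold:
        cls = "control"
    else:
        cls = "indeterminate"
    return score, cls


def compute_uici(resp, cfg: CompositeConfig | None = None) -> float:
    """Urge incontinence composite index (weighted sum of configured items)."""
    cfg = cfg or CompositeConfig()
    return _weighted_sum(_answers(resp), cfg.uici_items, "uici")


def compute_phenotype_measures(
    resp, population_stats: PopulationStats, cfg: CompositeConfig | None = None
) -> tuple[float, float, float]:
    """The three per-subject symptom-domain measures.

    * bladder-pain measure (BPS): weighted mean of the z-scored bladder-pain
      items (ICSI4, pain-with-filling, urinary-frequency);
    * non-urologic pelvic pain measure (NUPP): count of endorsed pain
      locations/activities (introitus, vagina, urethra, dysuria,
      dyspareunia), range 0-5;
    * myofascial measure (MFP): mean of the unit-scaled incomplete-emptying,
      abdominal-pressure and defecatory-straining items, range 0-1.
    """
    cfg = cfg or CompositeConfig()
    a = _answers(resp)

    total_w = sum(cfg.bps_weights.values())
    if total_w <= 0:
        raise ConfigurationError("bps weights sum to zero")
    z_terms = []
    for item, w in cfg.bps_weights.items():
        sd = population_stats.sd.get(item, 0.0)
        if sd == 0:
            raise DegenerateFeatureError(f"zero SD for z-scored item {item}")
        z_terms.append(w * (float(_require(a, [item])[0]) - population_stats.mean[item]) / sd)
    bps = float(np.sum(z_terms) / total_w)

    nupp = float(_require(a, list(cfg.nupp_items)).sum())

    scaled = []
    for item in cfg.mfp_items:
        lo, hi = population_stats.min[item], population_stats.max[item]
        if hi <= lo:
            raise DegenerateFeatureError(f"degenerate range for unit-scaled item {item}")
        scaled.append((float(_require(a, [item])[0]) - lo) / (hi - lo))
    mfp = float(np.mean(scaled))
    return bps, nupp, mfp


# ---------------------------------------------------------------------------
# whole-profile scoring


def score_profile(
    resp: QuestionnaireResponse,
    cfg: CompositeConfig | None = None,
    population_stats: PopulationStats | None = None,
) -> ScoredProfile:
    """Score every subscale and composite for one subject.

    The three phenotype measures need cohort-level statistics and are left
    ``None`` unless ``population_stats`` is given.
    """
    cfg = cfg or CompositeConfig()
    icsi, icpi, ols = score_ics_indices(resp)
    oabq = score_oabq_sf(resp)
    pain, urinary, bother, ftotal = score_fgupi(resp)
    popdi6, cradi8, udi6, ptotal = score_pfdi(resp)
    bpci, bpci_class = compute_bpci(resp, cfg)
    uici = compute_uici(resp, cfg)
    bps = nupp = mfp = None
    if population_stats is not None:
        bps, nupp, mfp = compute_phenotype_measures(resp, population_stats, cfg)
    return ScoredProfile(
        subject_id=resp.subject_id,
        icsi_total=icsi, icpi_total=icpi, ols_total=ols,
        oabq_sf_total=oabq,
        fgupi_pain=pain, fgupi_urinary=urinary, fgupi_bother=bother, fgupi_total=ftotal,
        popdi6=popdi6, cradi8=cradi8, udi6=udi6, pfdi_total=ptotal,
        bpci=bpci, bpci_class=bpci_class, uici=uici,
        bps_measure=bps, nupp_measure=nupp, mfp_measure=mfp,
    )


def score_dataframe(
    df: pd.DataFrame,
    cfg: CompositeConfig | None = None,
    with_measures: bool = False,
) -> pd.DataFrame:
    """Score a cohort table (one row per subject, item columns per schema).

    With ``with_measures`` the cohort itself supplies the population
    statistics for the bladder-pain z-scaling.
    """
    cfg = cfg or CompositeConfig()
    stats = PopulationStats.from_frame(df) if with_measures else None
    rows = []
    for _, row in df.iterrows():
        resp = QuestionnaireResponse(
            subject_id=str(row.get("subject_id", row.name)),
            answers={c: row[c] for c in df.columns if c in _BATTERY},
        )
        rows.append(score_profile(resp, cfg, stats).__dict__)
    return pd.DataFrame(rows)


def add_phenotype_measures(
    df: pd.DataFrame,
    population_stats: PopulationStats | None = None,
    cfg: CompositeConfig | None = None,
) -> pd.DataFrame:
    """Return ``df`` with bps/nupp/mfp measure columns appended."""
    cfg = cfg or CompositeConfig()
    stats = population_stats or PopulationStats.from_frame(df)
    out = df.copy()
    vals = [
        compute_phenotype_measures({c: row[c] for c in df.columns if c in _BATTERY}, stats, cfg)
        for _, row in df.iterrows()
    ]
    arr = np.asarray(vals)
    out["bps_measure"], out["nupp_measure"], out["mfp_measure"] = arr[:, 0], arr[:, 1], arr[:, 2]
    return out
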