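"""Normative cohort screening: instrument classifiers and exclusion rules.

A subject enters the normative database only after passing four gates:
pre-screening history, cognitive function, emotional function, and (for
minors) a behavioral expert evaluation.  Instruments and cut-offs depend on
the subject's age group:

* infants (4-6 y): K-WPPSI (5 subtests + digit span), K-CBCL 1.5-5
* children/adolescents (7-19 y): CNSVS, STAI-KYZ, CDI, K-CBCL 6-18
* Adult 1 (20-49 y): CNSVS, STAI-KYZ, BDI
* Adult 2 (>= 50 y): CNSVS + MMSE, STAI-KYZ, BDI

Cognitive exclusion: any required test below the 2nd percentile, or three
or more below the 7th.  Emotional exclusion: any subdomain high-risk, or two
or more at-risk (infants: K-CBCL depression/anxiety percentile > 98).
Raw scores on the IQ-style instruments are mapped to percentiles through a
normal distribution with mean 100 and SD 15; the MMSE has no printed
percentile scale and participates only in the <7% tally through its
raw-score-25 anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from scipy.stats import norm

__all__ = [
    "ScreeningScores",
    "ScreeningResult",
    "IncompleteRecordError",
    "assign_age_group",
    "classify_kwppsi",
    "classify_cnsvs",
    "classify_mmse",
    "classify_stai",
    "classify_cdi",
    "classify_bdi",
    "classify_kcbcl",
    "cognitive_exclusion",
    "emotional_exclusion",
    "behavioral_exclusion",
    "screen_subject",
    "percentile_from_raw",
    "raw_from_percentile",
]

KWPPSI_TESTS = ("block", "maze", "picture", "vocabulary", "similarity", "digit_span")
CNSVS_TESTS = (
    "symbol_digit_coding",
    "reasoning",
    "shift_attention",
    "verbal_memory",
    "visual_memory",
)

AGE_GROUPS = ("infant", "child", "adult1", "adult2")


class IncompleteRecordError(ValueError):
    """A required instrument score is missing from a screening record."""


@dataclass(frozen=True)
class ScreeningScores:
    """Raw screening-instrument scores for one subject.

    Instruments not administered to the subject's age group may be ``None``
    (or empty mappings); the exclusion rules raise
    :class:`IncompleteRecordError` if a *required* instrument is missing.
    """

    kwppsi: Mapping[str, float] = field(default_factory=dict)
    cnsvs: Mapping[str, float] = field(default_factory=dict)
    mmse: Optional[int] = None
    stai_state: Optional[float] = None
    stai_trait: Optional[float] = None
    cdi: Optional[float] = None
    bdi: Optional[float] = None
    kcbcl_depression_pct: Optional[float] = None
    kcbcl_anxiety_pct: Optional[float] = None
    behavioral_expert_pass: Optional[bool] = None
    history_flags: frozenset = frozenset()


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the four-gate normative screening for one subject."""

    age_group: str
    categories: Mapping[str, str]
    prescreen_excluded: bool
    cognitive_excluded: bool
    emotional_excluded: bool
    behavioral_excluded: bool

    @property
    def eligible(self) -> bool:
        return not (
            self.prescreen_excluded
            or self.cognitive_excluded
            or self.emotional_excluded
            or self.behavioral_excluded
        )


def percentile_from_raw(raw: float, mean: float = 100.0, sd: float = 15.0) -> float:
    """Percentile (0-100) of an IQ-style raw score under N(mean, sd)."""
    return 100.0 * float(norm.cdf((raw - mean) / sd))


def raw_from_percentile(pct: float, mean: float = 100.0, sd: float = 15.0) -> float:
    """Inverse of :func:`percentile_from_raw`."""
    return mean + sd * float(norm.ppf(pct / 100.0))


def assign_age_group(age: float) -> str:
    """Map a continuous age (years) to the protocol age group.

    Boundaries are half-open: [4, 7) infant, [7, 20) child, [20, 50)
    Adult 1, [50, inf) Adult 2.  Ages below 4 are outside the protocol.
    """
    if age < 4:
        raise ValueError(f"age {age} is below the protocol minimum of 4 years")
    if age < 7:
        return "infant"
    if age < 20:
        return "child"
    if age < 50:
        return "adult1"
    return "adult2"


def classify_kwppsi(score: float) -> str:
    """K-WPPSI subtest category from the raw (standard) score."""
    if score < 0:
        raise ValueError(f"K-WPPSI score must be non-negative, got {score}")
    if score <= 69:
        return "Extremely Low"
    if score <= 79:
        return "Borderline"
    if score <= 89:
        return "Low Average"
    if score <= 109:
        return "Average"
    if score <= 119:
        return "High Average"
    if score <= 129:
        return "Superior"
    return "Very Superior"


def classify_cnsvs(raw: float) -> str:
    """CNSVS test category from the raw (standard) score."""
    if raw < 0:
        raise ValueError(f"CNSVS score must be non-negative, got {raw}")
    if raw >= 109:
        return "Above Average"
    if raw >= 90:
        return "Average"
    if raw >= 80:
        return "Low Average"
    if raw >= 70:
        return "Low"
    return "Very Low"


def classify_mmse(score: int) -> str:
    """MMSE category; scores 24-30 Normal down to <=9 Severe Dementia."""
    if not 0 <= score <= 30:
        raise ValueError(f"MMSE score must be in [0, 30], got {score}")
    if score >= 24:
        return "Normal"
    if score >= 20:
        return "Mild Dementia"
    if score >= 10:
        return "Moderate Dementia"
    return "Severe Dementia"


# STAI-KYZ cut-offs by (subscale, sex): per age bracket [7,20), [20,30), >=30,
# the lowest risk-band score and the lowest high-risk score.
_STAI_TABLE: dict[tuple[str, str], tuple[tuple[int, int], ...]] = {
    ("state", "male"): ((59, 64), (58, 63), (56, 61)),
    ("state", "female"): ((62, 67), (62, 67), (56, 61)),
    ("trait", "male"): ((63, 68), (58, 63), (60, 65)),
    ("trait", "female"): ((65, 70), (62, 67), (60, 65)),
}


def classify_stai(score: float, subscale: str, age: float, sex: str) -> str:
    """STAI-KYZ anxiety category: normal / risk / high-risk.

    Cut-offs depend on subscale (state or trait anxiety), sex, and the age
    bracket [7, 20), [20, 30) or >= 30 years.
    """
    if subscale not in ("state", "trait"):
        raise ValueError(f"subscale must be 'state' or 'trait', got {subscale!r}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if age < 7:
        raise ValueError("STAI-KYZ classification is defined for ages >= 7")
    if not 0 <= score <= 80:
        raise ValueError(f"STAI score must be in [0, 80], got {score}")
    bracket = 0 if age < 20 else (1 if age < 30 else 2)
    risk_low, high_low = _STAI_TABLE[(subscale, sex)][bracket]
    if score >= high_low:
        return "high-risk"
    if score >= risk_low:
        return "risk"
    return "normal"


def classify_cdi(score: float) -> str:
    """CDI depression category (children); maximum score 54."""
    if not 0 <= score <= 54:
        raise ValueError(f"CDI score must be in [0, 54], got {score}")
    if score <= 21:
        return "Normal"
    if score <= 25:
        return "Mild"
    if score <= 28:
        return "Risk"
    return "High-risk"


def classify_bdi(score: float) -> str:
    """BDI depression category (adults); maximum score 63."""
    if not 0 <= score <= 63:
        raise ValueError(f"BDI score must be in [0, 63], got {score}")
    if score <= 9:
        return "Normal"
    if score <= 15:
        return "Mild"
    if score <= 23:
        return "Risk"
    return "High-risk"


def classify_kcbcl(percentile: float) -> str:
    """K-CBCL syndrome-scale category from a percentile score."""
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    if percentile > 98:
        return "Clinical Range"
    if percentile >= 93:
        return "Borderline Clinical Range"
    return "Normal range"


def _require(value, instrument: str):
    if value is None:
        raise IncompleteRecordError(f"missing required instrument: {instrument}")
    return value


def _cognitive_percentiles(scores: ScreeningScores, age_group: str) -> list[float]:
    """Percentiles of the age group's required cognitive tests (MMSE excluded)."""
    if age_group == "infant":
        pcts = []
        for test in KWPPSI_TESTS:
            if test not in scores.kwppsi:
                raise IncompleteRecordError(f"missing required instrument: K-WPPSI {test}")
            pcts.append(percentile_from_raw(scores.kwppsi[test]))
        return pcts
    pcts = []
    for test in CNSVS_TESTS:
        if test not in scores.cnsvs:
            raise IncompleteRecordError(f"missing required instrument: CNSVS {test}")
        pcts.append(percentile_from_raw(scores.cnsvs[test]))
    return pcts


def cognitive_exclusion(scores: ScreeningScores, age_group: str) -> bool:
    """Cognitive-function exclusion rule.

    Excluded iff any required test falls below the 2nd percentile, or three
    or more fall below the 7th.  For Adult 2 the MMSE joins the required set:
    a raw score below 25 (the printed 7th-percentile anchor) counts toward
    the <7% tally.
    """
    pcts = _cognitive_percentiles(scores, age_group)
    below2 = sum(p < 2.0 for p in pcts)
    below7 = sum(p < 7.0 for p in pcts)
    if age_group == "adult2":
        mmse = _require(scores.mmse, "MMSE")
        classify_mmse(mmse)  # validate range
        if mmse < 25:
            below7 += 1
    return below2 >= 1 or below7 >= 3


def emotional_exclusion(scores: ScreeningScores, age_group: str, age: float | None = None,
                        sex: str | None = None) -> bool:
    """Emotional-function exclusion rule.

    Infants: excluded iff K-CBCL depression or anxiety percentile > 98.
    Older groups: three subdomains (STAI state, STAI trait, CDI for children /
    BDI for adults); excluded iff any is high-risk or two or more are at-risk.
    """
    if age_group == "infant":
        dep = _require(scores.kcbcl_depression_pct, "K-CBCL depression percentile")
        anx = _require(scores.kcbcl_anxiety_pct, "K-CBCL anxiety percentile")
        return dep > 98 or anx > 98

    if age is None or sex is None:
        raise IncompleteRecordError("age and sex are required for STAI classification")
    state = classify_stai(_require(scores.stai_state, "STAI state"), "state", age, sex)
    trait = classify_stai(_require(scores.stai_trait, "STAI trait"), "trait", age, sex)
    if age_group == "child":
        dep = classify_cdi(_require(scores.cdi, "CDI"))
    else:
        dep = classify_bdi(_require(scores.bdi, "BDI"))

    high = {"high-risk", "High-risk"}
    at_risk = {"risk", "Risk"}
    levels = (state, trait, dep)
    n_high = sum(lv in high for lv in levels)
    n_risk = sum(lv in at_risk for lv in levels)
    return n_high >= 1 or n_risk >= 2


def behavioral_exclusion(scores: ScreeningScores, age_group: str) -> bool:
    """Behavioral gate: K-CBCL expert evaluation for minors, vacuous for adults."""
    if age_group in ("infant", "child"):
        verdict = _require(scores.behavioral_expert_pass, "K-CBCL expert evaluation")
        return not verdict
    return False


def screen_subject(subject) -> ScreeningResult:
    """Run the full four-gate screening on a subject.

    *subject* needs ``age``, ``sex`` and ``screening`` attributes (any
    object will do, e.g. :class:`qeegnorm.synthetic.Subject`).  The verdict
    is a pure function of those inputs.
    """
    age = subject.age
    sex = subject.sex
    scores: ScreeningScores = subject.screening
    group = assign_age_group(age)

    prescreen = bool(scores.history_flags)
    cognitive = cognitive_exclusion(scores, group)
    emotional = emotional_exclusion(scores, group, age=age, sex=sex)
    behavioral = behavioral_exclusion(scores, group)

    categories: dict[str, str] = {}
    if group == "infant":
        for test, raw in scores.kwppsi.items():
            categories[f"kwppsi_{test}"] = classify_kwppsi(raw)
        if scores.kcbcl_depression_pct is not None:
            categories["kcbcl_depression"] = classify_kcbcl(scores.kcbcl_depression_pct)
        if scores.kcbcl_anxiety_pct is not None:
            categories["kcbcl_anxiety"] = classify_kcbcl(scores.kcbcl_anxiety_pct)
    else:
        for test, raw in scores.cnsvs.items():
            categories[f"cnsvs_{test}"] = classify_cnsvs(raw)
        if scores.stai_state is not None:
            categories["stai_state"] = classify_stai(scores.stai_state, "state", age, sex)
        if scores.stai_trait is not None:
            categories["stai_trait"] = classify_stai(scores.stai_trait, "trait", age, sex)
        if group == "child" and scores.cdi is not None:
            categories["cdi"] = classify_cdi(scores.cdi)
        if group in ("adult1", "adult2") and scores.bdi is not None:
            categories["bdi"] = classify_bdi(scores.bdi)
        if group == "adult2" and scores.mmse is not None:
            categories["mmse"] = classify_mmse(scores.mmse)

    return ScreeningResult(
        age_group=group,
        categories=categories,
        prescreen_excluded=prescreen,
        cognitive_excluded=cognitive,
        emotional_excluded=emotional,
        behavioral_excluded=behavioral,
    )
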