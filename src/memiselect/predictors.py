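"""Canonical baseline-predictor schema for the two-arm trial.

The analysis operates on 17 baseline predictors measured before
randomization: sociodemographics (age, gender, ethnicity, education),
treatment credibility and expectancy, symptom severities (social anxiety,
depression [BDI-II], generalized anxiety [GADQ-IV]), clinician-diagnosed
depression/anxiety, current psychotherapy and psychotropic medication, and
trait measures (attentional control [ACS], emotion dysregulation [DERS],
mindfulness [FFMQ], perseverative cognition [PCQ], self-compassion [SCS]).

This module is the single source of truth for predictor names, kinds, and
the marginal distributions the synthetic generator emulates. Continuous
marginals use instrument-typical means/SDs; variables with a hard floor
(age >= 18, symptom scales >= 0, screener-eligible social-anxiety severity
>= 20) use a shifted-gamma parameterization so the configured mean and SD
hold exactly despite the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "PredictorSpec",
    "DEFAULT_PREDICTORS",
    "PREDICTOR_NAMES",
    "canonical_rank",
    "predictor_of_feature",
    "feature_groups",
    "spec_by_name",
]

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal description of one baseline predictor.

    ``floor`` switches the sampling distribution from normal to
    ``floor + Gamma(k, theta)`` with ``k``/``theta`` solved from
    ``mean``/``sd`` (right-skewed, bounded below, exact first two moments).
    """

    name: str
    kind: str
    mean: float | None = None
    sd: float | None = None
    floor: float | None = None
    p: float | None = None  # P(X=1) for binary predictors
    levels: tuple[str, ...] = field(default_factory=tuple)
    probs: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY, CATEGORICAL):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == CONTINUOUS and (self.mean is None or self.sd is None or self.sd <= 0):
            raise ValueError(f"{self.name}: continuous spec needs mean and positive sd")
        if self.kind == BINARY and not (self.p is not None and 0.0 <= self.p <= 1.0):
            raise ValueError(f"{self.name}: binary spec needs p in [0,1]")
        if self.kind == CATEGORICAL:
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise ValueError(f"{self.name}: categorical spec needs matching levels/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: level probabilities must sum to 1")


#: Default marginals. Sample-frame quantities (age, gender, ethnicity,
#: education, medication, psychotherapy) follow the trial's reported
#: demographics (N=191, mean age 21.84 SD 3.37, ~78% female, ~86% Chinese,
#: 5.24% on psychotropic medication, 15.71% in psychotherapy); the
#: remaining continuous instruments use values typical for treatment-seeking
#: socially anxious young adults on each scale.
DEFAULT_PREDICTORS: tuple[PredictorSpec, ...] = (
    PredictorSpec("age", CONTINUOUS, mean=21.84, sd=3.37, floor=18.0),
    PredictorSpec(
        "gender",
        CATEGORICAL,
        levels=("female", "male", "other"),
        probs=(0.7801, 0.2147, 0.0052),
    ),
    PredictorSpec(
        "ethnicity",
        CATEGORICAL,
        levels=("chinese", "malay", "indian", "other"),
        probs=(0.8639, 0.0209, 0.0628, 0.0524),
    ),
    PredictorSpec(
        "education",
        CATEGORICAL,
        levels=("junior_college", "diploma", "university", "graduate"),
        probs=(0.7592, 0.0628, 0.1414, 0.0366),
    ),
    PredictorSpec("treatment_credibility", CONTINUOUS, mean=18.2, sd=4.1),
    PredictorSpec("treatment_expectancy", CONTINUOUS, mean=15.6, sd=4.8),
    PredictorSpec("sad_severity", CONTINUOUS, mean=34.5, sd=8.9, floor=20.0),
    PredictorSpec("depression_severity", CONTINUOUS, mean=18.9, sd=9.7, floor=0.0),
    PredictorSpec("gad_severity", CONTINUOUS, mean=6.9, sd=2.8, floor=0.0),
    PredictorSpec("dx_depression_anxiety", BINARY, p=0.22),
    PredictorSpec("current_psychotherapy", BINARY, p=0.1571),
    PredictorSpec("psychotropic_medication", BINARY, p=0.0524),
    PredictorSpec("attentional_control", CONTINUOUS, mean=47.3, sd=8.6),
    PredictorSpec("emotion_dysregulation", CONTINUOUS, mean=98.4, sd=21.7),
    PredictorSpec("trait_mindfulness", CONTINUOUS, mean=114.8, sd=16.2),
    PredictorSpec("perseverative_cognition", CONTINUOUS, mean=44.6, sd=11.3),
    PredictorSpec("self_compassion", CONTINUOUS, mean=2.71, sd=0.58),
)

PREDICTOR_NAMES: tuple[str, ...] = tuple(s.name for s in DEFAULT_PREDICTORS)

_RANK = {name: i for i, name in enumerate(PREDICTOR_NAMES)}


def spec_by_name(specs: Sequence[PredictorSpec] | None = None) -> dict[str, PredictorSpec]:
    specs = DEFAULT_PREDICTORS if specs is None else specs
    return {s.name: s for s in specs}


def canonical_rank(name: str) -> tuple[int, str]:
    """Sort key implementing the canonical predictor-name tie-break order."""
    return (_RANK.get(name, len(_RANK)), name)


def predictor_of_feature(feature: str) -> str:
    """Map an encoded feature column (``ethnicity=chinese``) to its predictor."""
    return feature.split("=", 1)[0]


def feature_groups(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group encoded feature columns by originating predictor, in column order."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        groups.setdefault(predictor_of_feature(col), []).append(col)
    return groups
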