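"""Seeded synthetic two-arm randomized trial generator.

Emulates a 191-participant trial of a mindfulness ecological momentary
intervention (arm 1, "MEMI") against a self-monitoring app (arm 0, "SM")
for social anxiety disorder: permuted-block randomization with block sizes
(2, 4, 6), 17 baseline predictors with realistic marginals, remission
outcomes at posttreatment and one-month follow-up generated from a logistic
model with configurable arm-by-predictor interactions (the planted
treatment-effect moderators), severity scores back-filled around the
remission cutoff, prompt-completion counts, and an exact-count MCAR/MAR
missingness mask.

The generator keeps the latent truth (counterfactual remission
probabilities under both arms and the individual treatment effect,
``true_ite = p_arm1 - p_arm0``) in a sidecar so that downstream stages can
be validated by parameter recovery; real datasets carry no such truth.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import derive_seed, rng_for
from .predictors import (
    BINARY,
    CONTINUOUS,
    DEFAULT_PREDICTORS,
    PREDICTOR_NAMES,
    PredictorSpec,
    spec_by_name,
)

__all__ = [
    "OutcomeModel",
    "GeneratorConfig",
    "TrialDataset",
    "permuted_block_randomize",
    "generate_trial",
    "apply_missingness",
]

REMISSION_CUTOFF = 12.13
TIME_POINTS = ("post", "1mfu")

#: Default planted moderators (arm-by-predictor interaction weights on the
#: log-odds scale, per standardized predictor unit). Higher trait
#: mindfulness and generalized-anxiety severity, and lower social-anxiety
#: severity, tilt the remission odds toward the momentary-mindfulness arm.
DEFAULT_MODERATORS: dict[str, float] = {
    "trait_mindfulness": 1.5,
    "gad_severity": 1.5,
    "sad_severity": -1.5,
}

#: Default prognostic main effects (shared across arms).
DEFAULT_MAIN_EFFECTS: dict[str, float] = {
    "sad_severity": -0.8,
    "depression_severity": -0.3,
    "trait_mindfulness": 0.4,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic remission model on the log-odds scale.

    ``logit P(remit) = a_t + x'beta + arm * (tau + x'gamma)`` where ``x``
    holds standardized predictor values, ``beta`` the main effects,
    ``gamma`` the moderators, and the per-time-point intercept ``a_t`` is
    calibrated numerically so the marginal remission rate (averaged over a
    50/50 arm split) matches ``base_rate_*``. Severity scores are
    back-filled as ``cutoff -/+ gap`` for remitters/non-remitters with a
    positive half-normal gap, so the binary outcome and the severity score
    always agree about the remission cutoff.
    """

    base_rate_post: float = 0.18
    base_rate_1mfu: float = 0.26
    arm_effect: float = 0.0
    balance_arms: bool = True
    main_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MAIN_EFFECTS))
    moderators: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MODERATORS))
    gap_sd_remit: float = 4.0
    gap_sd_nonremit: float = 9.0

    def base_rate(self, time_point: str) -> float:
        return self.base_rate_post if time_point == "post" else self.base_rate_1mfu


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic trial draw."""

    n_participants: int = 191
    block_sizes: tuple[int, ...] = (2, 4, 6)
    predictor_specs: tuple[PredictorSpec, ...] = DEFAULT_PREDICTORS
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    missing_rate: float = 0.10
    missing_mechanism: str = "mcar"  # 'mcar' or 'mar'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.block_sizes or any(b <= 0 or b % 2 for b in self.block_sizes):
            raise ValueError("block_sizes must be nonempty, positive, and even")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        for spec in self.predictor_specs:
            spec.__post_init__()  # re-validate (cheap, keeps invariants loud)


@dataclass
class TrialDataset:
    """Participant-level trial table plus (optional) generator truth.

    ``df`` columns: ``participant_id``, ``arm`` (1=MEMI, 0=SM), the 17
    predictors, ``spdq_post``, ``spdq_1mfu``, ``prompts_completed``.
    ``truth`` (generated data only) holds the complete pre-mask predictor
    and outcome values plus counterfactual probabilities and true ITEs.
    """

    df: pd.DataFrame
    truth: pd.DataFrame | None = None
    config: GeneratorConfig | None = None

    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.df.columns if c in PREDICTOR_NAMES]

    def predictors(self) -> pd.DataFrame:
        return self.df[self.predictor_names]

    def outcome(self, time_point: str) -> pd.Series:
        return self.df[_outcome_column(time_point)]

    @property
    def n_masked_cells(self) -> int:
        cols = self.predictor_names + ["spdq_post", "spdq_1mfu"]
        return int(self.df[cols].isna().to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        """Write the participant table (missing cells as empty fields) plus
        a JSON sidecar with the config, seed, and latent truth."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar: dict = {}
        if self.config is not None:
            sidecar["config"] = _config_to_jsonable(self.config)
            sidecar["seed"] = self.config.seed
        if self.truth is not None:
            buf = io.StringIO()
            self.truth.to_csv(buf, index=False)
            sidecar["truth_csv"] = buf.getvalue()
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialDataset":
        path = Path(path)
        df = pd.read_csv(path)
        truth = None
        config = None
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            if "truth_csv" in sidecar:
                truth = pd.read_csv(io.StringIO(sidecar["truth_csv"]))
            if "config" in sidecar:
                config = _config_from_jsonable(sidecar["config"])
        return cls(df=df, truth=truth, config=config)


def _outcome_column(time_point: str) -> str:
    if time_point not in TIME_POINTS:
        raise ValueError(f"time_point must be one of {TIME_POINTS}, got {time_point!r}")
    return f"spdq_{time_point}"


# ---------------------------------------------------------------------------
# randomization


def permuted_block_randomize(
    n: int, block_sizes: Sequence[int] = (2, 4, 6), seed: int = 0
) -> np.ndarray:
    """Permuted-block arm assignment (1=MEMI, 0=SM).

    Block sizes are drawn uniformly with replacement; each complete block
    allocates exactly half of its slots to each arm in a uniformly shuffled
    order, and a final partial block is a shuffled prefix of a balanced
    block — so the cumulative arm imbalance never exceeds half the largest
    block size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    block_sizes = tuple(int(b) for b in block_sizes)
    if not block_sizes or any(b <= 0 or b % 2 for b in block_sizes):
        raise ValueError("block sizes must be positive even integers")
    rng = rng_for(seed, "blocks")
    out: list[np.ndarray] = []
    total = 0
    while total < n:
        size = int(rng.choice(block_sizes))
        block = np.repeat([1, 0], size // 2)
        rng.shuffle(block)
        out.append(block)
        total += size
    return np.concatenate(out)[:n].astype(np.int64)


# ---------------------------------------------------------------------------
# predictors


def _draw_predictors(specs: Sequence[PredictorSpec], n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray | pd.Series] = {}
    for spec in specs:
        if spec.kind == CONTINUOUS:
            if spec.floor is not None:
                mu = spec.mean - spec.floor
                k = (mu / spec.sd) ** 2
                theta = spec.sd**2 / mu
                cols[spec.name] = spec.floor + rng.gamma(k, theta, size=n)
            else:
                cols[spec.name] = rng.normal(spec.mean, spec.sd, size=n)
        elif spec.kind == BINARY:
            cols[spec.name] = (rng.random(n) < spec.p).astype(np.int64)
        else:
            cols[spec.name] = pd.Series(
                rng.choice(spec.levels, size=n, p=spec.probs), dtype="object"
            )
    return pd.DataFrame(cols)


def _standardized_value(spec: PredictorSpec, values: pd.Series, weight_key: str) -> np.ndarray:
    """Standardized model input for an outcome-model weight key.

    Continuous: (x - mean)/sd. Binary: (x - p)/sqrt(p(1-p)). Categorical
    keys name a level (``ethnicity=chinese``) and use the centered,
    scaled level indicator.
    """
    if spec.kind == CONTINUOUS:
        return (values.to_numpy(dtype=float) - spec.mean) / spec.sd
    if spec.kind == BINARY:
        scale = np.sqrt(spec.p * (1.0 - spec.p)) if 0 < spec.p < 1 else 1.0
        return (values.to_numpy(dtype=float) - spec.p) / scale
    _, level = weight_key.split("=", 1)
    if level not in spec.levels:
        raise ValueError(f"unknown level {level!r} for predictor {spec.name!r}")
    p = spec.probs[spec.levels.index(level)]
    scale = np.sqrt(p * (1.0 - p)) if 0 < p < 1 else 1.0
    return ((values.to_numpy() == level).astype(float) - p) / scale


def _linear_terms(
    predictors: pd.DataFrame,
    specs: Mapping[str, PredictorSpec],
    weights: Mapping[str, float],
) -> np.ndarray:
    out = np.zeros(len(predictors))
    for key, w in weights.items():
        name = key.split("=", 1)[0]
        if name not in specs:
            raise ValueError(f"outcome-model weight refers to unknown predictor {name!r}")
        out += w * _standardized_value(specs[name], predictors[name], key)
    return out


def _calibrate_intercept(
    model: OutcomeModel,
    specs: Sequence[PredictorSpec],
    time_point: str,
    n_mc: int = 100_000,
) -> tuple[float, float]:
    """Solve the intercept (and, when arms are balanced, the arm offset)
    so the configured base rate holds, by Monte Carlo root finding on an
    internal fixed stream (independent of the user seed).

    With ``balance_arms`` (the default) both arms' expected remission
    rates equal the base rate — emulating a trial whose average
    between-arm effect is null even though moderators redistribute who
    benefits; the nonlinearity of the logistic link would otherwise let
    symmetric interaction weights shift one arm's mean rate. Returns
    ``(intercept, arm_offset)``.
    """
    rng = np.random.default_rng(20240917)
    sample = _draw_predictors(specs, n_mc, rng)
    spec_map = spec_by_name(specs)
    main = _linear_terms(sample, spec_map, model.main_effects)
    mod = _linear_terms(sample, spec_map, model.moderators)
    target = model.base_rate(time_point)

    if model.balance_arms:
        a = float(brentq(lambda a: expit(a + main).mean() - target, -30.0, 30.0, xtol=1e-10))
        tau = float(
            brentq(lambda t: expit(a + main + t + mod).mean() - target, -30.0, 30.0, xtol=1e-10)
        )
        return a, tau

    def gap(a: float) -> float:
        p0 = expit(a + main)
        p1 = expit(a + main + model.arm_effect + mod)
        return 0.5 * (p0.mean() + p1.mean()) - target

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10)), model.arm_effect


# ---------------------------------------------------------------------------
# trial generation


def generate_trial(config: GeneratorConfig) -> TrialDataset:
    """Draw one synthetic trial.

    Predictors follow the configured marginals; arms come from permuted-
    block randomization; remission at each time point is Bernoulli under
    the logistic outcome model; severity scores are back-filled around the
    remission cutoff; the configured missingness is applied at the end.
    The latent truth (complete values, counterfactual probabilities, true
    ITEs) is stored untouched in ``truth``.
    """
    n = config.n_participants
    seed = config.seed
    arm = permuted_block_randomize(n, config.block_sizes, seed=derive_seed(seed, "arm"))
    predictors = _draw_predictors(config.predictor_specs, n, rng_for(seed, "predictors"))

    spec_map = spec_by_name(config.predictor_specs)
    model = config.outcome_model
    main = _linear_terms(predictors, spec_map, model.main_effects)
    mod = _linear_terms(predictors, spec_map, model.moderators)

    df = pd.DataFrame({"participant_id": [f"P{i:04d}" for i in range(n)], "arm": arm})
    df = pd.concat([df, predictors], axis=1)

    truth_cols: dict[str, np.ndarray] = {"participant_id": df["participant_id"].to_numpy()}
    out_rng = rng_for(seed, "outcomes")
    for tp in TIME_POINTS:
        a, tau = _calibrate_intercept(model, config.predictor_specs, tp)
        p0 = expit(a + main)
        p1 = expit(a + main + tau + mod)
        p_own = np.where(arm == 1, p1, p0)
        remit = out_rng.random(n) < p_own
        gap_r = np.abs(out_rng.normal(0.0, model.gap_sd_remit, size=n)) + 0.01
        gap_n = np.abs(out_rng.normal(0.0, model.gap_sd_nonremit, size=n)) + 0.01
        spdq = np.where(remit, np.clip(REMISSION_CUTOFF - gap_r, 0.0, None), REMISSION_CUTOFF + gap_n)
        df[_outcome_column(tp)] = spdq
        truth_cols[f"p_memi_{tp}"] = p1
        truth_cols[f"p_sm_{tp}"] = p0
        truth_cols[f"true_ite_{tp}"] = p1 - p0
        truth_cols[f"spdq_{tp}"] = spdq

    # prompt completion: beta-binomial matched to ~85% mean, ~17% SD engagement
    eng_rng = rng_for(seed, "engagement")
    alpha, beta = _beta_params(0.853, 0.168)
    df["prompts_completed"] = eng_rng.binomial(70, eng_rng.beta(alpha, beta, size=n))

    truth = pd.DataFrame(truth_cols)
    for name in predictors.columns:  # complete pre-mask copies
        truth[name] = predictors[name].to_numpy()

    data = TrialDataset(df=df, truth=truth, config=config)
    if config.missing_rate > 0:
        data = apply_missingness(
            data,
            config.missing_rate,
            seed=derive_seed(seed, "missing"),
            mechanism=config.missing_mechanism,
        )
    return data


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(
    data: TrialDataset,
    rate: float,
    seed: int = 0,
    columns: Sequence[str] | None = None,
    mechanism: str = "mcar",
) -> TrialDataset:
    """Mask exactly ``round(rate * n_cells)`` analysis-matrix cells.

    The default analysis matrix is the 17 predictors plus the
    posttreatment severity score (18 columns — a 191-row trial therefore
    masks exactly 344 cells at rate 0.10). Arm assignment is never masked.
    ``mechanism='mar'`` tilts cell selection toward rows with higher
    observed generalized-anxiety severity.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if mechanism not in ("mcar", "mar"):
        raise ValueError("mechanism must be 'mcar' or 'mar'")
    df = data.df.copy()
    if columns is None:
        columns = data.predictor_names + ["spdq_post"]
    columns = list(columns)
    if "arm" in columns or "participant_id" in columns:
        raise ValueError("arm and participant_id can never be masked")
    n_rows = len(df)
    n_cells = n_rows * len(columns)
    n_mask = int(round(rate * n_cells))
    if n_mask == 0:
        return TrialDataset(df=df, truth=data.truth, config=data.config)

    rng = rng_for(seed, "mask")
    if mechanism == "mcar":
        flat = rng.choice(n_cells, size=n_mask, replace=False)
    else:
        gad = df["gad_severity"].to_numpy(dtype=float)
        gad = np.nan_to_num(gad, nan=np.nanmean(gad))
        row_w = np.exp((gad - gad.mean()) / (gad.std() + 1e-12))
        w = np.repeat(row_w, len(columns))
        flat = rng.choice(n_cells, size=n_mask, replace=False, p=w / w.sum())
    rows, cols = np.unravel_index(flat, (n_rows, len(columns)))
    for j, col in enumerate(columns):
        idx = rows[cols == j]
        if len(idx):
            if df[col].dtype == np.int64:
                df[col] = df[col].astype(float)
            df.iloc[idx, df.columns.get_loc(col)] = np.nan
    return TrialDataset(df=df, truth=data.truth, config=data.config)


# ---------------------------------------------------------------------------
# config (de)serialization


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["predictor_specs"] = [asdict(s) for s in config.predictor_specs]
    return d


def _config_from_jsonable(d: dict) -> GeneratorConfig:
    d = dict(d)
    specs = tuple(
        PredictorSpec(
            name=s["name"],
            kind=s["kind"],
            mean=s.get("mean"),
            sd=s.get("sd"),
            floor=s.get("floor"),
            p=s.get("p"),
            levels=tuple(s.get("levels") or ()),
            probs=tuple(s.get("probs") or ()),
        )
        for s in d.pop("predictor_specs")
    )
    om = d.pop("outcome_model")
    model = OutcomeModel(
        base_rate_post=om["base_rate_post"],
        base_rate_1mfu=om["base_rate_1mfu"],
        arm_effect=om["arm_effect"],
        main_effects=dict(om["main_effects"]),
        moderators=dict(om["moderators"]),
        gap_sd_remit=om["gap_sd_remit"],
        gap_sd_nonremit=om["gap_sd_nonremit"],
    )
    d["block_sizes"] = tuple(d["block_sizes"])
    return GeneratorConfig(predictor_specs=specs, outcome_model=model, **d)
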