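"""T-learner counterfactual estimation of per-person remission probabilities.

Separate outcome models are fitted to each arm (random forests by
default); every participant then receives two probabilities — remission
under the momentary-mindfulness arm (``p_memi``) and under self-monitoring
(``p_sm``). The same-arm probability comes from within-arm k-fold
cross-fitting (the model that predicts a participant never saw them),
while the counterfactual arm's probability comes from the full other-arm
model, which never contains the participant by construction. The
individual treatment effect is ``ite = p_memi - p_sm`` and the
"optimized to MEMI" label is 1 exactly when ``p_memi > p_sm`` (strictly;
ties label 0).

Preprocessing (imputation, standardization, encoding) is refitted inside
every cross-fit training split so that no held-out row leaks into fitted
state. Per-arm seeds are derived from the participant-id set of the arm,
which makes the estimator antisymmetric: relabelling the arms swaps the
two fitted models exactly and negates every ITE.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed
from .fold_preprocess import rf_impute_fit, standardize_and_encode
from .synthetic_rct import TrialDataset, _outcome_column
from .trial_stats import classify_remission

__all__ = ["TLearnerResult", "fit_arm_models", "label_optimization", "recovery_report"]


def _default_learner(seed: int, n_estimators: int = 500):
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


@dataclass
class TLearnerResult:
    """Counterfactual estimates plus audit bookkeeping.

    ``estimates`` columns: participant_id, arm, p_memi, p_sm, ite,
    optimized, time_point. ``crossfit_audit`` maps each participant to the
    training-row ids of the model that produced their same-arm
    prediction, for leakage audits.
    """

    estimates: pd.DataFrame
    time_point: str
    full_models: dict[int, object] = field(default_factory=dict)
    crossfit_audit: dict[str, frozenset] = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.estimates.set_index("participant_id")["optimized"]


def label_optimization(p_memi, p_sm) -> pd.DataFrame:
    """ITE and strict optimization label from paired probabilities."""
    p1 = np.asarray(p_memi, dtype=float)
    p0 = np.asarray(p_sm, dtype=float)
    if p1.shape != p0.shape:
        raise ValueError("p_memi and p_sm must be paired")
    for name, p in (("p_memi", p1), ("p_sm", p0)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    ite = p1 - p0
    return pd.DataFrame(
        {"p_memi": p1, "p_sm": p0, "ite": ite, "optimized": (ite > 0).astype(np.int64)}
    )


def _arm_seed(master: int, ids: pd.Series) -> int:
    """Seed derived from the arm's participant-id set (order invariant)."""
    tag = zlib.crc32(",".join(sorted(map(str, ids))).encode())
    return derive_seed(master, "armset", tag)


def fit_arm_models(
    data: TrialDataset,
    time_point: str = "post",
    n_splits: int = 10,
    n_estimators: int = 500,
    seed: int = 0,
    learner_factory=None,
    impute_max_iter: int = 2,
    impute_trees: int = 30,
) -> TLearnerResult:
    """Fit the two arm-specific outcome models and cross-fit predictions.

    Rows with a missing outcome at ``time_point`` are excluded from model
    training (they still receive both counterfactual predictions, from the
    full arm models).
    """
    learner_factory = learner_factory or (
        lambda s: _default_learner(s, n_estimators=n_estimators)
    )
    df = data.df.reset_index(drop=True)
    predictors = df[data.predictor_names]
    outcome = classify_remission(df[_outcome_column(time_point)].to_numpy())
    arm = df["arm"].to_numpy()

    preds = {1: np.full(len(df), np.nan), 0: np.full(len(df), np.nan)}
    full_models: dict[int, object] = {}
    full_states: dict[int, object] = {}
    audit: dict[str, frozenset] = {}

    for a in (1, 0):
        own = np.flatnonzero(arm == a)
        labelled = own[~np.isnan(outcome[own])]
        y = outcome[labelled].astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"arm {a} contains a single outcome class; cannot fit an outcome model"
            )
        aseed = _arm_seed(seed, df.loc[own, "participant_id"])

        # full arm model: used for the other arm and for own unlabelled rows
        state = rf_impute_fit(
            predictors.iloc[labelled],
            seed=derive_seed(aseed, "full", "impute"),
            max_iter=impute_max_iter,
            n_estimators=impute_trees,
            partition_id=f"arm{a}-full",
        )
        X_full = standardize_and_encode(state, predictors.iloc[labelled])
        model = learner_factory(derive_seed(aseed, "full", "model"))
        model.fit(X_full.to_numpy(), y)
        full_models[a], full_states[a] = model, state

        # within-arm cross-fit for same-arm predictions
        k = min(n_splits, np.bincount(y).min())
        if k < 2:
            raise ValueError("too few outcome events in one arm for cross-fitting")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(aseed, "cf"))
        for f, (tr, te) in enumerate(skf.split(np.zeros((len(labelled), 1)), y)):
            tr_rows, te_rows = labelled[tr], labelled[te]
            st = rf_impute_fit(
                predictors.iloc[tr_rows],
                seed=derive_seed(aseed, "cf", f, "impute"),
                max_iter=impute_max_iter,
                n_estimators=impute_trees,
                partition_id=f"arm{a}-fold{f}",
            )
            Xtr = standardize_and_encode(st, predictors.iloc[tr_rows])
            Xte = standardize_and_encode(st, predictors.iloc[te_rows])
            m = learner_factory(derive_seed(aseed, "cf", f, "model"))
            m.fit(Xtr.to_numpy(), outcome[tr_rows].astype(int))
            preds[a][te_rows] = m.predict_proba(Xte.to_numpy())[:, 1]
            train_ids = frozenset(df.loc[tr_rows, "participant_id"])
            for pid in df.loc[te_rows, "participant_id"]:
                audit[pid] = train_ids

    # fill cross-arm predictions and own-arm unlabelled rows
    for a in (1, 0):
        rows = np.flatnonzero(np.isnan(preds[a]))
        if len(rows):
            X = standardize_and_encode(full_states[a], predictors.iloc[rows])
            preds[a][rows] = full_models[a].predict_proba(X.to_numpy())[:, 1]

    est = label_optimization(preds[1], preds[0])
    est.insert(0, "participant_id", df["participant_id"].to_numpy())
    est.insert(1, "arm", arm)
    est["time_point"] = time_point
    return TLearnerResult(
        estimates=est, time_point=time_point, full_models=full_models, crossfit_audit=audit
    )


def recovery_report(result: TLearnerResult | pd.DataFrame, data: TrialDataset) -> dict:
    """Sign-agreement and rank-correlation of estimated against true ITEs.

    Only meaningful for generated data; raises if the dataset carries no
    latent truth (real-data mode).
    """
    if data.truth is None:
        raise ValueError("dataset has no latent truth; recovery_report is for synthetic data")
    est = result.estimates if isinstance(result, TLearnerResult) else result
    tp = est["time_point"].iloc[0]
    merged = est.merge(
        data.truth[["participant_id", f"true_ite_{tp}"]], on="participant_id", validate="1:1"
    )
    true_ite = merged[f"true_ite_{tp}"].to_numpy()
    est_ite = merged["ite"].to_numpy()
    agree = float(np.mean((est_ite > 0) == (true_ite > 0)))
    from scipy.stats import spearmanr

    rho = spearmanr(est_ite, true_ite).statistic if np.std(true_ite) > 0 else np.nan
    return {
        "n": len(merged),
        "sign_agreement": agree,
        "spearman": float(rho) if rho == rho else float("nan"),
    }
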