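"""Elastic-net variable screening of the optimization label.

A penalized logistic regression (elastic-net penalty, mixing parameter
0.5, penalty strength tuned by inner cross-validated deviance) ranks the
original predictors by the largest absolute standardized coefficient
within each predictor's one-hot block, and keeps the top-k (default 10).
Run inside each outer training fold only; the reported final predictor
set is the modal top-k across folds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed
from .predictors import canonical_rank, feature_groups

__all__ = ["ScreeningResult", "elastic_net_screen", "modal_selection"]

DEFAULT_C_GRID = tuple(np.logspace(-3, 2, 11))


@dataclass
class ScreeningResult:
    """Ranked predictors with group-level importances and the top-k set."""

    ranking: list[str]
    importances: dict[str, float]
    selected: list[str]
    l1_ratio: float
    C: float
    all_zero: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "predictor": self.ranking,
                "importance": [self.importances[p] for p in self.ranking],
                "selected": [p in self.selected for p in self.ranking],
            }
        )


def elastic_net_screen(
    features: pd.DataFrame,
    labels,
    k: int = 10,
    alpha_mix: float = 0.5,
    Cs=DEFAULT_C_GRID,
    n_inner: int = 5,
    seed: int = 0,
    max_iter: int = 5000,
) -> ScreeningResult:
    """Screen standardized features down to the top-k original predictors.

    Group importance for a predictor is the maximum absolute coefficient
    over its indicator block, so a categorical predictor enters or leaves
    the selected set as a unit. Ties (including the fully shrunk fit where
    every coefficient is zero) break by canonical predictor-name order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = pd.DataFrame(features)
    groups = feature_groups(X.columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter at tiny C
        cv = StratifiedKFold(
            n_splits=n_inner, shuffle=True, random_state=derive_seed(seed, "screen")
        )
        fit = LogisticRegressionCV(
            Cs=list(Cs),
            penalty="elasticnet",
            solver="saga",
            l1_ratios=[alpha_mix],
            scoring="neg_log_loss",
            cv=cv,
            max_iter=max_iter,
            random_state=derive_seed(seed, "saga"),
            n_jobs=1,
        ).fit(X.to_numpy(), y)
    coefs = pd.Series(np.abs(fit.coef_.ravel()), index=X.columns)

    importances = {g: float(coefs[cols].max()) for g, cols in groups.items()}
    all_zero = all(v == 0.0 for v in importances.values())
    ranking = sorted(importances, key=lambda g: (-importances[g], canonical_rank(g)))
    selected = ranking[: min(k, len(ranking))]
    return ScreeningResult(
        ranking=ranking,
        importances=importances,
        selected=selected,
        l1_ratio=alpha_mix,
        C=float(np.atleast_1d(fit.C_)[0]),
        all_zero=all_zero,
    )


def modal_selection(results: list[ScreeningResult], k: int = 10) -> list[str]:
    """Final reported predictor set: modal top-k across outer folds.

    Predictors are ordered by how often they were selected, ties broken
    by mean importance, then canonical name order.
    """
    if not results:
        raise ValueError("no screening results to aggregate")
    counts: Counter = Counter()
    importance_sum: Counter = Counter()
    for r in results:
        counts.update(r.selected)
        for g, v in r.importances.items():
            importance_sum[g] += v
    pool = sorted(
        set().union(*(r.importances.keys() for r in results)),
        key=lambda g: (-counts[g], -importance_sum[g] / len(results), canonical_rank(g)),
    )
    return pool[:k]
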