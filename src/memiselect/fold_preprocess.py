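"""Fold-aware preprocessing fitted strictly on training partitions.

This layer owns leakage control for the nested cross-validation: repeated
stratified fold plans; iterative chained random-forest imputation
(missForest-style) fitted on a training partition and applied frozen to
held-out rows; standardization of continuous columns to the training mean
and SD; one-hot encoding against a training-level registry; and the SMOTE
variant used to rebalance training labels — the majority class is randomly
undersampled to the midpoint between the class counts, then the minority
class is augmented with convex combinations of minority nearest-neighbour
pairs until the configured target ratio holds exactly. Evaluation rows are
never rebalanced and never touch fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from ._utils import derive_seed, rng_for

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "PreprocessorState",
    "rf_impute_fit",
    "standardize_and_encode",
    "RebalancedSample",
    "smote_rebalance",
]

#: Singleton categorical levels that cannot survive stratified folding are
#: collapsed into a neighbouring level before encoding (configurable).
DEFAULT_COLLAPSE: dict[str, dict[str, str]] = {"gender": {"other": "female"}}


# ---------------------------------------------------------------------------
# fold plans


@dataclass(frozen=True)
class FoldPlan:
    """Repeated stratified outer-fold assignments.

    ``assignments[r, i]`` is the outer-fold id of participant ``i`` in
    repeat ``r``. Inner folds are drawn later, inside each outer training
    partition, from seeds derived off the same master seed.
    """

    n_outer: int
    n_inner: int
    n_repeats: int
    assignments: np.ndarray
    stratify_on: str
    seed: int

    def outer_split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        mask = self.assignments[repeat] == fold
        idx = np.arange(self.assignments.shape[1])
        return idx[~mask], idx[mask]

    def to_frame(self) -> pd.DataFrame:
        reps, n = self.assignments.shape
        return pd.DataFrame(
            {
                "repeat": np.repeat(np.arange(reps), n),
                "row": np.tile(np.arange(n), reps),
                "outer_fold": self.assignments.ravel(),
            }
        )


def make_fold_plan(
    labels,
    n_outer: int = 10,
    n_inner: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    stratify_on: str = "label",
) -> FoldPlan:
    """Stratified ``n_outer``-fold partition, repeated with distinct seeds."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_outer:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} members; "
            f"use fewer than {n_outer} folds"
        )
    n = len(y)
    assignments = np.empty((n_repeats, n), dtype=np.int64)
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_outer, shuffle=True, random_state=derive_seed(seed, "repeat", r)
        )
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
            assignments[r, test_idx] = f
    return FoldPlan(n_outer, n_inner, n_repeats, assignments, stratify_on, seed)


# ---------------------------------------------------------------------------
# imputation + standardization + encoding


@dataclass
class PreprocessorState:
    """Everything fitted on one training partition.

    Holds the per-column chained imputation forests (with the mean/mode
    initial fill and the number of refinement passes that training used),
    the continuous-column means/SDs, and the categorical level registry.
    Applying the state to new rows never mutates any stored parameter.
    """

    kinds: dict[str, str]
    level_registry: dict[str, list]
    fill_values: dict[str, object]
    forests: dict[str, object]
    n_passes: int
    means: dict[str, float]
    sds: dict[str, float]
    collapse: dict[str, dict[str, str]]
    partition_id: str | None = None
    impute_order: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for col, kind in self.kinds.items():
            if kind == "categorical" and len(self.level_registry[col]) > 2:
                names.extend(f"{col}={lv}" for lv in self.level_registry[col])
            elif kind == "categorical":
                names.append(f"{col}={self.level_registry[col][-1]}")
            else:
                names.append(col)
        return names


def _infer_kinds(df: pd.DataFrame) -> dict[str, str]:
    kinds = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            kinds[col] = "categorical"
        else:
            vals = s.dropna().unique()
            kinds[col] = "binary" if set(np.asarray(vals)) <= {0, 1, 0.0, 1.0} else "continuous"
    return kinds


def _collapse_levels(df: pd.DataFrame, collapse: dict[str, dict[str, str]]) -> pd.DataFrame:
    df = df.copy()
    for col, mapping in collapse.items():
        if col in df.columns:
            df[col] = df[col].replace(mapping)
    return df


def _to_codes(df: pd.DataFrame, state: PreprocessorState) -> pd.DataFrame:
    """Numeric working matrix for the imputation forests (categoricals as
    registry codes; unseen levels code to -1)."""
    out = pd.DataFrame(index=df.index)
    for col, kind in state.kinds.items():
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from input rows")
        if kind == "categorical":
            levels = state.level_registry[col]
            codes = df[col].map({lv: i for i, lv in enumerate(levels)}).astype(float)
            # unseen-but-observed levels get the sentinel code -1 (all-zero
            # indicators downstream); only true NaN counts as missing
            unseen = df[col].notna() & codes.isna()
            codes[unseen] = -1.0
            out[col] = codes
        else:
            out[col] = df[col].astype(float)
    return out


def _impute_pass(
    X: pd.DataFrame, missing: pd.DataFrame, state: PreprocessorState, cols: list[str]
) -> pd.DataFrame:
    X = X.copy()
    for col in cols:
        forest = state.forests.get(col)
        rows = missing[col].to_numpy()
        if forest is None or not rows.any():
            continue
        others = X.drop(columns=[col]).to_numpy()
        X.loc[rows, col] = forest.predict(others[rows])
    return X


def rf_impute_fit(
    train_df: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 50,
    collapse: dict[str, dict[str, str]] | None = None,
    partition_id: str | None = None,
) -> PreprocessorState:
    """Fit the full preprocessing state on one training partition.

    Chained random-forest imputation: initialize missing cells with the
    training mean/mode, then repeatedly regress (or classify) each
    incomplete column on all others, sweeping columns in order of
    increasing missingness, until the change in imputed values stops
    decreasing or ``max_iter`` passes. Standardization statistics and the
    categorical level registry are then fitted on the imputed matrix.
    Observed cells are never altered.
    """
    collapse = DEFAULT_COLLAPSE if collapse is None else collapse
    df = _collapse_levels(train_df, collapse)
    kinds = _infer_kinds(df)
    for col in df.columns:
        if df[col].isna().all():
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        if df[col].notna().sum() < 2:
            raise ValueError(f"column {col!r} observed in fewer than 2 rows")

    registry = {
        col: sorted(df[col].dropna().unique().tolist())
        for col, kind in kinds.items()
        if kind == "categorical"
    }
    state = PreprocessorState(
        kinds=kinds,
        level_registry=registry,
        fill_values={},
        forests={},
        n_passes=0,
        means={},
        sds={},
        collapse=collapse,
        partition_id=partition_id,
    )
    X = _to_codes(df, state)
    missing = X.isna()
    for col in X.columns:
        obs = X[col].dropna()
        state.fill_values[col] = float(obs.mean()) if kinds[col] == "continuous" else float(
            obs.mode().iloc[0]
        )
    filled = X.fillna(pd.Series(state.fill_values))

    miss_cols = [c for c in X.columns if missing[c].any()]
    miss_cols.sort(key=lambda c: int(missing[c].sum()))
    state.impute_order = miss_cols

    def fit_forest(col: str, data: pd.DataFrame):
        cls = RandomForestRegressor if kinds[col] == "continuous" else RandomForestClassifier
        forest = cls(
            n_estimators=n_estimators,
            random_state=derive_seed(seed, "impute", col),
            n_jobs=1,
        )
        obs = ~missing[col].to_numpy()
        forest.fit(data.drop(columns=[col]).to_numpy()[obs], data[col].to_numpy()[obs])
        return forest

    if miss_cols and len(X.columns) > 1:
        prev_change = np.inf
        prev_filled = filled
        for _ in range(max_iter):
            new = prev_filled.copy()
            for col in miss_cols:
                state.forests[col] = fit_forest(col, new)
                rows = missing[col].to_numpy()
                new.loc[rows, col] = state.forests[col].predict(
                    new.drop(columns=[col]).to_numpy()[rows]
                )
            change = 0.0
            for col in miss_cols:
                a = new.loc[missing[col], col].to_numpy(dtype=float)
                b = prev_filled.loc[missing[col], col].to_numpy(dtype=float)
                if kinds[col] == "continuous":
                    change += float(((a - b) ** 2).sum() / max((a**2).sum(), 1e-12))
                else:
                    change += float((a != b).mean())
            state.n_passes += 1
            if change >= prev_change:
                filled = prev_filled  # keep the better (previous) sweep
                break
            prev_change, prev_filled, filled = change, new, new

    # forests for every column, so held-out rows missing in columns that
    # were complete in training can still be imputed by model; a fully
    # complete training partition skips this (held-out missing cells then
    # fall back to the stored mean/mode fill)
    if miss_cols and len(X.columns) > 1:
        for col in X.columns:
            if col not in state.forests:
                state.forests[col] = fit_forest(col, filled)

    # standardization statistics come from the frozen-state imputation of
    # the training rows themselves, so transforming the fitting partition
    # reproduces mean 0 / SD 1 exactly
    final = _impute_codes(state, train_df)
    for col, kind in kinds.items():
        if kind == "continuous":
            state.means[col] = float(final[col].mean())
            state.sds[col] = float(final[col].std(ddof=0))
    return state


def _impute_codes(state: PreprocessorState, df: pd.DataFrame) -> pd.DataFrame:
    """Impute new rows with the frozen state (observed cells preserved)."""
    X = _to_codes(_collapse_levels(df, state.collapse), state)
    missing = X.isna()
    filled = X.fillna(pd.Series(state.fill_values))
    incomplete = {c for c in X.columns if missing[c].any()}
    cols = [c for c in state.impute_order if c in incomplete]
    cols += sorted(incomplete - set(cols))
    for _ in range(max(1, state.n_passes)):
        filled = _impute_pass(filled, missing, state, cols)
    # snap categorical/binary imputations onto valid codes
    for col, kind in state.kinds.items():
        if kind == "binary":
            filled.loc[missing[col], col] = filled.loc[missing[col], col].round().clip(0, 1)
        elif kind == "categorical":
            hi = len(state.level_registry[col]) - 1
            filled.loc[missing[col], col] = filled.loc[missing[col], col].round().clip(0, hi)
    return filled


def standardize_and_encode(state: PreprocessorState, rows: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature matrix for model fitting.

    Missing cells are imputed with the frozen state; continuous columns
    are centred/scaled with the training mean/SD; categorical columns with
    more than two registered levels expand to one indicator per level
    (full one-hot), two-level columns to a single indicator. Unseen test
    levels produce all-zero indicators with a warning.
    """
    for col in state.kinds:
        if col not in rows.columns:
            raise ValueError(f"column {col!r} expected by the preprocessor is absent")
    extra = [c for c in rows.columns if c not in state.kinds]
    if extra:
        raise ValueError(f"columns {extra} were not present when the preprocessor was fitted")
    collapsed = _collapse_levels(rows, state.collapse)
    for col, kind in state.kinds.items():
        if kind == "categorical":
            seen = set(state.level_registry[col])
            unseen = set(collapsed[col].dropna().unique()) - seen
            if unseen:
                warnings.warn(
                    f"{col!r}: levels {sorted(unseen)} unseen in training; encoding as all-zero"
                )
    filled = _impute_codes(state, rows)
    out = pd.DataFrame(index=rows.index)
    for col, kind in state.kinds.items():
        if kind == "continuous":
            sd = state.sds[col]
            out[col] = (filled[col] - state.means[col]) / (sd if sd > 0 else 1.0)
        elif kind == "binary":
            out[col] = filled[col].astype(float)
        else:
            levels = state.level_registry[col]
            codes = filled[col].to_numpy()
            if len(levels) > 2:
                for i, lv in enumerate(levels):
                    out[f"{col}={lv}"] = (codes == i).astype(float)
            else:
                out[f"{col}={levels[-1]}"] = (codes == len(levels) - 1).astype(float)
    return out


# ---------------------------------------------------------------------------
# SMOTE rebalancing


@dataclass
class RebalancedSample:
    """Training rows after midpoint undersampling + SMOTE augmentation."""

    features: pd.DataFrame
    labels: np.ndarray
    provenance: np.ndarray  # 'original' | 'synthetic'
    k_used: int


def smote_rebalance(
    features: pd.DataFrame,
    labels,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> RebalancedSample:
    """Rebalance a binary training sample.

    The majority class is randomly undersampled to the midpoint between
    the two class counts; the minority class is then augmented with
    synthetic points — each a uniform convex combination of a minority
    point and one of its ``k_neighbors`` nearest minority neighbours
    (Euclidean distance, so features should already be standardized) —
    until ``minority = round(target_ratio * majority)`` exactly. Balanced
    input is returned unchanged. Never apply this to evaluation rows.
    """
    X = pd.DataFrame(features).reset_index(drop=True)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_rebalance requires exactly two classes")
    minority = classes[counts.argmin()]
    majority = classes[counts.argmax()]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return RebalancedSample(X, y.copy(), np.full(len(y), "original"), k_neighbors)
    if n_min < 2:
        raise ValueError("minority class must have at least 2 members")

    k = k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(f"minority class smaller than k; reducing k to {k}")

    rng = rng_for(seed, "smote")
    maj_target = int(round((n_min + n_maj) / 2.0))
    min_target = int(round(target_ratio * maj_target))

    maj_idx = np.flatnonzero(y == majority)
    min_idx = np.flatnonzero(y == minority)
    keep_maj = rng.choice(maj_idx, size=maj_target, replace=False)
    keep = np.sort(np.concatenate([min_idx, keep_maj]))

    X_min = X.iloc[min_idx].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    n_new = max(0, min_target - n_min)
    base = rng.integers(0, n_min, size=n_new)
    pick = neigh[base, rng.integers(0, k, size=n_new)]
    lam = rng.random((n_new, 1))
    synth = X_min[base] + lam * (X_min[pick] - X_min[base])

    feats = pd.concat(
        [X.iloc[keep], pd.DataFrame(synth, columns=X.columns)], ignore_index=True
    )
    labs = np.concatenate([y[keep], np.full(n_new, minority, dtype=y.dtype)])
    prov = np.concatenate([np.full(len(keep), "original"), np.full(n_new, "synthetic")])
    return RebalancedSample(feats, labs, prov, k)

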