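"""Kernel SHAP attribution of the final prescriptive model.

Model-agnostic Shapley-value attribution by weighted least squares over
feature coalitions with the Shapley kernel weighting. Coalitions operate
at the level of the original predictors: all indicator columns belonging
to one categorical predictor are switched in or out together, so the
resulting attribution is already aggregated to the predictor level (the
sum of its indicator attributions). When the coalition space is small
enough the full ``2^p`` enumeration is used and the solution is exact;
otherwise coalitions are sampled from the kernel distribution. The
additivity constraint ``base + sum(phi) = f(x)`` is enforced exactly.

Ranking takes the mean absolute attribution across explained instances;
the direction label is the sign of the Spearman correlation between a
predictor's value and its attribution, and a consistency check flags
predictors whose direction flips between the posttreatment and follow-up
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import spearmanr

from ._utils import rng_for
from .predictors import canonical_rank, feature_groups

__all__ = ["ShapSummary", "kernel_shap", "rank_and_sign", "direction_consistency", "plot_beeswarm"]


@dataclass
class ShapSummary:
    """Per-instance, per-predictor attributions plus bookkeeping.

    ``values[i, j]`` is predictor j's additive contribution to the model
    output for instance i, relative to ``base_value`` (the mean model
    output over the background sample). ``instance_values`` holds a
    numeric per-predictor value per instance (standardized value for
    continuous, 0/1 for binary, registry level code for categoricals) used
    for direction estimates and beeswarm colouring.
    """

    values: np.ndarray
    base_value: float
    predictors: list[str]
    instance_values: pd.DataFrame
    predictions: np.ndarray
    additivity_gap: float

    def importance(self) -> pd.Series:
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=self.predictors, name="mean_abs_shap"
        )


def _kernel_weight(p: int, s: int) -> float:
    """Shapley kernel weight for a coalition of size s out of p players."""
    log_comb = gammaln(p + 1) - gammaln(s + 1) - gammaln(p - s + 1)
    return float(np.exp(np.log(p - 1.0) - log_comb - np.log(s) - np.log(p - s)))


def _enumerate_coalitions(p: int) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.arange(1, p)
    Z = []
    w = []
    for s in sizes:
        from itertools import combinations

        for idx in combinations(range(p), int(s)):
            row = np.zeros(p)
            row[list(idx)] = 1.0
            Z.append(row)
            w.append(_kernel_weight(p, int(s)))
    return np.asarray(Z), np.asarray(w)


def _sample_coalitions(p: int, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.arange(1, p)
    size_w = (p - 1.0) / (sizes * (p - sizes))  # kernel mass per size (C(p,s) cancels)
    size_w = size_w / size_w.sum()
    drawn = rng.choice(sizes, size=n, p=size_w)
    Z = np.zeros((n, p))
    for i, s in enumerate(drawn):
        Z[i, rng.choice(p, size=int(s), replace=False)] = 1.0
    return Z, np.ones(n)


def kernel_shap(
    predict_fn,
    background: pd.DataFrame,
    instances: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    n_coalitions: int = 2048,
    seed: int = 0,
    batch_rows: int = 200_000,
) -> ShapSummary:
    """Kernel SHAP attributions at the original-predictor level.

    ``predict_fn`` maps a feature matrix (ndarray, columns as in
    ``background``) to a score per row. ``groups`` maps predictor names to
    their encoded columns (derived from ``name=level`` column names when
    omitted). Requires ``n_coalitions >= p + 2``.
    """
    background = pd.DataFrame(background)
    instances = pd.DataFrame(instances)
    if background.empty:
        raise ValueError("background sample must be nonempty")
    if list(background.columns) != list(instances.columns):
        raise ValueError("background and instances must share columns")
    groups = groups or feature_groups(background.columns)
    names = list(groups)
    p = len(names)
    if n_coalitions < p + 2:
        raise ValueError(f"n_coalitions must be at least p + 2 = {p + 2}")
    col_idx = [
        [background.columns.get_loc(c) for c in cols] for cols in groups.values()
    ]

    B = background.to_numpy(dtype=float)
    X = instances.to_numpy(dtype=float)
    nb, ni = len(B), len(X)

    base = float(np.mean(predict_fn(B)))
    fx = np.asarray(predict_fn(X), dtype=float)

    if p == 1:  # single player: everything beyond the base is that player's
        phi = (fx - base).reshape(-1, 1)
        return _summary(phi, base, names, instances, groups, fx)

    exact = (2**p - 2) <= n_coalitions
    if exact:
        Z, w = _enumerate_coalitions(p)
    else:
        Z, w = _sample_coalitions(p, n_coalitions - 2, rng_for(seed, "coalitions"))

    # value of each coalition per instance: mean over background of the
    # model on rows where coalition features come from x, the rest from b
    nc = len(Z)
    V = np.empty((nc, ni))
    feat_mask = np.zeros((nc, B.shape[1]), dtype=bool)
    for j, cols in enumerate(col_idx):
        on = Z[:, j] == 1.0
        for c in cols:
            feat_mask[on, c] = True

    per_coal = ni * nb
    batch = max(1, batch_rows // per_coal)
    for start in range(0, nc, batch):
        stop = min(nc, start + batch)
        rows = []
        for ci in range(start, stop):
            m = feat_mask[ci]
            # tile background per instance, overwrite coalition columns from x
            synth = np.repeat(B[None, :, :], ni, axis=0)  # (ni, nb, d)
            synth[:, :, m] = X[:, None, m]
            rows.append(synth.reshape(ni * nb, -1))
        preds = np.asarray(predict_fn(np.vstack(rows)), dtype=float)
        preds = preds.reshape(stop - start, ni, nb).mean(axis=2)
        V[start:stop] = preds

    # constrained WLS: phi_0 = base; sum(phi) = fx - base
    y = V - base  # (nc, ni)
    zp = Z[:, -1:]
    Zr = Z[:, :-1] - zp
    sqw = np.sqrt(w)[:, None]
    A = Zr * sqw
    target = (y - zp * (fx - base)[None, :]) * sqw
    # small ridge guards rank deficiency in sampled designs
    G = A.T @ A + 1e-10 * np.eye(p - 1)
    phi_head = np.linalg.solve(G, A.T @ target)  # (p-1, ni)
    phi_last = (fx - base) - phi_head.sum(axis=0)
    phi = np.vstack([phi_head, phi_last[None, :]]).T  # (ni, p)
    return _summary(phi, base, names, instances, groups, fx)


def _summary(phi, base, names, instances, groups, fx) -> ShapSummary:
    vals = {}
    for name, cols in groups.items():
        block = instances[cols].to_numpy(dtype=float)
        if len(cols) == 1:
            vals[name] = block[:, 0]
        else:  # categorical one-hot block -> registry level code
            vals[name] = block.argmax(axis=1).astype(float)
    inst_vals = pd.DataFrame(vals)
    gap = float(np.max(np.abs(base + phi.sum(axis=1) - fx))) if len(fx) else 0.0
    return ShapSummary(
        values=phi,
        base_value=base,
        predictors=list(names),
        instance_values=inst_vals,
        predictions=np.asarray(fx, dtype=float),
        additivity_gap=gap,
    )


def rank_and_sign(summary: ShapSummary, k: int = 10) -> pd.DataFrame:
    """Ordered top-k predictors with direction labels.

    Importance is the mean absolute attribution; direction is the sign of
    the Spearman correlation between predictor value and attribution
    ("positive" when higher values push predictions up). All-zero
    attribution blocks rank by canonical name order with direction
    "null".
    """
    p = len(summary.predictors)
    if k > p:
        warnings.warn(f"k={k} exceeds the {p} available predictors; clamping")
        k = p
    imp = summary.importance()
    order = sorted(summary.predictors, key=lambda g: (-imp[g], canonical_rank(g)))
    rows = []
    for rank, name in enumerate(order[:k], start=1):
        j = summary.predictors.index(name)
        phi_j = summary.values[:, j]
        val_j = summary.instance_values[name].to_numpy()
        if np.allclose(phi_j, 0.0) or np.std(val_j) == 0 or np.std(phi_j) == 0:
            direction = "null"
        else:
            rho = spearmanr(val_j, phi_j).statistic
            direction = "null" if not rho == rho or rho == 0 else (
                "positive" if rho > 0 else "negative"
            )
        rows.append(
            {"rank": rank, "predictor": name, "importance": float(imp[name]), "direction": direction}
        )
    return pd.DataFrame(rows)


def direction_consistency(ranked_a: pd.DataFrame, ranked_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-time-point sign stability for predictors ranked at both
    time points; ``consistent`` is False when the direction flips."""
    merged = ranked_a.merge(ranked_b, on="predictor", suffixes=("_a", "_b"))
    merged["consistent"] = (merged["direction_a"] == merged["direction_b"]) & (
        merged["direction_a"] != "null"
    )
    return merged[["predictor", "direction_a", "direction_b", "consistent"]]


def plot_beeswarm(summary: ShapSummary, k: int = 10, path=None, title: str | None = None):
    """Beeswarm-style attribution plot (one row per top-k predictor,
    points coloured by predictor value)."""
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "memiselect"  # reproducible SVG ids
    import matplotlib.pyplot as plt

    ranked = rank_and_sign(summary, k=min(k, len(summary.predictors)))
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(ranked) + 1.5))
    rng = np.random.default_rng(0)
    for i, name in enumerate(reversed(list(ranked["predictor"]))):
        j = summary.predictors.index(name)
        phi = summary.values[:, j]
        val = summary.instance_values[name].to_numpy()
        spread = np.ptp(val) or 1.0
        colors = (val - val.min()) / spread
        ax.scatter(
            phi,
            np.full_like(phi, i) + rng.normal(0, 0.06, size=len(phi)),
            c=colors,
            cmap="coolwarm",
            s=12,
            alpha=0.8,
            linewidths=0,
        )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(ranked)))
    ax.set_yticklabels(list(reversed(list(ranked["predictor"]))))
    ax.set_xlabel("SHAP attribution (probability scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, metadata={"Date": None})
        plt.close(fig)
    return fig
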