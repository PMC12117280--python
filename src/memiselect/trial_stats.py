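"""Trial-level descriptive and inferential statistics.

Remission classification against the severity cutoff, uncorrected Pearson
chi-square tests on 2x2 remission tables (within- and between-arm),
Welch's t test from raw vectors or summary statistics, and engagement
rates out of the 70 scheduled prompts. Within-group pre-vs-post change is
tested as two independent proportions without continuity correction; that
is the formulation whose statistics match a remission paragraph computed
from counts reconstructed as ``round(pct * n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_rct import REMISSION_CUTOFF, TrialDataset, _outcome_column

__all__ = [
    "ContingencyTable2x2",
    "classify_remission",
    "pearson_chi_square",
    "welch_t_test",
    "welch_t_test_ind",
    "engagement_rate",
    "reconstruct_count",
    "remission_results_block",
    "summarize_remission",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows = groups or time points, columns = remitted vs not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")


def classify_remission(spdq_score, cutoff: float = REMISSION_CUTOFF):
    """Remission indicator: severity strictly below the cutoff.

    Accepts scalars or arrays; NaN scores (missing assessments) propagate
    as NaN. Negative scores are invalid.
    """
    score = np.asarray(spdq_score, dtype=float)
    if np.nanmin(score) < 0 if score.size else False:
        raise ValueError("severity scores must be nonnegative")
    out = np.where(np.isnan(score), np.nan, (score < cutoff).astype(float))
    if np.isscalar(spdq_score) or np.ndim(spdq_score) == 0:
        return float(out)
    return out


def pearson_chi_square(table) -> tuple[float, float]:
    """Uncorrected 1-df Pearson chi-square on a 2x2 table.

    ``chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; a zero marginal
    makes the statistic 0 (with a warning) and p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = np.asarray(table, dtype=float)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn("degenerate 2x2 table (zero marginal); chi-square set to 0")
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def welch_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def welch_t_test_ind(x, y) -> tuple[float, float, float]:
    """Welch's t test from raw vectors (NaN entries dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    return welch_t_test(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))


def engagement_rate(prompts_completed):
    """Percentage of the 70 scheduled prompts completed."""
    counts = np.asarray(prompts_completed, dtype=float)
    valid = counts[~np.isnan(counts)]
    if valid.size and (valid.min() < 0 or valid.max() > 70):
        raise ValueError("prompt counts must lie in [0, 70]")
    out = 100.0 * counts / 70.0
    if np.isscalar(prompts_completed) or np.ndim(prompts_completed) == 0:
        return float(out)
    return out


def reconstruct_count(pct: float, n: int) -> int:
    """Remission count implied by a printed percentage: ``round(pct/100 * n)``."""
    return int(round(pct / 100.0 * n))


def remission_results_block(
    n_memi: int,
    n_sm: int,
    pct_memi_post: float,
    pct_sm_post: float,
    pct_memi_1mfu: float,
    pct_sm_1mfu: float,
) -> dict[str, dict[str, float]]:
    """Within- and between-arm remission chi-squares from printed rates.

    Counts are reconstructed as ``round(pct * n)``; baseline remission is
    zero in both arms (every participant met diagnostic criteria at
    entry). Within-group change is tested as two independent proportions.
    """
    out: dict[str, dict[str, float]] = {}
    counts = {
        "post": (reconstruct_count(pct_memi_post, n_memi), reconstruct_count(pct_sm_post, n_sm)),
        "1mfu": (reconstruct_count(pct_memi_1mfu, n_memi), reconstruct_count(pct_sm_1mfu, n_sm)),
    }
    for tp, (r_memi, r_sm) in counts.items():
        for arm_name, n_arm, r_arm in (("memi", n_memi, r_memi), ("sm", n_sm, r_sm)):
            chi2, p = pearson_chi_square(ContingencyTable2x2(0, n_arm, r_arm, n_arm - r_arm))
            out[f"within_{arm_name}_{tp}"] = {"chi2": chi2, "p": p, "remitted": r_arm, "n": n_arm}
        chi2, p = pearson_chi_square(
            ContingencyTable2x2(r_memi, n_memi - r_memi, r_sm, n_sm - r_sm)
        )
        out[f"between_{tp}"] = {"chi2": chi2, "p": p}
    return out


def summarize_remission(data: TrialDataset, cutoff: float = REMISSION_CUTOFF) -> pd.DataFrame:
    """Observed remission rates and between-arm chi-squares for a dataset.

    Rows with a missing severity score at a time point are excluded from
    that time point's table.
    """
    rows = []
    for tp in ("post", "1mfu"):
        scores = data.df[_outcome_column(tp)]
        remit = classify_remission(scores.to_numpy())
        for arm in (1, 0):
            m = (data.df["arm"] == arm).to_numpy() & ~np.isnan(remit)
            rows.append(
                {
                    "time_point": tp,
                    "arm": "memi" if arm else "sm",
                    "n": int(m.sum()),
                    "remitted": int(np.nansum(remit[m])),
                    "rate": float(np.nanmean(remit[m])) if m.any() else np.nan,
                }
            )
        tab = ContingencyTable2x2(
            rows[-2]["remitted"],
            rows[-2]["n"] - rows[-2]["remitted"],
            rows[-1]["remitted"],
            rows[-1]["n"] - rows[-1]["remitted"],
        )
        chi2, p = pearson_chi_square(tab)
        rows[-2]["between_chi2"] = rows[-1]["between_chi2"] = chi2
        rows[-2]["between_p"] = rows[-1]["between_p"] = p
    return pd.DataFrame(rows)
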