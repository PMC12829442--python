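"""Performance metrics and EDL-vs-random comparison statistics.

Per-iteration model quality is summarized by RMSE and R^2 on a held-out test
set.  Strategy comparisons across replicate runs use a one-tailed t test
(paired when the two arms share seeds, Welch otherwise) oriented so that the
alternative is "uncertainty-based acquisition is better" (lower RMSE, higher
R^2), together with Cohen's d computed from the pooled standard deviation,
classed at the conventional 0.2 / 0.5 / 0.8 thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "rmse",
    "r_squared",
    "compare_arms",
    "significance_table",
]

P_FLOOR = 1e-300


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("constant y_true: R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _effect_class(d: float) -> str:
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


@dataclass
class ComparisonResult:
    """One EDL-vs-random comparison at a given iteration and metric."""

    iteration: int
    metric: str
    mean_edl: float
    sd_edl: float
    mean_rand: float
    sd_rand: float
    p_one_tailed: float
    neg_log10_p: float
    cohens_d: float
    significant_05: bool
    significant_01: bool
    effect_class: str


def compare_arms(edl_values, rand_values, direction: str = "lower",
                 paired: bool = True, iteration: int = 0,
                 metric: str = "rmse") -> ComparisonResult:
    """One-tailed comparison of the two acquisition arms across runs.

    ``direction`` states which way is better for this metric ("lower" for
    RMSE, "higher" for R^2).  The t statistic is computed directly (paired t
    or Welch) and the p-value taken from the t survival function; Cohen's d
    uses the pooled-SD definition with the sign oriented so positive d means
    the EDL arm is better.
    """
    x = np.asarray(edl_values, dtype=float)
    y = np.asarray(rand_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per arm")
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal-length arms")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")

    # orient so positive delta = EDL better
    sign = 1.0 if direction == "higher" else -1.0
    n1, n2 = x.size, y.size
    m1, m2 = float(x.mean()), float(y.mean())
    s1, s2 = float(x.std(ddof=1)), float(y.std(ddof=1))

    pooled_var = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if pooled_var > 0:
        d = sign * (m1 - m2) / math.sqrt(pooled_var)
    else:
        d = 0.0 if m1 == m2 else sign * math.copysign(math.inf, m1 - m2)

    if paired:
        diff = sign * (x - y)
        sd_diff = float(diff.std(ddof=1))
        if sd_diff > 0:
            t = float(diff.mean()) / (sd_diff / math.sqrt(n1))
            p = float(sps.t.sf(t, df=n1 - 1))
        else:
            p = 0.5 if float(diff.mean()) == 0.0 else (P_FLOOR if diff.mean() > 0 else 1.0)
    else:
        se2 = s1 ** 2 / n1 + s2 ** 2 / n2
        if se2 > 0:
            t = sign * (m1 - m2) / math.sqrt(se2)
            df = se2 ** 2 / ((s1 ** 2 / n1) ** 2 / (n1 - 1) + (s2 ** 2 / n2) ** 2 / (n2 - 1))
            p = float(sps.t.sf(t, df=df))
        else:
            p = 0.5 if m1 == m2 else (P_FLOOR if sign * (m1 - m2) > 0 else 1.0)

    p = max(p, P_FLOOR)
    return ComparisonResult(
        iteration=iteration, metric=metric,
        mean_edl=m1, sd_edl=s1, mean_rand=m2, sd_rand=s2,
        p_one_tailed=p, neg_log10_p=-math.log10(p),
        cohens_d=d, significant_05=p < 0.05, significant_01=p < 0.01,
        effect_class=_effect_class(d),
    )


def significance_table(records: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """Per-(iteration, metric) comparison table from an IterationRecord table.

    ``records`` must have columns run, iteration, strategy, rmse, r2 with
    strategies 'edl' and 'random'.  Iterations missing either arm are
    skipped with a warning.
    """
    rows = []
    for it, grp in records.groupby("iteration"):
        edl = grp[grp["strategy"] == "edl"].sort_values("run")
        rnd = grp[grp["strategy"] == "random"].sort_values("run")
        if len(edl) < 2 or len(rnd) < 2:
            warnings.warn(f"iteration {it}: missing arm, skipped", stacklevel=2)
            continue
        for metric, direction in (("rmse", "lower"), ("r2", "higher")):
            res = compare_arms(edl[metric].to_numpy(), rnd[metric].to_numpy(),
                               direction=direction, paired=paired,
                               iteration=int(it), metric=metric)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
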