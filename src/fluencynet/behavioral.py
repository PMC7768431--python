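"""Divergent-thinking scoring and group construction.

The Alternative Uses Task (AUT) asks for unusual uses of a common object;
each idea is assigned to a concept category and rated for creativity (1-5)
by two raters.  Per participant:

* fluency      -- number of non-redundant ideas;
* flexibility  -- number of distinct concept categories used;
* creativity sum  -- sum over ideas of the two raters' mean rating;
* creativity mean -- creativity sum / fluency;
* ODT (overall divergent thinking) = creativity mean + flexibility.

Groups are formed by an equal-size median split on a chosen score, and group
contrasts use Student's pooled-variance t with Cohen's d.  Inter-rater
agreement is summarized by the two-way consistency intraclass correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

AUT_COLUMNS = ("participant", "idea", "rater1", "rater2", "category")


@dataclass(frozen=True)
class AUTScores:
    participant_id: str
    fluency: int
    flexibility: int
    creativity_sum: float
    creativity_mean: float
    odt: float
    degenerate: bool = False  # no scorable ideas


@dataclass(frozen=True)
class GroupAssignment:
    """Equal-size low/high split of participants on one score."""

    labels: dict[str, str]  # participant id -> "low" | "high"
    variable: str
    threshold: float

    def group(self, label: str) -> list[str]:
        return [p for p, g in self.labels.items() if g == label]


def score_aut(ideas: pd.DataFrame, participant_id: str = "") -> AUTScores:
    """Score one participant's AUT idea list.

    ``ideas`` needs columns ``idea``, ``rater1``, ``rater2``, ``category``;
    ratings must lie in [1, 5].  Duplicate idea strings count once (the
    fluency score includes only non-redundant ideas).  A participant with no
    ideas gets ODT 0 and the ``degenerate`` flag, with a warning.
    """
    ideas = ideas.drop_duplicates(subset="idea")
    if len(ideas) == 0:
        warnings.warn(f"participant {participant_id!r} produced no scorable ideas",
                      stacklevel=2)
        return AUTScores(participant_id, 0, 0, 0.0, float("nan"), 0.0, degenerate=True)
    ratings = ideas[["rater1", "rater2"]].astype(float)
    if ((ratings < 1) | (ratings > 5)).any().any():
        raise ValidationError("creativity ratings must lie in [1, 5]")
    idea_creativity = ratings.mean(axis=1)
    fluency = len(ideas)
    flexibility = int(ideas["category"].nunique())
    creativity_sum = float(idea_creativity.sum())
    creativity_mean = creativity_sum / fluency
    return AUTScores(
        participant_id=participant_id,
        fluency=fluency,
        flexibility=flexibility,
        creativity_sum=creativity_sum,
        creativity_mean=creativity_mean,
        odt=creativity_mean + flexibility,
    )


def score_aut_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant AUT score table from a long idea-level table."""
    missing = [c for c in AUT_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigurationError(f"AUT table lacks column(s): {', '.join(missing)}")
    rows = [
        score_aut(group, participant_id=str(pid)).__dict__
        for pid, group in records.groupby("participant", sort=True)
    ]
    return pd.DataFrame(rows).set_index("participant_id")


def icc_consistency(rater1: np.ndarray, rater2: np.ndarray) -> tuple[float, float]:
    """Two-way consistency intraclass correlation for two raters.

    Returns the single-measure ICC, (MSR - MSE) / (MSR + MSE) for k = 2, and
    the average-measure ICC, (MSR - MSE) / MSR, from the two-way ANOVA mean
    squares (MSR between items, MSE residual).  The consistency form ignores
    additive rater shifts.  Zero between-item variance makes the coefficient
    undefined: NaNs with a warning.
    """
    r1 = np.asarray(rater1, dtype=float)
    r2 = np.asarray(rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) < 3:
        raise ValidationError("ICC needs two equal-length vectors with n >= 3")
    data = np.column_stack([r1, r2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr + (k - 1) * mse == 0 or msr == 0:
        warnings.warn("zero between-item variance; ICC undefined", stacklevel=2)
        return float("nan"), float("nan")
    single = (msr - mse) / (msr + (k - 1) * mse)
    average = (msr - mse) / msr
    return float(single), float(average)


def correlate_indices(
    scores: pd.DataFrame,
    log_columns: tuple[str, ...] = ("flexibility", "fluency", "creativity_sum"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations among score columns, log-transforming skewed ones.

    Columns listed in ``log_columns`` get a natural-log transform first; a
    column containing zeros (possible for sparse idea lists) falls back to
    log(x + 1) with a warning.  Returns (rho, p) square DataFrames.
    """
    if len(scores) < 5:
        raise ValidationError("correlation table needs at least 5 participants")
    working = scores.astype(float).copy()
    for col in log_columns:
        if col not in working.columns:
            continue
        if (working[col] <= 0).any():
            warnings.warn(f"column {col!r} has non-positive values; using log(x+1)",
                          stacklevel=2)
            working[col] = np.log1p(working[col])
        else:
            working[col] = np.log(working[col])
    cols = list(working.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r, p = stats.spearmanr(working[a], working[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return rho, pvals


def median_split(scores: pd.Series, variable: str = "score") -> GroupAssignment:
    """Equal-size low/high split at the median.

    Participants are stably sorted by (score, id); the lower half is "low",
    the upper half "high", so ties spanning the median are resolved
    deterministically by id order (with a warning).  With odd n the middle
    participant joins the low group, with a warning.
    """
    n = len(scores)
    if n < 2:
        raise ValidationError("median split needs at least 2 participants")
    order = sorted(scores.index, key=lambda pid: (scores[pid], str(pid)))
    half = n // 2
    if n % 2:
        warnings.warn(f"odd sample size {n}: middle participant assigned to 'low'",
                      stacklevel=2)
        half = half + 1
    if half < n and scores[order[half - 1]] == scores[order[half]]:
        warnings.warn("tied scores span the median; split by participant id order",
                      stacklevel=2)
    labels = {pid: ("low" if i < half else "high") for i, pid in enumerate(order)}
    return GroupAssignment(labels=labels, variable=variable,
                           threshold=float(scores.median()))


def compare_groups(
    values: pd.Series,
    assignment: GroupAssignment,
) -> tuple[float, float, float]:
    """Student t-test (pooled variance) of high - low with Cohen's d.

    ``t`` and ``d`` are oriented high minus low, so a negative t means the
    high group scored lower.  Zero pooled spread is flagged with an infinite t.
    """
    low = values.loc[[p for p in values.index if assignment.labels.get(p) == "low"]]
    high = values.loc[[p for p in values.index if assignment.labels.get(p) == "high"]]
    if len(low) == 0 or len(high) == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = len(high), len(low)
    pooled_var = (
        ((n1 - 1) * high.var(ddof=1) + (n2 - 1) * low.var(ddof=1)) / (n1 + n2 - 2)
    )
    diff = high.mean() - low.mean()
    if pooled_var == 0:
        warnings.warn("zero pooled variance; t is infinite", stacklevel=2)
        t = float(np.inf * np.sign(diff)) if diff else 0.0
        return t, (0.0 if diff else 1.0), t
    t = diff / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
    d = diff / np.sqrt(pooled_var)
    return float(t), float(p), float(d)
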