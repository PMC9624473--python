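"""Gene-signature scoring and median-split survival comparison.

Subjects are scored by the mean of z-scored expression over a signature
gene list, split at the cohort median (strictly above the median is
"high", at or below is "low"), and the two strata are compared with the
standard two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from lifelines import KaplanMeierFitter

HIGH, LOW = "high", "low"


def zscore_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across subjects ((x - mean) / sd, sd with the n-1
    denominator).  Zero-variance genes are dropped with a warning; an
    all-constant matrix is an error."""
    if len(expression) < 2:
        raise ValueError("need at least two subjects")
    sd = expression.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("every gene has zero variance")
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance gene(s)"
        )
    kept = expression.loc[:, ~constant]
    return (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)


def signature_score(z: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Mean z-score over the signature genes present in the matrix.

    Missing genes are dropped with a warning; a signature with no gene in
    the matrix is an error."""
    present = [g for g in genes if g in z.columns]
    missing = [g for g in genes if g not in z.columns]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) not in matrix: {missing}")
    return z[present].mean(axis=1).rename("score")


def median_split(scores: pd.Series) -> pd.Series:
    """Stratify subjects: ``high`` iff score strictly above the sample
    median, ``low`` otherwise.  All-equal scores degenerate to all-low
    (reported with a warning)."""
    if len(scores) < 2:
        raise ValueError("need at least two subjects")
    med = scores.median()
    strata = pd.Series(
        np.where(scores > med, HIGH, LOW), index=scores.index, name="stratum"
    )
    if (strata == LOW).all():
        warnings.warn("degenerate split: no score above the median")
    return strata


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    n_high: int
    n_low: int


def logrank(
    time: pd.Series, event: pd.Series, strata: pd.Series
) -> LogrankResult:
    """Two-group log-rank test between the ``high`` and ``low`` strata.

    statistic = (sum O - E)^2 / sum V over distinct event times with the
    hypergeometric variance; p from chi-square with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    strata = np.asarray(strata)
    hi = strata == HIGH
    lo = strata == LOW
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both strata must be non-empty")
    if event.sum() == 0:
        raise ValueError("need at least one observed event")
    res = logrank_test(
        time[hi], time[lo], event_observed_A=event[hi], event_observed_B=event[lo]
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        n_high=int(hi.sum()),
        n_low=int(lo.sum()),
    )


def km_table(time, event, strata) -> pd.DataFrame:
    """Kaplan-Meier event table per stratum (time, at risk, events,
    survival), for reporting."""
    df = pd.DataFrame({
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=bool),
        "stratum": np.asarray(strata),
    })
    frames = []
    for stratum, block in df.groupby("stratum", observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(block["time"], block["event"])
        tab = kmf.event_table.reset_index().rename(
            columns={"event_at": "time"}
        )
        tab["survival"] = kmf.survival_function_.iloc[:, 0].to_numpy()
        tab["stratum"] = stratum
        frames.append(tab[["stratum", "time", "at_risk", "observed",
                           "censored", "survival"]])
    return pd.concat(frames, ignore_index=True)


def score_and_compare(
    expression: pd.DataFrame,
    genes: Sequence[str],
    records: pd.DataFrame,
    prezscored: bool = False,
) -> dict:
    """End-to-end: z-score (unless the matrix already is), score, split at
    the median, log-rank compare.  ``records`` needs subject_id, time,
    event columns aligned to the expression index."""
    z = expression if prezscored else zscore_genes(expression)
    scores = signature_score(z, genes)
    strata = median_split(scores)
    rec = records.set_index("subject_id").loc[scores.index]
    res = logrank(rec["time"], rec["event"], strata)
    return {
        "scores": scores,
        "strata": strata,
        "logrank": res,
        "km_table": km_table(rec["time"], rec["event"], strata),
    }
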