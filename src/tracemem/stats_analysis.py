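"""Behavioural statistics for trial logs: binomial and chi-square tests on
choice counts, learning-criterion detection, and block/delay performance
summaries.

The exact two-sided binomial test uses the minimum-likelihood convention
(sum the probability of every outcome whose mass does not exceed the
observed outcome's mass), the convention of standard statistical software.
The chi-square test is the plain Pearson statistic on a contingency table
with margin-derived expected counts and no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .experiment_sim import TrialLog

__all__ = [
    "ContingencyTable",
    "TestResult",
    "PerformanceSeries",
    "binom_test_two_sided",
    "chisq_contingency",
    "windowed_criterion",
    "block_performance",
    "probe_tables",
    "delay_performance",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-classified by row and column labels (e.g. probe
    condition x which sample stimulus was chosen)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class PerformanceSeries:
    """Proportion correct per consecutive block of trials, optionally
    stratified by trial type.  The final block may be partial and is then
    flagged with its own n."""

    block_size: int
    positions: tuple[int, ...]
    proportion_correct: tuple[float, ...]
    n_trials: tuple[int, ...]
    by_type: Mapping[str, Mapping[int, tuple[float, int]]] | None = None
    partial_final: bool = False


# ---------------------------------------------------------------------------
# Tests on counts
# ---------------------------------------------------------------------------

def binom_test_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of ``k`` successes in ``n`` trials
    against success probability ``p0``.

    The p-value sums Binomial(n, p0) mass over every outcome whose
    probability does not exceed that of the observed ``k`` (with the usual
    1 + 1e-7 relative tolerance for floating-point ties).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    ks = np.arange(n + 1)
    mass = sps.binom.pmf(ks, n, p0)
    observed = mass[k]
    p = float(mass[mass <= observed * (1.0 + 1e-7)].sum())
    return TestResult(statistic=float(k), df=None, p_value=min(p, 1.0),
                      method="binomial_two_sided_minlike", n=int(n))


def chisq_contingency(table: ContingencyTable,
                      correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the row/column margins; df = (r-1)(c-1).  No
    continuity correction by default.  A zero row or column margin makes the
    expected counts degenerate and raises.
    """
    obs = np.asarray(table.counts, dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0):
        bad = [table.row_labels[i] for i in np.flatnonzero(row == 0)]
        raise ValueError(f"zero row margin for {bad}")
    if np.any(col == 0):
        bad = [table.col_labels[i] for i in np.flatnonzero(col == 0)]
        raise ValueError(f"zero column margin for {bad}")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if correction and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p,
                      method="pearson_chi2", n=int(obs.sum()))


# ---------------------------------------------------------------------------
# Trial-log summaries
# ---------------------------------------------------------------------------

def windowed_criterion(log: TrialLog, window: int = 20,
                       threshold: float = 0.8) -> int | None:
    """First trial at which performance reaches the learning criterion.

    Returns the earliest 1-based trial index ``t`` (counting within the log)
    such that at least ``ceil(threshold * window)`` of the last ``window``
    trials *within the same session* were correct, or ``None`` if the
    criterion is never met.  Windows never straddle sessions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    need = math.ceil(threshold * window)
    by_session: dict[int, list[tuple[int, bool]]] = {}
    for t, r in enumerate(log.results, start=1):
        by_session.setdefault(r.session, []).append((t, r.correct))
    for _, items in sorted(by_session.items()):
        running = 0
        correct_flags = [c for _, c in items]
        for i, (t, c) in enumerate(items):
            running += c
            if i >= window:
                running -= correct_flags[i - window]
            if i >= window - 1 and running >= need:
                return t
    return None


def block_performance(log: TrialLog, block: int = 120,
                      by_type: bool = True) -> PerformanceSeries:
    """Proportion correct per consecutive block of ``block`` trials.

    Correction trials count like any other trial (as in the source task's
    scoring).  A trailing partial block is reported with its own n and the
    series flagged.
    """
    if len(log) == 0:
        raise ValueError("log is empty")
    if block < 1:
        raise ValueError("block must be >= 1")
    frame = log.to_frame()
    pos = np.arange(len(frame)) // block + 1
    frame = frame.assign(_block=pos)
    grouped = frame.groupby("_block")["correct"]
    props = grouped.mean()
    ns = grouped.size()
    by = None
    if by_type:
        g = frame.groupby(["_block", "trial_type"])["correct"].agg(["mean", "size"])
        by = {}
        for (b, tt), row in g.iterrows():
            by.setdefault(str(tt), {})[int(b)] = (float(row["mean"]),
                                                  int(row["size"]))
    return PerformanceSeries(
        block_size=block,
        positions=tuple(int(b) for b in props.index),
        proportion_correct=tuple(float(v) for v in props.values),
        n_trials=tuple(int(v) for v in ns.values),
        by_type=by,
        partial_final=len(frame) % block != 0,
    )


def probe_tables(log: TrialLog) -> tuple[ContingencyTable, int, int]:
    """Cross-tabulate probe responses by condition and chosen sample.

    Returns a (conditions x {chose_first, chose_second}) table, the number
    ``k`` of probes on which either sample stimulus was chosen, and the
    total probe count ``n``.  Condition rows are labelled by the first and
    second sample durations, ordered long-standard before standard-long.
    """
    probes = [r for r in log.results if r.spec.is_probe]
    if not probes:
        raise ValueError("log contains no probe trials")
    conditions: dict[tuple[float, float], list[int]] = {}
    k = 0
    for r in probes:
        ev = r.spec.sample_events
        # durations are reconstructed from event times; round away float drift
        cond = (round(ev[0].duration, 6), round(ev[1].duration, 6))
        row = conditions.setdefault(cond, [0, 0])
        first_id, second_id = r.spec.sample_ids
        if r.response == first_id:
            row[0] += 1
            k += 1
        elif r.response == second_id:
            row[1] += 1
            k += 1
    # stable condition order: varied-first rows, then varied-second rows
    ordered = sorted(conditions, key=lambda c: (c[1] != 1.0, c))
    counts = np.array([conditions[c] for c in ordered], dtype=int)
    labels = tuple(f"first={c[0]:g}s,second={c[1]:g}s" for c in ordered)
    table = ContingencyTable(
        row_labels=labels,
        col_labels=("chose_first", "chose_second"),
        counts=counts,
    )
    return table, k, len(probes)


def delay_performance(log: TrialLog, p0: float = 0.5,
                      ci_method: str = "wilson") -> pd.DataFrame:
    """Per-delay performance summary for a delayed-MTS log.

    One row per delay: successes ``k``, trials ``n``, proportion correct,
    the exact two-sided binomial p-value against ``p0``, and a 95% Wilson
    score confidence interval.
    """
    frame = log.to_frame()
    rows = []
    for delay, grp in frame.groupby("delay_s"):
        k = int(grp["correct"].sum())
        n = int(len(grp))
        test = binom_test_two_sided(k, n, p0)
        lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
        rows.append({
            "delay_s": float(delay), "k": k, "n": n,
            "proportion": k / n, "p_value": test.p_value,
            "ci_low": float(lo), "ci_high": float(hi),
        })
    return pd.DataFrame(rows).sort_values("delay_s").reset_index(drop=True)
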