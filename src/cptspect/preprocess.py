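"""Response classification under an extended window and the accuracy filter.

A response is scored against the trial whose window it falls in: targets get
an extended window of one SOA plus 150 ms (default 1135 ms), so a very slow
response landing shortly after the next stimulus onset is still credited to
the target that elicited it. Each physical response is attributed to at most
one trial, and only the first response inside a window counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RESPONSE_WINDOW_MS = 1135.0
DEFAULT_SOA_MS = 985.0
DEFAULT_MIN_ACCURACY = 0.60


@dataclass(frozen=True)
class ResponseCounts:
    hits: int
    misses: int
    commissions: int
    correct_rejections: int

    @property
    def n_targets(self) -> int:
        return self.hits + self.misses

    @property
    def n_nontargets(self) -> int:
        return self.commissions + self.correct_rejections


@dataclass
class SessionResult:
    """Classified responses for one participant session.

    ``rt_series`` holds only the correct (hit) responses as
    ``(trial_index, onset_time_s, rt_ms)`` triples ordered by onset.
    ``passed_filter`` is None until the accuracy filter has been applied.
    """

    participant_id: str
    counts: ResponseCounts
    rt_series: pd.DataFrame
    accuracy: float
    passed_filter: bool | None = None
    group: str | None = None
    age: float | None = None
    sex: str | None = None


def hit_threshold(n_targets: int, min_accuracy: float = DEFAULT_MIN_ACCURACY) -> int:
    """Smallest hit count that satisfies the accuracy filter."""
    # guard float artefacts such as 0.6 * 100 = 60.000000000000007
    return int(math.ceil(min_accuracy * n_targets - 1e-9))


def classify_responses(
    records: pd.DataFrame,
    response_window: float = DEFAULT_RESPONSE_WINDOW_MS,
    soa: float = DEFAULT_SOA_MS,
) -> SessionResult:
    """Classify one participant's trials into hits/misses/commissions/CRs.

    Parameters
    ----------
    records : DataFrame
        One row per trial, sorted by ``trial_index``, with columns
        ``trial_index, onset_time_s, is_target, rt_ms`` (``rt_ms`` NaN
        where no response was recorded; latencies are relative to that
        trial's onset) and optionally ``participant_id, group, age, sex``.
    response_window : float
        Hit window after a target onset, ms. Must be at least ``soa``; the
        excess spills into the first ``response_window - soa`` ms of the
        following trial, and a response there is credited to the preceding
        target if and only if that target has no earlier response.
    soa : float
        Trial onset spacing, ms; also the scoring window for non-targets.
    """
    if response_window < soa:
        raise ValueError("response_window must be >= soa")
    idx = records["trial_index"].to_numpy()
    if idx.size == 0:
        raise ValueError("empty trial table")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trial records must be sorted by unique trial_index")

    onset_ms = records["onset_time_s"].to_numpy(dtype=float) * 1000.0
    is_target = records["is_target"].to_numpy(dtype=bool)
    rt = records["rt_ms"].to_numpy(dtype=float)

    # physical response times on the session clock, sorted
    has_resp = np.isfinite(rt)
    resp_t = np.sort(onset_ms[has_resp] + rt[has_resp])
    used = np.zeros(resp_t.size, dtype=bool)

    hits = misses = commissions = crs = 0
    series_rows: list[tuple[int, float, float]] = []
    ptr = 0  # first response that could still match any later trial
    n = idx.size
    for i in range(n):
        t0 = onset_ms[i]
        win = response_window if is_target[i] else soa
        while ptr < resp_t.size and (used[ptr] or resp_t[ptr] <= t0):
            ptr += 1
        j = ptr
        match = -1
        while j < resp_t.size and resp_t[j] <= t0 + win:
            if not used[j]:
                match = j
                break
            j += 1
        if is_target[i]:
            if match >= 0:
                used[match] = True
                hits += 1
                series_rows.append(
                    (int(idx[i]), onset_ms[i] / 1000.0, resp_t[match] - t0)
                )
            else:
                misses += 1
        else:
            if match >= 0:
                used[match] = True
                commissions += 1
            else:
                crs += 1

    counts = ResponseCounts(hits, misses, commissions, crs)
    rt_series = pd.DataFrame(
        series_rows, columns=["trial_index", "onset_time_s", "rt_ms"]
    )
    accuracy = hits / counts.n_targets if counts.n_targets else float("nan")

    pid = str(records["participant_id"].iloc[0]) if "participant_id" in records else ""
    meta = {}
    for col in ("group", "age", "sex"):
        if col in records:
            meta[col] = records[col].iloc[0]
    return SessionResult(
        participant_id=pid,
        counts=counts,
        rt_series=rt_series,
        accuracy=accuracy,
        **meta,
    )


def classify_cohort(
    trials: pd.DataFrame,
    response_window: float = DEFAULT_RESPONSE_WINDOW_MS,
    soa: float = DEFAULT_SOA_MS,
) -> list[SessionResult]:
    """Classify every participant in a long trial table (grouped by id)."""
    sessions = []
    for pid, chunk in trials.groupby("participant_id", sort=True):
        chunk = chunk.sort_values("trial_index")
        sessions.append(classify_responses(chunk, response_window, soa))
    return sessions


@dataclass
class FilterReport:
    threshold: int
    n_input: int
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)


def apply_accuracy_filter(
    sessions: list[SessionResult],
    min_accuracy: float = DEFAULT_MIN_ACCURACY,
) -> tuple[list[SessionResult], FilterReport]:
    """Drop sessions whose hit count falls below ``min_accuracy`` of targets.

    A session with exactly the threshold number of hits (e.g. 60 of 100 at
    the default 60%) is retained. Returns the retained sessions and a
    report listing each exclusion with its reason.
    """
    if not (0.0 <= min_accuracy <= 1.0):
        raise ValueError("min_accuracy must lie in [0, 1]")
    n_targets = sessions[0].counts.n_targets if sessions else 0
    thr = hit_threshold(n_targets, min_accuracy)
    report = FilterReport(threshold=thr, n_input=len(sessions))
    if not sessions:
        report.warnings.append("no sessions supplied to accuracy filter")
        return [], report

    retained = []
    rows = []
    for s in sessions:
        s_thr = hit_threshold(s.counts.n_targets, min_accuracy)
        if s.counts.hits >= s_thr:
            s.passed_filter = True
            retained.append(s)
        else:
            s.passed_filter = False
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "hits": s.counts.hits,
                    "n_targets": s.counts.n_targets,
                    "accuracy": s.accuracy,
                    "reason": f"hits {s.counts.hits} < threshold {s_thr}",
                }
            )
    report.excluded = pd.DataFrame(
        rows, columns=["participant_id", "hits", "n_targets", "accuracy", "reason"]
    )
    return retained, report


def summary_table(sessions: list[SessionResult]) -> pd.DataFrame:
    """Per-participant counts/accuracy table (the `preprocess` CLI output)."""
    rows = []
    for s in sessions:
        c = s.counts
        rows.append(
            {
                "participant_id": s.participant_id,
                "hits": c.hits,
                "misses": c.misses,
                "commissions": c.commissions,
                "correct_rejections": c.correct_rejections,
                "accuracy": s.accuracy,
                "passed_filter": s.passed_filter,
            }
        )
    return pd.DataFrame(rows)
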