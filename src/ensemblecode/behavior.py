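"""Conditioned-response scoring from eyelid EMG and learning-stage labels.

A conditioned response (CR) is an anticipatory eyelid muscle burst just before
the expected US. Scoring follows the standard envelope procedure: the
instantaneous EMG amplitude is the magnitude of the analytic signal (absolute
value of the Hilbert transform); the mean amplitude over the 300 ms before CS
onset is the trial's Pre-Value, the mean over the 200 ms immediately before US
onset is its CR-Value; a session-level Threshold is the across-trial mean
Pre-Value plus two standard deviations. A trial contains a CR when its
CR-Value exceeds both its own Pre-Value and the Threshold; a trial whose
Pre-Value exceeds the Threshold is hyperactive (grooming, climbing, teeth
grinding) and excluded from CR% denominators.

Sessions are segmented into five learning stages from the daily CR%
trajectory: Before learning (all days preceding the first day with >= 30%
CRs), Learning, and three one-week Post-learning blocks beginning the day
after the first two consecutive days with >= 60% CRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .errors import CorruptInputError, ScheduleError, UndefinedValueError
from .synthetic import EmgTrace

__all__ = [
    "CrResult",
    "trial_envelope_values",
    "detect_cr",
    "score_session",
    "compute_cr_percent",
    "session_behavior",
    "assign_stages",
    "STAGES",
]

STAGES = ("BEFORE", "LEARNING", "POST_1W", "POST_2W", "POST_3W")

# scoring windows relative to CS onset (seconds, half-open)
PRE_WINDOW = (-0.300, 0.0)          # Pre-Value
PRE_PHASE_WINDOW = (-1.000, -0.800)  # CR value in the pre-CS phase (~0.9 s before CS)
CR_WINDOW_SPAN = 0.200               # CR-Value: the 200 ms ending at US onset
TRACE_MARGIN = 1.1                   # trace must cover [cs - 1.1 s, us]


@dataclass
class CrResult:
    """Per-trial CR scoring outcome."""

    session_id: int
    trial_key: tuple
    pre_value: float
    cr_value_post: float
    cr_value_pre_phase: float
    threshold: float
    is_cr: bool
    is_hyperactive: bool


def _envelope(samples: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(samples)):
        raise CorruptInputError("EMG segment contains non-finite samples")
    return np.abs(hilbert(np.asarray(samples, dtype=float)))


def trial_envelope_values(emg: EmgTrace, cs_onset_s: float,
                          us_onset_s: float) -> tuple[float, float, float]:
    """(pre_value, cr_value_post, cr_value_pre_phase) for one trial.

    The envelope is computed once over the trial segment
    ``[cs - 1.1 s, us_onset)`` so edge effects of the analytic signal fall
    outside the scoring windows.
    """
    seg_start = cs_onset_s - TRACE_MARGIN
    if seg_start < emg.t0 or us_onset_s > emg.t_end:
        raise ScheduleError(
            f"trial window [{seg_start:.3f}, {us_onset_s:.3f}) exceeds trace "
            f"bounds [{emg.t0:.3f}, {emg.t_end:.3f})")
    seg = _envelope(emg.time_slice(seg_start, us_onset_s))
    fs = emg.sample_rate

    def mean_in(rel_lo: float, rel_hi: float) -> float:
        # windows relative to CS onset, mapped into the segment
        i0 = int(round((rel_lo + TRACE_MARGIN) * fs))
        i1 = int(round((rel_hi + TRACE_MARGIN) * fs))
        return float(seg[i0:i1].mean())

    pre_value = mean_in(*PRE_WINDOW)
    cr_rel_hi = us_onset_s - cs_onset_s
    cr_value_post = mean_in(cr_rel_hi - CR_WINDOW_SPAN, cr_rel_hi)
    cr_value_pre = mean_in(*PRE_PHASE_WINDOW)
    return pre_value, cr_value_post, cr_value_pre


def detect_cr(emg: EmgTrace, cs_onset_s: float, us_onset_s: float,
              session_threshold: float, session_id: int | None = None,
              trial_key: tuple = ()) -> CrResult:
    """Score one trial against a precomputed session threshold.

    ``is_cr`` is true iff the CR-Value exceeds both the trial's Pre-Value and
    the Threshold; ``is_hyperactive`` iff the Pre-Value exceeds the Threshold.
    """
    pre, post, pre_phase = trial_envelope_values(emg, cs_onset_s, us_onset_s)
    hyper = pre > session_threshold
    is_cr = (not hyper) and (post > pre) and (post > session_threshold)
    return CrResult(
        session_id=emg.session_id if session_id is None else session_id,
        trial_key=trial_key, pre_value=pre, cr_value_post=post,
        cr_value_pre_phase=pre_phase, threshold=session_threshold,
        is_cr=is_cr, is_hyperactive=hyper)


def score_session(emg: EmgTrace, trial_table: pd.DataFrame,
                  us_offset_s: float = 0.6) -> pd.DataFrame:
    """Score every trial of one session, two-pass.

    First pass computes per-trial envelope values; the session Threshold is
    then the mean Pre-Value across all trials plus two standard deviations
    (single pass — no iterative re-thresholding after hyperactive exclusion);
    second pass applies the CR / hyperactive rules.
    """
    sess = trial_table[trial_table["session_id"] == emg.session_id]
    if sess.empty:
        raise ScheduleError(f"no trials for session {emg.session_id}")
    vals = np.array([
        trial_envelope_values(emg, row.cs_onset_s, row.cs_onset_s + us_offset_s)
        for row in sess.itertuples()
    ])
    pre, post, pre_phase = vals.T
    threshold = float(pre.mean() + 2.0 * pre.std(ddof=1))
    hyper = pre > threshold
    is_cr = ~hyper & (post > pre) & (post > threshold)
    out = sess.loc[:, ["session_id", "epoch", "trial_index", "condition"]].copy()
    out["pre_value"] = pre
    out["cr_value_post"] = post
    out["cr_value_pre_phase"] = pre_phase
    out["threshold"] = threshold
    out["is_cr"] = is_cr
    out["is_hyperactive"] = hyper
    return out.reset_index(drop=True)


def compute_cr_percent(cr_results: pd.DataFrame, condition: str) -> float:
    """CR% for a condition: 100 x (#CR trials) / (#valid trials).

    Hyperactive trials are excluded from the denominator. Zero valid trials is
    an explicit undefined-CR% condition, never a silent zero.
    """
    sub = cr_results[cr_results["condition"] == condition]
    valid = sub[~sub["is_hyperactive"]]
    if len(valid) == 0:
        raise UndefinedValueError(
            f"CR% undefined for condition {condition!r}: no valid trials")
    return 100.0 * float(valid["is_cr"].sum()) / len(valid)


def session_behavior(cr_results: pd.DataFrame) -> pd.DataFrame:
    """Per (session, condition) CR% and hyperactive fraction."""
    rows = []
    for (sid, cond), sub in cr_results.groupby(["session_id", "condition"]):
        valid = sub[~sub["is_hyperactive"]]
        rows.append({
            "session_id": sid, "condition": cond,
            "n_trials": len(sub), "n_valid": len(valid),
            "cr_percent": (100.0 * valid["is_cr"].mean()
                           if len(valid) else np.nan),
            "hyperactive_fraction": sub["is_hyperactive"].mean(),
        })
    return pd.DataFrame(rows)


def assign_stages(daily_cr_percent, before_threshold: float = 30.0,
                  post_threshold: float = 60.0, run_length: int = 2,
                  week_length: int = 7, n_post_weeks: int = 3) -> pd.DataFrame:
    """Label each day with a learning stage from its daily CR% trajectory.

    BEFORE: the maximal prefix of days with CR% below ``before_threshold``
    (30%), ending at the first day that reaches it. LEARNING: from that day
    through the second day of the first ``run_length`` consecutive days at or
    above ``post_threshold`` (60%). Post-learning weeks: subsequent days in
    ``week_length``-day blocks (POST_1W/2W/3W); days beyond the last block are
    labelled ``BEYOND`` and excluded from stage analyses. If the asymptote
    criterion is never met, all non-BEFORE days are LEARNING and a warning is
    raised.

    Parameters
    ----------
    daily_cr_percent : sequence of float
        Daily CR% (paired conditions), ordered by training day.
    """
    cr = np.asarray(list(daily_cr_percent), dtype=float)
    n = len(cr)
    stages = np.array(["LEARNING"] * n, dtype=object)

    reached = np.nonzero(cr >= before_threshold)[0]
    first_learning = reached[0] if len(reached) else n
    stages[:first_learning] = "BEFORE"

    # first run of `run_length` consecutive days at/above the post threshold
    trigger_end = None
    run = 0
    for d in range(n):
        run = run + 1 if cr[d] >= post_threshold else 0
        if run >= run_length:
            trigger_end = d
            break
    if trigger_end is None:
        if first_learning < n:
            warnings.warn("asymptote criterion never met; all non-BEFORE days "
                          "labelled LEARNING", stacklevel=2)
    else:
        for d in range(trigger_end + 1, n):
            week = (d - trigger_end - 1) // week_length
            stages[d] = (f"POST_{week + 1}W" if week < n_post_weeks else "BEYOND")
    return pd.DataFrame({"day": np.arange(1, n + 1), "cr_percent": cr,
                         "stage": stages})
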