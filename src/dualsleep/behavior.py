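"""Sleep-architecture metrics from per-minute activity logs, and arousal rates.

Fly sleep is scored from per-minute activity counts (DART pixel-change or
Trikinetics beam-crossing style): a maximal run of zero-activity minutes is
an inactivity bout; bouts of 5 min or more are sleep, bouts of 1 up to (but
not including) 5 min are "short sleep" — a behavioral proxy for the active
sleep stage. Bouts are split at light transitions under the 12:12 schedule
(lights on 08:00–20:00), so no bout can exceed 720 min. Architecture
summaries (total sleep, bout count and mean duration, short-sleep
percentage, waking activity) are reported per fly and phase, averaged per
day for multi-day logs. Air-puff responsiveness is summarized as a mean
response rate with SEM across flies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_SLEEP_MIN = 5
SHORT_SLEEP_MIN = 1
MINUTES_PER_DAY = 1440
PHASE_MINUTES = 720

BOUT_COLUMNS = ["fly_id", "start_min", "duration_min", "phase", "bout_class"]


def detect_bouts(log: pd.DataFrame) -> pd.DataFrame:
    """Find maximal inactivity runs, split at day/night boundaries.

    ``log`` needs columns fly_id, minute_index, activity, phase with
    contiguous minutes per fly. Returns one row per inactivity bout with
    start_min, duration_min, phase and bout_class = None (classification is
    a separate step).
    """
    required = {"fly_id", "minute_index", "activity", "phase"}
    if missing := required - set(log.columns):
        raise ValueError(f"log missing columns: {sorted(missing)}")

    records = []
    for fly, sub in log.groupby("fly_id", sort=False):
        sub = sub.sort_values("minute_index")
        minutes = sub["minute_index"].to_numpy()
        if len(minutes) and np.any(np.diff(minutes) != 1):
            raise ValueError(f"gaps in minute_index for fly {fly}")
        inactive = sub["activity"].to_numpy() == 0
        phase = sub["phase"].to_numpy()
        start = None
        for i in range(len(minutes) + 1):
            # a bout ends at the log end, at activity, or at a phase change
            ending = (
                start is not None
                and (i == len(minutes) or not inactive[i] or phase[i] != phase[start])
            )
            if ending:
                records.append(
                    {
                        "fly_id": fly,
                        "start_min": int(minutes[start]),
                        "duration_min": int(i - start),
                        "phase": phase[start],
                        "bout_class": None,
                    }
                )
                start = None
            if i < len(minutes) and inactive[i] and start is None:
                start = i
    return pd.DataFrame(records, columns=BOUT_COLUMNS)


def classify_bouts(
    bouts: pd.DataFrame,
    min_sleep: int = MIN_SLEEP_MIN,
    short_min: int = SHORT_SLEEP_MIN,
) -> pd.DataFrame:
    """Label inactivity bouts: >= ``min_sleep`` min is sleep, [short_min, min_sleep) is short sleep.

    A bout of exactly ``min_sleep`` minutes counts as sleep ("5 min or
    more"); anything shorter than ``short_min`` would be wake, which cannot
    occur for whole-minute logs.
    """
    out = bouts.copy()
    dur = out["duration_min"]
    out["bout_class"] = np.select(
        [dur >= min_sleep, dur >= short_min],
        ["sleep", "short_sleep"],
        default="wake",
    )
    return out


def architecture_summary(
    bouts: pd.DataFrame,
    log: pd.DataFrame,
    per_day: bool = True,
) -> pd.DataFrame:
    """Sleep architecture per fly and phase.

    Columns: total_sleep_min (sleep bouts only), bout_count, mean_bout_min
    (mean sleep-bout duration), short_sleep_pct = 100 x short-sleep minutes
    over all inactivity minutes (short + sleep), and
    waking_activity_per_min = total activity counts over waking minutes
    (minutes with activity > 0; NaN if a phase has none). With ``per_day``
    (default), totals and counts from multi-day logs are averaged per day;
    means and percentages are ratios and are unaffected.
    """
    rows = []
    for (fly, phase), sub_log in log.groupby(["fly_id", "phase"], sort=False):
        n_days = len(sub_log) / PHASE_MINUTES
        sub = bouts[(bouts["fly_id"] == fly) & (bouts["phase"] == phase)]
        sleep = sub[sub["bout_class"] == "sleep"]["duration_min"]
        short = sub[sub["bout_class"] == "short_sleep"]["duration_min"]
        total_sleep = float(sleep.sum())
        inact_total = total_sleep + float(short.sum())
        active = sub_log["activity"].to_numpy()
        waking = active > 0
        div = n_days if per_day else 1.0
        rows.append(
            {
                "fly_id": fly,
                "phase": phase,
                "total_sleep_min": total_sleep / div,
                "bout_count": len(sleep) / div,
                "mean_bout_min": float(sleep.mean()) if len(sleep) else np.nan,
                "short_sleep_pct": 100.0 * float(short.sum()) / inact_total if inact_total else np.nan,
                "waking_activity_per_min": float(active[waking].sum() / waking.sum()) if waking.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def label_windows(responses: pd.DataFrame, n_pre: int = 10) -> pd.DataFrame:
    """Tag each fly's first ``n_pre`` stimuli as 'pre' and the rest 'post'."""
    out = responses.copy()
    rank = out.groupby("fly_id")["stimulus_index"].rank(method="first") - 1
    out["window"] = np.where(rank < n_pre, "pre", "post")
    return out


def response_rate(responses: pd.DataFrame, group_col: str = "window") -> pd.DataFrame:
    """Mean behavioral response rate (%) with SEM across flies, per group.

    Each fly contributes one rate per group (its mean response to the
    stimuli in that group); the table reports 100 x the across-fly mean and
    the SEM of the fly rates. Groups with zero stimuli are absent (missing).
    """
    if group_col not in responses.columns:
        raise ValueError(f"responses missing grouping column {group_col!r}")
    per_fly = (
        responses.groupby([group_col, "fly_id"])["response"].mean().mul(100.0).rename("rate_pct")
    )
    grouped = per_fly.groupby(level=0)
    out = pd.DataFrame(
        {
            "rate_pct": grouped.mean(),
            "sem_pct": grouped.sem(),
            "n_flies": grouped.size(),
        }
    ).reset_index()
    return out
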