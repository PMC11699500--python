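"""Device resting-heart-rate derivation from PPG interbeat intervals.

The derivation reproduces a gated estimator: a 2-minute sensor window centered
on the ECG acquisition midpoint is extracted; windows containing any off-wrist
state (or no wrist data at all) are excluded; IBIs falling in "Active"
actigraphy epochs (nonzero 30-second count, or no epoch coverage) are removed;
IBIs failing the jump-distance quality rule |I_i - I_{i-1}| >= 100 ms are
removed; and if fewer than 3 IBIs remain the participant is excluded.
Otherwise RHR = 60000 * N / sum(I_i) bpm, the reciprocal of the mean retained
interval.

Quality labels are computed on the full in-window IBI run *before* any
removal, so deletions cannot manufacture spurious jumps, and the first IBI of
each contiguous run (undefined jump) is labeled good.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "VERDICT_OK",
    "VERDICT_OFF_WRIST",
    "VERDICT_NO_WRIST_DATA",
    "VERDICT_LOW_IBI",
    "MeasurementWindow",
    "label_ibi_quality",
    "extract_window",
    "compute_device_rhr",
    "mean_daily_steps_30d",
    "derive_rhr_table",
    "build_analysis_cohort",
]

VERDICT_OK = "ok"
VERDICT_OFF_WRIST = "excluded_off_wrist"
VERDICT_NO_WRIST_DATA = "excluded_no_wrist_data"
VERDICT_LOW_IBI = "excluded_low_ibi"

WINDOW_MS = 120_000
EPOCH_MS = 30_000

ACCEPTED_ECG_QUALITY = ("Excellent", "Good")


@dataclass
class MeasurementWindow:
    """The 2-minute sensor snapshot around one ECG session, plus its verdict."""

    participant_id: str
    window_start: float
    window_end: float
    ibi_t: np.ndarray  # beat timestamps (interval end), ms
    ibi: np.ndarray  # interval lengths, ms
    epoch_start: np.ndarray  # actigraphy epoch starts, ms
    epoch_count: np.ndarray
    wrist_t: np.ndarray
    wrist_on: np.ndarray  # boolean
    verdict: str | None = None
    n_retained: int = 0
    rhr: float | None = None
    quality_good: np.ndarray | None = field(default=None, repr=False)


def label_ibi_quality(t, ibi, threshold: float = 100.0) -> np.ndarray:
    """Jump-distance quality labels: True where the IBI is "good".

    The jump distance of record *i* is |I_i - I_{i-1}| taken within a
    contiguous run (consecutive timestamps differing by exactly the IBI);
    records with jump distance strictly below ``threshold`` are good, run
    starts (undefined jump) are good.
    """
    t = np.asarray(t, float)
    ibi = np.asarray(ibi, float)
    if ibi.size == 0:
        return np.zeros(0, bool)
    bad_vals = np.flatnonzero(ibi <= 0)
    if bad_vals.size:
        raise DataError(f"nonpositive IBI at record index {int(bad_vals[0])}")
    if np.any(np.diff(t) < 0):
        raise DataError("IBI records are not sorted by timestamp")
    good = np.ones(ibi.size, bool)
    if ibi.size > 1:
        gap = t[1:] - t[:-1] - ibi[1:]
        run_start = np.abs(gap) > 0.5  # ms tolerance for contiguity
        jump = np.abs(ibi[1:] - ibi[:-1])
        good[1:] = run_start | (jump < threshold)
    return good


def extract_window(session: pd.Series, streams: dict[str, pd.DataFrame]) -> MeasurementWindow:
    """Slice one participant's streams to the 2-minute window.

    The window is the half-open interval [mid - 60 s, mid + 60 s) around the
    ECG acquisition midpoint; an IBI belongs iff its end-timestamp falls in the
    window; actigraphy epochs and wrist records are attached if they overlap.
    """
    mid = (float(session["ecg_start_ms"]) + float(session["ecg_end_ms"])) / 2.0
    ws, we = mid - WINDOW_MS / 2, mid + WINDOW_MS / 2

    ibi_df = streams.get("ibi")
    if ibi_df is not None and len(ibi_df):
        t = ibi_df["t_ms"].to_numpy(float)
        sel = (t >= ws) & (t < we)
        ibi_t, ibi = t[sel], ibi_df["ibi_ms"].to_numpy(float)[sel]
    else:
        ibi_t = ibi = np.zeros(0)

    acti_df = streams.get("actigraphy")
    if acti_df is not None and len(acti_df):
        es = acti_df["epoch_start_ms"].to_numpy(float)
        sel = (es + EPOCH_MS > ws) & (es < we)
        epoch_start, epoch_count = es[sel], acti_df["count"].to_numpy(float)[sel]
    else:
        epoch_start = epoch_count = np.zeros(0)

    wrist_df = streams.get("wrist")
    if wrist_df is not None and len(wrist_df):
        wt = wrist_df["t_ms"].to_numpy(float)
        on = wrist_df["on_wrist"].to_numpy(float) > 0
        # a wrist record's state holds until the next record: the records
        # overlapping the window are those inside it plus the latest one at or
        # before the window start
        inside = (wt >= ws) & (wt < we)
        before = np.flatnonzero(wt <= ws)
        if before.size:
            inside[before[-1]] = True
        wrist_t, wrist_on = wt[inside], on[inside]
    else:
        wrist_t, wrist_on = np.zeros(0), np.zeros(0, bool)

    return MeasurementWindow(
        participant_id=str(session["participant_id"]),
        window_start=ws,
        window_end=we,
        ibi_t=ibi_t,
        ibi=ibi,
        epoch_start=epoch_start,
        epoch_count=epoch_count,
        wrist_t=wrist_t,
        wrist_on=wrist_on,
    )


def compute_device_rhr(
    window: MeasurementWindow,
    jump_threshold: float = 100.0,
    min_ibis: int = 3,
) -> MeasurementWindow:
    """Apply the gating filters in order and set verdict / N / RHR in place.

    Filter order: off-wrist (or absent wrist data) excludes the window
    outright; quality labels are then computed on the full in-window run;
    IBIs in Active epochs are removed (no epoch coverage counts as Active);
    bad-quality IBIs are removed; fewer than ``min_ibis`` survivors excludes
    the participant, otherwise RHR = 60000 * N / sum(I).
    """
    if window.wrist_t.size == 0:
        window.verdict = VERDICT_NO_WRIST_DATA
        return window
    if np.any(~window.wrist_on):
        window.verdict = VERDICT_OFF_WRIST
        return window

    good = label_ibi_quality(window.ibi_t, window.ibi, jump_threshold)
    window.quality_good = good

    still = np.zeros(window.ibi_t.size, bool)
    if window.epoch_start.size and window.ibi_t.size:
        order = np.argsort(window.epoch_start)
        starts = window.epoch_start[order]
        counts = window.epoch_count[order]
        idx = np.searchsorted(starts, window.ibi_t, side="right") - 1
        covered = (idx >= 0) & (window.ibi_t < starts[np.clip(idx, 0, None)] + EPOCH_MS)
        still = covered & (counts[np.clip(idx, 0, None)] == 0)

    keep = still & good
    n = int(keep.sum())
    if n < min_ibis:
        window.verdict = VERDICT_LOW_IBI
        window.n_retained = n
        return window
    window.verdict = VERDICT_OK
    window.n_retained = n
    window.rhr = 60_000.0 * n / float(window.ibi[keep].sum())
    return window


def mean_daily_steps_30d(
    step_days: pd.DataFrame,
    enrollment_date,
    min_wear_minutes: int = 600,
) -> float | None:
    """Mean daily steps over the 30 days after enrollment with >= 10 h wear.

    Only days 1..30 following ``enrollment_date`` with
    ``wear_minutes >= min_wear_minutes`` contribute; returns None when no day
    qualifies.
    """
    if not len(step_days):
        return None
    dates = pd.to_datetime(step_days["date"])
    enrollment = pd.Timestamp(enrollment_date)
    offset = (dates - enrollment).dt.days
    ok = (offset >= 1) & (offset <= 30) & (step_days["wear_minutes"] >= min_wear_minutes)
    if not ok.any():
        return None
    return float(step_days.loc[ok, "steps"].mean())


def _streams_by_participant(df: pd.DataFrame | None) -> dict:
    if df is None or not len(df):
        return {}
    return {pid: g for pid, g in df.groupby("participant_id", sort=False)}


def derive_rhr_table(
    ecg: pd.DataFrame,
    ibi: pd.DataFrame,
    actigraphy: pd.DataFrame,
    wrist: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    jump_threshold: float = 100.0,
    min_ibis: int = 3,
) -> pd.DataFrame:
    """Run window extraction + gating for every ECG session.

    Returns one row per session: participant_id, verdict, n_retained,
    device_rhr_bpm, ecg_rhr_bpm, ecg_quality (+ sex/age when ``participants``
    is given).
    """
    if ecg["participant_id"].duplicated().any():
        dup = ecg.loc[ecg["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise DataError(f"duplicate ECG session for participant {dup!r}")
    ibi_by = _streams_by_participant(ibi)
    acti_by = _streams_by_participant(actigraphy)
    wrist_by = _streams_by_participant(wrist)

    rows = []
    for _, session in ecg.iterrows():
        pid = session["participant_id"]
        window = extract_window(
            session,
            {
                "ibi": ibi_by.get(pid),
                "actigraphy": acti_by.get(pid),
                "wrist": wrist_by.get(pid),
            },
        )
        compute_device_rhr(window, jump_threshold=jump_threshold, min_ibis=min_ibis)
        rows.append(
            {
                "participant_id": pid,
                "verdict": window.verdict,
                "n_retained": window.n_retained,
                "device_rhr_bpm": window.rhr,
                "ecg_rhr_bpm": float(session["ecg_rhr_bpm"]),
                "ecg_quality": session["quality"],
            }
        )
    out = pd.DataFrame(rows)
    if participants is not None:
        out = out.merge(participants[["participant_id", "sex", "age"]], on="participant_id", how="left")
    return out


def build_analysis_cohort(rhr_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply cohort criteria and produce the exclusion-flow accounting.

    Participants enter the paired analysis cohort when their ECG quality is
    Excellent/Good and the device window verdict is ok.  Returns
    (pairs, flow): ``pairs`` has participant_id, ecg_rhr, device_rhr (+ sex,
    age if present); ``flow`` counts each stage so that
    cohort + sum(exclusions) equals the input count.
    """
    if rhr_table["participant_id"].duplicated().any():
        dup = rhr_table.loc[rhr_table["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise DataError(f"duplicate participant {dup!r} in RHR table")
    n_input = len(rhr_table)
    ecg_ok = rhr_table["ecg_quality"].isin(ACCEPTED_ECG_QUALITY)
    n_ecg_excl = int((~ecg_ok).sum())
    remaining = rhr_table[ecg_ok]

    counts = {
        VERDICT_NO_WRIST_DATA: int((remaining["verdict"] == VERDICT_NO_WRIST_DATA).sum()),
        VERDICT_OFF_WRIST: int((remaining["verdict"] == VERDICT_OFF_WRIST).sum()),
        VERDICT_LOW_IBI: int((remaining["verdict"] == VERDICT_LOW_IBI).sum()),
    }
    cohort = remaining[remaining["verdict"] == VERDICT_OK]

    flow = pd.DataFrame(
        [
            ("input", n_input),
            ("excluded_ecg_quality", n_ecg_excl),
            (VERDICT_NO_WRIST_DATA, counts[VERDICT_NO_WRIST_DATA]),
            (VERDICT_OFF_WRIST, counts[VERDICT_OFF_WRIST]),
            (VERDICT_LOW_IBI, counts[VERDICT_LOW_IBI]),
            ("cohort", len(cohort)),
        ],
        columns=["stage", "count"],
    )

    cols = ["participant_id", "ecg_rhr_bpm", "device_rhr_bpm"]
    extra = [c for c in ("sex", "age") if c in cohort.columns]
    pairs = cohort[cols + extra].rename(
        columns={"ecg_rhr_bpm": "ecg_rhr", "device_rhr_bpm": "device_rhr"}
    )
    return pairs.reset_index(drop=True), flow
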