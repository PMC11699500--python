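"""Synthetic wearable-cohort generator.

Produces the full bundle of sensor and clinical tables a wearable RHR study
would collect: per-participant PPG interbeat-interval (IBI) streams around a
single in-clinic ECG session, 30-second actigraphy epochs, on-wrist states,
30 days of daily step summaries, and a domain-tagged baseline-covariate table
— together with a ground-truth table recording each participant's latent RHR
and any deliberately induced exclusion.

Mechanisms
----------
* Latent RHR: sex-specific mean plus an inverted-U age term
  ``age_curvature * (age - age_peak)^2`` (centered within sex), with the
  Gaussian residual scaled so the marginal SD hits the configured target.
* ECG reference: latent RHR plus N(0, ecg_noise_sd).
* Device: beats are emitted at 60000/latent-device-RHR ms with N(0, hrv_sd)
  jitter; with per-beat probability ``artifact_rate * (IBI/1000 ms)**
  artifact_hr_coupling`` a beat is split into two near-halves (a false beat).
  Splitting shortens the retained mean IBI downstream, giving a small positive
  device bias that declines with reference RHR when the coupling is positive.
* Clean injection knobs ``device_offset_bpm`` / ``device_slope`` shift the
  latent device RHR additively and proportionally to (latent - configured
  cohort mean), for parameter-recovery studies with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .covariates import CovariateTable, generate_covariates
from .exceptions import ConfigError

__all__ = [
    "CohortBundle",
    "generate_cohort",
    "generate_ibi_stream",
    "simulate_paired_rhr",
]

SESSION_START_MS = 3_600_000  # 1 h into the participant's day-0 record
ECG_DURATION_MS = 10_000  # 10-second ECG acquisition
EPOCH_MS = 30_000
WRIST_INTERVAL_MS = 60_000
STREAM_MARGIN_MS = 70_000  # sensor coverage beyond the 2-min window
ENROLLMENT_DATE = pd.Timestamp("2017-06-01")


@dataclass
class CohortBundle:
    """All tables for one synthetic cohort (CSV-ready DataFrames)."""

    participants: pd.DataFrame  # participant_id, sex, age
    ibi: pd.DataFrame  # participant_id, t_ms, ibi_ms
    actigraphy: pd.DataFrame  # participant_id, epoch_start_ms, count
    wrist: pd.DataFrame  # participant_id, t_ms, on_wrist
    ecg: pd.DataFrame  # participant_id, ecg_start_ms, ecg_end_ms, ecg_rhr_bpm, quality
    steps: pd.DataFrame  # participant_id, date, steps, wear_minutes
    covariates: CovariateTable
    ground_truth: pd.DataFrame  # participant_id, sex, age, true_rhr, device_rhr_latent, induced_exclusion

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.ibi.to_csv(out / "ibi.csv", index=False)
        self.actigraphy.to_csv(out / "actigraphy.csv", index=False)
        self.wrist.to_csv(out / "wrist.csv", index=False)
        self.ecg.to_csv(out / "ecg.csv", index=False)
        self.steps.to_csv(out / "steps.csv", index=False)
        self.covariates.to_long().to_csv(out / "covariates.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def _draw_true_rhr(sex, age, config, rng):
    """Sex mean + centered inverted-U age term, residual scaled to target SD."""
    rhr = np.empty(len(sex))
    for s, mean, sd in (
        ("female", config.rhr_mean_female, config.rhr_sd_female),
        ("male", config.rhr_mean_male, config.rhr_sd_male),
    ):
        idx = np.flatnonzero(sex == s)
        if idx.size == 0:
            continue
        d = config.age_curvature * (age[idx] - config.age_peak) ** 2
        d = d - d.mean()
        var_d = float(np.var(d))
        if var_d >= sd**2 and var_d > 0:
            d = d * (sd / np.sqrt(var_d))
            resid_sd = 0.0
        else:
            resid_sd = np.sqrt(sd**2 - var_d)
        rhr[idx] = mean + d + rng.normal(0.0, resid_sd, idx.size)
    return np.maximum(rhr, 30.0)


def generate_ibi_stream(
    device_rhr: float,
    span: tuple[float, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Emit (t_ms, ibi_ms) integer arrays covering ``span``.

    Timestamps mark the *end* of each interval and consecutive timestamps
    differ by exactly the emitted IBI, so elapsed time is conserved — a split
    beat yields two IBIs summing to the original interval.
    """
    start, end = span
    if end <= start:
        raise ConfigError("IBI stream span must have positive duration")
    mean_ibi = 60_000.0 / device_rhr
    n_base = int(np.ceil((end - start) / mean_ibi)) + 8
    base = np.rint(mean_ibi + rng.normal(0.0, config.hrv_sd, n_base))
    base = np.maximum(base, 250.0)  # physiological floor, 240 bpm

    if config.artifact_rate > 0:
        p = config.artifact_rate * (base / 1000.0) ** config.artifact_hr_coupling
        split = rng.random(n_base) < np.clip(p, 0.0, 0.95)
    else:
        split = np.zeros(n_base, bool)
    frac = rng.uniform(0.45, 0.55, n_base)
    first = np.rint(frac * base)
    second = base - first

    reps = np.where(split, 2, 1)
    out = np.empty(int(reps.sum()))
    pos = np.cumsum(reps) - reps
    out[pos[~split]] = base[~split]
    out[pos[split]] = first[split]
    out[pos[split] + 1] = second[split]

    t = start + np.cumsum(out)
    keep = t <= end + out.max()
    return t[keep].astype(np.int64), out[keep].astype(np.int64)


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the full cohort bundle; identical config+seed is reproducible."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    pid = np.array([f"P{i:05d}" for i in range(n)], object)
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    age = np.round(rng.uniform(*config.age_range, n), 1)
    true_rhr = _draw_true_rhr(sex, age, config, rng)

    ecg_rhr = true_rhr + rng.normal(0.0, config.ecg_noise_sd, n)
    ecg_rhr = np.maximum(ecg_rhr, 30.0)
    device_latent = (
        true_rhr
        + config.device_offset_bpm
        + config.device_slope * (true_rhr - config.rhr_mean_overall)
    )

    # deliberately induced exclusions (mutually exclusive per participant)
    u = rng.random(n)
    induced = np.full(n, "none", object)
    induced[u < config.p_off_wrist] = "off_wrist"
    hi = config.p_off_wrist + config.p_induce_active
    induced[(u >= config.p_off_wrist) & (u < hi)] = "active"
    induced[(u >= hi) & (u < hi + config.p_induce_low_ibi)] = "low_ibi"

    mid = SESSION_START_MS + ECG_DURATION_MS // 2
    win_start, win_end = mid - 60_000, mid + 60_000
    span = (mid - STREAM_MARGIN_MS, mid + STREAM_MARGIN_MS)

    ibi_parts, acti_parts, wrist_parts = [], [], []
    epoch_grid = np.arange(
        (span[0] // EPOCH_MS) * EPOCH_MS, span[1] + EPOCH_MS, EPOCH_MS, dtype=np.int64
    )
    in_window_epochs = (epoch_grid + EPOCH_MS > win_start) & (epoch_grid < win_end)
    wrist_grid = np.arange(span[0], span[1] + WRIST_INTERVAL_MS, WRIST_INTERVAL_MS, dtype=np.int64)

    for i in range(n):
        if induced[i] == "low_ibi":
            # sparse stream: two isolated beats inside the window
            t = np.array([mid - 10_000, mid - 9_100], np.int64)
            ibis = np.array([900, 900], np.int64)
        else:
            t, ibis = generate_ibi_stream(device_latent[i], span, config, rng)
        ibi_parts.append(pd.DataFrame({"participant_id": pid[i], "t_ms": t, "ibi_ms": ibis}))

        if induced[i] == "active":
            counts = 1 + rng.poisson(25.0, epoch_grid.size)
        else:
            active = rng.random(epoch_grid.size) < config.p_active_epoch
            counts = np.where(active, 1 + rng.poisson(25.0, epoch_grid.size), 0)
        acti_parts.append(
            pd.DataFrame({"participant_id": pid[i], "epoch_start_ms": epoch_grid, "count": counts})
        )

        on = np.ones(wrist_grid.size, np.int64)
        if induced[i] == "off_wrist":
            inside = (wrist_grid >= win_start) & (wrist_grid < win_end)
            on[np.flatnonzero(inside)[0]] = 0
        wrist_parts.append(pd.DataFrame({"participant_id": pid[i], "t_ms": wrist_grid, "on_wrist": on}))

    participants = pd.DataFrame({"participant_id": pid, "sex": sex, "age": age})
    ecg = pd.DataFrame(
        {
            "participant_id": pid,
            "ecg_start_ms": SESSION_START_MS,
            "ecg_end_ms": SESSION_START_MS + ECG_DURATION_MS,
            "ecg_rhr_bpm": np.round(ecg_rhr, 2),
            "quality": "Excellent",
        }
    )

    # 30 days of step summaries; steps decline mildly with latent RHR
    dates = ENROLLMENT_DATE + pd.to_timedelta(np.arange(1, 31), unit="D")
    log_steps = (
        np.log(8000.0)
        - 0.010 * (true_rhr - config.rhr_mean_overall)[:, None]
        + rng.normal(0.0, 0.35, (n, 30))
    )
    steps_mat = np.rint(np.exp(log_steps)).astype(np.int64)
    wear = np.clip(np.rint(rng.normal(840.0, 200.0, (n, 30))), 0, 1440).astype(np.int64)
    steps = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, 30),
            "date": np.tile(dates.strftime("%Y-%m-%d"), n),
            "steps": steps_mat.ravel(),
            "wear_minutes": wear.ravel(),
        }
    )

    gt_df = participants.assign(
        true_rhr=np.round(true_rhr, 3),
        device_rhr_latent=np.round(device_latent, 3),
        induced_exclusion=induced,
    )
    covariates = generate_covariates(
        gt_df[["participant_id", "sex", "true_rhr"]], config,
        rng=np.random.default_rng(rng.integers(2**31)),
    )

    return CohortBundle(
        participants=participants,
        ibi=pd.concat(ibi_parts, ignore_index=True),
        actigraphy=pd.concat(acti_parts, ignore_index=True),
        wrist=pd.concat(wrist_parts, ignore_index=True),
        ecg=ecg,
        steps=steps,
        covariates=covariates,
        ground_truth=gt_df,
    )


def simulate_paired_rhr(
    n: int,
    mean: float = 65.0,
    between_sd: float = 11.5,
    ecg_error_sd: float = 2.7,
    device_error_sd: float = 2.7,
    bias: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Directly simulate paired (ECG, device) RHR readings.

    A lightweight generator for agreement-statistic studies: both methods read
    the same latent per-participant RHR, each with independent Gaussian error;
    ``bias`` is added to the device reading.  Returns columns participant_id,
    ecg_rhr, device_rhr, sex, age.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(mean, between_sd, n)
    ecg = latent + rng.normal(0.0, ecg_error_sd, n)
    dev = latent + bias + rng.normal(0.0, device_error_sd, n)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "ecg_rhr": ecg,
            "device_rhr": dev,
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age": np.round(rng.uniform(18, 84, n), 1),
        }
    )
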