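"""Method-comparison statistics for device vs ECG resting heart rate.

Implements the agreement analysis between a wrist device and a 12-lead ECG
reference: the two-way random-effects absolute-agreement single-measure
intraclass correlation ICC(2,1), the mean bias (device minus reference), the
slope of the difference regressed on the reference (proportional error), and
seeded percentile-bootstrap confidence intervals — overall and per sex.

The modelling interface follows the Model/Results convention:

>>> res = MethodAgreement(pairs).fit(n_boot=1000, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientDataError

__all__ = [
    "icc_agreement",
    "bias_and_slope",
    "bootstrap_ci",
    "MethodAgreement",
    "MethodAgreementResults",
]


def icc_agreement(ecg, device) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2
    (participant x method) table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with k = 2 methods.
    """
    x = np.column_stack([np.asarray(ecg, float), np.asarray(device, float)])
    n, k = x.shape
    if n < 3:
        raise InsufficientDataError(f"ICC needs at least 3 pairs, got {n}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0  # all readings identical
    return float((msr - mse) / denom)


def bias_and_slope(ecg, device) -> tuple[float, float]:
    """Mean difference (device - ecg) and OLS slope of the difference on ecg."""
    ecg = np.asarray(ecg, float)
    device = np.asarray(device, float)
    if ecg.size < 3:
        raise InsufficientDataError(f"bias/slope need at least 3 pairs, got {ecg.size}")
    diff = device - ecg
    bias = float(diff.mean())
    sxx = np.sum((ecg - ecg.mean()) ** 2)
    if sxx == 0:
        raise DataError("slope undefined: zero variance in ECG RHR")
    slope = float(np.sum((ecg - ecg.mean()) * (diff - diff.mean())) / sxx)
    return bias, slope


def bootstrap_ci(
    pairs: pd.DataFrame,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap over participants.

    ``statistic`` maps a resampled pairs DataFrame to a scalar.  Degenerate
    resamples (statistic raises or returns non-finite) are redrawn, with a cap
    of ``10 * n_boot`` total draws.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"bootstrap needs at least 3 pairs, got {n}")
    values = np.empty(n_boot)
    attempts = 0
    filled = 0
    while filled < n_boot:
        if attempts >= 10 * n_boot:
            raise DataError("bootstrap failed: too many degenerate resamples")
        attempts += 1
        idx = rng.integers(0, n, n)
        try:
            v = float(statistic(pairs.iloc[idx]))
        except DataError:
            continue
        if not np.isfinite(v):
            continue
        values[filled] = v
        filled += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class StratumReport:
    stratum: str
    n: int
    icc: float
    bias: float
    bias_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]


class MethodAgreement:
    """Agreement model for paired device/reference RHR readings.

    Parameters
    ----------
    pairs : DataFrame with columns ``ecg_rhr``, ``device_rhr`` and optionally
        ``sex`` (values "female"/"male") for the subgroup analyses.
    """

    def __init__(self, pairs: pd.DataFrame):
        missing = {"ecg_rhr", "device_rhr"} - set(pairs.columns)
        if missing:
            raise DataError(f"pairs table missing columns: {sorted(missing)}")
        bad = pairs[(pairs["ecg_rhr"] <= 0) | (pairs["device_rhr"] <= 0)]
        if len(bad):
            raise DataError(
                f"nonpositive RHR for participant "
                f"{bad.iloc[0].get('participant_id', bad.index[0])!r}"
            )
        self.pairs = pairs.reset_index(drop=True)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, ecg_col: str = "ecg_rhr", device_col: str = "device_rhr"
    ) -> "MethodAgreement":
        renamed = df.rename(columns={ecg_col: "ecg_rhr", device_col: "device_rhr"})
        return cls(renamed)

    def _strata(self):
        yield "all", self.pairs
        if "sex" in self.pairs.columns:
            for s in ("female", "male"):
                yield s, self.pairs[self.pairs["sex"] == s]

    def fit(
        self, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
    ) -> "MethodAgreementResults":
        reports = []
        for i, (name, sub) in enumerate(self._strata()):
            if len(sub) < 3:
                warnings.warn(f"stratum {name!r} has fewer than 3 pairs; skipped")
                continue
            icc = icc_agreement(sub["ecg_rhr"], sub["device_rhr"])
            bias, slope = bias_and_slope(sub["ecg_rhr"], sub["device_rhr"])
            stratum_seed = None if seed is None else seed + i
            bias_ci = bootstrap_ci(
                sub, lambda d: bias_and_slope(d["ecg_rhr"], d["device_rhr"])[0],
                n_boot=n_boot, level=level, seed=stratum_seed,
            )
            slope_ci = bootstrap_ci(
                sub, lambda d: bias_and_slope(d["ecg_rhr"], d["device_rhr"])[1],
                n_boot=n_boot, level=level, seed=stratum_seed,
            )
            reports.append(StratumReport(name, len(sub), icc, bias, bias_ci, slope, slope_ci))
        return MethodAgreementResults(self, reports, n_boot=n_boot, level=level, seed=seed)


class MethodAgreementResults:
    """Fitted agreement statistics with per-stratum bootstrap intervals."""

    def __init__(self, model, reports, n_boot, level, seed):
        self.model = model
        self.reports = {r.stratum: r for r in reports}
        self.n_boot = n_boot
        self.level = level
        self.seed = seed

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": r.stratum,
                "n": r.n,
                "icc": r.icc,
                "bias": r.bias,
                "bias_lo": r.bias_ci[0],
                "bias_hi": r.bias_ci[1],
                "slope": r.slope,
                "slope_lo": r.slope_ci[0],
                "slope_hi": r.slope_ci[1],
            }
            for r in self.reports.values()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pct = int(round(self.level * 100))
        lines = [
            "Device vs ECG resting-heart-rate agreement",
            f"(percentile bootstrap, {self.n_boot} resamples, {pct}% CI)",
            "",
            f"{'stratum':<8}{'n':>6}{'ICC(2,1)':>10}{'bias bpm':>10}"
            f"{'bias CI':>18}{'slope':>9}{'slope CI':>20}",
        ]
        for r in self.reports.values():
            lines.append(
                f"{r.stratum:<8}{r.n:>6}{r.icc:>10.3f}{r.bias:>10.2f}"
                f"{f'({r.bias_ci[0]:.2f}, {r.bias_ci[1]:.2f})':>18}"
                f"{r.slope:>9.3f}"
                f"{f'({r.slope_ci[0]:.3f}, {r.slope_ci[1]:.3f})':>20}"
            )
        return "\n".join(lines)

    def plot_agreement(self, ax=None):
        """Scatter of device vs ECG RHR with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.model.pairs
        ax.scatter(p["ecg_rhr"], p["device_rhr"], s=8, alpha=0.5)
        lims = [min(p["ecg_rhr"].min(), p["device_rhr"].min()),
                max(p["ecg_rhr"].max(), p["device_rhr"].max())]
        ax.plot(lims, lims, color="k", lw=1)
        overall = self.reports.get("all")
        title = "Device vs ECG RHR"
        if overall is not None:
            title += f" (ICC={overall.icc:.3f})"
        ax.set_xlabel("ECG RHR (bpm)")
        ax.set_ylabel("Device RHR (bpm)")
        ax.set_title(title)
        return ax
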