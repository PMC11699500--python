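"""Baseline-covariate dictionary, container, and synthetic generation.

Covariates are grouped into five domains mirroring a deep-phenotyping baseline
assessment: demographics & socioeconomic status, medical conditions, vitals &
physical function, laboratory assessments, and patient-reported outcomes
(PROs).  Each synthetic covariate is linked to the participant's latent
resting heart rate through a simple generative form — a logistic link for
binary traits, a linear-Gaussian (or log-linear for skewed labs) form for
continuous ones — so downstream trend tests and penalized regressions have
known ground truth.  Effect sizes are expressed per bpm of latent RHR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .exceptions import ConfigError, DataError

__all__ = ["CovariateSpec", "CovariateTable", "COVARIATE_DICTIONARY", "generate_covariates"]

DOMAINS = ("demographics_ses", "conditions", "vitals_physical", "labs", "pros")


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    domain: str
    kind: str  # "binary" | "categorical" | "continuous"
    # binary: prevalence; continuous: (mean, sd); categorical: {level: prob}
    params: object
    effect: float = 0.0  # default link slope per bpm (logit/bpm or units/bpm)
    lognormal: bool = False  # continuous only: generate on the log scale
    lower: float | None = None  # truncation bound after generation
    boxcox: bool = False  # Box-Cox candidate in the regression pipeline


def _spec(name, domain, kind, params, effect=0.0, **kw):
    return CovariateSpec(name, domain, kind, params, effect, **kw)


# Defaults chosen once as realistic for a middle-aged ambulatory cohort; the
# signed effects reproduce the association directions the analysis is built to
# detect (e.g. smoking, BMI, CRP, diabetes, disability score all positive;
# six-minute-walk distance negative; unemployment the strongest
# demographics signal).
COVARIATE_DICTIONARY: dict[str, CovariateSpec] = {
    s.name: s
    for s in [
        # demographics & SES
        _spec("race", "demographics_ses", "categorical",
              {"White": 0.65, "Black": 0.17, "Asian": 0.08, "Other": 0.10}),
        _spec("hispanic", "demographics_ses", "binary", 0.12),
        _spec("education", "demographics_ses", "categorical",
              {"high_school_or_less": 0.12, "any_college": 0.60, "graduate_degree": 0.28}),
        _spec("married", "demographics_ses", "binary", 0.55, effect=-0.02),
        _spec("unemployed", "demographics_ses", "binary", 0.08, effect=0.07),
        _spec("no_insurance", "demographics_ses", "binary", 0.07, effect=0.05),
        _spec("current_smoker", "demographics_ses", "binary", 0.15, effect=0.05),
        # medical conditions
        _spec("type2_diabetes", "conditions", "binary", 0.10, effect=0.07),
        _spec("hypertension", "conditions", "binary", 0.30, effect=0.04),
        _spec("asthma", "conditions", "binary", 0.14),
        _spec("depression_mdd", "conditions", "binary", 0.15, effect=0.04),
        _spec("gerd", "conditions", "binary", 0.15),
        # vitals & physical function
        _spec("bmi", "vitals_physical", "continuous", (27.5, 5.0), effect=0.18,
              lower=14.0, boxcox=True),
        _spec("systolic_bp", "vitals_physical", "continuous", (122.0, 13.0), effect=0.15,
              lower=70.0, boxcox=True),
        _spec("diastolic_bp", "vitals_physical", "continuous", (76.0, 9.0), effect=0.28,
              lower=40.0, boxcox=True),
        _spec("waist_circumference_cm", "vitals_physical", "continuous", (95.0, 13.0),
              effect=0.35, lower=50.0, boxcox=True),
        _spec("six_minute_walk_m", "vitals_physical", "continuous", (520.0, 85.0),
              effect=-2.0, lower=50.0, boxcox=True),
        _spec("grip_strength_kg", "vitals_physical", "continuous", (32.0, 9.0),
              effect=-0.10, lower=5.0, boxcox=True),
        # laboratory assessments
        _spec("crp_mg_l", "labs", "continuous", (0.4, 0.9), effect=0.025,
              lognormal=True, boxcox=True),
        _spec("hba1c_pct", "labs", "continuous", (5.6, 0.6), effect=0.012,
              lower=4.0, boxcox=True),
        _spec("ldl_mg_dl", "labs", "continuous", (110.0, 28.0), lower=30.0, boxcox=True),
        _spec("hdl_mg_dl", "labs", "continuous", (55.0, 14.0), effect=-0.30,
              lower=15.0, boxcox=True),
        _spec("platelets_10e9_l", "labs", "continuous", (250.0, 55.0), effect=1.0,
              lower=80.0, boxcox=True),
        _spec("triglycerides_mg_dl", "labs", "continuous", (4.7, 0.45), effect=0.01,
              lognormal=True, boxcox=True),
        # patient-reported outcomes
        _spec("whodas_score", "pros", "continuous", (12.0, 7.5), effect=0.25, lower=0.0),
        _spec("phq9_score", "pros", "continuous", (4.0, 3.8), effect=0.08, lower=0.0),
        _spec("gad7_score", "pros", "continuous", (3.0, 3.3), effect=0.06, lower=0.0),
        _spec("brfss_ace_score", "pros", "continuous", (1.8, 2.0), effect=0.05, lower=0.0),
        _spec("sleep_hours", "pros", "continuous", (7.0, 1.0), effect=-0.02, lower=2.0),
    ]
}


class CovariateTable:
    """Wide per-participant covariate table plus per-covariate metadata.

    ``data`` is indexed by participant_id; ``meta`` maps covariate name to
    (domain, kind).  Missing entries are NaN (continuous/binary) or pandas NA
    (categorical labels).
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame):
        unknown_domains = set(meta["domain"]) - set(DOMAINS)
        if unknown_domains:
            raise DataError(f"unknown covariate domains: {sorted(unknown_domains)}")
        missing_meta = [c for c in data.columns if c not in meta.index]
        if missing_meta:
            raise DataError(f"covariates without metadata: {missing_meta}")
        self.data = data
        self.meta = meta.loc[list(data.columns)]

    def names(self, domain: str | None = None, kind: str | None = None) -> list[str]:
        m = self.meta
        if domain is not None:
            m = m[m["domain"] == domain]
        if kind is not None:
            m = m[m["kind"] == kind]
        return list(m.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format (participant_id, covariate, domain, type, value)."""
        frames = []
        for name in self.data.columns:
            domain, kind = self.meta.loc[name, ["domain", "kind"]]
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": self.data.index,
                        "covariate": name,
                        "domain": domain,
                        "type": kind,
                        "value": self.data[name].values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, long_df: pd.DataFrame) -> "CovariateTable":
        required = {"participant_id", "covariate", "domain", "type", "value"}
        missing = required - set(long_df.columns)
        if missing:
            raise DataError(f"covariate table missing columns: {sorted(missing)}")
        meta = (
            long_df[["covariate", "domain", "type"]]
            .drop_duplicates()
            .set_index("covariate")
            .rename(columns={"type": "kind"})
        )
        if meta.index.duplicated().any():
            dupes = meta.index[meta.index.duplicated()].tolist()
            raise DataError(f"covariates with conflicting metadata: {dupes}")
        wide = long_df.pivot(index="participant_id", columns="covariate", values="value")
        wide = wide[list(meta.index)]
        for name in meta.index:
            if meta.loc[name, "kind"] in ("binary", "continuous"):
                wide[name] = pd.to_numeric(wide[name], errors="coerce")
        return cls(wide, meta)


def generate_covariates(
    participants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CovariateTable:
    """Draw domain-tagged covariates linked to each participant's latent RHR.

    ``participants`` needs columns participant_id, sex, true_rhr.  Effects in
    ``config.covariate_effects`` override the dictionary defaults (per-bpm
    slopes; unknown names raise :class:`ConfigError`).  A ``missing_rate``
    fraction of cells is then blanked completely at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    effects = dict(config.covariate_effects or {})
    unknown = set(effects) - set(COVARIATE_DICTIONARY)
    if unknown:
        raise ConfigError(f"unknown covariate name(s) in covariate_effects: {sorted(unknown)}")

    n = len(participants)
    rhr = participants["true_rhr"].to_numpy(float)
    sex = participants["sex"].to_numpy()
    centered = rhr.copy()
    for s, mean in (("female", config.rhr_mean_female), ("male", config.rhr_mean_male)):
        centered[sex == s] = rhr[sex == s] - mean

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for name, spec in COVARIATE_DICTIONARY.items():
        beta = effects.get(name, spec.effect)
        if spec.kind == "binary":
            base_logit = np.log(spec.params / (1.0 - spec.params))
            p = 1.0 / (1.0 + np.exp(-(base_logit + beta * centered)))
            cols[name] = (rng.random(n) < p).astype(float)
        elif spec.kind == "categorical":
            levels = list(spec.params)
            probs = np.asarray([spec.params[lv] for lv in levels], float)
            probs = probs / probs.sum()
            draw = rng.choice(len(levels), size=n, p=probs)
            cols[name] = np.asarray(levels, object)[draw]
        else:
            mean, sd = spec.params
            values = mean + beta * centered + rng.normal(0.0, sd, n)
            if spec.lognormal:
                values = np.exp(values)
            if spec.lower is not None:
                values = np.maximum(values, spec.lower)
            cols[name] = np.round(values, 3)
        meta_rows.append((name, spec.domain, spec.kind))

    data = pd.DataFrame(cols, index=pd.Index(participants["participant_id"], name="participant_id"))
    if config.missing_rate > 0:
        mask = rng.random(data.shape) < config.missing_rate
        for j, name in enumerate(data.columns):
            data.loc[mask[:, j], name] = (
                pd.NA if COVARIATE_DICTIONARY[name].kind == "categorical" else np.nan
            )
    meta = pd.DataFrame(meta_rows, columns=["covariate", "domain", "kind"]).set_index("covariate")
    return CovariateTable(data, meta)
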