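"""End-to-end orchestration: simulate -> derive -> validate -> trends ->
associations, with a reproducibility manifest.

Each stage's randomness is seeded from a master seed via fixed offsets, so a
run is a pure function of (inputs, config, seed).  The manifest records the
config snapshot, per-stage seeds and timings, SHA-256 digests of every output
file, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .associations import RHRAssociationModel
from .config import SimulationConfig
from .covariates import CovariateTable
from .derive import build_analysis_cohort, derive_rhr_table
from .exceptions import DataError
from .io import read_input_dir
from .simulate import generate_cohort
from .trends import categorize_rhr, trend_report
from .validity import MethodAgreement

__all__ = ["run_all", "STAGE_SEED_OFFSETS"]

STAGE_SEED_OFFSETS = {"simulate": 0, "validate": 1000, "associations": 2000}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    in_dir: str | Path | None = None,
    n_boot: int = 1000,
    m: int = 5,
    folds: int = 5,
) -> Path:
    """Run the full pipeline; returns the output directory.

    With ``in_dir=None`` the synthetic generator provides the inputs
    (written alongside the outputs); otherwise the sensor tables are read
    from ``in_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if in_dir is None:
        bundle = generate_cohort(config.replace(seed=seed + STAGE_SEED_OFFSETS["simulate"]))
        bundle.to_dir(out / "inputs")
        tables = {
            "ecg": bundle.ecg,
            "ibi": bundle.ibi,
            "actigraphy": bundle.actigraphy,
            "wrist": bundle.wrist,
            "participants": bundle.participants,
            "covariates": bundle.covariates,
        }
    else:
        tables = read_input_dir(in_dir)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rhr = derive_rhr_table(
        tables["ecg"], tables["ibi"], tables["actigraphy"], tables["wrist"],
        participants=tables["participants"],
    )
    rhr.to_csv(out / "rhr.csv", index=False)
    pairs, flow = build_analysis_cohort(rhr)
    flow.to_csv(out / "flow.csv", index=False)
    timings["derive"] = time.perf_counter() - t0
    if len(pairs) < 3:
        raise DataError("derive-rhr: analysis cohort smaller than 3 participants")

    t0 = time.perf_counter()
    validity = MethodAgreement(pairs).fit(
        n_boot=n_boot, seed=seed + STAGE_SEED_OFFSETS["validate"]
    )
    validity.as_frame().to_csv(out / "validity.csv", index=False)
    timings["validate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    covariates: CovariateTable | None = tables.get("covariates")
    if covariates is None:
        raise DataError("trends: covariates.csv not found in inputs")
    categories, cutpoints = categorize_rhr(pairs)
    for sex in ("female", "male"):
        trend_report(covariates, categories, sex).to_csv(out / f"trends_{sex}.csv", index=False)
    timings["trends"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    assoc = RHRAssociationModel(covariates, pairs).fit(
        m=m, folds=folds, seed=seed + STAGE_SEED_OFFSETS["associations"]
    )
    assoc.report().to_csv(out / "associations.csv", index=False)
    assoc.meta_frame().to_csv(out / "model_meta.csv", index=False)
    timings["associations"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else (dict(v) if hasattr(v, "items") else v))
            for k, v in config.__dict__.items()
        },
        "stage_seeds": {k: seed + v for k, v in STAGE_SEED_OFFSETS.items()},
        "n_boot": n_boot,
        "m": m,
        "folds": folds,
        "cutpoints": cutpoints,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _digest(p) for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
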