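import numpy as np
import pandas as pd
import pytest

from wristrhr import SimulationConfig, build_analysis_cohort, derive_rhr_table, generate_cohort


@pytest.fixture(scope="session")
def clean_config():
    """Small cohort with no induced exclusions and no missingness."""
    return SimulationConfig(
        n_participants=60,
        p_off_wrist=0.0,
        p_active_epoch=0.0,
        missing_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_pairs(clean_bundle):
    rhr = derive_rhr_table(
        clean_bundle.ecg,
        clean_bundle.ibi,
        clean_bundle.actigraphy,
        clean_bundle.wrist,
        participants=clean_bundle.participants,
    )
    pairs, _ = build_analysis_cohort(rhr)
    return pairs


def make_window(ibis_ms, start=0, epoch_counts=None, wrist_on=(True,), participant="P0"):
    """Construct a MeasurementWindow directly from a list of IBI lengths.

    Beats are laid head-to-tail from ``start``; actigraphy epochs cover the
    window with the given counts (all Still by default); a single on-wrist
    record sits at the window start unless overridden.
    """
    from wristrhr.derive import MeasurementWindow

    ibis = np.asarray(ibis_ms, float)
    t = start + np.cumsum(ibis) - ibis[0]  # first beat at the window start
    window_start, window_end = float(start), float(start) + 120_000.0
    if epoch_counts is None:
        epoch_counts = [0, 0, 0, 0]
    epoch_start = window_start + 30_000.0 * np.arange(len(epoch_counts))
    wrist_on = np.asarray(wrist_on, bool)
    wrist_t = window_start + 60_000.0 * np.arange(len(wrist_on))
    return MeasurementWindow(
        participant_id=participant,
        window_start=window_start,
        window_end=window_end,
        ibi_t=t,
        ibi=ibis,
        epoch_start=np.asarray(epoch_start, float),
        epoch_count=np.asarray(epoch_counts, float),
        wrist_t=wrist_t,
        wrist_on=wrist_on,
    )


@pytest.fixture
def window_factory():
    return make_window
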