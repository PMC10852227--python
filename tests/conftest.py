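"""Shared fixtures.

The expensive fixture here is ``recovery_study``: a 20-seed simulation of
full study-geometry sessions (8 trials x 240 s usable at 4096 Hz) pushed
through the complete pipeline — generation, EEG preprocessing, predictor
computation, LOO evaluation across 2..8 trials, and circular-shift null
models.  Several recovery/validity tests share its records so the
simulation cost is paid once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import subtrf as st
from subtrf import pipeline as pl
from subtrf.evaluation import SessionEvaluator, wave_v_metrics

N_STUDY_SEEDS = 20
STUDY_LENGTHS = (2, 3, 4, 5, 6, 7, 8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240208)


@pytest.fixture(scope="session")
def short_stimulus():
    """A 6 s speech-like stimulus for predictor unit tests."""
    return st.gen_stimulus(6.0, 16384.0, seed=7)


@pytest.fixture(scope="session")
def recovery_study():
    """Per-seed pipeline outcomes under the default study conditions.

    Returns a list of dicts with keys ``seed``, ``snr_by_n`` (data-length ->
    wave V SNR dB), ``latency_by_n``, ``r_by_n`` (prediction correlations),
    ``null_r`` (mean over 30/60/90 s shifts at 8 trials), and the true
    kernel peak latency.
    """
    records = []
    cfg = pl.RunConfig(kinds=("RS",), with_null=False)
    for seed in range(N_STUDY_SEEDS):
        stimuli, raw_session, truth = st.default_session(seed=seed)
        session, pairs_by_kind = pl._prepare_session(cfg, raw_session, stimuli)
        ev = SessionEvaluator(session, pairs_by_kind["RS"])
        snr_by_n, lat_by_n, r_by_n = {}, {}, {}
        for n in STUDY_LENGTHS:
            r, mean_trf = ev.loo(n)
            wv = wave_v_metrics(mean_trf)
            snr_by_n[n] = wv.snr_db
            lat_by_n[n] = wv.latency_ms
            r_by_n[n] = r
        null_r = float(
            np.mean([ev.loo(8, shift_s=s)[0] for s in (30.0, 60.0, 90.0)])
        )
        records.append(
            dict(
                seed=seed,
                snr_by_n=snr_by_n,
                latency_by_n=lat_by_n,
                r_by_n=r_by_n,
                null_r=null_r,
                true_peak_ms=truth.peak_ms,
                minutes_by_n={n: n * session.trials[0].duration_s / 60 for n in STUDY_LENGTHS},
            )
        )
    return records
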