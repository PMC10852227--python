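"""End-to-end experiment orchestration.

``run_experiment`` takes a :class:`RunConfig`, obtains sessions (simulated
or loaded from disk), computes predictor pairs, preprocesses the EEG,
sweeps TRF estimation over data lengths with leave-one-out CV and
circular-shift null models, scores wave V peaks, and runs the group-level
statistics.  Every fixed constant of the analysis lives in the config with
the conventional defaults (1 kHz stimulus / 1 Hz EEG highpass, 4096 Hz
analysis rate, 30-1000 Hz TRF band, 2 ms smoothing, [-10, 30] ms extraction,
5-10 ms wave V search, 5 ms power windows over [-500, -20] ms, null shifts
of 30/60/90 s, 3 dB detection threshold).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import evaluation as ev_mod
from . import predictors as pred_mod
from . import stats as stats_mod
from . import synthetic as synth_mod
from .eeg import EEGSession, EEGTrial
from .predictors import PredictorPair


@dataclass
class RunConfig:
    """All analysis parameters; defaults are the standard protocol values."""

    # data source
    source: str = "simulate"  # or "files"
    n_participants: int = 2
    base_seed: int = 1
    n_trials: int = 8
    trial_s: float = 244.0
    session_paths: tuple = ()

    # stimulus conditioning
    stim_hp_hz: float = 1000.0
    target_rms: float = 1.0
    calibrate_after_highpass: bool = True

    # predictors
    kinds: tuple = ("RS", "GT", "OSS", "OSSA")
    eeg_rate_hz: float = 4096.0
    filterbank: tuple = (80.0, 8000.0, 1.0)

    # EEG preprocessing
    eeg_hp_hz: float = 1.0
    notch_max_hz: float = 1000.0
    artifact_sd: float = 5.0
    artifact_window_s: float = 1.0
    trim_s: tuple = (2.0, 242.0)

    # TRF post-processing and metrics
    band_hz: tuple = (30.0, 1000.0)
    smooth_ms: float = 2.0
    extract_ms: tuple = (-10.0, 30.0)
    search_ms: tuple = (5.0, 10.0)
    noise_range_ms: tuple = (-500.0, -20.0)
    power_window_ms: float = 5.0
    threshold_db: float = 3.0

    # evaluation sweep
    lengths: tuple = (2, 3, 4, 5, 6, 7, 8)
    null_shifts_s: tuple = (30.0, 60.0, 90.0)
    with_null: bool = True

    # statistics
    contrasts: tuple = ()  # default: all pairs of `kinds`, filled at run time
    stats_length: int | None = None  # default: max(lengths)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    stats: pd.DataFrame | None
    trfs: dict
    manifest: dict


def _prepare_session(config: RunConfig, raw_session: EEGSession, stimuli) -> tuple:
    """Preprocess EEG trials and build predictor pairs for each kind."""
    lo, hi = config.trim_s
    trials = []
    for t in raw_session.trials:
        pre = eeg_mod.preprocess_eeg(
            t.samples,
            t.rate_hz,
            out_rate=config.eeg_rate_hz,
            hp_hz=config.eeg_hp_hz,
            notch_max_hz=config.notch_max_hz,
            trial_index=t.trial_index,
        )
        pre = eeg_mod.suppress_artifacts(
            pre, n_sd=config.artifact_sd, window_s=config.artifact_window_s
        )
        trials.append(eeg_mod.trim_trial(pre, lo, hi))
    session = EEGSession(trials, raw_session.participant_id, config.eeg_rate_hz)

    i0 = int(round(lo * config.eeg_rate_hz))
    i1 = int(round(hi * config.eeg_rate_hz))
    fb = pred_mod.erb_center_frequencies(*config.filterbank)
    pairs_by_kind: dict = {}
    for kind in config.kinds:
        pairs = []
        for stim in stimuli:
            pair = pred_mod.make_predictor_pair(
                pred_mod.PolarityStimulusPair(positive=stim),
                kind,
                config.eeg_rate_hz,
                filterbank=fb,
            )
            trimmed = []
            for p in (pair.positive, pair.negative):
                s = p.samples[i0:i1]
                sd = s.std()
                if sd == 0:
                    raise ValueError("constant predictor after trimming")
                trimmed.append(
                    pred_mod.Predictor(
                        s / sd, p.rate_hz, p.kind, p.polarity, p.alignment_shift
                    )
                )
            pairs.append(PredictorPair(*trimmed))
        pairs_by_kind[kind] = pairs
    return session, pairs_by_kind


def _evaluate_participant(config: RunConfig, session, pairs_by_kind, pid) -> list:
    rows = []
    for kind, pairs in pairs_by_kind.items():
        evaluator = ev_mod.SessionEvaluator(
            session,
            pairs,
            band_hz=config.band_hz,
            smooth_ms=config.smooth_ms,
        )
        for n in config.lengths:
            if n > len(session.trials):
                continue
            r, mean_trf = evaluator.loo(n, extract_ms=config.extract_ms)
            wv = ev_mod.wave_v_metrics(
                mean_trf,
                search_ms=config.search_ms,
                window_ms=config.power_window_ms,
                noise_range_ms=config.noise_range_ms,
                threshold_db=config.threshold_db,
            )
            null_r = np.nan
            if config.with_null:
                null_r = np.mean(
                    [evaluator.loo(n, shift_s=s)[0] for s in config.null_shifts_s]
                )
            rows.append(
                dict(
                    participant=pid,
                    predictor_kind=kind,
                    n_trials=n,
                    minutes=n * session.trials[0].duration_s / 60.0,
                    prediction_r=r,
                    null_r=float(null_r),
                    snr_db=wv.snr_db,
                    latency_ms=wv.latency_ms,
                    amplitude=wv.amplitude,
                    detected=wv.detected,
                )
            )
    return rows


def run_experiment(config: RunConfig) -> ResultsBundle:
    """Run the full analysis described by ``config``; see module docstring."""
    rows: list = []
    trfs: dict = {}
    excluded: list = []
    if config.source == "simulate":
        participants = [
            (f"sim{i:02d}", (config.base_seed + i) % 2**31)
            for i in range(config.n_participants)
        ]
        for pid, seed in participants:
            stimuli, raw_session, _truth = synth_mod.default_session(
                seed, n_trials=config.n_trials, trial_s=config.trial_s
            )
            try:
                session, pairs_by_kind = _prepare_session(config, raw_session, stimuli)
            except ValueError as err:
                excluded.append({"participant": pid, "reason": str(err)})
                continue
            rows.extend(_evaluate_participant(config, session, pairs_by_kind, pid))
    elif config.source == "files":
        from .stimulus import calibrate_rms, preprocess_stimulus

        def _prepare_stimulus(s):
            if config.calibrate_after_highpass:
                out = preprocess_stimulus(s.samples, s.rate_hz, hp_hz=config.stim_hp_hz)
                return calibrate_rms(out, config.target_rms)
            out = calibrate_rms(s, config.target_rms)
            return preprocess_stimulus(out.samples, out.rate_hz, hp_hz=config.stim_hp_hz)

        for pid, paths in enumerate(config.session_paths):
            raw_stimuli, raw_session = load_session_dir(paths)
            stimuli = [_prepare_stimulus(s) for s in raw_stimuli]
            try:
                session, pairs_by_kind = _prepare_session(config, raw_session, stimuli)
            except ValueError as err:
                excluded.append({"participant": str(pid), "reason": str(err)})
                continue
            rows.extend(
                _evaluate_participant(config, session, pairs_by_kind, str(pid))
            )
    else:
        raise ValueError(f"unknown source {config.source!r}")

    results = pd.DataFrame(rows)
    stats_df = _group_stats(config, results) if len(results) else None
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "excluded_participants": excluded,
        "n_rows": int(len(results)),
    }
    return ResultsBundle(results=results, stats=stats_df, trfs=trfs, manifest=manifest)


def _group_stats(config: RunConfig, results: pd.DataFrame) -> pd.DataFrame | None:
    """Pairwise Wilcoxon tests on wave V SNR at the longest data length."""
    length = config.stats_length or max(config.lengths)
    at_len = results[results.n_trials == length]
    kinds = [k for k in config.kinds if k in set(at_len.predictor_kind)]
    # participants must have the full data length for every kind
    counts = at_len.groupby("participant").size()
    complete = counts[counts == len(kinds)].index
    at_len = at_len[at_len.participant.isin(complete)]
    if len(complete) < 5 or len(kinds) < 2:
        return None
    metric = {
        k: at_len[at_len.predictor_kind == k]
        .sort_values("participant")
        .snr_db.to_numpy()
        for k in kinds
    }
    contrasts = list(config.contrasts) or [
        (a, b) for i, a in enumerate(kinds) for b in kinds[i + 1 :]
    ]
    tests = stats_mod.pairwise_predictor_tests(metric, contrasts)
    return pd.DataFrame(
        [
            dict(
                kind_a=t.pair[0],
                kind_b=t.pair[1],
                T=t.T,
                p_raw=t.p_raw,
                p_holm=t.p_holm,
                n_subjects=t.n_subjects,
                median_a=float(np.median(metric[t.pair[0]])),
                median_b=float(np.median(metric[t.pair[1]])),
            )
            for t in tests
        ]
    )


def serialize_results(bundle: ResultsBundle, outdir) -> dict:
    """Write results.csv, stats.csv and manifest.json; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    p = os.path.join(outdir, "results.csv")
    bundle.results.to_csv(p, index=False)
    paths["results"] = p
    if bundle.stats is not None:
        p = os.path.join(outdir, "stats.csv")
        bundle.stats.to_csv(p, index=False)
        paths["stats"] = p
    p = os.path.join(outdir, "manifest.json")
    with open(p, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    paths["manifest"] = p
    return paths


def read_results_csv(path) -> pd.DataFrame:
    """Read a results/stats CSV with exact float round-tripping."""
    return pd.read_csv(path, float_precision="round_trip")


def load_session_dir(path) -> tuple:
    """Load a session directory of WAV stimuli and columnar EEG trials.

    Expects ``trialNN.wav`` / ``trialNN_eeg.txt`` pairs (sorted order); EEG
    text files carry a ``# rate_hz:`` header.
    """
    import glob
    import os

    from .stimulus import read_wav

    wavs = sorted(glob.glob(os.path.join(path, "trial*.wav")))
    if not wavs:
        raise ValueError(f"no trial*.wav found under {path!r}")
    stimuli, trials = [], []
    rate = None
    for i, wav in enumerate(wavs):
        data, srate = read_wav(wav)
        from .stimulus import AudioStimulus

        stimuli.append(AudioStimulus(data if data.ndim == 1 else data.mean(1), srate))
        eeg_path = wav.replace(".wav", "_eeg.txt")
        if not os.path.exists(eeg_path):
            raise ValueError(f"missing EEG file {eeg_path!r}")
        samples, erate = eeg_mod.read_text_eeg(eeg_path)
        rate = erate if rate is None else rate
        trials.append(EEGTrial(samples, erate, trial_index=i))
    return stimuli, EEGSession(trials, participant_id=os.path.basename(str(path)),
                               rate_hz=rate)
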