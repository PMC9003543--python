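"""End-to-end synthetic run: generate every modality, apply every analysis,
persist derived outputs to a ModalityStore plus a run log.

Only derived records (signals, features, keypoints, sensor readings and
summaries) reach the store; waveforms and frames exist transiently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import alarms, audiofeat, envstats, geoloc, motion, posekit, synthgen
from .store import (
    ModalityStore,
    RunConfig,
    write_env,
    write_feature_table,
    write_keypoints,
    write_motion,
    write_rssi,
)


def synth_frame_stack(
    n_frames: int = 30, shape: tuple[int, int] = (320, 240), seed: int = 0
) -> np.ndarray:
    """Synthetic 1 Hz grayscale stack: a bright square walking over a static
    background, the single-moving-object regime the motion signals assume."""
    rng = np.random.default_rng(seed)
    background = rng.integers(20, 60, size=shape, dtype=np.int64)
    frames = np.repeat(background[None], n_frames, axis=0)
    size = 20
    x = rng.integers(0, shape[0] - size)
    y = rng.integers(0, shape[1] - size)
    for t in range(n_frames):
        frames[t, x : x + size, y : y + size] = 220
        x = int(np.clip(x + rng.integers(-8, 9), 0, shape[0] - size))
        y = int(np.clip(y + rng.integers(-8, 9), 0, shape[1] - size))
    return frames


def synth_light_log(seed: int = 0):
    """Two-day 1 Hz illuminance log: a clear then a cloudy day, an evening
    lamp, and a nightly upload hour with no capture.  Returns
    ``(timestamps, lux, schedule)`` with a period schedule naming Dclear,
    N1, Dcloudy, N2."""
    h = 3600.0
    sunrise, sunset = 7.5 * h, 18.2 * h
    lights_off = 23.75 * h
    day_amp = {0: 185.0, 1: 115.0}  # cloudy second day
    lamp = {0: 15.3, 1: 10.1}
    rng = np.random.default_rng(seed)
    t = np.arange(0, 2 * 24 * h)
    lux = np.zeros(len(t))
    for d in (0, 1):
        td = t - d * 24 * h
        day = (td >= sunrise) & (td < sunset)
        phase = (td[day] - sunrise) / (sunset - sunrise)
        lux[day] = day_amp[d] * np.sin(np.pi * phase) ** 2 + rng.uniform(
            0.2, 1.0, day.sum()
        )
        evening = (td >= sunset) & (td < lights_off)
        lux[evening] = lamp[d] + rng.uniform(-0.2, 0.2, evening.sum())
    upload = (t >= 24 * h + 1 * h) & (t < 24 * h + 2 * h)
    keep = ~upload
    schedule = envstats.PeriodSchedule(
        periods={
            "Dclear": (sunrise, sunset),
            "N1": (sunset, 24 * h + sunrise),
            "Dcloudy": (24 * h + sunrise, 24 * h + sunset),
            "N2": (24 * h + sunset, 48 * h),
        },
        excluded=((24 * h + 1 * h, 24 * h + 2 * h),),
    )
    return t[keep], lux[keep], schedule


def run_pipeline(
    config: RunConfig, root, run_experiment: bool = False
) -> dict:
    """Run all five applications on a fresh synthetic bundle.

    Writes per-modality outputs under ``root`` and a ``run_log.json``
    recording the exact configuration and the headline numbers.  Reruns
    with the same config produce byte-identical outputs.  Set
    ``run_experiment`` to also cross-validate the note classifier (slower).
    """
    store = ModalityStore(root)
    log: dict = {"config": json.loads(config.to_json()), "outputs": {}, "summary": {}}
    seed = config.seed

    # 1. motion signals from a synthetic frame stack
    frames = synth_frame_stack(seed=seed)
    sig = motion.motion_signals(frames, delta=config.delta, K=config.K, L=config.L)
    write_motion(store.path("motion", "motion.csv"), sig["GDS"], sig["GDPC"],
                 sig["LDS"], sig["LDPC"])
    log["outputs"]["motion"] = ["motion.global.csv", "motion.local.csv"]

    # 2. alarm corpus -> features + note labels (raw audio discarded here)
    spec = audiofeat.WindowSpec(length=config.window_s, overlap=config.overlap)
    X_parts, y_parts, s_parts = [], [], []
    for w in (synthgen.synth_alarm(a) for a in synthgen.default_alarm_corpus(config.sample_rate)):
        X, raw, starts = audiofeat.feature_rows(w, config.sample_rate, spec)
        y = [alarms.annotate_window(r, config.sample_rate) for r in raw]
        X_parts.append(X)
        y_parts.extend(y)
        s_parts.append(starts)
    X = np.vstack(X_parts)
    y = np.array(y_parts)
    starts = np.concatenate(s_parts)
    write_feature_table(store.path("audio_features", "features.csv"), X, starts, y)
    log["outputs"]["audio_features"] = ["features.csv"]
    log["summary"]["n_feature_rows"] = int(len(X))
    if run_experiment:
        res = alarms.run_note_experiment(X, y, seed=seed)
        log["summary"]["f1_micro"] = res.f1_micro
        log["summary"]["f1_macro"] = res.f1_macro

    # 3. RSSI -> room probabilities
    traces, room_map, schedule = synthgen.synth_rssi(synthgen.RssiSimConfig(seed=seed))
    write_rssi(store.path("rssi", "rssi.csv"), traces)
    cfg = geoloc.DecayConfig(beta=config.beta, floor=config.rssi_floor)
    rooms, probs, assigned = geoloc.geolocate(
        traces, room_map, cfg, t_start=0, t_end=schedule[-1][1]
    )
    df = pd.DataFrame(probs, columns=[f"p_room{r}" for r in rooms])
    df.insert(0, "t", np.arange(len(probs)))
    df["argmax"] = assigned
    df.to_csv(store.path("rssi", "rooms.csv"), index=False, float_format="%.12g")
    log["outputs"]["rssi"] = ["rssi.csv", "rooms.csv"]
    log["summary"]["geolocation_accuracy"] = geoloc.score_accuracy(
        assigned, rooms, schedule
    )

    # 4. keypoints -> occupancy counts + activity calls
    kp_cfg = synthgen.KeypointSimConfig(seed=seed)
    kp_frames, truth = synthgen.synth_occupancy_session(kp_cfg)
    write_keypoints(store.path("keypoints", "keypoints.jsonl"), kp_frames)
    counts = posekit.occupancy_series(kp_frames)
    pd.DataFrame({"t": np.arange(len(counts)), "count": counts, "truth": truth}).to_csv(
        store.path("keypoints", "occupancy.csv"), index=False
    )
    log["summary"]["occupancy_accuracy"] = posekit.occupancy_accuracy(counts, truth)
    std_frames, std_labels = synthgen.synth_keypoints(
        kp_cfg, activities=("standing",) * kp_cfg.n_subjects
    )
    exe_frames, exe_labels = synthgen.synth_keypoints(
        synthgen.KeypointSimConfig(seed=seed + 1),
        activities=("exercising",) * kp_cfg.n_subjects,
    )
    calls = []
    for fr, labels in ((std_frames, std_labels), (exe_frames, exe_labels)):
        for k, call in enumerate(
            posekit.classify_subjects(fr, kp_cfg.n_subjects, config.activity_threshold_px)
        ):
            calls.append((k, labels[k], call.label, call.mean_iqr))
    pd.DataFrame(calls, columns=["subject", "truth", "call", "mean_iqr_px"]).to_csv(
        store.path("keypoints", "activity.csv"), index=False, float_format="%.6g"
    )
    log["outputs"]["keypoints"] = ["keypoints.jsonl", "occupancy.csv", "activity.csv"]
    log["summary"]["activity_accuracy"] = float(
        np.mean([truth_l == call_l for _, truth_l, call_l, _ in calls])
    )

    # 5. light log -> period statistics
    lt, lux, sched = synth_light_log(seed=seed)
    write_env(store.path("light", "light.csv"), np.column_stack([lt, lux]))
    stats = envstats.period_stats(lt, lux, sched)
    log["outputs"]["light"] = ["light.csv"]
    log["summary"]["light_periods"] = stats

    # 6. paired temperature traces -> agreement report
    fast, slow = synthgen.synth_paired_env(
        duration=24 * 3600, bias=-0.4, noise_sd=0.1, seed=seed
    )
    write_env(store.path("temp_humidity", "fast.csv"), fast)
    write_env(store.path("temp_humidity", "slow.csv"), slow)
    report = envstats.validate_pair(fast, slow, window=config.align_window_s)
    log["outputs"]["temp_humidity"] = ["fast.csv", "slow.csv"]
    log["summary"]["temperature_agreement"] = report.as_dict()

    log_path = Path(root) / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
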