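"""Shared data model: modality directory layout, formats, run configuration.

All captured data lives under one root with a subdirectory per modality
(motion, audio_features, rssi, keypoints, light, temp_humidity), every
record carrying a UTC integer-second timestamp from a single clock domain.
The privacy contract is structural: the store accepts only derived records
(signals, feature rows, keypoints, sensor readings) — raw audio waveforms
and video frames cannot be written into it.

Delimited text uses comma separation with a header row and '.' decimals;
keypoints use one JSON-lines record per frame.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

MODALITIES = ("motion", "audio_features", "rssi", "keypoints", "light", "temp_humidity")


class ModalityStore:
    """Per-modality directory layout for derived records."""

    def __init__(self, root):
        self.root = Path(root)
        for m in MODALITIES:
            (self.root / m).mkdir(parents=True, exist_ok=True)

    def path(self, modality: str, name: str) -> Path:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        if name.lower().endswith((".wav", ".png", ".pgm", ".jpg", ".npy")):
            raise PermissionError(
                "raw audio/video may not be persisted in a ModalityStore"
            )
        return self.root / modality / name

    def contents(self) -> list[Path]:
        return sorted(p for p in self.root.rglob("*") if p.is_file())


# ---------------------------------------------------------------------------
# Format writers / readers (round-trip safe: exact for ints/strings, 1e-9
# for reals via repr-precision floats)
# ---------------------------------------------------------------------------


def write_motion(path, gds, gdpc, lds, ldpc) -> None:
    path = Path(path)
    t = np.arange(2, len(gds) + 2)  # difference frames exist for t = 2..T
    pd.DataFrame({"t": t, "GDS": gds, "GDPC": gdpc}).to_csv(
        path.with_suffix(".global.csv"), index=False
    )
    tt, ss = np.meshgrid(t, np.arange(lds.shape[1]), indexing="ij")
    pd.DataFrame(
        {"t": tt.ravel(), "s": ss.ravel(), "LDS": lds.ravel(), "LDPC": ldpc.ravel()}
    ).to_csv(path.with_suffix(".local.csv"), index=False)


def read_motion(path):
    path = Path(path)
    g = pd.read_csv(path.with_suffix(".global.csv"))
    l = pd.read_csv(path.with_suffix(".local.csv"))
    n_blocks = l["s"].nunique()
    lds = l["LDS"].to_numpy().reshape(-1, n_blocks)
    ldpc = l["LDPC"].to_numpy().reshape(-1, n_blocks)
    return g["GDS"].to_numpy(), g["GDPC"].to_numpy(), lds, ldpc


def write_feature_table(path, features: np.ndarray, starts, labels=None) -> None:
    """One window-feature row per line: start time, 20 MFCC, 10 mel energies,
    optional note label."""
    features = np.asarray(features)
    cols = [f"mfcc_{i:02d}" for i in range(20)] + [f"mel_{i:02d}" for i in range(10)]
    if features.shape[1] != 30:
        raise ValueError(f"expected 30 feature columns, got {features.shape[1]}")
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "start_s", np.asarray(starts))
    if labels is not None:
        df["label"] = np.asarray(labels)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path):
    df = pd.read_csv(path)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    feats = df.drop(columns=[c for c in ("start_s", "label") if c in df.columns])
    return feats.to_numpy(), df["start_s"].to_numpy(), labels


def write_rssi(path, traces: dict[int, np.ndarray], mac: str = "AA:BB:CC:DD:EE:FF") -> None:
    rows = []
    for rx in sorted(traces):
        for t, v in traces[rx]:
            rows.append((int(t), rx, mac, v))
    pd.DataFrame(rows, columns=["timestamp", "receiver_id", "mac", "rssi_dbm"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_rssi(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(rx): g[["timestamp", "rssi_dbm"]].to_numpy(dtype=float)
        for rx, g in df.groupby("receiver_id")
    }


def write_keypoints(path, frames) -> None:
    """One JSON-lines record per frame: the list of 17-point x-y arrays."""
    with open(path, "w") as fh:
        for t, frame in enumerate(frames):
            rec = {"t": t, "people": [np.asarray(p).round(9).tolist() for p in frame]}
            fh.write(json.dumps(rec) + "\n")


def read_keypoints(path):
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                frames.append([np.asarray(p, dtype=float) for p in rec["people"]])
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed keypoint record") from exc
    return frames


def write_env(path, trace: np.ndarray) -> None:
    pd.DataFrame(np.asarray(trace), columns=["timestamp", "value"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_env(path) -> np.ndarray:
    return pd.read_csv(path)[["timestamp", "value"]].to_numpy(dtype=float)


def write_pir(path, trace: np.ndarray) -> None:
    """Binary PIR spike train, `timestamp,0|1` records (capture format; no
    further analytics are defined on it)."""
    df = pd.DataFrame(np.asarray(trace, dtype=int), columns=["timestamp", "value"])
    if not df["value"].isin((0, 1)).all():
        raise ValueError("PIR values must be 0 or 1")
    df.to_csv(path, index=False)


def write_wav(path, samples: np.ndarray, sample_rate: int = 22050) -> None:
    """16-bit PCM WAV writer (refuses paths inside a ModalityStore by the
    store's own suffix guard — raw audio never enters the store)."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))


def read_wav(path):
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return np.asarray(data, dtype=float), int(rate)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every tunable parameter of the analysis pipeline, serializable so a
    run log can record the exact configuration used."""

    seed: int = 0
    sample_rate: int = 22050
    # motion
    delta: float = 0.0
    K: int = 5
    L: int = 4
    # audio windowing
    window_s: float = 0.030
    overlap: float = 0.5
    # speech mixing grid
    alphas: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))
    # geolocation
    beta: float = 0.2
    rssi_floor: float = -200.0
    # activity phenotyping
    activity_threshold_px: float = 5.0
    # environmental agreement
    align_window_s: float = 600.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["alphas"] = tuple(d["alphas"])
        return cls(**d)
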