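"""Room-level geolocation from multi-receiver Bluetooth RSSI logs.

Non-uniformly sampled per-receiver RSSI traces are regularized to a 1 Hz
grid: seconds with a reading keep it, and a missing second t takes
``rssi[previous] * max(beta * (t - previous), 1)`` where ``previous`` is the
most recent second with an actual reading — i.e. the last value is held for
gaps up to 1/beta seconds and decays multiplicatively (more negative dBm)
beyond.  Values below a floor are clamped.  Per-room means over the room's
receivers are passed through a softmax to give a per-second room-probability
vector; the argmax is the room assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import room_membership


@dataclass(frozen=True)
class DecayConfig:
    beta: float = 0.2  # per-second decay rate for missing data
    floor: float = -200.0  # dBm clamp
    grid_rate: float = 1.0  # Hz

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.floor >= 0:
            raise ValueError("floor must be negative dBm")


def resample_decay(
    trace: np.ndarray,
    cfg: DecayConfig = DecayConfig(),
    t_start: int | None = None,
    t_end: int | None = None,
) -> np.ndarray:
    """Decay-interpolate one receiver's (timestamp, rssi) records onto a
    1 Hz grid covering [t_start, t_end).

    Readings are binned to the nearest grid second (last write wins).  Grid
    seconds before the first reading take the clamp floor, since the decay
    rule has no predecessor there.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty RSSI trace")
    ts = np.rint(trace[:, 0]).astype(int)
    if t_start is None:
        t_start = int(ts.min())
    if t_end is None:
        t_end = int(ts.max()) + 1
    grid = np.arange(t_start, t_end)
    readings: dict[int, float] = {}
    for t, v in zip(ts, trace[:, 1]):
        readings[int(t)] = float(v)  # last write within a second wins

    out = np.empty(len(grid))
    prev_t: int | None = None
    prev_v = float("nan")
    for i, t in enumerate(grid):
        if t in readings:
            prev_t, prev_v = t, readings[t]
            out[i] = prev_v
        elif prev_t is None:
            out[i] = cfg.floor
        else:
            out[i] = prev_v * max(cfg.beta * (t - prev_t), 1.0)
    return np.maximum(out, cfg.floor) if cfg.floor < 0 else out


def room_average(series: dict[int, np.ndarray], room_map: dict[int, object]):
    """Mean RSSI per room per grid second.

    ``series`` maps receiver id to an equal-length 1 Hz array;
    ``room_map`` maps receiver id to its room.  Returns ``(rooms, means)``
    with ``means`` of shape (n_seconds, n_rooms), rooms in sorted order.
    """
    missing = set(series) - set(room_map)
    if missing:
        raise ValueError(f"receivers with no room assignment: {sorted(missing)}")
    rooms = sorted({room_map[rx] for rx in series})
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise ValueError("receiver series must share a common grid")
    n = lengths.pop()
    means = np.empty((n, len(rooms)))
    for j, room in enumerate(rooms):
        members = [series[rx] for rx in series if room_map[rx] == room]
        if not members:
            raise ValueError(f"room {room!r} has no receivers")
        means[:, j] = np.mean(members, axis=0)
    return rooms, means


def room_probabilities(means: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Softmax over per-room mean RSSI at each second (shift-invariant)."""
    if means.shape[1] < 2:
        raise ValueError("need at least two rooms")
    z = scale * np.asarray(means, dtype=float)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def score_accuracy(assigned_rooms: np.ndarray, rooms: list, schedule) -> float:
    """Fraction of grid seconds whose argmax room matches the schedule.

    During transition intervals either endpoint room counts as correct,
    mirroring ground truth that overlaps both rooms while the subject moves
    between them.
    """
    t_end = schedule[-1][1]
    if len(assigned_rooms) < t_end:
        raise ValueError(
            f"series covers {len(assigned_rooms)} s but schedule spans {t_end} s"
        )
    correct = 0
    for t in range(t_end):
        allowed = room_membership(schedule, float(t)).keys()
        if assigned_rooms[t] in allowed:
            correct += 1
    return correct / t_end


def geolocate(
    traces: dict[int, np.ndarray],
    room_map: dict[int, object],
    cfg: DecayConfig = DecayConfig(),
    t_start: int = 0,
    t_end: int | None = None,
    scale: float = 1.0,
):
    """Full pipeline: decay-resample -> room means -> softmax -> argmax.

    Returns ``(rooms, probs, assigned)`` where ``probs`` is (n_seconds,
    n_rooms) and ``assigned`` the per-second argmax room ids.
    """
    if t_end is None:
        t_end = int(max(tr[:, 0].max() for tr in traces.values())) + 1
    series = {
        rx: resample_decay(tr, cfg, t_start=t_start, t_end=t_end)
        for rx, tr in traces.items()
    }
    rooms, means = room_average(series, room_map)
    probs = room_probabilities(means, scale=scale)
    assigned = np.array([rooms[i] for i in probs.argmax(axis=1)])
    return rooms, probs, assigned
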