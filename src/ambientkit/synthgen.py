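"""Synthetic generators for every captured modality.

Nothing in this package requires hardware or external recordings: alarms,
speech surrogates, Bluetooth RSSI logs, pose-keypoint streams and paired
environmental traces are all generated here with the statistical structure
the downstream analyses assume.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: The nine musical notes used by IEC 60601-1-8 melodic alarms and their
#: fundamental frequencies in Hz.
NOTE_TABLE: dict[str, float] = {
    "C4": 261.63,
    "D4": 293.66,
    "E4": 329.63,
    "F4": 349.23,
    "F4#": 369.99,
    "G4": 392.00,
    "A4": 440.00,
    "B4": 493.88,
    "C5": 523.25,
}

ALARM_CATEGORIES = (
    "general",
    "oxygen",
    "ventilation",
    "cardiovascular",
    "temperature",
    "drug_delivery",
    "perfusion",
    "power_failure",
)

#: Default note sheets per (category, priority).  The standard's exact note
#: sheets are not reproduced here; these defaults are chosen so the sixteen
#: alarms jointly exercise all nine notes (hence all eleven annotation
#: classes).  They are configurable via :class:`AlarmSpec`.
DEFAULT_ALARM_NOTES: dict[tuple[str, str], tuple[str, ...]] = {
    ("general", "medium"): ("C4", "E4", "G4"),
    ("general", "high"): ("C4", "E4", "G4", "G4", "C5"),
    ("oxygen", "medium"): ("C5", "B4", "A4"),
    ("oxygen", "high"): ("C5", "B4", "A4", "G4", "F4"),
    ("ventilation", "medium"): ("C4", "A4", "F4"),
    ("ventilation", "high"): ("C4", "A4", "F4", "A4", "F4"),
    ("cardiovascular", "medium"): ("C4", "E4", "A4"),
    ("cardiovascular", "high"): ("C4", "E4", "A4", "G4", "E4"),
    ("temperature", "medium"): ("C4", "D4", "E4"),
    ("temperature", "high"): ("C4", "D4", "E4", "F4", "G4"),
    ("drug_delivery", "medium"): ("C5", "D4", "G4"),
    ("drug_delivery", "high"): ("C5", "D4", "G4", "C5", "D4"),
    ("perfusion", "medium"): ("C4", "F4#", "C5"),
    ("perfusion", "high"): ("C4", "F4#", "C5", "F4#", "C4"),
    ("power_failure", "medium"): ("E4", "D4", "C4"),
    ("power_failure", "high"): ("E4", "D4", "C4", "D4", "E4"),
}


@dataclass(frozen=True)
class AlarmSpec:
    """One melodic medical-equipment alarm.

    Medium-priority alarms play three notes once (about one second in
    total); high-priority alarms play a five-note sequence twice (about
    4.5 s).  Notes are separated by exact-zero gaps so that downstream
    window annotation can identify Empty and Transition windows.
    """

    category: str
    priority: str  # "medium" | "high"
    notes: tuple[str, ...] = ()
    sample_rate: int = 22050
    note_duration: float | None = None  # seconds; None -> priority default
    gap_duration: float = 0.15
    amplitude: float = 0.6

    def __post_init__(self):
        if self.priority not in ("medium", "high"):
            raise ValueError(f"priority must be medium|high, got {self.priority!r}")
        if not self.notes:
            key = (self.category, self.priority)
            if key not in DEFAULT_ALARM_NOTES:
                raise ValueError(f"no default note sheet for {key}")
            object.__setattr__(self, "notes", DEFAULT_ALARM_NOTES[key])
        n_expected = 3 if self.priority == "medium" else 5
        if len(self.notes) != n_expected:
            raise ValueError(
                f"{self.priority} priority takes {n_expected} notes, got {len(self.notes)}"
            )
        if self.note_duration is None:
            object.__setattr__(
                self, "note_duration", 0.15 if self.priority == "medium" else 0.30
            )

    @property
    def repeats(self) -> int:
        return 1 if self.priority == "medium" else 2


def default_alarm_corpus(sample_rate: int = 22050) -> list[AlarmSpec]:
    """The sixteen default alarms: eight categories x {medium, high}."""
    return [
        AlarmSpec(category=c, priority=p, sample_rate=sample_rate)
        for c in ALARM_CATEGORIES
        for p in ("medium", "high")
    ]


def _tone(freq: float, duration: float, sample_rate: int, amplitude: float) -> np.ndarray:
    """Harmonic tone burst: fundamental plus 2nd/3rd harmonics at -12/-18 dB,
    with 10 ms raised-cosine onset/offset ramps to limit spectral splatter."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    w = (
        np.sin(2 * np.pi * freq * t)
        + 10 ** (-12 / 20) * np.sin(2 * np.pi * 2 * freq * t)
        + 10 ** (-18 / 20) * np.sin(2 * np.pi * 3 * freq * t)
    )
    ramp_n = min(int(round(0.010 * sample_rate)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        w[:ramp_n] *= ramp
        w[-ramp_n:] *= ramp[::-1]
    return amplitude * w


def synth_alarm(spec: AlarmSpec, table: dict[str, float] | None = None) -> np.ndarray:
    """Synthesize one alarm waveform.

    Parameters
    ----------
    spec
        Alarm description (notes, priority, timing).
    table
        Mapping note name -> fundamental Hz; defaults to :data:`NOTE_TABLE`.

    Returns
    -------
    numpy.ndarray
        Single-channel float waveform in [-1, 1].  Each note is one harmonic
        tone burst; inter-note gaps are exactly zero.
    """
    table = NOTE_TABLE if table is None else table
    unknown = [n for n in spec.notes if n not in table]
    if unknown:
        raise KeyError(f"unknown note name(s): {unknown}")
    gap = np.zeros(int(round(spec.gap_duration * spec.sample_rate)))
    pieces: list[np.ndarray] = []
    for _ in range(spec.repeats):
        for name in spec.notes:
            pieces.append(
                _tone(table[name], spec.note_duration, spec.sample_rate, spec.amplitude)
            )
            pieces.append(gap)
    return np.concatenate(pieces)


def synth_speech_surrogate(
    duration: float, sample_rate: int = 22050, seed: int = 0
) -> np.ndarray:
    """Broadband nonstationary speech stand-in.

    Band-passed white noise with a slow syllabic-rate amplitude envelope,
    plus three weak drifting formant-like resonances.  Not intelligible
    speech — just a signal with speech-like spectro-temporal statistics for
    stress-testing the note classifier under mixing.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    noise = rng.standard_normal(n)
    sos = signal.butter(4, [100, 4000], btype="bandpass", fs=sample_rate, output="sos")
    broadband = signal.sosfilt(sos, noise)

    # syllabic envelope: rectified low-pass noise, ~2-6 Hz fluctuations
    env_src = rng.standard_normal(n)
    sos_env = signal.butter(2, 4.0, btype="lowpass", fs=sample_rate, output="sos")
    env = signal.sosfilt(sos_env, env_src)
    env = np.abs(env)
    env /= max(env.max(), 1e-12)

    t = np.arange(n) / sample_rate
    formants = np.zeros(n)
    for base in (500.0, 1500.0, 2500.0):
        drift = signal.sosfilt(sos_env, rng.standard_normal(n))
        drift /= max(np.abs(drift).max(), 1e-12)
        freq = base * (1.0 + 0.2 * drift)
        phase = 2 * np.pi * np.cumsum(freq) / sample_rate
        formants += 0.15 * np.sin(phase)

    w = env * (broadband / max(np.abs(broadband).max(), 1e-12) + formants)
    peak = np.abs(w).max()
    if peak > 0:
        w = 0.8 * w / peak
    return w


# ---------------------------------------------------------------------------
# RSSI simulation
# ---------------------------------------------------------------------------

#: The 600 s three-room occupancy schedule used by the room-tracking
#: experiment: entries are (start s, end s, rooms); one room id means the
#: subject stays in that room, a pair means a transition between the two.
TRACKING_SCHEDULE: tuple[tuple[int, int, tuple[int, ...]], ...] = (
    (0, 146, (1,)),
    (146, 159, (1, 2)),
    (159, 268, (2,)),
    (268, 286, (2, 3)),
    (286, 470, (3,)),
    (470, 480, (3, 1)),
    (480, 600, (1,)),
)


@dataclass(frozen=True)
class RssiSimConfig:
    schedule: tuple[tuple[int, int, tuple[int, ...]], ...] = TRACKING_SCHEDULE
    receivers_per_room: int = 3
    in_room_mean: float = -60.0  # dBm, beacon in the receiver's room
    out_room_mean: float = -80.0  # dBm, beacon elsewhere
    noise_sd: float = 3.0  # dBm
    missing_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.schedule:
            raise ValueError("schedule must not be empty")
        prev_end = self.schedule[0][0]
        for start, end, rooms in self.schedule:
            if start != prev_end or end <= start:
                raise ValueError("schedule intervals must be contiguous and forward")
            if not 1 <= len(rooms) <= 2:
                raise ValueError("schedule entry needs one room or a transition pair")
            prev_end = end
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.in_room_mean <= self.out_room_mean:
            raise ValueError("in_room_mean must exceed out_room_mean")


def _room_order(schedule) -> list:
    """Rooms in order of first appearance in the schedule.  Receiver slots
    are tied to this order, which makes the generator equivariant under a
    relabelling of the rooms."""
    seen: list = []
    for _, _, rooms in schedule:
        for r in rooms:
            if r not in seen:
                seen.append(r)
    return seen


def room_membership(schedule, t: float) -> dict:
    """Weight of the subject's presence per room at time ``t``.

    Within a stay interval the occupied room has weight 1.  Within a
    transition the weight ramps linearly from the origin room to the
    destination room.
    """
    for start, end, rooms in schedule:
        if start <= t < end or (t == end and end == schedule[-1][1]):
            if len(rooms) == 1:
                return {rooms[0]: 1.0}
            theta = (t - start) / (end - start)
            return {rooms[0]: 1.0 - theta, rooms[1]: theta}
    raise ValueError(f"t={t} outside schedule span")


def synth_rssi(config: RssiSimConfig):
    """Simulate per-receiver RSSI logs for a scheduled walk between rooms.

    Returns
    -------
    traces : dict[int, numpy.ndarray]
        receiver id (1-based) -> array of (timestamp s, rssi dBm) rows.
        Samples are drawn at 1 Hz, Normal(mean, noise_sd) around the
        membership-dependent mean, then dropped independently with
        ``missing_prob`` (emulating missed Bluetooth polls).
    room_map : dict[int, room]
        receiver id -> room id, ``receivers_per_room`` receivers per room.
    schedule
        The ground-truth schedule (echoed from the config).
    """
    rooms = _room_order(config.schedule)
    t_end = config.schedule[-1][1]
    ticks = np.arange(t_end)
    rng = np.random.default_rng(config.seed)
    n_rx = len(rooms) * config.receivers_per_room
    noise = rng.normal(0.0, config.noise_sd, size=(len(ticks), n_rx))
    drop = rng.random(size=(len(ticks), n_rx)) < config.missing_prob

    weights = np.zeros((len(ticks), len(rooms)))
    for i, t in enumerate(ticks):
        for room, w in room_membership(config.schedule, float(t)).items():
            weights[i, rooms.index(room)] = w

    traces: dict[int, np.ndarray] = {}
    room_map: dict[int, object] = {}
    for j, room in enumerate(rooms):
        for slot in range(config.receivers_per_room):
            rx = j * config.receivers_per_room + slot + 1
            room_map[rx] = room
            mean = config.out_room_mean + (
                config.in_room_mean - config.out_room_mean
            ) * weights[:, j]
            vals = mean + noise[:, rx - 1]
            keep = ~drop[:, rx - 1]
            traces[rx] = np.column_stack([ticks[keep], vals[keep]]).astype(float)
    return traces, room_map, config.schedule


# ---------------------------------------------------------------------------
# Keypoint simulation
# ---------------------------------------------------------------------------

N_KEYPOINTS = 17
#: Indices of the four hand keypoints in the 17-point convention.
HAND_KEYPOINTS = {"left_elbow": 7, "right_elbow": 8, "left_wrist": 9, "right_wrist": 10}

#: The 180 s occupancy/activity protocol: (start frame, end frame,
#: people present, activity of those present).
OCCUPANCY_PROTOCOL: tuple[tuple[int, int, int, str], ...] = (
    (0, 30, 1, "standing"),
    (30, 60, 2, "standing"),
    (60, 90, 3, "standing"),
    (90, 120, 3, "exercising"),
    (120, 150, 2, "exercising"),
    (150, 180, 1, "exercising"),
)


@dataclass(frozen=True)
class KeypointSimConfig:
    n_subjects: int = 3
    n_frames: int = 60
    standing_jitter_sd: float = 1.0  # px
    exercise_amplitude: float = 30.0  # px
    exercise_period: int = 10  # frames per oscillation
    frame_size: tuple[int, int] = (640, 480)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.exercise_amplitude <= self.standing_jitter_sd:
            raise ValueError("exercise_amplitude must exceed standing_jitter_sd")


def _base_pose(rng: np.random.Generator, frame_size) -> np.ndarray:
    """A plausible standing skeleton (17 x-y points) at a random position."""
    w, h = frame_size
    cx = rng.uniform(0.2 * w, 0.8 * w)
    cy = rng.uniform(0.35 * h, 0.55 * h)
    # rough offsets, px: nose/eyes/ears, shoulders, elbows, wrists, hips, knees, ankles
    offsets = np.array(
        [
            (0, -80), (-5, -85), (5, -85), (-12, -82), (12, -82),
            (-25, -55), (25, -55), (-35, -20), (35, -20), (-38, 10), (38, 10),
            (-18, 15), (18, 15), (-18, 60), (18, 60), (-18, 105), (18, 105),
        ],
        dtype=float,
    )
    return np.array([cx, cy]) + offsets


def synth_keypoints(
    config: KeypointSimConfig, activities: tuple[str, ...] | None = None
):
    """Generate per-frame keypoint arrays and per-subject activity labels.

    Standing subjects jitter with Normal(0, standing_jitter_sd) on every
    keypoint.  Exercising subjects additionally move their elbow and wrist
    keypoints sinusoidally with the configured amplitude and period.

    Returns ``(frames, labels)`` where ``frames[t]`` is a list of
    ``n_subjects`` arrays of shape (17, 2) and ``labels[k]`` is the k-th
    subject's activity ("standing" or "exercising", alternating by default).
    """
    if activities is None:
        activities = tuple(
            "standing" if k % 2 == 0 else "exercising" for k in range(config.n_subjects)
        )
    if len(activities) != config.n_subjects:
        raise ValueError("one activity per subject required")
    rng = np.random.default_rng(config.seed)
    tracks = []
    for k in range(config.n_subjects):
        base = _base_pose(rng, config.frame_size)
        jitter = rng.normal(
            0.0, config.standing_jitter_sd, size=(config.n_frames, N_KEYPOINTS, 2)
        )
        track = base[None, :, :] + jitter
        if activities[k] == "exercising":
            t = np.arange(config.n_frames)
            osc = config.exercise_amplitude * np.sin(
                2 * np.pi * t / config.exercise_period
            )
            for idx in HAND_KEYPOINTS.values():
                track[:, idx, 1] += osc  # vertical arm oscillation
        tracks.append(track)
    frames = [
        [tracks[k][t] for k in range(config.n_subjects)]
        for t in range(config.n_frames)
    ]
    return frames, tuple(activities)


def synth_occupancy_session(
    config: KeypointSimConfig,
    protocol: tuple[tuple[int, int, int, str], ...] = OCCUPANCY_PROTOCOL,
):
    """Generate a keypoint stream following an occupancy/activity protocol.

    Absent subjects emit all-zero (17, 2) arrays, the convention the
    occupancy counter expects.  Returns ``(frames, truth_counts)``.
    """
    n_frames = protocol[-1][1]
    cfg = replace(config, n_frames=n_frames)
    truth = np.zeros(n_frames, dtype=int)
    segments = []
    for start, end, n_present, activity in protocol:
        truth[start:end] = n_present
        segments.append((start, end, n_present, activity))

    all_frames: list[list[np.ndarray]] = []
    # one full track per subject per activity; presence masks select per frame
    standing, _ = synth_keypoints(
        cfg, activities=("standing",) * config.n_subjects
    )
    exercising, _ = synth_keypoints(
        replace(cfg, seed=cfg.seed + 1),
        activities=("exercising",) * config.n_subjects,
    )
    zero = np.zeros((N_KEYPOINTS, 2))
    for t in range(n_frames):
        seg = next(s for s in segments if s[0] <= t < s[1])
        _, _, n_present, activity = seg
        source = standing if activity == "standing" else exercising
        frame = [
            source[t][k] if k < n_present else zero.copy()
            for k in range(config.n_subjects)
        ]
        all_frames.append(frame)
    return all_frames, truth


# ---------------------------------------------------------------------------
# Paired environmental traces
# ---------------------------------------------------------------------------


def synth_paired_env(
    duration: float,
    slow_period: float = 600.0,
    bias: float = 0.0,
    noise_sd: float = 0.0,
    mean: float = 22.0,
    diurnal_amplitude: float = 2.0,
    seed: int = 0,
):
    """Paired fast/slow sensor traces around a smooth diurnal curve.

    The fast trace samples the curve at 1 Hz with an additive calibration
    ``bias`` (the fast sensor reading low for negative bias, as a DHT22-style
    hobby sensor does against a commercial reference).  The slow trace
    samples once per ``slow_period`` seconds; each slow reading equals the
    curve's mean over the preceding period plus Normal(0, noise_sd)
    measurement noise.

    Returns two ``(timestamp, value)`` arrays: ``(fast, slow)``.
    """
    if duration <= 0 or slow_period < 1:
        raise ValueError("duration must be positive and slow_period >= 1 s")
    rng = np.random.default_rng(seed)
    t_fast = np.arange(int(duration))
    curve = mean + diurnal_amplitude * np.sin(2 * np.pi * t_fast / 86400.0)
    fast = np.column_stack([t_fast, curve + bias]).astype(float)

    slow_ts = np.arange(slow_period, duration + 1, slow_period)
    slow_vals = np.empty(len(slow_ts))
    for i, ts in enumerate(slow_ts):
        window = curve[(t_fast > ts - slow_period) & (t_fast <= ts)]
        slow_vals[i] = window.mean() + rng.normal(0.0, noise_sd)
    slow = np.column_stack([slow_ts, slow_vals]).astype(float)
    return fast, slow
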