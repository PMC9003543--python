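"""Privacy-preserving audio featurization.

Audio is cut into 30 ms Hann-tapered windows with 50% overlap and reduced
to a 30-dimensional feature row per window: 20 MFCCs plus the signal energy
in 10 triangular mel bands (E = M S, each mask row summing to one).  Sample
entropy of a windowed snippet is available as an additional feature.  The
pipeline retains only feature rows; raw samples are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft


@dataclass(frozen=True)
class WindowSpec:
    length: float = 0.030  # seconds
    overlap: float = 0.5  # fraction of the window shared with its successor

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.length <= 0:
            raise ValueError("window length must be positive")

    def n_samples(self, sample_rate: int) -> int:
        n = int(np.floor(self.length * sample_rate))
        if n < 2:
            raise ValueError("window shorter than 2 samples")
        return n

    def hop(self, sample_rate: int) -> int:
        n = self.n_samples(sample_rate)
        return max(1, int(round(n * (1 - self.overlap))))


def n_windows(n_total: int, win: int, hop: int) -> int:
    if n_total < win:
        return 0
    return (n_total - win) // hop + 1


def window_audio(samples: np.ndarray, sample_rate: int, spec: WindowSpec | None = None):
    """Slice a clip into Hann-tapered windows.

    Returns ``(tapered, raw, starts)``: the tapered windows (n_win, win), the
    untapered snippets (kept for zero-content annotation), and the window
    start times in seconds.  A trailing partial window is discarded.
    """
    spec = spec or WindowSpec()
    samples = np.asarray(samples, dtype=float)
    win = spec.n_samples(sample_rate)
    hop = spec.hop(sample_rate)
    n_win = n_windows(len(samples), win, hop)
    if n_win == 0:
        raise ValueError(f"clip of {len(samples)} samples is shorter than one window ({win})")
    idx = np.arange(win)[None, :] + hop * np.arange(n_win)[:, None]
    raw = samples[idx]
    taper = np.hanning(win)
    return raw * taper, raw, hop * np.arange(n_win) / sample_rate


def stft_window(window: np.ndarray, n_fft: int | None = None) -> np.ndarray:
    """One-sided magnitude spectrum of a single (tapered) window.

    With ``n_fft=None`` the bin spacing is sample_rate / len(window); a
    larger ``n_fft`` zero-pads for finer peak localization.
    """
    window = np.asarray(window, dtype=float)
    return np.abs(rfft(window, n=n_fft))


def stft_frequencies(win: int, sample_rate: int, n_fft: int | None = None) -> np.ndarray:
    n = n_fft or win
    return np.arange(n // 2 + 1) * sample_rate / n


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_bank(
    n_bands: int, n_bins: int, sample_rate: int, win: int, fmin: float = 0.0,
    fmax: float | None = None,
) -> np.ndarray:
    """Triangular mel filter mask matrix of shape (n_bands, n_bins).

    Band centers are equally spaced on the mel scale between ``fmin`` and
    ``fmax`` (default Nyquist); each triangular row is normalized to sum to
    one, so a flat spectrum yields unit energy in every band.
    """
    fmax = sample_rate / 2 if fmax is None else fmax
    freqs = stft_frequencies(win, sample_rate)[:n_bins]
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_bands + 2))
    bank = np.zeros((n_bands, n_bins))
    for i in range(n_bands):
        lo, center, hi = edges[i], edges[i + 1], edges[i + 2]
        rising = (freqs - lo) / max(center - lo, 1e-12)
        falling = (hi - freqs) / max(hi - center, 1e-12)
        bank[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        s = bank[i].sum()
        if s <= 0:
            raise ValueError(
                f"mel band {i} has no support on {n_bins} bins; widen the FFT"
            )
        bank[i] /= s
    return bank


def mel_energies(S: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Signal energy per mel band: E = M S (matrix-vector product)."""
    S = np.asarray(S, dtype=float)
    if bank.shape[1] != S.shape[-1]:
        raise ValueError(
            f"bank has {bank.shape[1]} columns but spectrum has {S.shape[-1]} bins"
        )
    return S @ bank.T if S.ndim > 1 else bank @ S


def mfcc_features(
    tapered: np.ndarray, sample_rate: int, n_mfcc: int = 20, n_mels: int = 26
) -> np.ndarray:
    """First ``n_mfcc`` cepstral coefficients of one window (or a stack).

    Standard front end: power spectrum -> ``n_mels`` triangular mel bands ->
    natural log (floored) -> orthonormal DCT-II.  The mel count here is
    independent of the 10-band energy bank; coefficient 0 carries overall
    log-energy, so scaling the waveform shifts only that coefficient.
    """
    arr = np.asarray(tapered, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    win = arr.shape[1]
    power = np.abs(rfft(arr, axis=1)) ** 2
    bank = mel_bank(n_mels, power.shape[1], sample_rate, win)
    mel_power = power @ bank.T
    log_mel = np.log(np.maximum(mel_power, 1e-30))
    coefs = dct(log_mel, type=2, norm="ortho", axis=1)[:, :n_mfcc]
    return coefs[0] if single else coefs


def feature_rows(
    samples: np.ndarray,
    sample_rate: int,
    spec: WindowSpec | None = None,
    n_mfcc: int = 20,
    n_mel_bands: int = 10,
):
    """Window a clip and compute the 30-feature row per window.

    Returns ``(features, raw, starts)`` where ``features`` has shape
    (n_windows, n_mfcc + n_mel_bands): MFCCs first, then the 10 mel-band
    energies of the magnitude spectrum.  ``raw`` (untapered snippets) is
    returned for annotation only and must not be persisted.
    """
    tapered, raw, starts = window_audio(samples, sample_rate, spec)
    win = tapered.shape[1]
    S = np.abs(rfft(tapered, axis=1))
    bank = mel_bank(n_mel_bands, S.shape[1], sample_rate, win)
    energies = S @ bank.T
    mfccs = np.atleast_2d(mfcc_features(tapered, sample_rate, n_mfcc=n_mfcc))
    return np.hstack([mfccs, energies]), raw, starts


def sample_entropy(snippet: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) of a snippet.

    -ln(A/B) where B counts pairs of length-m templates within Chebyshev
    distance r and A the same for length m+1 (self-matches excluded).
    ``r`` defaults to 0.15 x SD of the snippet.  Returns NaN when either
    count is zero (entropy undefined, e.g. on a constant snippet).
    """
    x = np.asarray(snippet, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"snippet of length {n} too short for m={m}")
    if r is None:
        r = 0.15 * x.std()
    if r <= 0:
        return float("nan")

    def count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        q = len(templ)
        return int((d[np.triu_indices(q, k=1)] <= r).sum())

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))
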