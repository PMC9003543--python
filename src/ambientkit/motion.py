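"""Frame-difference motion signals from 1 Hz grayscale video.

Consecutive frames are subtracted in signed arithmetic and reduced to four
privacy-preserving time series: the global difference sum (GDS), the global
changed-pixel count (GDPC, pixels whose absolute difference exceeds a
threshold delta), and their per-block local analogues (LDS, LDPC) on a
K x L partition of the frame.  Only these series leave the pipeline; the
frames themselves are never persisted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BlockPartition:
    """K x L partition of an M x N frame into equal blocks of m x n pixels.

    K splits the M axis (rows), L splits the N axis (columns).  Blocks are
    enumerated row-major: s = (row-group index) * L + (column-group index),
    0-based.
    """

    M: int
    N: int
    K: int
    L: int

    def __post_init__(self):
        if self.K <= 0 or self.L <= 0:
            raise ValueError("K and L must be positive")
        if self.M % self.K:
            raise ValueError(f"K={self.K} does not divide frame height M={self.M}")
        if self.N % self.L:
            raise ValueError(f"L={self.L} does not divide frame width N={self.N}")

    @property
    def m(self) -> int:
        return self.M // self.K

    @property
    def n(self) -> int:
        return self.N // self.L

    @property
    def n_blocks(self) -> int:
        return self.K * self.L


def as_grayscale(frame: np.ndarray) -> np.ndarray:
    """Color frames (H, W, C) collapse to grayscale by unweighted channel mean."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return frame.mean(axis=2)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D or 3-D, got shape {frame.shape}")
    return frame


def difference_stack(frames) -> np.ndarray:
    """Signed consecutive differences D_t = F_t - F_{t-1}, t = 2..T.

    Input frames are promoted to signed wide integers (or float64) before
    subtraction so that unsigned 8-bit pixel values cannot wrap around.
    Returns an array of shape (T-1, M, N).
    """
    arrs = [as_grayscale(f) for f in frames]
    if len(arrs) < 2:
        raise ValueError("need at least two frames to difference")
    shape = arrs[0].shape
    for i, a in enumerate(arrs):
        if a.shape != shape:
            raise ValueError(f"frame {i} has shape {a.shape}, expected {shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"frame {i} contains non-finite pixels")
    stack = np.stack(arrs)
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.int64)
    else:
        stack = stack.astype(np.float64)
    return np.diff(stack, axis=0)


def global_signals(diffs: np.ndarray, delta: float = 0.0):
    """GDS and GDPC per difference frame.

    GDS[t] is the sum of absolute pixel differences; GDPC[t] counts pixels
    with absolute difference strictly greater than ``delta``.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    diffs = np.asarray(diffs)
    absd = np.abs(diffs)
    gds = absd.sum(axis=(1, 2))
    gdpc = (absd > delta).sum(axis=(1, 2))
    return gds, gdpc


def _blocks(diffs: np.ndarray, part: BlockPartition) -> np.ndarray:
    """Reshape (T-1, M, N) into (T-1, n_blocks, m, n), row-major block order."""
    t = diffs.shape[0]
    b = diffs.reshape(t, part.K, part.m, part.L, part.n)
    return b.transpose(0, 1, 3, 2, 4).reshape(t, part.n_blocks, part.m, part.n)


def local_signals(diffs: np.ndarray, part: BlockPartition, delta: float = 0.0):
    """Per-block LDS and LDPC, shape (T-1, n_blocks) each.

    Summing either series over blocks recovers the corresponding global
    signal for any delta (the blocks partition the frame).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    diffs = np.asarray(diffs)
    if diffs.shape[1:] != (part.M, part.N):
        raise ValueError(
            f"difference frames are {diffs.shape[1:]}, partition expects "
            f"({part.M}, {part.N})"
        )
    blocks = np.abs(_blocks(diffs, part))
    lds = blocks.sum(axis=(2, 3))
    ldpc = (blocks > delta).sum(axis=(2, 3))
    return lds, ldpc


def motion_signals(frames, delta: float = 0.0, K: int = 5, L: int = 4):
    """Convenience wrapper: frames -> dict with GDS, GDPC, LDS, LDPC."""
    diffs = difference_stack(frames)
    part = BlockPartition(M=diffs.shape[1], N=diffs.shape[2], K=K, L=L)
    gds, gdpc = global_signals(diffs, delta)
    lds, ldpc = local_signals(diffs, part, delta)
    return {"GDS": gds, "GDPC": gdpc, "LDS": lds, "LDPC": ldpc, "partition": part}
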