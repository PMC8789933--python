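"""Local-variance envelope, STMHT curve, and its signed zero crossings.

The envelope HS_E is a sliding-window (Viola-integral) variance of the
preconditioned trace.  The short-time modified Hilbert transform (STMHT)
slides an antisymmetric kernel over that envelope; because the kernel weighs
past samples positively and future samples negatively, the STMHT crosses zero
negative-to-positive (N2P) at envelope peaks — the geometric centers of the
S1/S2 bursts — and positive-to-negative (P2N) at the quiet midpoints between
bursts.  Those two event families drive the cycle segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .errors import DegenerateInputError, ParameterError, SegmentationError
from .preprocess import SignalTrace

#: Envelope half-width in samples at the 44.1 kHz reference rate (= 50 ms).
DEFAULT_HALF_WIDTH = 2205
#: STMHT window length in samples at the 44.1 kHz reference rate (~1 s, odd).
DEFAULT_WINDOW_LENGTH = 44101


def default_half_width(fs: float) -> int:
    """50 ms expressed in samples (2205 at the 44.1 kHz reference rate)."""
    return int(round(0.05 * fs))


def default_window_length(fs: float) -> int:
    """The nearest odd sample count to 1 s (44101 at the reference rate)."""
    n = int(round(fs)) + 1
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class EnvelopeTrace:
    """Sliding-variance envelope aligned with its parent trace."""

    values: np.ndarray
    fs: float
    half_width: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid_range(self) -> tuple[int, int]:
        """Inclusive index interval where the window fits entirely."""
        return self.half_width, self.values.size - 1 - self.half_width


@dataclass(frozen=True)
class StmhtTrace:
    """STMHT curve; edges where the window does not fit are zero."""

    values: np.ndarray
    fs: float
    window_length: int
    kernel: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SegmentationEvents:
    """Signed zero-crossing events of the STMHT curve, in seconds."""

    n2p: np.ndarray
    p2n: np.ndarray
    signum: np.ndarray
    dsignum: np.ndarray
    fs: float


def _sliding_sum(x: np.ndarray, width: int) -> np.ndarray:
    """Sum of x over every length-``width`` window (length len(x)-width+1)."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[width:] - c[:-width]


def viola_envelope(
    trace: SignalTrace,
    half_width: int | None = None,
    *,
    normalized: bool = True,
) -> EnvelopeTrace:
    """Windowed-variance envelope of a trace.

    For every index m where the window fits, the value is the variance of the
    2*half_width+1 samples centred on m (mean removed over the same window).
    Border indices are filled by edge replication of the nearest valid value.
    With ``normalized`` the envelope is scaled to a maximum of 1.
    """
    w = default_half_width(trace.fs) if half_width is None else int(half_width)
    if w < 1:
        raise ParameterError("half_width must be >= 1")
    m = len(trace)
    width = 2 * w + 1
    if m <= 2 * w:
        raise DegenerateInputError(
            f"trace of {m} samples is shorter than the {width}-sample window"
        )
    x = trace.samples
    mean = _sliding_sum(x, width) / width
    mean_sq = _sliding_sum(x * x, width) / width
    var = np.maximum(mean_sq - mean * mean, 0.0)
    # round-off from the cumulative sums leaves O(eps) residue on constant
    # traces; snap it to zero so they are detected as envelope-free
    var[var < 1e-14 * max(float(mean_sq.max()), 1e-300)] = 0.0
    values = np.empty(m)
    values[w : m - w] = var
    values[:w] = var[0]
    values[m - w :] = var[-1]
    if normalized:
        peak = float(values.max())
        if peak == 0.0:
            raise DegenerateInputError("zero-variance trace has no envelope")
        values = values / peak
    return EnvelopeTrace(values, trace.fs, w)


def stmht_kernel(window_length: int) -> np.ndarray:
    """Antisymmetric STMHT kernel of odd length N (center tap zero).

    W_E[i] = [cos((N-1-2i)pi/(2N)) - cos((N-1-2i)pi/2)] / [N sin((N-1-2i)pi/(2N))]
    """
    n = int(window_length)
    if n < 3 or n % 2 == 0:
        raise ParameterError("window_length must be an odd integer >= 3")
    i = np.arange(n)
    a = (n - 1 - 2 * i).astype(float)
    kernel = np.zeros(n)
    off = a != 0
    theta = a[off] * np.pi / (2 * n)
    kernel[off] = (np.cos(theta) - np.cos(a[off] * np.pi / 2)) / (n * np.sin(theta))
    return kernel


def stmht(env: EnvelopeTrace, window_length: int | None = None) -> StmhtTrace:
    """Correlate the envelope with the STMHT kernel (rectangular moving window).

    Defined on indices where the odd window fits; the borders are zero-padded.
    """
    n = default_window_length(env.fs) if window_length is None else int(window_length)
    if n % 2 == 0:
        raise ParameterError("window_length must be odd")
    m = len(env)
    if m <= n:
        raise DegenerateInputError(
            f"envelope of {m} samples is not longer than the {n}-sample window"
        )
    kernel = stmht_kernel(n)
    # correlation == convolution with the reversed kernel
    valid = fftconvolve(env.values, kernel[::-1], mode="valid")
    half = (n - 1) // 2
    values = np.zeros(m)
    values[half : half + valid.size] = valid
    return StmhtTrace(values, env.fs, n, kernel)


def zero_cross_events(st: StmhtTrace, fs: float | None = None) -> SegmentationEvents:
    """Locate the signed zero crossings of the STMHT curve.

    The signum trace is computed, exact-zero dwells inherit the previous
    nonzero sign (so a -,0,+ run produces exactly one N2P), and a jump of +2
    (resp. -2) in its first difference marks an N2P (resp. P2N) at time i/fs
    of the sample before the crossing.
    """
    fs = st.fs if fs is None else fs
    s = np.sign(st.values)
    nonzero = s != 0
    if nonzero.any():
        idx = np.where(nonzero, np.arange(s.size), -1)
        idx = np.maximum.accumulate(idx)
        filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    else:
        filled = s
    ds = np.diff(filled)
    n2p_idx = np.flatnonzero(ds == 2)
    p2n_idx = np.flatnonzero(ds == -2)
    if n2p_idx.size == 0 and p2n_idx.size == 0:
        raise SegmentationError("STMHT curve has no sign changes; no events found")
    return SegmentationEvents(
        n2p=n2p_idx / fs,
        p2n=p2n_idx / fs,
        signum=filled,
        dsignum=ds,
        fs=fs,
    )


def events_to_csv(ev: SegmentationEvents, path) -> None:
    """Write events as (time_s, kind) rows sorted by time."""
    rows = [(t, "N2P") for t in ev.n2p] + [(t, "P2N") for t in ev.p2n]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("time_s,kind\n")
        for t, kind in rows:
            fh.write(f"{t:.6f},{kind}\n")
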