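"""Loading and preconditioning of phonocardiogram (PCG) recordings.

A raw stethoscope recording is reduced to the working trace used by every
downstream stage: mono, resampled to the reference rate, band-limited to the
heart-sound band (roughly 20-700 Hz) by a db10 wavelet multilevel
decomposition, and peak-normalized to unit amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import DegenerateInputError, InputError, ParameterError

#: Reference sampling rate (Hz) of the electronic-stethoscope recordings the
#: method's sample-count constants (50 ms envelope half-width, ~1 s STMHT
#: window) are tied to.
REFERENCE_FS = 44100

#: Heart-sound band edges in Hz retained by the wavelet filter.
BAND_LOW_HZ = 21.5
BAND_HIGH_HZ = 689.0


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitudes.
    fs : float
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ParameterError("SignalTrace samples must be one-dimensional")
        if samples.size < 1:
            raise DegenerateInputError("SignalTrace must hold at least one sample")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def load_recording(path, *, target_fs: int | None = REFERENCE_FS) -> SignalTrace:
    """Read a WAV recording into a mono :class:`SignalTrace`.

    Multi-channel audio is averaged to mono (single-point stethoscope
    capture is assumed).  Integer PCM is rescaled to [-1, 1].  Unless
    ``target_fs`` is None, the trace is resampled to ``target_fs`` so that
    the pipeline's sample-count constants keep their intended time scale.
    """
    try:
        fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on corrupt files
        raise InputError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path!r} contains no audio")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    trace = SignalTrace(data, float(fs))
    if target_fs is not None and fs != target_fs:
        trace = resample(trace, target_fs)
    return trace


def save_recording(trace: SignalTrace, path) -> None:
    """Write a trace as a 32-bit float WAV file."""
    wavfile.write(path, int(round(trace.fs)), trace.samples.astype(np.float32))


def resample(trace: SignalTrace, target_fs: int) -> SignalTrace:
    """Polyphase-resample a trace to ``target_fs`` Hz."""
    if target_fs <= 0:
        raise ParameterError("target_fs must be positive")
    if target_fs == trace.fs:
        return trace
    g = math.gcd(int(round(trace.fs)), int(target_fs))
    up, down = int(target_fs) // g, int(round(trace.fs)) // g
    out = resample_poly(trace.samples, up, down)
    return SignalTrace(out, float(target_fs))


def _decomposition_levels(fs: float, low: float) -> int:
    """Depth of the wavelet decomposition.

    Chosen so the deepest detail band's lower edge fs / 2**(L+1) sits at the
    low cut: L = round(log2(fs / low)) - 1.  At 44.1 kHz and low=21.5 Hz this
    is a 10-level decomposition whose levels 6..10 tile ~21.5-689 Hz.
    """
    return max(1, int(round(math.log2(fs / low))) - 1)


def bandlimit(
    trace: SignalTrace,
    low: float = BAND_LOW_HZ,
    high: float = BAND_HIGH_HZ,
    wavelet: str = "db10",
) -> SignalTrace:
    """Suppress energy outside [low, high] Hz by wavelet band selection.

    The trace is decomposed with the db10 mother wavelet; detail bands whose
    nominal dyadic range (fs/2**(j+1), fs/2**j) does not overlap (low, high)
    and the final approximation are zeroed before reconstruction.
    """
    if not (0 < low < high):
        raise ParameterError("need 0 < low < high")
    if trace.fs < 2 * high:
        raise ParameterError(
            f"fs={trace.fs} Hz cannot represent the {high} Hz band edge"
        )
    levels = _decomposition_levels(trace.fs, low)
    levels = min(levels, pywt.dwt_max_level(len(trace), pywt.Wavelet(wavelet).dec_len))
    coeffs = pywt.wavedec(trace.samples, wavelet, level=levels)
    # coeffs[0] is the approximation; coeffs[j] (j>=1) is detail level levels-j+1
    kept = [np.zeros_like(coeffs[0])]
    for j, c in enumerate(coeffs[1:], start=1):
        level = levels - j + 1
        band_lo = trace.fs / 2 ** (level + 1)
        band_hi = trace.fs / 2**level
        if band_lo < high and band_hi > low:
            kept.append(c)
        else:
            kept.append(np.zeros_like(c))
    out = pywt.waverec(kept, wavelet)[: len(trace)]
    return replace(trace, samples=out)


def normalize(trace: SignalTrace) -> SignalTrace:
    """Scale so the maximum absolute amplitude is exactly 1."""
    peak = float(np.max(np.abs(trace.samples)))
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an identically zero trace")
    return replace(trace, samples=trace.samples / peak)


def preprocess_recording(path, *, target_fs: int | None = REFERENCE_FS) -> SignalTrace:
    """load -> bandlimit -> normalize, the Stage-1 front end."""
    return normalize(bandlimit(load_recording(path, target_fs=target_fs)))


def trace_to_csv(trace: SignalTrace, path) -> None:
    """Write (sample_index, amplitude) rows."""
    idx = np.arange(len(trace))
    np.savetxt(
        path,
        np.column_stack([idx, trace.samples]),
        delimiter=",",
        header="sample_index,amplitude",
        comments="",
        fmt=("%d", "%.10g"),
    )
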