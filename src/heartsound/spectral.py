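"""Frequency-domain features of the complex sounds and their PCA reduction.

Per cycle, each segment (CS1, CS2) yields a magnitude spectrum whose smoothed
"secondary envelope" is unit-normalized; from it come three threshold-crossing
frequency widths (at Thv = 0.3, 0.5, 0.8) and the spectral center of gravity,
giving the 8-feature vector

    FF = [CS1_FW1, CS1_FW2, CS1_FW3, CS1_G, CS2_FW1, CS2_FW2, CS2_FW3, CS2_G]

(all in Hz).  Standardized PCA reduces FF to the three diagnostic components
[gamma1, gamma2, gamma3] used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateInputError, ParameterError
from .preprocess import SignalTrace

#: Column names of the 8-feature frequency matrix, in canonical order.
FEATURE_NAMES = (
    "CS1_FW1",
    "CS1_FW2",
    "CS1_FW3",
    "CS1_G",
    "CS2_FW1",
    "CS2_FW2",
    "CS2_FW3",
    "CS2_G",
)

DEFAULT_L1 = 9
DEFAULT_L2 = 17
DEFAULT_THV = (0.3, 0.5, 0.8)


@dataclass(frozen=True)
class Spectrum:
    """Half-spectrum DFT magnitudes; bin_hz = fs / segment_length."""

    values: np.ndarray
    bin_hz: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpectrumEnvelope:
    """Smoothed, unit-normalized spectrum envelope."""

    values: np.ndarray
    bin_hz: float
    l1: int
    l2: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def magnitude_spectrum(segment: SignalTrace) -> Spectrum:
    """Magnitude DFT of a segment restricted to the half spectrum [0, M/2].

    No zero padding: the bin spacing fs/M is set by the segment's own length,
    i.e. by the segment duration.
    """
    m = len(segment)
    if m < 2:
        raise DegenerateInputError("segment must hold at least 2 samples")
    mags = np.abs(np.fft.rfft(segment.samples, n=m))
    return Spectrum(mags[: m // 2 + 1], segment.fs / m)


def secondary_envelope(
    spectrum: Spectrum,
    l1: int = DEFAULT_L1,
    l2: int = DEFAULT_L2,
    *,
    swap_windows: bool = False,
) -> SpectrumEnvelope:
    """Double-window smoothed envelope of a magnitude spectrum.

    A triangular window of half-width l1+l2 (weights l1+l2+1-|offset|) is
    applied, an inner rectangular window over offsets [-(l1-l2-1), l1-l2-1]
    is subtracted (this range is empty when l1 <= l2 and then contributes
    nothing), and the result is divided by (2*l1+1)(2*l2+1).  Edge bins use
    reflected padding; the envelope is then normalized to a maximum of 1.

    ``swap_windows`` exchanges the two window roles, for the alternative
    reading in which the wider window is the triangular one.
    """
    if swap_windows:
        l1, l2 = l2, l1
    if l1 < 0 or l2 < 0:
        raise ParameterError("window half-widths must be nonnegative")
    outer = l1 + l2
    v = spectrum.values
    if v.size <= 2 * outer + 1:
        raise DegenerateInputError(
            f"spectrum of {v.size} bins is too short for half-width {outer}"
        )
    padded = np.pad(v, outer, mode="reflect")
    tri = (outer + 1) - np.abs(np.arange(-outer, outer + 1))
    acc = np.convolve(padded, tri.astype(float), mode="valid")
    inner = l1 - l2 - 1
    if inner >= 0:
        rect_width = 2 * inner + 1
        start = outer - inner
        rect = np.convolve(padded[start : padded.size - start], np.ones(rect_width), mode="valid")
        acc = acc - rect
    env = acc / ((2 * l1 + 1) * (2 * l2 + 1))
    peak = float(env.max())
    if peak <= 0.0:
        raise DegenerateInputError("secondary envelope has no positive peak")
    return SpectrumEnvelope(env / peak, spectrum.bin_hz, l1, l2)


def gravity_center(env: SpectrumEnvelope) -> float:
    """Spectral center of gravity in Hz: sum(k*env[k]) / sum(env[k]) * bin_hz."""
    total = float(env.values.sum())
    if total == 0.0:
        raise DegenerateInputError("cannot take the gravity of a zero envelope")
    k = np.arange(env.values.size)
    return float((k * env.values).sum() / total) * env.bin_hz


def frequency_widths(
    env: SpectrumEnvelope, thv_list=DEFAULT_THV
) -> np.ndarray:
    """Width in Hz of the outermost crossing span above each threshold.

    For each Thv, Lp is the first bin exceeding Thv and Rp the last; the
    width is (Rp - Lp) * bin_hz, or 0 when the envelope never exceeds Thv.
    """
    widths = np.empty(len(thv_list))
    for j, thv in enumerate(thv_list):
        if not (0.0 < thv < 1.0):
            raise ParameterError(f"threshold must lie in (0, 1), got {thv}")
        above = np.flatnonzero(env.values > thv)
        widths[j] = 0.0 if above.size == 0 else (above[-1] - above[0]) * env.bin_hz
    return widths


def feature_vector(
    cs1: SignalTrace,
    cs2: SignalTrace,
    l1: int = DEFAULT_L1,
    l2: int = DEFAULT_L2,
    thv_list=DEFAULT_THV,
    *,
    swap_windows: bool = False,
) -> np.ndarray:
    """The 8-feature FF vector of one cardiac cycle (widths then gravity,
    CS1 block before CS2 block)."""
    parts = []
    for seg in (cs1, cs2):
        env = secondary_envelope(
            magnitude_spectrum(seg), l1, l2, swap_windows=swap_windows
        )
        parts.append(np.concatenate([frequency_widths(env, thv_list), [gravity_center(env)]]))
    return np.concatenate(parts)


@dataclass(frozen=True)
class PcaModel:
    """Standardized-covariance PCA of the 8-feature matrix.

    ``eigenvectors[i]`` is the loading vector of the (i+1)-th principal
    component; eigenvalues are sorted descending and sum to 8 when fitted on
    standardized 8-feature data.
    """

    mu: np.ndarray
    sigma: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        for name in ("mu", "sigma", "eigenvectors", "eigenvalues"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def standardize(self, ff) -> np.ndarray:
        return (np.asarray(ff, dtype=float) - self.mu) / self.sigma

    def to_dict(self) -> dict:
        return {
            "mu_ff": self.mu.tolist(),
            "sigma_ff": self.sigma.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            mu=d["mu_ff"],
            sigma=d["sigma_ff"],
            eigenvectors=d["eigenvectors"],
            eigenvalues=d["eigenvalues"],
        )


def fit_pca(ff_matrix) -> PcaModel:
    """Fit standardized PCA to an n-by-8 feature matrix.

    Columns are standardized by their sample mean and SD (ddof=1); the
    eigenpairs of the resulting correlation matrix are sorted by descending
    eigenvalue and each eigenvector's sign is fixed so its largest-magnitude
    entry is positive.
    """
    x = np.asarray(ff_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(FEATURE_NAMES):
        raise DataError(f"expected an n-by-{len(FEATURE_NAMES)} matrix, got {x.shape}")
    if x.shape[0] < 9:
        raise DataError(f"need at least 9 rows to fit PCA, got {x.shape[0]}")
    if not np.isfinite(x).all():
        raise DataError("feature matrix contains non-finite values")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(sigma == 0)]
        raise DataError(f"constant feature column(s): {bad}")
    z = (x - mu) / sigma
    cov = np.cov(z, rowvar=False, ddof=1)
    eigenvalues, vectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order].T  # rows are eigenvectors
    for i, vec in enumerate(vectors):
        if vec[np.argmax(np.abs(vec))] < 0:
            vectors[i] = -vec
    return PcaModel(mu, sigma, vectors, eigenvalues)


def project(ff, model: PcaModel, m: int = 3) -> np.ndarray:
    """Project one FF vector (or an n-by-8 matrix) onto the first m components."""
    if not (1 <= m <= model.eigenvalues.size):
        raise ParameterError(f"m must be in [1, {model.eigenvalues.size}], got {m}")
    z = model.standardize(ff)
    return z @ model.eigenvectors[:m].T


def explained_variance(model: PcaModel, m: int) -> float:
    """Percentage of total variance carried by the first m components."""
    if not (1 <= m <= model.eigenvalues.size):
        raise ParameterError(f"m must be in [1, {model.eigenvalues.size}], got {m}")
    return 100.0 * float(model.eigenvalues[:m].sum() / model.eigenvalues.sum())
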