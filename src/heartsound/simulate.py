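"""Synthetic labelled phonocardiograms and feature datasets.

The generator reproduces the structural assumptions the diagnostic method
relies on — two Gaussian-windowed tone bursts per cycle (S1, S2), diastole
longer than systole, and class-specific murmurs as band-limited noise — so
every pipeline stage can be exercised with known ground truth.  It does not
attempt hemodynamic realism; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classifier import ClassifierModel
from .errors import ParameterError
from .preprocess import SignalTrace


@dataclass(frozen=True)
class Murmur:
    """Band-limited noise added between the tone bursts."""

    band: tuple[float, float]
    amplitude: float
    placement: str = "systolic"  # systolic | diastolic | both

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ParameterError("murmur band must satisfy 0 < lo < hi")
        if self.placement not in ("systolic", "diastolic", "both"):
            raise ParameterError(f"unknown murmur placement {self.placement!r}")


@dataclass(frozen=True)
class CycleSpec:
    """Timing and spectral content of one synthetic cardiac cycle.

    Diastole must exceed systole — that asymmetry is what lets the N2P-gap
    comparison identify S1.  Tone frequencies default to the S1~30-100 Hz,
    S2~50-150 Hz bands typical of fundamental heart sounds.
    """

    s1_center_hz: float = 65.0
    s2_center_hz: float = 130.0
    s1_dur: float = 0.06
    s2_dur: float = 0.05
    systole: float = 0.30
    diastole: float = 0.50
    murmur: Murmur | None = None
    fs: float = 44100.0
    noise_sd: float = 0.01
    s2_amplitude: float = 0.8
    #: relative SD of the per-burst tone-frequency and per-cycle murmur-gain
    #: variation (beat-to-beat physiological variability)
    cycle_jitter: float = 0.02

    def __post_init__(self):
        if not self.diastole > self.systole:
            raise ParameterError("diastole must be longer than systole")
        for name in ("s1_dur", "s2_dur", "systole", "diastole"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.murmur is not None and self.murmur.band[1] >= self.fs / 2:
            raise ParameterError("murmur band must lie below the Nyquist rate")

    @property
    def period(self) -> float:
        return self.systole + self.diastole


def _tone_burst(t: np.ndarray, center: float, dur: float, freq: float, rng) -> np.ndarray:
    """Gaussian-windowed sinusoid centred at ``center`` (sigma = dur/6)."""
    sigma = dur / 6.0
    window = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    window[np.abs(t - center) > dur] = 0.0
    phase = rng.uniform(0, 2 * np.pi)
    return window * np.sin(2 * np.pi * freq * (t - center) + phase)


def _band_noise(n: int, band: tuple[float, float], fs: float, rng) -> np.ndarray:
    """Spectrally tapered noise scaled to unit peak amplitude.

    The amplitude spectrum ramps up over the octave below ``lo``, peaks at
    ``lo`` and decays as a raised cosine to zero at ``hi`` — the decrescendo
    shape typical of real murmurs.  The taper keeps the spectral envelope
    smooth, so threshold crossings of the downstream secondary envelope move
    continuously with the murmur gain instead of jumping between modes.
    """
    lo, hi = band
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = np.zeros_like(freqs)
    ramp = (freqs >= 0.5 * lo) & (freqs < lo)
    mask[ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp] - 0.5 * lo) / (0.5 * lo)))
    body = (freqs >= lo) & (freqs <= hi)
    mask[body] = np.cos(0.5 * np.pi * (freqs[body] - lo) / (hi - lo))
    spec = np.fft.rfft(rng.standard_normal(n)) * mask
    x = np.fft.irfft(spec, n)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _interval_window(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """Unit window over [start, stop] with raised-cosine ramps."""
    w = np.zeros_like(t)
    core = (t >= start) & (t <= stop)
    w[core] = 1.0
    for edge, sign in ((start, 1), (stop, -1)):
        zone = (t >= edge - ramp) & (t < edge) if sign > 0 else (t > edge) & (t <= edge + ramp)
        w[zone] = 0.5 * (1 + np.cos(np.pi * (t[zone] - edge) / ramp))
    return w


def generate_recording(
    spec: CycleSpec, n_cycles: int, seed: int | None = None
) -> tuple[SignalTrace, dict]:
    """Synthesize a recording of ``n_cycles`` cycles plus ground truth.

    The recording starts and ends mid-diastole.  Ground truth holds the S1/S2
    burst-center times and the cycle start times (mid-diastole points).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be at least 1")
    rng = np.random.default_rng(seed)
    lead = spec.diastole / 2
    total = lead + n_cycles * spec.period + spec.diastole / 2
    n = int(round(total * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    s1_centers, s2_centers, cycle_starts = [], [], []
    for i in range(n_cycles):
        s1 = lead + i * spec.period
        s2 = s1 + spec.systole
        s1_centers.append(s1)
        s2_centers.append(s2)
        cycle_starts.append(s1 - spec.diastole / 2)
        jit = lambda: 1.0 + spec.cycle_jitter * rng.standard_normal()
        x += _tone_burst(t, s1, spec.s1_dur, spec.s1_center_hz * jit(), rng)
        x += spec.s2_amplitude * _tone_burst(t, s2, spec.s2_dur, spec.s2_center_hz * jit(), rng)
        if spec.murmur is not None:
            mur = spec.murmur
            noise = _band_noise(n, mur.band, spec.fs, rng)
            ramp = 0.02
            if mur.placement in ("systolic", "both"):
                w = _interval_window(t, s1 + spec.s1_dur / 2, s2 - spec.s2_dur / 2, ramp)
                x += mur.amplitude * jit() * noise * w
            if mur.placement in ("diastolic", "both"):
                # early-diastolic decrescendo: the murmur hugs S2 and decays,
                # leaving late diastole quiet (its midpoint event intact)
                start = s2 + spec.s2_dur / 2
                stop = s2 + 0.45 * spec.diastole
                w = _interval_window(t, start, stop, ramp)
                decay = np.ones_like(t)
                dz = (t >= start) & (t <= stop)
                decay[dz] = np.cos(0.5 * np.pi * (t[dz] - start) / (stop - start))
                x += mur.amplitude * jit() * _band_noise(n, mur.band, spec.fs, rng) * w * decay
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    truth = {
        "s1_centers": s1_centers,
        "s2_centers": s2_centers,
        "cycle_starts": cycle_starts,
        "systole": spec.systole,
        "diastole": spec.diastole,
        "fs": spec.fs,
    }
    return SignalTrace(x, spec.fs), truth


#: Per-class designs giving the seven classes distinct spectral signatures:
#: the murmur band location drives the gravity features, the band extent the
#: width features, and the tone frequencies shift the fundamental peaks.
_PRESETS: dict[str, dict] = {
    "NM": dict(s1=60.0, s2=120.0, murmur=None),
    "MS": dict(s1=40.0, s2=80.0,
               murmur=Murmur(band=(20.0, 170.0), amplitude=3.5, placement="diastolic")),
    "MR": dict(s1=65.0, s2=130.0,
               murmur=Murmur(band=(60.0, 300.0), amplitude=3.5, placement="systolic")),
    "ASD": dict(s1=60.0, s2=120.0,
                murmur=Murmur(band=(60.0, 460.0), amplitude=3.5, placement="systolic")),
    "AR": dict(s1=70.0, s2=140.0,
               murmur=Murmur(band=(60.0, 580.0), amplitude=3.5, placement="diastolic")),
    "AS": dict(s1=65.0, s2=130.0,
               murmur=Murmur(band=(400.0, 688.0), amplitude=6.0, placement="systolic")),
    "VSD": dict(s1=60.0, s2=125.0,
                murmur=Murmur(band=(40.0, 688.0), amplitude=5.0, placement="both")),
}

CLASS_LABELS = tuple(_PRESETS)


def class_presets(fs: float = 44100.0) -> dict[str, CycleSpec]:
    """Seven named cycle specifications, one per diagnostic class."""
    return {
        label: CycleSpec(
            s1_center_hz=p["s1"], s2_center_hz=p["s2"], murmur=p["murmur"], fs=fs
        )
        for label, p in _PRESETS.items()
    }


def generate_feature_dataset(
    model: ClassifierModel, n_per_class: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled 3-D features from each component of a classifier model.

    Returns (features, labels) with n_per_class draws from every
    N(mu_k, Sigma_k), in component order.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for comp in model.components:
        xs.append(rng.multivariate_normal(comp.mu, comp.sigma, size=n_per_class))
        ys.extend([comp.label] * n_per_class)
    return np.vstack(xs), np.array(ys, dtype=object)


def jittered(spec: CycleSpec, rng: np.random.Generator, scale: float = 0.015) -> CycleSpec:
    """Small per-recording variation of tone frequencies and timing."""
    f = lambda: 1.0 + scale * rng.standard_normal()
    return replace(
        spec,
        s1_center_hz=spec.s1_center_hz * f(),
        s2_center_hz=spec.s2_center_hz * f(),
        systole=spec.systole * (1.0 + 0.5 * scale * rng.standard_normal()),
        diastole=spec.diastole * (1.0 + 0.5 * scale * rng.standard_normal()),
    )
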