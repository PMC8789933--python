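"""Pairing of STMHT events into cardiac-cycle boundaries and slicing.

A normal cycle is S1 -> systole -> S2 -> diastole, with diastole longer than
systole.  N2P events sit on burst centers (S1 or S2) and P2N events on the
quiet midpoints between bursts.  Comparing consecutive N2P gaps tells which
N2P is an S1 (the shorter gap, systole, follows it); the complex sounds are
then CS1 = [mid-diastole, mid-systole) around S1 and CS2 = [mid-systole,
next mid-diastole) around S2, so each P2N is simultaneously the end of one
segment and the start of the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import (
    SegmentationEvents,
    default_half_width,
    default_window_length,
    stmht,
    viola_envelope,
    zero_cross_events,
)
from .errors import ParameterError, SegmentationError
from .preprocess import SignalTrace


@dataclass(frozen=True)
class CyclePair:
    """Boundaries of one cardiac cycle, in seconds.

    ``cs21`` starts CS1 (mid-diastole), ``cs12`` splits CS1 from CS2
    (mid-systole), ``cs21_next`` ends CS2 (the following mid-diastole).
    """

    cs21: float
    cs12: float
    cs21_next: float

    def __post_init__(self):
        if not (self.cs21 < self.cs12 < self.cs21_next):
            raise ParameterError(
                f"cycle boundaries must increase: {self.cs21}, {self.cs12}, "
                f"{self.cs21_next}"
            )

    def spans(self, fs: float) -> tuple[tuple[int, int], tuple[int, int]]:
        """Half-open sample-index spans (cs1_span, cs2_span)."""
        i21 = int(round(self.cs21 * fs))
        i12 = int(round(self.cs12 * fs))
        i21n = int(round(self.cs21_next * fs))
        return (i21, i12), (i12, i21n)


#: Minimum plausible duration of a complex sound, in seconds.  Strong murmurs
#: can wiggle the STMHT through zero between true events; boundary pairs
#: bracketing less than this are treated as spurious.
MIN_CS_DURATION = 0.13


def pair_boundaries(
    ev: SegmentationEvents, min_cs_duration: float = MIN_CS_DURATION
) -> list[CyclePair]:
    """Pair N2P/P2N events into per-cycle (cs21, cs12, cs21_next) boundaries.

    The stream is aligned so each P2N[i] is the last midpoint before N2P[i];
    where the N2P gap comparison identifies N2P as an S1 center, the two
    midpoints bracketing it become (cs21, cs12).  Pairs spanning less than
    ``min_cs_duration`` seconds are discarded as spurious, and trailing
    cycles lacking their closing boundary are dropped.
    """
    n2p = np.asarray(ev.n2p, dtype=float)
    p2n = np.asarray(ev.p2n, dtype=float)
    if n2p.size < 3 or p2n.size < 3:
        raise SegmentationError(
            f"need at least 3 events of each kind, got {n2p.size} N2P / "
            f"{p2n.size} P2N"
        )
    # align: drop burst centers that precede the first midpoint
    n2p = n2p[n2p > p2n[0]]
    if n2p.size < 3:
        raise SegmentationError("too few N2P events after alignment")
    d_n2p = np.diff(n2p)
    pairs: set[tuple[float, float]] = set()
    for i in range(d_n2p.size - 1):
        if d_n2p[i] < d_n2p[i + 1]:  # N2P[i] is an S1 center
            if i + 1 < p2n.size:
                pairs.add((p2n[i], p2n[i + 1]))
        else:  # N2P[i+1] is the S1 center
            if i + 2 < p2n.size:
                pairs.add((p2n[i + 1], p2n[i + 2]))
    ordered = sorted(p for p in pairs if p[1] - p[0] >= min_cs_duration)
    cycles = []
    for (cs21, cs12), (cs21_next, _) in zip(ordered, ordered[1:]):
        if cs12 < cs21_next and cs21_next - cs12 >= min_cs_duration:
            cycles.append(CyclePair(cs21, cs12, cs21_next))
    if not cycles:
        raise SegmentationError("no complete cardiac cycle could be paired")
    return cycles


def extract_cycles(
    trace: SignalTrace, boundaries: list[CyclePair]
) -> list[tuple[SignalTrace, SignalTrace]]:
    """Slice the trace into per-cycle (CS1, CS2) segment pairs.

    Half-open sample spans: CS1 = trace[cs21:cs12), CS2 = trace[cs12:cs21_next),
    so adjacent segments never share a sample and their concatenation
    reproduces the inter-boundary span exactly.
    """
    out = []
    for cp in boundaries:
        (i21, i12), (_, i21n) = cp.spans(trace.fs)
        if i21 < 0 or i21n > len(trace):
            raise ParameterError(
                f"cycle boundaries [{cp.cs21}, {cp.cs21_next}] s fall outside "
                f"the {trace.duration:.3f} s trace"
            )
        out.append(
            (
                SignalTrace(trace.samples[i21:i12], trace.fs),
                SignalTrace(trace.samples[i12:i21n], trace.fs),
            )
        )
    return out


def segment_recording(
    trace: SignalTrace,
    half_width: int | None = None,
    window_length: int | None = None,
    min_cs_duration: float = MIN_CS_DURATION,
) -> tuple[list[CyclePair], list[tuple[SignalTrace, SignalTrace]]]:
    """Run Stage 1 end to end on a preprocessed trace.

    Window defaults scale with the sampling rate (50 ms envelope half-width,
    ~1 s STMHT window), reproducing the reference 44.1 kHz sample counts.
    """
    w = default_half_width(trace.fs) if half_width is None else half_width
    n = default_window_length(trace.fs) if window_length is None else window_length
    env = viola_envelope(trace, w)
    st = stmht(env, n)
    ev = zero_cross_events(st)
    boundaries = pair_boundaries(ev, min_cs_duration)
    return boundaries, extract_cycles(trace, boundaries)


def boundaries_to_csv(boundaries: list[CyclePair], path) -> None:
    with open(path, "w") as fh:
        fh.write("cycle_index,cs21_s,cs12_s,cs21_next_s\n")
        for i, cp in enumerate(boundaries):
            fh.write(f"{i},{cp.cs21:.6f},{cp.cs12:.6f},{cp.cs21_next:.6f}\n")
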