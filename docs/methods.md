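# Methods

## Signal model and preprocessing

A phonocardiogram is treated as a uniformly sampled mono trace. Recordings
are resampled to the 44.1 kHz reference rate on load (the pipeline's window
constants are sample counts tied to that rate), averaged to mono, band-limited
and peak-normalized. Band limiting uses a db10 multilevel wavelet
decomposition: the depth is L = round(log₂(fs/21.5)) − 1, so the deepest
detail band's lower edge sits at the 21.5 Hz cut; detail bands whose dyadic
range (fs/2^(j+1), fs/2^j) overlaps (21.5, 689) Hz are kept and all other
bands, including the final approximation, are zeroed before reconstruction.
At 44.1 kHz this keeps detail levels 6–10 (≈21.5–689 Hz). The dyadic edges
only approximate the nominal band; the db10 filters are not brick-wall, and
the tests therefore assert energy ratios (≥ 90% pass-band retention, ≤ 10%
stop-band leakage, ≥ 20 dB two-tone contrast) rather than exact masks.

When a different sampling rate is used without resampling, the window
constants scale as time constants: envelope half-width W = round(0.05·fs)
(50 ms; 2205 samples at the reference rate) and STMHT window N = the odd
count nearest fs (≈1 s; 44101). The test suite and the standard protocols
run the simulator at 4 kHz under this scaling: the spectral features are
unchanged because their bin spacing fs/M is fixed by segment duration, and
the signal content lies below 700 Hz.

## Envelope, STMHT and events

The envelope is the windowed variance (local mean removed) over 2W+1
samples, computed with cumulative sums, valid on [W, M−1−W], edge-replicated
outside, and normalized to a unit maximum. Variance below 1e−14 of the
window-mean-square scale is snapped to zero so constant traces are reported
as envelope-free rather than normalized against numerical residue.

The STMHT slides an antisymmetric kernel (center tap zero, moving window
rectangular) over the envelope; the implementation is an FFT correlation and
is checked against a literal nested-loop transcription at 1e−10. Its zero
crossings are read from the signum difference: +2 is an N2P event, −2 a P2N
event, timestamped i/fs at the sample before the crossing. Exact zero dwells
inherit the previous nonzero sign, so a −,0,+ run yields one N2P; zeros at
the very start of the trace (the zero-padded STMHT border) have no preceding
sign and emit no event.

## Cycle pairing

Events are aligned so that P2N[i] is the last midpoint before burst center
N2P[i] (leading burst centers without a preceding midpoint are dropped).
Where the N2P gap comparison D[i] < D[i+1] marks N2P[i] as an S1 (the short
gap, systole, follows it), the bracketing midpoints (P2N[i], P2N[i+1]) become
(CS21, CS12); in the opposite phase the recurrence consumes (P2N[i+1],
P2N[i+2]). Duplicate pairs from the two phases are merged, pairs spanning
less than 0.13 s — the plausibility floor for a complex-sound duration — are
discarded as murmur-induced artefacts, and consecutive pairs are chained into
cycles (CS21, CS12, CS21_next). Slices are half-open sample intervals, so
CS1 and CS2 partition the inter-boundary span exactly. The first and last
ground-truth cycles of a recording are structurally unrecoverable (they lack
a bracketing midpoint) and are excluded from recovery statistics.

## Spectral features

Per segment the magnitude DFT (no zero padding; bin width fs/M) is restricted
to [0, fs/2] — the full-spectrum centroid of a real signal's symmetric DFT
would collapse to M/2 regardless of content. The secondary envelope applies
a triangular window of half-width L1+L2 (weights L1+L2+1−|offset|) and
subtracts an inner rectangular window over offsets [−(L1−L2−1), L1−L2−1],
divided by (2L1+1)(2L2+1); with the default L1 = 9 < L2 = 17 the inner range
is empty and contributes nothing. That literal reading is the default; a
`swap_windows` switch exchanges the two roles for the alternative reading in
which the wider window is triangular. Edges use reflected padding, and the
envelope is normalized to a unit maximum.

Widths are outermost threshold crossings: for each Thv ∈ {0.3, 0.5, 0.8},
Lp is the first bin strictly above Thv and Rp the last, width = (Rp−Lp)·bin,
with 0 when the envelope never exceeds Thv (murmur-free or
missing-component segments then contribute a defined value instead of a
missing one). Crossings are located at integer bins; no sub-bin
interpolation. The gravity is Σ k·E[k] / Σ E[k] in Hz. The 8-vector FF
stacks [FW1, FW2, FW3, G] for CS1 then CS2.

## PCA

Columns are standardized by sample mean and SD (ddof = 1); the eigensystem of
the resulting correlation matrix is sorted by descending eigenvalue, and each
eigenvector's sign is fixed so its largest-magnitude entry is positive
(classification is otherwise sign-ambiguous). Three components are retained
(the smallest m with cumulative explained variance above 80%). The bundled
reference constants reproduce the tabulated explained-variance bookkeeping
(67.58% at m = 2, 86.73% at m = 3). The bundled second loading vector is kept
as tabulated even though its squared norm is 0.603 rather than 1 —
evidently a typographical defect in the reference table; orthonormality
invariants are asserted on fitted models, which satisfy them to 1e−8.

## Gaussian-mixture / Mahalanobis-distance classifier

The mixture is fitted with scikit-learn's EM (full covariance, reg_covar
0.01 added to every covariance diagonal per M step, up to 1000 iterations,
convergence tolerance 1e−8). Initialization: with class labels available, EM
starts from the per-class moments and refines unsupervised; without labels it
uses k-means with 4 restarts. The moment start matters: with seven close
clusters of very unequal spread, likelihood-maximizing EM from k-means
reproducibly splits the widest cluster and merges neighbours, which breaks
the component→class correspondence. Components are then named by Hungarian
assignment on the label-by-component contingency of highest-posterior
memberships (plain majority voting can give two components the same name).

Decision rule: d²ₖ(x) ≤ MDCₖ = χ²₃,βₖ puts x in class k; no qualifying
ellipsoid gives "unknown"; among several, the smallest normalized distance
d²ₖ/MDCₖ wins (the normalization respects per-class β). The β sweep
evaluates, per class over the grid 0.63:0.02:0.97, the one-vs-rest accuracy
of the binary rule "inside ellipsoid k ⇔ predicted k", and selects the
largest grid value within 1e−9 of the class maximum — the largest ellipsoid
among the most accurate ones. The full accuracy-vs-β table is kept in the
model metadata. Metrics are one-vs-rest TP/FP/TN/FN with CA, Se, Sp in
percent; per-cycle predictions are reported as-is (no per-recording
aggregation).

## Synthetic phonocardiograms

Each cycle is two Gaussian-windowed tone bursts — S1 (default 65 Hz, 60 ms,
amplitude 1) and S2 (130 Hz, 50 ms, amplitude 0.8) — with systole 0.3 s and
diastole 0.5 s by default (diastole > systole always; it is the premise the
gap comparison exploits). Murmurs are noise with a raised-cosine
(decrescendo) amplitude spectrum from a class-specific onset to a cutoff,
scaled to unit peak and placed in systole, in early diastole (hugging S2 and
decaying by 0.45·diastole, the shape of regurgitant diastolic murmurs — and
the placement that leaves the late-diastolic midpoint event intact), or
both. Per-burst tone frequency and per-cycle murmur gain jitter by 2%
(beat-to-beat variability); white measurement noise has SD 0.01 before peak
normalization. The seven presets differ in murmur cutoff (none for NM; 170,
300, 460, 580, 688 Hz for MS, MR, ASD, AR, AS; 40–688 Hz broadband for VSD),
placement, amplitude and tone frequencies, giving each class a distinct
(widths, gravity, CS1/CS2-asymmetry) signature.

Preset murmurs are deliberately prominent (peak amplitudes 0.65–6 relative
to S1), the loud-murmur regime the classifier targets. Two consequences are
documented rather than hidden: (i) ground-truth burst-center recovery by the
STMHT segmenter is guaranteed only for murmur amplitudes ≤ 0.5 — louder
sustained murmurs can out-weigh the bursts in the one-second STMHT integral
(envelope-based segmenters share this failure mode on loud regurgitation
sounds); the segmentation-recovery protocol therefore caps amplitudes at
0.5. (ii) With the full-strength presets the segmenter still produces
consistent per-class cycles, which is what the end-to-end protocol measures.
What the simulator does not model: band-limited S1/S2 with internal
splitting (A2/P2), heart-rate variability beyond small jitter, respiration
or friction artefacts, sensor coloration, and inter-patient variability
beyond the jitter above — so passing tests demonstrate the pipeline's
mechanics and calibration, not clinical performance.

## Standard protocol sizes

Coverage calibration: 100 000 draws per component (binomial SE ≈ 0.0015).
EM recovery: 2000 draws per component, sup-norm mean error after matching
(observed ≤ 0.05 across seeds). Segmentation recovery: 50 recordings of 10
cycles, presets cycled, systole ∼ U(0.25, 0.35) s, diastole ∼ U(0.45, 0.60)
s, amplitudes capped at 0.5; interior cycles scored. End-to-end: 10 training
and 3 held-out recordings per class, 12 cycles each, at a 4 kHz simulator
rate. These sizes give stable statistics in tens of seconds on one CPU.

## Known limitations

- The pairing recurrence assumes strict N2P/P2N alternation from a
  reasonably clean envelope; recordings whose STMHT yields too few events
  raise a segmentation error rather than a partial answer.
- The 0.13 s minimum segment duration is a heuristic guard; pathologically
  fast rhythms (period < 0.26 s) would be rejected by it.
- The bundled reference model scores features on the clinical feature scale
  of its source statistics; synthetic-preset features live on a different
  scale, so classifying simulator audio requires training on simulator
  features (as the end-to-end protocol does).
- Confidence-ellipsoid classification assumes one Gaussian mode per class;
  multi-modal classes (e.g. compound disease) violate the model.
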