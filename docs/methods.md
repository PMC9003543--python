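# Methods

This note records the models and procedures `ambientkit` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Motion signals

Consecutive 1 Hz grayscale frames are subtracted (`Dₜ = Fₜ − Fₜ₋₁`) in
signed wide integers — unsigned 8-bit input would otherwise wrap around —
and reduced to four series: GDS (sum of |Dₜ|), GDPC (count of pixels with
|d| strictly greater than δ), and per-block LDS/LDPC on a K×L partition.
Defaults δ=0, K=5, L=4; on 320×240 frames this gives 20 blocks of 64×60 px.
Blocks are enumerated row-major over the partition grid,
`s = (group along axis 0)·L + (group along axis 1)`, 0-based. A K or L
that does not divide the frame exactly is rejected rather than padded.
Color input collapses to grayscale by unweighted channel mean. The model
assumes a single moving subject, a static background and noise-free
frames; no noise-robustness procedure is applied.

## Audio features

Windows are `floor(0.030·fs)` samples (661 at 22 050 Hz) with 50% overlap
(hop 330); a trailing partial window is discarded; the taper is a Hann
window. The untapered snippet is retained transiently for annotation and
never persisted. The 10-band energy vector is `E = M S` with `S` the
one-sided STFT magnitude of the tapered window and `M` triangular mel
masks on 0–fs/2, each row normalized to unit sum (so a flat spectrum gives
unit energy per band). MFCCs use an independent 26-band log-mel front end
(power spectrum → mel → natural log floored at 1e−30 → orthonormal
DCT-II), keeping the first 20 coefficients; coefficient 0 carries overall
log-energy, so amplitude scaling shifts only that coefficient. Sample
entropy defaults to m=2, r=0.15·SD (the conventional setting for the
multiscale-entropy family); it returns NaN when a template count is zero,
e.g. on constant snippets.

## Alarm-note annotation and classification

The eleven classes are the nine note names plus Empty and Transition.
Empty fires when `max|STFT| < 1e−10 ·` window length (the generators emit
exact zeros; real recordings need the tolerance). Transition is
operationalized as 10–90% of the snippet's samples being exactly zero
while the remainder carries a detectable note peak. Otherwise the window
takes the note nearest the spectral peak, accepted within ±3% of the
note's fundamental (≈ half a semitone); peaks outside every band are
flagged `unassignable` and excluded from the corpus.

The 661-sample window gives 33.4 Hz bins — coarser than the spacing of
adjacent note fundamentals (E4 329.63 Hz vs F4 349.23 Hz), so a raw
peak-bin rule cannot separate them. Annotation therefore localizes the
peak on an 8192-point zero-padded FFT (2.7 Hz bins) refined by parabolic
interpolation of the log magnitude, searching above 100 Hz to skip
DC/ramp leakage. A handful of near-silent note-edge windows (> 90% zeros
with a sliver of onset ramp) receive smeared peaks and come out as odd
notes or `unassignable`; they are genuine boundary ambiguity, kept as the
rule labels them.

Classification uses gradient-boosted trees with the fixed hyperparameters
n_estimators=150, softmax multi-class objective, max_depth=6, everything
else default, under stratified 5-fold cross-validation (shuffled with a
fixed seed; every class must have at least `n_folds` examples).
Out-of-fold predictions are pooled for F1_micro (equal to accuracy in this
single-label setting, which the tests cross-check); per-class F1 scores
average with equal weight into F1_macro. Argmax ties break toward the
lowest class index (the classifier's native behaviour).

Speech mixing draws one snippet start per alarm uniformly at random,
fixed across the α grid {0.0, …, 0.9}; labels for every α are inherited
from the α=0 annotation, so the pooled corpus is exactly ten times the
clean corpus. Note that pooled cross-validation refolds over the pooled
rows — per-window predictions are not comparable row-by-row with the
clean run, only the aggregate scores are.

## Synthetic alarm corpus

Medium-priority alarms are 3 × (0.15 s note + 0.15 s gap) ≈ 0.9 s; high
priority plays its 5-note sequence twice at 2 × 5 × (0.3 s note + 0.15 s
gap) = 4.5 s. Tones carry 2nd/3rd harmonics at −12/−18 dB with 10 ms
raised-cosine ramps — enough timbre to be non-trivial without the spectral
splatter that would corrupt fundamental-peak annotation. Gap samples are
exactly zero, which is what makes Empty/Transition annotation exact. The
standard's actual per-category note sheets are not public in a usable
form, so the shipped defaults are configurable sequences chosen to cover
all nine notes across the sixteen alarms (populating all eleven classes);
the synthetic corpus reproduces the qualitative class imbalance of real
recordings (Empty modal) but not their exact per-class counts. The speech
surrogate is band-passed (100–4000 Hz) noise under a ~4 Hz syllabic
envelope plus three weak drifting formant-like resonances — broadband and
nonstationary, but not intelligible speech; results under mixing probe
robustness to speech-like interference, not to any particular speaker.

## Geolocation

Missing grid seconds take `RSSI[prev] · max(β·Δt, 1)` where `prev` is the
most recent second with an actual reading; with β=0.2 the previous value
is held for gaps up to exactly 5 s and decays multiplicatively beyond
(dBm values are negative, so decay means weaker). Values below −200 dBm
clamp to −200. Readings bin to the nearest grid second, last write wins;
seconds before a receiver's first reading take the clamp floor, since the
rule has no predecessor there. Room means average the three receivers per
room; the softmax uses unit scale on raw dBm (a temperature option exists
but defaults to 1). Scoring counts a second correct when the argmax room
matches the schedule; during transitions either endpoint room counts,
matching ground truth that overlaps both rooms while the subject moves.
The simulator draws Normal(mean, 3 dBm) per receiver-second around
−60 dBm (beacon in the room) / −80 dBm (elsewhere), ramping the mean
linearly across transition intervals, and drops 30% of samples
independently. Receiver noise streams are keyed to the room's position in
schedule order, which makes the generator exactly equivariant under room
relabelling.

## Pose analytics

A person is present when any coordinate of their 17-point array is
non-zero, so partial detections count. Activity uses the four hand
keypoints (left/right elbow, left/right wrist): Euclidean frame-to-frame
displacement per keypoint, IQR per keypoint with linear quantile
interpolation, and the mean IQR over the four compared against 5 px —
the empirical upper bound of standing-still displacement. The generator
jitters all keypoints with Normal(0, 1 px) and adds a 30 px, 10-frame
vertical sinusoid to the hand keypoints of exercising subjects; with
these defaults standing mean IQRs sit near 1.2 px and exercising near
7–8 px, so the rule separates perfectly. Occlusion handling and person
re-identification are out of scope.

## Environmental statistics

Period statistics are order statistics of illuminance restricted to named
half-open periods, with excluded windows (e.g. a nightly upload hour)
dropped first. Alignment windows are half-open `(t_slow − 600 s, t_slow]`,
avoiding double-counting of boundary samples; a window with no fast
samples marks that pair missing rather than interpolating. Differences
are fast-derived minus reference, so a low-reading hobby sensor yields a
negative mean difference; the limits-of-agreement SD uses the n−1
denominator; a zero-variance reference is rejected (r² undefined). The
paired generator puts the calibration bias on the fast trace and defines
each slow reading as the curve's window mean plus Normal noise, so a
noiseless, unbiased pair aligns exactly and an injected bias is recovered
as the Bland–Altman mean difference.

## Problem sizes and determinism

The default synthetic study conditions are: a 2822-window alarm corpus
from 16 alarms (plus a 28 220-row pooled corpus under the 10-point α
grid), a 600 s tracking run with 9 receivers, 180-frame occupancy
sessions with 3 subjects, and 3-day paired environmental traces at one
reference sample per 10 min (432 pairs). All generators are deterministic
under their seed; the alarm corpus itself involves no randomness at all
(the sixteen recordings are fixed), randomness entering only at fold
assignment, speech-snippet choice, and the noise processes of the RSSI,
keypoint and environmental simulators.

## Known limitations

Synthetic alarms have clean zero gaps and stationary tones; real
recordings add room acoustics, level drift and overlapping sources, so
the near-ceiling synthetic F1 scores bound, rather than estimate,
real-world performance. The RSSI simulator draws i.i.d. Gaussian noise
with no multipath or body-shadowing structure. Keypoint tracks have no
detection dropouts or identity switches. The light and temperature
generators emulate smooth diurnal structure only. PIR spike trains are
stored in capture format but no analytics are defined on them.
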