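# Methods

This note documents the models behind `echonav`: what is simulated, how the
processing chain works, which parameters matter, and where the design was
genuinely open.

## World model and synthetic scenes

The world is 2D: objects are closed polygons carrying point reflectors, each
with a dimensionless strength in (0, 1]. Two acoustic archetypes are
generated:

- **plant** objects: 15–40 weak scatterers (strength 0.02–0.15) scattered in
  a disc — a diffuse echo train, like foliage;
- **non-plant** objects: 1–3 strong scatterers (strength 0.6–1.0) on a
  smooth footprint — a specular glint, like a pot, trunk or fence post.

Corridor scenes place regularly spaced wall reflectors at ±width/2 around a
free centerline; ground-truth contours lie exactly on the wall faces. All
generators are bit-reproducible given a seed. Conventions: x right, y up,
meters; heading counter-clockwise from +x; azimuth positive to the robot's
left.

The generator densities and strengths are free parameters chosen to look
like cluttered vegetation rows at desk scale; they are not calibrated to
any measured site statistics.

## Echo synthesis

The emitted signal is a linear FM chirp, 100 kHz down to 20 kHz in 10 ms,
unit peak amplitude, sampled at 250 kS/s. One acquisition synthesizes a
0.035 s two-ear recording:

- the direct emission appears at time 0 in both ears at unit amplitude;
- each reflector inside the beam adds a delayed, attenuated chirp copy per
  ear; delays are `(|mouth→reflector| + |reflector→ear|)/c` with c = 343 m/s
  (configurable) and are realized at fractional-sample precision by
  evaluating the chirp formula at shifted times;
- attenuation is two-way spherical spreading `1/(r_out·r_back)` times a
  cosine beam gain (half-width 60° by default; the speaker beam width is a
  free parameter). Spreading ranges are clamped below at 0.5 m — without the
  clamp a reflector at 0.3 m would return an echo an order of magnitude
  louder than the emission itself, which no physical transducer chain would
  deliver;
- white Gaussian noise is added at 20 dB SNR relative to the strongest echo
  in the recording (relative to a small fixed reference, −60 dB re emission,
  when the scene is empty).

Echoes whose delay exceeds the window contribute nothing: the 0.035 s
window is equivalent to a ~6 m maximum range. Occlusion, multipath beyond
one bounce, Doppler, and frequency-dependent air absorption are not
modeled.

## Matched filtering and peak detection

Each ear is cross-correlated with the theoretical chirp; the analytic
(Hilbert) envelope of the correlation is the detection trace. Three
numerical choices matter here:

- **Emission reference and self-interference.** The emission compresses to
  a ~1/B = 12.5 µs pulse at lag 0 and serves as the time reference. Its
  correlation (sidelobes included) is subtracted — scaled by the correlation
  value at the reference — before envelope extraction. Without this, in
  scenes with little echo energy the emission sidelobes would normalize
  above threshold and appear as identical-in-both-ears "objects" at azimuth
  0 within a meter of the robot.
- **Blanking and normalization.** Only a 1 ms guard after the emission peak
  is blanked (plus the final 1 ms of the trace, which carries Hilbert edge
  artifacts). The post-blanking envelope is normalized to its own maximum,
  so the 0.3 amplitude threshold applies to echoes rather than to the much
  louder emission. Blanking the full chirp duration instead would make
  every target within ~2 m undetectable.
- **Noise floor.** Peaks must also exceed 6× a MAD-based sigma estimate of
  the post-blanking envelope, so a reflector-free recording produces no
  detections even though normalization would otherwise push noise to 1.0.

Peak detection keeps local maxima ≥ 0.3 separated by ≥ 2 ms, with
sub-sample refinement by parabolic interpolation (the 4 µs sampling grid
alone would quantize broadside azimuth to ~1.1° steps; interpolation
removes most of that floor).

## Interaural matching

For each left-ear peak the nearest right-ear peak within ±1 ms is tried,
and the pair is accepted only if the Pearson correlation of the segments
around the two peaks exceeds 0.9 — deliberately conservative: unmatched
echoes are dropped rather than risking phantom objects. Two adaptations are
needed because the comparison operates on the correlation envelope rather
than the raw waveform:

- Raw 100–20 kHz waveforms cut at integer samples decorrelate under the
  residual sub-sample interaural shift (~86° of carrier phase per sample at
  60 kHz), so the envelope — smooth at the sample scale — is compared
  instead, after light Gaussian smoothing (σ = 2 samples) to remove
  sub-sample phase sensitivity of the 3-sample-wide compressed pulse.
- The envelope-domain support of one echo is the compressed pulse, not the
  10 ms of the raw chirp; the Pearson support is therefore the central 1 ms
  around the peak (`match_support_s`), and the neighborhoods of *other*
  detected peaks inside the compared windows are blanked identically in
  both ears, since each neighbor carries its own interaural shift. With
  these rules a cluttered corridor yields ~4–6 accepted matches per
  three-heading acquisition; without them essentially every genuine pair in
  clutter fails the 0.9 threshold.

Localization: range from the mean two-ear delay, azimuth from
`arcsin(c·ITD/baseline)`. The arcsin argument is clamped to [−1, 1] to
survive noise-perturbed lag differences, but a pair whose implied ITD
exceeds the geometric maximum by more than 10% is rejected outright — it
cannot come from any real direction and is a mismatch, not noise. Ranges
beyond 6 m are discarded; duplicates across headings within 10 cm merge to
the highest-correlation detection.

On 100 simulated single-reflector trials (0.3–3 m, ±50°, 20 dB SNR) the
pipeline recovers range with ~0.02 cm and azimuth with ~0.02° mean absolute
error — far below hardware-scale error budgets, as expected for a
synthesizer and matched filter that share the same waveform model; the
errors scale with noise and clutter, not with the grid.

## Occupancy mapping

The grid is 2000×2000 cells of 5×5 cm, world-anchored with the mission
start at the center cell. Each detection is stamped as a 20×20-cell square
(1×1 m) centered on its cell; every 5 steps (2.5 m) the buffered squares
are integrated and joined by binary morphological closing (3×3 structuring
element, 3 iterations — the operator itself was an open choice; closing is
the minimal standard morphology that merges near-adjacent squares while
leaving isolated ones unchanged). Trajectory cells are forced free after
every mutation, so the traversed path is never walled off.

Contours are extracted as the free-space-facing boundary: boundary cells
(occupied, adjacent to free) are projected onto the trajectory, split by
side, binned by arc length (0.25 m bins), and the cell nearest the path
wins each bin.

## Navigation

A reactive bug automaton with 0.5 m cruise steps and 1 m sidesteps:
obstacle within 1.2 m inside a ±30° frontal sector (the sector width is a
design choice; the trigger uses the detections of the most recent
acquisition, the map being kept for reporting) → turn 90° right; sidestep
1 m when clear (another right turn when not — a wall-following fallback);
turn back left and re-check; resume the pre-avoidance heading once clear.
A mission terminates on leaving the scene bounds, at the step budget, or
as "boxed in" after eight consecutive rotations without progress. Entering
any object footprint raises a mission failure with a state dump — the
shipped corridor and cylinder-obstacle fixtures complete with zero
collisions, and the cylinder fixture reproduces the detour-and-resume
behavior. Odometry is assumed exact; there is no SLAM-style
self-localization and no goal-directed planning.

In **summed-beam mode** the three headings are superposed into one
wide-beam recording before processing. Echoes from different directions
then overlap at equal delays and partially decorrelate between the ears, so
far fewer pairs pass the 0.9 threshold and azimuths of off-axis reflectors
are distorted: the corridor still completes, with contour error roughly
2–4× the three-heading value — degraded but usable, which is the point of
the comparison.

## Classification

Echoes of objects within 3 m are classified. Each 35 ms recording, with the
emission interval silenced, passes three 4th-order Butterworth band-pass
filters (20–40, 40–60, 60–100 kHz) per ear — six signals. Each signal is
divided into 23 half-overlapping windows (window = length/12, hop =
window/2) and 21 features are computed per window: zero-crossing rate,
short-time energy, energy entropy, spectral entropy, centroid, spread,
flux, rolloff (0.90), and a 12-bin log-frequency chroma folded within the
ultrasonic band plus its deviation. Laid out feature-major this gives the
483-element vector per signal with block sizes
23/46/23/23/23/23/23/299. All-zero windows yield zeros by convention.

Six identical networks — input 483, dense 105 (ReLU), dropout 0.5, dense 50
(ReLU), dense 6 (ReLU), dense 1 (sigmoid) — are trained independently, one
per band×ear signal (binary cross-entropy, Adam, 100 epochs, batch 32,
per-feature standardization; all configurable, seeded). Prediction is the
majority of the six votes (sigmoid ≥ 0.5 ⇒ plant); a 3–3 tie falls to the
mean sigmoid; the reported probability is the mean sigmoid of the winning
side's voters. Balanced accuracy (mean per-class recall) is the headline
metric, and significance comes from retraining the full ensemble on 100
label permutations and counting permuted test scores that reach the
observed one, with add-one smoothing: p = (k+1)/101.

At a dead end with obstacles right, ahead and left, the robot classifies
all three and drives through the (highest-probability) plant; with no plant
it reports "boxed in".

## What the synthetic data does and does not show

The diffuse-vs-glint populations make the classification task genuinely
learnable from echo structure (a many-weak-scatterer train against a sparse
strong glint), and the corridor fixtures exercise the full
perception–mapping–navigation loop in clutter. They do not emulate real
vegetation acoustics (frequency-dependent scattering, wind motion, ground
reflections), real transducer responses, or the label noise of
camera-annotated field data. Passing tests therefore demonstrate the
internal consistency and robustness of the processing chain at realistic
SNR and geometry — not field-level accuracy figures, which depend on the
environment actually sensed.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen for
tight feedback loops: 100 localization trials, a 10 m corridor traversed in
~22 steps, a 40-per-class echo corpus with a 75/25 split, and the full
100-permutation significance test (which retrains 606 networks). All are
configurable upward; error statistics were stable across seeds at these
sizes.

## Known limitations

- The acoustic model is single-bounce, occlusion-free and
  absorption-free; echo strengths are not radiometrically calibrated.
- Interaural matching compares correlation envelopes, not raw waveforms;
  this is what makes the 0.9 Pearson rule workable at 250 kS/s, but it
  discards fine spectral-interference cues a raw comparison would carry.
- Contour accuracy is floored at ~half the inflation width (~0.5 m) by
  construction; the mapping is binary with no probabilistic occupancy or
  re-observation correction.
- The classifier is validated on synthetic archetypes only; its absolute
  accuracy says nothing about any particular real corpus.
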