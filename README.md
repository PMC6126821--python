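# echonav

Bat-like binaural echolocation at desk scale: a simulator and processing
pipeline for a sonar-guided ground robot that maps and navigates a novel
2D environment using nothing but wide-band chirp echoes received at two
"ears".

Echolocating bats solve mapping and obstacle avoidance with a single sound
emitter and two receivers. `echonav` re-creates that sensing loop in
software: synthetic scenes (rows of vegetation-like scatterers, corridors,
isolated obstacles) stand in for the physical world, and the full
perception-to-action chain runs exactly as it would on a robot:

1. **Acquisition** — at every 0.5 m step, a 10 ms linear FM chirp sweeping
   100→20 kHz is "emitted" at three headings (−60°, 0°, +60° relative to
   travel) and a 0.035 s two-ear recording is synthesized at 250 kS/s per
   ear (ears 7 cm apart). The window limits sensing to ≈ 6 m
   (`c·T/2 = 343·0.035/2`).
2. **Perception** — each ear is cross-correlated with the emitted chirp
   (matched filter). Envelope peaks ≥ 0.3 (normalized) separated by ≥ 2 ms
   are detected; for each left-ear peak an equivalent right-ear peak is
   sought within ±1 ms and accepted only if the Pearson correlation of the
   segments around the peaks exceeds 0.9. Each accepted pair is localized
   by

   `range = c·(τ_L + τ_R)/4`,  `azimuth = arcsin(c·(τ_R − τ_L)/d)`

   where τ are the echo delays, d = 0.07 m is the ear baseline, and
   positive azimuth is to the robot's left. Several reflectors inside a
   single beam resolve into separate objects.
3. **Mapping** — detections land on a 2000×2000 occupancy grid (5×5 cm
   cells), each inflated to a 20×20-cell (1×1 m) square; every 5 steps the
   squares are joined by three iterations of morphological closing. Cells
   on the robot's own trajectory are always free.
4. **Navigation** — a bug-style controller: obstacle detected within 1.2 m
   inside a ±30° frontal sector → turn 90° right, sidestep 1 m, turn back
   left and re-check, resuming the original heading once clear.
5. **Classification** — each echo is band-passed (20–40, 40–60,
   60–100 kHz) per ear; 21 short-time features × 23 windows give a
   483-dimensional vector per signal; six small networks
   (483–105–50–6–1, ReLU, dropout 0.5, sigmoid) vote by majority to label
   objects within 3 m as plant (diffuse echo train) or non-plant (specular
   glint). Significance is assessed with a 100-permutation test on
   balanced accuracy.

Each mapped object carries the record **C | T | P**: interaural Pearson
correlation, acoustic type, and classification probability.

## Worked example

Generate a 6 m corridor, run a 12-step autonomous mission, and score the
reconstructed wall contours against ground truth:

```bash
echonav scene make-corridor --length 6 --width 3 --out sc.json
echonav run --scene sc.json --start 0.3,0.3,0 --max-steps 12 --seed 1 --out run2
echonav eval map --run run2 --truth sc.json
```

The run report

```json
{
 "status": "max_steps",
 "steps": 12,
 "n_detections": 44,
 "occupied_cells": 4511,
 "config_hash": "b10e2c9d177afb3e",
 "seed": 1
}
```

says the robot completed 12 half-meter steps (44 wall detections, ~3.7 per
acquisition) without a collision, occupying 4511 grid cells (≈ 11 m²) of
map. The contour evaluation

```json
{
 "left":  {"rms_m": 0.525, "mean_m": 0.525, "std_m": 0.0},
 "right": {"rms_m": 0.425, "mean_m": 0.425, "std_m": 0.0}
}
```

shows the estimated wall faces sit ~0.4–0.5 m inside the true walls: each
point detection is inflated to a 1 m square, so the free-space-facing
contour is offset by about half the inflation width — the inflation
geometry, not the sonar, dominates the mapping error.

Train the echo classifier on a synthetic diffuse-vs-glint population and
report held-out balanced accuracy:

```bash
echonav classify demo --seed 0
# {"balanced_accuracy": 0.8, "n_test": 20}
```

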