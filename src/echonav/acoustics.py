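"""Chirp emission and binaural echo synthesis.

The physics stand-in for the sonar head: a single emitter at the robot
center and two ears on a 7 cm baseline perpendicular to the sensor heading.
Each reflector inside the beam contributes a delayed, attenuated copy of the
emitted linear FM chirp to each ear; delays are evaluated analytically at
fractional-sample precision by sampling the chirp formula at shifted times.
The direct emission appears at time zero in both channels, followed by
additive white Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import SonarConfig
from .scene import Scene

Pose = Tuple[float, float, float]  # x [m], y [m], heading [deg CCW from +x]


@dataclass
class BinauralRecording:
    """A fixed-length two-ear recording with acquisition metadata.

    ``heading_offset_deg`` is the sensor heading relative to the direction of
    movement (-60, 0 or +60), or the string ``"summed"`` after superposition
    of the three headings.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    pose: Pose
    heading_offset_deg: Union[float, str]

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left/right channels must have equal length")
        if not isinstance(self.heading_offset_deg, str):
            if float(self.heading_offset_deg) not in (-60.0, 0.0, 60.0):
                raise ValueError("heading offset must be one of -60, 0, +60 deg")

    @property
    def n_samples(self) -> int:
        return len(self.left)


def generate_chirp(config: SonarConfig) -> np.ndarray:
    """The emitted signal: a linear FM sweep f_start -> f_end, unit peak."""
    n = config.chirp_samples
    t = np.arange(n) / config.sample_rate
    return _chirp_at(t, config)


def _chirp_at(t: np.ndarray, config: SonarConfig) -> np.ndarray:
    """Evaluate the chirp waveform at arbitrary times (zero outside its span).

    Linear sweep: instantaneous frequency f(t) = f0 + (f1-f0) t/T, so the
    phase is 2*pi*(f0 t + (f1-f0) t^2 / (2T)).
    """
    f0, f1, T = config.f_start, config.f_end, config.chirp_duration
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * T))
    out = np.cos(phase)
    out[(t < 0) | (t >= T)] = 0.0
    return out


def instantaneous_frequency(t: float, config: SonarConfig) -> float:
    """f(t) of the linear sweep, for t within the chirp."""
    return config.f_start + (config.f_end - config.f_start) * t / config.chirp_duration


def ear_positions(pose: Pose, heading_offset_deg: float,
                  config: SonarConfig) -> Tuple[np.ndarray, np.ndarray]:
    """World positions of (left, right) ears for a sensor heading."""
    x, y, h = pose
    sensor = math.radians(h + heading_offset_deg)
    # left ear is 90 deg CCW of the sensor axis
    lx = x + (config.ear_baseline / 2) * math.cos(sensor + math.pi / 2)
    ly = y + (config.ear_baseline / 2) * math.sin(sensor + math.pi / 2)
    rx = x + (config.ear_baseline / 2) * math.cos(sensor - math.pi / 2)
    ry = y + (config.ear_baseline / 2) * math.sin(sensor - math.pi / 2)
    return np.array([lx, ly]), np.array([rx, ry])


def beam_gain(azimuth_deg: float, config: SonarConfig) -> float:
    """Cosine-shaped one-way beam pattern; zero outside +/- halfwidth."""
    a = abs(azimuth_deg)
    if a >= config.beam_halfwidth_deg:
        return 0.0
    return math.cos(math.pi / 2 * a / config.beam_halfwidth_deg)


def synthesize_echoes(scene: Scene, pose: Pose, heading_offset_deg: float,
                      config: SonarConfig, seed: int) -> BinauralRecording:
    """Simulate one acquisition: emission + per-reflector echoes + noise.

    For each reflector within the beam, the per-ear delay is
    (|mouth->reflector| + |reflector->ear|) / c and the amplitude is
    strength * beam_gain / (r_out * r_back) with ranges clamped below at
    ``spreading_min_range`` (two-way spherical spreading).  Reflectors whose
    echoes fall beyond the recording window contribute nothing.  Noise is
    white Gaussian, scaled to ``noise_snr_db`` below the strongest echo.
    """
    xmin, ymin, xmax, ymax = scene.bounds
    if not (xmin <= pose[0] <= xmax and ymin <= pose[1] <= ymax):
        raise ValueError("pose outside scene bounds")
    n = config.recording_samples
    t = np.arange(n) / config.sample_rate
    mouth = np.array(pose[:2], dtype=float)
    sensor_heading = pose[2] + heading_offset_deg
    ears = ear_positions(pose, heading_offset_deg, config)

    channels = [np.zeros(n), np.zeros(n)]
    # direct emission at time zero in both ears
    emission = config.emission_amplitude * _chirp_at(t, config)
    strongest_echo = 0.0
    for ch in channels:
        ch += emission

    rmin = config.spreading_min_range
    for refl in scene.all_reflectors():
        d = np.asarray(refl.position, dtype=float) - mouth
        r_out = float(np.hypot(*d))
        if r_out < 1e-6:
            continue
        az = math.degrees(math.atan2(d[1], d[0])) - sensor_heading
        az = (az + 180.0) % 360.0 - 180.0
        g = beam_gain(az, config)
        if g <= 0.0:
            continue
        for ch, ear in zip(channels, ears):
            r_back = float(np.hypot(*(np.asarray(refl.position) - ear)))
            delay = (r_out + r_back) / config.speed_of_sound
            if delay >= config.recording_duration:
                continue
            amp = (config.emission_amplitude * refl.strength * g
                   / (max(r_out, rmin) * max(r_back, rmin)))
            ch += amp * _chirp_at(t - delay, config)
            strongest_echo = max(strongest_echo, amp)

    ref = strongest_echo if strongest_echo > 0 else config.empty_scene_noise_ref
    noise_std = ref * 10.0 ** (-config.noise_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    left = channels[0] + rng.normal(0.0, noise_std, n)
    right = channels[1] + rng.normal(0.0, noise_std, n)
    return BinauralRecording(left=left, right=right, sample_rate=config.sample_rate,
                             pose=pose, heading_offset_deg=heading_offset_deg)


def acquire_three_headings(scene: Scene, pose: Pose, config: SonarConfig,
                           seed: int) -> List[BinauralRecording]:
    """The three-heading acquisition protocol (-60, 0, +60 degrees)."""
    return [
        synthesize_echoes(scene, pose, off, config, seed + i)
        for i, off in enumerate((-60.0, 0.0, 60.0))
    ]


def sum_headings(recordings: Sequence[BinauralRecording]) -> BinauralRecording:
    """Superpose the three headings into one wide-beam echo."""
    if len(recordings) != 3:
        raise ValueError("expected exactly three recordings")
    offsets = sorted(float(r.heading_offset_deg) for r in recordings)
    if offsets != [-60.0, 0.0, 60.0]:
        raise ValueError("expected one recording per heading -60/0/+60")
    ref = recordings[0]
    for r in recordings[1:]:
        if r.n_samples != ref.n_samples:
            raise ValueError("recordings have mismatched lengths")
        if r.pose != ref.pose:
            raise ValueError("recordings are not from the same pose")
    left = sum(r.left for r in recordings)
    right = sum(r.right for r in recordings)
    return BinauralRecording(left=left, right=right, sample_rate=ref.sample_rate,
                             pose=ref.pose, heading_offset_deg="summed")
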