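"""Configuration for the whole sonar stack.

Every constant of the sensing/processing chain lives here so that a single
validated :class:`RunConfig` (plus a seed) fully determines a run.  Models
use pydantic with ``extra="forbid"``: unknown keys in a config file are an
error, not a silent no-op.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

ACQUISITION_HEADINGS_DEG: Tuple[float, float, float] = (-60.0, 0.0, 60.0)


class SonarConfig(BaseModel):
    """Emitter, receivers and recording geometry.

    Defaults describe a desk-scale binaural sonar head: a 10 ms linear FM
    chirp sweeping 100 kHz down to 20 kHz, sampled at 250 kS/s per ear, two
    ears 7 cm apart, and a 0.035 s recording window (about 6 m of two-way
    travel at 343 m/s).
    """

    model_config = ConfigDict(extra="forbid")

    chirp_duration: float = Field(0.010, gt=0)
    f_start: float = Field(100_000.0, gt=0)
    f_end: float = Field(20_000.0, gt=0)
    sample_rate: float = Field(250_000.0, gt=0)
    recording_duration: float = Field(0.035, gt=0)
    ear_baseline: float = Field(0.07, gt=0)
    speed_of_sound: float = Field(343.0, gt=0)
    beam_halfwidth_deg: float = Field(60.0, gt=0, le=180)
    noise_snr_db: float = 20.0
    emission_amplitude: float = Field(1.0, gt=0)
    #: spreading-law range clamp [m]; 1/(r_out*r_back) with r < spreading_min_range
    #: would make a close echo arbitrarily louder than the direct emission.
    spreading_min_range: float = Field(0.5, gt=0)
    #: reference echo amplitude used to scale noise when a scene is empty
    empty_scene_noise_ref: float = Field(1e-3, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SonarConfig":
        nyquist = self.sample_rate / 2.0
        if self.f_start > nyquist or self.f_end > nyquist:
            raise ValueError("chirp frequencies must not exceed Nyquist")
        if self.recording_duration < self.chirp_duration:
            raise ValueError("recording must be at least as long as the chirp")
        n = self.sample_rate * self.chirp_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate * chirp_duration must be an integer")
        return self

    @property
    def chirp_samples(self) -> int:
        return int(round(self.sample_rate * self.chirp_duration))

    @property
    def recording_samples(self) -> int:
        return int(round(self.sample_rate * self.recording_duration))

    @property
    def max_range(self) -> float:
        """One-way range [m] equivalent to the recording window."""
        return self.speed_of_sound * self.recording_duration / 2.0


class DetectionConfig(BaseModel):
    """Matched-filter peak detection, interaural matching and localization."""

    model_config = ConfigDict(extra="forbid")

    min_peak_amplitude: float = Field(0.3, gt=0, le=1)
    min_peak_distance_s: float = Field(0.002, gt=0)
    match_window_s: float = Field(0.001, gt=0)
    segment_duration_s: float = Field(0.01, gt=0)
    #: central support of the envelope-domain Pearson comparison [s]; after
    #: pulse compression one echo occupies ~1/bandwidth, so correlating the
    #: full raw-signal segment length would mostly compare unrelated clutter
    match_support_s: float = Field(0.001, gt=0)
    min_pearson_r: float = Field(0.9, gt=-1, lt=1)
    #: post-emission guard blanked on the correlation lag axis [s]
    blank_after_emission_s: float = Field(0.001, ge=0)
    #: peaks must also exceed this multiple of a MAD-based noise sigma
    noise_floor_factor: float = Field(6.0, ge=0)
    max_range_m: float = Field(6.0, gt=0)
    merge_radius_m: float = Field(0.10, ge=0)


class NavigationConfig(BaseModel):
    """Step sizes and the reactive obstacle-avoidance thresholds."""

    model_config = ConfigDict(extra="forbid")

    step_m: float = Field(0.5, gt=0)
    sidestep_m: float = Field(1.0, gt=0)
    trigger_range_m: float = Field(1.2, gt=0)
    frontal_halfwidth_deg: float = Field(30.0, gt=0, le=90)
    map_update_every: int = Field(5, ge=1)


class MappingConfig(BaseModel):
    """Occupancy grid geometry and the object-inflation operator."""

    model_config = ConfigDict(extra="forbid")

    grid_size: int = Field(2000, ge=10)
    resolution_m: float = Field(0.05, gt=0)
    inflate_cells: int = Field(20, ge=1)
    closing_iterations: int = Field(3, ge=0)


class ClassifyConfig(BaseModel):
    """Band filters, short-time features and the network ensemble."""

    model_config = ConfigDict(extra="forbid")

    bands_hz: Tuple[Tuple[float, float], ...] = (
        (20_000.0, 40_000.0),
        (40_000.0, 60_000.0),
        (60_000.0, 100_000.0),
    )
    filter_order: int = Field(4, ge=1)
    n_windows: int = Field(23, ge=1)
    #: window length = signal length // window_divisor, hop = window // 2
    window_divisor: int = Field(12, ge=1)
    chroma_bins: int = Field(12, ge=2)
    chroma_ref_hz: float = Field(20_000.0, gt=0)
    hidden_layers: Tuple[int, int, int] = (105, 50, 6)
    dropout: float = Field(0.5, ge=0, lt=1)
    epochs: int = Field(100, ge=1)
    batch_size: int = Field(32, ge=1)
    learning_rate: float = Field(1e-3, gt=0)
    #: objects farther than this never receive a class label [m]
    max_classify_range_m: float = Field(3.0, gt=0)

    @property
    def n_features(self) -> int:
        # 8 scalar features + chroma (bins + deviation), per window
        return (8 + self.chroma_bins + 1) * self.n_windows


class RunConfig(BaseModel):
    """Everything a mission needs, plus the master seed.

    The single seed fans out to named sub-seeds (scene, noise, training) via
    :meth:`subseed` so each module is independently reproducible.
    """

    model_config = ConfigDict(extra="forbid")

    sonar: SonarConfig = SonarConfig()
    detection: DetectionConfig = DetectionConfig()
    navigation: NavigationConfig = NavigationConfig()
    mapping: MappingConfig = MappingConfig()
    classify: ClassifyConfig = ClassifyConfig()
    seed: int = 0

    def subseed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


Side = Literal["left", "right"]
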