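"""Matched filtering, peak detection, interaural matching and localization.

The processing chain per acquisition:

1. Cross-correlate each ear with the theoretical emitted chirp and take the
   analytic envelope.  The direct emission compresses to a ~1/bandwidth
   pulse at lag zero and serves as the time reference; a short guard after
   it is blanked and the remaining trace is normalized to its own maximum,
   so the 0.3 amplitude threshold applies to echoes rather than to the
   (much louder) emission.
2. Detect envelope peaks >= 0.3 separated by >= 2 ms; peaks must also clear
   an absolute noise floor (a MAD-based sigma estimate times a factor) so a
   reflector-free recording yields no detections.
3. For each left-ear peak, search the right ear within +/- 1 ms, cut 10 ms
   segments around each peak and accept the pair only if their Pearson
   correlation exceeds 0.9 (conservative: unmatched echoes are dropped).
4. Localize: range from the mean two-ear delay, azimuth from the interaural
   time difference via arcsin(c * ITD / baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .acoustics import BinauralRecording
from .config import DetectionConfig, SonarConfig

UNKNOWN = "unknown"


@dataclass
class EchoPeak:
    """One detected correlation peak: lag [s] past the emission, in one ear."""

    lag: float
    amplitude: float
    ear: str  # "left" | "right"


@dataclass
class MatchedPair:
    """Left/right peaks judged to come from the same reflector."""

    left_peak: EchoPeak
    right_peak: EchoPeak
    pearson_r: float


@dataclass
class DetectedObject:
    """A localized reflector with the C | T | P annotation.

    C is the interaural Pearson correlation, T the acoustic class
    (plant / non_plant / unknown) and P the classification probability.
    """

    range_m: float
    azimuth_deg: float
    C: float
    T: str = UNKNOWN
    P: float = 0.0

    def to_xy(self) -> Tuple[float, float]:
        a = math.radians(self.azimuth_deg)
        return self.range_m * math.cos(a), self.range_m * math.sin(a)


@dataclass
class CorrelationTrace:
    """Normalized post-emission correlation envelope for one ear."""

    envelope: np.ndarray          # normalized, emission interval blanked
    emission_index: int           # sample index of the emission reference
    noise_floor: float            # absolute detection floor, normalized units
    sample_rate: float
    ear: str
    raw: np.ndarray = field(repr=False, default=None)  # the ear's recording


def matched_filter(recording: BinauralRecording, chirp: np.ndarray,
                   config: DetectionConfig) -> Tuple[CorrelationTrace, CorrelationTrace]:
    """Cross-correlate both ears with the emitted chirp template."""
    if len(chirp) >= recording.n_samples:
        raise ValueError("chirp must be shorter than the recording")
    traces = []
    acorr = sps.fftconvolve(chirp, chirp[::-1], mode="full")  # peak at len-1
    acorr_peak = float(acorr[len(chirp) - 1])
    for ear, x in (("left", recording.left), ("right", recording.right)):
        if not np.any(x):
            raise ValueError("all-zero recording")
        corr = sps.fftconvolve(x, chirp[::-1], mode="full")[len(chirp) - 1:]
        env = np.abs(sps.hilbert(corr))
        fs = recording.sample_rate
        # emission reference: the loudest peak within the first millisecond
        head = max(1, int(round(1e-3 * fs)))
        em_idx = int(np.argmax(env[:head]))
        # cancel the direct emission's own correlation (sidelobes included):
        # without a dominant echo its sidelobes would otherwise normalize
        # into spurious zero-azimuth "objects" near the blanking edge
        scale = corr[em_idx] / acorr_peak
        span = min(len(corr) - em_idx, len(chirp))
        corr = corr.copy()
        corr[em_idx:em_idx + span] -= scale * acorr[len(chirp) - 1:len(chirp) - 1 + span]
        lead = min(em_idx, len(chirp) - 1)
        if lead:
            corr[em_idx - lead:em_idx] -= scale * acorr[len(chirp) - 1 - lead:len(chirp) - 1]
        env = np.abs(sps.hilbert(corr))
        blank_end = em_idx + len(chirp) // 100 + int(round(config.blank_after_emission_s * fs))
        env = env.copy()
        env[:blank_end] = 0.0
        # the last millisecond of lags carries Hilbert edge artifacts that
        # can form a spurious global maximum; ranges there exceed max range
        env[-int(round(1e-3 * fs)):] = 0.0
        post = env[blank_end:]
        peak = float(post.max()) if post.size else 0.0
        if peak <= 0:
            raise ValueError("recording carries no post-emission energy")
        med = float(np.median(post))
        mad = float(np.median(np.abs(post - med)))
        sigma = 1.4826 * mad
        floor = config.noise_floor_factor * (med + sigma) / peak
        traces.append(CorrelationTrace(envelope=env / peak, emission_index=em_idx,
                                       noise_floor=floor, sample_rate=fs,
                                       ear=ear, raw=x))
    return traces[0], traces[1]


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak position by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def detect_peaks(trace: CorrelationTrace, config: DetectionConfig) -> List[EchoPeak]:
    """Local maxima >= the amplitude threshold, >= 2 ms apart, sorted by lag."""
    fs = trace.sample_rate
    height = max(config.min_peak_amplitude, trace.noise_floor)
    distance = max(1, int(round(config.min_peak_distance_s * fs)))
    idx, _ = sps.find_peaks(trace.envelope, height=height, distance=distance)
    peaks = []
    for i in idx:
        pos = _parabolic_refine(trace.envelope, int(i))
        lag = (pos - trace.emission_index) / fs
        if lag < 0:
            continue
        peaks.append(EchoPeak(lag=float(lag), amplitude=float(trace.envelope[i]),
                              ear=trace.ear))
    peaks.sort(key=lambda p: p.lag)
    return peaks


def _segment(trace: CorrelationTrace, peak: EchoPeak, config: DetectionConfig,
             chirp_len: int) -> np.ndarray:
    """Cut a window of the correlation envelope centered on the peak.

    The envelope (not the raw waveform) is compared across ears: the raw
    ultrasonic carrier decorrelates under the sub-sample interaural shift
    left after cutting at integer samples, while the envelope of the
    compressed pulse is smooth at the sample scale.  The window is the
    matching support (~the compressed pulse scale), the envelope-domain
    counterpart of cutting one full chirp echo from the raw signal.
    """
    fs = trace.sample_rate
    half = int(round(min(config.segment_duration_s, config.match_support_s) * fs / 2))
    center = int(round(trace.emission_index + peak.lag * fs))
    # zero-pad at the edges so the peak stays at the window center in both
    # ears; otherwise edge clamping breaks the interaural alignment
    seg = np.zeros(2 * half)
    lo = max(0, center - half)
    hi = min(len(trace.envelope), center + half)
    seg[lo - (center - half): hi - (center - half)] = trace.envelope[lo:hi]
    # the compressed pulse is only ~1/bandwidth (3 samples) wide; a light
    # smoothing makes the comparison insensitive to sub-sample phase
    return gaussian_filter1d(seg, sigma=2.0)


def match_interaural(left_peaks: Sequence[EchoPeak], right_peaks: Sequence[EchoPeak],
                     left_trace: CorrelationTrace, right_trace: CorrelationTrace,
                     config: DetectionConfig, chirp_len: int = 2500) -> List[MatchedPair]:
    """Pair left/right peaks from the same reflector.

    For each left peak the nearest-lag right peak within the +/- 1 ms window
    is tried; the pair is accepted iff the Pearson correlation of the two
    10 ms segments exceeds the 0.9 threshold.  Each peak is used at most
    once; ambiguity is resolved by nearest lag (left ear is the reference).
    """
    pairs: List[MatchedPair] = []
    used = [False] * len(right_peaks)
    fs = left_trace.sample_rate
    half = int(round(min(config.segment_duration_s, config.match_support_s) * fs / 2))
    guard = int(round(0.25e-3 * fs))
    for lp in left_peaks:
        candidates = [
            (abs(rp.lag - lp.lag), j, rp)
            for j, rp in enumerate(right_peaks)
            if not used[j] and abs(rp.lag - lp.lag) <= config.match_window_s
        ]
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[0])
        _, j, rp = candidates[0]
        a = _segment(left_trace, lp, config, chirp_len)
        b = _segment(right_trace, rp, config, chirp_len)
        # other echoes inside the window carry their own interaural shifts
        # and would decorrelate the pair; blank them identically in both ears
        mask = np.ones(2 * half, dtype=bool)
        for peaks, ref in ((left_peaks, lp), (right_peaks, rp)):
            for q in peaks:
                if q is ref:
                    continue
                rel = int(round((q.lag - ref.lag) * fs)) + half
                if -guard < rel < 2 * half + guard:
                    mask[max(0, rel - guard): rel + guard] = False
        m = min(len(a), len(b))
        sel = mask[:m]
        if sel.sum() < 8:
            continue
        r = float(pearsonr(a[:m][sel], b[:m][sel]).statistic)
        if r > config.min_pearson_r:
            used[j] = True
            pairs.append(MatchedPair(left_peak=lp, right_peak=rp, pearson_r=r))
    return pairs


def localize(pair: MatchedPair, sonar: SonarConfig,
             detection: Optional[DetectionConfig] = None) -> Optional[DetectedObject]:
    """Range from mean delay, azimuth from the ITD; None beyond max range.

    Positive azimuth means the object is to the robot's left: the echo then
    reaches the left ear first, so (right lag - left lag) > 0.
    """
    detection = detection or DetectionConfig()
    c = sonar.speed_of_sound
    mean_lag = 0.5 * (pair.left_peak.lag + pair.right_peak.lag)
    rng_m = c * mean_lag / 2.0
    if rng_m <= 0 or rng_m > detection.max_range_m:
        return None
    itd = pair.right_peak.lag - pair.left_peak.lag
    s_raw = c * itd / sonar.ear_baseline
    if abs(s_raw) > 1.1:
        # an ITD well beyond the baseline/c geometric maximum cannot come
        # from any real direction: a mismatched pair, not a noisy one
        return None
    s = np.clip(s_raw, -1.0, 1.0)
    az = math.degrees(math.asin(s))
    return DetectedObject(range_m=rng_m, azimuth_deg=az, C=pair.pearson_r)


def _merge_duplicates(objects: List[DetectedObject], radius: float) -> List[DetectedObject]:
    """Greedy merge of detections within `radius` meters; keep the highest C."""
    kept: List[DetectedObject] = []
    for obj in sorted(objects, key=lambda o: -o.C):
        x, y = obj.to_xy()
        if all(math.hypot(x - k.to_xy()[0], y - k.to_xy()[1]) > radius for k in kept):
            kept.append(obj)
    return kept


def process_acquisition(recordings: Sequence[BinauralRecording], chirp: np.ndarray,
                        sonar: SonarConfig,
                        detection: Optional[DetectionConfig] = None) -> List[DetectedObject]:
    """Full chain over one or three recordings -> detections in the robot frame.

    Each recording's detections are rotated by its acquisition heading
    offset (a summed recording counts as heading 0); duplicates across
    headings within the merge radius collapse to the strongest detection.
    """
    detection = detection or DetectionConfig()
    out: List[DetectedObject] = []
    for rec in recordings:
        lt, rt = matched_filter(rec, chirp, detection)
        lp = detect_peaks(lt, detection)
        rp = detect_peaks(rt, detection)
        pairs = match_interaural(lp, rp, lt, rt, detection, chirp_len=len(chirp))
        offset = 0.0 if isinstance(rec.heading_offset_deg, str) else float(rec.heading_offset_deg)
        for pair in pairs:
            obj = localize(pair, sonar, detection)
            if obj is not None:
                obj.azimuth_deg += offset
                out.append(obj)
    return _merge_duplicates(out, detection.merge_radius_m)
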