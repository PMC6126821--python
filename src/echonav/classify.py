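"""Acoustic plant / non-plant classification.

Each 35 ms binaural echo is band-passed into three ultrasonic bands
(20-40, 40-60, 60-100 kHz) per ear — six signals.  Each signal is divided
into 23 half-overlapping windows and 21 short-time acoustic features are
computed per window (zero-crossing rate, short-time energy, energy entropy,
spectral entropy, centroid, spread, flux, rolloff, and a 12-bin chroma
vector plus its deviation), giving a 483-dimensional vector per signal.
Six small feed-forward networks (483-105-50-6-1, ReLU with 0.5 dropout
after the first layer, sigmoid output), one per signal, vote by majority.
Only objects closer than 3 m are ever classified.  Significance is assessed
with a label-permutation test on balanced accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from sklearn.metrics import balanced_accuracy_score

from .acoustics import BinauralRecording
from .config import ClassifyConfig, SonarConfig
from .perception import DetectedObject
from .scene import PLANT, NON_PLANT

#: fixed feature-block layout of one 483-element vector (block -> length)
FEATURE_LAYOUT: Dict[str, int] = {
    "zcr": 23,
    "energy": 46,          # short-time energy (23) + energy entropy (23)
    "entropy": 23,         # spectral entropy
    "spectral_centroid": 23,
    "spectral_spread": 23,
    "spectral_flux": 23,
    "spectral_rolloff": 23,
    "chroma_vector": 299,  # (12 bins + deviation) x 23 windows
}

SIGNAL_KEYS: Tuple[Tuple[int, str], ...] = tuple(
    (band, ear) for band in range(3) for ear in ("left", "right")
)


# ---------------------------------------------------------------------------
# Band splitting
# ---------------------------------------------------------------------------

def band_split(recording: BinauralRecording,
               sonar: SonarConfig,
               config: Optional[ClassifyConfig] = None) -> List[np.ndarray]:
    """Six band-limited signals (3 bands x 2 ears), emission interval blanked.

    The transmitted pulse (the first ``chirp_duration`` of the recording) is
    zeroed before filtering so features describe echoes only.  Each output
    keeps the full recording length.
    """
    config = config or ClassifyConfig()
    blank = int(round(sonar.chirp_duration * recording.sample_rate))
    out: List[np.ndarray] = []
    for lo, hi in config.bands_hz:
        sos = sps.butter(config.filter_order, [lo, hi], btype="bandpass",
                         fs=recording.sample_rate, output="sos")
        for x in (recording.left, recording.right):
            y = np.array(x, dtype=float)
            y[:blank] = 0.0
            if np.any(y):
                y = sps.sosfiltfilt(sos, y)
            out.append(y)
    # reorder to (band0 L, band0 R, band1 L, ...) == SIGNAL_KEYS order
    return out


# ---------------------------------------------------------------------------
# Short-time features
# ---------------------------------------------------------------------------

def _frame_signal(x: np.ndarray, config: ClassifyConfig) -> np.ndarray:
    win = max(2, len(x) // config.window_divisor)
    hop = max(1, win // 2)
    n_frames = 1 + (len(x) - win) // hop
    if n_frames < config.n_windows:
        raise ValueError(
            f"signal too short: {n_frames} windows available, "
            f"{config.n_windows} required")
    idx = hop * np.arange(config.n_windows)[:, None] + np.arange(win)[None, :]
    return x[idx]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum())


def _block_entropy(x: np.ndarray, n_blocks: int = 10) -> float:
    """Entropy of the energy distribution over sub-blocks of a window."""
    total = float((x**2).sum())
    if total <= 0:
        return 0.0
    m = len(x) // n_blocks
    sub = x[: m * n_blocks].reshape(n_blocks, m)
    e = (sub**2).sum(axis=1) / total
    return _entropy(e)


def extract_features(signal_: np.ndarray, sample_rate: float,
                     config: Optional[ClassifyConfig] = None) -> np.ndarray:
    """One band-limited signal -> the 483-element feature vector.

    Values are laid out feature-major (all 23 ZCR values, then all 23
    short-time energies, ...), matching :data:`FEATURE_LAYOUT`.  All-zero
    windows yield zeros by convention.
    """
    config = config or ClassifyConfig()
    frames = _frame_signal(np.asarray(signal_, dtype=float), config)
    nw, win = frames.shape
    freqs = np.fft.rfftfreq(win, d=1.0 / sample_rate)
    nyq = sample_rate / 2.0

    zcr = np.zeros(nw)
    st_energy = np.zeros(nw)
    energy_entropy = np.zeros(nw)
    spec_entropy = np.zeros(nw)
    centroid = np.zeros(nw)
    spread = np.zeros(nw)
    flux = np.zeros(nw)
    rolloff = np.zeros(nw)
    chroma = np.zeros((nw, config.chroma_bins + 1))

    # chroma bin of each (positive) frequency: fold log2(f/fref) into 12 classes
    pos = freqs > 0
    chroma_class = np.zeros(len(freqs), dtype=int)
    chroma_class[pos] = np.round(
        config.chroma_bins * np.log2(freqs[pos] / config.chroma_ref_hz)
    ).astype(int) % config.chroma_bins

    prev_spec_norm: Optional[np.ndarray] = None
    for k in range(nw):
        x = frames[k]
        if np.any(x):
            zcr[k] = float(np.mean(np.abs(np.diff(np.sign(x))) > 0))
            st_energy[k] = float(np.mean(x**2))
            energy_entropy[k] = _block_entropy(x)
            spec = np.abs(np.fft.rfft(x))
            total = spec.sum()
            if total > 0:
                p = spec / total
                spec_entropy[k] = _entropy_binned(p)
                fn = freqs / nyq
                centroid[k] = float((fn * p).sum())
                spread[k] = float(math.sqrt(((fn - centroid[k]) ** 2 * p).sum()))
                cume = np.cumsum(spec**2)
                thresh = 0.90 * cume[-1]
                rolloff[k] = float(freqs[int(np.searchsorted(cume, thresh))] / nyq)
                if prev_spec_norm is not None:
                    flux[k] = float(((p - prev_spec_norm) ** 2).sum())
                prev_spec_norm = p
                cv = np.bincount(chroma_class[pos],
                                 weights=(spec[pos] ** 2),
                                 minlength=config.chroma_bins)
                s = cv.sum()
                if s > 0:
                    cv = cv / s
                chroma[k, : config.chroma_bins] = cv
                chroma[k, -1] = float(cv.std())
        else:
            prev_spec_norm = None
    parts = [zcr, st_energy, energy_entropy, spec_entropy, centroid, spread,
             flux, rolloff, chroma.T.reshape(-1)]
    # chroma stored bin-major ((12+1) blocks of 23) to keep the layout
    # feature-major throughout
    vec = np.concatenate(parts)
    assert len(vec) == config.n_features
    return vec


def _entropy_binned(p: np.ndarray, n_blocks: int = 10) -> float:
    m = len(p) // n_blocks
    if m == 0:
        return _entropy(p)
    blocks = p[: m * n_blocks].reshape(n_blocks, m).sum(axis=1)
    return _entropy(blocks)


def features_for_recording(recording: BinauralRecording, sonar: SonarConfig,
                           config: Optional[ClassifyConfig] = None) -> np.ndarray:
    """All six signals of one echo -> array of shape (6, 483)."""
    config = config or ClassifyConfig()
    signals = band_split(recording, sonar, config)
    return np.stack([
        extract_features(s, recording.sample_rate, config) for s in signals
    ])


# ---------------------------------------------------------------------------
# The network ensemble
# ---------------------------------------------------------------------------

class _MLP:
    """Minimal dense network 483-105-50-6-1 (ReLU, dropout, sigmoid), Adam/BCE."""

    def __init__(self, n_in: int, hidden: Tuple[int, int, int], dropout: float,
                 seed: int):
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, 1]
        self.W = [
            rng.normal(0.0, math.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.dropout = dropout
        self._rng = rng
        self._adam = None

    def _forward(self, X: np.ndarray, train: bool):
        acts = [X]
        h = X
        masks = []
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if li < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if train and li == 0 and self.dropout > 0:
                    mask = (self._rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = 1.0 / (1.0 + np.exp(-z))
            acts.append(h)
        return acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        acts, _ = self._forward(np.atleast_2d(X), train=False)
        return acts[-1].ravel()

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            lr: float) -> None:
        n = len(X)
        m_t = [np.zeros_like(W) for W in self.W] + [np.zeros_like(b) for b in self.b]
        v_t = [np.zeros_like(p) for p in m_t]
        t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for _ in range(epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                Xb, yb = X[idx], y[idx]
                acts, masks = self._forward(Xb, train=True)
                out = acts[-1].ravel()
                # dL/dz for sigmoid + BCE
                delta = (out - yb)[:, None] / len(idx)
                grads_W, grads_b = [], []
                for li in range(len(self.W) - 1, -1, -1):
                    grads_W.insert(0, acts[li].T @ delta)
                    grads_b.insert(0, delta.sum(axis=0))
                    if li > 0:
                        delta = delta @ self.W[li].T
                        if masks[li - 1] is not None:
                            delta = delta * masks[li - 1]
                        delta = delta * (acts[li] > 0)
                t += 1
                params = self.W + self.b
                grads = grads_W + grads_b
                for i, (p, g) in enumerate(zip(params, grads)):
                    m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
                    v_t[i] = beta2 * v_t[i] + (1 - beta2) * g * g
                    mhat = m_t[i] / (1 - beta1**t)
                    vhat = v_t[i] / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class EnsembleModel:
    """Six networks, one per band x ear signal, plus per-signal scalers."""

    nets: List[_MLP]
    means: List[np.ndarray]
    stds: List[np.ndarray]
    config: ClassifyConfig
    seed: int

    def signal_probs(self, x6: np.ndarray) -> np.ndarray:
        """Per-signal plant probabilities for one echo's (6, 483) features."""
        probs = []
        for net, mu, sd, x in zip(self.nets, self.means, self.stds, x6):
            probs.append(float(net.predict_proba((x - mu) / sd)[0]))
        return np.array(probs)


def train_ensemble(X: np.ndarray, y: np.ndarray,
                   config: Optional[ClassifyConfig] = None,
                   seed: int = 0) -> EnsembleModel:
    """Train the six per-signal networks independently.

    X has shape (n, 6, 483); y is 1 for plant, 0 for non-plant.  Both
    classes must be present.  Deterministic given the seed.
    """
    config = config or ClassifyConfig()
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    nets, means, stds = [], [], []
    for s in range(X.shape[1]):
        Xs = X[:, s, :]
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        sd[sd == 0] = 1.0
        net = _MLP(Xs.shape[1], config.hidden_layers, config.dropout,
                   seed=seed + 1000 * s)
        net.fit((Xs - mu) / sd, y, config.epochs, config.batch_size,
                config.learning_rate)
        nets.append(net)
        means.append(mu)
        stds.append(sd)
    return EnsembleModel(nets=nets, means=means, stds=stds, config=config, seed=seed)


def predict(model: EnsembleModel, x6: np.ndarray) -> Tuple[str, float]:
    """Majority vote of the six networks -> (class, probability).

    A 3-3 tie is broken by the mean sigmoid over all six networks.  P is
    the mean sigmoid of the networks voting for the winning class (for
    non-plant, the mean of 1 - sigmoid).
    """
    probs = model.signal_probs(x6)
    votes_plant = probs >= 0.5
    n_plant = int(votes_plant.sum())
    if n_plant > len(probs) - n_plant:
        label = PLANT
    elif n_plant < len(probs) - n_plant:
        label = NON_PLANT
    else:
        label = PLANT if probs.mean() >= 0.5 else NON_PLANT
    if label == PLANT:
        voters = probs[votes_plant] if votes_plant.any() else probs
        p = float(voters.mean())
    else:
        voters = probs[~votes_plant] if (~votes_plant).any() else probs
        p = float((1.0 - voters).mean())
    return label, p


def classify_detection(model: EnsembleModel, obj: DetectedObject,
                       x6: np.ndarray,
                       config: Optional[ClassifyConfig] = None) -> DetectedObject:
    """Fill T and P on a detection; objects at >= 3 m stay unknown."""
    config = config or ClassifyConfig()
    if obj.range_m >= config.max_classify_range_m:
        return obj
    label, p = predict(model, x6)
    obj.T = label
    obj.P = p
    return obj


def balanced_accuracy(predictions: Sequence[str], labels: Sequence[str]) -> float:
    """Mean of per-class recalls (robust to class imbalance)."""
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present in labels")
    return float(balanced_accuracy_score(labels, list(predictions)))


def evaluate(model: EnsembleModel, X: np.ndarray, y: Sequence[str]) -> float:
    preds = [predict(model, x6)[0] for x6 in X]
    return balanced_accuracy(preds, y)


def permutation_test(X_train: np.ndarray, y_train: np.ndarray,
                     X_test: np.ndarray, y_test: Sequence[str],
                     observed_ba: float, n_perm: int = 100,
                     config: Optional[ClassifyConfig] = None,
                     seed: int = 0) -> Tuple[float, np.ndarray]:
    """Label-permutation significance of the observed balanced accuracy.

    Training labels are shuffled, a fresh ensemble is trained per
    permutation and scored on the untouched test set; the p-value is
    (k + 1) / (n_perm + 1) where k counts permuted scores >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or ClassifyConfig()
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train, dtype=float)
    scores = np.zeros(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y_train)
        while len(np.unique(y_perm)) < 2:  # cannot happen for balanced data
            y_perm = rng.permutation(y_train)
        m = train_ensemble(X_train, y_perm, config, seed=seed + 7919 * (i + 1))
        preds = [predict(m, x6)[0] for x6 in X_test]
        scores[i] = balanced_accuracy(preds, y_test)
    k = int((scores >= observed_ba).sum())
    return (k + 1) / (n_perm + 1), scores


def dead_end_decision(candidates: Sequence[Tuple[str, DetectedObject, np.ndarray]],
                      model: EnsembleModel,
                      config: Optional[ClassifyConfig] = None) -> str:
    """Choose the drivable direction at a dead end.

    ``candidates`` are (direction, detection, features) triples for the
    obstacles right, ahead and left.  Exactly one plant -> drive through it;
    several -> the highest-probability plant; none -> "boxed_in".
    """
    config = config or ClassifyConfig()
    plants: List[Tuple[float, str]] = []
    for direction, obj, x6 in candidates:
        obj = classify_detection(model, obj, x6, config)
        if obj.T == PLANT:
            plants.append((obj.P, direction))
    if not plants:
        return "boxed_in"
    return max(plants)[1]
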