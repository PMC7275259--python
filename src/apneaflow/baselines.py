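"""The three comparison classifiers.

* **Autocorrelation** — the capped movement-magnitude image is averaged per
  frame into a 1-D signal m(t), band-passed to the breathing band
  (0.05-0.5 Hz Butterworth), autocorrelated up to a lag equal to the event
  duration, and the heights of the first 10 autocorrelation peaks feed a
  classical classifier (linear SVM / logistic regression / random forest)
  tuned by 3-fold cross-validation.  Obstructive apneas remain periodic
  (breathing effort) and show strong peaks; central apneas do not.
* **Movement histograms** — 1000-bin histograms of the capped magnitudes
  over [0, 0.5] px/s, averaged across the event, reduced to 100 principal
  components, classified with a random forest.  The classes differ in
  their range of motion.
* **2DFFT-CNN** — the per-frame histograms are concatenated over time into
  an image, resized to 128×128, transformed with a 2-D FFT (log-magnitude,
  zero-frequency centered), and classified by a compact DarkNet19-style
  CNN trained with the shared loop (RMSProp, class-weighted BCE, MCC early
  stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from skimage.transform import resize
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .flowproc import MagnitudeSequence
from .nn import (
    BatchNorm,
    Conv3D,
    Dense,
    GlobalAvgPool,
    LeakyReLU,
    MaxPool3D,
    Sequential,
    Sigmoid,
    TrainConfig,
    TrainedModel,
    train_model,
)
from .windowing import ApneaEvent

__all__ = [
    "MovementSignal",
    "AutocorrSeries",
    "HistogramSequence",
    "mean_movement_signal",
    "bandpass",
    "autocorrelation",
    "peak_features",
    "fit_baseline1",
    "movement_histograms",
    "pca_reduce",
    "build_spectral_image",
    "build_darknet",
    "fit_baseline3_cnn",
    "predict_baseline3",
    "Baseline3Config",
    "N_BINS",
    "HIST_RANGE",
    "SPECTRAL_SIZE",
]

N_BINS = 1000
HIST_RANGE = (0.0, 0.5)  # px/s
SPECTRAL_SIZE = 128
N_PEAKS = 10
BUTTER_ORDER = 4
PEAK_PROMINENCE = 0.01


@dataclass
class MovementSignal:
    """Frame-mean capped movement magnitude m(t), px/s."""

    values: np.ndarray
    fps: float
    event: ApneaEvent | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("movement signal must be a non-empty 1-D array")


@dataclass
class AutocorrSeries:
    """Normalized autocorrelation r(l), l = 0..L."""

    r: np.ndarray
    fps: float

    @property
    def max_lag(self) -> int:
        return len(self.r) - 1


@dataclass
class HistogramSequence:
    """Per-frame 1000-bin magnitude histograms plus the event-mean feature."""

    counts: np.ndarray  # (T, N_BINS)
    feature: np.ndarray  # (N_BINS,) per-bin mean over frames
    fps: float


def _event_slice(mags: MagnitudeSequence, event: ApneaEvent | None) -> np.ndarray:
    if event is None:
        return mags.mags
    i0 = int(np.floor(event.start * mags.fps + 1e-9))
    i1 = int(np.floor(event.end * mags.fps + 1e-9))
    sliced = mags.mags[max(i0, 0) : i1]
    if sliced.shape[0] == 0:
        raise ValueError(f"magnitudes do not cover event [{event.start}, {event.end}]")
    return sliced


def mean_movement_signal(mags: MagnitudeSequence, event: ApneaEvent | None = None) -> MovementSignal:
    """Spatial mean of the capped magnitude image at each frame of the event."""
    frames = _event_slice(mags, event)
    return MovementSignal(values=frames.mean(axis=(1, 2)), fps=mags.fps, event=event)


def bandpass(signal: MovementSignal, low: float = 0.05, high: float = 0.5) -> MovementSignal:
    """Zero-phase Butterworth band-pass to the breathing band.

    Order 4, applied forward-backward (``filtfilt``).  If the upper cutoff
    would meet or exceed the Nyquist frequency it is clamped to 0.999x
    Nyquist (inactive at 2 Hz sampling, where Nyquist is 1 Hz).
    """
    n = len(signal.values)
    if n <= 3 * BUTTER_ORDER:
        raise ValueError(f"signal of length {n} is too short to band-pass filter")
    nyq = signal.fps / 2.0
    high_c = min(high, 0.999 * nyq)
    sos = sp_signal.butter(BUTTER_ORDER, [low / nyq, high_c / nyq], btype="bandpass", output="sos")
    padlen = min(3 * (2 * BUTTER_ORDER + 1), n - 1)
    filtered = sp_signal.sosfiltfilt(sos, signal.values, padlen=padlen)
    return MovementSignal(values=filtered, fps=signal.fps, event=signal.event)


def autocorrelation(signal: MovementSignal) -> AutocorrSeries:
    """Biased, mean-centered, variance-normalized autocorrelation.

    Lags run from 0 to the event duration (the full signal length).  A
    constant signal has no variance; its series is defined as all zeros.
    """
    m = signal.values
    n = len(m)
    centered = m - m.mean()
    denom = float(np.dot(centered, centered))
    if denom <= 1e-30:
        return AutocorrSeries(r=np.zeros(n), fps=signal.fps)
    r = np.array([np.dot(centered[: n - l], centered[l:]) / denom for l in range(n)])
    return AutocorrSeries(r=r, fps=signal.fps)


def peak_features(series: AutocorrSeries) -> np.ndarray:
    """Heights of the first 10 autocorrelation peaks, zero-padded.

    Peaks are strict local maxima at lags >= 1 with prominence >= 0.01,
    scanned in increasing lag; absent peaks contribute 0.
    """
    peaks, _ = sp_signal.find_peaks(series.r, prominence=PEAK_PROMINENCE)
    heights = series.r[peaks[:N_PEAKS]]
    out = np.zeros(N_PEAKS)
    out[: len(heights)] = heights
    return out


_BASELINE1_GRIDS = {
    "linear-svm": (
        lambda seed: SVC(kernel="linear", random_state=seed),
        {"C": [0.1, 1.0, 10.0]},
    ),
    "logistic": (
        lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
        {"C": [0.1, 1.0, 10.0]},
    ),
    "random-forest": (
        lambda seed: RandomForestClassifier(random_state=seed),
        {"n_estimators": [100], "max_depth": [None, 5, 10]},
    ),
}


def fit_baseline1(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "random-forest",
    cv_folds: int = 3,
    seed: int = 0,
) -> GridSearchCV:
    """Fit one of the three classical classifiers with CV-tuned hyperparameters.

    ``labels`` are {0, 1} with CA = 1.  Hyperparameters are selected by
    ``cv_folds``-fold stratified cross-validation on the training data
    only (deterministic, independent of row order up to class layout); the
    returned object is refit on the full training set and exposes
    ``predict`` / ``best_params_``.
    """
    try:
        make, grid = _BASELINE1_GRIDS[classifier]
    except KeyError:
        raise ValueError(
            f"unknown classifier {classifier!r}; choose from {sorted(_BASELINE1_GRIDS)}"
        ) from None
    labels = np.asarray(labels).astype(int).ravel()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 examples per class")
    search = GridSearchCV(make(seed), grid, cv=cv_folds, scoring="accuracy")
    search.fit(np.asarray(features), labels)
    return search


def movement_histograms(mags: MagnitudeSequence, event: ApneaEvent | None = None) -> HistogramSequence:
    """Per-frame 1000-bin histograms over [0, 0.5] px/s + their event mean."""
    frames = _event_slice(mags, event)
    edges = np.linspace(*HIST_RANGE, N_BINS + 1)
    counts = np.stack([np.histogram(f, bins=edges)[0] for f in frames]).astype(np.float64)
    return HistogramSequence(counts=counts, feature=counts.mean(axis=0), fps=mags.fps)


def pca_reduce(train_features: np.ndarray, k: int = 100) -> tuple[PCA, np.ndarray]:
    """Fit a k-component PCA on training rows; returns (projector, projections)."""
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(train_features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 training rows")
    k = min(k, min(x.shape))
    pca = PCA(n_components=k, random_state=0)
    return pca, pca.fit_transform(x)


def build_spectral_image(hists: HistogramSequence) -> np.ndarray:
    """128×128 log-magnitude, center-shifted 2DFFT of the time×bin image.

    The per-frame histograms are stacked over time (rows = frames), the
    image is resized to 128×128, Fourier-transformed, and ``log1p`` of the
    centered magnitude is returned.
    """
    if hists.counts.shape[0] < 2:
        raise ValueError("need >= 2 frames of histograms")
    # anti-aliasing matters: the 1000 narrow bins are decimated ~8x along
    # the bin axis and alias badly without pre-smoothing
    img = resize(
        hists.counts, (SPECTRAL_SIZE, SPECTRAL_SIZE), order=1, anti_aliasing=True,
        preserve_range=True,
    )
    spectrum = np.fft.fftshift(np.fft.fft2(img))
    return np.log1p(np.abs(spectrum)).astype(np.float32)


# ---------------------------------------------------------------------------
# Baseline 3 CNN

#: DarkNet19 convolutional plan: ints are 3×3 convs, (c, 1) are 1×1
#: bottlenecks, "M" is a 2×2/2 max pool.
_DARKNET_PLAN = [
    32, "M", 64, "M", 128, (64, 1), 128, "M", 256, (128, 1), 256, "M",
    512, (256, 1), 512, (256, 1), 512, "M", 1024, (512, 1), 1024, (512, 1), 1024,
]


@dataclass
class Baseline3Config:
    width: float = 0.25  # channel multiplier on the DarkNet19 plan
    train: TrainConfig = field(default_factory=lambda: TrainConfig(batch_size=16, patience=10))
    val_fraction: float = 0.2


def build_darknet(width: float = 0.25) -> Sequential:
    """Compact DarkNet19-style classifier for 1-channel 128×128 spectra.

    Images are treated as (H, W, 1, C) volumes.  Each conv is followed by
    batch norm and leaky ReLU; the head is a global average pool, a dense
    unit, and a sigmoid emitting P(CA).
    """
    layers: list = []
    c_in = 1
    for item in _DARKNET_PLAN:
        if item == "M":
            layers.append(MaxPool3D((2, 2, 1), (2, 2, 1)))
            continue
        if isinstance(item, tuple):
            c_out, k = item
        else:
            c_out, k = item, 3
        c_out = max(4, int(round(c_out * width)))
        layers.append(Conv3D(c_in, c_out, (k, k, 1), padding="same"))
        layers.append(BatchNorm(c_out))
        layers.append(LeakyReLU(0.01))
        c_in = c_out
    layers += [GlobalAvgPool(), Dense(c_in, 1), Sigmoid()]
    return Sequential(layers)


def _as_volumes(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3 or images.shape[1:] != (SPECTRAL_SIZE, SPECTRAL_SIZE):
        raise ValueError(
            f"expected (N, {SPECTRAL_SIZE}, {SPECTRAL_SIZE}) spectral images, got {images.shape}"
        )
    # standardize per batch statistic-free: fixed affine keeps determinism
    return images[..., None, None]


def fit_baseline3_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    config: Baseline3Config | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the spectral-image CNN with the shared training loop.

    A seeded stratified tail of the training events (``val_fraction``) is
    held out for MCC early stopping.
    """
    config = config or Baseline3Config()
    x = _as_volumes(images)
    y = np.asarray(labels).astype(int).ravel()
    rng = np.random.default_rng(seed)
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError("need >= 2 examples per class")
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_idx.extend(rng.permutation(idx)[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True

    model = build_darknet(config.width)
    train_cfg = TrainConfig(
        learning_rate=config.train.learning_rate,
        max_epochs=config.train.max_epochs,
        batch_size=config.train.batch_size,
        patience=config.train.patience,
        seed=seed,
    )
    return train_model(model, x[~val_mask], y[~val_mask], x[val_mask], y[val_mask], train_cfg)


def predict_baseline3(trained: TrainedModel, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """P(CA) for a batch of 128×128 spectral images."""
    return trained.model.predict_proba(_as_volumes(images), batch_size=batch_size)
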