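"""Metrics, confusion-matrix utilities, grouped splits, and the benchmark.

The positive class is CA throughout.  ``run_benchmark`` exercises the full
pipeline on seeded synthetic data: flow generation → per-method features →
fitting → event-level prediction (window voting for the CNNs) → metrics,
one row per method.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import baselines, cnn3d, flowproc, synthdata, windowing
from .nn import TrainConfig
from .windowing import ApneaEvent

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "classification_metrics",
    "reconstruct_confusion",
    "ReconstructionError",
    "grouped_split",
    "BenchmarkConfig",
    "run_benchmark",
    "BENCHMARK_METHODS",
]

log = logging.getLogger(__name__)

BENCHMARK_METHODS = (
    "autocorrelation",
    "histogram",
    "2dfft-cnn",
    "3d-cnn",
    "3d-cnn-two-branch",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with CA as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def from_labels(y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int).ravel()
        y_pred = np.asarray(y_pred).astype(int).ravel()
        return ConfusionMatrix(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 (harmonic mean), and MCC.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=float(mcc),
        undefined=tuple(undefined),
    )


class ReconstructionError(ValueError):
    pass


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    targets: dict[str, float],
    tolerance: float = 0.06,
) -> ConfusionMatrix:
    """Exhaustively recover the integer confusion matrix behind printed metrics.

    ``targets`` maps metric names (accuracy/precision/recall/f1) to the
    printed *percent* values; ``tolerance`` is in percentage points and
    defaults to ±0.06 so that either rounding or truncation of one-decimal
    values is admitted.  Raises :class:`ReconstructionError` when no matrix
    matches or more than one does (listing the candidates).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    candidates = []
    near_misses = []
    for tp in range(n_pos + 1):
        for fp in range(n_neg + 1):
            cm = ConfusionMatrix(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)
            rep = classification_metrics(cm)
            errs = {
                name: abs(getattr(rep, name) * 100.0 - target)
                for name, target in targets.items()
            }
            if max(errs.values()) <= tolerance:
                candidates.append(cm)
            elif max(errs.values()) <= 10 * tolerance:
                near_misses.append((max(errs.values()), cm))
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        near_misses.sort(key=lambda t: t[0])
        raise ReconstructionError(
            f"no confusion matrix on ({n_pos} pos, {n_neg} neg) matches {targets} "
            f"within ±{tolerance}; nearest: {[cm for _, cm in near_misses[:3]]}"
        )
    raise ReconstructionError(
        f"ambiguous reconstruction: {len(candidates)} matrices match {targets}: {candidates}"
    )


def grouped_split(
    events: list,
    group_key,
    test_selector=None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, list]:
    """Partition events into train/validation/test with no group split across sets.

    ``group_key(event)`` names the group (recording/subject); groups for
    which ``test_selector(group)`` is true form the test set (without a
    selector, the second half of the sorted group list is held out — the
    two-room design).  The remaining groups are shuffled (seeded) and
    ``val_fraction`` of them become validation.  Membership depends only on
    the group set, never on event order.
    """
    groups = sorted({group_key(e) for e in events})
    if len(groups) < 2:
        raise ValueError("grouped split needs >= 2 groups")
    if test_selector is None:
        n_test = max(1, len(groups) // 2)
        test_groups = set(groups[-n_test:])
    else:
        test_groups = {g for g in groups if test_selector(g)}
    rest = [g for g in groups if g not in test_groups]
    if not test_groups or not rest:
        raise ValueError("test selector must keep both sides of the split non-empty")
    rng = np.random.default_rng(seed)
    rest = list(np.array(sorted(rest), dtype=object)[rng.permutation(len(rest))])
    n_val = int(round(val_fraction * len(rest))) if len(rest) > 1 else 0
    val_groups = set(rest[:n_val])
    split = {"train": [], "val": [], "test": []}
    for e in events:
        g = group_key(e)
        part = "test" if g in test_groups else ("val" if g in val_groups else "train")
        split[part].append(e)
    log.info(
        "grouped split: %d train / %d val / %d test events over %d groups",
        len(split["train"]), len(split["val"]), len(split["test"]), len(groups),
    )
    return split


# ---------------------------------------------------------------------------
# synthetic end-to-end benchmark


@dataclass
class BenchmarkConfig:
    """Problem sizes and training budgets for the synthetic benchmark."""

    seed: int = 1
    frame_hw: tuple[int, int] = cnn3d.DESK_INPUT_HW
    fps: float = 2.0
    n_room1: int = 40  # events per class in the training room (train + val)
    n_test: int = 100  # events per class, test room
    val_fraction: float = 0.2  # of training-room subjects, for early stopping
    duration_range: tuple[float, float] = (15.0, 28.0)
    crop_size: int = 32  # chest/abdomen crop for the two-branch net
    cnn_input: str = "raw"  # "raw" or "capped" flow into the 3D-CNNs
    methods: tuple[str, ...] = BENCHMARK_METHODS
    cnn_epochs: int = 10
    cnn_patience: int = 3
    cnn_batch: int = 16
    b3_epochs: int = 20
    b3_patience: int = 6
    subjects_per_room: int = 10


@dataclass
class _EventRecord:
    event: ApneaEvent
    flow: flowproc.FlowSequence
    room: str
    subject: str


def _generate_events(config: BenchmarkConfig) -> list[_EventRecord]:
    """One padded mini-recording per event; NORMAL breathing in the pads."""
    scene = synthdata.default_scene(config.frame_hw)
    records = []
    plan = [
        ("room1", config.n_room1),
        ("room2", config.n_test),
    ]
    counter = 0
    for room, n_per_class in plan:
        for label in ("OA", "CA"):
            for i in range(n_per_class):
                seed = (config.seed * 1_000_003 + counter) % (2**31 - 1)
                rng = np.random.default_rng(seed)
                duration = float(rng.uniform(*config.duration_range))
                spec = synthdata.make_event_spec(label, start=5.0, duration=duration, rng=rng)
                rec = synthdata.generate_recording(
                    scene,
                    [spec],
                    fps=config.fps,
                    seed=seed,
                    duration=duration + 10.5,
                    recording_id=f"{room}_s{counter % config.subjects_per_room}",
                    render_frames=False,
                )
                records.append(
                    _EventRecord(
                        event=rec["events"][0],
                        flow=rec["flow"],
                        room=room,
                        subject=f"{room}_subj{counter % config.subjects_per_room}",
                    )
                )
                counter += 1
    return records


def _capped_mags(rec: _EventRecord) -> flowproc.MagnitudeSequence:
    return flowproc.cap_magnitude(flowproc.flow_magnitude(rec.flow))


def _baseline1_features(records: list[_EventRecord]) -> np.ndarray:
    feats = []
    for rec in records:
        sig = baselines.mean_movement_signal(_capped_mags(rec), rec.event)
        series = baselines.autocorrelation(baselines.bandpass(sig))
        feats.append(baselines.peak_features(series))
    return np.stack(feats)


def _baseline2_features(records: list[_EventRecord]) -> np.ndarray:
    return np.stack(
        [
            baselines.movement_histograms(_capped_mags(rec), rec.event).feature
            for rec in records
        ]
    )


def _baseline3_images(records: list[_EventRecord]) -> np.ndarray:
    return np.stack(
        [
            baselines.build_spectral_image(
                baselines.movement_histograms(_capped_mags(rec), rec.event)
            )
            for rec in records
        ]
    )


def _cnn_flow(rec, cnn_input):
    return flowproc.cap_flow(rec.flow) if cnn_input == "capped" else rec.flow


def _window_arrays(records, crop_centers=None, crop_size=100, cnn_input="raw"):
    """Training windows (label-dependent stride) as one array + labels."""
    tensors, labels = [], []
    for rec in records:
        stride = 1.0 if rec.event.label == "CA" else 5.0
        ws = windowing.make_windows(rec.event, _cnn_flow(rec, cnn_input), stride=stride, mode="train")
        for w in ws.windows:
            if crop_centers is None:
                tensors.append(w.tensor)
            else:
                tensors.append(
                    tuple(
                        flowproc.crop_region_flow_array(w.tensor, c, crop_size)
                        for c in crop_centers
                    )
                )
            labels.append(rec.event.y)
    y = np.array(labels)
    if crop_centers is None:
        return np.stack(tensors).astype(np.float32), y
    a = np.stack([t[0] for t in tensors]).astype(np.float32)
    b = np.stack([t[1] for t in tensors]).astype(np.float32)
    return (a, b), y


def _labels(records) -> np.ndarray:
    return np.array([rec.event.y for rec in records])


def run_benchmark(config: BenchmarkConfig | None = None, out_path=None) -> pd.DataFrame:
    """Run every method end to end on the seeded synthetic benchmark.

    Returns a table with one row per method and columns
    accuracy/precision/recall/f1/mcc (fractions); optionally writes it as a
    tab-delimited file with 4-decimal values.  Fully deterministic given
    ``config.seed``.
    """
    config = config or BenchmarkConfig()
    t0 = time.perf_counter()
    records = _generate_events(config)
    split = grouped_split(
        records,
        group_key=lambda r: r.subject,
        test_selector=lambda g: g.startswith("room2"),
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    train_recs, val_recs, test_recs = split["train"], split["val"], split["test"]
    log.info(
        "benchmark data: %d train / %d val / %d test events (%.1f s)",
        len(train_recs), len(val_recs), len(test_recs), time.perf_counter() - t0,
    )

    y_test = _labels(test_recs)
    rows = {}

    def add_row(method, y_pred):
        cm = ConfusionMatrix.from_labels(y_test, y_pred)
        rep = classification_metrics(cm)
        rows[method] = {
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
            "mcc": rep.mcc,
        }
        log.info("%s: accuracy %.3f (%.1f s)", method, rep.accuracy, time.perf_counter() - t0)

    fit_recs = train_recs + val_recs  # classical baselines tune via CV instead

    if "autocorrelation" in config.methods:
        # the three candidate classifiers are compared on training data;
        # the best cross-validation score wins (ties: first in order)
        x_fit = _baseline1_features(fit_recs)
        fits = [
            baselines.fit_baseline1(x_fit, _labels(fit_recs), classifier=name,
                                    seed=config.seed)
            for name in ("linear-svm", "logistic", "random-forest")
        ]
        clf = max(fits, key=lambda f: f.best_score_)
        add_row("autocorrelation", clf.predict(_baseline1_features(test_recs)))

    if "histogram" in config.methods:
        x_fit = _baseline2_features(fit_recs)
        pca, proj = baselines.pca_reduce(x_fit, k=100)
        rf = RandomForestClassifier(n_estimators=100, random_state=config.seed)
        rf.fit(proj, _labels(fit_recs))
        add_row("histogram", rf.predict(pca.transform(_baseline2_features(test_recs))))

    if "2dfft-cnn" in config.methods:
        b3cfg = baselines.Baseline3Config(
            train=TrainConfig(
                batch_size=config.cnn_batch,
                max_epochs=config.b3_epochs,
                patience=config.b3_patience,
            )
        )
        trained = baselines.fit_baseline3_cnn(
            _baseline3_images(fit_recs), _labels(fit_recs), b3cfg, seed=config.seed
        )
        probs = baselines.predict_baseline3(trained, _baseline3_images(test_recs))
        add_row("2dfft-cnn", (probs > 0.5).astype(int))

    scene = synthdata.default_scene(config.frame_hw)
    crop_centers = (scene.chest_box.center, scene.abdomen_box.center)
    cnn_cfg = TrainConfig(
        batch_size=config.cnn_batch,
        max_epochs=config.cnn_epochs,
        patience=config.cnn_patience,
        seed=config.seed,
    )

    if "3d-cnn" in config.methods:
        h, w = config.frame_hw
        _, net = cnn3d.build_whole_body_net((h, w, 20, 2))
        x_tr, y_tr = _window_arrays(train_recs, cnn_input=config.cnn_input)
        x_va, y_va = _window_arrays(val_recs, cnn_input=config.cnn_input)
        trained = cnn3d.train(net, x_tr, y_tr, x_va, y_va, cnn_cfg)
        preds = [
            cnn3d.predict_event(trained, r.event, _cnn_flow(r, config.cnn_input)).label == "CA"
            for r in test_recs
        ]
        add_row("3d-cnn", np.array(preds, dtype=int))

    if "3d-cnn-two-branch" in config.methods:
        _, net2 = cnn3d.build_two_branch_net(crop_size=config.crop_size)
        x_tr, y_tr = _window_arrays(train_recs, crop_centers, config.crop_size, config.cnn_input)
        x_va, y_va = _window_arrays(val_recs, crop_centers, config.crop_size, config.cnn_input)
        trained2 = cnn3d.train(net2, x_tr, y_tr, x_va, y_va, cnn_cfg)
        preds = [
            cnn3d.predict_event(
                trained2, r.event, _cnn_flow(r, config.cnn_input),
                crop_centers=crop_centers, crop_size=config.crop_size,
            ).label
            == "CA"
            for r in test_recs
        ]
        add_row("3d-cnn-two-branch", np.array(preds, dtype=int))

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "method"
    if out_path is not None:
        table.round(4).to_csv(out_path, sep="\t", float_format="%.4f")
    log.info("benchmark finished in %.1f s", time.perf_counter() - t0)
    return table
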