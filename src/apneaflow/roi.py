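"""Torso-region inference and detection scoring.

The chest and abdomen of a sleeping person are usually under a blanket, so
they are not detected directly: given a head bounding box (from any head
detector) plus anthropometrics (BMI, weight, height, head/body position),
a random-forest regressor predicts the chest and abdomen boxes.  Detection
quality is scored as the percentage of boxes with IoU strictly above a
threshold (0.5 by default).

Boxes are (x, y, w, h), 0-based, half-open.  The regressor predicts box
centers plus sizes, matching how crops are taken around estimated centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "BoundingBox",
    "Anthropometrics",
    "TorsoRegressor",
    "fit_torso_regressor",
    "iou",
    "detection_accuracy",
]

POSITIONS = ("supine", "lateral")


@dataclass(frozen=True)
class BoundingBox:
    x: float
    y: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"degenerate box {self}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    @staticmethod
    def from_center(cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class Anthropometrics:
    bmi: float  # kg/m^2
    weight: float  # kg
    height: float  # m
    head_position: str  # supine | lateral
    body_position: str

    def __post_init__(self):
        if min(self.bmi, self.weight, self.height) <= 0:
            raise ValueError("anthropometric values must be positive")
        for pos in (self.head_position, self.body_position):
            if pos not in POSITIONS:
                raise ValueError(f"position must be one of {POSITIONS}, got {pos!r}")


FEATURE_COLUMNS = [
    "head_x",
    "head_y",
    "head_w",
    "head_h",
    "bmi",
    "weight",
    "height",
    "head_position",
    "body_position",
]
TARGET_COLUMNS = [
    "chest_cx",
    "chest_cy",
    "chest_w",
    "chest_h",
    "abd_cx",
    "abd_cy",
    "abd_w",
    "abd_h",
]


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    x = table[FEATURE_COLUMNS[:7]].to_numpy(dtype=float)
    onehot = np.column_stack(
        [
            (table["head_position"] == "lateral").to_numpy(dtype=float),
            (table["body_position"] == "lateral").to_numpy(dtype=float),
        ]
    )
    return np.column_stack([x, onehot])


@dataclass
class TorsoRegressor:
    model: RandomForestRegressor

    def predict(self, table: pd.DataFrame) -> list[tuple[BoundingBox, BoundingBox]]:
        """Predict (chest, abdomen) boxes for each row of a predictor table."""
        y = self.model.predict(_design_matrix(table))
        y = np.atleast_2d(y)
        out = []
        for row in y:
            chest = BoundingBox.from_center(*row[:4])
            abd = BoundingBox.from_center(*row[4:])
            out.append((chest, abd))
        return out


def fit_torso_regressor(
    table: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 300,
) -> TorsoRegressor:
    """Fit the torso-box random forest on a predictor/target table.

    ``table`` must carry the predictor columns (head box, BMI, weight,
    height, one-hot-able positions) and the 8 target columns (chest and
    abdomen centers and sizes) — the layout produced by
    :func:`apneaflow.synthdata.generate_anthropometrics`.
    """
    if len(table) < 10:
        raise ValueError(f"need >= 10 training rows, got {len(table)}")
    x = _design_matrix(table)
    y = table[TARGET_COLUMNS].to_numpy(dtype=float)
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    model.fit(x, y)
    return TorsoRegressor(model=model)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x + a.width, b.x + b.width) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.height, b.y + b.height) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return float(min(1.0, max(0.0, inter / union)))


def detection_accuracy(
    predicted: list[BoundingBox],
    truth: list[BoundingBox],
    threshold: float = 0.5,
) -> float:
    """Percent of box pairs with IoU strictly greater than ``threshold``."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"paired lists differ in length: {len(predicted)} vs {len(truth)}"
        )
    hits = sum(iou(p, t) > threshold for p, t in zip(predicted, truth))
    return 100.0 * hits / len(truth)
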