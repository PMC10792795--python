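"""Annotation ingestion: crops, keypoints, orientation and dataset splits.

Coordinate conventions used throughout the package:

* pixel coordinates are 0-based, origin at the top-left corner, ``x`` growing
  rightward and ``y`` growing downward;
* crop-frame keypoints are stored *normalized*, i.e. as fractions of the crop
  width and height, so every coordinate lives in ``[0, 1]``;
* a keypoint vector packs the six landmarks into 12 values ordered as
  mesial CEJ (x, y), mesial crest, mesial apex, distal CEJ, distal crest,
  distal apex.

The annotation JSON dialect accepted by :func:`load_annotation_export` is a
list of image records::

    [{"image": "crop_0001.png", "width": 96, "height": 128,
      "annotations": [
        {"type": "box", "label": "molar", "jaw": "lower",
         "x": 10.0, "y": 5.0, "w": 80.0, "h": 90.0},
        {"type": "point", "label": "cej", "side": "mesial",
         "x": 25.0, "y": 20.0},
        ...]}]

with ``x``/``y``/``w``/``h`` expressed in *percent of the image dimensions*,
matching Label-Studio export semantics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

LANDMARKS = ("cej", "crest", "apex")
SIDES = ("mesial", "distal")
JAWS = ("upper", "lower")

#: (side, landmark) pairs in keypoint-vector order; slot k occupies vector
#: positions 2k (x) and 2k + 1 (y).
SLOTS: tuple[tuple[str, str], ...] = tuple(
    (side, landmark) for side in SIDES for landmark in LANDMARKS
)

SLOT_INDEX = {pair: i for i, pair in enumerate(SLOTS)}


class AnnotationFormatError(ValueError):
    """Raised when an annotation export does not parse as the documented dialect."""


class AnnotationValidationError(ValueError):
    """Raised when an annotation uses labels outside the enumerated vocabularies."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned molar bounding box in radiograph pixel coordinates."""

    x: float
    y: float
    w: float
    h: float
    jaw: str = "lower"

    def __post_init__(self) -> None:
        if self.jaw not in JAWS:
            raise AnnotationValidationError(f"unknown jaw {self.jaw!r}; expected one of {JAWS}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px <= self.x + self.w and self.y <= py <= self.y + self.h


@dataclass(frozen=True)
class LabeledPoint:
    """One anatomical landmark in radiograph pixel coordinates."""

    x: float
    y: float
    landmark: str
    side: str

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARKS:
            raise AnnotationValidationError(
                f"unknown landmark {self.landmark!r}; expected one of {LANDMARKS}"
            )
        if self.side not in SIDES:
            raise AnnotationValidationError(f"unknown side {self.side!r}; expected one of {SIDES}")


@dataclass
class RadiographAnnotation:
    """All labels attached to one panoramic radiograph."""

    image_id: str
    image_path: str | None
    width: int
    height: int
    boxes: list[BoundingBox] = field(default_factory=list)
    points: list[LabeledPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationValidationError(
                f"{self.image_id}: image dimensions must be positive"
            )


@dataclass
class LabeledMolar:
    """One oriented rectangular molar crop with crop-frame keypoints.

    ``keypoints`` maps ``(side, landmark)`` to a normalized ``(u, v)`` pair; a
    side is either present with all three landmarks or entirely absent.
    """

    molar_id: str
    image: np.ndarray
    keypoints: dict[tuple[str, str], tuple[float, float]]
    jaw: str = "lower"
    oriented: bool = False

    def labeled_sides(self) -> list[str]:
        return [s for s in SIDES if (s, "cej") in self.keypoints]

    def keypoint_vector(self) -> tuple[np.ndarray, np.ndarray]:
        """Pack keypoints into a 12-vector plus a per-value availability mask."""
        vec = np.zeros(12)
        mask = np.zeros(12, dtype=bool)
        for (side, landmark), (u, v) in self.keypoints.items():
            k = SLOT_INDEX[(side, landmark)]
            vec[2 * k] = u
            vec[2 * k + 1] = v
            mask[2 * k : 2 * k + 2] = True
        return vec, mask


def vector_to_keypoints(vec: np.ndarray) -> dict[tuple[str, str], tuple[float, float]]:
    """Unpack a 12-vector into the ``(side, landmark) -> (u, v)`` map."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (12,):
        raise ValueError(f"keypoint vector must have 12 entries, got shape {vec.shape}")
    return {
        pair: (float(vec[2 * k]), float(vec[2 * k + 1])) for k, pair in enumerate(SLOTS)
    }


def _require(cond: bool, record: object, message: str) -> None:
    if not cond:
        raise AnnotationFormatError(f"{message} in record {record!r}")


def load_annotation_export(path: str | Path) -> list[RadiographAnnotation]:
    """Read a JSON annotation export into :class:`RadiographAnnotation` records.

    Percent-of-image coordinates from the export are converted to pixels.
    Raises :class:`AnnotationFormatError` on malformed records and
    :class:`AnnotationValidationError` on unknown landmark/side/jaw labels.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise AnnotationFormatError(f"{path}: top-level export must be a list of image records")

    out: list[RadiographAnnotation] = []
    for rec in raw:
        _require(isinstance(rec, dict), rec, "image record must be an object")
        for key in ("image", "width", "height", "annotations"):
            _require(key in rec, rec, f"missing field {key!r}")
        width, height = int(rec["width"]), int(rec["height"])
        image_name = str(rec["image"])
        image_path = str(path.parent / image_name)
        boxes: list[BoundingBox] = []
        points: list[LabeledPoint] = []
        for ann in rec["annotations"]:
            _require(isinstance(ann, dict) and "type" in ann, ann, "annotation must have a type")
            kind = ann["type"]
            if kind == "box":
                _require(all(k in ann for k in ("x", "y", "w", "h")), ann, "box needs x/y/w/h")
                boxes.append(
                    BoundingBox(
                        x=ann["x"] / 100.0 * width,
                        y=ann["y"] / 100.0 * height,
                        w=ann["w"] / 100.0 * width,
                        h=ann["h"] / 100.0 * height,
                        jaw=ann.get("jaw", "lower"),
                    )
                )
            elif kind == "point":
                _require(all(k in ann for k in ("x", "y", "label")), ann, "point needs x/y/label")
                points.append(
                    LabeledPoint(
                        x=ann["x"] / 100.0 * width,
                        y=ann["y"] / 100.0 * height,
                        landmark=str(ann["label"]).lower(),
                        side=str(ann.get("side", "")).lower(),
                    )
                )
            else:
                raise AnnotationFormatError(f"unknown annotation type {kind!r} in record {rec!r}")
        out.append(
            RadiographAnnotation(
                image_id=Path(image_name).stem,
                image_path=image_path,
                width=width,
                height=height,
                boxes=boxes,
                points=points,
            )
        )
    return out


def _load_image(path: str) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse any RGB(A) channels from 8-bit PNG round-trips
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=np.float32)


def extract_crops(
    annotation: RadiographAnnotation, image: np.ndarray | None = None
) -> list[LabeledMolar]:
    """Cut each bounding box into a :class:`LabeledMolar` with normalized keypoints.

    Points inside a box are re-referenced to the box frame and normalized by
    its width/height; points outside every box are dropped with a warning.
    Sides that do not carry all three landmarks are cleared entirely — a side
    is only usable when CEJ, crest and apex are all labeled.
    """
    if image is None:
        if annotation.image_path is None:
            raise ValueError(f"{annotation.image_id}: no image array and no image_path")
        image = _load_image(annotation.image_path)
    image = np.asarray(image, dtype=np.float32)

    crops: list[LabeledMolar] = []
    claimed = [False] * len(annotation.points)
    for b, box in enumerate(annotation.boxes):
        if box.area <= 0:
            warnings.warn(f"{annotation.image_id}: skipping zero-area box {b}", stacklevel=2)
            continue
        x0, y0 = int(round(box.x)), int(round(box.y))
        x1 = min(int(round(box.x + box.w)), image.shape[1])
        y1 = min(int(round(box.y + box.h)), image.shape[0])
        crop_img = image[max(y0, 0) : y1, max(x0, 0) : x1]
        keypoints: dict[tuple[str, str], tuple[float, float]] = {}
        for i, pt in enumerate(annotation.points):
            if box.contains(pt.x, pt.y):
                claimed[i] = True
                u = (pt.x - box.x) / box.w
                v = (pt.y - box.y) / box.h
                keypoints[(pt.side, pt.landmark)] = (u, v)
        for side in SIDES:
            have = [lm for lm in LANDMARKS if (side, lm) in keypoints]
            if have and len(have) < len(LANDMARKS):
                logger.warning(
                    "%s box %d: %s side has %s but not all three landmarks; clearing side",
                    annotation.image_id, b, side, have,
                )
                for lm in have:
                    del keypoints[(side, lm)]
        # single-box exports (one crop per image) keep the bare image id
        crop_id = (
            annotation.image_id
            if len(annotation.boxes) == 1
            else f"{annotation.image_id}_m{b:02d}"
        )
        crops.append(
            LabeledMolar(
                molar_id=crop_id,
                image=crop_img,
                keypoints=keypoints,
                jaw=box.jaw,
                oriented=False,
            )
        )
    for i, pt in enumerate(annotation.points):
        if not claimed[i]:
            warnings.warn(
                f"{annotation.image_id}: point {pt.landmark}/{pt.side} at "
                f"({pt.x:.1f}, {pt.y:.1f}) lies outside every box; dropped",
                stacklevel=2,
            )
    return crops


def orient_molar(molar: LabeledMolar) -> LabeledMolar:
    """Rotate upper-jaw crops by 180° so the root apex points downward.

    Lower-jaw crops pass through unchanged apart from the ``oriented`` flag.
    The 180° rotation maps a normalized keypoint ``(u, v)`` to ``(1-u, 1-v)``.
    """
    if molar.oriented:
        raise ValueError(f"{molar.molar_id} is already oriented")
    if molar.jaw == "upper":
        image = molar.image[::-1, ::-1].copy()
        keypoints = {
            key: (1.0 - u, 1.0 - v) for key, (u, v) in molar.keypoints.items()
        }
    else:
        image = molar.image
        keypoints = dict(molar.keypoints)
    return replace(molar, image=image, keypoints=keypoints, oriented=True)


def split_dataset(
    molars: list[LabeledMolar],
    test_n: int,
    train_frac: float,
    seed: int,
) -> tuple[list[LabeledMolar], list[LabeledMolar], list[LabeledMolar]]:
    """Partition crops into (train, validation, test) sets.

    ``test_n`` crops are sampled uniformly without replacement and have their
    keypoints removed (the test items are presented unlabeled); the remainder
    is shuffled and split ``floor(train_frac * n)`` / rest into train and
    validation.  The same seed always yields the same membership.
    """
    n = len(molars)
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if test_n >= n:
        raise ValueError(f"test_n={test_n} must be smaller than the corpus size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = [
        replace(molars[i], keypoints={}) for i in order[:test_n]
    ]
    rest = [molars[i] for i in order[test_n:]]
    n_train = int(np.floor(train_frac * len(rest)))
    return rest[:n_train], rest[n_train:], test
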