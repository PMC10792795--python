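"""Component 3: geometric PBL percentage and stage from a keypoint vector.

Per anatomical side, root length ``A`` is the Euclidean distance from the
cementoenamel junction (CEJ) to the root apex, and bone height ``B`` is the
Euclidean distance from the alveolar crest to the apex, both measured in
pixels after denormalizing the keypoints by the crop dimensions.  Periodontal
bone loss is the fraction of the root no longer supported by bone,

    PBL (%) = (A - B) / A * 100,

clamped to [0, 100] to absorb malformed predictions (crest beyond the CEJ or
beyond the apex).  Staging follows the severity bands of the Classification
of Periodontal and Peri-Implant Diseases and Conditions: stage 1 below 15%,
stage 2 from 15% to 33% inclusive, stage 3/4 above 33% (token ``34``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from perioloss.annotations import SIDES, vector_to_keypoints

STAGES = (1, 2, 34)

#: Stage band edges in PBL percent; both boundary values belong to stage 2
#: because the bands below and above are strict (< 15 and > 33).
STAGE_1_UPPER = 15.0
STAGE_2_UPPER = 33.0

_MIN_ROOT_PX = 1.0


@dataclass(frozen=True)
class SideMeasurement:
    """Root length, bone height, PBL percent and stage for one side."""

    side: str
    root_length_A: float
    bone_height_B: float
    pbl_percent: float
    stage: int | None
    valid: bool


def assign_stage(pbl_percent: float) -> int:
    """Map a PBL percentage to its severity stage (1, 2 or 34)."""
    if not 0.0 <= pbl_percent <= 100.0:
        raise ValueError(f"PBL percentage must be in [0, 100], got {pbl_percent}")
    if pbl_percent < STAGE_1_UPPER:
        return 1
    if pbl_percent <= STAGE_2_UPPER:
        return 2
    return 34


def compute_side_measurement(
    cej: tuple[float, float] | None,
    crest: tuple[float, float] | None,
    apex: tuple[float, float] | None,
    image_dims: tuple[float, float],
    side: str = "mesial",
) -> SideMeasurement:
    """Measure one side from its three normalized keypoints.

    Points are denormalized by ``image_dims = (width, height)`` before the
    Euclidean distances are taken.  Returns an invalid measurement when any
    point is missing or the root degenerates below one pixel.
    """
    if cej is None or crest is None or apex is None:
        return SideMeasurement(side, np.nan, np.nan, np.nan, None, valid=False)
    w, h = image_dims
    scale = np.array([w, h], dtype=float)
    cej_px = np.asarray(cej, dtype=float) * scale
    crest_px = np.asarray(crest, dtype=float) * scale
    apex_px = np.asarray(apex, dtype=float) * scale
    a = float(np.linalg.norm(apex_px - cej_px))
    b = float(np.linalg.norm(apex_px - crest_px))
    if a < _MIN_ROOT_PX:
        return SideMeasurement(side, a, b, np.nan, None, valid=False)
    pbl = float(np.clip((a - b) / a * 100.0, 0.0, 100.0))
    return SideMeasurement(side, a, b, pbl, assign_stage(pbl), valid=True)


def measure_molar(
    keypoints: np.ndarray,
    image_dims: tuple[float, float],
) -> tuple[SideMeasurement, SideMeasurement]:
    """Measure both sides of a molar from its 12-value keypoint vector."""
    kp = vector_to_keypoints(keypoints)
    mesial, distal = (
        compute_side_measurement(
            kp[(side, "cej")], kp[(side, "crest")], kp[(side, "apex")], image_dims, side=side
        )
        for side in SIDES
    )
    return mesial, distal
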