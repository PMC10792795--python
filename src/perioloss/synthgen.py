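"""Synthetic molar-crop renderer with known keypoint geometry and bone loss.

Each crop is a stylized two-rooted molar on a darker bone-textured
background: a bright crown-and-roots silhouette, plus an additive bone band
whose upper boundary runs through the two alveolar-crest keypoints.  The six
keypoints (mesial/distal CEJ, crest, apex) are emitted in crop-normalized
coordinates, and the crest is placed *on* the CEJ-apex segment at the exact
fraction that realizes the requested bone-loss percentage, so the Euclidean
PBL of the emitted keypoints equals the sampled target by construction.

The default stage mix (57.14% / 35.71% / 7.14% for stages 1 / 2 / 3-4)
emulates the imbalance of the study population; per-stage PBL ranges keep a
2-point margin from the 15% and 33% staging boundaries so labels stay
unambiguous under rendering noise.  Upper-jaw crops are emitted apex-up, i.e.
still requiring the 180° orientation step downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from perioloss.annotations import LabeledMolar
from perioloss.staging import STAGES

#: stage probabilities matching the study mix (48/84, 30/84, 6/84)
DEFAULT_STAGE_MIX = (48 / 84, 30 / 84, 6 / 84)

DEFAULT_PBL_RANGES = {1: (2.0, 13.0), 2: (17.0, 31.0), 34: (35.0, 60.0)}


@dataclass
class SynthParams:
    """Rendering and sampling settings for the synthetic molar generator."""

    image_size: tuple[int, int] = (96, 128)  # (width, height) pixels
    stage_mix: tuple[float, float, float] = DEFAULT_STAGE_MIX
    pbl_ranges: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PBL_RANGES)
    )
    root_length_range: tuple[float, float] = (0.45, 0.60)  # fraction of height
    noise_sd: float = 6.0  # additive Gaussian, 8-bit intensity units
    blur_sigma: float = 0.7  # pixels
    contrast_jitter: float = 0.15  # multiplicative fraction
    upper_fraction: float = 0.5
    side_correlation: float = 0.7  # mesial/distal bone-level correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ValueError("stage_mix must sum to 1")
        for s in STAGES:
            if s not in self.pbl_ranges:
                raise ValueError(f"pbl_ranges missing stage {s}")


def _correlated_uniform_pair(rng: np.random.Generator, rho: float) -> tuple[float, float]:
    """Two correlated U(0,1) draws via a Gaussian copula."""
    from scipy.stats import norm

    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
    return float(norm.cdf(z1)), float(norm.cdf(z2))


def _render(
    w: int,
    h: int,
    cej: dict[str, np.ndarray],
    apex: dict[str, np.ndarray],
    crest: dict[str, np.ndarray],
    params: SynthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    from skimage.draw import polygon

    img = np.full((h, w), 40.0, dtype=np.float32)

    # crown: bright block spanning the two CEJs and the space above them
    crown_top = 0.04 * h
    cx0 = cej["mesial"][0] - 0.08 * w
    cx1 = cej["distal"][0] + 0.08 * w
    rr, cc = polygon(
        [crown_top, crown_top, cej["distal"][1] + 0.04 * h, cej["mesial"][1] + 0.04 * h],
        [cx0, cx1, cx1, cx0],
        shape=img.shape,
    )
    tooth = np.zeros_like(img)
    tooth[rr, cc] = 1.0

    # two tapered roots from just below each CEJ down to the apices
    for side in ("mesial", "distal"):
        cx, cy = cej[side]
        ax, ay = apex[side]
        half_top, half_tip = 0.06 * w, 0.015 * w
        rr, cc = polygon(
            [cy, cy, ay, ay],
            [cx - half_top, cx + half_top, ax + half_tip, ax - half_tip],
            shape=img.shape,
        )
        tooth[rr, cc] = 1.0
    img += 90.0 * tooth

    # additive bone band; its upper boundary passes through both crest points
    mx, my = crest["mesial"]
    dx, dy = crest["distal"]
    xs = np.arange(w, dtype=np.float32)
    line = np.where(
        xs <= mx, my, np.where(xs >= dx, dy, my + (dy - my) * (xs - mx) / max(dx - mx, 1e-6))
    )
    bone = (np.arange(h, dtype=np.float32)[:, None] >= line[None, :]).astype(np.float32)
    img += 50.0 * bone

    if params.contrast_jitter > 0:
        img *= 1.0 + rng.uniform(-params.contrast_jitter, params.contrast_jitter)
    if params.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.float32)


def generate_molar(
    params: SynthParams,
    target_stage: int,
    rng: np.random.Generator,
    molar_id: str = "synth_0000",
) -> LabeledMolar:
    """Render one labeled crop whose keypoint PBL falls in the target stage band.

    The same generator state always yields the same image and keypoints.
    """
    if target_stage not in STAGES:
        raise ValueError(f"unknown stage {target_stage}")
    w, h = params.image_size

    cej = {}
    apex = {}
    cej["mesial"] = np.array(
        [rng.uniform(0.22, 0.30) * w, rng.uniform(0.20, 0.28) * h]
    )
    cej["distal"] = np.array(
        [rng.uniform(0.70, 0.78) * w, rng.uniform(0.20, 0.28) * h]
    )
    base_len = rng.uniform(*params.root_length_range)
    for side, sign in (("mesial", -1.0), ("distal", 1.0)):
        length = base_len * (1.0 + rng.uniform(-0.05, 0.05))
        flare = sign * rng.uniform(0.03, 0.08) * w
        apex[side] = cej[side] + np.array([flare, length * h])

    lo, hi = params.pbl_ranges[target_stage]
    u1, u2 = _correlated_uniform_pair(rng, params.side_correlation)
    pbl = {"mesial": lo + (hi - lo) * u1, "distal": lo + (hi - lo) * u2}
    crest = {
        side: cej[side] + (pbl[side] / 100.0) * (apex[side] - cej[side])
        for side in ("mesial", "distal")
    }

    image = _render(w, h, cej, apex, crest, params, rng)
    keypoints = {}
    for side in ("mesial", "distal"):
        for landmark, pt in (("cej", cej[side]), ("crest", crest[side]), ("apex", apex[side])):
            keypoints[(side, landmark)] = (float(pt[0] / w), float(pt[1] / h))

    jaw = "upper" if rng.random() < params.upper_fraction else "lower"
    if jaw == "upper":  # emit apex-up, as cropped from an upper jaw
        image = image[::-1, ::-1].copy()
        keypoints = {key: (1.0 - u, 1.0 - v) for key, (u, v) in keypoints.items()}
    return LabeledMolar(
        molar_id=molar_id, image=image, keypoints=keypoints, jaw=jaw, oriented=False
    )


def _allocate_exact(n: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items to the stage mix."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(r)) for r in raw]
    remainders = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % len(mix)]] += 1
    return counts


def generate_dataset(
    params: SynthParams,
    n: int,
    out_dir: str | Path | None = None,
    exact_mix: bool = False,
) -> tuple[list[LabeledMolar], pd.DataFrame]:
    """Generate ``n`` labeled crops plus a per-side ground-truth table.

    Stages are drawn from ``params.stage_mix`` (or allocated exactly
    proportionally when ``exact_mix`` is set).  When ``out_dir`` is given,
    PNG crops, an annotation JSON export in the package dialect and the
    ground-truth CSV are written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed)
    if exact_mix:
        counts = _allocate_exact(n, params.stage_mix)
        stages = [s for s, c in zip(STAGES, counts) for _ in range(c)]
        stages = [stages[i] for i in rng.permutation(n)]
    else:
        stages = list(rng.choice(STAGES, size=n, p=params.stage_mix))

    molars: list[LabeledMolar] = []
    rows = []
    w, h = params.image_size
    for i, stage in enumerate(stages):
        molar = generate_molar(params, int(stage), rng, molar_id=f"synth_{i:04d}")
        molars.append(molar)
        for side in ("mesial", "distal"):
            cej = np.array(molar.keypoints[(side, "cej")]) * (w, h)
            crest = np.array(molar.keypoints[(side, "crest")]) * (w, h)
            apex = np.array(molar.keypoints[(side, "apex")]) * (w, h)
            a = np.linalg.norm(apex - cej)
            b = np.linalg.norm(apex - crest)
            rows.append(
                {
                    "molar_id": molar.molar_id,
                    "side": side,
                    "pbl_percent": (a - b) / a * 100.0,
                    "stage": int(stage),
                }
            )
    truth = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_outputs(molars, truth, out_dir)
    return molars, truth


def _write_outputs(molars: list[LabeledMolar], truth: pd.DataFrame, out_dir: Path) -> None:
    import imageio.v3 as iio

    records = []
    for molar in molars:
        name = f"{molar.molar_id}.png"
        iio.imwrite(out_dir / name, np.round(molar.image).astype(np.uint8))
        h, w = molar.image.shape
        anns: list[dict] = [
            {"type": "box", "label": "molar", "jaw": molar.jaw,
             "x": 0.0, "y": 0.0, "w": 100.0, "h": 100.0}
        ]
        for (side, landmark), (u, v) in molar.keypoints.items():
            anns.append(
                {"type": "point", "label": landmark, "side": side,
                 "x": u * 100.0, "y": v * 100.0}
            )
        records.append(
            {"image": name, "width": w, "height": h, "annotations": anns}
        )
    (out_dir / "annotations.json").write_text(json.dumps(records))
    truth.to_csv(out_dir / "truth.csv", index=False)
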