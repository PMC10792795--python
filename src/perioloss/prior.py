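"""Component 1: statistical keypoint prior.

Each of the 12 keypoint coordinates (six landmarks × x/y, in crop-normalized
units) is modeled by its own one-dimensional probability function.  For every
coordinate slot, each candidate family is fitted by maximum likelihood and the
families are ranked by the sum of squared differences between the empirical
histogram density and the fitted density; the minimizer is kept.  Sampling the
12 fitted functions simultaneously yields a purely statistical keypoint
prediction, which both seeds the convolutional refiner and acts as a data
augmentation mechanism (several distinct prior samples per training image).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

from perioloss.annotations import LabeledMolar

#: Candidate families, as scipy.stats names.  The set covers symmetric,
#: skewed and bounded coordinate behavior.
DEFAULT_FAMILIES = ("norm", "lognorm", "beta", "gamma", "uniform", "logistic")

POINT_MASS = "point_mass"

_MIN_VECTORS = 30


@dataclass(frozen=True)
class FittedDistribution:
    """Best-fitting family for one coordinate slot."""

    family: str
    params: tuple[float, ...]
    fit_error: float

    def frozen(self):
        if self.family == POINT_MASS:
            raise ValueError("point-mass pseudo-family has no scipy frozen form")
        return getattr(scipy.stats, self.family)(*self.params)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == POINT_MASS:
            return np.full(n, self.params[0])
        return np.clip(self.frozen().rvs(size=n, random_state=rng), 0.0, 1.0)


@dataclass
class PriorModel:
    """Twelve fitted one-dimensional probability functions, one per coordinate."""

    distributions: list[FittedDistribution]
    n_train: int

    def __post_init__(self) -> None:
        if len(self.distributions) != 12:
            raise ValueError(f"PriorModel needs exactly 12 slots, got {len(self.distributions)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_train": self.n_train,
            "distributions": [
                {"family": d.family, "params": list(d.params), "fit_error": d.fit_error}
                for d in self.distributions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PriorModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            distributions=[
                FittedDistribution(d["family"], tuple(d["params"]), d["fit_error"])
                for d in payload["distributions"]
            ],
            n_train=payload["n_train"],
        )


def _fit_one_family(family: str, data: np.ndarray, hist: np.ndarray, centers: np.ndarray):
    dist = getattr(scipy.stats, family)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = dist.fit(data)
        pdf = dist.pdf(centers, *params)
    if not np.all(np.isfinite(pdf)):
        raise FloatingPointError(f"{family}: non-finite density on histogram support")
    err = float(np.sum((hist - pdf) ** 2))
    if not np.isfinite(err):
        raise FloatingPointError(f"{family}: non-finite fit error")
    return FittedDistribution(family, tuple(float(p) for p in params), err)


def fit_coordinate_distributions(
    vectors: list[np.ndarray] | np.ndarray,
    candidates: tuple[str, ...] = DEFAULT_FAMILIES,
    bins: int = 100,
) -> PriorModel:
    """Fit and rank candidate families for each of the 12 coordinate slots.

    Parameters are estimated by maximum likelihood within each family; the
    families are ranked by the histogram sum-of-squares criterion (``bins``
    equal-width bins over the observed range).  Zero-variance slots are stored
    as a point-mass pseudo-family with fit error 0.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 12:
        raise ValueError(f"expected an (n, 12) array of keypoint vectors, got {arr.shape}")
    if arr.shape[0] < _MIN_VECTORS:
        raise ValueError(
            f"need at least {_MIN_VECTORS} keypoint vectors to fit the prior, got {arr.shape[0]}"
        )
    if not candidates:
        raise ValueError("candidate family list is empty")

    fitted: list[FittedDistribution] = []
    for slot in range(12):
        data = arr[:, slot]
        if np.ptp(data) < 1e-12:
            fitted.append(FittedDistribution(POINT_MASS, (float(data[0]),), 0.0))
            continue
        hist, edges = np.histogram(data, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        best: FittedDistribution | None = None
        for family in candidates:
            try:
                cand = _fit_one_family(family, data, hist, centers)
            except Exception as exc:  # scipy fit failures are family-specific
                warnings.warn(f"slot {slot}: {family} fit failed ({exc}); skipped", stacklevel=2)
                continue
            if best is None or cand.fit_error < best.fit_error:
                best = cand
        if best is None:
            raise RuntimeError(f"slot {slot}: every candidate family failed to fit")
        fitted.append(best)
    return PriorModel(distributions=fitted, n_train=arr.shape[0])


def sample_prior(prior: PriorModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` statistical keypoint predictions, one value per slot.

    Slots are sampled independently from their fitted distributions and
    clamped to the unit interval; a fixed seed yields identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 12))
    for slot, dist in enumerate(prior.distributions):
        out[:, slot] = dist.sample(n, rng)
    return out


@dataclass
class TrainingExample:
    """One refiner training example: image, prior guess, supervision target.

    ``mask`` marks which of the 12 target values came from a real label;
    unmasked (False) slots were filled with the prior sample and must be
    excluded from the training loss.
    """

    molar_id: str
    image: np.ndarray
    prior_vector: np.ndarray
    true_vector: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: np.ones(12, dtype=bool))


def augment_training_set(
    train: list[LabeledMolar],
    prior: PriorModel,
    k: int = 25,
    seed: int = 0,
) -> list[TrainingExample]:
    """Pair each training crop with ``k`` distinct prior samples.

    Produces exactly ``k * len(train)`` examples.  Unlabeled sides have their
    target slots filled with the prior sample and flagged in ``mask`` so the
    refiner loss can ignore them.
    """
    if not train:
        raise ValueError("training set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    for m in train:
        if not m.labeled_sides():
            raise ValueError(f"{m.molar_id}: no fully labeled side; cannot supervise")
    samples = sample_prior(prior, k * len(train), seed)
    out: list[TrainingExample] = []
    for i, molar in enumerate(train):
        true_vec, mask = molar.keypoint_vector()
        for j in range(k):
            prior_vec = samples[i * k + j]
            target = np.where(mask, true_vec, prior_vec)
            out.append(
                TrainingExample(
                    molar_id=molar.molar_id,
                    image=molar.image,
                    prior_vector=prior_vec,
                    true_vector=target,
                    mask=mask.copy(),
                )
            )
    return out
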