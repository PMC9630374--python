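"""ROI-driven pseudo-coloring of depolarization observable images.

Each tissue class i is characterized by the per-observable means m_j^i and
standard deviations sigma_j^i estimated over user-drawn rectangular ROIs,
plus an RGB color C^i with components in [0, 1].  Two renderers are
provided:

* Euclidean (exactly two classes): each pixel's observable triplet p is
  compared to both class means through per-observable normalized distances

      d^{i,norm} = sqrt( sum_j ((m_j^i - p_j) / (m_j^1 - m_j^2))^2 ),

  and colored with weights R^i = 1 - d^{i,norm} / (d^{1,norm} + d^{2,norm}),
  which always sum to 1.  Pixels far from both classes get ~1/2 of each
  color, so the output is a visual-contrast aid, not a classifier.

* Normal (any k >= 1 classes): each class contributes its color weighted by
  the product-of-Gaussians membership

      P^i = prod_j exp(-((p_j - m_j^i) / sigma_j^i)^2),

  with no 1/2 factor in the exponent and no normalizing constant, so
  P^i in (0, 1] with the maximum attained exactly at the class means.
  Pixels far from every class come out black without any threshold.  The
  probability map supports an optional argmax classification export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .observables import ObservableStack

__all__ = [
    "ClassModel",
    "ROISpec",
    "EuclideanWeights",
    "COLOR_PRESETS",
    "SIGMA_FLOOR",
    "roi_statistics",
    "euclidean_weights",
    "euclidean_pseudocolor",
    "normal_probability",
    "normal_pseudocolor",
    "classify",
    "apply_mask",
]

#: Standard deviations below this are replaced by it before entering the
#: Gaussian membership; constant ROIs would otherwise divide by zero.
SIGMA_FLOOR = 1e-6

#: Default classification threshold: pixels whose best class membership falls
#: below it are exported as unassigned (-1) in the label map.
CLASSIFY_THRESHOLD = 1e-3

#: RGB presets named after the tissue-class colors used in practice.
COLOR_PRESETS = {
    "yellow": (1.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "pink": (1.0, 0.0, 0.5),
    "lime_green": (0.0, 1.0, 0.5),
}


class DegenerateObservableWarning(UserWarning):
    """Two class means coincide in some observable; it is dropped from Eq.-space distances."""


@dataclass
class ClassModel:
    """Statistics and display color of one tissue class."""

    name: str
    means: np.ndarray  # (n,) per-observable means
    stds: np.ndarray  # (n,) per-observable standard deviations, >= SIGMA_FLOOR
    color: np.ndarray  # (3,) RGB in [0, 1]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        self.color = np.asarray(self.color, dtype=float)
        if self.means.shape != self.stds.shape:
            raise ValueError("means and stds must have the same length")
        if np.any(self.stds <= 0):
            raise ValueError("standard deviations must be positive (floored)")
        if self.color.shape != (3,) or np.any(self.color < 0) or np.any(self.color > 1):
            raise ValueError("color must be an RGB triplet with components in [0, 1]")


@dataclass
class ROISpec:
    """One class's region of interest: a union of axis-aligned rectangles.

    Rectangles are (x0, y0, x1, y1), 0-based, half-open: columns x0 <= x < x1
    and rows y0 <= y < y1.
    """

    name: str
    rectangles: list = field(default_factory=list)

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if not self.rectangles:
            raise ValueError(f"ROI {self.name!r} has no rectangles")
        h, w = shape
        mask = np.zeros(shape, dtype=bool)
        for rect in self.rectangles:
            x0, y0, x1, y1 = (int(v) for v in rect)
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(
                    f"ROI {self.name!r} rectangle {rect} out of bounds for image {w}x{h}"
                )
            mask[y0:y1, x0:x1] = True
        return mask


@dataclass
class EuclideanWeights:
    """Per-pixel normalized distances and color weights for the two-class method."""

    d_norm: np.ndarray  # (..., 2) normalized distance to each class
    d_total: np.ndarray  # (...,) sum of the two distances
    weights: np.ndarray  # (..., 2) color weights, summing to 1


def roi_statistics(
    stack: ObservableStack,
    roi: ROISpec,
    basis: str,
    color=(1.0, 1.0, 1.0),
    sigma_floor: float = SIGMA_FLOOR,
) -> ClassModel:
    """Estimate a class model from the valid pixels under an ROI.

    Means and sample standard deviations (ddof=1) are pooled over the union
    of the ROI rectangles; standard deviations are floored at
    ``sigma_floor``.  Requires at least two valid pixels.
    """
    sel = roi.pixel_mask(stack.shape) & stack.mask
    n = int(sel.sum())
    if n < 2:
        raise ValueError(
            f"ROI {roi.name!r} covers {n} valid pixel(s); at least 2 are required"
        )
    obs = stack.triplet(basis)[sel]  # (n, 3)
    means = obs.mean(axis=0)
    stds = np.maximum(obs.std(axis=0, ddof=1), sigma_floor)
    return ClassModel(name=roi.name, means=means, stds=stds, color=np.asarray(color, float))


def euclidean_weights(
    p: np.ndarray,
    class1: ClassModel,
    class2: ClassModel,
    degenerate_tol: float = 1e-9,
) -> EuclideanWeights:
    """Two-class color weights from per-observable normalized distances.

    Each observable's residual is scaled by the separation of the two class
    means in that observable.  Observables in which the class means coincide
    (within ``degenerate_tol``) make that scale undefined and are dropped
    with a warning; if every observable is degenerate the classes are
    indistinguishable and an error is raised.  Pixels at zero total distance
    (possible only in degenerate geometry) get weights (1/2, 1/2).
    """
    p = np.asarray(p, dtype=float)
    denom = class1.means - class2.means
    keep = np.abs(denom) > degenerate_tol
    if not np.any(keep):
        raise ValueError(
            f"classes {class1.name!r} and {class2.name!r} have identical means "
            "in every observable; the Euclidean method cannot separate them"
        )
    if not np.all(keep):
        dropped = [str(j) for j in np.nonzero(~keep)[0]]
        warnings.warn(
            f"observable(s) {', '.join(dropped)} have equal class means and are "
            "dropped from the Euclidean distance",
            DegenerateObservableWarning,
            stacklevel=2,
        )
    denom = denom[keep]
    d1 = np.sqrt(np.sum(((class1.means[keep] - p[..., keep]) / denom) ** 2, axis=-1))
    d2 = np.sqrt(np.sum(((class2.means[keep] - p[..., keep]) / denom) ** 2, axis=-1))
    total = d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(total > 0, 1.0 - d1 / np.where(total == 0, 1.0, total), 0.5)
    r2 = 1.0 - r1
    return EuclideanWeights(
        d_norm=np.stack([d1, d2], axis=-1),
        d_total=total,
        weights=np.stack([r1, r2], axis=-1),
    )


def apply_mask(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out (render black) the RGB values of invalid pixels."""
    out = np.array(rgb, dtype=float, copy=True)
    out[~mask] = 0.0
    return out


def euclidean_pseudocolor(
    stack: ObservableStack,
    class1: ClassModel,
    class2: ClassModel,
    basis: str,
) -> np.ndarray:
    """Two-class Euclidean pseudo-colored RGB image.

    Per-pixel color R^1 C^1 + R^2 C^2 clipped to [0, 1]; masked pixels are
    black.  The mixing is intentional: the output enhances visual contrast
    and is not a classification.
    """
    p = stack.triplet(basis)
    w = euclidean_weights(p, class1, class2).weights
    rgb = w[..., 0:1] * class1.color + w[..., 1:2] * class2.color
    return apply_mask(np.clip(rgb, 0.0, 1.0), stack.mask)


def normal_probability(p: np.ndarray, cls: ClassModel) -> np.ndarray:
    """Gaussian class membership P^i = prod_j exp(-((p_j - m_j)/sigma_j)^2)."""
    z = (np.asarray(p, dtype=float) - cls.means) / cls.stds
    return np.exp(-np.sum(z * z, axis=-1))


def normal_pseudocolor(
    stack: ObservableStack,
    classes: list[ClassModel],
    basis: str,
) -> tuple[np.ndarray, np.ndarray]:
    """k-class Normal-probability pseudo-colored RGB image.

    Returns ``(rgb, probabilities)``: the per-pixel color sum_i P^i C^i
    clipped to [0, 1] (black where every membership underflows, with no
    explicit threshold), and the (H, W, k) membership map usable for
    classification via :func:`classify`.  Masked pixels are black with zero
    membership in every class.
    """
    if not classes:
        raise ValueError("at least one class is required")
    p = stack.triplet(basis)
    probs = np.stack([normal_probability(p, c) for c in classes], axis=-1)
    probs[~stack.mask] = 0.0
    colors = np.stack([c.color for c in classes], axis=0)  # (k, 3)
    rgb = np.einsum("...k,kc->...c", probs, colors)
    return apply_mask(np.clip(rgb, 0.0, 1.0), stack.mask), probs


def classify(probs: np.ndarray, threshold: float = CLASSIFY_THRESHOLD) -> np.ndarray:
    """Argmax label map from a Normal membership map.

    Pixels whose best membership is below ``threshold`` (including masked
    pixels, which carry zero membership) are labeled -1 (unassigned).  The
    threshold only affects this export, never the RGB rendering.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.argmax(probs, axis=-1).astype(np.int64)
    labels[np.max(probs, axis=-1) < threshold] = -1
    return labels
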