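"""Subregion activation maps for auditing what a classifier looks at.

With a global-average-pool head, the per-class score of the model is a
linear read-out of the final convolutional feature grid. Applying the same
linear head to each grid cell individually gives a g x g map of class
evidence (a class activation map); passing each cell's class scores through
a softmax gives a per-subregion class probability, from which we count the
"decisive" subregions — cells that on their own assign probability >= tau
(default 0.95) to the target class. The influence heatmap (target score
minus the sum of the competing class scores, mean-centred) highlights which
cells dominate the decision, e.g. a corner metal token.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureMapStack",
    "HeadWeights",
    "SubregionScoreMap",
    "SubregionProbabilityMap",
    "DecisiveSummary",
    "subregion_scores",
    "subregion_probability",
    "count_decisive",
    "influence_heatmap",
    "summarize_decisive",
]


@dataclass
class FeatureMapStack:
    """Final-layer activations X[k, i, j]: K channels on a g x g grid."""

    x: np.ndarray  # (K, g, g)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 3 or self.x.shape[1] != self.x.shape[2]:
            raise ValueError("expected (K, g, g) activations")
        if not np.isfinite(self.x).all():
            raise ValueError("activations must be finite")

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def grid(self) -> int:
        return self.x.shape[1]


@dataclass
class HeadWeights:
    """Per-class linear read-out over pooled channels: weights B (K,), bias B0."""

    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)


@dataclass
class SubregionScoreMap:
    """Y[c, i, j] = sum_k B_k[c] X[k, i, j] + B0[c] for each class c."""

    y: np.ndarray  # (C, g, g)


@dataclass
class SubregionProbabilityMap:
    """Cellwise softmax probability of the target class, shape (g, g)."""

    p: np.ndarray
    target: int


@dataclass
class DecisiveSummary:
    counts: np.ndarray  # per-image decisive-cell counts
    mean: float
    min: int
    max: int
    total_cells: int

    @property
    def mean_fraction(self) -> float:
        return self.mean / self.total_cells


def subregion_scores(features: FeatureMapStack, heads: list[HeadWeights]) -> SubregionScoreMap:
    """Apply each class's linear head to every cell of the feature grid."""
    k = features.n_channels
    for h in heads:
        if len(h.weights) != k:
            raise ValueError(
                f"head expects {len(h.weights)} channels, feature map has {k}"
            )
    b = np.stack([h.weights for h in heads])  # (C, K)
    b0 = np.array([h.bias for h in heads])
    y = np.einsum("ck,kij->cij", b, features.x) + b0[:, None, None]
    return SubregionScoreMap(y=y)


def subregion_probability(scores: SubregionScoreMap, target: int) -> SubregionProbabilityMap:
    """Cellwise softmax across classes; return the target class slice."""
    y = scores.y
    if y.shape[0] < 2:
        raise ValueError("cellwise softmax requires at least two classes")
    shifted = y - y.max(axis=0, keepdims=True)  # softmax is shift-invariant
    e = np.exp(shifted)
    p = e[target] / e.sum(axis=0)
    return SubregionProbabilityMap(p=p, target=target)


def count_decisive(pmap: SubregionProbabilityMap, tau: float = 0.95) -> int:
    """Number of cells whose target-class probability is >= tau (inclusive)."""
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    return int(np.count_nonzero(pmap.p >= tau))


def influence_heatmap(scores: SubregionScoreMap, target: int) -> np.ndarray:
    """Mean-centred (target minus sum-of-others) score map.

    With many cells contributing positively to the target class, the raw
    difference map is uniformly positive; subtracting its mean leaves the
    cells that are unusually influential. The result always sums to zero.
    """
    y = scores.y
    if y.shape[0] < 2:
        raise ValueError("influence map requires at least two classes")
    others = np.delete(y, target, axis=0).sum(axis=0)
    d = y[target] - others
    return d - d.mean()


def save_heatmap_png(
    heatmap: np.ndarray,
    path,
    image: np.ndarray | None = None,
    cmap: str = "coolwarm",
) -> None:
    """Write an influence heatmap as a PNG, optionally over the image.

    The heatmap grid is upsampled to the image resolution with nearest-
    neighbour interpolation and alpha-blended over the grayscale study.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3), dpi=100)
    extent = None
    if image is not None:
        ax.imshow(image, cmap="gray", vmin=0, vmax=1)
        extent = (0, image.shape[1], image.shape[0], 0)
    limit = float(np.abs(heatmap).max()) or 1.0
    ax.imshow(
        heatmap, cmap=cmap, vmin=-limit, vmax=limit,
        alpha=0.5 if image is not None else 1.0,
        interpolation="nearest", extent=extent,
    )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def summarize_decisive(model, images, target: int, tau: float = 0.95) -> DecisiveSummary:
    """Per-image decisive-subregion counts for a set of images.

    ``model`` must expose ``extract_final_features(image)`` returning a
    (FeatureMapStack, list[HeadWeights]) pair, as the modeling module's
    trained classifiers do.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    counts = []
    total_cells = None
    for img in images:
        features, heads = model.extract_final_features(img)
        pmap = subregion_probability(subregion_scores(features, heads), target)
        counts.append(count_decisive(pmap, tau))
        total_cells = features.grid ** 2
    counts = np.array(counts, dtype=int)
    return DecisiveSummary(
        counts=counts,
        mean=float(counts.mean()),
        min=int(counts.min()),
        max=int(counts.max()),
        total_cells=int(total_cells),
    )
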