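"""Feature normalization and PCA projection ahead of Euclidean-distance ranking.

Concatenated pair vectors mix heterogeneous units (fingerprint bits, substructure
counts, composition fractions), so distances on the raw features are dominated by
whichever block has the widest numeric range.  Features are therefore rescaled
(min-max by default) and decorrelated with PCA before any distance is computed.

Both transforms are fit on the pair population of the partition being ranked and
are fully deterministic; the PCA sign convention (largest-magnitude loading of
each component positive) makes runs bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np

from .dataset_io import PairFeatureBlock

NormMode = Literal["minmax", "zscore"]


@dataclasses.dataclass
class Normalizer:
    """Per-column affine rescaling: x -> (x - offset) * inv_scale.

    minmax mode maps the fitting block's columns onto [0, 1]; constant columns
    map to 0 (inv_scale 0, no division by zero).  New data outside the fitted
    range is extrapolated, never clipped.
    """

    mode: NormMode
    offset: np.ndarray
    inv_scale: np.ndarray

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            "offset": self.offset.tolist(),
            "inv_scale": self.inv_scale.tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "Normalizer":
        return cls(d["mode"], np.asarray(d["offset"]), np.asarray(d["inv_scale"]))


def fit_normalizer(block: PairFeatureBlock, mode: NormMode = "minmax") -> Normalizer:
    if block.n_pairs == 0:
        raise ValueError("cannot fit a normalizer on an empty block")
    x = block.matrix
    if mode == "minmax":
        lo = x.min(axis=0)
        span = x.max(axis=0) - lo
        inv = np.where(span > 0, 1.0 / np.where(span > 0, span, 1.0), 0.0)
        return Normalizer("minmax", lo, inv)
    if mode == "zscore":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        inv = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 0.0)
        return Normalizer("zscore", mu, inv)
    raise ValueError(f"unknown normalization mode {mode!r}")


def apply_normalizer(n: Normalizer, block: PairFeatureBlock) -> PairFeatureBlock:
    if block.matrix.shape[1] != n.offset.shape[0]:
        raise ValueError(
            f"normalizer fitted on {n.offset.shape[0]} features, "
            f"block has {block.matrix.shape[1]}"
        )
    out = (block.matrix - n.offset) * n.inv_scale
    return PairFeatureBlock(block.pairs, out, block.feature_pair_id)


@dataclasses.dataclass
class ProjectionModel:
    """Linear PCA projection: rows map to (row - center) @ components.

    ``components`` has orthonormal columns (one per retained component) chosen as
    the smallest set whose cumulative explained variance reaches the target.
    """

    components: np.ndarray  # (n_features, n_components)
    center: np.ndarray
    explained_variance_ratio: np.ndarray  # over ALL components, non-increasing
    variance_target: float

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def to_json(self) -> dict:
        return {
            "components": self.components.tolist(),
            "center": self.center.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "variance_target": self.variance_target,
        }

    @classmethod
    def from_json(cls, d: dict) -> "ProjectionModel":
        return cls(
            np.asarray(d["components"]),
            np.asarray(d["center"]),
            np.asarray(d["explained_variance_ratio"]),
            d["variance_target"],
        )


def fit_projection(block: PairFeatureBlock, variance_target: float = 0.95) -> ProjectionModel:
    """PCA of the block's rows, keeping the fewest components that explain
    ``variance_target`` of the total variance.

    Component signs are fixed so each component's largest-magnitude loading is
    positive, making the decomposition unique (up to exact eigenvalue ties) and
    runs reproducible.
    """
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    if block.n_pairs < 2:
        raise ValueError("PCA needs at least 2 rows")
    x = block.matrix
    center = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - center, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:  # all rows identical: keep one (zero-variance) component
        ratios = np.zeros(len(var))
        k = 1
    else:
        ratios = var / total
        k = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
        k = min(k, len(ratios))
    comps = vt[:k].T.copy()
    # sign convention: largest-|loading| entry of each component positive
    flip = comps[np.abs(comps).argmax(axis=0), np.arange(k)] < 0
    comps[:, flip] *= -1
    return ProjectionModel(comps, center, ratios, variance_target)


def project(p: ProjectionModel, block: PairFeatureBlock) -> PairFeatureBlock:
    if block.matrix.shape[1] != p.components.shape[0]:
        raise ValueError(
            f"projection fitted on {p.components.shape[0]} features, "
            f"block has {block.matrix.shape[1]}"
        )
    out = (block.matrix - p.center) @ p.components
    return PairFeatureBlock(block.pairs, out, block.feature_pair_id)


def save_models(path: str | Path, normalizer: Normalizer, projection: ProjectionModel) -> None:
    """Persist a fitted normalize+project stage as JSON for run reproducibility."""
    with open(path, "w") as fh:
        json.dump(
            {"normalizer": normalizer.to_json(), "projection": projection.to_json()}, fh
        )


def load_models(path: str | Path) -> tuple[Normalizer, ProjectionModel]:
    with open(path) as fh:
        d = json.load(fh)
    return Normalizer.from_json(d["normalizer"]), ProjectionModel.from_json(d["projection"])
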