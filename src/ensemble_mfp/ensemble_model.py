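"""Per-feature-pair RBF-SVM sub-models and their weighted decision-score fusion.

One soft-margin RBF-kernel SVM is trained per feature pair (libsvm backend via
scikit-learn; defaults c = 2^-4, gamma = 2^-7).  The ensemble score of a pair is
the weighted sum of the sub-models' raw decision values,

    dec = sum_i w_i * dec_i,      w on the probability simplex,

and the weight vector is chosen by exhaustive grid search on the simplex
(default step 0.1, 66 grid points for three sub-models) to maximize validation
AUC.  Because the grid contains the corner vectors, the optimized ensemble can
never do worse on validation than the best individual sub-model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .dataset_io import PairFeatureBlock
from .evaluation import auc

DEFAULT_C = 2.0**-4
DEFAULT_GAMMA = 2.0**-7


@dataclasses.dataclass
class SubModelConfig:
    feature_pair_id: str
    c: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")


@dataclasses.dataclass
class SubModel:
    classifier: SVC
    config: SubModelConfig
    n_features: int
    n_positive: int
    n_negative: int

    @property
    def backend(self) -> str:
        return "sklearn.svm.SVC (libsvm)"


def train_submodel(block: PairFeatureBlock, labels, cfg: SubModelConfig) -> SubModel:
    """Fit one RBF-SVM on +/-1-labeled pair vectors; deterministic for fixed data."""
    y = np.asarray(labels)
    if len(y) != block.n_pairs:
        raise ValueError("labels length does not match block rows")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be +/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes present")
    clf = SVC(kernel="rbf", C=cfg.c, gamma=cfg.gamma)
    clf.fit(block.matrix, y.astype(int))
    return SubModel(
        classifier=clf,
        config=cfg,
        n_features=block.n_features,
        n_positive=int((y == 1).sum()),
        n_negative=int((y == -1).sum()),
    )


@dataclasses.dataclass
class SubModelScores:
    """Raw (signed, uncalibrated) decision values, higher = more interaction-like."""

    pairs: list
    values: np.ndarray
    feature_pair_id: str


def decision_values(m: SubModel, block: PairFeatureBlock) -> SubModelScores:
    if block.n_features != m.n_features:
        raise ValueError(
            f"model trained on {m.n_features} features, block has {block.n_features}"
        )
    if block.n_pairs == 0:
        vals = np.empty(0)
    else:
        vals = np.asarray(m.classifier.decision_function(block.matrix), dtype=float)
    return SubModelScores(list(block.pairs), vals, m.config.feature_pair_id)


def _check_weights(w: Sequence[float]) -> np.ndarray:
    wv = np.asarray(w, dtype=float)
    if (wv < -1e-9).any() or (wv > 1 + 1e-9).any():
        raise ValueError("weights must lie in [0, 1]")
    if abs(wv.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {wv.sum()}")
    return wv


def ensemble_decision(w: Sequence[float], scores: Sequence[SubModelScores]) -> np.ndarray:
    """Fuse sub-model decision vectors: dec_k = sum_i w_i * dec_{i,k}."""
    wv = _check_weights(w)
    if len(scores) != len(wv):
        raise ValueError(f"{len(wv)} weights but {len(scores)} score vectors")
    ref = scores[0].pairs
    for s in scores[1:]:
        if s.pairs != ref:
            raise ValueError("sub-model score vectors cover different pairs or orders")
    return sum(wi * s.values for wi, s in zip(wv, scores))


def enumerate_weight_grid(step: float, n_components: int = 3) -> list[tuple[float, ...]]:
    """All simplex points with coordinates that are multiples of ``step``.

    Enumeration order is w1 ascending, then w2 ascending (w3 determined); ties
    during optimization resolve to the first point in this order.
    """
    if not (0.0 < step <= 1.0):
        raise ValueError("step must lie in (0, 1]")
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    if n_components < 2:
        raise ValueError("grid needs at least 2 components")

    def compositions(total: int, parts: int) -> list[tuple[int, ...]]:
        if parts == 1:
            return [(total,)]
        return [(i, *rest) for i in range(total + 1) for rest in compositions(total - i, parts - 1)]

    return [tuple(i / k for i in c) for c in compositions(k, n_components)]


def optimize_weights(
    scores: Sequence[SubModelScores], labels, step: float = 0.1
) -> tuple[tuple[float, ...], float]:
    """Exhaustive simplex grid search for the weights maximizing validation AUC.

    Returns (best weight vector, its AUC).  Strictly-greater comparison keeps
    the first grid point on ties.
    """
    if len(scores) < 2:
        raise ValueError("weight optimization needs at least 2 sub-models")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("validation labels must contain both classes")
    best_w: tuple[float, ...] | None = None
    best_auc = -np.inf
    for w in enumerate_weight_grid(step, n_components=len(scores)):
        a = auc(ensemble_decision(w, scores), y)
        if a > best_auc:
            best_auc, best_w = a, w
    assert best_w is not None
    return best_w, float(best_auc)
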