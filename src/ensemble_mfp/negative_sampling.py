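"""Reliable-negative selection for the positive-unlabeled setting.

Interaction databases record positives only, so training negatives must be
inferred.  The heuristic here: unlabeled pairs far (in Euclidean distance,
after normalization and PCA) from the centroid of the positive pairs are the
most reliable non-interactions,

    Dis = sqrt( sum_j (pos_center_j - x_j)^2 ),

and the top of the descending-Dis ranking is taken as the negative set.

Each feature pair induces its own ranking.  For validation/test partitions the
per-feature-pair selections are merged into a union pool (U-vali / U-test) and
balanced negatives are drawn from it at random, which decouples the evaluation
negatives from any single feature pair's geometry.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset_io import Pair, PairFeatureBlock


def positive_centroid(positives: PairFeatureBlock) -> np.ndarray:
    """Arithmetic mean of the positive pair vectors (the positive center)."""
    if positives.n_pairs == 0:
        raise ValueError("no positive pairs: cannot compute a positive centroid")
    return positives.matrix.mean(axis=0)


@dataclasses.dataclass
class DistanceRanking:
    """Unlabeled pairs ordered by descending distance from the positive centroid.

    Ties are broken by ascending (drug_id, target_id) so rankings are
    deterministic.
    """

    pairs: list[Pair]  # descending Dis order
    distances: np.ndarray  # aligned with pairs

    def __len__(self) -> int:
        return len(self.pairs)


def distance_rank(unlabeled: PairFeatureBlock, centroid: np.ndarray) -> DistanceRanking:
    centroid = np.asarray(centroid, dtype=float)
    if unlabeled.matrix.shape[1] != centroid.shape[0]:
        raise ValueError(
            f"centroid dimension {centroid.shape[0]} does not match "
            f"block dimension {unlabeled.matrix.shape[1]}"
        )
    dis = np.sqrt(((unlabeled.matrix - centroid) ** 2).sum(axis=1))
    drugs = np.array([p[0] for p in unlabeled.pairs])
    targets = np.array([p[1] for p in unlabeled.pairs])
    # lexsort: last key is primary; descending distance, then ascending pair id
    order = np.lexsort((targets, drugs, -dis))
    return DistanceRanking([unlabeled.pairs[i] for i in order], dis[order])


def select_negatives(r: DistanceRanking, n: int) -> list[Pair]:
    """Top-n most distant unlabeled pairs, i.e. the n most reliable negatives."""
    if n < 1:
        raise ValueError("must select at least one negative")
    if n > len(r):
        raise ValueError(f"requested {n} negatives but only {len(r)} unlabeled pairs ranked")
    return list(r.pairs[:n])


@dataclasses.dataclass
class CandidateNegativePool:
    """Union of per-feature-pair negative selections for one partition.

    ``provenance`` records which feature pair(s) selected each member.  The
    member list is sorted lexicographically so downstream random draws depend
    only on the seed, not on insertion order.
    """

    pairs: list[Pair]
    provenance: dict[Pair, list[str]]

    def __len__(self) -> int:
        return len(self.pairs)


def build_union_pool(selections: Mapping[str, Sequence[Pair]]) -> CandidateNegativePool:
    if not selections:
        raise ValueError("need at least one per-feature-pair selection")
    provenance: dict[Pair, list[str]] = {}
    for fp_id in sorted(selections):
        for p in selections[fp_id]:
            provenance.setdefault(p, []).append(fp_id)
    return CandidateNegativePool(sorted(provenance), provenance)


def sample_from_pool(pool: CandidateNegativePool, n: int, seed: int) -> list[Pair]:
    """Uniform draw of n pairs without replacement, reproducible by seed."""
    if n > len(pool):
        raise ValueError(f"requested {n} negatives but pool holds only {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool.pairs[i] for i in idx]


def write_pool_tsv(
    pool: CandidateNegativePool,
    distances: Mapping[Pair, float],
    partition: str,
    path: str | Path,
) -> None:
    """Export a pool as TSV: drug_id, target_id, Dis, selected_by, partition."""
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tDis\tselected_by\tpartition\n")
        for p in pool.pairs:
            dis = distances.get(p, float("nan"))
            fh.write(
                f"{p[0]}\t{p[1]}\t{dis:.6g}\t{';'.join(pool.provenance[p])}\t{partition}\n"
            )
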