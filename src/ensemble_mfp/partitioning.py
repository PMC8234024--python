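"""Cold-start train/validation/test splits by entity.

To evaluate prediction for *new* drugs, whole drugs (or, symmetrically, whole
targets) are assigned to a role, and every pair of an entity inherits its
entity's role -- so no test drug is ever seen in training.  The default scheme
is repeated random 60/20/20 entity splits; a strict 5-fold rotation is also
provided for users who prefer fold-based evaluation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .dataset_io import PairLabelIndex

Role = Literal["train", "validation", "test"]
SplitMode = Literal["by_drug", "by_target"]

ROLES: tuple[Role, ...] = ("train", "validation", "test")


@dataclasses.dataclass
class SplitAssignment:
    roles: dict[str, Role]  # entity id -> role
    mode: SplitMode
    seed: int

    def ids_for(self, role: Role) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [e for e, r in self.roles.items() if r == role]


def split_by_entity(
    ids: Sequence[str],
    ratios: tuple[float, float, float],
    seed: int,
    mode: SplitMode = "by_drug",
) -> SplitAssignment:
    """Randomly assign entities to train/validation/test at the given ratios.

    The seeded permutation is cut at floor boundaries for validation and test;
    the remainder goes to train (the largest bucket).
    """
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 entities to split, got {n}")
    if any(r <= 0 for r in ratios):
        raise ValueError("all ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n_vali = math.floor(ratios[1] * n)
    n_test = math.floor(ratios[2] * n)
    n_train = n - n_vali - n_test
    perm = np.random.default_rng(seed).permutation(n)
    roles: dict[str, Role] = {}
    for k, i in enumerate(perm):
        if k < n_train:
            roles[ids[i]] = "train"
        elif k < n_train + n_vali:
            roles[ids[i]] = "validation"
        else:
            roles[ids[i]] = "test"
    return SplitAssignment(roles, mode, seed)


def restrict_pairs(idx: PairLabelIndex, a: SplitAssignment, role: Role) -> PairLabelIndex:
    """Pairs whose split-axis entity carries the given role; labels preserved."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    axis = 0 if a.mode == "by_drug" else 1
    missing = sorted({p[axis] for p in idx.pairs} - a.roles.keys())
    if missing:
        raise ValueError(f"assignment does not cover entities: {missing[:10]}")
    mask = np.array([a.roles[p[axis]] == role for p in idx.pairs])
    return idx.subset(mask)


def make_repeats(
    ids: Sequence[str],
    ratios: tuple[float, float, float],
    n_repeats: int,
    base_seed: int,
    mode: SplitMode = "by_drug",
) -> list[SplitAssignment]:
    """Independent splits for repeated experiments, seeds base_seed .. base_seed+n-1."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return [split_by_entity(ids, ratios, base_seed + k, mode) for k in range(n_repeats)]


def make_folds(ids: Sequence[str], seed: int, mode: SplitMode = "by_drug") -> list[SplitAssignment]:
    """Strict 5-fold rotation: fold k is the test slice, fold k+1 validation,
    the remaining three train.  One seeded permutation is shared by all folds."""
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 entities for 5-fold rotation, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    bounds = [round(f * n / 5) for f in range(6)]
    slices = [perm[bounds[f] : bounds[f + 1]] for f in range(5)]
    out = []
    for f in range(5):
        roles: dict[str, Role] = {ids[i]: "train" for i in perm}
        for i in slices[f]:
            roles[ids[i]] = "test"
        for i in slices[(f + 1) % 5]:
            roles[ids[i]] = "validation"
        out.append(SplitAssignment(roles, mode, seed))
    return out


def write_assignment_tsv(a: SplitAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\trole\tseed\tmode\n")
        for e in sorted(a.roles):
            fh.write(f"{e}\t{a.roles[e]}\t{a.seed}\t{a.mode}\n")
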