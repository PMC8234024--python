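"""Readers, writers and containers for interaction matrices and descriptor tables.

The interaction matrix is the binary drug-target adjacency of a chemogenomic
benchmark: a TSV with one header row of column IDs and one leading column of
row IDs, every body cell 0 or 1.  Descriptor tables hold one precomputed
numeric descriptor vector per entity (drug fingerprints, protein sequence
composition features, ...); descriptor computation itself happens upstream and
is consumed here as given.

A drug-target *pair* is labeled positive when its matrix cell is 1 and
unlabeled otherwise -- there are no verified negatives, which is what makes
the downstream problem positive-unlabeled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

Pair = tuple[str, str]

POSITIVE = "positive"
UNLABELED = "unlabeled"


class ValidationError(ValueError):
    """An input violates a structural contract (duplicate IDs, non-binary cell, ...)."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValidationError(f"duplicate {axis} IDs: {dupes[:10]}")


@dataclasses.dataclass
class InteractionMatrix:
    """Dense 0/1 adjacency, stored drug-major regardless of file orientation."""

    drug_ids: list[str]
    target_ids: list[str]
    values: np.ndarray  # shape (n_drugs, n_targets), dtype int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.target_ids)} targets"
            )
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at drug {self.drug_ids[bad[0]]!r}, "
                f"target {self.target_ids[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class DescriptorTable:
    """One numeric descriptor vector per entity (row)."""

    entity_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_entities, n_features), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.entity_ids),
            len(self.feature_names),
        ):
            raise ValidationError("descriptor table shape mismatch")
        if len(self.feature_names) == 0:
            raise ValidationError("descriptor table has zero feature columns")
        _check_unique(self.entity_ids, "entity")
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-numeric value at entity {self.entity_ids[r]!r}, "
                f"column {self.feature_names[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {e: i for i, e in enumerate(self.entity_ids)}
        missing = sorted({i for i in ids if i not in index})
        if missing:
            raise ValidationError(f"unknown entity IDs: {missing[:10]}")
        return self.values[[index[i] for i in ids]]


@dataclasses.dataclass
class PairLabelIndex:
    """Every (drug, target) pair of a matrix with its positive/unlabeled label."""

    pairs: list[Pair]
    labels: np.ndarray  # bool, True = positive

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.pairs) != len(self.labels):
            raise ValidationError("pairs/labels length mismatch")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_unlabeled(self) -> int:
        return len(self.pairs) - self.n_positive

    def subset(self, mask: np.ndarray) -> "PairLabelIndex":
        mask = np.asarray(mask, dtype=bool)
        return PairLabelIndex(
            [p for p, m in zip(self.pairs, mask) if m], self.labels[mask]
        )

    def positives(self) -> list[Pair]:
        return [p for p, m in zip(self.pairs, self.labels) if m]

    def unlabeled(self) -> list[Pair]:
        return [p for p, m in zip(self.pairs, self.labels) if not m]


@dataclasses.dataclass
class PairFeatureBlock:
    """Concatenated [drug descriptor | target descriptor] vectors, one row per pair."""

    pairs: list[Pair]
    matrix: np.ndarray  # shape (n_pairs, d_drug + d_target)
    feature_pair_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.pairs):
            raise ValidationError("pair feature block shape mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


Orientation = Literal["drugs_in_rows", "targets_in_rows"]


def read_interaction_matrix(
    path: str | Path, orientation: Orientation = "targets_in_rows"
) -> InteractionMatrix:
    """Read a TSV adjacency file into a drug-major :class:`InteractionMatrix`.

    ``orientation`` names what the file's *rows* are.  The benchmark downloads
    do not state row/column roles, so the flag is explicit; pass
    ``drugs_in_rows`` if your file lists drugs down the first column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    cells = df.to_numpy()
    parsed = np.empty(cells.shape, dtype=np.int8)
    for v, out in (("0", 0), ("1", 1)):
        parsed[cells == v] = out
    bad = ~np.isin(cells, ("0", "1"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary cell {cells[r, c]!r} at row {row_ids[r]!r}, "
            f"column {col_ids[c]!r} in {path}"
        )
    if orientation == "drugs_in_rows":
        return InteractionMatrix(row_ids, col_ids, parsed)
    if orientation == "targets_in_rows":
        return InteractionMatrix(col_ids, row_ids, parsed.T)
    raise ValueError(f"unknown orientation {orientation!r}")


def write_interaction_matrix(
    m: InteractionMatrix, path: str | Path, orientation: Orientation = "targets_in_rows"
) -> None:
    """Write the TSV mirror of :func:`read_interaction_matrix` (bit-exact round trip)."""
    if orientation == "drugs_in_rows":
        df = pd.DataFrame(m.values, index=m.drug_ids, columns=m.target_ids)
    else:
        df = pd.DataFrame(m.values.T, index=m.target_ids, columns=m.drug_ids)
    df.to_csv(path, sep="\t")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a CSV/TSV descriptor table (delimiter chosen by extension).

    First column is the entity ID; every remaining cell must parse as a
    finite number.  A missing or non-numeric cell raises
    :class:`ValidationError` naming its coordinates.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: descriptor table has zero feature columns")
    ids = [str(i) for i in df.index]
    names = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(numeric).all():
        r, c = np.argwhere(~np.isfinite(numeric))[0]
        raise ValidationError(
            f"{path}: missing/non-numeric cell at entity {ids[r]!r}, column {names[c]!r}"
        )
    return DescriptorTable(ids, names, numeric)


def write_descriptor_table(t: DescriptorTable, path: str | Path) -> None:
    df = pd.DataFrame(t.values, index=t.entity_ids, columns=t.feature_names)
    df.to_csv(path, sep=_sep_for(path))


def enumerate_pairs(m: InteractionMatrix) -> PairLabelIndex:
    """Enumerate all |drugs| x |targets| pairs in drug-major order.

    Positives are the 1-cells; everything else is unlabeled, so
    ``n_positive + n_unlabeled == n_drugs * n_targets`` always.
    """
    pairs = [(d, t) for d in m.drug_ids for t in m.target_ids]
    labels = m.values.reshape(-1).astype(bool)
    return PairLabelIndex(pairs, labels)


def assemble_pair_vectors(
    idx: PairLabelIndex,
    drugs: DescriptorTable,
    targets: DescriptorTable,
    feature_pair_id: str,
) -> PairFeatureBlock:
    """Concatenate drug and target descriptor vectors row-wise per pair."""
    if len(idx.pairs) == 0:
        return PairFeatureBlock(
            [], np.empty((0, drugs.n_features + targets.n_features)), feature_pair_id
        )
    d_rows = drugs.rows_for([p[0] for p in idx.pairs])
    t_rows = targets.rows_for([p[1] for p in idx.pairs])
    return PairFeatureBlock(list(idx.pairs), np.hstack([d_rows, t_rows]), feature_pair_id)
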