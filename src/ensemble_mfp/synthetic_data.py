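"""Synthetic drug-target benchmarks with planted geometry.

Real gold-standard benchmarks pair a binary interaction matrix with externally
computed descriptor tables (drug fingerprints / substructure counts; protein
sequence-composition features).  This module emulates that input bundle with a
known ground truth so every pipeline stage -- distance ranking, union pools,
cold-start splits, ensemble fusion -- can be tested end to end without
downloads.

Geometry.  Entities are either *core* or *outlier*.  Core entities share a
per-feature-pair base descriptor profile plus small noise, so every pair of
core entities (including all positives) clusters near one centroid in
concatenated pair-vector space.  Outlier entities carry an additional offset,
calibrated per descriptor block so that a pair of two outlier entities sits at
approximately ``separation`` times the core cloud's RMS radius from the
centroid.  The planted reliable negatives are exactly the outlier-drug x
outlier-target pairs; with a comfortable separation they are the top of every
feature pair's distance ranking.  All remaining unlabeled pairs are
"ambiguous": near (core x core) or between (mixed) the two clouds.

Descriptor realism is kept at the level of column *types*: two drug tables are
fingerprint-like 0/1 blocks, the third holds small substructure counts, and
all target tables are simplex-normalized composition vectors -- so min-max
normalization is exercised on genuinely heterogeneous units.  Each feature
pair draws its own base profiles, noise and offset columns, giving the three
sub-models correlated but non-identical views of the same truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np

from .dataset_io import (
    DescriptorTable,
    InteractionMatrix,
    Pair,
    write_descriptor_table,
    write_interaction_matrix,
)

#: descriptor dimensions (drug, target) per feature pair, mirroring the three
#: standard fingerprint/composition combinations
DEFAULT_DIMS: dict[str, tuple[int, int]] = {
    "fp1": (79, 20),
    "fp2": (166, 80),
    "fp3": (307, 160),
}

#: drug-block column type per feature pair position (cycled for custom dims)
_DRUG_KINDS = ("binary", "binary", "count")

_FLIP_RATE = 0.02  # per-column bit-flip / count-jitter probability of core noise


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark.

    ``separation`` is the distance of the planted-negative cloud from the
    positive centroid in multiples of the core cloud's RMS radius (the noise
    scale); at the default 5 the planted pairs are unambiguously the farthest
    unlabeled pairs.  ``label_noise`` relocates that fraction of positives to
    uniformly random non-planted cells, breaking their geometric coherence.
    """

    n_drugs: int = 54
    n_targets: int = 26
    n_positives: int = 90
    dims: Mapping[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DIMS)
    )
    separation: float = 5.0
    label_noise: float = 0.0
    seed: int = 0
    outlier_drug_frac: float = 0.15
    outlier_target_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must lie in [0, 1]")
        for fp, (dd, dt) in self.dims.items():
            if dd < 1 or dt < 1:
                raise ValueError(f"{fp}: descriptor dims must be positive")
        n_od = self._n_outlier(self.n_drugs, self.outlier_drug_frac)
        n_ot = self._n_outlier(self.n_targets, self.outlier_target_frac)
        core_cells = (self.n_drugs - n_od) * (self.n_targets - n_ot)
        if self.n_positives < 1 or self.n_positives > core_cells:
            raise ValueError(
                f"n_positives={self.n_positives} infeasible: only {core_cells} "
                "core drug x core target cells available"
            )

    @staticmethod
    def _n_outlier(n: int, frac: float) -> int:
        return min(n - 2, max(1, round(frac * n)))

    @property
    def n_outlier_drugs(self) -> int:
        return self._n_outlier(self.n_drugs, self.outlier_drug_frac)

    @property
    def n_outlier_targets(self) -> int:
        return self._n_outlier(self.n_targets, self.outlier_target_frac)


def tiny_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Small fast profile (12 drugs x 8 targets, 8/4-dimensional descriptors)."""
    kw = dict(
        n_drugs=12,
        n_targets=8,
        n_positives=20,
        dims={"fp1": (8, 4), "fp2": (8, 4), "fp3": (8, 4)},
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


@dataclasses.dataclass
class SyntheticTruth:
    planted_negatives: list[Pair]
    ambiguous_unlabeled: list[Pair]
    outlier_drugs: list[str]
    outlier_targets: list[str]
    spec: SyntheticSpec

    def to_json(self) -> dict:
        return {
            "planted_negatives": [list(p) for p in self.planted_negatives],
            "ambiguous_unlabeled": [list(p) for p in self.ambiguous_unlabeled],
            "outlier_drugs": self.outlier_drugs,
            "outlier_targets": self.outlier_targets,
            "spec": {
                **{
                    f.name: getattr(self.spec, f.name)
                    for f in dataclasses.fields(self.spec)
                    if f.name != "dims"
                },
                "dims": {k: list(v) for k, v in self.spec.dims.items()},
            },
        }


@dataclasses.dataclass
class SyntheticBenchmark:
    """The full input bundle: interactions + per-feature-pair descriptor tables."""

    interactions: InteractionMatrix
    drug_tables: dict[str, DescriptorTable]
    target_tables: dict[str, DescriptorTable]
    truth: SyntheticTruth

    @property
    def feature_pair_ids(self) -> list[str]:
        return sorted(self.drug_tables)


def _binary_block(
    rng: np.random.Generator, ids: list[str], dim: int, outliers: set[str], sep: float
) -> np.ndarray:
    """Fingerprint-like 0/1 block: shared base pattern, flip-noise, and for
    outliers an extra flip on m columns with m ~ sep^2 * (core flip variance)."""
    base = (rng.random(dim) < 0.3).astype(float)
    eps = _FLIP_RATE
    m = math.ceil(sep**2 * dim * eps * (1 - eps) / (1 - 2 * eps) ** 2)
    m = min(m, dim)
    offset_cols = rng.choice(dim, size=m, replace=False) if m > 0 else np.empty(0, int)
    rows = np.empty((len(ids), dim))
    for i, e in enumerate(ids):
        v = base.copy()
        if e in outliers:
            v[offset_cols] = 1.0 - v[offset_cols]
        noise = rng.random(dim) < eps
        v[noise] = 1.0 - v[noise]
        rows[i] = v
    return rows


def _count_block(
    rng: np.random.Generator, ids: list[str], dim: int, outliers: set[str], sep: float
) -> np.ndarray:
    """Substructure-count-like block: small integer base counts with +/-1
    jitter; outliers add +3 on m columns.

    m is calibrated for the *min-max-normalized* geometry: an offset column's
    range becomes h+2 (jitter plus offset h=3) while pure-jitter columns span
    2, so the normalized offset is h/(h+2) per column against a normalized
    noise radius of ~ sqrt(dim * eps / 2)."""
    base = rng.integers(0, 4, size=dim).astype(float)
    eps = _FLIP_RATE
    h = 3.0
    m = math.ceil(sep**2 * (dim * eps / 2.0) * (h + 2.0) ** 2 / h**2)
    m = min(m, dim)
    offset_cols = rng.choice(dim, size=m, replace=False) if m > 0 else np.empty(0, int)
    rows = np.empty((len(ids), dim))
    for i, e in enumerate(ids):
        v = base + rng.choice([-1.0, 0.0, 1.0], size=dim, p=[eps, 1 - 2 * eps, eps])
        if e in outliers:
            v[offset_cols] += h
        rows[i] = np.clip(v, 0.0, None)
    return rows


def _composition_block(
    rng: np.random.Generator, ids: list[str], dim: int, outliers: set[str], sep: float
) -> np.ndarray:
    """Composition-like block: every row lies on the probability simplex.

    Core rows mix a base composition p with flat-Dirichlet noise,
    (1-lam)*p + lam*r; outlier rows use a shifted base p + o instead.  The
    offset o has equal magnitude in every column (alternating sign, summing
    to zero), i.e. proportional to the roughly uniform per-column noise scale
    of the flat Dirichlet -- so per-column min-max rescaling preserves the
    offset-to-noise ratio, which is calibrated to ``sep``.  The noise weight
    lam shrinks as 1/sep so the shifted base stays on the simplex.
    """
    p = 0.5 * rng.dirichlet(np.ones(dim)) + 0.5 / dim  # entries >= 1/(2 dim)
    lam = min(0.3, 0.5 / max(sep, 1.0))
    # flat-Dirichlet per-column variance; ~1/dim^2 in every column
    noise_radius = lam * math.sqrt((dim - 1) / (dim * (dim + 1)))
    a = sep * noise_radius / math.sqrt(dim)  # per-column offset magnitude
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(dim)])
    if dim % 2 == 1:
        signs[-1] = 0.0  # keep the offset summing to zero
    offset = a * signs
    q = np.clip(p + offset, 1e-9, None)
    q /= q.sum()
    rows = np.empty((len(ids), dim))
    for i, e in enumerate(ids):
        center = q if e in outliers else p
        rows[i] = (1.0 - lam) * center + lam * rng.dirichlet(np.ones(dim))
    return rows


def generate_benchmark(spec: SyntheticSpec) -> SyntheticBenchmark:
    """Generate a complete benchmark; bitwise reproducible for a given spec."""
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    target_ids = [f"T{i:04d}" for i in range(spec.n_targets)]

    od = sorted(rng.choice(spec.n_drugs, size=spec.n_outlier_drugs, replace=False))
    ot = sorted(rng.choice(spec.n_targets, size=spec.n_outlier_targets, replace=False))
    outlier_drugs = [drug_ids[i] for i in od]
    outlier_targets = [target_ids[i] for i in ot]
    core_d = [i for i in range(spec.n_drugs) if i not in set(od)]
    core_t = [i for i in range(spec.n_targets) if i not in set(ot)]

    # positives live on core x core cells
    core_cells = [(i, j) for i in core_d for j in core_t]
    chosen = rng.choice(len(core_cells), size=spec.n_positives, replace=False)
    values = np.zeros((spec.n_drugs, spec.n_targets), dtype=np.int8)
    for k in chosen:
        values[core_cells[k]] = 1

    # label noise: relocate a fraction of positives to random non-planted cells
    n_noisy = round(spec.label_noise * spec.n_positives)
    if n_noisy > 0:
        planted_cells = {(i, j) for i in od for j in ot}
        pos_cells = list(map(tuple, np.argwhere(values == 1)))
        move = rng.choice(len(pos_cells), size=n_noisy, replace=False)
        free = [
            (i, j)
            for i in range(spec.n_drugs)
            for j in range(spec.n_targets)
            if values[i, j] == 0 and (i, j) not in planted_cells
        ]
        dest = rng.choice(len(free), size=n_noisy, replace=False)
        for k_src, k_dst in zip(move, dest):
            values[pos_cells[k_src]] = 0
            values[free[k_dst]] = 1

    interactions = InteractionMatrix(drug_ids, target_ids, values)

    out_d, out_t = set(outlier_drugs), set(outlier_targets)
    drug_tables: dict[str, DescriptorTable] = {}
    target_tables: dict[str, DescriptorTable] = {}
    for pos, fp_id in enumerate(sorted(spec.dims)):
        dd, dt = spec.dims[fp_id]
        kind = _DRUG_KINDS[pos % len(_DRUG_KINDS)]
        maker = _binary_block if kind == "binary" else _count_block
        d_rows = maker(rng, drug_ids, dd, out_d, spec.separation)
        t_rows = _composition_block(rng, target_ids, dt, out_t, spec.separation)
        drug_tables[fp_id] = DescriptorTable(
            list(drug_ids), [f"{fp_id}_d{j}" for j in range(dd)], d_rows
        )
        target_tables[fp_id] = DescriptorTable(
            list(target_ids), [f"{fp_id}_t{j}" for j in range(dt)], t_rows
        )

    planted = [(d, t) for d in outlier_drugs for t in outlier_targets]
    planted_set = set(planted)
    ambiguous = [
        (drug_ids[i], target_ids[j])
        for i in range(spec.n_drugs)
        for j in range(spec.n_targets)
        if values[i, j] == 0 and (drug_ids[i], target_ids[j]) not in planted_set
    ]
    truth = SyntheticTruth(planted, ambiguous, outlier_drugs, outlier_targets, spec)
    return SyntheticBenchmark(interactions, drug_tables, target_tables, truth)


def degrade_feature_pair(
    benchmark: SyntheticBenchmark,
    feature_pair_id: str,
    signal_fraction: float,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Convexly mix one feature pair's descriptors with column-shuffled noise.

    ``signal_fraction`` 1 returns the benchmark unchanged; 0 destroys every
    entity-level association in that feature pair (marginals preserved), so
    its sub-model carries no signal.  Other feature pairs are untouched.
    """
    if feature_pair_id not in benchmark.drug_tables:
        raise ValueError(f"unknown feature pair {feature_pair_id!r}")
    if not (0.0 <= signal_fraction <= 1.0):
        raise ValueError("signal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def mix(table: DescriptorTable) -> DescriptorTable:
        x = table.values
        noise = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        return DescriptorTable(
            list(table.entity_ids),
            list(table.feature_names),
            signal_fraction * x + (1.0 - signal_fraction) * noise,
        )

    drug_tables = dict(benchmark.drug_tables)
    target_tables = dict(benchmark.target_tables)
    drug_tables[feature_pair_id] = mix(benchmark.drug_tables[feature_pair_id])
    target_tables[feature_pair_id] = mix(benchmark.target_tables[feature_pair_id])
    return SyntheticBenchmark(
        benchmark.interactions, drug_tables, target_tables, benchmark.truth
    )


def write_benchmark(benchmark: SyntheticBenchmark, out_dir: str | Path) -> None:
    """Write the benchmark in the same TSV/CSV formats the readers consume,
    plus the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_interaction_matrix(benchmark.interactions, out / "interactions.tsv")
    for fp_id in benchmark.feature_pair_ids:
        write_descriptor_table(benchmark.drug_tables[fp_id], out / f"drugs_{fp_id}.csv")
        write_descriptor_table(benchmark.target_tables[fp_id], out / f"targets_{fp_id}.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(benchmark.truth.to_json(), fh, indent=2)
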