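"""End-to-end orchestration: split, sample, train, fuse, optimize, evaluate.

One repeat of the experiment runs the full flow on a cold-start entity split:

1. split entities 60/20/20 into train/validation/test (by drug by default);
2. per feature pair, rank the training partition's unlabeled pairs by distance
   from the training-positive centroid (after per-partition normalization and
   PCA) and train an RBF-SVM on the positives plus the top-ranked negatives;
3. for validation and test partitions, build the union pool of the three
   feature pairs' distance-selected negatives (U-vali / U-test) and draw a
   balanced random negative sample from it;
4. optimize the simplex weight vector on validation AUC and apply the frozen
   weights to the test partition.

The `random` negative strategy replaces every distance-based selection with a
uniform draw from the partition's unlabeled pairs (same counts, same seeds),
giving the random-sampling baseline for comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import yaml

from . import negative_sampling as ns
from . import partitioning as pt
from .dataset_io import (
    DescriptorTable,
    InteractionMatrix,
    Pair,
    PairFeatureBlock,
    PairLabelIndex,
    assemble_pair_vectors,
    enumerate_pairs,
    read_descriptor_table,
    read_interaction_matrix,
)
from .ensemble_model import (
    DEFAULT_C,
    DEFAULT_GAMMA,
    SubModelConfig,
    SubModelScores,
    decision_values,
    ensemble_decision,
    optimize_weights,
    train_submodel,
)
from .evaluation import auc, basic_metrics, confusion_counts
from .preprocessing import apply_normalizer, fit_normalizer, fit_projection, project
from .synthetic_data import SyntheticBenchmark, SyntheticSpec, generate_benchmark

NegativeStrategy = Literal["euclidean", "random"]


@dataclasses.dataclass
class DTIDataset:
    """Interaction matrix plus one drug and one target descriptor table per
    feature pair."""

    interactions: InteractionMatrix
    drug_tables: dict[str, DescriptorTable]
    target_tables: dict[str, DescriptorTable]

    def __post_init__(self) -> None:
        if sorted(self.drug_tables) != sorted(self.target_tables):
            raise ValueError("drug and target tables must cover the same feature pairs")

    @property
    def feature_pair_ids(self) -> list[str]:
        return sorted(self.drug_tables)

    @classmethod
    def from_benchmark(cls, b: SyntheticBenchmark) -> "DTIDataset":
        return cls(b.interactions, dict(b.drug_tables), dict(b.target_tables))

    @classmethod
    def from_files(
        cls,
        interaction_path: str | Path,
        drug_paths: Mapping[str, str | Path],
        target_paths: Mapping[str, str | Path],
        orientation: str = "targets_in_rows",
    ) -> "DTIDataset":
        return cls(
            read_interaction_matrix(interaction_path, orientation),  # type: ignore[arg-type]
            {k: read_descriptor_table(p) for k, p in drug_paths.items()},
            {k: read_descriptor_table(p) for k, p in target_paths.items()},
        )


@dataclasses.dataclass
class RunConfig:
    interaction_path: str | None = None
    drug_descriptor_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    target_descriptor_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    orientation: str = "targets_in_rows"
    synthetic: SyntheticSpec | None = None
    split_mode: pt.SplitMode = "by_drug"
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    negative_strategy: NegativeStrategy = "euclidean"
    weight_step: float = 0.1
    c: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    threshold: float = 0.0
    variance_target: float = 0.95
    train_negative_ratio: float = 1.0
    normalization: str = "minmax"
    n_repeats: int = 1
    base_seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["dims"] = {k: list(v) for k, v in self.synthetic.dims.items()}
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "dims" in syn:
                syn["dims"] = {k: tuple(v) for k, v in syn["dims"].items()}
            raw["synthetic"] = SyntheticSpec(**syn)
        if "ratios" in raw:
            raw["ratios"] = tuple(raw["ratios"])
        return cls(**raw)


class RepeatError(RuntimeError):
    """A repeat could not be completed (e.g. a partition without positives)."""


def _derived_seed(base: int, *tags: int) -> int:
    return int(np.random.SeedSequence([base, *tags]).generate_state(1)[0] % (2**31))


def _euclidean_selection(
    block: PairFeatureBlock,
    labels: np.ndarray,
    n: int,
    variance_target: float,
    normalization: str,
) -> list[Pair]:
    """Normalize -> PCA -> centroid of positives -> top-n most distant unlabeled."""
    norm = fit_normalizer(block, normalization)  # type: ignore[arg-type]
    normed = apply_normalizer(norm, block)
    proj = fit_projection(normed, variance_target)
    projected = project(proj, normed)
    pos = PairFeatureBlock(
        [p for p, m in zip(projected.pairs, labels) if m],
        projected.matrix[labels],
        projected.feature_pair_id,
    )
    unl = PairFeatureBlock(
        [p for p, m in zip(projected.pairs, labels) if not m],
        projected.matrix[~labels],
        projected.feature_pair_id,
    )
    centroid = ns.positive_centroid(pos)
    ranking = ns.distance_rank(unl, centroid)
    return ns.select_negatives(ranking, n)


def _random_selection(idx: PairLabelIndex, n: int, seed: int) -> list[Pair]:
    unl = sorted(idx.unlabeled())
    if n > len(unl):
        raise RepeatError(f"requested {n} random negatives from {len(unl)} unlabeled pairs")
    rng = np.random.default_rng(seed)
    return [unl[i] for i in rng.choice(len(unl), size=n, replace=False)]


def _eval_index(positives: list[Pair], negatives: list[Pair]) -> PairLabelIndex:
    return PairLabelIndex(
        positives + negatives,
        np.r_[np.ones(len(positives), bool), np.zeros(len(negatives), bool)],
    )


@dataclasses.dataclass
class SamplePlan:
    """The complete sample selection of one repeat: per-feature-pair training
    negatives plus the validation/test evaluation pair sets.

    Re-running a repeat under a plan holds every positive and negative sample
    fixed, which is how controlled arm comparisons (ensemble vs individual,
    intact vs degraded features) are made: only the features and models vary,
    never the data points."""

    train_negatives: dict[str, list[Pair]]
    validation_pairs: PairLabelIndex
    test_pairs: PairLabelIndex
    pool_sizes: dict[str, int]


def run_single_repeat(
    data: DTIDataset, cfg: RunConfig, seed: int, plan: SamplePlan | None = None
) -> dict[str, Any]:
    """One complete split/train/optimize/test cycle; returns a flat record.

    With ``plan`` given, all negative selections and evaluation sets are taken
    from the plan instead of being recomputed from ``data``."""
    fp_ids = data.feature_pair_ids
    m = data.interactions
    entity_ids = m.drug_ids if cfg.split_mode == "by_drug" else m.target_ids
    assignment = pt.split_by_entity(entity_ids, cfg.ratios, seed, cfg.split_mode)
    full_idx = enumerate_pairs(m)
    parts = {role: pt.restrict_pairs(full_idx, assignment, role) for role in pt.ROLES}
    for role, idx in parts.items():
        if idx.n_positive == 0:
            raise RepeatError(f"{role} partition has no positive pairs (seed {seed})")
        if idx.n_unlabeled == 0:
            raise RepeatError(f"{role} partition has no unlabeled pairs (seed {seed})")

    # --- training: per-feature-pair negatives, one sub-model each -------------
    train_idx = parts["train"]
    n_train_neg = max(1, round(cfg.train_negative_ratio * train_idx.n_positive))
    models = {}
    train_normalizers = {}
    train_negatives: dict[str, list[Pair]] = {}
    for k, fp in enumerate(fp_ids):
        block = assemble_pair_vectors(train_idx, data.drug_tables[fp], data.target_tables[fp], fp)
        if plan is not None:
            negs = plan.train_negatives[fp]
        elif cfg.negative_strategy == "euclidean":
            negs = _euclidean_selection(
                block, train_idx.labels, n_train_neg, cfg.variance_target, cfg.normalization
            )
        else:
            negs = _random_selection(train_idx, n_train_neg, _derived_seed(seed, 0, k))
        train_negatives[fp] = list(negs)
        norm = fit_normalizer(block, cfg.normalization)  # type: ignore[arg-type]
        train_normalizers[fp] = norm
        fit_idx = _eval_index(train_idx.positives(), negs)
        fit_block = apply_normalizer(
            norm, assemble_pair_vectors(fit_idx, data.drug_tables[fp], data.target_tables[fp], fp)
        )
        labels = np.where(fit_idx.labels, 1, -1)
        models[fp] = train_submodel(fit_block, labels, SubModelConfig(fp, cfg.c, cfg.gamma))

    # --- validation / test: union pools, balanced negative draws --------------
    def build_eval(role: pt.Role, tag: int) -> tuple[PairLabelIndex, int]:
        idx = parts[role]
        n_neg = idx.n_positive
        if cfg.negative_strategy == "euclidean":
            selections = {}
            for fp in fp_ids:
                block = assemble_pair_vectors(
                    idx, data.drug_tables[fp], data.target_tables[fp], fp
                )
                n_sel = min(n_neg, idx.n_unlabeled)
                selections[fp] = _euclidean_selection(
                    block, idx.labels, n_sel, cfg.variance_target, cfg.normalization
                )
            pool = ns.build_union_pool(selections)
            negs = ns.sample_from_pool(pool, min(n_neg, len(pool)), _derived_seed(seed, tag))
            pool_size = len(pool)
        else:
            negs = _random_selection(idx, min(n_neg, idx.n_unlabeled), _derived_seed(seed, tag))
            pool_size = idx.n_unlabeled
        return _eval_index(idx.positives(), negs), pool_size

    if plan is not None:
        vali_idx, vali_pool = plan.validation_pairs, plan.pool_sizes["validation"]
        test_idx, test_pool = plan.test_pairs, plan.pool_sizes["test"]
    else:
        vali_idx, vali_pool = build_eval("validation", 1)
        test_idx, test_pool = build_eval("test", 2)

    def score_all(idx: PairLabelIndex) -> list[SubModelScores]:
        out = []
        for fp in fp_ids:
            block = apply_normalizer(
                train_normalizers[fp],
                assemble_pair_vectors(idx, data.drug_tables[fp], data.target_tables[fp], fp),
            )
            out.append(decision_values(models[fp], block))
        return out

    vali_scores = score_all(vali_idx)
    vali_labels = np.where(vali_idx.labels, 1, -1)
    weights, vali_auc = optimize_weights(vali_scores, vali_labels, cfg.weight_step)

    test_scores = score_all(test_idx)
    test_labels = np.where(test_idx.labels, 1, -1)
    fused = ensemble_decision(weights, test_scores)
    test_auc = auc(fused, test_labels)
    counts = confusion_counts(fused, test_labels, cfg.threshold)
    metrics = basic_metrics(counts)

    return {
        "seed": seed,
        "weights": list(weights),
        "validation_auc": vali_auc,
        "test_auc": test_auc,
        "validation_auc_individual": {
            s.feature_pair_id: auc(s.values, vali_labels) for s in vali_scores
        },
        "test_auc_individual": {
            s.feature_pair_id: auc(s.values, test_labels) for s in test_scores
        },
        "test_metrics": {
            "accuracy": metrics.accuracy,
            "precision": metrics.precision,
            "recall": metrics.recall,
            "f1": metrics.f1,
        },
        "test_counts": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
        "pool_sizes": {"validation": vali_pool, "test": test_pool},
        "n_entities": {role: len(assignment.ids_for(role)) for role in pt.ROLES},
        "n_positives": {role: parts[role].n_positive for role in pt.ROLES},
        "test_pairs": {
            "positives": [list(p) for p in parts["test"].positives()],
            "negatives": [list(p) for p in test_idx.pairs[parts["test"].n_positive :]],
        },
        "_plan": SamplePlan(
            train_negatives,
            vali_idx,
            test_idx,
            {"validation": vali_pool, "test": test_pool},
        ),
    }


@dataclasses.dataclass
class ExperimentReport:
    config_hash: str
    records: list[dict[str, Any]]
    failures: list[dict[str, Any]]
    summary: dict[str, Any]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _summarize(records: Sequence[Mapping[str, Any]], fp_ids: Sequence[str]) -> dict[str, Any]:
    def stats(vals: Sequence[float]) -> dict[str, float]:
        a = np.asarray(vals, dtype=float)
        return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0}

    out: dict[str, Any] = {
        "n_repeats": len(records),
        "validation_auc": stats([r["validation_auc"] for r in records]),
        "test_auc": stats([r["test_auc"] for r in records]),
        "test_accuracy": stats([r["test_metrics"]["accuracy"] for r in records]),
        "mean_weights": np.mean([r["weights"] for r in records], axis=0).tolist(),
    }
    for fp in fp_ids:
        out[f"test_auc_{fp}"] = stats([r["test_auc_individual"][fp] for r in records])
    return out


def _load_data(cfg: RunConfig) -> DTIDataset:
    if cfg.synthetic is not None:
        return DTIDataset.from_benchmark(generate_benchmark(cfg.synthetic))
    if cfg.interaction_path is None:
        raise ValueError("config needs either file paths or a synthetic spec")
    return DTIDataset.from_files(
        cfg.interaction_path,
        cfg.drug_descriptor_paths,
        cfg.target_descriptor_paths,
        cfg.orientation,
    )


def run_experiment(cfg: RunConfig, data: DTIDataset | None = None) -> ExperimentReport:
    """Run ``cfg.n_repeats`` independent repeats and aggregate mean +/- sd.

    A failed repeat is recorded with its reason and excluded from the summary;
    the report is fully determined by the config (seeds included).
    """
    if data is None:
        data = _load_data(cfg)
    records, failures = [], []
    for k in range(cfg.n_repeats):
        seed = cfg.base_seed + k
        try:
            r = run_single_repeat(data, cfg, seed)
            r.pop("_plan")
            records.append(r)
        except RepeatError as e:
            failures.append({"seed": seed, "reason": str(e)})
    if not records:
        raise RuntimeError(f"all {cfg.n_repeats} repeats failed: {failures}")
    report = ExperimentReport(
        config_hash=cfg.config_hash(),
        records=records,
        failures=failures,
        summary=_summarize(records, data.feature_pair_ids),
    )
    if cfg.out_dir:
        _write_report(report, cfg)
    return report


def compare_individual_vs_ensemble(
    cfg: RunConfig, data: DTIDataset | None = None
) -> dict[str, Any]:
    """Test-set AUC of each individual sub-model vs the optimized ensemble on
    *identical* positive/negative samples (the arms share every selection)."""
    if data is None:
        data = _load_data(cfg)
    report = run_experiment(cfg, data)
    arms: dict[str, Any] = {"records": []}
    for r in report.records:
        arms["records"].append(
            {
                "seed": r["seed"],
                "ensemble": r["test_auc"],
                **{fp: r["test_auc_individual"][fp] for fp in data.feature_pair_ids},
            }
        )
    arms["summary"] = {
        "ensemble": report.summary["test_auc"],
        **{fp: report.summary[f"test_auc_{fp}"] for fp in data.feature_pair_ids},
    }
    return arms


def run_paired_arms(
    cfg: RunConfig,
    reference: DTIDataset,
    arms: Mapping[str, DTIDataset],
) -> dict[str, Any]:
    """Run several feature-set arms on *identical* samples per repeat.

    Selections (training negatives, union pools, evaluation draws) are
    computed once per repeat from ``reference``; every arm then trains,
    optimizes and tests on exactly those samples with its own descriptor
    tables.  This is the controlled comparison design: differences between
    arms reflect the features and models only, never the sampled data.
    Used for feature-degradation ablations, where re-sampling from the
    degraded features would let a noise feature pair reshape the very
    evaluation sets it is judged on.
    """
    out: dict[str, Any] = {name: [] for name in arms}
    out["reference"] = []
    failures: list[dict[str, Any]] = []
    for k in range(cfg.n_repeats):
        seed = cfg.base_seed + k
        try:
            ref_record = run_single_repeat(reference, cfg, seed)
        except RepeatError as e:
            failures.append({"seed": seed, "reason": str(e)})
            continue
        plan = ref_record.pop("_plan")
        out["reference"].append(ref_record)
        for name, data in arms.items():
            rec = run_single_repeat(data, cfg, seed, plan=plan)
            rec.pop("_plan")
            out[name].append(rec)
    out["failures"] = failures
    return out


def _write_report(report: ExperimentReport, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=2)
    with open(out / "summary.tsv", "w") as fh:
        fh.write("quantity\tmean\tsd\n")
        for key, val in report.summary.items():
            if isinstance(val, dict) and "mean" in val:
                fh.write(f"{key}\t{val['mean']:.6f}\t{val['sd']:.6f}\n")
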