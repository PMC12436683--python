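"""Orchestration of the three comparative experiment designs.

Case 1 trains one model per single property (8 subcases), case 2 one per
unordered property pair (28 subcases), case 3 a single model on all eight
properties.  Each subcase is trained ``repeats`` times from different seeds
and its test-set metrics are repeat-averaged; properties are then ranked by
the mean of a chosen metric.  Repeat ``r`` of subcase ``s`` is seeded
``base_seed + 1000*s + r``, so every subcase is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

from .encoder import CaseSpec, encode_matrix, enumerate_pairs
from .evaluation import (
    MetricsReport,
    RepeatSummary,
    RocCurve,
    aggregate_repeats,
    auc,
    confusion,
    metric_suite,
    roc_curve,
)
from .peptide_io import DatasetSplit, FoldPlan, PeptideRecord, make_folds
from .properties import (
    CANONICAL_ORDER,
    PropertySet,
    ScaleStats,
    fit_scale_stats,
    load_builtin_property_set,
)
from .rnn_model import (
    ModelConfig,
    TrainingHistory,
    build_model,
    classify,
    predict_proba,
    train,
)


@dataclass(frozen=True)
class ExperimentPlan:
    """How a case is executed: repeats, seeding and the model template."""

    repeats: int = 20
    base_seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ExperimentResult:
    """Repeat-averaged metric tables for every subcase of one case."""

    case: int
    subcases: List[CaseSpec]
    summaries: Dict[str, RepeatSummary]
    reports: Dict[str, List[MetricsReport]]
    histories: Dict[str, List[TrainingHistory]]
    roc_curves: Dict[str, RocCurve]
    ranking: List[str]
    provenance: Dict

    def to_dict(self) -> Dict:
        return {
            "case": self.case,
            "subcases": [list(cs.properties) for cs in self.subcases],
            "summaries": {
                k: {"mean": v.mean, "sd": v.sd, "n_repeats": v.n_repeats}
                for k, v in self.summaries.items()
            },
            "reports": {
                k: [r.as_dict() | {"n": r.n, "undefined": sorted(r.undefined)}
                    for r in reps]
                for k, reps in self.reports.items()
            },
            "roc_curves": {k: {"fpr": list(c.fpr), "tpr": list(c.tpr)}
                           for k, c in self.roc_curves.items()},
            "ranking": self.ranking,
            "provenance": self.provenance,
        }

    @staticmethod
    def from_dict(d: Dict) -> "ExperimentResult":
        case = d["case"]
        subcases = [CaseSpec(case=case, properties=tuple(p)) for p in d["subcases"]]
        summaries = {
            k: RepeatSummary(mean=v["mean"], sd=v["sd"], n_repeats=v["n_repeats"])
            for k, v in d["summaries"].items()
        }
        reports = {
            k: [MetricsReport(
                    accuracy=r["accuracy"], precision=r["precision"],
                    sensitivity=r["sensitivity"], specificity=r["specificity"],
                    mcc=r["mcc"], auc=r.get("auc"), n=r.get("n", 0),
                    undefined=frozenset(r.get("undefined", ())))
                for r in reps]
            for k, reps in d["reports"].items()
        }
        rocs = {k: RocCurve(fpr=tuple(c["fpr"]), tpr=tuple(c["tpr"]))
                for k, c in d["roc_curves"].items()}
        return ExperimentResult(case=case, subcases=subcases, summaries=summaries,
                                reports=reports, histories={}, roc_curves=rocs,
                                ranking=list(d["ranking"]), provenance=d["provenance"])


def dataset_hash(records: Sequence[PeptideRecord]) -> str:
    """Order-insensitive SHA-256 digest of (id, sequence, label) triples."""
    h = hashlib.sha256()
    for rec in sorted(records, key=lambda r: r.id):
        h.update(f"{rec.id}\t{rec.sequence}\t{rec.label}\n".encode())
    return h.hexdigest()


def _fit_stats(split: DatasetSplit, property_set: PropertySet,
               normalize: bool) -> ScaleStats:
    return fit_scale_stats(split.train, property_set) if normalize else ScaleStats.identity()


def _run_subcases(split: DatasetSplit, subcases: Sequence[CaseSpec],
                  property_set: PropertySet, plan: ExperimentPlan,
                  case: int) -> ExperimentResult:
    stats = _fit_stats(split, property_set, plan.normalize)
    summaries: Dict[str, RepeatSummary] = {}
    reports: Dict[str, List[MetricsReport]] = {}
    histories: Dict[str, List[TrainingHistory]] = {}
    rocs: Dict[str, RocCurve] = {}
    ytest_ref = np.array([r.label for r in split.test], dtype=np.int64)
    for s_idx, cs in enumerate(subcases):
        Xtr, ytr = encode_matrix(split.train, cs, property_set, stats)
        Xval, yval = encode_matrix(split.validation, cs, property_set, stats)
        Xte, _ = encode_matrix(split.test, cs, property_set, stats)
        sub_reports: List[MetricsReport] = []
        sub_hist: List[TrainingHistory] = []
        for r in range(plan.repeats):
            seed = plan.base_seed + 1000 * s_idx + r
            config = dataclasses.replace(plan.model, input_width=cs.width, seed=seed)
            net = build_model(config)
            trained = train(net, Xtr, Xval, config, train_labels=ytr, val_labels=yval)
            pairs = predict_proba(trained, Xte)
            preds = classify(pairs)
            rep = metric_suite(confusion(ytest_ref, preds))
            curve = roc_curve(ytest_ref, pairs[:, 0])
            rep.auc = auc(curve)
            sub_reports.append(rep)
            sub_hist.append(trained.history)
            if r == 0:
                rocs[cs.label] = curve
        reports[cs.label] = sub_reports
        histories[cs.label] = sub_hist
        summaries[cs.label] = aggregate_repeats(sub_reports)
    provenance = {
        "case": case,
        "subcases": [cs.label for cs in subcases],
        "property_order": list(CANONICAL_ORDER),
        "repeats": plan.repeats,
        "base_seed": plan.base_seed,
        "seed_rule": "base_seed + 1000*subcase_index + repeat",
        "model_config": plan.model.to_dict(),
        "normalize": plan.normalize,
        "scale_stats": {"mean": dict(stats.mean), "sd": dict(stats.sd)},
        "dataset_hash": {
            "train": dataset_hash(split.train),
            "validation": dataset_hash(split.validation),
            "test": dataset_hash(split.test),
        },
        "split_seed": split.seed,
    }
    result = ExperimentResult(case=case, subcases=list(subcases),
                              summaries=summaries, reports=reports,
                              histories=histories, roc_curves=rocs,
                              ranking=[], provenance=provenance)
    result.ranking = rank_properties(result, "accuracy")
    return result


def run_case1(split: DatasetSplit, property_set: Optional[PropertySet] = None,
              plan: Optional[ExperimentPlan] = None,
              properties: Sequence[str] = CANONICAL_ORDER) -> ExperimentResult:
    """One subcase per single property (31x2 inputs, duplicated column)."""
    property_set = property_set or load_builtin_property_set()
    plan = plan or ExperimentPlan()
    subcases = [CaseSpec.single(p) for p in properties]
    return _run_subcases(split, subcases, property_set, plan, case=1)


def run_case2(split: DatasetSplit, property_set: Optional[PropertySet] = None,
              plan: Optional[ExperimentPlan] = None,
              properties: Sequence[str] = CANONICAL_ORDER) -> ExperimentResult:
    """One subcase per unordered property pair (28 for the full set)."""
    property_set = property_set or load_builtin_property_set()
    plan = plan or ExperimentPlan()
    subcases = [CaseSpec.pair(a, b) for a, b in enumerate_pairs(properties)]
    return _run_subcases(split, subcases, property_set, plan, case=2)


def run_case3(split: DatasetSplit, property_set: Optional[PropertySet] = None,
              plan: Optional[ExperimentPlan] = None) -> ExperimentResult:
    """A single subcase with all eight properties (31x8 inputs)."""
    property_set = property_set or load_builtin_property_set()
    plan = plan or ExperimentPlan()
    return _run_subcases(split, [CaseSpec.all_eight()], property_set, plan, case=3)


def rank_properties(result: ExperimentResult, metric: str = "accuracy") -> List[str]:
    """Subcase labels in descending order of the metric's repeat mean.

    Ties break by subcase enumeration order (canonical property order).
    """
    if not result.summaries:
        raise ValueError("result has no subcases to rank")
    labels = [cs.label for cs in result.subcases]
    for lab in labels:
        if metric not in result.summaries[lab].mean:
            raise ValueError(f"unknown metric {metric!r}; available: "
                             f"{sorted(result.summaries[lab].mean)}")
    return sorted(labels, key=lambda lab: (-result.summaries[lab].mean[metric],
                                           labels.index(lab)))


@dataclass
class CrossValidationResult:
    """Per-fold reports, the pooled summary and the winning configuration."""

    fold_reports: List[MetricsReport]
    fold_val_reports: List[MetricsReport]
    summary: RepeatSummary
    fold_plan: FoldPlan
    best_config: Optional[ModelConfig] = None
    grid_scores: Optional[List[Dict]] = None


def _cv_single(records: List[PeptideRecord], case_spec: CaseSpec,
               property_set: PropertySet, plan: ExperimentPlan, k: int,
               val_fraction: float, model: ModelConfig) -> Tuple[List[MetricsReport], List[MetricsReport], FoldPlan]:
    fold_plan = make_folds(records, k=k, seed=plan.base_seed)
    by_id = {r.id: r for r in records}
    fold_reports: List[MetricsReport] = []
    val_reports: List[MetricsReport] = []
    for f_idx, fold_ids in enumerate(fold_plan.folds):
        test_recs = [by_id[i] for i in fold_ids]
        rest = [r for r in records if r.id not in set(fold_ids)]
        y_rest = [r.label for r in rest]
        tr_recs, val_recs = train_test_split(
            rest, test_size=val_fraction, stratify=y_rest,
            random_state=(plan.base_seed + f_idx) % (2 ** 32),
        )
        stats = (fit_scale_stats(tr_recs, property_set)
                 if plan.normalize else ScaleStats.identity())
        Xtr, ytr = encode_matrix(tr_recs, case_spec, property_set, stats)
        Xval, yval = encode_matrix(val_recs, case_spec, property_set, stats)
        Xte, yte = encode_matrix(test_recs, case_spec, property_set, stats)
        reps: List[MetricsReport] = []
        vreps: List[MetricsReport] = []
        for r in range(plan.repeats):
            seed = plan.base_seed + 1000 * f_idx + r
            config = dataclasses.replace(model, input_width=case_spec.width, seed=seed)
            net = build_model(config)
            trained = train(net, Xtr, Xval, config, train_labels=ytr, val_labels=yval)
            pairs = predict_proba(trained, Xte)
            rep = metric_suite(confusion(yte, classify(pairs)))
            rep.auc = auc(roc_curve(yte, pairs[:, 0]))
            reps.append(rep)
            vpairs = predict_proba(trained, Xval)
            vreps.append(metric_suite(confusion(yval, classify(vpairs))))
        fold_reports.append(_mean_report(reps))
        val_reports.append(_mean_report(vreps))
    return fold_reports, val_reports, fold_plan


def _mean_report(reports: List[MetricsReport]) -> MetricsReport:
    s = aggregate_repeats(reports)
    return MetricsReport(
        accuracy=s.mean["accuracy"], precision=s.mean["precision"],
        sensitivity=s.mean["sensitivity"], specificity=s.mean["specificity"],
        mcc=s.mean["mcc"], auc=s.mean.get("auc"), n=reports[0].n,
    )


def cross_validate(records: Sequence[PeptideRecord], case_spec: CaseSpec,
                   plan: Optional[ExperimentPlan] = None, k: int = 10,
                   property_set: Optional[PropertySet] = None,
                   val_fraction: float = 0.15,
                   grid: Optional[Sequence[Dict]] = None) -> CrossValidationResult:
    """Stratified k-fold cross-validation with an internal validation carve-out.

    Each fold trains on the other k-1 folds (minus a stratified
    ``val_fraction`` used for early stopping) and evaluates on the held-out
    fold.  If *grid* (a list of :class:`ModelConfig` override dicts) is
    given, the configuration with the highest mean validation sensitivity
    wins (mean validation accuracy breaks ties) and its result is returned.
    """
    records = list(records)
    if len(records) < 2 * k:
        raise ValueError(f"need at least {2 * k} records for k={k} cross-validation")
    property_set = property_set or load_builtin_property_set()
    plan = plan or ExperimentPlan()
    candidates = [{}] if not grid else list(grid)
    best: Optional[CrossValidationResult] = None
    best_key: Tuple[float, float] = (-np.inf, -np.inf)
    grid_scores: List[Dict] = []
    for overrides in candidates:
        model = dataclasses.replace(plan.model, **overrides)
        fold_reports, val_reports, fold_plan = _cv_single(
            records, case_spec, property_set, plan, k, val_fraction, model)
        sens = float(np.mean([r.sensitivity for r in val_reports]))
        acc = float(np.mean([r.accuracy for r in val_reports]))
        res = CrossValidationResult(
            fold_reports=fold_reports, fold_val_reports=val_reports,
            summary=aggregate_repeats(fold_reports), fold_plan=fold_plan,
            best_config=model,
        )
        grid_scores.append({"overrides": overrides, "val_sensitivity": sens,
                            "val_accuracy": acc})
        if (sens, acc) > best_key:
            best_key = (sens, acc)
            best = res
    assert best is not None
    best.grid_scores = grid_scores
    return best


def export_results(result: ExperimentResult, out_dir) -> List[Path]:
    """Write the metrics table, per-subcase ROC CSVs and provenance JSON.

    Deterministic: re-exporting the same result is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    table = out_dir / f"case{result.case}_metrics.tsv"
    cols = ("accuracy", "precision", "sensitivity", "specificity", "mcc", "auc")
    with open(table, "w", encoding="utf-8", newline="\n") as fh:
        header = ["subcase"]
        for c in cols:
            header += [f"{c}_mean", f"{c}_sd"]
        fh.write("\t".join(header) + "\n")
        for cs in result.subcases:
            s = result.summaries[cs.label]
            row = [cs.label]
            for c in cols:
                row += [f"{s.mean.get(c, float('nan')):.6f}",
                        f"{s.sd.get(c, float('nan')):.6f}"]
            fh.write("\t".join(row) + "\n")
    written.append(table)

    for label, curve in sorted(result.roc_curves.items()):
        roc_path = out_dir / f"case{result.case}_roc_{label.replace('+', '_')}.csv"
        with open(roc_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("fpr,tpr\n")
            for x, y in zip(curve.fpr, curve.tpr):
                fh.write(f"{x:.10g},{y:.10g}\n")
        written.append(roc_path)

    prov = out_dir / f"case{result.case}_provenance.json"
    with open(prov, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.provenance | {"ranking": result.ranking},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(prov)

    full = out_dir / f"case{result.case}_result.json"
    with open(full, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(full)
    return written
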