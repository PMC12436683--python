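import numpy as np
import pytest

from glylstm.encoder import CaseSpec
from glylstm.evaluation import MetricsReport, RepeatSummary
from glylstm.experiments import (
    ExperimentPlan,
    ExperimentResult,
    cross_validate,
    export_results,
    rank_properties,
    run_case1,
    run_case2,
    run_case3,
)
from glylstm.peptide_io import PeptideRecord, make_split
from glylstm.properties import CANONICAL_ORDER
from glylstm.rnn_model import ModelConfig
from glylstm.synthetic_data import SyntheticConfig, generate_null, generate_separable

TINY_MODEL = ModelConfig(input_width=2, lstm1_units=6, lstm2_units=4, dense_units=4,
                         max_epochs=1, patience=1, batch_size=32, seed=0)
TINY_PLAN = ExperimentPlan(repeats=1, base_seed=0, model=TINY_MODEL)


@pytest.fixture(scope="module")
def tiny_split():
    records = generate_null(SyntheticConfig(n=160, seed=0))
    return make_split(records, sizes=(100, 30, 30), seed=0)


class TestRunCases:
    def test_case1_has_eight_subcases(self, tiny_split, pset):
        result = run_case1(tiny_split, pset, TINY_PLAN)
        assert [cs.label for cs in result.subcases] == list(CANONICAL_ORDER)
        assert set(result.summaries) == set(CANONICAL_ORDER)
        assert sorted(result.ranking) == sorted(CANONICAL_ORDER)

    def test_case2_restricted_to_three_properties(self, tiny_split, pset):
        result = run_case2(tiny_split, pset, TINY_PLAN,
                           properties=("SoA", "Mass", "IEP"))
        assert [cs.label for cs in result.subcases] == \
               ["SoA+Mass", "SoA+IEP", "Mass+IEP"]

    def test_case2_pairs_reported_once(self, tiny_split, pset):
        result = run_case2(tiny_split, pset, TINY_PLAN,
                           properties=("Mass", "ToA"))
        assert [cs.label for cs in result.subcases] == ["Mass+ToA"]

    def test_case3_single_subcase_with_canonical_provenance(self, tiny_split, pset):
        result = run_case3(tiny_split, pset, TINY_PLAN)
        assert len(result.subcases) == 1
        assert result.subcases[0].width == 8
        assert result.provenance["property_order"] == list(CANONICAL_ORDER)

    def test_repeats_are_aggregated(self, tiny_split, pset):
        plan = ExperimentPlan(repeats=2, base_seed=0, model=TINY_MODEL)
        result = run_case1(tiny_split, pset, plan, properties=("IEP",))
        assert result.summaries["IEP"].n_repeats == 2
        assert len(result.reports["IEP"]) == 2


class TestRankProperties:
    def _result_with_means(self, means):
        subcases = [CaseSpec.single(p) for p in means]
        summaries = {
            p: RepeatSummary(mean={"accuracy": m, "mcc": 0.0}, sd={}, n_repeats=1)
            for p, m in means.items()
        }
        return ExperimentResult(case=1, subcases=subcases, summaries=summaries,
                                reports={}, histories={}, roc_curves={},
                                ranking=[], provenance={})

    def test_descending_sort_by_mean(self):
        result = self._result_with_means({"IEP": 0.596, "Mass": 0.58, "ToA": 0.576})
        assert rank_properties(result, "accuracy") == ["IEP", "Mass", "ToA"]

    def test_ties_break_by_canonical_order(self):
        result = self._result_with_means({"Hyd": 0.5, "SoA": 0.5, "IEP": 0.5})
        assert rank_properties(result, "accuracy") == ["Hyd", "SoA", "IEP"]

    def test_unknown_metric_rejected(self):
        result = self._result_with_means({"IEP": 0.5})
        with pytest.raises(ValueError, match="unknown metric"):
            rank_properties(result, "f1")

    def test_ranking_can_differ_between_metrics(self):
        subcases = [CaseSpec.single("SoA"), CaseSpec.single("IEP")]
        summaries = {
            "SoA": RepeatSummary(mean={"accuracy": 0.6, "mcc": 0.1}, sd={}, n_repeats=1),
            "IEP": RepeatSummary(mean={"accuracy": 0.55, "mcc": 0.3}, sd={}, n_repeats=1),
        }
        result = ExperimentResult(case=1, subcases=subcases, summaries=summaries,
                                  reports={}, histories={}, roc_curves={},
                                  ranking=[], provenance={})
        assert rank_properties(result, "accuracy") != rank_properties(result, "mcc")


class TestCrossValidate:
    def test_k2_smoke_run_yields_two_fold_reports(self, pset):
        records = generate_null(SyntheticConfig(n=200, seed=1))
        res = cross_validate(records, CaseSpec.single("Mass"), TINY_PLAN, k=2,
                             property_set=pset)
        assert len(res.fold_reports) == 2
        assert all(isinstance(r, MetricsReport) for r in res.fold_reports)
        assert res.summary.n_repeats == 2

    def test_folds_are_disjoint_cover(self, pset):
        records = generate_null(SyntheticConfig(n=100, seed=2))
        res = cross_validate(records, CaseSpec.single("Hyd"), TINY_PLAN, k=5,
                             property_set=pset)
        folds = res.fold_plan.folds
        assert sum(len(f) for f in folds) == 100
        assert set().union(*map(set, folds)) == {r.id for r in records}
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_grid_hook_selects_by_validation_sensitivity(self, pset):
        records = generate_separable(
            SyntheticConfig(n=120, seed=3, planted_properties=("IEP",)))
        grid = [{"max_epochs": 1, "patience": 1}, {"max_epochs": 2, "patience": 2}]
        res = cross_validate(records, CaseSpec.single("IEP"), TINY_PLAN, k=2,
                             property_set=pset, grid=grid)
        assert res.best_config is not None
        assert len(res.grid_scores) == 2
        best_score = max((g["val_sensitivity"], g["val_accuracy"])
                         for g in res.grid_scores)
        chosen = next(g for g in res.grid_scores
                      if (g["val_sensitivity"], g["val_accuracy"]) == best_score)
        assert res.best_config.max_epochs == chosen["overrides"]["max_epochs"]


class TestLeakageAndDeterminism:
    def test_corrupting_test_labels_changes_no_training_artifact(self, pset):
        records = generate_null(SyntheticConfig(n=160, seed=4))
        split = make_split(records, sizes=(100, 30, 30), seed=0)
        corrupted_test = tuple(
            PeptideRecord(id=r.id, sequence=r.sequence, label=1 - r.label)
            for r in split.test
        )
        from glylstm.peptide_io import DatasetSplit
        corrupted = DatasetSplit(train=split.train, validation=split.validation,
                                 test=corrupted_test, seed=split.seed)
        r1 = run_case1(split, pset, TINY_PLAN, properties=("IEP",))
        r2 = run_case1(corrupted, pset, TINY_PLAN, properties=("IEP",))
        # normalization stats and the entire training trajectory are identical
        assert r1.provenance["scale_stats"] == r2.provenance["scale_stats"]
        h1, h2 = r1.histories["IEP"][0], r2.histories["IEP"][0]
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy
        # while the test metrics flip as expected
        assert r1.reports["IEP"][0].accuracy == pytest.approx(
            1 - r2.reports["IEP"][0].accuracy)

    def test_same_seed_rerun_exports_identical_tables(self, tiny_split, pset, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            result = run_case1(tiny_split, pset, TINY_PLAN, properties=("Mass", "IEP"))
            export_results(result, out)
        for name in ("case1_metrics.tsv", "case1_provenance.json",
                     "case1_roc_IEP.csv", "case1_result.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


class TestExport:
    def test_case1_table_shape_and_roundtrip(self, tiny_split, pset, tmp_path):
        result = run_case1(tiny_split, pset, TINY_PLAN)
        files = export_results(result, tmp_path)
        table = tmp_path / "case1_metrics.tsv"
        lines = table.read_text().splitlines()
        assert len(lines) == 9  # header + 8 subcases
        assert lines[0].split("\t")[0] == "subcase"
        assert len(lines[1].split("\t")) == 1 + 2 * 6
        # full result JSON round-trips to an equivalent structure
        import json
        loaded = ExperimentResult.from_dict(
            json.loads((tmp_path / "case1_result.json").read_text()))
        assert loaded.ranking == result.ranking
        assert loaded.summaries["IEP"].mean == pytest.approx(
            result.summaries["IEP"].mean)
        assert {p.name for p in files} >= {"case1_metrics.tsv", "case1_provenance.json"}
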