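"""Split stratification, the metric formulas, tidy-result plumbing, and
reduced-scale experiment-grid behavior."""

import numpy as np
import pandas as pd
import pytest

from eegfc.bands import ALPHA
from eegfc.evaluation import (ConfusionCounts, SplitPlan,
                              classification_report, compute_metrics,
                              confusion_counts, connectivity_tensor,
                              epoch_table, make_splits, median_summary,
                              probability_severity_report, run_experiment)
from eegfc.network import ThresholdSpec


def table_of(n_per_class, n_subjects=5):
    rows = []
    for c, g in enumerate(("AD", "FTD", "HC")):
        for i in range(n_per_class):
            rows.append({"group": g, "subject_id": f"{g}{i % n_subjects}",
                         "epoch": i // n_subjects})
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_sizes_70_15_15(self):
        table = table_of(334)  # 1002 epochs total
        plan = SplitPlan(n_repeats=2, seeds=(0, 1))
        for tr, va, te in make_splits(table, plan):
            assert len(tr) + len(va) + len(te) == len(table)
            assert len(tr) == round(0.7 * 334) * 3
            assert len(va) == round(0.15 * 334) * 3
            # disjoint and exhaustive
            assert len(set(tr) | set(va) | set(te)) == len(table)

    def test_class_proportions_preserved(self):
        table = table_of(100)
        (tr, va, te), = make_splits(table, SplitPlan(n_repeats=1, seeds=(3,)))
        for part, frac in ((tr, 0.7), (va, 0.15), (te, 0.15)):
            counts = table.loc[part, "group"].value_counts()
            assert (abs(counts - frac * 100) <= 1).all()

    def test_subject_mode_keeps_subjects_whole(self):
        table = table_of(100, n_subjects=10)
        plan = SplitPlan(n_repeats=3, unit="subject")
        for tr, va, te in make_splits(table, plan):
            parts = [set(table.loc[p, "subject_id"]) for p in (tr, va, te)]
            assert not (parts[0] & parts[1])
            assert not (parts[0] & parts[2])
            assert not (parts[1] & parts[2])

    def test_class_too_small_rejected(self):
        table = table_of(2)
        with pytest.raises(ValueError):
            make_splits(table, SplitPlan(n_repeats=1, seeds=(0,)))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitPlan(fractions=(0.8, 0.15, 0.15))


class TestMetricFormulas:
    def test_hand_computed_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=8, tn=85, fp=5, fn=2))
        assert m["accuracy"] == pytest.approx(0.93)
        assert m["sensitivity"] == pytest.approx(0.80)
        assert m["specificity"] == pytest.approx(0.9444, abs=1e-4)
        assert m["precision"] == pytest.approx(0.6154, abs=1e-4)
        assert m["f1"] == pytest.approx(0.6957, abs=1e-4)

    def test_perfect_predictions(self):
        m = compute_metrics(ConfusionCounts(tp=10, tn=20, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_conventions(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert m["sensitivity"] == 0.0 and m["f1"] == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, tn=0, fp=0, fn=0)

    def test_counts_partition_test_set(self):
        y_true = np.array([0, 0, 1, 1, 2, 2, 2])
        y_pred = np.array([0, 1, 1, 2, 2, 2, 0])
        for c in confusion_counts(y_true, y_pred):
            assert c.total == 7

    def test_report_overall_accuracy_cross_check(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        rep = classification_report(y_true, y_pred)
        assert rep["overall_accuracy"] == (y_true == y_pred).mean()
        assert set(rep["per_class"]) == {"AD", "FTD", "HC"}


class TestResultPlumbing:
    def test_median_summary_invariant_to_repeat_order(self):
        rng = np.random.default_rng(0)
        rows = [{"model": "cnn", "repeat": r, "class": "overall",
                 "metric": "accuracy", "value": rng.uniform()}
                for r in range(10)]
        df = pd.DataFrame(rows)
        a = median_summary(df)
        b = median_summary(df.sample(frac=1, random_state=1))
        assert a["value"].iloc[0] == b["value"].iloc[0]


class TestSeverityReport:
    def _table(self, n=60):
        groups = np.repeat(["AD", "FTD", "HC"], n // 3)
        return pd.DataFrame({"group": groups,
                             "subject_id": [f"{g}{i}" for i, g in enumerate(groups)]})

    def test_absent_covariate_skipped(self):
        table = self._table()
        manifest = pd.DataFrame({"subject_id": table["subject_id"],
                                 "severity": np.nan})
        assert probability_severity_report(np.full((60, 3), 1 / 3),
                                           table, manifest) is None

    def test_constant_covariate_skipped(self):
        table = self._table()
        manifest = pd.DataFrame({"subject_id": table["subject_id"],
                                 "severity": 1.0})
        proba = np.random.default_rng(0).dirichlet(np.ones(3), 60)
        assert probability_severity_report(proba, table, manifest) is None

    def test_monotone_probability_recovered(self):
        table = self._table()
        rng = np.random.default_rng(0)
        sev = rng.uniform(0.5, 1.5, 60)
        manifest = pd.DataFrame({"subject_id": table["subject_id"],
                                 "severity": sev})
        # own-class probability increases with severity by construction
        proba = np.full((60, 3), 0.2)
        for c, g in enumerate(("AD", "FTD", "HC")):
            mask = table["group"] == g
            proba[mask, c] = 0.3 + 0.4 * (sev[mask] - 0.5) \
                + 0.02 * rng.standard_normal(mask.sum())
        rep = probability_severity_report(proba, table, manifest)
        assert (rep["correlation"] > 0.8).all()

    def test_uncorrelated_probability_near_zero(self):
        table = self._table(180)
        rng = np.random.default_rng(1)
        manifest = pd.DataFrame({"subject_id": table["subject_id"],
                                 "severity": rng.uniform(0.5, 1.5, 180)})
        proba = rng.dirichlet(np.ones(3), 180)
        rep = probability_severity_report(proba, table, manifest)
        assert (rep["correlation"].abs() < 0.2).all()


class TestExperimentGrid:
    """Reduced-scale integration runs of the method grid."""

    @pytest.fixture(scope="class")
    def effect_dataset(self):
        from eegfc.synth import simulate_dataset
        return simulate_dataset(5, 4, effect_size=0.3, seed=21)

    def test_epoch_table_matches_dataset(self, effect_dataset):
        t = epoch_table(effect_dataset)
        assert len(t) == 15 * 4
        assert set(t["group"]) == {"AD", "FTD", "HC"}

    def test_phase_and_envelope_methods_outrank_imcoh(self, effect_dataset):
        # zero-lag shared-driver coupling is invisible to ImCoh but
        # visible to AEC/Corr: the cross-method ordering must reflect it
        plan = SplitPlan(n_repeats=2, seeds=(0, 1))
        res = run_experiment(effect_dataset, methods=("aec", "corr", "imcoh"),
                             bands=("alpha",), models=("cnn",), plan=plan)
        med = median_summary(res)
        acc = med[(med["class"] == "overall") & (med["metric"] == "accuracy")]
        by_method = acc.set_index("method")["value"]
        assert by_method["aec"] > by_method["imcoh"]
        assert by_method["corr"] > by_method["imcoh"]

    def test_absolute_threshold_discards_subthreshold_structure(self, effect_dataset):
        # the planted couplings mostly measure below 0.7, so an absolute
        # 0.7 cut zeroes nearly all discriminative entries (only the
        # estimator's upper tail survives) and classification degrades
        # markedly relative to unthresholded matrices
        plan = SplitPlan(n_repeats=2, seeds=(0, 1))
        res = run_experiment(
            effect_dataset, methods=("aec",), bands=("alpha",),
            thresholds=(ThresholdSpec(mode="none"),
                        ThresholdSpec(mode="absolute", value=0.7)),
            models=("cnn",), plan=plan)
        med = median_summary(res)
        acc = med[(med["class"] == "overall") & (med["metric"] == "accuracy")]
        by_thr = acc.set_index("threshold")["value"]
        assert by_thr["none"] >= 0.6
        assert by_thr["none"] - by_thr["absolute:0.7"] >= 0.1

    def test_rerun_with_same_seeds_is_identical(self, effect_dataset):
        plan = SplitPlan(n_repeats=1, seeds=(4,))
        kw = dict(methods=("aec",), bands=("alpha",), models=("cnn",), plan=plan)
        a = run_experiment(effect_dataset, **kw)
        b = run_experiment(effect_dataset, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_single_cell_grid(self, effect_dataset):
        plan = SplitPlan(n_repeats=1, seeds=(0,))
        res = run_experiment(effect_dataset, methods=("corr",),
                             bands=("alpha",), models=("cnn",), plan=plan)
        assert res["method"].unique().tolist() == ["corr"]
        assert (res["repeat"] == 0).all()
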