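import numpy as np
import pandas as pd
import pytest

import rsndyn as r
from rsndyn.classify import ALGORITHMS, SCHEMES, ClassifierSpec, FittedModel, _loocv
from rsndyn.core import FeatureTable


def _table(n_aca=10, n_ctrl=14, n_features=2, seed=0, session="RS1", separation=0.0):
    rng = np.random.default_rng(seed)
    rows, keys = [], []
    for i in range(n_ctrl):
        keys.append((f"ctrl{i:02d}", session, "CONTROL"))
        rows.append(rng.normal(0.0, 1.0, n_features))
    for i in range(n_aca):
        keys.append((f"aca{i:02d}", session, "ACA"))
        rows.append(rng.normal(separation, 1.0, n_features))
    return FeatureTable(
        pd.DataFrame(keys, columns=["subject_id", "session_id", "group"]),
        pd.DataFrame(np.array(rows), columns=[f"f{k}" for k in range(n_features)]),
    )


class _ConstantPredictor:
    """Degenerate classifier assigning every observation to one class."""

    def __init__(self, label, feature_names):
        self.label = label
        self.feature_names = feature_names

    def predict(self, table):
        return np.array([self.label] * table.n_observations)


class TestTrainEvaluate:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_data_training_accuracy_one(self, algorithm):
        table = _table(separation=10.0, seed=1)
        model = r.train(table, ClassifierSpec(algorithm, seed=0))
        acc, sens, spec = r.evaluate(model, table)
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("algorithm", ["SVM", "LDA"])
    def test_conflicting_duplicates_are_inseparable(self, algorithm):
        keys = pd.DataFrame(
            [("a", "RS1", "ACA"), ("b", "RS1", "CONTROL"), ("c", "RS1", "ACA"), ("d", "RS1", "CONTROL")],
            columns=["subject_id", "session_id", "group"],
        )
        values = pd.DataFrame([[1.0], [1.0], [0.0], [0.0]], columns=["f0"])
        table = FeatureTable(keys, values)
        model = r.train(table, ClassifierSpec(algorithm, seed=0))
        acc, _, _ = r.evaluate(model, table)
        assert acc < 1.0

    def test_determinism(self):
        table = _table(separation=1.0, seed=2)
        p1 = r.train(table, ClassifierSpec("SVM", seed=7)).predict(table)
        p2 = r.train(table, ClassifierSpec("SVM", seed=7)).predict(table)
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        table = _table(n_aca=0, n_ctrl=6)
        with pytest.raises(ValueError, match="single class"):
            r.train(table, ClassifierSpec("SVM"))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="invalid hyperparameters"):
            ClassifierSpec("KNN", {"kernel": "rbf"})

    def test_degenerate_all_positive_predictor_metrics(self):
        """All-ACA predictor on 10 patients vs 14 controls: 0.417/1.000/0.000."""
        table = _table()
        model = _ConstantPredictor("ACA", table.feature_names)
        acc, sens, spec = r.evaluate(model, table)
        assert acc == pytest.approx(10 / 24, abs=5e-4)
        assert round(acc, 3) == 0.417
        assert sens == 1.0 and spec == 0.0

    def test_degenerate_all_negative_predictor_metrics(self):
        table = _table()
        model = _ConstantPredictor("CONTROL", table.feature_names)
        acc, sens, spec = r.evaluate(model, table)
        assert acc == pytest.approx(14 / 24, abs=1e-12)
        assert sens == 0.0 and spec == 1.0

    def test_namespace_mismatch_rejected(self):
        table = _table(seed=3)
        model = r.train(table, ClassifierSpec("DT"))
        other = _table(n_features=3, seed=3)
        with pytest.raises(ValueError, match="namespace"):
            model.predict(other)


class TestValidationSuite:
    def _pair(self, separation=3.0, seed=0):
        rs1 = _table(separation=separation, seed=seed, session="RS1")
        rs2 = _table(separation=separation, seed=seed + 50, session="RS2")
        return rs1, rs2

    def test_five_schemes_plus_average(self):
        rs1, rs2 = self._pair()
        report = r.validation_suite(rs1, rs2, [ClassifierSpec("LDA")])
        schemes = report.frame.loc["LDA"].index.tolist()
        assert schemes == list(SCHEMES) + ["Average"]
        avg = report.average("LDA")
        per = report.frame.loc["LDA"].drop("Average")
        assert np.allclose(avg, per.mean(), atol=1e-12)

    def test_accuracy_identity(self):
        """acc = (sens*n_pos + spec*n_neg) / n holds for every row."""
        rs1, rs2 = self._pair(separation=1.0, seed=4)
        report = r.validation_suite(rs1, rs2, r.default_specs(0))
        n_pos, n_neg = 10, 14
        for (_, scheme), row in report.frame.iterrows():
            if scheme == "Average":
                continue
            expect = (row["sensitivity"] * n_pos + row["specificity"] * n_neg) / (n_pos + n_neg)
            assert row["accuracy"] == pytest.approx(expect, abs=1e-12)

    def test_session_swap_transposes_cross_rows(self):
        rs1, rs2 = self._pair(seed=6)
        a = r.validation_suite(rs1, rs2, [ClassifierSpec("KNN")]).frame
        b = r.validation_suite(rs2, rs1, [ClassifierSpec("KNN")]).frame
        assert a.loc[("KNN", "TRAIN_RS1_VAL_RS2")].equals(b.loc[("KNN", "TRAIN_RS2_VAL_RS1")])
        assert a.loc[("KNN", "LOOCV_CONCAT")].equals(b.loc[("KNN", "LOOCV_CONCAT")])

    def test_subject_mismatch_rejected(self):
        rs1, _ = self._pair()
        other = _table(n_aca=9, n_ctrl=14, session="RS2")
        with pytest.raises(ValueError, match="subjects"):
            r.validation_suite(rs1, other, [ClassifierSpec("DT")])

    def test_report_determinism(self):
        rs1, rs2 = self._pair(separation=0.5, seed=8)
        a = r.validation_suite(rs1, rs2, r.default_specs(3)).frame
        b = r.validation_suite(rs1, rs2, r.default_specs(3)).frame
        assert a.equals(b)


class TestSelectBest:
    def _report(self, rows):
        frame = pd.DataFrame(rows, columns=["setup", "scheme", "accuracy", "sensitivity", "specificity"])
        return r.ValidationReport(frame.set_index(["setup", "scheme"]))

    def test_single_entry(self):
        rep = self._report([("A", "Average", 0.9, 0.8, 0.9)])
        assert r.select_best(rep)[0] == "A"

    def test_higher_average_wins(self):
        rep = self._report([("A", "Average", 0.90, 0.8, 0.9), ("B", "Average", 0.85, 0.99, 0.9)])
        assert r.select_best(rep)[0] == "A"

    def test_tie_broken_by_sensitivity(self):
        rep = self._report([("A", "Average", 0.9, 0.7, 0.9), ("B", "Average", 0.9, 0.8, 0.9)])
        assert r.select_best(rep)[0] == "B"


class TestRefineSubsets:
    def test_network_filter_reproduces_admissible_subset(self):
        rs1 = _table(separation=3.0, seed=10)
        rs2 = _table(separation=3.0, seed=11, session="RS2")
        rs1.values.columns = ["sFC-DMN-DAN", "In-EP_SN"]
        rs2.values.columns = ["sFC-DMN-DAN", "In-EP_SN"]
        result = r.refine_subsets(rs1, rs2, ["sFC-DMN-DAN", "In-EP_SN"], [ClassifierSpec("LDA")], max_iterations=0)
        assert set(result.candidates["network_filter"]) == {"sFC-DMN-DAN", "In-EP_SN"}
        assert result.trail[0]["action"] == "init"

    def test_zero_iterations_returns_initial_subset(self):
        rs1 = _table(separation=2.0, seed=12, n_features=4)
        rs2 = _table(separation=2.0, seed=13, session="RS2", n_features=4)
        names = ["f_DMN_a", "f_DAN_b", "x0", "x1"]
        rs1.values.columns = names
        rs2.values.columns = names
        result = r.refine_subsets(rs1, rs2, names, [ClassifierSpec("DT")], max_iterations=0)
        assert set(result.best_features) == {"f_DMN_a", "f_DAN_b"}

    def test_greedy_keeps_informative_feature(self):
        """One informative + noise features: greedy refinement retains it."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n_f = 6
            rs1 = _table(separation=0.0, seed=20 + seed, n_features=n_f)
            rs2 = _table(separation=0.0, seed=40 + seed, session="RS2", n_features=n_f)
            for t in (rs1, rs2):
                shift = np.where(t.groups == "ACA", 4.0, 0.0)
                t.values.iloc[:, 0] += shift
                t.values.columns = ["sig_DMN"] + [f"noise{k}" for k in range(n_f - 1)]
            result = r.refine_subsets(
                rs1, rs2, list(rs1.feature_names), [ClassifierSpec("LDA")], max_iterations=1, seed=seed
            )
            hits += "sig_DMN" in result.best_features
        assert hits >= 2
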