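"""Small-sample classifier benchmark over five validation schemes.

Four algorithms (SVM with Gaussian kernel and median-heuristic bandwidth,
LDA, k-nearest neighbours, CART decision tree) are trained and validated
under five schemes: train on RS1 / validate on RS2, the reverse,
leave-one-observation-out within each session, and leave-one-out over both
sessions concatenated (2n folds).  Every (algorithm x scheme) cell reports
accuracy, sensitivity and specificity with the patient group (ACA) as the
positive class; per-algorithm averages over the five schemes pick the best
set-up.  Features are z-scored by training-fold statistics for SVM, LDA
and KNN; trees consume raw values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import FeatureTable

__all__ = [
    "ALGORITHMS",
    "SCHEMES",
    "ClassifierSpec",
    "FittedModel",
    "ValidationReport",
    "train",
    "evaluate",
    "validation_suite",
    "select_best",
    "refine_subsets",
]

ALGORITHMS = ("SVM", "LDA", "KNN", "DT")

SCHEMES = (
    "TRAIN_RS1_VAL_RS2",
    "TRAIN_RS2_VAL_RS1",
    "LOOCV_RS1",
    "LOOCV_RS2",
    "LOOCV_CONCAT",
)

POSITIVE = "ACA"
NEGATIVE = "CONTROL"


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier set-up: algorithm, hyperparameters, scaling, seed."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    standardize: bool | None = None
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        allowed = {
            "SVM": {"C", "kernel", "gamma", "degree"},
            "LDA": {"shrinkage", "solver"},
            "KNN": {"k"},
            "DT": {"criterion", "max_depth"},
        }[self.algorithm]
        bad = set(self.hyperparameters) - allowed
        if bad:
            raise ValueError(f"invalid hyperparameters for {self.algorithm}: {sorted(bad)}")
        if self.standardize is None:
            # trees are scale-invariant; the distance/margin methods are not
            object.__setattr__(self, "standardize", self.algorithm != "DT")

    @property
    def label(self) -> str:
        return self.name or self.algorithm


def default_specs(seed: int = 0) -> tuple[ClassifierSpec, ...]:
    """The four benchmark algorithms with their default set-ups."""
    return tuple(ClassifierSpec(alg, seed=seed) for alg in ALGORITHMS)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF bandwidth gamma = 1 / (2 * median^2) of pairwise distances."""
    n = X.shape[0]
    if n < 2:
        return 1.0
    if n > 200:  # subsample for large training sets; deterministic stride
        X = X[:: max(1, n // 200)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


class FittedModel:
    """A fitted classifier plus its feature namespace and scaling."""

    def __init__(self, estimator, feature_names: list[str], mean: np.ndarray | None, std: np.ndarray | None):
        self.estimator = estimator
        self.feature_names = feature_names
        self.mean = mean
        self.std = std

    def predict(self, table: FeatureTable) -> np.ndarray:
        if table.feature_names != self.feature_names:
            raise ValueError("feature namespace does not match the training table")
        X = table.matrix()
        if self.mean is not None:
            X = (X - self.mean) / self.std
        return self.estimator.predict(X)


def train(table: FeatureTable, spec: ClassifierSpec) -> FittedModel:
    """Fit one classifier on a feature table; deterministic under spec.seed."""
    X = table.matrix()
    y = table.groups
    classes = set(y)
    if len(classes) < 2:
        raise ValueError(f"training set has a single class {classes}")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 observations per class")
    mean = std = None
    if spec.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        X = (X - mean) / std
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "SVM":
        kernel = hp.get("kernel", "rbf")
        gamma = hp.get("gamma", "median")
        if gamma == "median" and kernel == "rbf":
            gamma = _median_heuristic_gamma(X)
        est = SVC(C=float(hp.get("C", 1.0)), kernel=kernel, gamma=gamma,
                  degree=int(hp.get("degree", 3)), random_state=spec.seed)
    elif spec.algorithm == "LDA":
        solver = hp.get("solver")
        shrinkage = hp.get("shrinkage")
        if solver is None:
            # pooled covariance; shrinkage fallback when features >= observations
            if X.shape[1] >= X.shape[0]:
                solver, shrinkage = "lsqr", "auto"
            else:
                solver = "svd"
        est = LinearDiscriminantAnalysis(solver=solver, shrinkage=shrinkage)
    elif spec.algorithm == "KNN":
        est = KNeighborsClassifier(n_neighbors=int(hp.get("k", 1)))
    else:  # DT
        est = DecisionTreeClassifier(
            criterion=hp.get("criterion", "gini"),
            max_depth=hp.get("max_depth"),
            random_state=spec.seed,
        )
    est.fit(X, y)
    return FittedModel(est, table.feature_names, mean, std)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    pos = y_true == POSITIVE
    neg = ~pos
    accuracy = float(np.mean(y_pred == y_true))
    sensitivity = float(np.mean(y_pred[pos] == POSITIVE)) if pos.any() else np.nan
    specificity = float(np.mean(y_pred[neg] == NEGATIVE)) if neg.any() else np.nan
    return accuracy, sensitivity, specificity


def evaluate(model: FittedModel, table: FeatureTable) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity on a validation table.

    Sensitivity is the fraction of patients (ACA) correctly identified;
    specificity the fraction of controls correctly identified.
    """
    return _metrics(table.groups, model.predict(table))


def _loocv(table: FeatureTable, spec: ClassifierSpec) -> tuple[float, float, float]:
    y = table.groups
    preds = np.empty(len(y), dtype=object)
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        fold = FeatureTable(table.keys.loc[keep].copy(), table.values.loc[keep].copy())
        model = train(fold, spec)
        held = FeatureTable(table.keys.loc[[i]].copy(), table.values.loc[[i]].copy())
        preds[i] = model.predict(held)[0]
    return _metrics(y, preds.astype(str))


@dataclass
class ValidationReport:
    """Per-(set-up x scheme) metrics plus per-set-up averages.

    ``frame`` rows are indexed by (setup, scheme) with scheme "Average"
    holding the mean of the five scheme rows.
    """

    frame: pd.DataFrame

    def average(self, setup: str) -> pd.Series:
        return self.frame.loc[(setup, "Average")]

    @property
    def setups(self) -> list[str]:
        return list(dict.fromkeys(self.frame.index.get_level_values(0)))

    def to_table_layout(self) -> pd.DataFrame:
        """Rows = validation schemes + Average; column triplets per set-up."""
        wide = self.frame.unstack(level=0)
        wide = wide.reindex(list(SCHEMES) + ["Average"])
        wide = wide.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
        cols = [(s, m) for s in self.setups for m in ("accuracy", "sensitivity", "specificity")]
        return wide.loc[:, cols]

    def to_csv(self, path) -> None:
        self.to_table_layout().to_csv(path, float_format="%.3f")

    def to_json(self, path) -> None:
        self.frame.reset_index().to_json(path, orient="records", indent=1)


def validation_suite(
    rs1: FeatureTable,
    rs2: FeatureTable,
    specs: Sequence[ClassifierSpec],
) -> ValidationReport:
    """Run every spec under the five validation schemes.

    ``rs1`` and ``rs2`` must share the feature namespace and subject roster.
    The concatenated leave-one-out scheme holds out one observation (one
    session), giving 2n folds.
    """
    if rs1.feature_names != rs2.feature_names:
        raise ValueError("RS1/RS2 tables have different feature namespaces")
    subj1 = sorted(rs1.keys["subject_id"])
    subj2 = sorted(rs2.keys["subject_id"])
    if subj1 != subj2:
        raise ValueError("RS1/RS2 tables cover different subjects")
    concat = FeatureTable(
        pd.concat([rs1.keys, rs2.keys], ignore_index=True),
        pd.concat([rs1.values, rs2.values], ignore_index=True),
    )
    rows = []
    for spec in specs:
        per_scheme = {}
        m1 = train(rs1, spec)
        per_scheme["TRAIN_RS1_VAL_RS2"] = evaluate(m1, rs2)
        m2 = train(rs2, spec)
        per_scheme["TRAIN_RS2_VAL_RS1"] = evaluate(m2, rs1)
        per_scheme["LOOCV_RS1"] = _loocv(rs1, spec)
        per_scheme["LOOCV_RS2"] = _loocv(rs2, spec)
        per_scheme["LOOCV_CONCAT"] = _loocv(concat, spec)
        for scheme in SCHEMES:
            rows.append((spec.label, scheme, *per_scheme[scheme]))
        avg = np.mean([per_scheme[s] for s in SCHEMES], axis=0)
        rows.append((spec.label, "Average", *avg))
    frame = pd.DataFrame(rows, columns=["setup", "scheme", "accuracy", "sensitivity", "specificity"])
    frame = frame.set_index(["setup", "scheme"])
    return ValidationReport(frame)


def select_best(report: ValidationReport) -> tuple[str, pd.Series]:
    """Best set-up by average accuracy; ties by sensitivity, then name."""
    setups = report.setups
    if not setups:
        raise ValueError("empty report")
    ranked = sorted(
        setups,
        key=lambda s: (-report.average(s)["accuracy"], -report.average(s)["sensitivity"], s),
    )
    best = ranked[0]
    return best, report.average(best)


def _dt_predictors(rs1: FeatureTable, rs2: FeatureTable, seed: int) -> list[str]:
    """Features used as split variables by a CART tree on the pooled data."""
    concat = FeatureTable(
        pd.concat([rs1.keys, rs2.keys], ignore_index=True),
        pd.concat([rs1.values, rs2.values], ignore_index=True),
    )
    model = train(concat, ClassifierSpec("DT", seed=seed))
    importances = model.estimator.feature_importances_
    return [n for n, imp in zip(concat.feature_names, importances) if imp > 0]


@dataclass
class RefinementResult:
    """Outcome of the greedy feature-subset search with its audit trail."""

    best_features: list[str]
    best_report: ValidationReport
    candidates: dict[str, list[str]]
    trail: list[dict]


def refine_subsets(
    rs1: FeatureTable,
    rs2: FeatureTable,
    selected: Sequence[str],
    specs: Sequence[ClassifierSpec] | None = None,
    *,
    networks: Sequence[str] = ("DMN", "DAN", "SN"),
    max_iterations: int = 2,
    seed: int = 0,
) -> RefinementResult:
    """Greedy refinement of the selected feature set.

    Candidate pools follow the two admission criteria: (a) predictors used
    by a fitted decision tree, (b) features whose name involves one of the
    configured networks.  Starting from the criteria-filtered subset, greedy
    passes remove then add one admissible feature at a time, keeping a
    change iff it improves the best average accuracy over the given specs.
    ``max_iterations = 0`` returns the initial criteria-filtered subsets
    unchanged.  Every evaluation is logged in the audit trail.
    """
    if not selected:
        raise ValueError("selected feature set is empty")
    specs = list(specs) if specs is not None else list(default_specs(seed))
    selected = list(selected)
    dt_pool = [f for f in _dt_predictors(rs1.subset(selected), rs2.subset(selected), seed) ]
    net_pool = [f for f in selected if any(net in f for net in networks)]
    candidates = {"dt_predictors": dt_pool, "network_filter": net_pool}
    start = net_pool or selected
    trail: list[dict] = []

    def score(features: list[str]) -> float:
        report = validation_suite(rs1.subset(features), rs2.subset(features), specs)
        _, best = select_best(report)
        return float(best["accuracy"])

    current = list(dict.fromkeys(start))
    current_score = score(current)
    trail.append({"action": "init", "features": list(current), "accuracy": current_score})
    admissible = list(dict.fromkeys(dt_pool + net_pool))
    for _ in range(max_iterations):
        improved = False
        for f in list(current):
            if len(current) <= 1:
                break
            candidate = [g for g in current if g != f]
            s = score(candidate)
            trail.append({"action": f"remove {f}", "accuracy": s})
            if s > current_score:
                current, current_score, improved = candidate, s, True
        for f in admissible:
            if f in current:
                continue
            candidate = current + [f]
            s = score(candidate)
            trail.append({"action": f"add {f}", "accuracy": s})
            if s > current_score:
                current, current_score, improved = candidate, s, True
        if not improved:
            break
    report = validation_suite(rs1.subset(current), rs2.subset(current), specs)
    return RefinementResult(best_features=current, best_report=report, candidates=candidates, trail=trail)
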