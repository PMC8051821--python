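"""Permutation-test feature screening and coherence-feature reduction.

Every feature is tested for a group difference with a label-permutation
test on the absolute group-mean difference; p-values use the add-one rule
``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` so they are valid at
finite permutation counts (the minimum attainable p with 5000 permutations
is 1/5001).  Thresholding is at an uncorrected alpha (default 0.05); an
optional Benjamini-Hochberg correction is available but off by default.

The coherence features get an extra reduction pass against overfitting:
(i) drop features that also differ between the controls' two sessions,
then keep a feature only if (ii) its network pair is significant in at
least two period bands for the same phase, or in at least two phases, or
(iii) its own p-value clears a stricter threshold (default 0.01).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTable

__all__ = [
    "PermutationResult",
    "permutation_pvalue",
    "select_features",
    "reduce_wcoh",
]

_WCOH_NAME = re.compile(r"^(ip|ap|lead|lag)_(.+)_s(\d)$")


@dataclass
class PermutationResult:
    """Per-feature permutation-test outcomes.

    ``frame`` has one row per feature with columns ``statistic`` (absolute
    group-mean difference), ``p`` and ``selected``; ``n_permutations`` and
    ``seed`` record the test configuration.
    """

    frame: pd.DataFrame
    n_permutations: int
    seed: int
    alpha: float

    @property
    def mask(self) -> np.ndarray:
        return self.frame["selected"].to_numpy()

    @property
    def selected(self) -> list[str]:
        return list(self.frame.index[self.mask])

    def p_of(self, feature: str) -> float:
        return float(self.frame.loc[feature, "p"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _permutation_core(
    X: np.ndarray, is_a: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided permutation test for all columns of X at once."""
    n = len(is_a)
    n_a = int(is_a.sum())
    n_b = n - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least 2 observations")
    w = np.where(is_a, 1.0 / n_a, -1.0 / n_b)
    observed = np.abs(w @ X)
    perm_w = np.empty((n_perm, n))
    for k in range(n_perm):
        perm_w[k] = w[rng.permutation(n)]
    perm_stats = np.abs(perm_w @ X)
    count = np.sum(perm_stats >= observed[None, :], axis=0)
    p = (1.0 + count) / (n_perm + 1.0)
    return observed, p


def permutation_pvalue(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for one feature's group difference.

    Statistic: absolute difference of group means (two-sided by
    construction).  Returns ``(statistic, p)``; identical groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    X = np.concatenate([a, b])[:, None]
    is_a = np.zeros(len(X), dtype=bool)
    is_a[: len(a)] = True
    observed, p = _permutation_core(X, is_a, n_perm, np.random.default_rng(seed))
    return float(observed[0]), float(p[0])


def select_features(
    table: FeatureTable,
    alpha: float = 0.05,
    *,
    n_perm: int = 5000,
    seed: int = 0,
    group_a: str = "ACA",
    group_b: str = "CONTROL",
    bh_correct: bool = False,
) -> PermutationResult:
    """Permutation-screen every feature of a table for a group difference.

    Tests ``group_a`` vs ``group_b`` rows with a shared permutation
    ensemble; features with p < alpha (uncorrected by default) are flagged
    selected.  ``bh_correct=True`` applies Benjamini-Hochberg instead.
    """
    groups = table.groups
    present = set(groups)
    if group_a not in present or group_b not in present:
        raise ValueError(f"need both groups {group_a!r} and {group_b!r} in the table")
    keep = (groups == group_a) | (groups == group_b)
    X = table.matrix()[keep]
    is_a = (groups[keep] == group_a)
    observed, p = _permutation_core(X, is_a, n_perm, np.random.default_rng(seed))
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        selected = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        selected = p < alpha
    frame = pd.DataFrame(
        {"statistic": observed, "p": p, "selected": selected},
        index=pd.Index(table.feature_names, name="feature"),
    )
    return PermutationResult(frame=frame, n_permutations=n_perm, seed=seed, alpha=alpha)


def _parse_wcoh(name: str) -> tuple[str, str, int]:
    m = _WCOH_NAME.match(name)
    if not m:
        raise ValueError(f"not a coherence feature name: {name!r}")
    return m.group(2), m.group(1), int(m.group(3))  # pair, phase, scale band


def reduce_wcoh(
    results_rs1: PermutationResult,
    results_rs2: PermutationResult,
    control_consistency: PermutationResult,
    *,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """Reduce the significant coherence features against overfitting.

    All three results must share the coherence feature namespace.  A feature
    is group-significant when p < alpha in either session.  It survives iff
    it passes rule (i) — not significant in the controls' RS1-vs-RS2
    comparison — and then rule (ii) — its pair/phase significant in >= 2
    period bands, or its pair significant in >= 2 phases — or rule (iii) —
    min session p < strict_alpha.  Returns the surviving names and a
    per-feature rule trace.
    """
    names = list(results_rs1.frame.index)
    if list(results_rs2.frame.index) != names or list(control_consistency.frame.index) != names:
        raise ValueError("result sets do not share a feature namespace")
    p1 = results_rs1.frame["p"]
    p2 = results_rs2.frame["p"]
    p_min = np.minimum(p1, p2)
    significant = p_min < alpha
    control_sig = control_consistency.frame["p"] < alpha

    parsed = {name: _parse_wcoh(name) for name in names}
    sig_names = [n for n in names if significant[n]]
    bands_per_pair_phase: dict[tuple[str, str], set[int]] = {}
    phases_per_pair: dict[str, set[str]] = {}
    for n in sig_names:
        pair, phase, band = parsed[n]
        bands_per_pair_phase.setdefault((pair, phase), set()).add(band)
        phases_per_pair.setdefault(pair, set()).add(phase)

    rows = []
    survivors = []
    for n in names:
        pair, phase, band = parsed[n]
        is_sig = bool(significant[n])
        rule_i = is_sig and not bool(control_sig[n])
        rule_ii = is_sig and (
            len(bands_per_pair_phase.get((pair, phase), ())) >= 2
            or len(phases_per_pair.get(pair, ())) >= 2
        )
        rule_iii = is_sig and bool(p_min[n] < strict_alpha)
        kept = rule_i and (rule_ii or rule_iii)
        if kept:
            survivors.append(n)
        rows.append((is_sig, rule_i, rule_ii, rule_iii, kept))
    trace = pd.DataFrame(
        rows,
        index=pd.Index(names, name="feature"),
        columns=["significant", "passes_control_rule", "multi_band_or_phase", "strict_p", "kept"],
    )
    return survivors, trace
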