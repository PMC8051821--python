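"""End-to-end pipeline: simulate/load -> extract -> select -> classify.

Feature extraction runs the enabled metrics per session and horizontally
concatenates their named blocks (for the study design of 14 networks:
91 sFC + 315 GC + 1820 WCoh + 42 EGN = 2268 columns).  Selection screens
each session's table with permutation tests; coherence features get the
extra reduction pass.  Classification benchmarks the four algorithms over
the five validation schemes on the selected features.

Every stochastic stage receives a seed derived from the master seed and
the stage name, so re-runs with an identical configuration are
byte-identical; a JSON manifest of stage parameter hashes accompanies the
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import classify as _classify
from . import egn as _egn
from . import granger as _granger
from . import selection as _selection
from . import sfc as _sfc
from . import wavelet as _wavelet
from .core import Cohort, FeatureTable, derive_seed, load_cohort, write_feature_table
from .simulate import default_benchmark_config, gen_benchmark_dataset

__all__ = ["PipelineConfig", "extract_features", "select_pipeline", "run_pipeline"]

logger = logging.getLogger("rsndyn")

ALL_METRICS = ("sfc", "gc", "wcoh", "egn")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (see ``from_yaml``)."""

    seed: int = 0
    metrics: tuple[str, ...] = ALL_METRICS
    manifest_rs1: str | None = None
    manifest_rs2: str | None = None
    simulate: bool = True
    selection_alpha: float = 0.05
    strict_alpha: float = 0.01
    n_permutations: int = 5000
    gc_order: int | None = None
    gc_max_order: int = 10
    wcoh_surrogates: int = 300
    wcoh_alpha: float = 0.05
    egn_margin: float = 0.05
    egn_ridge: float = 1e-3
    out_dir: str = "rsndyn_out"

    def __post_init__(self) -> None:
        self.metrics = tuple(self.metrics)
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}; expected subset of {ALL_METRICS}")
        if not self.simulate and not (self.manifest_rs1 and self.manifest_rs2):
            raise ValueError("either enable simulation or provide both session manifests")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def extract_features(
    cohort: Cohort,
    metrics: Sequence[str] = ALL_METRICS,
    *,
    seed: int = 0,
    gc_order: int | None = None,
    gc_max_order: int = 10,
    wcoh_surrogates: int = 300,
    wcoh_alpha: float = 0.05,
    egn_margin: float = 0.05,
    egn_ridge: float = 1e-3,
) -> FeatureTable:
    """Extract the enabled metric blocks for every session of a cohort."""
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    wcoh_cache = None
    if "wcoh" in metrics:
        ref = cohort.sessions[0]
        wcoh_cache = _wavelet.ThresholdCache(
            ref.n_samples,
            ref.dt,
            n_surrogates=wcoh_surrogates,
            alpha=wcoh_alpha,
            seed=derive_seed(seed, "wcoh"),
            max_period=min(128.0, ref.duration / 2.0),
        )
    rows = []
    for ts in cohort:
        blocks = []
        for metric in metrics:
            if metric == "sfc":
                blocks.append(_sfc.sfc_features(ts))
            elif metric == "gc":
                blocks.append(_granger.gc_features(ts, order=gc_order, max_order=gc_max_order))
            elif metric == "wcoh":
                blocks.append(_wavelet.wcoh_features(ts, cache=wcoh_cache))
            elif metric == "egn":
                blocks.append(_egn.ep_features(ts, margin=egn_margin, ridge_lambda=egn_ridge))
        row = pd.concat(blocks) if blocks else pd.Series(dtype=float)
        logger.info("extracted %d features for %s/%s", len(row), ts.subject_id, ts.session_id)
        rows.append((ts, row))
    return FeatureTable.from_rows(rows)


def select_pipeline(
    table_rs1: FeatureTable,
    table_rs2: FeatureTable,
    *,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Group screening per session plus the coherence reduction pass.

    Returns a dict with the per-session :class:`PermutationResult` objects,
    the control RS1-vs-RS2 consistency result for coherence features, the
    reduced coherence list, and the final selected feature names (union of
    sessions for non-coherence features; reduced set for coherence ones).
    """
    res1 = _selection.select_features(table_rs1, alpha, n_perm=n_perm, seed=derive_seed(seed, "sel-rs1"))
    res2 = _selection.select_features(table_rs2, alpha, n_perm=n_perm, seed=derive_seed(seed, "sel-rs2"))
    wcoh_names = [n for n in table_rs1.feature_names if _is_wcoh(n)]
    selected: list[str] = []
    for name in table_rs1.feature_names:
        if _is_wcoh(name):
            continue
        if res1.p_of(name) < alpha or res2.p_of(name) < alpha:
            selected.append(name)
    reduced: list[str] = []
    trace = None
    control_res = None
    if wcoh_names:
        # controls' RS1-vs-RS2 comparison on the coherence block
        ctrl1 = _controls_only(table_rs1.subset(wcoh_names))
        ctrl2 = _controls_only(table_rs2.subset(wcoh_names))
        paired = FeatureTable(
            pd.concat([_relabel(ctrl1.keys, "ACA"), ctrl2.keys], ignore_index=True),
            pd.concat([ctrl1.values, ctrl2.values], ignore_index=True),
        )
        control_res = _selection.select_features(
            paired, alpha, n_perm=n_perm, seed=derive_seed(seed, "sel-ctrl")
        )
        reduced, trace = _selection.reduce_wcoh(
            _subset_result(res1, wcoh_names),
            _subset_result(res2, wcoh_names),
            control_res,
            alpha=alpha,
            strict_alpha=strict_alpha,
        )
        selected.extend(reduced)
    return {
        "rs1": res1,
        "rs2": res2,
        "control_consistency": control_res,
        "wcoh_reduced": reduced,
        "wcoh_trace": trace,
        "selected": selected,
    }


def _is_wcoh(name: str) -> bool:
    return name.split("_", 1)[0] in ("ip", "ap", "lead", "lag")


def _controls_only(table: FeatureTable) -> FeatureTable:
    mask = table.keys["group"] == "CONTROL"
    return FeatureTable(table.keys.loc[mask].copy(), table.values.loc[mask].copy())


def _relabel(keys: pd.DataFrame, group: str) -> pd.DataFrame:
    # RS1-vs-RS2 consistency check reuses the two-sample test machinery by
    # relabelling one session as the pseudo-positive class.
    out = keys.copy()
    out["group"] = group
    out["session_id"] = "RS1"
    out["subject_id"] = out["subject_id"] + "_rs1"
    return out


def _subset_result(res: _selection.PermutationResult, names: list[str]) -> _selection.PermutationResult:
    return _selection.PermutationResult(
        frame=res.frame.loc[names].copy(),
        n_permutations=res.n_permutations,
        seed=res.seed,
        alpha=res.alpha,
    )


def _stage_hash(**params) -> str:
    text = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write artifacts under ``config.out_dir``.

    Writes per-session feature tables, the selection report, the validation
    report (Tables-style CSV layout plus JSON), and a manifest of stage
    hashes.  Returns the in-memory artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    if config.simulate:
        rs1, rs2 = gen_benchmark_dataset(config.seed)
        manifest["simulate"] = _stage_hash(stage="simulate", seed=config.seed)
    else:
        rs1 = load_cohort(config.manifest_rs1)
        rs2 = load_cohort(config.manifest_rs2)
        manifest["load"] = _stage_hash(
            stage="load", rs1=config.manifest_rs1, rs2=config.manifest_rs2
        )

    tables = {}
    for name, cohort in (("RS1", rs1), ("RS2", rs2)):
        logger.info("extracting metrics %s for session %s", config.metrics, name)
        tables[name] = extract_features(
            cohort,
            config.metrics,
            seed=config.seed,
            gc_order=config.gc_order,
            gc_max_order=config.gc_max_order,
            wcoh_surrogates=config.wcoh_surrogates,
            wcoh_alpha=config.wcoh_alpha,
            egn_margin=config.egn_margin,
            egn_ridge=config.egn_ridge,
        )
        write_feature_table(tables[name], out / f"features_{name}.csv")
    manifest["extract"] = _stage_hash(
        stage="extract", metrics=config.metrics, seed=config.seed,
        gc_order=config.gc_order, wcoh_surrogates=config.wcoh_surrogates,
    )

    sel = select_pipeline(
        tables["RS1"],
        tables["RS2"],
        alpha=config.selection_alpha,
        strict_alpha=config.strict_alpha,
        n_perm=config.n_permutations,
        seed=config.seed,
    )
    sel["rs1"].to_csv(out / "selection_rs1.csv")
    sel["rs2"].to_csv(out / "selection_rs2.csv")
    if sel["wcoh_trace"] is not None:
        sel["wcoh_trace"].to_csv(out / "selection_wcoh_trace.csv")
    manifest["select"] = _stage_hash(
        stage="select", alpha=config.selection_alpha, strict=config.strict_alpha,
        n_perm=config.n_permutations, seed=config.seed,
    )

    report = None
    best = None
    if sel["selected"]:
        specs = _classify.default_specs(config.seed)
        report = _classify.validation_suite(
            tables["RS1"].subset(sel["selected"]).sort_by_subject(),
            tables["RS2"].subset(sel["selected"]).sort_by_subject(),
            specs,
        )
        report.to_csv(out / "validation_report.csv")
        report.to_json(out / "validation_report.json")
        best = _classify.select_best(report)
        manifest["classify"] = _stage_hash(
            stage="classify", n_features=len(sel["selected"]), seed=config.seed
        )
        logger.info("best set-up %s with average accuracy %.3f", best[0], best[1]["accuracy"])
    else:
        logger.warning("no features survived selection; skipping classification")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"config": asdict(config), "stages": manifest}, fh, indent=1, default=str)
    return {"tables": tables, "selection": sel, "report": report, "best": best}
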