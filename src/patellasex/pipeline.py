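"""End-to-end pipeline: cohort → screening → discriminant analysis → ML.

Each stage writes one machine-readable JSON report (schema-versioned and
validated before writing) plus a combined CSV summary; identical
configuration and seed reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from . import descriptives as _desc
from . import discriminant as _dfa
from . import ml_stacking as _ml
from .cohort import VARIABLES

log = logging.getLogger("patellasex")

SCHEMA_VERSION = 1

#: Variable sets of the published direct multivariate functions.
DIRECT_SETS = {
    "D1": ("maxh", "maxb"),
    "D2": ("maxh", "maxb", "maxt"),
    "D3": ("lafb", "maxb", "maxh", "maxt", "haf", "mafb"),
    "D4": ("maxh", "maxt"),
    "D5": ("maxh", "lafb"),
}


class PipelineConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (a measurement table) or ``cohort_preset`` (name of
    a packaged generative preset: ``pooled``, ``saad``, ``saed``, ``masa``)
    supplies the data. Stage toggles must respect the dependency order
    describe → dfa/ml → stack.
    """

    input_csv: str | None = None
    cohort_preset: str = "pooled"
    describe: bool = True
    dfa: bool = True
    ml: bool = True
    stack: bool = True
    seed: int = 0
    out_dir: str = "patellasex_out"
    correlation_threshold: float = 0.85
    f_enter: float = 3.84
    f_remove: float = 2.71
    k_folds: int = 5
    base_learners: tuple[str, ...] = ("random-forest", "extra-trees")
    meta_learner: str = "gradient-boosting"

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise PipelineConfigError("seed must be an integer")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise PipelineConfigError(f"input CSV not found: {self.input_csv}")
        if (self.dfa or self.ml) and not self.describe:
            raise PipelineConfigError("dfa/ml stages require the describe stage")
        if self.stack and not self.ml:
            raise PipelineConfigError("stack stage requires the ml stage")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        if isinstance(cfg.base_learners, list):
            cfg.base_learners = tuple(cfg.base_learners)
        return cfg


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _as_jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not isinstance(v, np.ndarray)
        }
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return _round(obj)


def _validate_report(report: dict, required: tuple[str, ...]) -> None:
    if report.get("schema_version") != SCHEMA_VERSION:
        raise PipelineStageError("report", ValueError("missing schema_version"))
    missing = [k for k in required if k not in report]
    if missing:
        raise PipelineStageError("report", ValueError(f"missing keys {missing}"))


def _write_json(report: dict, required: tuple[str, ...], path: Path) -> None:
    _validate_report(report, required)
    path.write_text(json.dumps(_as_jsonable(report), indent=2, sort_keys=True) + "\n")


def _metricset_dict(ms: _ml.MetricSet) -> dict:
    d = {}
    for name in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
        m = getattr(ms, name)
        d[name] = {"value_pct": m.value, "ci_half_width_pct": m.ci_half_width}
    if ms.auc is not None:
        d["auc"] = {"value_pct": ms.auc.value, "ci_half_width_pct": None}
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write one JSON report per stage.

    Returns the report bundle as a dict keyed by stage name. Any stage error
    raises :class:`PipelineStageError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, dict] = {}
    if not any((config.describe, config.dfa, config.ml, config.stack)):
        return bundle

    # --- data ---------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.input_csv is not None:
            table = _cohort.read_csv(config.input_csv)
            source = config.input_csv
        else:
            if config.cohort_preset == "pooled":
                spec = _cohort.pooled_spec(seed=config.seed)
            else:
                spec = _cohort.population_spec(config.cohort_preset, seed=config.seed)
            table = _cohort.generate_cohort(spec)
            _cohort.write_csv(table, out_dir / "cohort.csv")
            source = f"generated:{config.cohort_preset}"
    except Exception as err:
        raise PipelineStageError("generate", err) from err
    log.info("stage=generate source=%s rows=%d seed=%d elapsed=%.2fs",
             source, len(table), config.seed, time.perf_counter() - t0)

    if config.describe:
        t0 = time.perf_counter()
        try:
            summaries = _desc.describe_by_sex(table)
            ranksum = [
                _desc.rank_sum_test(
                    table.loc[table["sex"] == "M", v],
                    table.loc[table["sex"] == "F", v],
                    variable=v,
                )
                for v in VARIABLES
            ]
            filt = _desc.correlation_filter(
                table, threshold=config.correlation_threshold
            )
            report = {
                "schema_version": SCHEMA_VERSION,
                "stage": "describe",
                "source": source,
                "summaries": [_as_jsonable(s) for s in summaries],
                "rank_sum": [_as_jsonable(r) for r in ranksum],
                "correlation": {
                    "matrix": _as_jsonable(
                        {a: dict(filt.matrix[a].round(6)) for a in filt.matrix}
                    ),
                    "threshold": config.correlation_threshold,
                    "removed": filt.removed,
                    "undefined": filt.undefined,
                },
            }
            _write_json(report, ("summaries", "rank_sum", "correlation"),
                        out_dir / "describe.json")
            bundle["describe"] = report
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError("describe", err) from err
        log.info("stage=describe elapsed=%.2fs", time.perf_counter() - t0)

    features_after_filter = tuple(
        v for v in VARIABLES
        if config.describe and v not in bundle["describe"]["correlation"]["removed"]
    ) if config.describe else VARIABLES

    if config.dfa:
        t0 = time.perf_counter()
        try:
            univariate = []
            for v in VARIABLES:
                fn = _dfa.fit_lda(table, (v,))
                rep_o, rep_c = _dfa.loocv(table, (v,))
                univariate.append({
                    "variables": [v],
                    "coefficients": {v: float(fn.coefficients[0])},
                    "constant": fn.constant,
                    "original": _as_jsonable(rep_o),
                    "cross_validated": _as_jsonable(rep_c),
                })
            trace = _dfa.stepwise_select(
                table, features_after_filter,
                f_enter=config.f_enter, f_remove=config.f_remove,
            )
            multivariate = []
            sets = {"stepwise": tuple(trace.entered), **DIRECT_SETS}
            for name, vs in sets.items():
                if not vs:
                    multivariate.append({"name": name, "variables": [],
                                         "note": "no variable passed entry"})
                    continue
                fn = _dfa.fit_lda(table, vs)
                rep_o, rep_c = _dfa.loocv(table, vs)
                multivariate.append({
                    "name": name,
                    "variables": list(vs),
                    "coefficients": {
                        v: float(c) for v, c in zip(vs, fn.coefficients)
                    },
                    "constant": fn.constant,
                    "original": _as_jsonable(rep_o),
                    "cross_validated": _as_jsonable(rep_c),
                })
            report = {
                "schema_version": SCHEMA_VERSION,
                "stage": "dfa",
                "univariate": univariate,
                "multivariate": multivariate,
                "stepwise_trace": _as_jsonable(trace),
            }
            _write_json(report, ("univariate", "multivariate"), out_dir / "dfa.json")
            bundle["dfa"] = report
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError("dfa", err) from err
        log.info("stage=dfa elapsed=%.2fs", time.perf_counter() - t0)

    top3 = ("maxh", "maxb", "maxt")
    if config.ml:
        t0 = time.perf_counter()
        try:
            rankings = [
                _ml.rank_features(table, m, features_after_filter, seed=config.seed)
                for m in _ml.RANKING_METHODS
            ]
            rf_ranking = next(
                r for r in rankings if r.method == "random-forest-impurity"
            )
            top3 = tuple(rf_ranking.top(3))
            classifiers = []
            for cid in _ml.CLASSIFIER_IDS:
                res = _ml.crossval_evaluate(
                    table, cid, top3, k=config.k_folds, seed=config.seed
                )
                classifiers.append({
                    "classifier": cid,
                    "features": list(top3),
                    "metrics": _metricset_dict(res.metrics),
                    "confusion": _as_jsonable(res.confusion),
                })
            report = {
                "schema_version": SCHEMA_VERSION,
                "stage": "ml",
                "rankings": [_as_jsonable(r) for r in rankings],
                "top3_features": list(top3),
                "classifiers": classifiers,
            }
            _write_json(report, ("rankings", "classifiers"), out_dir / "ml.json")
            bundle["ml"] = report
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError("ml", err) from err
        log.info("stage=ml elapsed=%.2fs", time.perf_counter() - t0)

    if config.stack:
        t0 = time.perf_counter()
        try:
            res, model = _ml.stack_fit_evaluate(
                table, config.base_learners, config.meta_learner, top3,
                k=config.k_folds, seed=config.seed,
            )
            points, auc_pct = _ml.roc_curve(res.scores, res.labels)
            points.to_csv(out_dir / "stack_roc.csv", index=False)
            report = {
                "schema_version": SCHEMA_VERSION,
                "stage": "stack",
                "base_learners": list(config.base_learners),
                "meta_learner": config.meta_learner,
                "features": list(top3),
                "stacking": [{
                    "metrics": _metricset_dict(res.metrics),
                    "confusion": _as_jsonable(res.confusion),
                    "auc_pct": _round(auc_pct),
                }],
            }
            _write_json(report, ("stacking",), out_dir / "stack.json")
            bundle["stack"] = report
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError("stack", err) from err
        log.info("stage=stack elapsed=%.2fs", time.perf_counter() - t0)

    _write_summary_csv(bundle, out_dir / "summary.csv")
    return bundle


def _write_summary_csv(bundle: dict, path: Path) -> None:
    rows = []
    for entry in bundle.get("dfa", {}).get("univariate", []):
        rows.append({
            "stage": "dfa-univariate",
            "name": entry["variables"][0],
            "accuracy_pct": entry["cross_validated"]["average_pct"],
        })
    for entry in bundle.get("dfa", {}).get("multivariate", []):
        if entry.get("variables"):
            rows.append({
                "stage": "dfa-multivariate",
                "name": entry["name"],
                "accuracy_pct": entry["cross_validated"]["average_pct"],
            })
    for entry in bundle.get("ml", {}).get("classifiers", []):
        rows.append({
            "stage": "ml",
            "name": entry["classifier"],
            "accuracy_pct": entry["metrics"]["accuracy"]["value_pct"],
        })
    for entry in bundle.get("stack", {}).get("stacking", []):
        rows.append({
            "stage": "stack",
            "name": "stacking",
            "accuracy_pct": entry["metrics"]["accuracy"]["value_pct"],
        })
    if rows:
        pd.DataFrame(rows).to_csv(path, index=False)
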