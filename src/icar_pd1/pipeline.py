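"""Top-level pipeline: score plates, analyse the cohort, evaluate prediction.

Each stage is independently re-runnable through the library or CLI; this
module chains them, logs counts at stage boundaries (so silent data loss is
impossible) and writes a machine-readable config echo plus a MANIFEST noting
which stages completed, so any output directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort as ca
from . import io as cio
from . import predict as pm
from .cps import classify_cps
from .errors import IcarError
from .scoring import score_plates

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("icar_pd1")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; echoed verbatim next to the outputs."""

    out_dir: str
    plate_csv: str | None = None
    cohort_csv: str | None = None
    pc_reference: float | None = None
    score_name: str = "pd1"
    score_cutoff: float = 4.0
    cps_threshold: float = 1.0
    sizes: tuple[int, ...] = pm.PROTOCOL_SIZES
    repeats: int = 100
    seed: int = 0
    run_predict: bool = True

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["sizes"] = list(self.sizes)
        return d


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def _jsonable(value):
    import numpy as np

    if value is None or isinstance(value, (bool, int, str)):
        return value
    if isinstance(value, np.bool_):
        return bool(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, (float, np.floating)):
        return float(value)
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    try:
        if value != value:  # pandas NA / NaN
            return None
    except (TypeError, ValueError):
        pass
    return str(value)


def _survival_rows(label: str, curve: ca.SurvivalCurve):
    return [
        {"group": label, "time_months": t, "survival": s, "at_risk": r}
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk)
    ]


def _km_pair(groups: dict, endpoint: str):
    """KM curves per group plus the pairwise log-rank (two groups only)."""
    import pandas as pd

    rows, arms = [], []
    for label, patients in groups.items():
        if not patients:
            continue
        times = [getattr(p, f"{endpoint}_months") for p in patients]
        events = [getattr(p, f"{endpoint}_event") for p in patients]
        rows.extend(_survival_rows(label, ca.km_estimate(times, events)))
        arms.append((times, events))
    result = {"endpoint": endpoint, "groups": {k: len(v) for k, v in groups.items()}}
    if len(arms) == 2:
        stat, p = ca.logrank_test(arms[0], arms[1])
        result.update({"logrank_statistic": stat, "logrank_p": p})
    return pd.DataFrame(rows), result


def _cohort_stage(patients, config: RunConfig, out: Path) -> dict:
    import pandas as pd

    summary: dict = {"n_patients": len(patients)}
    strat = ca.stratify_by_score(patients, config.score_name, config.score_cutoff)
    log.info("cohort: %d patients (%d without %s score)", len(patients), len(strat.excluded), config.score_name)

    tables = [ca.response_rate_table(strat.as_dict())]
    with_cps = [p for p in patients if p.cps_value is not None]
    if with_cps:
        cps_groups = {
            f"CPS_{call}": [p for p in with_cps if classify_cps(p.cps_value, config.cps_threshold) == call]
            for call in ("positive", "negative")
        }
        tables.append(ca.response_rate_table(cps_groups))
    else:
        summary["cps_tables"] = "not computed (no CPS values in cohort)"
    line_groups = {
        "first_line": [p for p in patients if p.line_of_treatment == 1],
        "later_line": [p for p in patients if p.line_of_treatment > 1],
    }
    tables.append(ca.response_rate_table(line_groups))
    rates = pd.concat(tables, ignore_index=True)
    rates.to_csv(out / "response_rates.csv", index=False)
    summary["response_rates"] = _jsonable(rates.to_dict("records"))

    surv_frames, surv_results = [], []
    score_groups = dict(zip(strat.labels, (strat.above, strat.at_or_below)))
    resp_groups = {
        "responder": [p for p in patients if p.responder],
        "non_responder": [p for p in patients if not p.responder],
    }
    for endpoint in ("os", "pfs"):
        for groups in (score_groups, resp_groups):
            if all(groups.values()):
                frame, res = _km_pair(groups, endpoint)
                surv_frames.append(frame)
                surv_results.append(res)
    if surv_frames:
        pd.concat(surv_frames, ignore_index=True).to_csv(out / "survival_curves.csv", index=False)
    summary["survival"] = _jsonable(surv_results)

    mortality = [
        [sum(p.os_event for p in grp), sum(not p.os_event for p in grp)]
        for grp in (resp_groups["non_responder"], resp_groups["responder"])
    ]
    if all(sum(r) for r in mortality):
        res = ca.contingency_test(mortality)
        summary["mortality_test"] = {
            "table": _jsonable(res.table),
            "test_used": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }

    dur = ca.duration_summary(patients, config.score_name, config.score_cutoff)
    summary["response_duration"] = _jsonable(
        {"mean_duration": dur["mean_duration"], "p_value": dur["p_value"], "excluded": dur["excluded"]}
    )
    ca.swimmer_table(patients, config.score_name, config.score_cutoff).to_csv(
        out / "swimmer.csv", index=False
    )
    return summary


def _predict_stage(patients, config: RunConfig, out: Path) -> dict:
    fm = pm.FeatureMatrix.from_cohort(patients)
    log.info("predict: %d/%d patients with complete scores", fm.n, len(patients))
    results = pm.cohort_sampling_curve(
        fm, sizes=config.sizes, repeats=config.repeats, seed=config.seed
    )
    pm.curve_to_frame(results).to_csv(out / "predictive_auc.csv", index=False)
    per_size = {
        str(r.cohort_size): {"min_auc": r.min_auc, "mean_auc": r.mean_auc} for r in results
    }
    return {
        "n_used": fm.n,
        "per_size": per_size,
        "overall_min_auc": min(r.min_auc for r in results),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run score -> cohort -> predict; returns (and writes) the JSON summary.

    A stage failure raises ``IcarError`` tagged with the stage name; outputs
    written before the failure are preserved and the MANIFEST records how
    far the run got.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(config.echo(), out / "config.json")
    completed: list[str] = []
    summary: dict = {"seed": config.seed}

    def manifest():
        _write_json({"completed_stages": completed}, out / "MANIFEST.json")

    def run_stage(name, fn):
        try:
            result = fn()
        except IcarError as exc:
            manifest()
            raise IcarError(exc.code, f"stage {name}: {exc}") from exc
        completed.append(name)
        manifest()
        return result

    patients = None
    if config.plate_csv:
        def score_stage():
            wells = cio.read_plate_csv(config.plate_csv)
            log.info("score: %d wells read from %s", len(wells), config.plate_csv)
            score_sets = score_plates(wells, pc_reference=config.pc_reference)
            cio.write_scores_csv(score_sets, out / "scores.csv")
            return {"n_samples_scored": len(score_sets)}

        summary["score"] = run_stage("score", score_stage)

    if config.cohort_csv:
        patients = cio.read_cohort_csv(config.cohort_csv)
        summary["cohort"] = run_stage("cohort", lambda: _cohort_stage(patients, config, out))
        if config.run_predict:
            summary["predict"] = run_stage("predict", lambda: _predict_stage(patients, config, out))

    _write_json(_jsonable(summary), out / "summary.json")
    return summary
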