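"""Cohort-level analyses: responder classification, score stratification,
contingency tests, survival curves and response-duration summaries.

Patients are classified responder (RECIST best response CR or PR) versus
non-responder (SD or PD).  The central stratifier is a functionality-score
cutoff — score strictly above the cutoff is the high stratum, ties go low —
mirroring how the assay is intended to be used clinically.  Survival
machinery (product-limit estimation, log-rank) is delegated to lifelines;
group comparisons use Pearson chi-squared with a Fisher fallback for sparse
2x2 tables and the Wilcoxon rank-sum test for continuous variables.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import IcarError
from .scoring import LigandScoreSet

__all__ = [
    "PatientRecord",
    "SurvivalCurve",
    "ContingencyResult",
    "Stratification",
    "classify_response",
    "stratify_by_score",
    "response_rate_table",
    "km_estimate",
    "logrank_test",
    "contingency_test",
    "compare_groups",
    "duration_summary",
    "swimmer_table",
]

RECIST_CODES = ("CR", "PR", "SD", "PD")
RESPONDER_CODES = ("CR", "PR")


@dataclass
class PatientRecord:
    """One clinical row: outcome, survival, treatment line, CPS and scores.

    Times are in months.  ``os_event`` is True when death was observed,
    ``pfs_event`` when progression or death was observed; otherwise the time
    is right-censored at last follow-up.  ``cps_value`` may be None (CPS not
    assessable) — such patients are excluded from CPS-stratified analyses,
    never silently dropped elsewhere.
    """

    patient_id: str
    best_response: str
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    line_of_treatment: int
    scores: LigandScoreSet
    cps_value: float | None = None
    response_start_months: float | None = None
    response_end_months: float | None = None
    ongoing: bool = False

    def __post_init__(self):
        if self.best_response not in RECIST_CODES:
            raise IcarError("invalid_recist_code", f"unknown RECIST code {self.best_response!r}")
        if self.line_of_treatment not in (1, 2, 3):
            raise IcarError("invalid_line", f"line_of_treatment must be 1-3, got {self.line_of_treatment}")
        if min(self.os_months, self.pfs_months) < 0:
            raise IcarError("invalid_time", "survival times must be nonnegative")
        if self.os_event and self.pfs_event and self.pfs_months > self.os_months + 1e-9:
            raise IcarError("invalid_time", f"{self.patient_id}: PFS exceeds OS with both events recorded")
        if self.ongoing and self.response_end_months is not None:
            raise IcarError("invalid_time", f"{self.patient_id}: ongoing response cannot have an end time")

    @property
    def responder(self) -> bool:
        return self.best_response in RESPONDER_CODES

    def score(self, name: str) -> float | None:
        return getattr(self.scores, f"{name}_score")


def classify_response(best_response: str) -> str:
    """RECIST best response -> ``"responder"`` (CR/PR) or ``"non_responder"`` (SD/PD)."""
    code = str(best_response).strip().upper()
    if code not in RECIST_CODES:
        raise IcarError("invalid_recist_code", f"unknown RECIST code {best_response!r}")
    return "responder" if code in RESPONDER_CODES else "non_responder"


@dataclass
class Stratification:
    """Score-cutoff partition of a cohort; exhaustive and disjoint over
    patients with the score, with score-less patients listed separately."""

    score_name: str
    cutoff: float
    above: list[PatientRecord] = field(default_factory=list)
    at_or_below: list[PatientRecord] = field(default_factory=list)
    excluded: list[PatientRecord] = field(default_factory=list)

    @property
    def labels(self) -> tuple[str, str]:
        return (f"{self.score_name}>{self.cutoff:g}", f"{self.score_name}<={self.cutoff:g}")

    def as_dict(self) -> dict[str, list[PatientRecord]]:
        hi, lo = self.labels
        return {hi: self.above, lo: self.at_or_below}


def stratify_by_score(
    cohort: list[PatientRecord], score_name: str = "pd1", cutoff: float = 4.0
) -> Stratification:
    """Partition a cohort at a functionality-score cutoff.

    Strict inequality: score > cutoff is the high stratum, exact ties go to
    the low stratum.  Patients missing the score land in ``excluded``.
    """
    out = Stratification(score_name=score_name, cutoff=cutoff)
    for p in cohort:
        s = p.score(score_name)
        if s is None:
            out.excluded.append(p)
        elif s > cutoff:
            out.above.append(p)
        else:
            out.at_or_below.append(p)
    return out


def response_rate_table(strata: dict[str, list[PatientRecord]]) -> pd.DataFrame:
    """Responders / total / percent per stratum.

    Percent is rounded to the nearest integer; an empty stratum reports
    total 0 with percent NA (undefined, not 0).
    """
    rows = []
    for label, patients in strata.items():
        responders = sum(p.responder for p in patients)
        total = len(patients)
        percent = round(100.0 * responders / total) if total else pd.NA
        rows.append({"stratum": label, "responders": responders, "total": total, "percent": percent})
    return pd.DataFrame(rows, columns=["stratum", "responders", "total", "percent"])


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate evaluated at the event times."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t); 1 before the first event."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator with events-before-censorings tie handling.

    ``times`` are months, ``events`` booleans (True = event observed).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise IcarError("empty_cohort", "cannot estimate survival from an empty cohort")
    if np.any(times < 0):
        raise IcarError("invalid_time", "survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    sf = kmf.survival_function_["KM_estimate"]
    t_ev = [float(t) for t in event_rows.index]
    return SurvivalCurve(
        times=tuple(t_ev),
        survival=tuple(float(sf.loc[t]) for t in t_ev),
        at_risk=tuple(int(v) for v in event_rows["at_risk"]),
        n=int(times.size),
    )


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Unweighted log-rank test between two (times, events) groups.

    Returns the 1-df chi-squared statistic and its upper-tail p-value.
    """
    (ta, ea), (tb, eb) = group_a, group_b
    ta, tb = np.asarray(ta, dtype=float), np.asarray(tb, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise IcarError("empty_group", "both groups must be nonempty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(ea, bool), event_observed_B=np.asarray(eb, bool))
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of one group comparison, with the test actually used."""

    table: tuple[tuple[int, ...], ...] | None
    test_used: str  # chi_squared | fisher_exact | wilcoxon_rank_sum
    statistic: float
    p_value: float


def contingency_test(table) -> ContingencyResult:
    """Pearson chi-squared on a 2xk count table, Fisher's exact fallback.

    Fisher's exact test replaces the chi-squared when the table is 2x2 and
    any expected cell count is below 5 (the classical validity rule); the
    chi-squared is uncorrected (no Yates continuity correction).
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.min() < 0:
        raise IcarError("invalid_table", "expected a 2xk table of nonnegative counts")
    if arr.sum() == 0:
        raise IcarError("no_data", "empty contingency table")
    expected = stats.contingency.expected_freq(arr)
    if arr.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(arr)
        return ContingencyResult(tuple(map(tuple, arr)), "fisher_exact", float(odds), float(p))
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(tuple(map(tuple, arr)), "chi_squared", float(chi2), float(p))


def _rank_sum(values_a, values_b) -> ContingencyResult:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    # exact enumeration is feasible (and preferable) for the small strata
    # seen here; ties force the normal approximation with tie correction
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return ContingencyResult(None, "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue))


def compare_groups(values_a, values_b, kind: str = "continuous") -> ContingencyResult:
    """Compare a variable between responders and non-responders.

    ``kind="continuous"`` -> Wilcoxon rank-sum (exact for small tie-free
    groups, otherwise normal approximation with tie correction).
    ``kind="categorical"`` -> build the 2xk table of category counts and
    apply :func:`contingency_test`.
    """
    a = [v for v in values_a if v is not None and not (isinstance(v, float) and np.isnan(v))]
    b = [v for v in values_b if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not a or not b:
        raise IcarError("no_data", "a group has no non-missing observations")
    if kind == "continuous":
        return _rank_sum(a, b)
    if kind == "categorical":
        cats = sorted(set(a) | set(b), key=str)
        table = [[sum(v == c for v in grp) for c in cats] for grp in (a, b)]
        return contingency_test(table)
    raise IcarError("invalid_kind", f"kind must be continuous or categorical, got {kind!r}")


def _response_duration(p: PatientRecord) -> float | None:
    """Months of response: (end or last follow-up) - start; None if no start."""
    if p.response_start_months is None:
        return None
    end = p.os_months if (p.ongoing or p.response_end_months is None) else p.response_end_months
    return max(end - p.response_start_months, 0.0)


def duration_summary(
    cohort: list[PatientRecord], score_name: str = "pd1", cutoff: float = 4.0
) -> dict:
    """Mean response duration per score stratum, with a rank-sum comparison.

    Only responders contribute; ongoing responses are censored at last
    follow-up and included.  Responders missing a response start are
    excluded and reported under ``"excluded"``.
    """
    strat = stratify_by_score([p for p in cohort if p.responder], score_name, cutoff)
    excluded: list[str] = []
    per_stratum: dict[str, list[float]] = {}
    for label, patients in strat.as_dict().items():
        durations = []
        for p in patients:
            d = _response_duration(p)
            if d is None:
                excluded.append(p.patient_id)
            else:
                durations.append(d)
        per_stratum[label] = durations
    means = {
        label: (statistics.fmean(d) if d else None) for label, d in per_stratum.items()
    }
    hi, lo = strat.labels
    p_value = None
    if per_stratum[hi] and per_stratum[lo]:
        p_value = _rank_sum(per_stratum[hi], per_stratum[lo]).p_value
    return {
        "durations": per_stratum,
        "mean_duration": means,
        "p_value": p_value,
        "excluded": excluded,
    }


def swimmer_table(
    cohort: list[PatientRecord], score_name: str = "pd1", cutoff: float = 4.0
) -> pd.DataFrame:
    """Per-patient timeline rows for a swimmer plot, sorted by stratum then
    follow-up length; plotting itself is left to downstream tools."""
    strat = stratify_by_score(cohort, score_name, cutoff)
    label_of: dict[str, str] = {}
    for label, patients in strat.as_dict().items():
        for p in patients:
            label_of[p.patient_id] = label
    for p in strat.excluded:
        label_of[p.patient_id] = "no_score"

    rows = []
    for p in cohort:
        rows.append(
            {
                "patient_id": p.patient_id,
                "stratum": label_of[p.patient_id],
                "responder": p.responder,
                "followup_months": p.os_months,
                "response_start_months": p.response_start_months,
                "response_end_months": p.response_end_months,
                "ongoing": p.ongoing,
                "duration_months": _response_duration(p),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "stratum",
            "responder",
            "followup_months",
            "response_start_months",
            "response_end_months",
            "ongoing",
            "duration_months",
        ],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["stratum", "followup_months"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
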