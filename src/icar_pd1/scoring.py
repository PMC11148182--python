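"""Functionality scoring of PD-1 ligands from reporter-assay plate data.

A PD-1-overexpressing reporter cell line secretes murine IL-2 when its
receptor engages functional PD-L1/PD-L2 on a tissue sample.  Blocking the
receptor (pembrolizumab) or one ligand (durvalumab for PD-L1, anti-CD273 for
PD-L2) suppresses that signal; the drop relative to the unblocked wells
quantifies how much functional ligand the sample presents.  The per-sample
functionality score is

    score = (mean unblocked signal - mean blocked signal)
            / log2(tissue coverage in mm^2) * PC ratio

where the log2 coverage term normalises for the amount of tissue in the well
and the PC (positive-control) ratio harmonises signal levels across plates
and experiments.

This module is purely computational: signals arrive as numbers (optical
density or ELISA-interpolated IL-2 concentration), coverage arrives as mm^2.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import IcarError

__all__ = [
    "BlockingCondition",
    "WellRecord",
    "StandardCurve",
    "PlateNormalization",
    "LigandScoreSet",
    "DeltaResponse",
    "fit_standard_curve",
    "interpolate_concentration",
    "compute_delta_response",
    "compute_icar_score",
    "compute_plate_normalizations",
    "subtract_blank",
    "score_patient",
    "score_plates",
]

#: minimum coverage (mm^2); at or below this log2(coverage) <= 0 and the
#: score would flip sign or blow up, so it is a hard error.
MIN_COVERAGE_MM2 = 1.0


class BlockingCondition(str, enum.Enum):
    """Which antibody (if any) was present in a well.

    ``BLOCK_PD1`` = pembrolizumab on the reporter receptor, ``BLOCK_PDL1`` =
    durvalumab, ``BLOCK_PDL2`` = anti-CD273.  ``POSITIVE_CONTROL`` wells carry
    a ligand-coated standard instead of tissue; ``BLANK`` wells carry medium
    only.
    """

    NO_AB = "NO_AB"
    BLOCK_PD1 = "BLOCK_PD1"
    BLOCK_PDL1 = "BLOCK_PDL1"
    BLOCK_PDL2 = "BLOCK_PDL2"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"
    BLANK = "BLANK"

    @classmethod
    def parse(cls, label: str) -> "BlockingCondition":
        """Parse a condition label case-insensitively; reject anything else."""
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise IcarError("invalid_condition", f"unknown blocking condition {label!r}")


#: blocking conditions that yield a ligand/receptor functionality score
SCORED_CONDITIONS = (
    BlockingCondition.BLOCK_PD1,
    BlockingCondition.BLOCK_PDL1,
    BlockingCondition.BLOCK_PDL2,
)

_SCORE_ATTR = {
    BlockingCondition.BLOCK_PD1: "pd1_score",
    BlockingCondition.BLOCK_PDL1: "pdl1_score",
    BlockingCondition.BLOCK_PDL2: "pdl2_score",
}


@dataclass(frozen=True)
class WellRecord:
    """One well of a 96-well reporter co-culture plate."""

    plate_id: str
    sample_id: str
    condition: BlockingCondition
    signal: float
    coverage_mm2: float | None = None
    replicate_index: int = 1
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.signal < 0:
            raise IcarError("negative_signal", f"well signal {self.signal} < 0")
        needs_coverage = self.condition not in (
            BlockingCondition.POSITIVE_CONTROL,
            BlockingCondition.BLANK,
        )
        if needs_coverage:
            if self.coverage_mm2 is None or not self.coverage_mm2 > 0:
                raise IcarError(
                    "invalid_coverage",
                    f"sample well {self.sample_id}/{self.condition.value} needs coverage_mm2 > 0",
                )
        if self.replicate_index < 1:
            raise IcarError("invalid_replicate", "replicate_index must be >= 1")


@dataclass(frozen=True)
class StandardCurve:
    """Four-parameter logistic (4PL) ELISA calibration curve.

    signal(c) = upper + (lower - upper) / (1 + (c / inflection) ** slope)

    ``lower``/``upper`` are the asymptotes, ``inflection`` the concentration
    at the half-maximal signal, ``slope`` the Hill coefficient (negative for
    a decreasing curve).  Interpolation is defined only strictly between the
    asymptotes and within the observed calibrator signal range.
    """

    lower: float
    upper: float
    inflection: float
    slope: float
    fit_residual: float
    calibrator_points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.upper > self.lower:
            raise IcarError("degenerate_curve", "upper asymptote must exceed lower")

    def signal_at(self, concentration: float) -> float:
        """Forward 4PL evaluation."""
        return _four_pl(concentration, self.lower, self.upper, self.inflection, self.slope)

    @property
    def signal_range(self) -> tuple[float, float]:
        sigs = [s for _, s in self.calibrator_points]
        return min(sigs), max(sigs)


def _four_pl(x, lower, upper, inflection, slope):
    return upper + (lower - upper) / (1.0 + (x / inflection) ** slope)


def fit_standard_curve(
    calibrators: list[tuple[float, float]],
) -> StandardCurve:
    """Least-squares 4PL fit to (known concentration, observed signal) pairs.

    Requires at least five distinct calibrator concentrations and a clearly
    monotone concentration/signal trend (Spearman |rho| >= 0.9, the regime
    of a working sandwich ELISA).

    Raises
    ------
    IcarError
        ``insufficient_calibrators`` with < 5 distinct concentrations;
        ``degenerate_curve`` for flat or non-monotone calibrator trends.
    """
    pts = [(float(c), float(s)) for c, s in calibrators]
    if len({c for c, _ in pts}) < 5:
        raise IcarError("insufficient_calibrators", "need >= 5 distinct calibrator concentrations")
    if any(s < 0 for _, s in pts):
        raise IcarError("negative_signal", "calibrator signals must be nonnegative")
    conc = np.array([c for c, _ in pts])
    sig = np.array([s for _, s in pts])
    if np.ptp(sig) == 0:
        raise IcarError("degenerate_curve", "all calibrator signals identical")
    rho = stats.spearmanr(conc, sig).statistic
    if not abs(rho) >= 0.9:
        raise IcarError("degenerate_curve", f"calibrator trend not monotone (spearman rho={rho:.2f})")

    increasing = rho > 0
    lo, hi = float(sig.min()), float(sig.max())
    span = hi - lo
    p0 = (
        max(lo - 0.05 * span, 0.0),
        hi + 0.05 * span,
        float(np.exp(np.mean(np.log(np.maximum(conc, 1e-12))))),
        1.0 if increasing else -1.0,
    )
    bounds = (
        [0.0, lo, 1e-12, 0.01 if increasing else -50.0],
        [hi, np.inf, np.inf, 50.0 if increasing else -0.01],
    )
    try:
        popt, _ = optimize.curve_fit(_four_pl, conc, sig, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise IcarError("degenerate_curve", f"4PL fit failed: {exc}")
    residual = float(np.sum((sig - _four_pl(conc, *popt)) ** 2))
    return StandardCurve(
        lower=float(popt[0]),
        upper=float(popt[1]),
        inflection=float(popt[2]),
        slope=float(popt[3]),
        fit_residual=residual,
        calibrator_points=tuple(pts),
    )


def interpolate_concentration(curve: StandardCurve, signal: float) -> float:
    """Invert a 4PL curve: the unique concentration producing ``signal``.

    Defined only for signals strictly between the asymptotes and inside the
    calibrator signal range; anything else raises ``out_of_range``.
    """
    lo, hi = curve.signal_range
    if not (curve.lower < signal < curve.upper) or not (lo <= signal <= hi):
        raise IcarError(
            "out_of_range",
            f"signal {signal} outside invertible range ({max(curve.lower, lo)}, {min(curve.upper, hi)})",
        )
    # y = u + (l-u)/(1+t)  =>  t = (y-l)/(u-y),  c = inflection * t**(1/slope)
    t = (signal - curve.lower) / (curve.upper - signal)
    return float(curve.inflection * t ** (1.0 / curve.slope))


@dataclass(frozen=True)
class PlateNormalization:
    """Positive-control scaling for one plate.

    ``pc_ratio = pc_reference / pc_response`` rescales that plate's signals to
    a common reference level so scores are comparable across plates and
    experiments.
    """

    plate_id: str
    pc_response: float
    pc_reference: float

    def __post_init__(self):
        if not self.pc_response > 0 or not self.pc_reference > 0:
            raise IcarError("invalid_pc", "positive-control signals must be > 0")

    @property
    def pc_ratio(self) -> float:
        return self.pc_reference / self.pc_response


@dataclass(frozen=True)
class DeltaResponse:
    """Unblocked-minus-blocked response with replicate spread for QC."""

    delta: float
    unblocked_mean: float
    blocked_mean: float
    unblocked_sd: float
    blocked_sd: float
    flags: frozenset[str]


@dataclass
class LigandScoreSet:
    """Per-patient functionality scores for the three blocking conditions.

    A score is ``None`` when the corresponding blocking condition was absent
    from the plate (flagged ``missing_<condition>``).  Negative scores are
    retained — they indicate a blocking failure, not an impossible value —
    and flagged ``negative_delta``.
    """

    sample_id: str
    pd1_score: float | None = None
    pdl1_score: float | None = None
    pdl2_score: float | None = None
    qc_flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "pd1_score": self.pd1_score,
            "pdl1_score": self.pdl1_score,
            "pdl2_score": self.pdl2_score,
            "qc_flags": ";".join(sorted(self.qc_flags)),
        }


def compute_delta_response(
    unblocked_wells: list[WellRecord],
    blocked_wells: list[WellRecord],
) -> DeltaResponse:
    """Mean unblocked signal minus mean blocked signal for one sample.

    Both well lists must be nonempty, share one sample and one plate, and
    the unblocked wells must all be ``NO_AB``.  A negative delta (blocked
    wells brighter than unblocked) is kept and flagged ``negative_delta``.
    """
    if not unblocked_wells or not blocked_wells:
        raise IcarError("missing_condition", "need at least one unblocked and one blocked well")
    wells = list(unblocked_wells) + list(blocked_wells)
    if len({w.sample_id for w in wells}) != 1 or len({w.plate_id for w in wells}) != 1:
        raise IcarError("sample_mismatch", "wells span multiple samples or plates")
    if any(w.condition is not BlockingCondition.NO_AB for w in unblocked_wells):
        raise IcarError("condition_mismatch", "unblocked wells must have condition NO_AB")

    ub = [w.signal for w in unblocked_wells]
    bl = [w.signal for w in blocked_wells]
    delta = statistics.fmean(ub) - statistics.fmean(bl)
    flags = {"negative_delta"} if delta < 0 else set()
    return DeltaResponse(
        delta=delta,
        unblocked_mean=statistics.fmean(ub),
        blocked_mean=statistics.fmean(bl),
        unblocked_sd=statistics.stdev(ub) if len(ub) > 1 else 0.0,
        blocked_sd=statistics.stdev(bl) if len(bl) > 1 else 0.0,
        flags=frozenset(flags),
    )


def compute_icar_score(delta: float, coverage_mm2: float, pc_ratio: float) -> float:
    """Core functionality score: ``delta / log2(coverage_mm2) * pc_ratio``.

    ``coverage_mm2`` must exceed 1 mm^2 so the log2 term is positive;
    ``pc_ratio`` must be positive.
    """
    if not coverage_mm2 > MIN_COVERAGE_MM2:
        raise IcarError(
            "coverage_too_small",
            f"coverage {coverage_mm2} mm^2 <= {MIN_COVERAGE_MM2} mm^2: log2 normalisation undefined",
        )
    if not pc_ratio > 0:
        raise IcarError("invalid_pc", f"pc_ratio must be > 0, got {pc_ratio}")
    return delta / math.log2(coverage_mm2) * pc_ratio


def compute_plate_normalizations(
    wells: list[WellRecord],
    pc_reference: float | None = None,
) -> dict[str, PlateNormalization]:
    """Per-plate positive-control normalisation from the PC wells.

    ``pc_response`` is the mean POSITIVE_CONTROL signal on each plate.  The
    reference defaults to the grand mean of all PC wells across plates in the
    run, so a single-plate run has pc_ratio == 1; pass a configured
    ``pc_reference`` to harmonise against an external standard instead.
    """
    pc = [w for w in wells if w.condition is BlockingCondition.POSITIVE_CONTROL]
    plate_ids = sorted({w.plate_id for w in wells})
    if not pc:
        raise IcarError("missing_positive_control", "no POSITIVE_CONTROL wells in run")
    if pc_reference is None:
        pc_reference = statistics.fmean(w.signal for w in pc)
    out: dict[str, PlateNormalization] = {}
    for plate_id in plate_ids:
        plate_pc = [w.signal for w in pc if w.plate_id == plate_id]
        if not plate_pc:
            raise IcarError("missing_positive_control", f"plate {plate_id} has no POSITIVE_CONTROL wells")
        out[plate_id] = PlateNormalization(
            plate_id=plate_id,
            pc_response=statistics.fmean(plate_pc),
            pc_reference=float(pc_reference),
        )
    return out


def subtract_blank(wells: list[WellRecord]) -> list[WellRecord]:
    """Subtract each plate's mean BLANK signal from its other wells.

    Applied before any other processing when blank wells exist; results are
    floored at zero.  Plates without blanks pass through unchanged.
    """
    by_plate: dict[str, list[float]] = {}
    for w in wells:
        if w.condition is BlockingCondition.BLANK:
            by_plate.setdefault(w.plate_id, []).append(w.signal)
    if not by_plate:
        return list(wells)
    out = []
    for w in wells:
        if w.condition is BlockingCondition.BLANK:
            continue
        blank = statistics.fmean(by_plate[w.plate_id]) if w.plate_id in by_plate else 0.0
        out.append(
            WellRecord(
                plate_id=w.plate_id,
                sample_id=w.sample_id,
                condition=w.condition,
                signal=max(w.signal - blank, 0.0),
                coverage_mm2=w.coverage_mm2,
                replicate_index=w.replicate_index,
                extra=w.extra,
            )
        )
    return out


def score_patient(wells: list[WellRecord], norm: PlateNormalization) -> LigandScoreSet:
    """Score one sample's wells into PD-1 / PD-L1 / PD-L2 functionality scores.

    Requires NO_AB wells plus at least one blocking condition.  Replicates
    are aggregated by arithmetic mean (signals and coverage) before the
    score formula is applied; a blocking condition absent from the plate
    yields a ``None`` score with a ``missing_<condition>`` flag.
    """
    sample_wells = [
        w
        for w in wells
        if w.condition not in (BlockingCondition.POSITIVE_CONTROL, BlockingCondition.BLANK)
    ]
    if not sample_wells:
        raise IcarError("missing_condition", "no sample wells given")
    sample_ids = {w.sample_id for w in sample_wells}
    if len(sample_ids) != 1:
        raise IcarError("sample_mismatch", f"expected one sample, got {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    by_cond: dict[BlockingCondition, list[WellRecord]] = {}
    for w in sample_wells:
        by_cond.setdefault(w.condition, []).append(w)
    unblocked = by_cond.get(BlockingCondition.NO_AB)
    if not unblocked:
        raise IcarError("missing_condition", f"sample {sample_id} has no NO_AB wells")

    result = LigandScoreSet(sample_id=sample_id)
    if len(by_cond) == 1:
        raise IcarError("missing_condition", f"sample {sample_id} has no blocking-condition wells")
    for cond in SCORED_CONDITIONS:
        blocked = by_cond.get(cond)
        if not blocked:
            result.qc_flags.add(f"missing_{cond.value}")
            continue
        dr = compute_delta_response(unblocked, blocked)
        coverage = statistics.fmean(w.coverage_mm2 for w in unblocked + blocked)
        score = compute_icar_score(dr.delta, coverage, norm.pc_ratio)
        setattr(result, _SCORE_ATTR[cond], score)
        result.qc_flags |= dr.flags
    return result


def score_plates(
    wells: list[WellRecord],
    pc_reference: float | None = None,
    blank_subtract: bool = True,
) -> list[LigandScoreSet]:
    """Score every sample in a (possibly multi-plate) run.

    Blank subtraction (when blanks exist) and per-plate PC normalisation are
    applied first; each sample is then scored on its own plate.  Samples are
    returned in sorted sample_id order.
    """
    if blank_subtract:
        wells = subtract_blank(wells)
    norms = compute_plate_normalizations(wells, pc_reference=pc_reference)
    groups: dict[tuple[str, str], list[WellRecord]] = {}
    for w in wells:
        if w.condition in (BlockingCondition.POSITIVE_CONTROL, BlockingCondition.BLANK):
            continue
        groups.setdefault((w.sample_id, w.plate_id), []).append(w)

    by_sample: dict[str, list[LigandScoreSet]] = {}
    for (sample_id, plate_id), ws in sorted(groups.items()):
        by_sample.setdefault(sample_id, []).append(score_patient(ws, norms[plate_id]))

    out: list[LigandScoreSet] = []
    for sample_id in sorted(by_sample):
        per_plate = by_sample[sample_id]
        if len(per_plate) == 1:
            out.append(per_plate[0])
            continue
        # sample split across plates: average the plate-level scores
        merged = LigandScoreSet(sample_id=sample_id, qc_flags={"multi_plate"})
        for attr in ("pd1_score", "pdl1_score", "pdl2_score"):
            vals = [getattr(s, attr) for s in per_plate if getattr(s, attr) is not None]
            setattr(merged, attr, statistics.fmean(vals) if vals else None)
        for s in per_plate:
            merged.qc_flags |= s.qc_flags
        out.append(merged)
    return out
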