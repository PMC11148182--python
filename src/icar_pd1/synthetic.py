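"""Synthetic cohorts and plates with the statistical structure the pipeline assumes.

The generator produces two linked layers:

* a clinical cohort — latent per-patient PD-L1 and PD-L2 functionalities
  drawn log-normally, a PD-1 functionality equal to their sum (receptor
  blockade ablates both ligand interactions), treatment response drawn from
  a logistic model on the PD-1 functionality, exponential overall/progression
  survival with response-dependent hazards and uniform right-censoring, a
  CPS that agrees with PD-L1 functionality only with a configurable
  concordance probability (so CPS-negative responders exist), and a
  first/second/third treatment-line assignment;

* raw plates — the score formula run backwards: for each patient the
  unblocked wells sit at (blocked floor + largest delta) and each blocking
  condition's wells are depressed by latent x log2(coverage) / pc_ratio, so
  with zero noise the scoring module recovers the latent functionalities
  exactly, including across plates with different positive-control levels.

Defaults describe a 29-patient cohort balanced between responders and
non-responders with roughly 13 patients above the functionality cutoff of 4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .errors import IcarError
from .scoring import BlockingCondition, LigandScoreSet, PlateNormalization, WellRecord

__all__ = ["GeneratorConfig", "PRESETS", "generate_cohort", "generate_plates"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the target cohort."""

    n_patients: int = 29
    seed: int = 0
    # latent functionality layer (log-scale means/SD of the two ligand scores)
    ligand_means: tuple[float, float] = (0.7, -0.1)
    ligand_sd: float = 1.0
    # logistic response model on the PD-1 (summed) functionality
    response_intercept: float = -2.2
    response_slope: float = 0.55
    # half-width of a forbidden band around score_cutoff: latents landing
    # inside are redrawn, giving a strongly separated cohort (0 = off)
    score_margin: float = 0.0
    # CPS layer
    cps_concordance: float = 0.8
    cps_functional_cutoff: float = 2.0
    n_missing_cps: int = 1
    # survival layer (per-month exponential hazards; responders live longer)
    os_hazard_responder: float = 1 / 32.0
    os_hazard_nonresponder: float = 1 / 17.0
    pfs_hazard_responder: float = 1 / 27.0
    pfs_hazard_nonresponder: float = 1 / 7.0
    censor_time_max: float = 60.0
    # response-duration layer (months, exponential means by score stratum)
    duration_mean_high: float = 28.0
    duration_mean_low: float = 8.0
    score_cutoff: float = 4.0
    # treatment lines drawn multinomially (first/second/third)
    line_probs: tuple[float, float, float] = (10 / 29, 17 / 29, 2 / 29)
    # plate layer
    well_noise_sd: float = 0.0  # SD as a fraction of each well's clean signal
    coverage_range: tuple[float, float] = (2.0, 8.0)
    pc_ratio_spread: float = 0.0  # SD of log pc_ratio across plates
    n_plates: int = 3
    n_replicates: int = 2
    blocked_floor: float = 20.0
    pc_reference_signal: float = 150.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise IcarError("invalid_config", "n_patients must be >= 1")
        if not 0 <= self.cps_concordance <= 1:
            raise IcarError("invalid_config", "cps_concordance must be in [0, 1]")
        if not self.os_hazard_responder < self.os_hazard_nonresponder:
            raise IcarError("invalid_config", "responder OS hazard must be below non-responder hazard")
        if self.coverage_range[0] <= 1 or self.coverage_range[1] < self.coverage_range[0]:
            raise IcarError("invalid_config", "coverage_range must satisfy 1 < low <= high")
        if self.well_noise_sd < 0 or self.pc_ratio_spread < 0:
            raise IcarError("invalid_config", "noise parameters must be nonnegative")
        if abs(sum(self.line_probs) - 1.0) > 1e-9 or min(self.line_probs) < 0:
            raise IcarError("invalid_config", "line_probs must be a probability vector")
        if self.ligand_sd <= 0:
            raise IcarError("invalid_config", "ligand_sd must be positive")


#: named study conditions.  ``strong-effect`` makes response nearly
#: deterministic in the PD-1 functionality (steep logistic centred on the
#: cutoff) — the regime in which the sampling-curve evaluation should hold a
#: high minimum AUC.  ``null`` severs the response/score link entirely.
PRESETS: dict[str, GeneratorConfig] = {
    "default": GeneratorConfig(),
    "strong-effect": dataclasses.replace(
        GeneratorConfig(), response_slope=12.0, response_intercept=-48.0, score_margin=1.0
    ),
    "null": dataclasses.replace(
        GeneratorConfig(), response_slope=0.0, response_intercept=0.0
    ),
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: GeneratorConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Draw a synthetic cohort plus its latent truth table.

    The truth table carries the latent functionalities, response
    probabilities and CPS agreement indicators so downstream recovery tests
    can compare observed against generating values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    pdl1 = rng.lognormal(config.ligand_means[0], config.ligand_sd, size=n)
    pdl2 = rng.lognormal(config.ligand_means[1], config.ligand_sd, size=n)
    pd1 = pdl1 + pdl2
    if config.score_margin > 0:
        # rejection step: keep the summed functionality out of the band
        # (cutoff - margin, cutoff + margin) so the two strata separate cleanly
        lo, hi = config.score_cutoff - config.score_margin, config.score_cutoff + config.score_margin
        for _ in range(1000):
            inside = (pd1 > lo) & (pd1 < hi)
            if not inside.any():
                break
            k = int(inside.sum())
            pdl1[inside] = rng.lognormal(config.ligand_means[0], config.ligand_sd, size=k)
            pdl2[inside] = rng.lognormal(config.ligand_means[1], config.ligand_sd, size=k)
            pd1 = pdl1 + pdl2

    p_resp = _sigmoid(config.response_intercept + config.response_slope * pd1)
    responder = rng.random(n) < p_resp
    # split responder/non-responder into RECIST codes (CR rarer than PR,
    # SD/PD roughly even — cosmetic, the analyses only use the dichotomy)
    best = np.where(
        responder,
        np.where(rng.random(n) < 0.25, "CR", "PR"),
        np.where(rng.random(n) < 0.45, "SD", "PD"),
    )

    os_hazard = np.where(responder, config.os_hazard_responder, config.os_hazard_nonresponder)
    pfs_hazard = np.where(responder, config.pfs_hazard_responder, config.pfs_hazard_nonresponder)
    t_death = rng.exponential(1.0 / os_hazard)
    t_censor = rng.uniform(0.0, config.censor_time_max, size=n)
    os_months = np.minimum(t_death, t_censor)
    os_event = t_death <= t_censor
    t_prog = rng.exponential(1.0 / pfs_hazard)
    pfs_months = np.minimum(t_prog, os_months)
    pfs_event = (t_prog <= os_months) | os_event

    functional_pos = pdl1 > config.cps_functional_cutoff
    agree = rng.random(n) < config.cps_concordance
    cps_positive = np.where(agree, functional_pos, ~functional_pos)
    cps_value = np.where(
        cps_positive,
        np.minimum(np.exp(rng.normal(2.0, 1.0, size=n)) + 1.0, 100.0),
        rng.uniform(0.0, 1.0, size=n),
    )
    missing_cps = rng.choice(n, size=min(config.n_missing_cps, n), replace=False)

    lines = rng.choice([1, 2, 3], size=n, p=config.line_probs)

    high = pd1 > config.score_cutoff
    dur_mean = np.where(high, config.duration_mean_high, config.duration_mean_low)
    resp_start = rng.uniform(1.0, 3.0, size=n)
    resp_duration = rng.exponential(dur_mean)

    patients: list[PatientRecord] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        start = end = None
        ongoing = False
        if responder[i]:
            start = float(min(resp_start[i], os_months[i]))
            planned_end = start + float(resp_duration[i])
            if planned_end >= os_months[i] and not os_event[i]:
                ongoing = True  # response still running at last follow-up
            else:
                end = float(min(planned_end, os_months[i]))
        patients.append(
            PatientRecord(
                patient_id=pid,
                best_response=str(best[i]),
                os_months=float(os_months[i]),
                os_event=bool(os_event[i]),
                pfs_months=float(pfs_months[i]),
                pfs_event=bool(pfs_event[i]),
                line_of_treatment=int(lines[i]),
                cps_value=None if i in missing_cps else float(cps_value[i]),
                scores=LigandScoreSet(
                    sample_id=pid,
                    pd1_score=float(pd1[i]),
                    pdl1_score=float(pdl1[i]),
                    pdl2_score=float(pdl2[i]),
                ),
                response_start_months=start,
                response_end_months=end,
                ongoing=ongoing,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "pdl1_latent": float(pdl1[i]),
                "pdl2_latent": float(pdl2[i]),
                "pd1_latent": float(pd1[i]),
                "response_prob": float(p_resp[i]),
                "responder": bool(responder[i]),
                "high_score": bool(high[i]),
                "cps_functional_positive": bool(functional_pos[i]),
                "cps_positive": bool(cps_positive[i]),
                "cps_missing": bool(i in missing_cps),
            }
        )
    return patients, pd.DataFrame(truth_rows)


def generate_plates(
    truth: pd.DataFrame, config: GeneratorConfig
) -> tuple[list[WellRecord], dict[str, PlateNormalization]]:
    """Emit raw wells realising the latent functionalities of a cohort.

    Construction inverts the score formula.  Per patient one coverage value
    is drawn (the same tissue preparation feeds all of that patient's
    wells) and, per blocking condition c,

        blocked_c = U - latent_c * log2(coverage) / pc_ratio,
        U = blocked_floor + max_c(latent_c * log2(coverage) / pc_ratio),

    with the NO_AB wells at U.  Positive-control wells realise the plate's
    drawn pc_ratio against the configured reference signal.  Multiplicative
    Gaussian noise (SD = ``well_noise_sd`` x clean signal) is added last.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the cohort stream
    lo, hi = config.coverage_range
    if lo <= 1:
        raise IcarError("invalid_config", "coverage_range low bound must exceed 1 mm^2")

    plate_ids = [f"PL{j + 1}" for j in range(config.n_plates)]
    pc_ratios = np.exp(rng.normal(0.0, config.pc_ratio_spread, size=config.n_plates))
    norms = {
        pid: PlateNormalization(
            plate_id=pid,
            pc_response=config.pc_reference_signal / pc_ratios[j],
            pc_reference=config.pc_reference_signal,
        )
        for j, pid in enumerate(plate_ids)
    }

    def emit(plate_id, sample_id, cond, clean, coverage, rep):
        noisy = clean
        if config.well_noise_sd > 0:
            noisy = clean * (1.0 + rng.normal(0.0, config.well_noise_sd))
        return WellRecord(
            plate_id=plate_id,
            sample_id=sample_id,
            condition=cond,
            signal=max(float(noisy), 0.0),
            coverage_mm2=coverage,
            replicate_index=rep,
        )

    wells: list[WellRecord] = []
    cond_of = {
        "pd1_latent": BlockingCondition.BLOCK_PD1,
        "pdl1_latent": BlockingCondition.BLOCK_PDL1,
        "pdl2_latent": BlockingCondition.BLOCK_PDL2,
    }
    for i, row in enumerate(truth.itertuples(index=False)):
        plate_idx = i % config.n_plates
        plate_id = plate_ids[plate_idx]
        pc_ratio = float(pc_ratios[plate_idx])
        coverage = float(rng.uniform(lo, hi))
        log2cov = np.log2(coverage)
        deltas = {
            key: getattr(row, key) * log2cov / pc_ratio for key in cond_of
        }
        unblocked = config.blocked_floor + max(max(deltas.values()), 0.0)
        for rep in range(1, config.n_replicates + 1):
            wells.append(emit(plate_id, row.patient_id, BlockingCondition.NO_AB, unblocked, coverage, rep))
            for key, cond in cond_of.items():
                wells.append(emit(plate_id, row.patient_id, cond, unblocked - deltas[key], coverage, rep))
    for j, plate_id in enumerate(plate_ids):
        for rep in range(1, config.n_replicates + 1):
            wells.append(
                emit(plate_id, "PC", BlockingCondition.POSITIVE_CONTROL,
                     norms[plate_id].pc_response, None, rep)
            )
    return wells, norms
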