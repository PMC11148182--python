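import dataclasses

import pytest

from icar_pd1.scoring import BlockingCondition, PlateNormalization, WellRecord
from icar_pd1.synthetic import PRESETS, GeneratorConfig, generate_cohort


def well(cond, signal, *, plate="PL1", sample="S1", coverage=4.0, rep=1):
    coverage = None if cond in (BlockingCondition.POSITIVE_CONTROL, BlockingCondition.BLANK) else coverage
    return WellRecord(
        plate_id=plate, sample_id=sample, condition=cond, signal=signal,
        coverage_mm2=coverage, replicate_index=rep,
    )


@pytest.fixture
def toy_plate():
    """One sample: unblocked 100, blocks at 40/70/90, coverage 4 mm^2.

    With pc_ratio 1 the three functionality scores are (60/2, 30/2, 10/2)
    = (30, 15, 5).
    """
    wells = [
        well(BlockingCondition.NO_AB, 100.0, rep=1),
        well(BlockingCondition.NO_AB, 100.0, rep=2),
        well(BlockingCondition.BLOCK_PD1, 40.0),
        well(BlockingCondition.BLOCK_PDL1, 70.0),
        well(BlockingCondition.BLOCK_PDL2, 90.0),
    ]
    norm = PlateNormalization(plate_id="PL1", pc_response=150.0, pc_reference=150.0)
    return wells, norm


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(dataclasses.replace(PRESETS["strong-effect"], seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(dataclasses.replace(PRESETS["null"], seed=11))
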