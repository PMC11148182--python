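"""Combined Positive Score (CPS) for PD-L1 immunohistochemistry.

CPS = 100 x (PD-L1-positive tumor cells + PD-L1-positive immune cells)
          / total viable tumor cells

Immune cells here are lymphocytes and macrophages within the tumor
microenvironment.  CPS >= 1 is conventionally called positive; cohort tables
additionally band values into <1, 1-20 and >20.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import IcarError

__all__ = ["CpsInput", "compute_cps", "classify_cps", "band_cps", "CPS_BANDS"]

CPS_BANDS = ("<1", "1-20", ">20")


@dataclass(frozen=True)
class CpsInput:
    pdl1_positive_tumor_cells: int
    pdl1_positive_immune_cells: int
    total_viable_tumor_cells: int

    def __post_init__(self):
        if self.total_viable_tumor_cells < 1:
            raise IcarError("count_inconsistency", "total viable tumor cells must be >= 1")
        if min(self.pdl1_positive_tumor_cells, self.pdl1_positive_immune_cells) < 0:
            raise IcarError("count_inconsistency", "cell counts must be nonnegative")
        if self.pdl1_positive_tumor_cells > self.total_viable_tumor_cells:
            raise IcarError(
                "count_inconsistency",
                "PD-L1-positive tumor cells exceed total viable tumor cells",
            )


def compute_cps(counts: CpsInput) -> float:
    """CPS from raw cell counts; scale-invariant in the three counts."""
    positive = counts.pdl1_positive_tumor_cells + counts.pdl1_positive_immune_cells
    return 100.0 * positive / counts.total_viable_tumor_cells


def classify_cps(cps_value: float, threshold: float = 1.0, inclusive: bool = True) -> str:
    """Positivity call: ``"positive"`` iff CPS >= threshold (default 1).

    The boundary value is positive by convention; set ``inclusive=False``
    for the strict reading used by some cohort groupings.
    """
    if cps_value < 0:
        raise IcarError("count_inconsistency", "CPS cannot be negative")
    hit = cps_value >= threshold if inclusive else cps_value > threshold
    return "positive" if hit else "negative"


def band_cps(cps_value: float) -> str:
    """Band a CPS value into the reporting categories <1, 1-20, >20.

    The bands partition [0, inf): [0,1), [1,20], (20, inf).
    """
    if cps_value < 0:
        raise IcarError("count_inconsistency", "CPS cannot be negative")
    if cps_value < 1:
        return CPS_BANDS[0]
    if cps_value <= 20:
        return CPS_BANDS[1]
    return CPS_BANDS[2]
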