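"""Published reference values from the motivating EMR cohort study.

These constants are the printed summary statistics of the large
pharmacoepidemiology study of CYP-mediated DDIs and myopathy that this
package reimplements as a pipeline: the five significant synergistic pairs
with their age/sex-adjusted group risks and counts, the cohort-level
myopathy demographics, and the design of the statin power scenario. They are
inputs for worked examples and regression checks; nothing in the pipeline
depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SynergyRow:
    drug1: str
    drug2: str
    enzymes: str
    risk1: float
    risk2: float
    risk12: float
    rr_published: float
    counts: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # (m,n) x 3


#: Age/sex-adjusted risks of the five significant synergistic DDI pairs.
SYNERGY_PAIRS: tuple[SynergyRow, ...] = (
    SynergyRow("loratadine", "simvastatin", "CYP3A4/5", 0.022, 0.033, 0.093,
               1.69, ((1264, 44245), (4197, 102345), (137, 1223))),
    SynergyRow("loratadine", "alprazolam", "CYP3A4/5", 0.022, 0.029, 0.095,
               1.86, ((1257, 43341), (2251, 52341), (176, 1448))),
    SynergyRow("loratadine", "duloxetine", "CYP2D6", 0.020, 0.047, 0.130,
               1.94, ((1220, 43552), (1385, 23470), (90, 631))),
    SynergyRow("loratadine", "ropinirole", "CYP2D6", 0.020, 0.018, 0.122,
               3.21, ((1218, 43491), (164, 6531), (17, 123))),
    SynergyRow("promethazine", "tegaserod", "CYP2D6", 0.011, 0.020, 0.093,
               3.00, ((1332, 78334), (109, 3745), (23, 224))),
)

#: Cohort myopathy counts (patients with / without a myopathy event).
MYOPATHY_YES = 59_572
MYOPATHY_NO = 769_333

#: Demographic effects: patient-level myopathy risks by sex and the
#: per-year age odds multiplier.
FEMALE_RISK = 0.086
MALE_RISK = 0.054
AGE_OR_PER_YEAR = 1.0015

#: Number of predicted pairs co-medicated in the EMR, defining the
#: Bonferroni family for the primary hypothesis tests.
N_TESTED_PAIRS = 3670

#: Statin power scenario: fewer than 110 patients took both drugs within the
#: one-month interval in each recognised statin pair; single-exposure risks
#: are at the ~2.5% scale of those cohorts.
STATIN_POWER_SCENARIO = {
    "n1": 20_000,
    "n2": 20_000,
    "n12": 110,
    "risk1": 0.026,
    "risk2": 0.023,
    "rr_alt": 1.5,
}


def myopathy_prevalence() -> float:
    """Cohort myopathy prevalence yes / (yes + no)."""
    return MYOPATHY_YES / (MYOPATHY_YES + MYOPATHY_NO)
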