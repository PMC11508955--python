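"""Published validation tables of the source study, as a datasets registry.

Each entry is one 2x2 comparison of a marker (or marker combination)
against reference HLA typing in the Spanish-hospital validation cohort,
with the study's printed point metrics (half-up percentages to 1 dp).
These counts are *inputs*: tests and the acceptance workflow reconstruct
minimal cohorts from them and re-derive every metric through the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StudyTable", "study_tables", "DEGENERATE_CI_BOUNDS"]


@dataclass(frozen=True)
class StudyTable:
    """One published marker-vs-reference 2x2 comparison."""

    key: str
    target: str
    marker: str              # evaluation unit label (rsID, combination, or assay)
    assay_ids: tuple[str, ...]  # default-panel assays realising the unit
    combinator: str          # how assay_ids combine for this unit
    tp: int
    fp: int
    fn: int
    tn: int
    n_indeterminate: int
    printed: dict            # metric -> percent to 1 dp

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


_TABLES = (
    StudyTable(
        "t01_a3101_rs1061235", "A*31:01", "rs1061235", ("ANKCPPX",), "SINGLE",
        22, 5, 0, 98, 0,
        {"sensitivity": 100.0, "specificity": 95.1, "ppv": 81.5, "npv": 100.0},
    ),
    StudyTable(
        "t02_a3101_rs17179220", "A*31:01", "rs17179220", ("C__33415939_10",), "SINGLE",
        22, 6, 0, 97, 0,
        {"sensitivity": 100.0, "specificity": 94.2, "ppv": 78.6, "npv": 100.0},
    ),
    StudyTable(
        "t03_a3101_combined", "A*31:01", "rs1061235+rs17179220",
        ("ANKCPPX", "C__33415939_10"), "ALL",
        22, 0, 0, 103, 0,
        {"sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0},
    ),
    StudyTable(
        "t04_b1502_rs10484555", "B*15:02", "rs10484555", ("ANEP7CD",), "SINGLE",
        10, 0, 0, 113, 2,
        {"sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0},
    ),
    StudyTable(
        "t05_b1502_rs144012689", "B*15:02", "rs144012689",
        ("AN33NRP", "AN49HCM"), "ANY",
        10, 0, 0, 115, 0,
        {"sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0},
    ),
    StudyTable(
        "t06_b5701_rs2395029", "B*57:01", "rs2395029", ("C__16222070_10",), "SINGLE",
        19, 1, 0, 213, 0,
        {"sensitivity": 100.0, "specificity": 99.5, "ppv": 95.0, "npv": 100.0},
    ),
    StudyTable(
        "t07_b5801_rs9263726", "B*58:01", "rs9263726", ("ANDKDRF",), "SINGLE",
        9, 35, 8, 80, 0,
        {"sensitivity": 52.9, "specificity": 69.6, "ppv": 20.5, "npv": 90.9},
    ),
    StudyTable(
        "t08_b5801_rs9262570", "B*58:01", "rs9262570", ("C__29757466_10",), "SINGLE",
        5, 14, 11, 102, 0,
        {"sensitivity": 31.3, "specificity": 87.9, "ppv": 26.3, "npv": 90.3},
    ),
    StudyTable(
        "t09_b5801_rs9469003", "B*58:01", "rs9469003", ("C_30505354_31",), "SINGLE",
        17, 34, 1, 80, 0,
        {"sensitivity": 94.4, "specificity": 70.2, "ppv": 33.3, "npv": 98.8},
    ),
    StudyTable(
        "t10_b5801_allele_specific", "B*58:01", "5801-taqman",
        ("5801A", "5801B"), "ANY",
        18, 0, 0, 114, 0,
        {"sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0},
    ),
)


def study_tables() -> dict[str, StudyTable]:
    """All ten published comparisons, keyed by short name."""
    return {t.key: t for t in _TABLES}


#: Printed 95% CI bounds reproduced exactly by the Clopper-Pearson interval:
#: (x, n) -> lower bound in percent as printed.  All are x=n degenerate
#: bounds (closed form (alpha/2)**(1/n)) except (213, 214).  The (19, 19)
#: entry prints 82.3 where half-up rounding of the exact 82.353 gives 82.4 —
#: the study truncated there, so comparisons should allow one unit in the
#: last printed digit.
DEGENERATE_CI_BOUNDS: dict[tuple[int, int], float] = {
    (22, 22): 84.6,
    (10, 10): 69.2,
    (103, 103): 96.5,
    (113, 113): 96.8,
    (115, 115): 96.8,
    (114, 114): 96.8,
    (18, 18): 81.5,
    (19, 19): 82.3,
    (98, 98): 96.3,
    (97, 97): 96.3,
    (213, 214): 97.4,
}
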