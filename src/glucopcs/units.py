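"""Unit handling for OGTT analytes.

All index formulas in :mod:`glucopcs.indices` are written for a single
canonical unit system (glucose mg/dl, insulin μU/ml, C-peptide ng/ml);
:class:`UnitPolicy` converts arbitrary input units to that system once,
centrally, so no formula ever guesses its input units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: mg/dl per mmol/l of glucose (molar mass 180.16 g/mol).
GLUCOSE_MGDL_PER_MMOLL = 18.016
#: pmol/l per μU/ml of insulin (standard molar conversion).
INSULIN_PMOLL_PER_UUML = 6.0
#: nmol/l per ng/ml of C-peptide (molar mass ~3020 g/mol).
CPEPTIDE_NMOLL_PER_NGML = 0.331

GLUCOSE_UNITS = ("mg/dl", "mmol/l")
INSULIN_UNITS = ("uU/ml", "pmol/l")
CPEPTIDE_UNITS = ("ng/ml", "nmol/l")


def glucose_to_mmoll(g_mgdl):
    """Glucose mg/dl -> mmol/l."""
    return np.asarray(g_mgdl, dtype=float) / GLUCOSE_MGDL_PER_MMOLL


def glucose_to_mgdl(g_mmoll):
    """Glucose mmol/l -> mg/dl."""
    return np.asarray(g_mmoll, dtype=float) * GLUCOSE_MGDL_PER_MMOLL


def insulin_to_pmoll(i_uuml):
    """Insulin μU/ml -> pmol/l."""
    return np.asarray(i_uuml, dtype=float) * INSULIN_PMOLL_PER_UUML


def insulin_to_uuml(i_pmoll):
    """Insulin pmol/l -> μU/ml."""
    return np.asarray(i_pmoll, dtype=float) / INSULIN_PMOLL_PER_UUML


def cpeptide_to_nmoll(cp_ngml):
    """C-peptide ng/ml -> nmol/l."""
    return np.asarray(cp_ngml, dtype=float) * CPEPTIDE_NMOLL_PER_NGML


def cpeptide_to_ngml(cp_nmoll):
    """C-peptide nmol/l -> ng/ml."""
    return np.asarray(cp_nmoll, dtype=float) / CPEPTIDE_NMOLL_PER_NGML


@dataclass(frozen=True)
class UnitPolicy:
    """Declares the units of an input record.

    ``to_canonical`` maps measurements to the canonical system
    (mg/dl, μU/ml, ng/ml) used by every index formula.
    """

    glucose_unit: str = "mg/dl"
    insulin_unit: str = "uU/ml"
    cpeptide_unit: str = "ng/ml"

    def __post_init__(self):
        if self.glucose_unit not in GLUCOSE_UNITS:
            raise ValueError(f"unknown glucose unit {self.glucose_unit!r}")
        if self.insulin_unit not in INSULIN_UNITS:
            raise ValueError(f"unknown insulin unit {self.insulin_unit!r}")
        if self.cpeptide_unit not in CPEPTIDE_UNITS:
            raise ValueError(f"unknown C-peptide unit {self.cpeptide_unit!r}")

    def glucose_mgdl(self, g):
        return np.asarray(g, dtype=float) if self.glucose_unit == "mg/dl" else glucose_to_mgdl(g)

    def insulin_uuml(self, i):
        return np.asarray(i, dtype=float) if self.insulin_unit == "uU/ml" else insulin_to_uuml(i)

    def cpeptide_ngml(self, cp):
        return np.asarray(cp, dtype=float) if self.cpeptide_unit == "ng/ml" else cpeptide_to_ngml(cp)


CANONICAL_POLICY = UnitPolicy()
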