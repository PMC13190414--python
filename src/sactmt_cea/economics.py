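"""Cost and utility arithmetic: dosing, vial pricing, adverse-event
expectations, follow-up bundles, and the incremental cost-effectiveness
ratio.

All prices are 2025 US dollars.  Dosing uses a reference patient (65 kg,
1.72 m^2, creatinine clearance 70 mL/min); carboplatin is dosed with the
Calvert formula AUC * (CrCl + 25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

DOSING_RULES = ("per_kg", "per_bsa", "auc", "flat")
VIAL_POLICIES = ("ceil", "exact")


class EconomicsConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PatientProfile:
    weight_kg: float = 65.0
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0

    def __post_init__(self):
        if min(self.weight_kg, self.bsa_m2, self.crcl_ml_min) <= 0:
            raise EconomicsConfigError("patient characteristics must be positive")


@dataclass(frozen=True)
class DrugCostItem:
    """One drug: vial strength, unit price and its dosing rule.

    ``dose_amount`` is mg/kg for per_kg, mg/m^2 for per_bsa, the AUC target
    (mg/mL*min) for auc, and mg per administration for flat dosing.
    """

    name: str
    vial_strength_mg: float
    unit_price: float
    dosing_rule: str
    dose_amount: float

    def __post_init__(self):
        if self.dosing_rule not in DOSING_RULES:
            raise EconomicsConfigError(f"unknown dosing rule {self.dosing_rule!r}")
        if self.vial_strength_mg <= 0 or self.unit_price < 0:
            raise EconomicsConfigError("vial strength must be > 0, price >= 0")


def administration_dose(item: DrugCostItem, patient: PatientProfile) -> float:
    """Dose in mg for one administration."""
    if item.dosing_rule == "per_kg":
        return item.dose_amount * patient.weight_kg
    if item.dosing_rule == "per_bsa":
        return item.dose_amount * patient.bsa_m2
    if item.dosing_rule == "auc":
        # Calvert: dose = AUC * (GFR + 25)
        return item.dose_amount * (patient.crcl_ml_min + 25.0)
    return item.dose_amount


def administration_dose_and_cost(
    item: DrugCostItem,
    patient: PatientProfile,
    vial_policy: str = "ceil",
    unit_price: float | None = None,
) -> tuple[float, float]:
    """(dose mg, cost USD) for one administration.

    ``vial_policy='ceil'`` buys whole vials with no sharing
    (vials = ceil(dose/strength)); ``'exact'`` prices the administered
    milligrams linearly (no wastage).  ``unit_price`` overrides the item's
    base price (used by sensitivity analysis).
    """
    if vial_policy not in VIAL_POLICIES:
        raise EconomicsConfigError(f"unknown vial policy {vial_policy!r}")
    price = item.unit_price if unit_price is None else unit_price
    dose = administration_dose(item, patient)
    if vial_policy == "ceil":
        vials = math.ceil(dose / item.vial_strength_mg - 1e-12)
        return dose, vials * price
    return dose, dose / item.vial_strength_mg * price


@dataclass(frozen=True)
class AEItem:
    """A grade >=3 treatment-related adverse event included in the model."""

    name: str
    cost_per_event: float
    disutility: float
    incidence: float

    def __post_init__(self):
        if not 0.0 <= self.incidence <= 1.0:
            raise EconomicsConfigError("AE incidence must be in [0, 1]")
        if self.disutility > 0:
            raise EconomicsConfigError("AE disutility must be <= 0")
        if self.cost_per_event < 0:
            raise EconomicsConfigError("AE cost must be >= 0")


def expected_ae_cost(aes) -> float:
    """One-off expected AE management cost at model entry."""
    return sum(a.incidence * a.cost_per_event for a in aes)


def expected_ae_qaly_loss(aes) -> float:
    """One-off expected QALY decrement at model entry (positive number)."""
    return sum(a.incidence * (-a.disutility) for a in aes)


@dataclass(frozen=True)
class UtilitySet:
    u_pfs: float = 0.804
    u_pd: float = 0.321

    def __post_init__(self):
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise EconomicsConfigError("utilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# results and the ICER


@dataclass(frozen=True)
class StrategyResult:
    name: str
    total_cost: float
    total_qalys: float
    total_lys: float


@dataclass(frozen=True)
class CEComparison:
    strategy: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    delta_lys: float
    icer: float | None
    status: str  # "icer" | "dominant" | "dominated" | "indifferent"


def icer(a: StrategyResult, b: StrategyResult, tol: float = 1e-12) -> CEComparison:
    """Incremental comparison of strategy ``a`` against comparator ``b``."""
    dc = a.total_cost - b.total_cost
    de = a.total_qalys - b.total_qalys
    dl = a.total_lys - b.total_lys
    if abs(de) <= tol:
        if abs(dc) <= tol:
            status, value = "indifferent", None
        elif dc < 0:
            status, value = "dominant", None
        else:
            status, value = "dominated", None
    elif de > 0 and dc < 0:
        status, value = "dominant", None
    elif de < 0 and dc > 0:
        status, value = "dominated", None
    else:
        status, value = "icer", dc / de
    return CEComparison(a.name, b.name, dc, de, dl, value, status)
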