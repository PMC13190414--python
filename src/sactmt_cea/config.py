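"""Model-specification schema and loader.

The full decision problem — strategies with their survival curves and
treatment regimens, prices, utilities, adverse events, time/discount
conventions, PSA settings and scenarios — is one validated YAML document.
Unknown keys are rejected and every schema violation is reported with its
location (pydantic's standard error listing).
"""

from __future__ import annotations

from importlib import resources
from typing import Literal

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

from .survival import FAMILIES, ParametricSurvival


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Range(_Strict):
    """A parameter with its sensitivity-analysis range (low <= base <= high)."""

    base: float
    low: float | None = None
    high: float | None = None

    @model_validator(mode="after")
    def _ordered(self):
        if self.low is not None and self.high is not None:
            if not self.low <= self.base <= self.high:
                raise ValueError(
                    f"range must satisfy low <= base <= high, got "
                    f"({self.low}, {self.base}, {self.high})"
                )
        return self


class PatientCfg(_Strict):
    weight_kg: float = Field(65.0, gt=0)
    bsa_m2: float = Field(1.72, gt=0)
    crcl_ml_min: float = Field(70.0, gt=0)


class UtilityRange(Range):
    @model_validator(mode="after")
    def _unit_interval(self):
        vals = [v for v in (self.base, self.low, self.high) if v is not None]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("utilities must lie in [0, 1]")
        return self


class UtilitiesCfg(_Strict):
    pfs: UtilityRange
    pd: UtilityRange


class DosingCfg(_Strict):
    rule: Literal["per_kg", "per_bsa", "auc", "flat"]
    amount: float = Field(gt=0)


class DrugCfg(_Strict):
    vial_strength_mg: float = Field(gt=0)
    unit_price: Range
    dosing: DosingCfg

    @field_validator("unit_price")
    @classmethod
    def _nonneg(cls, v):
        if v.base < 0:
            raise ValueError("drug price must be >= 0")
        return v


class FollowupScheduleCfg(_Strict):
    """Routine follow-up resource frequencies per 28-day model cycle.

    ``*_every_n_cycles = 0`` means the examination is not part of the
    routine bundle.  Per-administration items (injection, preparation,
    nursing day, bed day) scale with the administrations in the cycle.
    """

    consultations_per_cycle: float = Field(1.0, ge=0)
    cbc_per_cycle: float = Field(1.0, ge=0)
    biochemistry_per_cycle: float = Field(1.0, ge=0)
    urinalysis_per_cycle: float = Field(1.0, ge=0)
    ct_every_n_cycles: int = Field(2, ge=0)
    mri_every_n_cycles: int = Field(0, ge=0)
    include_in_pd: bool = True


class CostsCfg(_Strict):
    bsc_per_cycle: Range
    followup: dict[str, Range]

    @model_validator(mode="after")
    def _required_items(self):
        required = {
            "cbc",
            "biochemistry",
            "urinalysis",
            "ct",
            "mri",
            "nursing_day",
            "bed_day",
            "consultation",
            "injection",
            "preparation",
        }
        missing = required - set(self.followup)
        if missing:
            raise ValueError(f"missing follow-up cost items: {sorted(missing)}")
        return self


class AECfg(_Strict):
    name: str
    cost: Range
    disutility: Range
    incidence: dict[str, Range]

    @model_validator(mode="after")
    def _signs(self):
        if self.disutility.base > 0:
            raise ValueError(f"AE disutility must be <= 0 ({self.name})")
        if self.cost.base < 0:
            raise ValueError(f"AE cost must be >= 0 ({self.name})")
        for arm, r in self.incidence.items():
            vals = [v for v in (r.base, r.low, r.high) if v is not None]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"AE incidence out of [0,1] ({self.name}/{arm})")
        return self


class CurveCfg(_Strict):
    family: str
    params: list[float]

    @model_validator(mode="after")
    def _valid_spec(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        ParametricSurvival(self.family, tuple(self.params))  # raises if invalid
        return self

    def to_spec(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, tuple(self.params))


class CurvesCfg(_Strict):
    pfs: CurveCfg
    os: CurveCfg


class RegimenComponentCfg(_Strict):
    drug: str
    administrations_per_cycle: float = Field(gt=0)


class TreatmentCfg(_Strict):
    """On-treatment drug schedule while progression-free.

    ``fixed_cycle`` doses on the model's own cycle; ``induction_maintenance``
    runs a regimen on its own cycle length (e.g. 21 days), converted to a
    daily rate and accrued per model cycle, with induction for a fixed
    number of regimen cycles followed by maintenance until progression.
    """

    kind: Literal["fixed_cycle", "induction_maintenance"]
    components: list[RegimenComponentCfg] = []
    regimen_cycle_days: float | None = Field(None, gt=0)
    induction_regimen_cycles: int | None = Field(None, ge=0)
    induction: list[RegimenComponentCfg] = []
    maintenance: list[RegimenComponentCfg] = []

    @model_validator(mode="after")
    def _complete(self):
        if self.kind == "fixed_cycle" and not self.components:
            raise ValueError("fixed_cycle treatment needs components")
        if self.kind == "induction_maintenance":
            if self.regimen_cycle_days is None or self.induction_regimen_cycles is None:
                raise ValueError(
                    "induction_maintenance needs regimen_cycle_days and "
                    "induction_regimen_cycles"
                )
            if not self.induction:
                raise ValueError("induction_maintenance needs an induction list")
        return self


class PDMixCfg(_Strict):
    """Post-progression treatment mix (weights sum to 1)."""

    bsc: float = Field(1.0, ge=0, le=1)
    pemetrexed: float = Field(0.0, ge=0, le=1)
    osimertinib: float = Field(0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _normalized(self):
        total = self.bsc + self.pemetrexed + self.osimertinib
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"PD mix weights must sum to 1, got {total}")
        return self


class StrategyCfg(_Strict):
    label: str
    curves: CurvesCfg
    treatment: TreatmentCfg
    pd_mix: PDMixCfg = PDMixCfg()


class PSACfg(_Strict):
    iterations: int = Field(1000, ge=1)
    seed: int = 20260926


class ScenarioCfg(_Strict):
    name: str
    overrides: dict[str, float] = {}
    wtp_thresholds: list[float] = []


class ModelSpec(_Strict):
    """The full decision problem."""

    name: str = "base-case"
    engine: Literal["psm", "markov", "both"] = "both"
    cycle_days: float = Field(28.0, ge=1)
    horizon_years: float = Field(10.0, gt=0)
    discount_annual: float = Field(0.05, ge=0.0, le=0.08)
    wtp_per_qaly: float = Field(41811.0, gt=0)
    background_annual_mortality: float = Field(0.00804, ge=0, lt=1)
    vial_policy: Literal["ceil", "exact"] = "exact"
    patient: PatientCfg = PatientCfg()
    utilities: UtilitiesCfg
    drugs: dict[str, DrugCfg]
    costs: CostsCfg
    followup_schedule: FollowupScheduleCfg = FollowupScheduleCfg()
    adverse_events: list[AECfg]
    strategies: dict[str, StrategyCfg]
    comparator: str
    psa: PSACfg = PSACfg()
    scenarios: list[ScenarioCfg] = []

    @model_validator(mode="after")
    def _cross_refs(self):
        if self.comparator not in self.strategies:
            raise ValueError(f"comparator {self.comparator!r} not among strategies")
        if len(self.strategies) != 2:
            raise ValueError("exactly two strategies are required")
        for sname, strat in self.strategies.items():
            comps = list(strat.treatment.components) + list(
                strat.treatment.induction
            ) + list(strat.treatment.maintenance)
            for c in comps:
                if c.drug not in self.drugs:
                    raise ValueError(
                        f"strategy {sname!r} references unknown drug {c.drug!r}"
                    )
            if strat.pd_mix.pemetrexed > 0 and "pemetrexed" not in self.drugs:
                raise ValueError("PD mix uses pemetrexed but it is not configured")
            if strat.pd_mix.osimertinib > 0 and "osimertinib" not in self.drugs:
                raise ValueError("PD mix uses osimertinib but it is not configured")
        for ae in self.adverse_events:
            for arm in ae.incidence:
                if arm not in self.strategies:
                    raise ValueError(
                        f"AE {ae.name!r} incidence references unknown arm {arm!r}"
                    )
        return self

    @property
    def intervention(self) -> str:
        return next(s for s in self.strategies if s != self.comparator)


def load_model_spec(path) -> ModelSpec:
    """Load and validate a model specification from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ModelSpec.model_validate(raw)


def load_default() -> ModelSpec:
    """The bundled base case (current Chinese prices, 2025 USD)."""
    text = resources.files("sactmt_cea.data").joinpath("basecase.yaml").read_text()
    return ModelSpec.model_validate(yaml.safe_load(text))
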