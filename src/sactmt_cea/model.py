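"""Orchestration: ties the validated model specification, the two cohort
engines and the economics together into a single evaluable object.

The :class:`CEModel` exposes a flat named-parameter registry (every Table-1
style input with its range) so one-way and probabilistic sensitivity
analyses, and scenario overrides, all run through the same
``evaluate(overrides)`` path.  Survival-curve parameters are fixed model
structure and are not part of the registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .cohort import CycleSchedule, ModelSettings, Occupancy, accrue, trace_totals
from .config import ModelSpec
from .economics import (
    AEItem,
    CEComparison,
    DrugCostItem,
    PatientProfile,
    StrategyResult,
    administration_dose_and_cost,
    expected_ae_cost,
    expected_ae_qaly_loss,
    icer,
)
from .markov import compute_occupancy_markov
from .psm import compute_occupancy_psm
from .survival import annual_prob_to_cycle_prob

ENGINES = ("psm", "markov")

#: registry parameter kinds and their PSA distribution class
KIND_PSA = {
    "cost": "gamma",
    "utility": "beta",
    "probability": "beta",
    "disutility": "beta",  # drawn on |disutility|, then negated
    "rate": None,  # OWSA-only (discount rate)
}


@dataclass(frozen=True)
class ParamRange:
    name: str
    base: float
    low: float
    high: float
    kind: str


class UnknownParameterError(KeyError):
    pass


def _r(range_obj, pct: float = 0.2):
    """(low, high) from a config Range, defaulting to +-pct around base."""
    low = range_obj.low if range_obj.low is not None else range_obj.base * (1 - pct)
    high = range_obj.high if range_obj.high is not None else range_obj.base * (1 + pct)
    return low, high


class CEModel:
    """One evaluable cost-effectiveness decision problem."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.settings = ModelSettings(
            cycle_days=spec.cycle_days,
            horizon_years=spec.horizon_years,
            discount_annual=spec.discount_annual,
        )
        self.patient = PatientProfile(
            spec.patient.weight_kg, spec.patient.bsa_m2, spec.patient.crcl_ml_min
        )
        self.p_bg_cycle = annual_prob_to_cycle_prob(
            spec.background_annual_mortality, int(spec.cycle_days)
        )
        self._occupancy_cache: dict[tuple[str, str], Occupancy] = {}
        self._registry = self._build_registry()
        self._registry_by_name = {p.name: p for p in self._registry}

    # -- parameter registry ------------------------------------------------

    def _build_registry(self) -> list[ParamRange]:
        spec = self.spec
        reg: list[ParamRange] = []

        def add(name, range_obj, kind):
            low, high = _r(range_obj)
            reg.append(ParamRange(name, range_obj.base, low, high, kind))

        for dname, drug in spec.drugs.items():
            add(f"price.{dname}", drug.unit_price, "cost")
        add("cost.bsc", spec.costs.bsc_per_cycle, "cost")
        for iname, item in spec.costs.followup.items():
            add(f"cost.{iname}", item, "cost")
        for ae in spec.adverse_events:
            add(f"ae_cost.{ae.name}", ae.cost, "cost")
            add(f"disutility.{ae.name}", ae.disutility, "disutility")
            for arm, inc in ae.incidence.items():
                add(f"incidence.{arm}.{ae.name}", inc, "probability")
        add("utility.pfs", spec.utilities.pfs, "utility")
        add("utility.pd", spec.utilities.pd, "utility")
        reg.append(
            ParamRange("discount_annual", spec.discount_annual, 0.0, 0.08, "rate")
        )
        return reg

    @property
    def registry(self) -> list[ParamRange]:
        return list(self._registry)

    def base_params(self) -> dict[str, float]:
        return {p.name: p.base for p in self._registry}

    def resolve_params(self, overrides: dict | None) -> dict[str, float]:
        params = self.base_params()
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown:
                raise UnknownParameterError(
                    f"unknown parameter(s): {sorted(unknown)}"
                )
            params.update(overrides)
        return params

    # -- engines -----------------------------------------------------------

    def occupancy(self, engine: str, strategy: str) -> Occupancy:
        """State occupancy for one engine/arm (cached: it depends only on
        the fixed survival curves and time conventions)."""
        key = (engine, strategy)
        if key not in self._occupancy_cache:
            curves = self.spec.strategies[strategy].curves
            pfs, os_ = curves.pfs.to_spec(), curves.os.to_spec()
            if engine == "psm":
                occ = compute_occupancy_psm(pfs, os_, self.settings)
            elif engine == "markov":
                occ = compute_occupancy_markov(
                    pfs, os_, self.p_bg_cycle, self.settings
                )
            else:
                raise ValueError(f"unknown engine {engine!r}")
            self._occupancy_cache[key] = occ
        return self._occupancy_cache[key]

    # -- economics ---------------------------------------------------------

    def _drug_item(self, name: str, params) -> DrugCostItem:
        cfg = self.spec.drugs[name]
        return DrugCostItem(
            name,
            cfg.vial_strength_mg,
            params[f"price.{name}"],
            cfg.dosing.rule,
            cfg.dosing.amount,
        )

    def _admin_cost(self, drug: str, params) -> float:
        item = self._drug_item(drug, params)
        _, cost = administration_dose_and_cost(
            item, self.patient, self.spec.vial_policy
        )
        return cost

    def _followup_per_cycle(self, params, n_admin: float) -> float:
        sch = self.spec.followup_schedule
        c = (
            sch.consultations_per_cycle * params["cost.consultation"]
            + sch.cbc_per_cycle * params["cost.cbc"]
            + sch.biochemistry_per_cycle * params["cost.biochemistry"]
            + sch.urinalysis_per_cycle * params["cost.urinalysis"]
        )
        if sch.ct_every_n_cycles:
            c += params["cost.ct"] / sch.ct_every_n_cycles
        if sch.mri_every_n_cycles:
            c += params["cost.mri"] / sch.mri_every_n_cycles
        c += n_admin * (
            params["cost.injection"]
            + params["cost.preparation"]
            + params["cost.nursing_day"]
            + params["cost.bed_day"]
        )
        return c

    def _arm_aes(self, strategy: str, params) -> list[AEItem]:
        out = []
        for ae in self.spec.adverse_events:
            if strategy not in ae.incidence:
                continue
            out.append(
                AEItem(
                    ae.name,
                    params[f"ae_cost.{ae.name}"],
                    params[f"disutility.{ae.name}"],
                    params[f"incidence.{strategy}.{ae.name}"],
                )
            )
        return out

    def cycle_schedule(self, strategy: str, params) -> CycleSchedule:
        """Per-cycle cost arrays and utilities for one strategy."""
        spec = self.spec
        strat = spec.strategies[strategy]
        n = self.settings.n_cycles
        cd = self.settings.cycle_days
        tr = strat.treatment

        drug_cost = np.zeros(n)
        n_admin = np.zeros(n)
        if tr.kind == "fixed_cycle":
            per_cycle = sum(
                c.administrations_per_cycle * self._admin_cost(c.drug, params)
                for c in tr.components
            )
            drug_cost[:] = per_cycle
            n_admin[:] = sum(c.administrations_per_cycle for c in tr.components)
        else:  # induction then maintenance on the regimen's own clock
            rd = tr.regimen_cycle_days
            ind_days = tr.induction_regimen_cycles * rd
            ind_daily = sum(
                c.administrations_per_cycle * self._admin_cost(c.drug, params)
                for c in tr.induction
            ) / rd
            maint_daily = sum(
                c.administrations_per_cycle * self._admin_cost(c.drug, params)
                for c in tr.maintenance
            ) / rd
            starts = np.arange(n) * cd
            ends = starts + cd
            ind_overlap = np.clip(np.minimum(ends, ind_days) - starts, 0.0, cd)
            drug_cost = ind_daily * ind_overlap + maint_daily * (cd - ind_overlap)
            n_admin[:] = cd / rd * max(
                sum(c.administrations_per_cycle for c in tr.induction),
                sum(c.administrations_per_cycle for c in tr.maintenance),
            )

        cost_pfs = drug_cost + self._followup_per_cycle(params, 0.0)
        cost_pfs += n_admin * (
            params["cost.injection"]
            + params["cost.preparation"]
            + params["cost.nursing_day"]
            + params["cost.bed_day"]
        )

        # post-progression: subsequent-treatment mix + follow-up
        mix = strat.pd_mix
        pd_cost = mix.bsc * params["cost.bsc"]
        pd_admin = 0.0
        if mix.pemetrexed > 0:
            pem_daily = self._admin_cost("pemetrexed", params) / 21.0
            pd_cost += mix.pemetrexed * pem_daily * cd
            pd_admin += mix.pemetrexed * cd / 21.0
        if mix.osimertinib > 0:
            pd_cost += mix.osimertinib * self._admin_cost("osimertinib", params) * cd
        if spec.followup_schedule.include_in_pd:
            pd_cost += self._followup_per_cycle(params, pd_admin)
        cost_pd = np.full(n, pd_cost)

        aes = self._arm_aes(strategy, params)
        return CycleSchedule(
            cost_pfs=cost_pfs,
            cost_pd=cost_pd,
            u_pfs=params["utility.pfs"],
            u_pd=params["utility.pd"],
            entry_cost=expected_ae_cost(aes),
            entry_qaly_loss=expected_ae_qaly_loss(aes),
        )

    # -- evaluation --------------------------------------------------------

    def _settings_for(self, params) -> ModelSettings:
        return ModelSettings(
            cycle_days=self.settings.cycle_days,
            horizon_years=self.settings.horizon_years,
            discount_annual=params["discount_annual"],
            half_cycle_correction=self.settings.half_cycle_correction,
        )

    def strategy_result(
        self, engine: str, strategy: str, params: dict
    ) -> StrategyResult:
        occ = self.occupancy(engine, strategy)
        sched = self.cycle_schedule(strategy, params)
        trace = accrue(occ, sched, self._settings_for(params))
        cost, qalys, lys = trace_totals(trace)
        return StrategyResult(strategy, cost, qalys, lys)

    def evaluate(
        self, overrides: dict | None = None, engines=None
    ) -> dict[str, CEComparison]:
        """Deterministic run of both arms; one incremental comparison per
        engine (intervention vs comparator)."""
        params = self.resolve_params(overrides)
        engines = engines or self._engines()
        out = {}
        for engine in engines:
            a = self.strategy_result(engine, self.spec.intervention, params)
            b = self.strategy_result(engine, self.spec.comparator, params)
            out[engine] = icer(a, b)
        return out

    def strategy_results(
        self, overrides: dict | None = None, engines=None
    ) -> dict[str, dict[str, StrategyResult]]:
        params = self.resolve_params(overrides)
        engines = engines or self._engines()
        return {
            engine: {
                name: self.strategy_result(engine, name, params)
                for name in self.spec.strategies
            }
            for engine in engines
        }

    def _engines(self):
        return ENGINES if self.spec.engine == "both" else (self.spec.engine,)
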