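"""Mixture-interaction layer.

Two families of cross-chemical effects are supported on top of the kinetics
engine:

* **Enzyme-level specs** — competitive inhibition (populates the I constants
  of the saturable rate law), noncompetitive inhibition and induction
  (multiplies the effective Vmax).

* **Metal → metabolism modulation** — the liver burden of accumulating toxic
  metals depresses the maximum oxidation velocity of co-occurring organics.
  The effect level E follows a linear tissue exposure–response with a short
  first-order time lag:  dE/dt = (Σ_m w_m·C_liver,m − E)/τ, and the target
  reactions run at Vmax·max(0, 1 − E).  Because the true magnitudes of such
  interactions are unknown, the default weights are set by an
  equal-contribution rule (each metal contributes the same share of a chosen
  total baseline effect), and scenario variants sweep a common multiplier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exposure import ExposureProfile, scale_intakes
from .kinetics import (
    KineticsError,
    MMReaction,
    ODESystem,
    SimulationResult,
    simulate,
)

__all__ = [
    "InteractionSpec",
    "EffectState",
    "register_interaction",
    "remove_interaction",
    "effect_derivative",
    "equal_contribution_weights",
    "run_mixture_scenario",
    "MixtureResult",
]

_KINDS = ("competitive", "noncompetitive", "induction", "metal_vmax_modulation")


@dataclass(frozen=True)
class InteractionSpec:
    """Declarative description of one cross-chemical interaction.

    ``targets`` selects the affected reactions as ``(tissue, substrate)``
    pairs; a tissue of ``None`` matches any tissue.  For the enzyme-level
    kinds, ``source`` names the inhibiting/inducing chemical and ``constant``
    is I (competitive) or K_nc (noncompetitive) in μmol/L, or the induction
    factor.  For ``metal_vmax_modulation``, ``weights`` maps each metal
    species to w_m (L/μmol), ``source_tissue`` is where the metal burden is
    read (liver in the mixture case study) and ``lag_tau`` is the effect time
    constant in hours.
    """

    kind: str
    name: str
    targets: tuple[tuple[str | None, str], ...]
    source: str | None = None
    constant: float | None = None
    weights: Mapping[str, float] = field(default_factory=dict)
    source_tissue: str = "liver"
    lag_tau: float = 24.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise KineticsError(f"unknown interaction kind {self.kind!r}")
        if self.kind in ("competitive", "noncompetitive"):
            if self.source is None or self.constant is None or self.constant <= 0:
                raise KineticsError(
                    f"{self.kind} interaction needs a source chemical and a "
                    "positive constant"
                )
        if self.kind == "induction" and (self.constant is None or self.constant < 0):
            raise KineticsError("induction needs a factor >= 0")
        if self.kind == "metal_vmax_modulation":
            if self.lag_tau <= 0:
                raise KineticsError("lag time constant must be > 0")
            if any(w < 0 for w in self.weights.values()):
                raise KineticsError("modulation weights must be >= 0")
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "weights", dict(self.weights))


@dataclass
class EffectState:
    """Snapshot of one modulation effect level (dimensionless).

    The effective Vmax factor is max(0, 1 − E); E itself is an auxiliary ODE
    state integrated with the system.
    """

    name: str
    level: float

    @property
    def vmax_factor(self) -> float:
        return max(0.0, 1.0 - self.level)


def _matches(spec_targets, rxn: MMReaction) -> bool:
    return any(
        (tissue is None or tissue == rxn.tissue) and substrate == rxn.substrate
        for tissue, substrate in spec_targets
    )


def register_interaction(system: ODESystem, spec: InteractionSpec) -> ODESystem:
    """Return a new system with one interaction registered.

    Competitive specs populate the inhibition constants of the target
    reactions; noncompetitive/induction specs attach Vmax modifiers;
    modulation specs append an effect state and tag the target reactions with
    it.  The input system is left untouched.
    """
    network = copy.deepcopy(system.network)
    matched = 0
    for rxn in network.mm_reactions:
        if not _matches(spec.targets, rxn):
            continue
        matched += 1
        if spec.kind == "competitive":
            rxn.competitive_inhibitors[spec.source] = float(spec.constant)
        elif spec.kind == "noncompetitive":
            rxn.noncompetitive.append((spec.source, float(spec.constant)))
        elif spec.kind == "induction":
            rxn.induction.append(float(spec.constant))
        elif spec.kind == "metal_vmax_modulation":
            if spec.name not in rxn.effect_names:
                rxn.effect_names.append(spec.name)
    if matched == 0:
        raise KineticsError(
            f"interaction {spec.name!r} matched no reaction "
            f"(targets {spec.targets})"
        )
    interactions = system.interactions
    if spec.kind == "metal_vmax_modulation":
        if any(getattr(s, "name", None) == spec.name for s in interactions):
            raise KineticsError(f"interaction name {spec.name!r} already registered")
        interactions = interactions + (spec,)
    return system.rebuild(network=network, interactions=interactions)


def remove_interaction(system: ODESystem, name: str) -> ODESystem:
    """Strip one registered interaction (by name) and rebuild the system."""
    interactions = tuple(
        s for s in system.interactions if getattr(s, "name", None) != name
    )
    network = copy.deepcopy(system.network)
    for rxn in network.mm_reactions:
        if name in rxn.effect_names:
            rxn.effect_names.remove(name)
    return system.rebuild(network=network, interactions=interactions)


def effect_derivative(
    effect: float,
    tissue_concentrations: Mapping[str, float],
    weights: Mapping[str, float],
    lag_tau: float,
) -> float:
    """dE/dt of the lagged linear exposure–response effect.

    First-order relaxation toward the weighted metal burden:
    dE/dt = (Σ_m w_m · C_m − E)/τ, so at steady state E = Σ w_m C_m.
    """
    if lag_tau <= 0:
        raise KineticsError("lag time constant must be > 0")
    drive = sum(
        w * max(tissue_concentrations.get(chem, 0.0), 0.0)
        for chem, w in weights.items()
    )
    return (drive - effect) / lag_tau


def equal_contribution_weights(
    baseline_concentrations: Mapping[str, float],
    total_effect: float,
) -> dict[str, float]:
    """Weights giving every metal the same share of the steady-state effect.

    Metals with low tissue concentrations get proportionally higher weights
    so each contributes ``total_effect / n`` at the baseline concentrations
    (groups of species that represent one metal, e.g. the arsenicals, should
    be passed as a single summed entry and share the returned weight).
    """
    n = len(baseline_concentrations)
    if n == 0:
        raise KineticsError("need at least one baseline concentration")
    out = {}
    for chem, conc in baseline_concentrations.items():
        if conc <= 0:
            raise KineticsError(f"baseline concentration for {chem!r} must be > 0")
        out[chem] = total_effect / (n * conc)
    return out


# ---------------------------------------------------------------------------
# the mixture case study


@dataclass
class MixtureResult:
    """Labelled outputs of the mixture case study."""

    results: dict[str, SimulationResult]
    weights: dict[str, float]
    t_switch: float
    cadmium_initial: dict

    def __getitem__(self, label: str) -> SimulationResult:
        return self.results[label]

    def labels(self) -> list[str]:
        return list(self.results)


_DEFAULT_VARIANTS = {"base": 0.0, "half": 0.5, "nominal": 1.0, "double": 2.0}

#: Metal groups contributing to the modulation effect; arsenical species
#: share one group weight computed from their summed liver concentration.
_METAL_GROUPS: dict[str, tuple[str, ...]] = {
    "cadmium": ("cadmium",),
    "lead": ("lead",),
    "mehg": ("mehg",),
    "arsenic": ("asV", "asIII", "mmaV", "mmaIII", "dmaV", "dmaIII"),
}


def _mixture_exposures(cfg: dict) -> list[ExposureProfile]:
    from .exposure import Event

    def diet(chem: str, ug_per_day: float) -> ExposureProfile:
        return ExposureProfile(
            chemical=chem,
            route="oral_continuous",
            events=(Event(start=0.0, magnitude=ug_per_day, units="ug/day"),),
        )

    def air(chem: str, ppm: float) -> ExposureProfile:
        return ExposureProfile(
            chemical=chem,
            route="inhalation",
            events=(Event(start=0.0, magnitude=ppm, units="ppm"),),
        )

    profiles = [
        diet("cadmium", cfg["cadmium_ug_day"]),
        diet("mehg", cfg["mehg_ug_day"]),
        diet("lead", cfg["lead_ug_day"]),
        diet(cfg["arsenic_species"], cfg["arsenic_ug_day"]),
        air("toluene", cfg["toluene_ppm"]),
        air("benzene", cfg["benzene_ppm"]),
    ]
    metals = ["cadmium", "mehg", "lead", cfg["arsenic_species"]]
    return scale_intakes(
        profiles, cfg["step_factor"], cfg["t_switch_h"], chemicals=metals
    )


def _cadmium_prerun(cfg: dict, body) -> dict:
    """Birth-to-age-30 cadmium loading used as the mixture initial condition.

    Constant 0.2 μg/kg/day intake for 30 years with the cadmium model alone;
    the resulting tissue amounts seed the joint short-term simulation.
    """
    from .chemical_models import build_cadmium_model
    from .exposure import Event

    model = build_cadmium_model(body=body)
    years = cfg["prerun_years"]
    t_end = years * 365.0 * 24.0
    profile = ExposureProfile(
        chemical="cadmium",
        route="oral_continuous",
        events=(
            Event(start=0.0, magnitude=cfg["prerun_ug_kg_day"], units="ug/kg/day"),
        ),
    )
    system = model.assemble(exposures=[profile])
    res = simulate(system, t_end, report_grid=t_end / 60.0)
    return {
        (s.chemical, s.compartment, s.sub): res.y[-1, i]
        for i, s in enumerate(system.states)
        if s.kind == "pool" and res.y[-1, i] > 0
    }


def run_mixture_scenario(config: Mapping | None = None) -> MixtureResult:
    """Joint metals + volatile-organics co-exposure case study.

    A 30-year-old adult receives continuous dietary metal intakes (15 μg/day
    cadmium, 40 μg/day methylmercury, 70 μg/day lead, 100 μg/day inorganic
    arsenic) and constant inhalation of 20 ppm toluene and 10 ppm benzene.
    Cadmium tissue levels are initialised from a birth-to-age-30 pre-run at
    0.2 μg/kg/day.  After 500 days all metal intakes step up by 40% while the
    organics stay constant.  The base case has no metal → metabolism coupling;
    each variant applies the lagged liver-burden modulation with weights set
    by the equal-contribution rule times a variant multiplier.
    """
    from .chemical_models import (
        build_arsenic_model,
        build_cadmium_model,
        build_lead_model,
        build_mehg_model,
        build_voc_model,
        merge_models,
    )
    from .physiology import reference_adult

    cfg = {
        "cadmium_ug_day": 15.0,
        "mehg_ug_day": 40.0,
        "lead_ug_day": 70.0,
        "arsenic_ug_day": 100.0,
        "arsenic_species": "asIII",
        "toluene_ppm": 20.0,
        "benzene_ppm": 10.0,
        "t_switch_h": 500.0 * 24.0,
        "t_end_h": 750.0 * 24.0,
        "step_factor": 1.4,
        "prerun_ug_kg_day": 0.2,
        "prerun_years": 30.0,
        "total_baseline_effect": 0.25,
        "lag_tau_h": 24.0,
        "variants": dict(_DEFAULT_VARIANTS),
        "report_step_h": 24.0,
        "solver_options": None,
    }
    if config:
        cfg.update(config)

    body = reference_adult()
    merged = merge_models(
        build_cadmium_model(body=body),
        build_mehg_model(body=body),
        build_lead_model(body=body),
        build_arsenic_model(body=body),
        build_voc_model(body=body),
    )
    exposures = _mixture_exposures(cfg)
    initial = _cadmium_prerun(cfg, body)
    base_system = merged.assemble(exposures=exposures)

    def run(system) -> SimulationResult:
        return simulate(
            system,
            cfg["t_end_h"],
            report_grid=cfg["report_step_h"],
            solver_options=cfg["solver_options"],
            initial=initial,
        )

    results: dict[str, SimulationResult] = {}
    base = run(base_system)
    results["base"] = base

    # equal-contribution weights from baseline (pre-step) liver burdens
    i_switch = int(np.searchsorted(base.t, cfg["t_switch_h"]) - 1)
    group_conc = {}
    for group, members in _METAL_GROUPS.items():
        conc = sum(
            base.concentration(m, "liver")[i_switch] for m in members
        )
        group_conc[group] = conc
    group_w = equal_contribution_weights(group_conc, cfg["total_baseline_effect"])
    weights = {
        member: group_w[group]
        for group, members in _METAL_GROUPS.items()
        for member in members
    }

    targets = (("liver", "benzene"), ("liver", "toluene"))
    for label, multiplier in cfg["variants"].items():
        if multiplier == 0.0:
            if label != "base":
                results[label] = base
            continue
        spec = InteractionSpec(
            kind="metal_vmax_modulation",
            name=f"metal_liver_effect_{label}",
            targets=targets,
            weights={c: w * multiplier for c, w in weights.items()},
            source_tissue="liver",
            lag_tau=cfg["lag_tau_h"],
        )
        results[label] = run(register_interaction(base_system, spec))
    return MixtureResult(
        results=results,
        weights=weights,
        t_switch=cfg["t_switch_h"],
        cadmium_initial=initial,
    )
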