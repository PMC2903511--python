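"""Scenario configuration, result serialisation and orchestration.

A *scenario* is a YAML (or JSON) document naming a physiology, the chemical
models to map onto it, the exposure profiles (with mandatory unit strings on
every dosed quantity), optional interaction specs and the simulation
settings.  :func:`read_scenario` validates the document against a pydantic
schema — errors carry field paths — and resolves every cross-reference;
:func:`run_scenario` builds, merges, assembles and integrates the system and
writes the trajectory and ledger CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._data import load_packaged_yaml, packaged_data_path
from .exposure import Event, ExposureProfile
from .interactions import InteractionSpec, register_interaction
from .kinetics import SimulationResult, simulate
from .physiology import BodyPhysiology, load_physiology, reference_adult

__all__ = [
    "Scenario",
    "read_scenario",
    "write_scenario",
    "packaged_scenario_path",
    "build_scenario_system",
    "run_scenario",
    "write_timeseries",
    "write_ledger",
    "read_timeseries",
    "packaged_data_path",
]

TIMESERIES_COLUMNS = [
    "time_h",
    "chemical",
    "compartment",
    "subcompartment",
    "amount_umol",
    "concentration_umol_per_L",
]


class EventCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start_h: float
    magnitude: float
    units: str  # mandatory: every dosed quantity carries its units
    end_h: float | None = None


class ScaleCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_h: float
    factor: float


class ExposureCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chemical: str
    route: Literal["oral_bolus", "oral_continuous", "inhalation", "infusion"]
    events: list[EventCfg] = Field(min_length=1)
    scale: list[ScaleCfg] = []
    route_label: str = ""

    def to_profile(self) -> ExposureProfile:
        return ExposureProfile(
            chemical=self.chemical,
            route=self.route,
            events=tuple(
                Event(start=e.start_h, magnitude=e.magnitude, units=e.units, end=e.end_h)
                for e in self.events
            ),
            scaling_switches=tuple((s.time_h, s.factor) for s in self.scale),
            route_label=self.route_label,
        )


class ModelCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    options: dict = {}


class InteractionCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal[
        "competitive", "noncompetitive", "induction", "metal_vmax_modulation"
    ]
    name: str
    targets: list[tuple[str | None, str]]
    source: str | None = None
    constant: float | None = None
    weights: dict[str, float] = {}
    source_tissue: str = "liver"
    lag_tau_h: float = 24.0

    def to_spec(self) -> InteractionSpec:
        return InteractionSpec(
            kind=self.kind,
            name=self.name,
            targets=tuple((t, s) for t, s in self.targets),
            source=self.source,
            constant=self.constant,
            weights=self.weights,
            source_tissue=self.source_tissue,
            lag_tau=self.lag_tau_h,
        )


class SimulationCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end_h: float = Field(gt=0)
    report_step_h: float = 24.0
    rtol: float = 1e-8
    atol: float = 1e-12
    seed: int = 0


class Scenario(BaseModel):
    """Validated scenario document."""

    model_config = ConfigDict(extra="forbid")
    physiology: str = "reference_adult"
    models: list[ModelCfg] = Field(min_length=1)
    exposures: list[ExposureCfg] = []
    interactions: list[InteractionCfg] = []
    simulation: SimulationCfg
    outputs: dict = {}

    @field_validator("models")
    @classmethod
    def _known_models(cls, v: list[ModelCfg]) -> list[ModelCfg]:
        from .chemical_models import MODEL_BUILDERS

        for m in v:
            if m.name not in MODEL_BUILDERS:
                raise ValueError(
                    f"unknown model {m.name!r}; available: "
                    f"{sorted(MODEL_BUILDERS)}"
                )
        return v


def packaged_scenario_path(name: str) -> Path:
    return packaged_data_path("scenarios", f"{name}.yaml")


def read_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scenario = Scenario.model_validate(doc)
    _resolve(scenario)
    return scenario


def write_scenario(scenario: Scenario, path: str | Path) -> Path:
    """Serialise a scenario back to YAML (round-trips with read_scenario)."""
    path = Path(path)
    doc = scenario.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def _resolve(scenario: Scenario) -> None:
    """Check every cross-reference without running anything expensive."""
    from .chemical_models import MODEL_BUILDERS, merge_models

    body = _load_body(scenario.physiology)
    merged = merge_models(
        *(
            MODEL_BUILDERS[m.name](body=body, **m.options)
            for m in scenario.models
        )
    )
    known = set(merged.species_names())
    for exp in scenario.exposures:
        if exp.chemical not in known:
            raise ValueError(
                f"exposures: chemical {exp.chemical!r} is not provided by the "
                f"selected models {sorted(known)}"
            )
    for spec in scenario.interactions:
        for chem in spec.weights:
            if chem not in known:
                raise ValueError(
                    f"interactions[{spec.name}]: unknown chemical {chem!r}"
                )


def _load_body(ref: str) -> BodyPhysiology:
    if ref == "reference_adult":
        return reference_adult()
    return load_physiology(ref)


def build_scenario_system(scenario: Scenario):
    """Build the assembled system and exposure set for a scenario."""
    from .chemical_models import MODEL_BUILDERS, merge_models

    body = _load_body(scenario.physiology)
    merged = merge_models(
        *(
            MODEL_BUILDERS[m.name](body=body, **m.options)
            for m in scenario.models
        )
    )
    exposures = [e.to_profile() for e in scenario.exposures]
    system = merged.assemble(exposures=exposures)
    for spec in scenario.interactions:
        system = register_interaction(system, spec.to_spec())
    return system, merged


def run_scenario(
    scenario: Scenario, outdir: str | Path | None = None
) -> SimulationResult:
    """Simulate a scenario; optionally write the two CSV outputs."""
    system, _ = build_scenario_system(scenario)
    sim = scenario.simulation
    result = simulate(
        system,
        sim.t_end_h,
        report_grid=sim.report_step_h,
        solver_options={"rtol": sim.rtol, "atol": sim.atol},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_timeseries(result, outdir / "timeseries.csv")
        write_ledger(result, outdir / "ledger.csv")
    return result


# ---------------------------------------------------------------------------
# CSV serialisation


def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Tidy trajectory CSV with a deterministic column order."""
    path = Path(path)
    frame = result.to_frame()[TIMESERIES_COLUMNS]
    frame.to_csv(path, index=False)
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subcompartment": str}, keep_default_na=False)


def write_ledger(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    result.ledger_frame().to_csv(path, index=False)
    return path


def provenance_report(merged) -> str:
    """Human-readable dump of every parameter value's packaged source."""
    lines = [f"{key}: {src}" for key, src in sorted(merged.provenance.items())]
    return "\n".join(lines)


def plot_timeseries(result: SimulationResult, pairs: Sequence[tuple[str, str]], path=None):
    """Minimal trajectory plot helper: (chemical, compartment) pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for chem, comp in pairs:
        ax.plot(result.t / 24.0, result.concentration(chem, comp), label=f"{chem} {comp}")
    ax.set_xlabel("time (d)")
    ax.set_ylabel("concentration (μmol/L)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
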