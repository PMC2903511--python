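"""Multi-route exposure profiles.

An :class:`ExposureProfile` describes the time course of intake of one
chemical by one route — continuous dietary ingestion, discrete oral boluses,
or inhalation at a constant air concentration — as an ordered list of events.
Profiles are declarative; the kinetics engine compiles them into
piecewise-constant input vectors and bolus state jumps, restarting the stiff
solver at every event boundary so no switch is ever stepped over.

Dietary intake is modelled as a zero-order (piecewise-constant) input: meals
are not resolved, which is appropriate for the long time scales of metal
kinetics.  Intake magnitudes carry explicit unit strings; everything is
converted to the package-internal molar basis (μmol, h) using the chemical's
molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Event",
    "ExposureProfile",
    "ExposureError",
    "gi_absorption_split",
    "air_concentration",
    "inhalation_intake",
    "scale_intakes",
    "MOLAR_VOLUME_L",
]

#: Molar volume of an ideal gas at 25 °C and 1 atm, L/mol.  Used for the
#: ppm → μmol/L air-concentration conversion.
MOLAR_VOLUME_L = 24.45

ORAL_BOLUS = "oral_bolus"
ORAL_CONTINUOUS = "oral_continuous"
INHALATION = "inhalation"
INFUSION = "infusion"

_ROUTES = (ORAL_BOLUS, ORAL_CONTINUOUS, INHALATION, INFUSION)

_RATE_UNITS = {"ug/day", "ug/kg/day", "mg/day", "umol/day", "umol/h"}
_BOLUS_UNITS = {"ug", "mg", "umol"}


class ExposureError(ValueError):
    """Raised for malformed exposure descriptions."""


@dataclass(frozen=True)
class Event:
    """One dosing event.

    ``end`` is ``None`` for an instantaneous bolus; for continuous routes it
    may be ``None`` to mean "until the end of the simulation".
    """

    start: float  # h
    magnitude: float  # in `units`
    units: str
    end: float | None = None  # h

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ExposureError(f"event magnitude must be >= 0, got {self.magnitude}")
        if self.end is not None and self.end < self.start:
            raise ExposureError("event end precedes start")


@dataclass(frozen=True)
class ExposureProfile:
    chemical: str
    route: str
    events: tuple[Event, ...]
    scaling_switches: tuple[tuple[float, float], ...] = ()
    route_label: str = ""  # disambiguates when a chemical has several routes

    def __post_init__(self) -> None:
        if self.route not in _ROUTES:
            raise ExposureError(f"unknown exposure route {self.route!r}")
        events = tuple(self.events)
        if any(events[i].start > events[i + 1].start for i in range(len(events) - 1)):
            raise ExposureError("events must be time-ordered")
        for ev in events:
            self._check_units(ev)
        for _, factor in self.scaling_switches:
            if factor <= 0:
                raise ExposureError("scaling factors must be > 0")
        object.__setattr__(self, "events", events)
        object.__setattr__(
            self,
            "scaling_switches",
            tuple(sorted((float(t), float(f)) for t, f in self.scaling_switches)),
        )

    def _check_units(self, ev: Event) -> None:
        if self.route == INHALATION:
            ok = ev.units == "ppm"
        elif self.route == ORAL_BOLUS:
            ok = ev.units in _BOLUS_UNITS
        else:
            ok = ev.units in _RATE_UNITS
        if not ok:
            raise ExposureError(
                f"units {ev.units!r} invalid for route {self.route!r} "
                f"(chemical {self.chemical!r})"
            )

    def scale_at(self, t: float) -> float:
        """Cumulative scaling factor in force at time ``t``."""
        factor = 1.0
        for t_switch, f in self.scaling_switches:
            if t >= t_switch:
                factor *= f
        return factor

    def switch_times(self) -> list[float]:
        times = [t for t, _ in self.scaling_switches]
        for ev in self.events:
            times.append(ev.start)
            if ev.end is not None:
                times.append(ev.end)
        return times


# ---------------------------------------------------------------------------
# unit conversion


def rate_to_umol_per_h(
    magnitude: float, units: str, molecular_mass: float, body_mass: float
) -> float:
    """Convert a continuous intake magnitude to μmol/h."""
    if units == "umol/h":
        return magnitude
    if units == "umol/day":
        return magnitude / 24.0
    if units == "ug/day":
        return magnitude / molecular_mass / 24.0
    if units == "mg/day":
        return magnitude * 1e3 / molecular_mass / 24.0
    if units == "ug/kg/day":
        return magnitude * body_mass / molecular_mass / 24.0
    raise ExposureError(f"unknown rate units {units!r}")


def bolus_to_umol(magnitude: float, units: str, molecular_mass: float) -> float:
    """Convert a bolus magnitude to μmol."""
    if units == "umol":
        return magnitude
    if units == "ug":
        return magnitude / molecular_mass
    if units == "mg":
        return magnitude * 1e3 / molecular_mass
    raise ExposureError(f"unknown bolus units {units!r}")


# ---------------------------------------------------------------------------
# route physics


def gi_absorption_split(intake_rate: float, f_abs: float) -> tuple[float, float]:
    """Split a gastrointestinal intake into absorbed and unabsorbed parts.

    Returns ``(absorbed, fecal)`` in the units of ``intake_rate``.  The
    absorbed fraction is routed to the model's absorption target (portal
    blood or liver); the remainder is ledgered as unabsorbed fecal output so
    mass balance closes on administered dose.
    """
    if not 0.0 <= f_abs <= 1.0:
        raise ExposureError(f"absorption fraction must be in [0, 1], got {f_abs}")
    absorbed = f_abs * intake_rate
    return absorbed, intake_rate - absorbed


def air_concentration(ppm: float, molar_volume: float = MOLAR_VOLUME_L) -> float:
    """Air concentration (μmol/L) of a vapour at ``ppm`` by volume.

    One ppm is one μmol of vapour per mol of air, i.e. per ``molar_volume``
    litres at 25 °C / 1 atm, so C_air = ppm / 24.45 μmol/L.
    """
    if ppm < 0:
        raise ExposureError("ppm must be >= 0")
    return ppm / molar_volume


def inhalation_intake(
    ppm: float,
    alveolar_ventilation: float,
    blood_air_partition: float,
    c_blood: float = 0.0,
) -> float:
    """Net alveolar uptake rate (μmol/h) under continuous ventilation.

    Standard gas-exchange mass balance with a well-mixed blood pool: uptake =
    Q_alv · (C_air − C_blood / P_b:a).  Negative values mean net exhalation.
    """
    if blood_air_partition <= 0:
        raise ExposureError("blood:air partition must be > 0")
    return alveolar_ventilation * (
        air_concentration(ppm) - c_blood / blood_air_partition
    )


# ---------------------------------------------------------------------------
# scenario edits


def scale_intakes(
    profiles: Iterable[ExposureProfile],
    factor: float,
    t_switch: float,
    chemicals: Sequence[str] | None = None,
) -> list[ExposureProfile]:
    """Multiply intakes by ``factor`` from ``t_switch`` onward.

    Registers a scaling switch on every profile (or only those whose chemical
    is listed in ``chemicals``); the kinetics engine treats the switch time as
    a solver restart point.  ``factor == 1`` is the identity.
    """
    if factor <= 0:
        raise ExposureError("scaling factor must be > 0")
    out = []
    for prof in profiles:
        if chemicals is not None and prof.chemical not in chemicals:
            out.append(prof)
        elif factor == 1.0:
            out.append(prof)
        else:
            out.append(
                replace(
                    prof,
                    scaling_switches=prof.scaling_switches + ((t_switch, factor),),
                )
            )
    return out
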