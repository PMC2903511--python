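"""Chemical-independent whole-body physiology.

A :class:`BodyPhysiology` is the shared compartment network onto which every
chemical-specific model is mapped: tissue volumes, tissue blood flows and the
cardiac output that the perfused flows must sum to.  Keeping one body for all
chemicals is what makes a joint mixture simulation physiologically consistent —
two chemicals can disagree about partitioning or metabolism, but never about
how much blood flows through the liver.

Internal units are litres (L), litres per hour (L/h), hours (h) and kilograms
(kg) throughout the package; converters for other units live in
:mod:`pbtkmix.simio`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "BodyPhysiology",
    "PhysiologyError",
    "load_physiology",
    "reference_adult",
    "lump_compartments",
    "sample_individual",
    "FLOW_RTOL",
]

#: Relative tolerance for the cardiac-output conservation invariant.
FLOW_RTOL = 1e-9

PERFUSION_LIMITED = "perfusion_limited"
DIFFUSION_LIMITED = "diffusion_limited"
STORAGE = "storage"

_SCHEMES = (PERFUSION_LIMITED, DIFFUSION_LIMITED, STORAGE)

#: Default classification of tissues into rapidly and slowly perfused groups,
#: used when a chemical model does not represent a tissue explicitly.  The
#: split follows standard PBPK practice (viscera rapid; muscle, skin, fat and
#: bone slow); it can be overridden via the ``lump_classes`` argument of
#: :func:`lump_compartments`.
DEFAULT_LUMP_CLASSES: dict[str, str] = {
    "liver": "rapidly_perfused",
    "kidney": "rapidly_perfused",
    "brain": "rapidly_perfused",
    "gut": "rapidly_perfused",
    "viscera": "rapidly_perfused",
    "heart": "rapidly_perfused",
    "lung": "rapidly_perfused",
    "muscle": "slowly_perfused",
    "skin": "slowly_perfused",
    "fat": "slowly_perfused",
    "bone": "slowly_perfused",
}

_LUMP_NAMES = ("rapidly_perfused", "slowly_perfused")


class PhysiologyError(ValueError):
    """Raised when a physiology description violates an invariant."""


@dataclass(frozen=True)
class Compartment:
    """One tissue (or storage space) of the whole-body network.

    Parameters
    ----------
    name:
        Unique identifier, e.g. ``"liver"``.
    volume:
        Tissue volume in L; must be positive.
    blood_flow:
        Perfusion in L/h.  Zero for storage compartments (bone mineral,
        gastrointestinal lumen) that exchange by transport processes rather
        than by blood flow.
    scheme:
        ``"perfusion_limited"``, ``"diffusion_limited"`` or ``"storage"``.
    subvolumes:
        ``(extracellular, cellular)`` volumes in L, required when the scheme
        is diffusion limited; they must sum to ``volume``.
    tags:
        Free-form role tags (``{"liver"}``, ``{"blood"}``, ...) used by model
        builders and by the lumping classifier.
    """

    name: str
    volume: float
    blood_flow: float = 0.0
    scheme: str = PERFUSION_LIMITED
    subvolumes: tuple[float, float] | None = None
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise PhysiologyError("compartment name must be non-empty")
        if not np.isfinite(self.volume) or self.volume <= 0:
            raise PhysiologyError(
                f"compartment {self.name!r}: volume must be > 0, got {self.volume}"
            )
        if not np.isfinite(self.blood_flow) or self.blood_flow < 0:
            raise PhysiologyError(
                f"compartment {self.name!r}: blood_flow must be >= 0, "
                f"got {self.blood_flow}"
            )
        if self.scheme not in _SCHEMES:
            raise PhysiologyError(
                f"compartment {self.name!r}: unknown scheme {self.scheme!r}"
            )
        if self.scheme == DIFFUSION_LIMITED:
            if self.subvolumes is None:
                raise PhysiologyError(
                    f"compartment {self.name!r}: diffusion-limited scheme "
                    "requires subvolumes (extracellular, cellular)"
                )
            ve, vc = self.subvolumes
            if ve <= 0 or vc <= 0:
                raise PhysiologyError(
                    f"compartment {self.name!r}: subvolumes must be > 0"
                )
            if abs((ve + vc) - self.volume) > 1e-9 * self.volume:
                raise PhysiologyError(
                    f"compartment {self.name!r}: subvolumes {ve}+{vc} do not "
                    f"sum to volume {self.volume}"
                )
        if not isinstance(self.tags, frozenset):
            object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def is_perfused(self) -> bool:
        return self.scheme != STORAGE and self.blood_flow > 0

    @property
    def extracellular_volume(self) -> float:
        if self.scheme != DIFFUSION_LIMITED:
            raise PhysiologyError(f"{self.name} has no subcompartments")
        return self.subvolumes[0]  # type: ignore[index]

    @property
    def cellular_volume(self) -> float:
        if self.scheme != DIFFUSION_LIMITED:
            raise PhysiologyError(f"{self.name} has no subcompartments")
        return self.subvolumes[1]  # type: ignore[index]


@dataclass(frozen=True)
class BodyPhysiology:
    """Validated whole-body compartment network.

    The central invariant is flow conservation: the blood flows of all
    perfused compartments (explicit plus lumped) sum to the cardiac output
    within ``FLOW_RTOL`` relative tolerance.  Storage compartments and the
    central blood pool are excluded from the sum.
    """

    compartments: tuple[Compartment, ...]
    cardiac_output: float
    body_mass: float
    lumps: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "lumps", dict(self.lumps))
        self.validate()

    # -- access -----------------------------------------------------------

    def __getitem__(self, name: str) -> Compartment:
        for comp in self.compartments:
            if comp.name == name:
                return comp
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.compartments)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    @property
    def blood(self) -> Compartment:
        """The central blood pool (tagged ``blood``)."""
        for comp in self.compartments:
            if "blood" in comp.tags:
                return comp
        raise PhysiologyError("physiology has no compartment tagged 'blood'")

    def perfused(self) -> tuple[Compartment, ...]:
        return tuple(
            c
            for c in self.compartments
            if c.scheme != STORAGE and "blood" not in c.tags
        )

    def total_perfused_flow(self) -> float:
        return float(sum(c.blood_flow for c in self.perfused()))

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if not np.isfinite(self.cardiac_output) or self.cardiac_output <= 0:
            raise PhysiologyError(
                f"cardiac_output must be > 0, got {self.cardiac_output}"
            )
        if not np.isfinite(self.body_mass) or self.body_mass <= 0:
            raise PhysiologyError(f"body_mass must be > 0, got {self.body_mass}")
        names = [c.name for c in self.compartments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PhysiologyError(f"duplicate compartment names: {sorted(dupes)}")
        self.blood  # noqa: B018 - raises if missing
        total = self.total_perfused_flow()
        if abs(total - self.cardiac_output) > FLOW_RTOL * self.cardiac_output:
            raise PhysiologyError(
                f"perfused blood flows sum to {total:.6g} L/h but cardiac "
                f"output is {self.cardiac_output:.6g} L/h"
            )
        # Body density close to 1 kg/L; allow a small margin for the check.
        total_volume = sum(c.volume for c in self.compartments)
        if total_volume > 1.05 * self.body_mass:
            raise PhysiologyError(
                f"total compartment volume {total_volume:.6g} L exceeds the "
                f"body-mass-implied bound for {self.body_mass:.6g} kg"
            )


# ---------------------------------------------------------------------------
# construction


def load_physiology(source: str | Path | Mapping) -> BodyPhysiology:
    """Build a validated :class:`BodyPhysiology` from a YAML file or mapping.

    The document layout is::

        cardiac_output: 312.0   # L/h
        body_mass: 70.0         # kg
        compartments:
          - {name: blood, volume: 5.5, tags: [blood]}
          - {name: liver, volume: 1.8, blood_flow: 78.0, tags: [liver]}
          ...

    Raises
    ------
    PhysiologyError
        If a required field is missing, a name is duplicated or any quantity
        is negative; the message names the offending field.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if "cardiac_output" not in doc:
        raise PhysiologyError("physiology spec is missing 'cardiac_output'")
    if "body_mass" not in doc:
        raise PhysiologyError("physiology spec is missing 'body_mass'")
    if not doc.get("compartments"):
        raise PhysiologyError("physiology spec lists no compartments")
    comps = []
    for entry in doc["compartments"]:
        entry = dict(entry)
        sub = entry.pop("subvolumes", None)
        comps.append(
            Compartment(
                name=entry.pop("name", ""),
                volume=float(entry.pop("volume", np.nan)),
                blood_flow=float(entry.pop("blood_flow", 0.0)),
                scheme=entry.pop("scheme", PERFUSION_LIMITED),
                subvolumes=tuple(float(v) for v in sub) if sub else None,
                tags=frozenset(entry.pop("tags", ())),
            )
        )
    return BodyPhysiology(
        compartments=tuple(comps),
        cardiac_output=float(doc["cardiac_output"]),
        body_mass=float(doc["body_mass"]),
        lumps=doc.get("lumps", {}),
    )


def reference_adult() -> BodyPhysiology:
    """The packaged 70 kg reference-adult physiology.

    These are repository defaults assembled from standard human physiology
    compilations; they are not transcribed from any single source model.
    """
    from ._data import packaged_data_path

    return load_physiology(packaged_data_path("physiology_adult.yaml"))


# ---------------------------------------------------------------------------
# lumping


def lump_compartments(
    body: BodyPhysiology,
    explicit: Iterable[str],
    lump_classes: Mapping[str, str] | None = None,
) -> BodyPhysiology:
    """Merge non-explicit perfused tissues into rapidly/slowly perfused lumps.

    Every perfused tissue not named in ``explicit`` is assigned to one of two
    lump compartments by the classification table; each lump's volume is the
    sum of its members' volumes and the total lump flow equals the cardiac
    output minus the explicit flows exactly, so flow conservation is preserved
    by construction.  Storage compartments and blood are never lumped.

    The operation is idempotent: applying it twice with the same explicit set
    returns an equivalent body.
    """
    explicit = set(explicit)
    classes = dict(DEFAULT_LUMP_CLASSES)
    if lump_classes:
        classes.update(lump_classes)
    unknown = explicit - set(body.names)
    if unknown:
        raise PhysiologyError(f"explicit compartments not in body: {sorted(unknown)}")

    kept: list[Compartment] = []
    members: dict[str, list[Compartment]] = {n: [] for n in _LUMP_NAMES}
    for comp in body.compartments:
        if (
            comp.name in explicit
            or "blood" in comp.tags
            or comp.scheme == STORAGE
            or comp.blood_flow == 0
        ):
            kept.append(comp)
            continue
        if comp.name in _LUMP_NAMES:
            members[comp.name].append(comp)
            continue
        cls = None
        for key in (comp.name, *sorted(comp.tags)):
            if key in classes:
                cls = classes[key]
                break
        if cls is None:
            cls = "slowly_perfused"
        members[cls].append(comp)

    explicit_flow = sum(c.blood_flow for c in kept if c.scheme != STORAGE and "blood" not in c.tags)
    remainder = body.cardiac_output - explicit_flow
    if remainder < -FLOW_RTOL * body.cardiac_output:
        raise PhysiologyError(
            f"explicit flows ({explicit_flow:.6g} L/h) exceed cardiac output "
            f"({body.cardiac_output:.6g} L/h)"
        )
    member_flow = sum(c.blood_flow for cs in members.values() for c in cs)
    for lump_name in _LUMP_NAMES:
        group = members[lump_name]
        if not group:
            continue
        group_flow = sum(c.blood_flow for c in group)
        # Distribute the exact remainder in proportion to member flows so the
        # cardiac-output budget closes to machine precision.
        flow = remainder * group_flow / member_flow if member_flow else 0.0
        kept.append(
            Compartment(
                name=lump_name,
                volume=sum(c.volume for c in group),
                blood_flow=flow,
                scheme=PERFUSION_LIMITED,
                tags=frozenset({lump_name}),
            )
        )
    lumps = dict(body.lumps)
    for lump_name in _LUMP_NAMES:
        if members[lump_name]:
            prior: tuple[str, ...] = tuple(
                m
                for c in members[lump_name]
                for m in body.lumps.get(c.name, (c.name,))
            )
            lumps[lump_name] = prior
    return BodyPhysiology(
        compartments=tuple(kept),
        cardiac_output=body.cardiac_output,
        body_mass=body.body_mass,
        lumps=lumps,
    )


# ---------------------------------------------------------------------------
# virtual individuals


def sample_individual(
    base: BodyPhysiology,
    cv_spec: Mapping[str, float],
    seed: int,
) -> BodyPhysiology:
    """Draw one virtual individual around a reference body.

    Volumes, flows and the cardiac output are perturbed by mean-preserving
    lognormal factors with the requested coefficients of variation, after
    which all tissue flows are renormalised so they sum exactly to the
    sampled cardiac output — the individual is random but physiologically
    consistent.

    Parameters
    ----------
    cv_spec:
        Mapping with any of the keys ``volume``, ``blood_flow`` and
        ``cardiac_output`` giving the coefficient of variation for that
        field.  A CV of zero (or an absent key) leaves the field untouched,
        so an all-zero spec returns ``base`` unchanged.
    seed:
        Seed for the random draw; the same seed yields the same individual.
    """
    cvs = {k: float(v) for k, v in cv_spec.items()}
    for key, cv in cvs.items():
        if cv < 0:
            raise PhysiologyError(f"cv for {key!r} must be >= 0, got {cv}")
    if all(v == 0 for v in cvs.values()):
        return base
    rng = np.random.default_rng(seed)

    def draw(cv: float, n: int = 1) -> np.ndarray:
        if cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(cv * cv))
        return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)

    co = base.cardiac_output * draw(cvs.get("cardiac_output", 0.0))[0]
    comps: list[Compartment] = []
    for comp in base.compartments:
        vol = comp.volume * draw(cvs.get("volume", 0.0))[0]
        sub = comp.subvolumes
        if sub is not None:
            scale = vol / comp.volume
            sub = (sub[0] * scale, sub[1] * scale)
        flow = comp.blood_flow
        if comp.is_perfused and "blood" not in comp.tags:
            flow = comp.blood_flow * draw(cvs.get("blood_flow", 0.0))[0]
        comps.append(replace(comp, volume=vol, blood_flow=flow, subvolumes=sub))

    perfused_total = sum(
        c.blood_flow for c in comps if c.scheme != STORAGE and "blood" not in c.tags
    )
    norm = co / perfused_total
    comps = [
        replace(c, blood_flow=c.blood_flow * norm)
        if c.scheme != STORAGE and "blood" not in c.tags
        else c
        for c in comps
    ]
    # keep the individual internally consistent: body mass scales with the
    # sampled total tissue volume
    base_volume = sum(c.volume for c in base.compartments)
    new_volume = sum(c.volume for c in comps)
    body = BodyPhysiology(
        compartments=tuple(comps),
        cardiac_output=co,
        body_mass=base.body_mass * new_volume / base_volume,
        lumps=copy.deepcopy(dict(base.lumps)),
    )
    return body
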