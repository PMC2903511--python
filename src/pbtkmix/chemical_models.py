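"""Builders mapping published chemical-specific model structures onto the
shared whole-body physiology.

Each ``build_*_model`` function returns a :class:`ConfiguredSystem` — species,
reaction network, transport processes, auxiliary pools and intake routes —
parameterised from a packaged YAML file that records the provenance of every
value.  The builders encode *structure* only; all numbers live in the config
files and can be overridden per call.

The five metal models span the structural range of the field: a first-order
biokinetic transfer network (cadmium), a six-species saturable metabolic
network (arsenic), a bone-diffusion model with eight cortical shells (lead), a
fast-redox two-species model on the lead skeleton (chromium), and a
multi-route excretion model with an optional growing fetal subsystem
(methylmercury).  The volatile-organics builder adds benzene and toluene with
alveolar gas exchange and mutually competitively inhibited hepatic oxidation.
All builders share one reference body, so any subset can be merged with
:func:`merge_models` and simulated jointly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._data import load_packaged_yaml
from .exposure import ExposureProfile
from .kinetics import (
    AuxPool,
    ChemicalSpecies,
    ChemicalTissueParams,
    IntakeRoute,
    KineticsError,
    MMReaction,
    ODESystem,
    ReactionNetwork,
    TransportProcess,
    assemble_system,
)
from .physiology import BodyPhysiology, reference_adult

__all__ = [
    "ConfiguredSystem",
    "build_cadmium_model",
    "build_arsenic_model",
    "build_lead_model",
    "build_chromium_model",
    "build_mehg_model",
    "build_voc_model",
    "merge_models",
    "MODEL_BUILDERS",
]

HOURS_PER_DAY = 24.0


def _val(node) -> float:
    """Unwrap a ``{value: x, ...}`` config node or a bare number."""
    if isinstance(node, Mapping):
        return float(node["value"])
    return float(node)


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _load_config(filename: str, params: Mapping | None) -> dict:
    cfg = load_packaged_yaml(filename)
    if params:
        cfg = _deep_update(cfg, params)
    return cfg


def _collect_provenance(doc, filename: str, prefix: str = "") -> dict[str, str]:
    out: dict[str, str] = {}
    if isinstance(doc, Mapping):
        if "value" in doc:
            out[prefix] = f"{filename}: {doc.get('source', 'packaged default')}"
            return out
        for key, val in doc.items():
            if key == "source":
                continue
            sub = f"{prefix}.{key}" if prefix else str(key)
            out.update(_collect_provenance(val, filename, sub))
    elif isinstance(doc, (int, float)):
        out[prefix] = f"{filename}: packaged default"
    return out


@dataclass
class ConfiguredSystem:
    """A chemical model (or a merged set of models) ready for assembly.

    Everything the kinetics engine needs except the exposure scenario;
    ``provenance`` maps every parameter path to the packaged file and source
    note it came from.
    """

    body: BodyPhysiology
    chemicals: list[ChemicalSpecies]
    network: ReactionNetwork
    transports: list[TransportProcess] = field(default_factory=list)
    aux_pools: list[AuxPool] = field(default_factory=list)
    routes: list[IntakeRoute] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    notes: dict[str, object] = field(default_factory=dict)

    def assemble(
        self,
        exposures: Sequence[ExposureProfile] = (),
        interactions: Sequence = (),
    ) -> ODESystem:
        return assemble_system(
            body=self.body,
            chemicals=self.chemicals,
            network=self.network,
            transports=self.transports,
            aux_pools=self.aux_pools,
            routes=self.routes,
            exposures=exposures,
            interactions=interactions,
        )

    def species_names(self) -> list[str]:
        return [c.name for c in self.chemicals]


def merge_models(*models: ConfiguredSystem) -> ConfiguredSystem:
    """Join several chemical models on their common physiology.

    All models must share the same body (the physiological-consistency
    contract); species sets must be disjoint.  The per-tissue first-order
    networks are embedded block-diagonally into one matrix over the combined
    species list, so merged chemicals interact only through explicitly
    registered reactions or interaction specs.
    """
    if not models:
        raise KineticsError("merge_models needs at least one model")
    body = models[0].body
    for m in models[1:]:
        if m.body is not body and m.body != body:
            raise KineticsError("all merged models must share one BodyPhysiology")
    species: list[str] = []
    for m in models:
        for name in m.species_names():
            if name in species:
                raise KineticsError(f"duplicate chemical {name!r} across models")
            species.append(name)
    n = len(species)
    offset = {name: i for i, name in enumerate(species)}
    gamma: dict[str, np.ndarray] = {}
    mm: list[MMReaction] = []
    for m in models:
        sp = m.network.species
        for tissue, mat in m.network.gamma.items():
            target = gamma.setdefault(tissue, np.zeros((n, n)))
            for a, pa in enumerate(sp):
                for b, pb in enumerate(sp):
                    target[offset[pb], offset[pa]] += mat[b, a]
        mm.extend(copy.deepcopy(m.network.mm_reactions))
    merged_net = ReactionNetwork(species=tuple(species), gamma=gamma, mm_reactions=mm)
    prov: dict[str, str] = {}
    notes: dict[str, object] = {}
    for m in models:
        prov.update(m.provenance)
        notes.update(m.notes)
    return ConfiguredSystem(
        body=body,
        chemicals=[c for m in models for c in m.chemicals],
        network=merged_net,
        transports=[t for m in models for t in m.transports],
        aux_pools=[p for m in models for p in m.aux_pools],
        routes=[r for m in models for r in m.routes],
        provenance=prov,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# cadmium


def build_cadmium_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
    sex: str = "male",
) -> ConfiguredSystem:
    """Linear cadmium biokinetic network.

    First-order transfers between blood and liver, kidney and a lumped
    other-tissue pool, with sex-dependent GI absorption, slow urinary
    elimination from the kidney (the long cadmium half-life) and a fecal
    secretion route.  All transfers are entries of the transport matrix; the
    model is linear, so tissue levels scale with intake.
    """
    body = body or reference_adult()
    cfg = _load_config("cadmium.yaml", params)
    if sex not in ("male", "female"):
        raise KineticsError(f"sex must be 'male' or 'female', got {sex!r}")
    f_abs = _val(cfg["absorption"][f"f_abs_{sex}"])
    k = {
        name: _val(node) / HOURS_PER_DAY
        for name, node in cfg["transfers"].items()
        if node is not None
    }
    missing = {
        "blood_to_liver",
        "blood_to_kidney",
        "blood_to_other",
        "blood_to_urine",
        "blood_to_feces",
        "liver_to_blood",
        "kidney_to_urine",
        "kidney_to_blood",
        "other_to_blood",
    } - set(k)
    if missing:
        raise KineticsError(f"cadmium config missing transfers: {sorted(missing)}")
    cd = ChemicalSpecies(name="cadmium", molecular_mass=_val(cfg["molecular_mass"]))
    pools = [
        AuxPool("cadmium", "liver", body["liver"].volume),
        AuxPool("cadmium", "kidney", body["kidney"].volume),
        AuxPool("cadmium", "other", _val(cfg["other_tissue_volume"])),
    ]
    t = TransportProcess
    transports = [
        t("first_order_transfer", "cadmium", "blood", "liver", k["blood_to_liver"]),
        t("first_order_transfer", "cadmium", "blood", "kidney", k["blood_to_kidney"]),
        t("first_order_transfer", "cadmium", "blood", "other", k["blood_to_other"]),
        t("urinary_excretion", "cadmium", "blood", rate=k["blood_to_urine"]),
        t("fecal_excretion", "cadmium", "blood", rate=k["blood_to_feces"]),
        t("first_order_transfer", "cadmium", "liver", "blood", k["liver_to_blood"]),
        t("urinary_excretion", "cadmium", "kidney", rate=k["kidney_to_urine"]),
        t("first_order_transfer", "cadmium", "kidney", "blood", k["kidney_to_blood"]),
        t("first_order_transfer", "cadmium", "other", "blood", k["other_to_blood"]),
    ]
    routes = [IntakeRoute("cadmium", "oral", dest="blood", f_abs=f_abs)]
    return ConfiguredSystem(
        body=body,
        chemicals=[cd],
        network=ReactionNetwork(species=("cadmium",)),
        transports=transports,
        aux_pools=pools,
        routes=routes,
        provenance=_collect_provenance(cfg, "cadmium.yaml"),
        notes={"kidney_cortex_ratio": _val(cfg["kidney_cortex_ratio"]), "sex": sex},
    )


# ---------------------------------------------------------------------------
# arsenic


ARSENIC_SPECIES = ("asV", "asIII", "mmaV", "mmaIII", "dmaV", "dmaIII")


def build_arsenic_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
) -> ConfiguredSystem:
    """Six-species arsenic metabolic network.

    Tracked species AsV, AsIII, MMAV, MMAIII, DMAV, DMAIII with hepatic
    metabolism: first-order reductions V→III (steps 1, 4, 6), saturable AS3MT
    methylations (steps 2, 3, 5) with noncompetitive inhibition of step 2 by
    liver MMAIII and of step 5 by liver AsIII, minor back-oxidation III→V for
    all species, and no demethylation.  Urinary excretion is the only
    elimination route; GI uptake runs through the gut lumen.
    """
    body = body or reference_adult()
    cfg = _load_config("arsenic.yaml", params)
    mw = _val(cfg["molecular_mass"])
    pcs = cfg["partition_coefficients"]
    chems = []
    for sp in ARSENIC_SPECIES:
        if sp not in pcs:
            raise KineticsError(f"arsenic config missing partitions for {sp!r}")
        tissue_params = {
            tissue: ChemicalTissueParams(partition_coefficient=float(p))
            for tissue, p in pcs[sp].items()
        }
        chems.append(
            ChemicalSpecies(name=sp, molecular_mass=mw, tissue_params=tissue_params)
        )
    met = cfg["metabolism"]
    kox = _val(met["oxidation_III_to_V"])
    liver_paths = [
        ("asV", "asIII", _val(met["reduction_asV_to_asIII"])),  # step 1
        ("mmaV", "mmaIII", _val(met["reduction_mmaV_to_mmaIII"])),  # step 4
        ("dmaV", "dmaIII", _val(met["reduction_dmaV_to_dmaIII"])),  # step 6
        ("asIII", "asV", kox),
        ("mmaIII", "mmaV", kox),
        ("dmaIII", "dmaV", kox),
    ]
    step2 = met["methylation_asIII_to_mmaV"]
    step3 = met["methylation_asIII_to_dmaV"]
    step5 = met["methylation_mmaIII_to_dmaV"]
    mm = [
        MMReaction(
            tissue="liver",
            substrate="asIII",
            product="mmaV",
            vmax=float(step2["vmax"]),
            km=float(step2["km"]),
            noncompetitive=[("mmaIII", float(step2["k_nc"]))],
        ),
        MMReaction(
            tissue="liver",
            substrate="asIII",
            product="dmaV",
            vmax=float(step3["vmax"]),
            km=float(step3["km"]),
        ),
        MMReaction(
            tissue="liver",
            substrate="mmaIII",
            product="dmaV",
            vmax=float(step5["vmax"]),
            km=float(step5["km"]),
            noncompetitive=[("asIII", float(step5["k_nc"]))],
        ),
    ]
    network = ReactionNetwork.from_pathways(
        ARSENIC_SPECIES, {"liver": liver_paths}, mm_reactions=mm
    )
    k_abs = _val(cfg["gi"]["k_absorption"])
    k_fec = _val(cfg["gi"]["k_fecal"])
    transports = []
    for sp in ARSENIC_SPECIES:
        transports += [
            TransportProcess("gi_absorption", sp, "gi_lumen", "blood", k_abs),
            TransportProcess("fecal_excretion", sp, "gi_lumen", rate=k_fec),
            TransportProcess(
                "urinary_excretion",
                sp,
                "blood",
                rate=float(cfg["urinary_clearance"][sp]),
                basis="clearance",
            ),
        ]
    routes = [IntakeRoute(sp, "oral", dest="gi_lumen") for sp in ARSENIC_SPECIES]
    return ConfiguredSystem(
        body=body,
        chemicals=chems,
        network=network,
        transports=transports,
        routes=routes,
        provenance=_collect_provenance(cfg, "arsenic.yaml"),
    )


# ---------------------------------------------------------------------------
# lead


def build_lead_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
    include_age_growth: bool = False,
    tracer: bool = False,
) -> ConfiguredSystem:
    """Lead model with an eight-shell cortical bone subsystem.

    Diffusible blood lead exchanges fast with a deep red-cell pool, perfuses
    the soft tissues flow-limited, and is cleared into urine and into bone:
    a trabecular pool with first-order return and mature cortical bone
    discretised into eight concentric cylindrical shells (equal radial
    thickness) exchanging by diffusion, the innermost shell in contact with
    blood.  Bone dominates the chronic body burden.

    ``include_age_growth`` scales the bone-uptake clearances by a simplified
    piecewise-linear childhood bone-turnover multiplier evaluated at age 0
    onward; ``tracer`` adds a second species sharing all parameters (stable
    isotope tracer studies).
    """
    body = body or reference_adult()
    cfg = _load_config("lead.yaml", params)
    bone = cfg["bone"]
    n_shells = int(_val(bone["n_shells"]))
    if n_shells < 1:
        raise KineticsError("lead model needs at least one cortical shell")
    mw = _val(cfg["molecular_mass"])
    pc = cfg["partition_coefficients"]
    brain_h = float(pc["brain_h"])

    def species(name: str) -> ChemicalSpecies:
        tissue_params = {
            tissue: ChemicalTissueParams(partition_coefficient=float(p))
            for tissue, p in pc.items()
            if tissue != "brain_h"
        }
        tissue_params["brain"] = ChemicalTissueParams(
            partition_coefficient=float(pc["brain"]), permeability=brain_h
        )
        return ChemicalSpecies(name=name, molecular_mass=mw, tissue_params=tissue_params)

    names = ["lead"] + (["lead204"] if tracer else [])
    chems = [species(n) for n in names]

    # cortical shell geometry: equal-thickness annuli of a cylinder
    f_inner = _val(bone["inner_radius_fraction"])
    v_cort = _val(bone["cortical_volume"])
    radii = np.linspace(f_inner, 1.0, n_shells + 1)
    vol_fracs = np.diff(radii**2) / (1.0 - f_inner**2)
    shell_volumes = vol_fracs * v_cort
    dr = (1.0 - f_inner) / n_shells
    sc = _val(bone["shell_conductance"])
    conductances = sc * radii[1:-1] / dr  # interface i | i+1 at radius r_i

    p_bone = _val(bone["bone_blood_partition"])
    cl_cort = _val(bone["clearance_to_cortical"])
    cl_trab = _val(bone["clearance_to_trabecular"])
    k_trab_ret = _val(bone["trabecular_return"])
    turnover = 1.0
    if include_age_growth:
        ag = cfg["age_growth"]
        turnover = float(ag["bone_turnover_multiplier"][0])
    cl_cort *= turnover
    cl_trab *= turnover

    pools: list[AuxPool] = []
    transports: list[TransportProcess] = []
    t = TransportProcess
    for name in names:
        pools.append(AuxPool(name, "rbc", _val(cfg["blood_binding"]["rbc_pool_volume"])))
        pools.append(AuxPool(name, "trabecular", _val(bone["trabecular_volume"])))
        pools += [
            AuxPool(name, f"cortical_{i + 1}", shell_volumes[i])
            for i in range(n_shells)
        ]
        transports += [
            t("first_order_transfer", name, "blood", "rbc",
              _val(cfg["blood_binding"]["k_plasma_to_rbc"])),
            t("first_order_transfer", name, "rbc", "blood",
              _val(cfg["blood_binding"]["k_rbc_to_plasma"])),
            t("urinary_excretion", name, "blood",
              rate=_val(cfg["excretion"]["urinary_clearance"]), basis="clearance"),
            # bone exchange: uptake on blood concentration, return
            # partition-limited from the exchanging pools
            t("bone_exchange", name, "blood", "trabecular", cl_trab, basis="clearance"),
            t("bone_exchange", name, "trabecular", "blood", k_trab_ret),
            t("bone_exchange", name, "blood", "cortical_1", cl_cort, basis="clearance"),
            t("bone_exchange", name, "cortical_1", "blood", cl_cort / p_bone,
              basis="clearance"),
        ]
        # radial diffusion between adjacent shells: flux g_i (C_i − C_{i+1})
        for i in range(n_shells - 1):
            g = conductances[i]
            transports += [
                t("bone_exchange", name, f"cortical_{i + 1}", f"cortical_{i + 2}",
                  g, basis="clearance"),
                t("bone_exchange", name, f"cortical_{i + 2}", f"cortical_{i + 1}",
                  g, basis="clearance"),
            ]
    routes = [
        IntakeRoute(name, "oral", dest="blood", f_abs=_val(cfg["absorption"]["f_abs"]))
        for name in names
    ]
    return ConfiguredSystem(
        body=body,
        chemicals=chems,
        network=ReactionNetwork(species=tuple(names)),
        transports=transports,
        aux_pools=pools,
        routes=routes,
        provenance=_collect_provenance(cfg, "lead.yaml"),
        notes={"n_shells": n_shells, "shell_volumes": shell_volumes.tolist()},
    )


def bone_fraction(result, chemical: str = "lead") -> np.ndarray:
    """Fraction of the in-body burden residing in bone over time."""
    system = result.system
    bone_idx = [
        i
        for i, s in enumerate(system.states)
        if s.kind == "pool"
        and s.chemical == chemical
        and (s.compartment.startswith("cortical_") or s.compartment == "trabecular")
    ]
    total = result.body_burden(chemical)
    bone = result.y[:, bone_idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, bone / total, np.nan)


# ---------------------------------------------------------------------------
# chromium


def build_chromium_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
) -> ConfiguredSystem:
    """Two-species chromium model: fast blood reduction of Cr(VI) to Cr(III).

    Cr(VI) entering blood is reduced with a minutes-scale half-life, so only
    Cr(III) persists; Cr(III) distributes on the lead-model skeleton (soft
    tissues plus a slowly exchanging bone store) and both species are cleared
    into urine.
    """
    body = body or reference_adult()
    cfg = _load_config("chromium.yaml", params)
    mw = _val(cfg["molecular_mass"])
    pcs = cfg["partition_coefficients"]
    chems = [
        ChemicalSpecies(
            name=sp,
            molecular_mass=mw,
            tissue_params={
                tissue: ChemicalTissueParams(partition_coefficient=float(p))
                for tissue, p in pcs[sp].items()
            },
        )
        for sp in ("crVI", "crIII")
    ]
    network = ReactionNetwork.from_pathways(
        ("crVI", "crIII"),
        {"blood": [("crVI", "crIII", _val(cfg["blood_reduction"]))]},
    )
    t = TransportProcess
    k_fec = _val(cfg["gi"]["k_fecal"])
    transports = [
        t("gi_absorption", "crVI", "gi_lumen", "blood",
          _val(cfg["gi"]["k_absorption_crVI"])),
        t("fecal_excretion", "crVI", "gi_lumen", rate=k_fec),
        t("gi_absorption", "crIII", "gi_lumen", "blood",
          _val(cfg["gi"]["k_absorption_crIII"])),
        t("fecal_excretion", "crIII", "gi_lumen", rate=k_fec),
        t("urinary_excretion", "crVI", "blood",
          rate=_val(cfg["excretion"]["urinary_clearance_crVI"]), basis="clearance"),
        t("urinary_excretion", "crIII", "blood",
          rate=_val(cfg["excretion"]["urinary_clearance_crIII"]), basis="clearance"),
        t("bone_exchange", "crIII", "blood", "bone_store",
          _val(cfg["bone"]["clearance_to_bone"]), basis="clearance"),
        t("bone_exchange", "crIII", "bone_store", "blood",
          _val(cfg["bone"]["bone_return"])),
    ]
    pools = [AuxPool("crIII", "bone_store", _val(cfg["bone"]["bone_pool_volume"]))]
    routes = [
        IntakeRoute("crVI", "oral", dest="gi_lumen"),
        IntakeRoute("crIII", "oral", dest="gi_lumen"),
    ]
    return ConfiguredSystem(
        body=body,
        chemicals=chems,
        network=network,
        transports=transports,
        aux_pools=pools,
        routes=routes,
        provenance=_collect_provenance(cfg, "chromium.yaml"),
    )


# ---------------------------------------------------------------------------
# methylmercury


def build_mehg_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
    pregnancy: bool = False,
    lactation: bool = False,
) -> ConfiguredSystem:
    """Methylmercury and inorganic mercury.

    MeHg crosses the blood-brain barrier (diffusion-limited brain), is
    excreted in feces (dominant, biliary), hair and urine — plus breast milk
    when lactation is configured — and is demethylated to inorganic mercury in
    a configurable tissue set.  The pregnancy flag adds a fetal pool with
    bidirectional placental transfer and a linearly growing fetal volume; the
    fetal:maternal partition makes fetal blood levels exceed maternal ones.
    Amounts are expressed as Hg.
    """
    body = body or reference_adult()
    cfg = _load_config("methylmercury.yaml", params)
    mw = _val(cfg["molecular_mass"])
    pcs = cfg["partition_coefficients"]
    brain_h = _val(cfg["brain_permeability"])

    def make(sp: str) -> ChemicalSpecies:
        tp = {}
        for tissue, p in pcs[sp].items():
            h = brain_h if tissue == "brain" else None
            tp[tissue] = ChemicalTissueParams(
                partition_coefficient=float(p), permeability=h
            )
        return ChemicalSpecies(name=sp, molecular_mass=mw, tissue_params=tp)

    chems = [make("mehg"), make("ihg")]
    k_dem = _val(cfg["demethylation"]["rate"])
    dem_tissues = list(cfg["demethylation"]["tissues"])
    for tissue in dem_tissues:
        if tissue not in pcs["mehg"] or tissue not in pcs["ihg"]:
            raise KineticsError(
                f"demethylation tissue {tissue!r} must be occupied by both species"
            )
    network = ReactionNetwork.from_pathways(
        ("mehg", "ihg"),
        {tissue: [("mehg", "ihg", k_dem)] for tissue in dem_tissues},
    )
    exc = cfg["excretion"]
    t = TransportProcess
    transports = [
        t("fecal_excretion", "mehg", "liver", rate=_val(exc["mehg"]["fecal_from_liver"])),
        t("hair_excretion", "mehg", "blood",
          rate=_val(exc["mehg"]["hair_clearance"]), basis="clearance"),
        t("urinary_excretion", "mehg", "blood",
          rate=_val(exc["mehg"]["urinary_clearance"]), basis="clearance"),
        t("urinary_excretion", "ihg", "blood",
          rate=_val(exc["ihg"]["urinary_clearance"]), basis="clearance"),
        t("fecal_excretion", "ihg", "liver", rate=_val(exc["ihg"]["fecal_from_liver"])),
    ]
    if lactation:
        transports.append(
            t("milk_excretion", "mehg", "blood",
              rate=_val(exc["mehg"]["milk_clearance"]), basis="clearance")
        )
    pools: list[AuxPool] = []
    if pregnancy:
        preg = cfg.get("pregnancy")
        if not preg:
            raise KineticsError("pregnancy flag requires fetal parameters")
        v0 = _val(preg["fetal_volume_start"])
        v1 = _val(preg["fetal_volume_term"])
        t_term = _val(preg["gestation_days"]) * HOURS_PER_DAY
        cl_pl = _val(preg["placental_clearance"])
        ratio = _val(preg["fetal_maternal_ratio"])

        def fetal_volume(time_h: float) -> float:
            frac = min(max(time_h / t_term, 0.0), 1.0)
            return v0 + (v1 - v0) * frac

        pools.append(AuxPool("mehg", "fetus", v1))
        transports += [
            t("first_order_transfer", "mehg", "blood", "fetus", cl_pl,
              basis="clearance"),
            t("first_order_transfer", "mehg", "fetus", "blood", cl_pl / ratio,
              basis="clearance", volume_fn=fetal_volume),
        ]
    routes = [
        IntakeRoute("mehg", "oral", dest="blood", f_abs=_val(cfg["absorption"]["f_abs"])),
        IntakeRoute("ihg", "oral", dest="blood", f_abs=0.1),
    ]
    return ConfiguredSystem(
        body=body,
        chemicals=chems,
        network=network,
        transports=transports,
        aux_pools=pools,
        routes=routes,
        provenance=_collect_provenance(cfg, "methylmercury.yaml"),
        notes={"pregnancy": pregnancy, "lactation": lactation},
    )


# ---------------------------------------------------------------------------
# volatile organics


def build_voc_model(
    body: BodyPhysiology | None = None,
    params: Mapping | None = None,
    mutual_inhibition: bool = True,
) -> ConfiguredSystem:
    """Benzene and toluene on an inhalation PBTK skeleton.

    Continuous alveolar gas exchange against the central blood pool,
    flow-limited distribution, and saturable hepatic oxidation to untracked
    metabolites with mutual competitive inhibition: each chemical inflates the
    other's apparent Km by C/I with I equal to the inhibitor's own Km.
    """
    body = body or reference_adult()
    cfg = _load_config("voc.yaml", params)
    q_alv = _val(cfg["alveolar_ventilation"])
    chems = []
    mm: list[MMReaction] = []
    transports: list[TransportProcess] = []
    kms = {name: float(cfg[name]["km"]["value"]) for name in ("benzene", "toluene")}
    for name in ("benzene", "toluene"):
        sub = cfg[name]
        if "partition_coefficients" not in sub:
            raise KineticsError(f"voc config missing partitions for {name!r}")
        chems.append(
            ChemicalSpecies(
                name=name,
                molecular_mass=_val(sub["molecular_mass"]),
                tissue_params={
                    tissue: ChemicalTissueParams(partition_coefficient=float(p))
                    for tissue, p in sub["partition_coefficients"].items()
                },
            )
        )
        transports.append(
            TransportProcess(
                "gas_exchange",
                name,
                rate=q_alv,
                partition=_val(sub["blood_air_partition"]),
            )
        )
        other = "toluene" if name == "benzene" else "benzene"
        mm.append(
            MMReaction(
                tissue="liver",
                substrate=name,
                product=None,
                vmax=_val(sub["vmax"]),
                km=kms[name],
                competitive_inhibitors=(
                    {other: kms[other]} if mutual_inhibition else {}
                ),
            )
        )
    network = ReactionNetwork(
        species=("benzene", "toluene"), gamma={}, mm_reactions=mm
    )
    return ConfiguredSystem(
        body=body,
        chemicals=chems,
        network=network,
        transports=transports,
        provenance=_collect_provenance(cfg, "voc.yaml"),
        notes={"alveolar_ventilation": q_alv},
    )


MODEL_BUILDERS = {
    "cadmium": build_cadmium_model,
    "arsenic": build_arsenic_model,
    "lead": build_lead_model,
    "chromium": build_chromium_model,
    "methylmercury": build_mehg_model,
    "voc": build_voc_model,
}
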