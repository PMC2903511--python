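"""Structural and behavioural checks of the per-chemical model builders."""

import numpy as np
import pytest

from pbtkmix.chemical_models import (
    ARSENIC_SPECIES,
    bone_fraction,
    build_arsenic_model,
    build_cadmium_model,
    build_chromium_model,
    build_lead_model,
    build_mehg_model,
    build_voc_model,
    merge_models,
)
from pbtkmix.exposure import Event, ExposureProfile
from pbtkmix.kinetics import KineticsError, simulate

YEAR_H = 365.0 * 24.0


def oral(chem, ug_day, end=None):
    return ExposureProfile(
        chem, "oral_continuous", (Event(0.0, ug_day, "ug/day", end=end),)
    )


def ppm(chem, level):
    return ExposureProfile(chem, "inhalation", (Event(0.0, level, "ppm"),))


# ---------------------------------------------------------------------------
# cadmium


class TestCadmium:
    def test_linearity_doubling_intake(self, adult):
        model = build_cadmium_model(body=adult)

        def kidney(dose):
            res = simulate(
                model.assemble([oral("cadmium", dose)]),
                5 * YEAR_H,
                report_grid=YEAR_H / 4,
            )
            return res.concentration("cadmium", "kidney")[-1]

        assert kidney(30.0) == pytest.approx(2.0 * kidney(15.0), rel=1e-9)

    def test_zero_intake_zero_everywhere(self, adult):
        model = build_cadmium_model(body=adult)
        res = simulate(model.assemble([oral("cadmium", 0.0)]), 1000.0, report_grid=100.0)
        assert res.y[:, res.system.pool_slice].max() == 0.0

    def test_kidney_burden_still_rising_at_30_years(self, adult):
        """The long cadmium half-life: no kidney plateau within 30 years."""
        model = build_cadmium_model(body=adult)
        res = simulate(
            model.assemble([oral("cadmium", 15.0)]),
            30 * YEAR_H,
            report_grid=YEAR_H,
        )
        kidney = res.amounts("cadmium", "kidney")
        assert np.all(np.diff(kidney) > 0)

    def test_female_absorbs_more(self, adult):
        male = build_cadmium_model(body=adult, sex="male")
        female = build_cadmium_model(body=adult, sex="female")
        assert female.routes[0].f_abs > male.routes[0].f_abs

    def test_missing_coefficient_rejected(self, adult):
        with pytest.raises(KineticsError, match="missing"):
            build_cadmium_model(
                body=adult, params={"transfers": {"blood_to_liver": None}}
            )


# ---------------------------------------------------------------------------
# arsenic


@pytest.fixture(scope="module")
def model(adult):
    return build_arsenic_model(body=adult)


class TestArsenic:
    def test_network_pathway_audit(self, model):
        """Exactly the six listed steps plus per-species back-oxidation; no
        demethylation edges."""
        edges = {
            (parent, product)
            for _, parent, product in model.network.edges()
        }
        mm_edges = {
            (r.substrate, r.product) for r in model.network.mm_reactions
        }
        assert mm_edges == {
            ("asIII", "mmaV"),  # step 2
            ("asIII", "dmaV"),  # step 3
            ("mmaIII", "dmaV"),  # step 5
        }
        assert edges == {
            ("asV", "asIII"),  # step 1
            ("mmaV", "mmaIII"),  # step 4
            ("dmaV", "dmaIII"),  # step 6
            ("asIII", "asV"),
            ("mmaIII", "mmaV"),
            ("dmaIII", "dmaV"),
        }
        methyl_count = {"asV": 0, "asIII": 0, "mmaV": 1, "mmaIII": 1, "dmaV": 2, "dmaIII": 2}
        for parent, product in edges | mm_edges:
            assert methyl_count[product] >= methyl_count[parent]  # no demethylation

    def test_noncompetitive_inhibition_wiring(self, model):
        by_edge = {(r.substrate, r.product): r for r in model.network.mm_reactions}
        step2 = by_edge[("asIII", "mmaV")]
        step5 = by_edge[("mmaIII", "dmaV")]
        assert [c for c, _ in step2.noncompetitive] == ["mmaIII"]
        assert [c for c, _ in step5.noncompetitive] == ["asIII"]
        assert step2.tissue == step5.tissue == "liver"

    def test_urinary_excretion_balances_intake_at_steady_state(self, model):
        """Urinary output is the only elimination route, so at steady state
        total urinary arsenic excretion equals intake."""
        res = simulate(
            model.assemble([oral("asIII", 100.0)]), 1200.0, report_grid=12.0
        )
        led = res.ledger
        # excretion rate over the last reporting step vs intake rate
        t = res.t
        urine_total = np.zeros_like(t)
        for sp in ARSENIC_SPECIES:
            idx = res.system.ledger_idx(sp, "excreted::urine")
            urine_total += res.y[:, idx]
        # include the small unabsorbed fecal stream in the balance check
        rate = (urine_total[-1] - urine_total[-2]) / (t[-1] - t[-2])
        feces_total = np.zeros_like(t)
        for sp in ARSENIC_SPECIES:
            sidx = res.system.ledger_idx(sp, "excreted::feces")
            feces_total += res.y[:, sidx]
        frate = (feces_total[-1] - feces_total[-2]) / (t[-1] - t[-2])
        intake = 100.0 / 74.92 / 24.0  # μmol/h
        assert rate + frate == pytest.approx(intake, rel=1e-3)
        assert led.ok

    def test_step2_inhibition_reduces_methylated_fraction(self, adult):
        """Strengthening the noncompetitive inhibition of step 2 strictly
        decreases the methylated fraction of urinary arsenic (high-dose
        regime, where liver MMAIII is appreciable)."""
        fractions = []
        for k_nc in (0.5, 0.05, 0.005):
            model = build_arsenic_model(
                body=adult,
                params={
                    "metabolism": {
                        "methylation_asIII_to_mmaV": {
                            "vmax": 4.5, "km": 10.0, "k_nc": k_nc
                        }
                    }
                },
            )
            res = simulate(
                model.assemble([oral("asIII", 20000.0)]), 1200.0, report_grid=24.0
            )
            urine = {
                sp: res.ledger.excreted[sp].get("urine", 0.0)
                for sp in ARSENIC_SPECIES
            }
            tot = sum(urine.values())
            methylated = tot - urine["asV"] - urine["asIII"]
            fractions.append(methylated / tot)
        assert fractions[0] > fractions[1] > fractions[2]


# ---------------------------------------------------------------------------
# lead


class TestLead:
    def test_shell_count_and_volume(self, adult):
        model = build_lead_model(body=adult)
        shells = [p for p in model.aux_pools if p.name.startswith("cortical_")]
        assert len(shells) == 8
        assert sum(p.volume for p in shells) == pytest.approx(2.8)

    def test_shell_subsystem_conserves_without_blood_exchange(self, adult):
        """With blood↔bone exchange disabled the shell chain only
        redistributes mass internally."""
        model = build_lead_model(
            body=adult,
            params={
                "bone": {
                    "clearance_to_cortical": {"value": 0.0},
                    "clearance_to_trabecular": {"value": 0.0},
                    "trabecular_return": {"value": 0.0},
                }
            },
        )
        system = model.assemble()
        init = {("lead", "cortical_4", ""): 50.0}
        res = simulate(system, 5000.0, report_grid=100.0)
        res = simulate(system, 5000.0, report_grid=100.0, initial=init)
        shells = np.sum(
            [res.amounts("lead", f"cortical_{i}") for i in range(1, 9)], axis=0
        )
        assert np.allclose(shells, 50.0, rtol=1e-8)

    def test_uniform_shell_concentration_has_no_net_flux(self, adult):
        """Equal concentrations across shells are a null state of the
        discrete radial diffusion operator."""
        model = build_lead_model(body=adult)
        system = model.assemble()
        x = np.zeros(system.n_states)
        conc = 2.0
        for i in range(1, 9):
            idx = system.state_idx("lead", f"cortical_{i}")
            x[idx] = conc * system.volumes[idx]
        dx = system.rhs(0.0, x, np.zeros(system.n_states))
        # interior shells see zero net flux; shell 1 only loses to blood
        for i in range(2, 9):
            idx = system.state_idx("lead", f"cortical_{i}")
            assert abs(dx[idx]) < 1e-12
        idx1 = system.state_idx("lead", "cortical_1")
        assert dx[idx1] < 0.0  # partition-limited return to blood

    def test_shell_count_validated(self, adult):
        with pytest.raises(KineticsError, match="shell"):
            build_lead_model(body=adult, params={"bone": {"n_shells": {"value": 0}}})

    def test_tracer_species_shares_parameters(self, adult):
        model = build_lead_model(body=adult, tracer=True)
        names = model.species_names()
        assert names == ["lead", "lead204"]
        a, b = model.chemicals
        assert a.tissue_params == b.tissue_params


# ---------------------------------------------------------------------------
# chromium


@pytest.fixture(scope="module")
def bolus_run(adult):
    model = build_chromium_model(body=adult)
    prof = ExposureProfile("crVI", "oral_bolus", (Event(0.5, 5.0, "mg"),))
    return simulate(model.assemble([prof]), 96.0, report_grid=0.25)


class TestChromium:
    def test_crVI_vanishes_quickly(self, bolus_run):
        """Blood Cr(VI) falls below 1% of its peak on a timescale far shorter
        than Cr(III) elimination."""
        c6 = bolus_run.concentration("crVI", "blood")
        peak_i = c6.argmax()
        below = bolus_run.t[peak_i:][c6[peak_i:] < 0.01 * c6[peak_i]]
        assert below[0] - bolus_run.t[peak_i] < 24.0
        # Cr(III) is still present at the end of the window
        assert bolus_run.concentration("crIII", "blood")[-1] > 0

    def test_total_chromium_ledger_closes(self, bolus_run):
        assert bolus_run.ledger.ok

    def test_urinary_crIII_monotone(self, bolus_run):
        idx = bolus_run.system.ledger_idx("crIII", "excreted::urine")
        urine = bolus_run.y[:, idx]
        assert np.all(np.diff(urine) >= 0)


# ---------------------------------------------------------------------------
# methylmercury


class TestMethylmercury:
    def test_hair_ledger_tracks_blood_integral(self, adult):
        """Hair excretion is first order in blood concentration, so the hair
        ledger equals the clearance times the integrated blood curve."""
        model = build_mehg_model(body=adult)
        res = simulate(
            model.assemble([oral("mehg", 70.0)]), 2400.0, report_grid=24.0
        )
        cb = res.concentration("mehg", "blood")
        integral = np.trapezoid(cb, res.t)
        cl_hair = 0.003
        assert res.ledger.excreted["mehg"]["hair"] == pytest.approx(
            cl_hair * integral, rel=1e-3
        )

    def test_conserves_with_demethylation_off(self, adult):
        model = build_mehg_model(
            body=adult, params={"demethylation": {"rate": {"value": 0.0}}}
        )
        res = simulate(
            model.assemble([oral("mehg", 70.0, end=240.0)]), 2400.0, report_grid=48.0
        )
        led = res.ledger
        total = led.in_body["mehg"] + sum(led.excreted["mehg"].values())
        assert total == pytest.approx(led.administered["mehg"], rel=1e-9)
        assert led.in_body["ihg"] == 0.0

    def test_fetal_blood_can_exceed_maternal(self, adult):
        """With the fetal:maternal partition above one, fetal blood
        methylmercury exceeds the maternal level at matched times."""
        model = build_mehg_model(body=adult, pregnancy=True)
        res = simulate(
            model.assemble([oral("mehg", 42.0 * 70.0)]),
            108 * 24.0,
            report_grid=24.0,
        )
        v0, v1, term = 0.05, 3.0, 280.0 * 24.0
        v_fet = v0 + (v1 - v0) * np.minimum(res.t / term, 1.0)
        c_fet = res.amounts("mehg", "fetus") / v_fet
        c_mat = res.concentration("mehg", "blood")
        assert c_fet[-1] > c_mat[-1]

    def test_pregnancy_needs_parameters(self, adult):
        with pytest.raises(KineticsError, match="fetal"):
            build_mehg_model(body=adult, pregnancy=True, params={"pregnancy": None})

    def test_milk_route_only_when_lactating(self, adult):
        base = build_mehg_model(body=adult)
        lact = build_mehg_model(body=adult, lactation=True)
        assert not any(t.kind == "milk_excretion" for t in base.transports)
        assert any(t.kind == "milk_excretion" for t in lact.transports)


# ---------------------------------------------------------------------------
# volatile organics


class TestVoc:
    def test_coexposure_raises_benzene_liver_level(self, adult):
        """Competitive inhibition by toluene slows benzene metabolism, so
        co-exposure raises the benzene steady-state liver concentration."""
        model = build_voc_model(body=adult)
        alone = simulate(
            model.assemble([ppm("benzene", 10.0)]), 120.0, report_grid=4.0
        )
        both = simulate(
            model.assemble([ppm("benzene", 10.0), ppm("toluene", 20.0)]),
            120.0,
            report_grid=4.0,
        )
        c_alone = alone.concentration("benzene", "liver")[-1]
        c_both = both.concentration("benzene", "liver")[-1]
        assert c_both > 1.05 * c_alone

    def test_infinite_inhibition_constant_recovers_single_chemical(self, adult):
        big = 1e12
        model_off = build_voc_model(body=adult, mutual_inhibition=False)
        model_weak = build_voc_model(body=adult)
        for rxn in model_weak.network.mm_reactions:
            for chem in rxn.competitive_inhibitors:
                rxn.competitive_inhibitors[chem] = big
        exp = [ppm("benzene", 10.0), ppm("toluene", 20.0)]
        a = simulate(model_off.assemble(exp), 96.0, report_grid=4.0)
        b = simulate(model_weak.assemble(exp), 96.0, report_grid=4.0)
        assert np.allclose(
            a.concentration("benzene", "liver"),
            b.concentration("benzene", "liver"),
            rtol=1e-6,
        )

    def test_subsaturation_linearity_in_ppm(self, adult):
        model = build_voc_model(body=adult)

        def venous(level):
            res = simulate(
                model.assemble([ppm("benzene", level)]), 150.0, report_grid=10.0
            )
            return res.concentration("benzene", "blood")[-1]

        low, double = venous(0.5), venous(1.0)
        assert double == pytest.approx(2.0 * low, rel=0.02)


# ---------------------------------------------------------------------------
# cross-model invariants


class TestHarmonisation:
    def test_all_builders_share_one_body_and_pass_audit(self, adult):
        """Every builder output assembles, simulates a smoke-test exposure
        and closes its mass ledger on the shared physiology."""
        runs = [
            (build_cadmium_model(body=adult), oral("cadmium", 15.0)),
            (build_arsenic_model(body=adult), oral("asIII", 100.0)),
            (build_lead_model(body=adult), oral("lead", 70.0)),
            (build_chromium_model(body=adult), oral("crVI", 100.0)),
            (build_mehg_model(body=adult), oral("mehg", 40.0)),
            (build_voc_model(body=adult), ppm("benzene", 10.0)),
        ]
        for model, exposure in runs:
            assert model.body is adult
            res = simulate(model.assemble([exposure]), 240.0, report_grid=24.0)
            assert res.ledger.ok

    def test_merged_models_preserve_independent_kinetics(self, adult):
        """Without registered interactions, simulating two chemicals jointly
        equals simulating them separately."""
        cd = build_cadmium_model(body=adult)
        hg = build_mehg_model(body=adult)
        merged = merge_models(cd, hg)
        exp = [oral("cadmium", 15.0), oral("mehg", 40.0)]
        opts = {"rtol": 1e-11, "atol": 1e-14}
        joint = simulate(
            merged.assemble(exp), 720.0, report_grid=24.0, solver_options=opts
        )
        alone_cd = simulate(
            cd.assemble([exp[0]]), 720.0, report_grid=24.0, solver_options=opts
        )
        alone_hg = simulate(
            hg.assemble([exp[1]]), 720.0, report_grid=24.0, solver_options=opts
        )
        assert np.allclose(
            joint.amounts("cadmium", "kidney"),
            alone_cd.amounts("cadmium", "kidney"),
            rtol=1e-9,
        )
        assert np.allclose(
            joint.amounts("mehg", "brain", "C"),
            alone_hg.amounts("mehg", "brain", "C"),
            rtol=1e-9,
        )

    def test_provenance_recorded_for_parameters(self, adult):
        model = build_lead_model(body=adult)
        assert model.provenance  # every value names its packaged source file
        assert all("lead.yaml" in src for src in model.provenance.values())
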