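import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from pbtkmix.exposure import Event, ExposureProfile
from pbtkmix.kinetics import (
    AuxPool,
    ChemicalSpecies,
    ChemicalTissueParams,
    IntakeRoute,
    KineticsError,
    MMReaction,
    ReactionNetwork,
    TransportProcess,
    assemble_system,
    build_gamma_matrix,
    diffusion_tissue_rates,
    effective_vmax,
    first_order_metabolic_rates,
    mass_audit,
    mm_metabolic_rate,
    perfusion_tissue_rate,
    permeation_rate,
    simulate,
)
from pbtkmix.physiology import BodyPhysiology, Compartment


# ---------------------------------------------------------------------------
# elementary rate laws


class TestTissueRates:
    def test_perfusion_equilibrium_is_zero(self):
        assert perfusion_tissue_rate(c_tissue=4.0, c_in=2.0, q=10, v=5, p=2) == 0.0

    def test_perfusion_arithmetic(self):
        assert perfusion_tissue_rate(0.0, 1.0, q=10, v=5, p=2) == pytest.approx(2.0)

    def test_perfusion_steady_state_infusion(self, two_comp_body):
        """Constant infusion R0 against urinary clearance CL gives the
        closed-form steady state C_blood = R0/CL."""
        r0, cl = 12.0, 4.0  # μmol/h, L/h
        chem = ChemicalSpecies(
            "x", 100.0, {"rest": ChemicalTissueParams(partition_coefficient=2.0)}
        )
        system = assemble_system(
            body=two_comp_body,
            chemicals=[chem],
            transports=[
                TransportProcess(
                    "urinary_excretion", "x", "blood", rate=cl, basis="clearance"
                )
            ],
            routes=[IntakeRoute("x", "infusion", dest="blood")],
            exposures=[
                ExposureProfile(
                    "x", "infusion", (Event(0.0, r0, "umol/h"),)
                )
            ],
        )
        res = simulate(system, 2000.0, report_grid=50.0)
        assert res.concentration("x", "blood")[-1] == pytest.approx(r0 / cl, rel=1e-6)

    def test_permeation_equilibrium_sign_and_value(self):
        assert permeation_rate(c_e=1.0, c_c=2.0, h=5.0, p=2.0) == 0.0
        assert permeation_rate(1.0, 0.0, h=2.0, p=1.0) == pytest.approx(2.0)
        assert permeation_rate(1.0, 4.0, h=2.0, p=2.0) < 0  # flux reverses

    def test_diffusion_internal_flux_cancels(self):
        """Whole-tissue mass rate is Q(C_in − C_E): permeation is internal."""
        dce, dcc = diffusion_tissue_rates(
            c_e=0.3, c_c=1.4, c_in=1.0, q=10.0, v_e=0.4, v_c=1.6, h=3.0, p=2.0
        )
        total = dce * 0.4 + dcc * 1.6
        assert total == pytest.approx(10.0 * (1.0 - 0.3))

    def test_diffusion_h_zero_leaves_cellular_constant(self):
        _, dcc = diffusion_tissue_rates(0.5, 2.0, 1.0, 10.0, 0.4, 1.6, h=0.0, p=2.0)
        assert dcc == 0.0


class TestDiffusionPerfusionLimit:
    def _run(self, h):
        body = BodyPhysiology(
            compartments=(
                Compartment(name="blood", volume=5.0, tags=frozenset({"blood"})),
                Compartment(
                    name="t",
                    volume=10.0,
                    blood_flow=20.0,
                    scheme="diffusion_limited",
                    subvolumes=(2.0, 8.0),
                ),
            ),
            cardiac_output=20.0,
            body_mass=70.0,
        )
        p = 3.0
        if h is None:  # perfusion-limited reference with the effective P
            p_eff = (2.0 + p * 8.0) / 10.0
            body = BodyPhysiology(
                compartments=(
                    Compartment(name="blood", volume=5.0, tags=frozenset({"blood"})),
                    Compartment(name="t", volume=10.0, blood_flow=20.0),
                ),
                cardiac_output=20.0,
                body_mass=70.0,
            )
            params = ChemicalTissueParams(partition_coefficient=p_eff)
        else:
            params = ChemicalTissueParams(partition_coefficient=p, permeability=h)
        chem = ChemicalSpecies("x", 100.0, {"t": params})
        system = assemble_system(body=body, chemicals=[chem])
        res = simulate(
            system,
            20.0,
            report_grid=np.linspace(0, 20, 81),
            initial={("x", "blood", ""): 100.0},
        )
        return res.concentration("x", "blood")

    def test_convergence_monotone_in_h(self):
        """As H grows the diffusion-limited solution approaches the
        perfusion-limited one; < 1% of peak at H = 100·Q."""
        ref = self._run(None)
        q = 20.0
        errs = []
        for h in (q, 3 * q, 10 * q, 30 * q, 100 * q):
            got = self._run(h)
            errs.append(np.abs(got - ref).max())
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 0.01 * ref.max()


class TestGammaMatrix:
    def test_single_pathway_matrix(self):
        gamma = build_gamma_matrix([("A", "B", 0.5)], ["A", "B"])
        assert np.allclose(gamma, [[0.5, 0.0], [-0.5, 0.0]])

    def test_all_tracked_columns_sum_to_zero(self):
        gamma = build_gamma_matrix(
            [("A", "B", 1.0), ("B", "C", 2.0), ("A", "C", 0.3)], ["A", "B", "C"]
        )
        assert np.allclose(gamma.sum(axis=0), 0.0)

    def test_untracked_product_leaves_positive_column_sum(self):
        gamma = build_gamma_matrix([("A", None, 0.7)], ["A", "B"])
        assert gamma[0, 0] == 0.7
        assert np.allclose(gamma.sum(axis=0), [0.7, 0.0])

    def test_unknown_species_rejected(self):
        with pytest.raises(KineticsError, match="unknown species"):
            build_gamma_matrix([("A", "Z", 1.0)], ["A", "B"])

    def test_bateman_chain_matches_matrix_exponential(self):
        """A→B→C with k1=1, k2=2: Γ-driven kinetics equal the closed form."""
        species = ["A", "B", "C"]
        gamma = build_gamma_matrix([("A", "B", 1.0), ("B", "C", 2.0)], species)
        t = np.linspace(0.0, 5.0, 21)
        body = BodyPhysiology(
            compartments=(
                Compartment(name="blood", volume=1.0, tags=frozenset({"blood"})),
                Compartment(name="liver", volume=1.0, blood_flow=1.0),
            ),
            cardiac_output=1.0,
            body_mass=70.0,
        )
        chems = [
            ChemicalSpecies(
                s, 100.0, {"liver": ChemicalTissueParams(partition_coefficient=1.0)}
            )
            for s in species
        ]
        network = ReactionNetwork.from_pathways(
            species, {"liver": [("A", "B", 1.0), ("B", "C", 2.0)]}
        )
        system = assemble_system(body=body, chemicals=chems, network=network)
        init = {("A", "liver", ""): 10.0}
        res = simulate(system, 5.0, report_grid=t, initial=init)
        totals = np.stack([res.body_burden(s) for s in species], axis=1)
        # oracle: explicit matrix exponential on the joint (liver, blood)
        # system — blood flow moves species but conserves them
        n = 3
        m = np.zeros((2 * n, 2 * n))  # liver amounts then blood amounts
        q, v_l, v_b = 1.0, 1.0, 1.0
        for i in range(n):
            m[i, n + i] += q / v_b
            m[i, i] -= q / v_l
            m[n + i, i] += q / v_l
            m[n + i, n + i] -= q / v_b
        m[:n, :n] += -gamma
        x0 = np.zeros(2 * n)
        x0[0] = 10.0
        oracle2 = np.array([expm(m * ti) @ x0 for ti in t])
        liver_oracle = oracle2[:, :n] + oracle2[:, n:]
        assert np.allclose(totals, liver_oracle, rtol=1e-6, atol=1e-8)

    def test_first_order_rates_vector(self):
        gamma = build_gamma_matrix([("A", "B", 0.5)], ["A", "B"])
        rates = first_order_metabolic_rates(gamma, np.array([2.0, 0.0]))
        assert np.allclose(rates, [1.0, -1.0])
        assert np.allclose(first_order_metabolic_rates(gamma, np.zeros(2)), 0.0)
        with pytest.raises(KineticsError, match="mismatch"):
            first_order_metabolic_rates(gamma, np.zeros(3))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "B", "C", "D"]),
                st.sampled_from(["A", "B", "C", "D"]),
                st.floats(0.01, 5.0),
            ).filter(lambda p: p[0] != p[1]),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_tracked_network_conserves_for_any_y(self, pathways):
        species = ["A", "B", "C", "D"]
        gamma = build_gamma_matrix(pathways, species)
        y = np.array([1.3, 0.2, 4.0, 0.7])
        assert first_order_metabolic_rates(gamma, y).sum() == pytest.approx(
            0.0, abs=1e-9
        )


class TestMichaelisMenten:
    def _rxn(self, **kw):
        defaults = dict(
            tissue="liver", substrate="S", product=None, vmax=10.0, km=2.0
        )
        defaults.update(kw)
        return MMReaction(**defaults)

    def test_half_saturation(self):
        rxn = self._rxn()
        assert mm_metabolic_rate("S", {"S": 2.0}, rxn) == pytest.approx(5.0)

    def test_competitive_inhibitor_at_its_constant(self):
        rxn = self._rxn(competitive_inhibitors={"I": 1.5})
        # C_i = Km and C_k = I gives Vmax/3
        assert mm_metabolic_rate("S", {"S": 2.0, "I": 1.5}, rxn) == pytest.approx(
            10.0 / 3.0
        )

    def test_zero_inhibitor_reduces_to_plain_mm(self):
        rxn = self._rxn(competitive_inhibitors={"I": 1.5})
        plain = self._rxn()
        for c in (0.1, 1.0, 10.0):
            assert mm_metabolic_rate("S", {"S": c, "I": 0.0}, rxn) == pytest.approx(
                mm_metabolic_rate("S", {"S": c}, plain)
            )

    def test_low_concentration_first_order_limit(self):
        """At C ≪ Km the saturable rate equals a first-order rate with
        k = Vmax/(Km·V) to within 1%."""
        rxn = self._rxn(vmax=10.0, km=2.0)
        v_liver = 1.8
        c = 0.01  # ≪ Km
        amount_rate = mm_metabolic_rate("S", {"S": c}, rxn)
        k = rxn.vmax / (rxn.km * v_liver)
        first_order = k * c * v_liver
        assert amount_rate == pytest.approx(first_order, rel=0.01)

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rate_bounded_by_vmax_and_monotone_in_inhibitor(self, c_s, c_i):
        rxn = self._rxn(competitive_inhibitors={"I": 1.0})
        rate = mm_metabolic_rate("S", {"S": c_s, "I": c_i}, rxn)
        assert 0.0 <= rate <= rxn.vmax
        more = mm_metabolic_rate("S", {"S": c_s, "I": c_i + 1.0}, rxn)
        assert more <= rate + 1e-12


class TestEffectiveVmax:
    def test_no_modifiers_identity(self):
        assert effective_vmax(7.0) == 7.0

    def test_noncompetitive_halves_at_knc(self):
        assert effective_vmax(8.0, [("noncompetitive", 3.0, 3.0)]) == pytest.approx(4.0)

    def test_induction(self):
        assert effective_vmax(5.0, [("induction", 0.4)]) == pytest.approx(7.0)

    def test_effect_clamped_at_zero(self):
        assert effective_vmax(5.0, [("effect", 1.0)]) == 0.0
        assert effective_vmax(5.0, [("effect", 2.5)]) == 0.0

    def test_order_independent(self):
        mods = [("noncompetitive", 1.0, 2.0), ("induction", 0.5), ("effect", 0.3)]
        a = effective_vmax(10.0, mods)
        b = effective_vmax(10.0, list(reversed(mods)))
        assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# assembly and simulation


def _single_tissue_system(two_comp_body, p=2.0):
    chem = ChemicalSpecies(
        "x", 100.0, {"rest": ChemicalTissueParams(partition_coefficient=p)}
    )
    return assemble_system(body=two_comp_body, chemicals=[chem])


class TestAssembly:
    def test_reduces_to_perfusion_rate(self, two_comp_body):
        """With one perfused tissue and no R/T the assembled derivative is
        exactly the perfusion-limited rate law."""
        system = _single_tissue_system(two_comp_body)
        x = np.zeros(system.n_states)
        ib = system.state_idx("x", "blood")
        it = system.state_idx("x", "rest")
        x[ib], x[it] = 11.0, 3.0
        dx = system.rhs(0.0, x, np.zeros(system.n_states))
        c_b, c_t = 11.0 / 5.0, 3.0 / 65.0
        expected = perfusion_tissue_rate(c_t, c_b, q=312.0, v=65.0, p=2.0) * 65.0
        assert dx[it] == pytest.approx(expected)
        assert dx[ib] == pytest.approx(-expected)

    def test_linear_system_is_matrix_times_state(self):
        """A purely first-order multi-chemical system's derivative equals an
        explicitly constructed constant matrix applied to the state."""
        from pbtkmix.fixtures import generate_linear_fixture

        fix = generate_linear_fixture(5, 2, seed=7)
        system = fix.to_system()
        assert system.is_linear
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 3.0, system.n_states)
        u = np.zeros(system.n_states)
        assert np.allclose(system.rhs(0.0, x, u), system.matrix @ x)
        idx = fix.pool_indices(system)
        sub = system.matrix[np.ix_(idx, idx)]
        assert np.allclose(sub, fix.matrix)

    def test_untracked_pathway_is_dissipative(self, two_comp_body):
        chem = ChemicalSpecies(
            "x", 100.0, {"rest": ChemicalTissueParams(partition_coefficient=1.0)}
        )
        network = ReactionNetwork.from_pathways(
            ["x"], {"rest": [("x", None, 0.5)]}
        )
        system = assemble_system(
            body=two_comp_body, chemicals=[chem], network=network
        )
        res = simulate(
            system, 10.0, report_grid=0.25, initial={("x", "blood", ""): 5.0}
        )
        burden = res.body_burden("x")
        assert np.all(np.diff(burden) < 0)

    def test_unresolved_reference_rejected(self, two_comp_body):
        chem = ChemicalSpecies("x", 100.0)
        with pytest.raises(KineticsError):
            assemble_system(
                body=two_comp_body,
                chemicals=[chem],
                network=ReactionNetwork.from_pathways(
                    ["x", "ghost"], {"rest": [("x", "ghost", 1.0)]}
                ),
            )

    def test_state_layout_is_bijective(self, two_comp_body):
        system = _single_tissue_system(two_comp_body)
        keys = [(s.chemical, s.compartment, s.sub) for s in system.states]
        assert len(keys) == len(set(keys))


class TestSimulate:
    def test_exponential_decay(self, two_comp_body):
        k = 0.3
        chem = ChemicalSpecies("x", 100.0)
        system = assemble_system(
            body=two_comp_body,
            chemicals=[chem],
            transports=[TransportProcess("urinary_excretion", "x", "blood", rate=k)],
        )
        t = np.linspace(0.0, 20.0, 41)
        res = simulate(system, 20.0, report_grid=t, initial={("x", "blood", ""): 7.0})
        expected = 7.0 * np.exp(-k * res.t)
        assert np.allclose(res.amounts("x", "blood"), expected, rtol=1e-6)

    def test_random_linear_fixture_matches_expm(self):
        from pbtkmix.fixtures import generate_linear_fixture

        fix = generate_linear_fixture(6, 2, seed=3)
        system = fix.to_system()
        res = simulate(system, 15.0, report_grid=np.linspace(0, 15, 31))
        oracle = fix.solution(res.t)
        got = res.y[:, fix.pool_indices(system)]
        assert np.abs(got - oracle).max() / np.abs(oracle).max() < 1e-6

    def test_solver_failure_carries_time(self):
        # t_end <= t0 is rejected before integration
        from pbtkmix.fixtures import generate_linear_fixture

        system = generate_linear_fixture(3, 1, seed=0).to_system()
        with pytest.raises(KineticsError):
            simulate(system, 0.0)


class TestMassAudit:
    def test_no_exposure_zero_ledger(self, two_comp_body):
        system = _single_tissue_system(two_comp_body)
        res = simulate(system, 5.0, report_grid=1.0)
        audit = mass_audit(res)
        assert (audit["administered_umol"] == 0.0).all()
        assert audit["ok"].all()

    def test_bolus_fully_excreted_in_the_limit(self, two_comp_body):
        chem = ChemicalSpecies("x", 100.0)
        system = assemble_system(
            body=two_comp_body,
            chemicals=[chem],
            transports=[
                TransportProcess("urinary_excretion", "x", "blood", rate=1.0)
            ],
            routes=[IntakeRoute("x", "oral", dest="blood")],
            exposures=[
                ExposureProfile("x", "oral_bolus", (Event(0.0, 100.0, "umol"),))
            ],
        )
        res = simulate(system, 50.0, report_grid=1.0)
        led = res.ledger
        assert led.administered["x"] == pytest.approx(100.0)
        assert led.excreted["x"]["urine"] == pytest.approx(100.0, rel=1e-6)

    def test_parent_metabolite_molar_pairing(self, two_comp_body):
        chems = [
            ChemicalSpecies(
                s, 100.0, {"rest": ChemicalTissueParams(partition_coefficient=1.0)}
            )
            for s in ("P", "M")
        ]
        network = ReactionNetwork.from_pathways(["P", "M"], {"rest": [("P", "M", 0.4)]})
        system = assemble_system(
            body=two_comp_body, chemicals=chems, network=network
        )
        res = simulate(
            system, 30.0, report_grid=1.0, initial={("P", "blood", ""): 20.0}
        )
        led = res.ledger
        assert led.transformed_away["P"]["M"] == pytest.approx(
            led.transformed_in["M"]["P"], rel=1e-12
        )
        assert led.ok
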