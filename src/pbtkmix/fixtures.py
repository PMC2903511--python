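"""Synthetic linear compartment systems with closed-form solutions.

These fixtures are the engine's independent oracle: a random stable
compartmental (Metzler, column-diagonally-dominant) rate matrix with constant
inputs has the exact solution

    x(t) = e^{At} x0 + A^{-1} (e^{At} − I) b

via the matrix exponential.  ``to_system`` expresses the same system through
the public model surface (auxiliary pools, first-order transports, labelled
infusions), so integrating it with :func:`pbtkmix.kinetics.simulate` and
comparing against :meth:`LinearFixture.solution` exercises the full assembly
and integration path against an answer computed by entirely different means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exposure import Event, ExposureProfile
from .kinetics import (
    AuxPool,
    ChemicalSpecies,
    IntakeRoute,
    ODESystem,
    TransportProcess,
    assemble_system,
)
from .physiology import BodyPhysiology, Compartment

__all__ = ["LinearFixture", "generate_linear_fixture"]


def _fixture_body() -> BodyPhysiology:
    return BodyPhysiology(
        compartments=(
            Compartment(name="blood", volume=1.0, tags=frozenset({"blood"})),
            Compartment(name="tissue", volume=1.0, blood_flow=1.0),
        ),
        cardiac_output=1.0,
        body_mass=70.0,
    )


@dataclass(frozen=True)
class LinearFixture:
    """A random stable first-order system dx/dt = A x + b."""

    matrix: np.ndarray  # (n, n), Metzler, Hurwitz
    input_vector: np.ndarray  # (n,), constant inflow μmol/h
    seed: int

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def solution(self, t, x0=None) -> np.ndarray:
        """Closed-form trajectory on time points ``t`` (shape (len(t), n))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n = self.n_states
        x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
        a = self.matrix
        b = self.input_vector
        # particular solution: x_p = -A^{-1} b;  x(t) = e^{At}(x0 - x_p) + x_p
        x_p = np.linalg.solve(a, -b)
        out = np.empty((len(t), n))
        for i, ti in enumerate(t):
            out[i] = expm(a * ti) @ (x0 - x_p) + x_p
        return out

    def is_stable(self) -> bool:
        return bool(np.all(np.real(np.linalg.eigvals(self.matrix)) < 0))

    def to_system(self) -> ODESystem:
        """The same system expressed through the model surface."""
        n = self.n_states
        chem = ChemicalSpecies(name="X", molecular_mass=100.0)
        pools = [AuxPool("X", f"p{i}", 1.0) for i in range(n)]
        transports = []
        for j in range(n):
            col_off = 0.0
            for i in range(n):
                if i != j and self.matrix[i, j] > 0:
                    transports.append(
                        TransportProcess(
                            "first_order_transfer",
                            "X",
                            f"p{j}",
                            f"p{i}",
                            float(self.matrix[i, j]),
                        )
                    )
                    col_off += self.matrix[i, j]
            leak = -self.matrix[j, j] - col_off
            if leak > 1e-15:
                transports.append(
                    TransportProcess(
                        "urinary_excretion", "X", f"p{j}", rate=float(leak)
                    )
                )
        routes = []
        exposures = []
        for i in np.nonzero(self.input_vector)[0]:
            label = f"in{i}"
            routes.append(
                IntakeRoute("X", "infusion", dest=f"p{i}", label=label)
            )
            exposures.append(
                ExposureProfile(
                    chemical="X",
                    route="infusion",
                    events=(
                        Event(
                            start=0.0,
                            magnitude=float(self.input_vector[i]),
                            units="umol/h",
                        ),
                    ),
                    route_label=label,
                )
            )
        return assemble_system(
            body=_fixture_body(),
            chemicals=[chem],
            transports=transports,
            aux_pools=pools,
            routes=routes,
            exposures=exposures,
        )

    def pool_indices(self, system: ODESystem) -> list[int]:
        return [system.state_idx("X", f"p{i}") for i in range(self.n_states)]


def generate_linear_fixture(
    n_states: int, n_inputs: int = 1, seed: int = 0
) -> LinearFixture:
    """Draw a random stable compartmental system, deterministic per seed.

    Off-diagonal transfer constants are sparse uniform draws; every column
    gets a strictly positive leak so the matrix is Hurwitz (no conserved or
    growing modes).  The first ``n_inputs`` states receive constant inputs.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    n_inputs = min(max(n_inputs, 0), n_states)
    rng = np.random.default_rng(seed)
    a = np.zeros((n_states, n_states))
    for j in range(n_states):
        for i in range(n_states):
            if i != j and rng.random() < 0.4:
                a[i, j] = rng.uniform(0.05, 1.0)
    leaks = rng.uniform(0.05, 0.5, size=n_states)
    for j in range(n_states):
        a[j, j] = -(a[:, j].sum() - a[j, j] + leaks[j])
    b = np.zeros(n_states)
    b[:n_inputs] = rng.uniform(0.5, 2.0, size=n_inputs)
    return LinearFixture(matrix=a, input_vector=b, seed=seed)
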