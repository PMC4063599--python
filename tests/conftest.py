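"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fluxcap.model_core import MetabolicModel, Reaction, Species, parse_gpr
from fluxcap.synthetic_data import SyntheticSpec, generate_all


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lp_max_by_vertex_enumeration(S, lower, upper, c, tol=1e-7):
    """Brute-force LP maximum over {v : S v = 0, lower <= v <= upper}.

    Enumerates candidate vertices by fixing every subset of variables at a
    bound and solving the remaining square/overdetermined linear system.
    Exponential in the number of reactions; intended for networks with <= 8
    reactions only.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    best = None
    for assign in itertools.product((0, 1, 2), repeat=n):
        free = [j for j in range(n) if assign[j] == 0]
        v = np.array(
            [
                0.0 if a == 0 else (lower[j] if a == 1 else upper[j])
                for j, a in enumerate(assign)
            ]
        )
        if not np.all(np.isfinite(v[[j for j in range(n) if assign[j] != 0]])):
            continue
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A) < len(free):
                continue  # not a unique vertex under this assignment
            rhs = -S @ v
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = sol
        if np.max(np.abs(S @ v)) > tol:
            continue
        if np.any(v < np.asarray(lower) - tol) or np.any(v > np.asarray(upper) + tol):
            continue
        val = float(np.dot(c, v))
        if best is None or val > best:
            best = val
    return best


def exact_ranksum_less_p(a, b):
    """Exact one-sided rank-sum p-value, P(rank sum of a <= observed).

    Full enumeration of all C(n_a+n_b, n_a) rank assignments; tie-free data
    only.  Independent of scipy.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(rank[v] for v in a)
    n, na = len(pooled), len(a)
    hits = total = 0
    for comb in itertools.combinations(range(1, n + 1), na):
        total += 1
        if sum(comb) <= obs:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def vertex_oracle():
    return lp_max_by_vertex_enumeration


@pytest.fixture(scope="session")
def ranksum_oracle():
    return exact_ranksum_less_p


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

def _species(*ids, comp="c"):
    return [Species(f"{i}_{comp}", i, comp) for i in ids]


@pytest.fixture()
def chain_model():
    """E_in(10) -> A -(R1, ub 7)-> B -(R2, ub 5)-> C -> demand."""
    species = _species("A", "B", "C")
    reactions = [
        Reaction("E_in", {"A_c": 1.0}, 0, 10, is_exchange=True),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0, 7, gpr=parse_gpr("g1")),
        Reaction("R2", {"B_c": -1.0, "C_c": 1.0}, 0, 5, gpr=parse_gpr("g2")),
        Reaction("DM_C", {"C_c": -1.0}, 0, 1000, is_exchange=True),
    ]
    return MetabolicModel(species, reactions, id="chain_toy")


@pytest.fixture()
def parallel_model():
    """Two routes (ub 3 and 4) from A to B feeding one demand: max 7."""
    species = _species("A", "B")
    reactions = [
        Reaction("E_in", {"A_c": 1.0}, 0, 100, is_exchange=True),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0, 3),
        Reaction("R2", {"A_c": -1.0, "B_c": 1.0}, 0, 4),
        Reaction("DM_B", {"B_c": -1.0}, 0, 1000, is_exchange=True),
    ]
    return MetabolicModel(species, reactions, id="parallel_toy")


@pytest.fixture()
def four_step_pathway_model():
    """R1: A+B->C; R2: C+D->E; R3: E->F+G; R4: F+H->I+J (role-assignment toy)."""
    species = _species("A", "B", "C", "D", "E", "F", "G", "H", "I", "J")
    def rxn(rid, stoich):
        return Reaction(rid, stoich, 0, 1000)
    reactions = [
        rxn("R1", {"A_c": -1, "B_c": -1, "C_c": 1}),
        rxn("R2", {"C_c": -1, "D_c": -1, "E_c": 1}),
        rxn("R3", {"E_c": -1, "F_c": 1, "G_c": 1}),
        rxn("R4", {"F_c": -1, "H_c": -1, "I_c": 1, "J_c": 1}),
    ]
    return MetabolicModel(species, reactions, id="fourstep_toy")


# ---------------------------------------------------------------------------
# small synthetic dataset (fast enough for LP-backed tests)
# ---------------------------------------------------------------------------

SMALL_SPEC = SyntheticSpec(
    n_pathways=6,
    pathway_length=3,
    n_conditions=3,
    n_timepoints=8,
    n_planted_up=1,
    n_planted_down=1,
    n_background_chains=12,
    background_chain_length=4,
    seed=777,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_all(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size study conditions; cheap to generate (no LPs are solved)."""
    return generate_all(SyntheticSpec())
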