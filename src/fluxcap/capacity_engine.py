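"""Flux-capacity computation: FBA linear programs over functions x conditions x time.

The flux capacity of a metabolic function is the maximum steady-state flux
(``S v = 0``, ``lower <= v <= upper``) through the function's terminal
reaction within the whole network.  It is an upper bound on pathway activity
under the expression-derived bounds, not a predicted actual flux.

Two solver paths exist: :func:`solve_fba` is a direct, stateless call into
``scipy.optimize.linprog`` (HiGHS) and is the reference implementation;
:class:`CapacitySolver` keeps a persistent GLPK problem (via ``swiglpk``) whose
column bounds and objective are updated in place, so the hundreds of thousands
of closely-related LPs of a permutation-null run re-solve from a warm basis.
Both paths agree to solver tolerance and are cross-checked in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .expression_mapping import BoundsSet, ExpressionSeries, expression_to_bounds
from .model_core import MetabolicModel, Reaction

try:  # pragma: no cover - availability depends on the environment
    import swiglpk as _glp

    HAVE_GLPK = True
except ImportError:  # pragma: no cover
    _glp = None
    HAVE_GLPK = False

logger = logging.getLogger(__name__)

CAPACITY_TOL = 1e-9  # capacities below this are reported as exactly 0

__all__ = [
    "MetabolicFunction",
    "CapacityProfile",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "solve_fba",
    "CapacitySolver",
    "function_capacity",
    "capacity_profiles",
    "load_functions",
    "save_functions",
]


class InfeasibleProblemError(RuntimeError):
    """The FBA problem admits no flux vector under the given bounds."""


class UnboundedProblemError(RuntimeError):
    """The objective is unbounded; a finite flux cap (v_cap) is required."""


# ---------------------------------------------------------------------------
# metabolic functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetabolicFunction:
    """An ordered pathway probed for capacity.

    ``reactions`` lists the pathway's reactions in catalytic order,
    ``initial_reactions`` its declared first step(s), and
    ``terminal_reaction`` the reaction whose flux is maximized.  When the
    terminal reaction's products have no drain elsewhere in the network, a
    demand reaction consuming them in stoichiometric ratio is synthesized at
    solve time.
    """

    id: str
    reactions: tuple[str, ...]
    initial_reactions: tuple[str, ...]
    terminal_reaction: str
    description: str = ""

    def validate(self, model: MetabolicModel) -> None:
        missing = [r for r in self.reactions if r not in model.reaction_index]
        if missing:
            raise ValueError(f"function {self.id}: unknown reactions {missing}")
        if not self.initial_reactions:
            raise ValueError(f"function {self.id}: initial_reactions is empty")
        if not set(self.initial_reactions) <= set(self.reactions):
            raise ValueError(f"function {self.id}: initial reactions not in pathway")
        if self.terminal_reaction not in self.reactions:
            raise ValueError(f"function {self.id}: terminal reaction not in pathway")


def load_functions(path: str | Path) -> list[MetabolicFunction]:
    """Read function definitions from YAML (a list of mappings)."""
    import yaml

    docs = yaml.safe_load(Path(path).read_text())
    return [
        MetabolicFunction(
            id=d["id"],
            reactions=tuple(d["reactions"]),
            initial_reactions=tuple(d["initial_reactions"]),
            terminal_reaction=d["terminal_reaction"],
            description=d.get("description", ""),
        )
        for d in docs
    ]


def save_functions(fns: Sequence[MetabolicFunction], path: str | Path) -> None:
    import yaml

    docs = [
        {
            "id": fn.id,
            "reactions": list(fn.reactions),
            "initial_reactions": list(fn.initial_reactions),
            "terminal_reaction": fn.terminal_reaction,
            "description": fn.description,
        }
        for fn in fns
    ]
    Path(path).write_text(yaml.safe_dump(docs, sort_keys=False))


# ---------------------------------------------------------------------------
# reference LP path (scipy / HiGHS)
# ---------------------------------------------------------------------------

def solve_fba(
    model: MetabolicModel,
    bounds: BoundsSet | tuple[np.ndarray, np.ndarray],
    objective: dict[str, float] | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Maximize ``c^T v`` subject to ``S v = 0`` and ``lower <= v <= upper``.

    Returns the optimum and one optimal flux vector.  Raises
    :class:`InfeasibleProblemError` / :class:`UnboundedProblemError` on the
    respective solver statuses.
    """
    if isinstance(bounds, BoundsSet):
        lower, upper = bounds.lower, bounds.upper
    else:
        lower, upper = bounds
    n = len(model.reactions)
    if isinstance(objective, dict):
        c = np.zeros(n)
        for rid, coef in objective.items():
            c[model.reaction_index[rid]] = coef
    else:
        c = np.asarray(objective, dtype=float)
    if not np.any(c):
        raise ValueError("objective has no nonzero coefficient")
    res = linprog(
        -c,
        A_eq=model.S,
        b_eq=np.zeros(len(model.species)),
        bounds=np.column_stack([lower, upper]),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleProblemError("FBA problem is infeasible under these bounds")
    if res.status == 3:
        raise UnboundedProblemError(
            "FBA objective is unbounded; supply a finite flux cap (v_cap)"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return float(-res.fun), res.x


# ---------------------------------------------------------------------------
# batch solver with persistent GLPK problem
# ---------------------------------------------------------------------------

class _ExtendedProblem:
    """Model matrix extended with synthesized demand columns per function."""

    def __init__(self, model: MetabolicModel, fns: Sequence[MetabolicFunction]):
        for fn in fns:
            fn.validate(model)
        self.model = model
        self.fns = list(fns)
        n = len(model.reactions)

        # which species have a consumer or exporter besides a given reaction
        consumers: dict[int, set[int]] = {}
        S = model.S.tocsc()
        coo = S.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if v < 0:
                consumers.setdefault(int(i), set()).add(int(j))

        extra_cols: list[dict[int, float]] = []
        self.objective_col: dict[str, int] = {}
        self.demand_for: dict[str, str | None] = {}
        for fn in fns:
            j_term = model.reaction_index[fn.terminal_reaction]
            term = model.reactions[j_term]
            products = {
                model.species_index[sid]: coef
                for sid, coef in term.stoichiometry.items()
                if coef > 0
            }
            needs_demand = any(
                not (consumers.get(i, set()) - {j_term}) for i in products
            )
            if products and needs_demand:
                # demand draining the terminal products in stoichiometric ratio
                extra_cols.append({i: -coef for i, coef in products.items()})
                self.objective_col[fn.id] = n + len(extra_cols) - 1
                self.demand_for[fn.id] = f"DM__{fn.id}"
            else:
                self.objective_col[fn.id] = j_term
                self.demand_for[fn.id] = None

        self.n_model = n
        self.n_extra = len(extra_cols)
        self.extra_cols = extra_cols
        rows, cols, data = [], [], []
        for k, col in enumerate(extra_cols):
            for i, coef in col.items():
                rows.append(i)
                cols.append(n + k)
                data.append(coef)
        extra = sp.csr_matrix(
            (data, (rows, cols)), shape=(len(model.species), n + self.n_extra)
        )
        self.A = sp.hstack(
            [S, extra[:, n:]], format="csr"
        ) if self.n_extra else S.tocsr()
        self.extra_lower = np.zeros(self.n_extra)
        self.extra_upper = np.full(self.n_extra, np.inf)

    def full_bounds(self, bounds: BoundsSet) -> tuple[np.ndarray, np.ndarray]:
        lower = np.concatenate([bounds.lower, self.extra_lower])
        upper = np.concatenate([bounds.upper, self.extra_upper])
        return lower, upper


class CapacitySolver:
    """Computes function capacities for many bounds sets over one model.

    Uses a persistent GLPK problem with in-place bound/objective updates
    (warm-started simplex) when ``swiglpk`` is importable, otherwise falls
    back to stateless scipy calls.  Results are deterministic for a fixed
    model, function set and bounds.
    """

    def __init__(
        self,
        model: MetabolicModel,
        fns: Sequence[MetabolicFunction],
        backend: str = "auto",
    ) -> None:
        self.ext = _ExtendedProblem(model, fns)
        if backend == "auto":
            backend = "glpk" if HAVE_GLPK else "scipy"
        if backend == "glpk" and not HAVE_GLPK:
            raise RuntimeError("GLPK backend requested but swiglpk is not importable")
        self.backend = backend
        self._lp = None
        if backend == "glpk":
            self._build_glpk()

    # -- glpk plumbing -------------------------------------------------------

    def _build_glpk(self) -> None:
        A = self.ext.A.tocoo()
        n_rows, n_cols = A.shape
        lp = _glp.glp_create_prob()
        _glp.glp_add_rows(lp, n_rows)
        _glp.glp_add_cols(lp, n_cols)
        for i in range(n_rows):
            _glp.glp_set_row_bnds(lp, i + 1, _glp.GLP_FX, 0.0, 0.0)
        nnz = A.nnz
        ia, ja, ar = (
            _glp.intArray(nnz + 1),
            _glp.intArray(nnz + 1),
            _glp.doubleArray(nnz + 1),
        )
        for k, (i, j, v) in enumerate(zip(A.row, A.col, A.data)):
            ia[k + 1] = int(i) + 1
            ja[k + 1] = int(j) + 1
            ar[k + 1] = float(v)
        _glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        _glp.glp_set_obj_dir(lp, _glp.GLP_MAX)
        parm = _glp.glp_smcp()
        _glp.glp_init_smcp(parm)
        parm.msg_lev = _glp.GLP_MSG_OFF
        self._lp = lp
        self._parm = parm
        self._n_cols = n_cols
        # demand columns: fixed [0, +inf)
        for k in range(self.ext.n_extra):
            _glp.glp_set_col_bnds(
                lp, self.ext.n_model + k + 1, _glp.GLP_LO, 0.0, 0.0
            )

    def _set_glpk_bounds(self, lower: np.ndarray, upper: np.ndarray) -> None:
        lp = self._lp
        for j in range(len(lower)):
            lo, up = float(lower[j]), float(upper[j])
            if np.isinf(up) and np.isinf(lo):
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_FR, 0.0, 0.0)
            elif np.isinf(up):
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_LO, lo, 0.0)
            elif np.isinf(lo):
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_UP, 0.0, up)
            elif lo == up:
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_FX, lo, up)
            else:
                _glp.glp_set_col_bnds(lp, j + 1, _glp.GLP_DB, lo, up)

    def _glpk_maximize(self, col: int) -> tuple[float, str]:
        lp = self._lp
        _glp.glp_set_obj_coef(lp, col + 1, 1.0)
        ret = _glp.glp_simplex(lp, self._parm)
        if ret != 0:
            # numerical trouble: retry from a fresh basis
            _glp.glp_std_basis(lp)
            ret = _glp.glp_simplex(lp, self._parm)
        status = _glp.glp_get_status(lp)
        opt = _glp.glp_get_obj_val(lp)
        _glp.glp_set_obj_coef(lp, col + 1, 0.0)
        if ret != 0:
            return np.nan, "solver_failure"
        if status == _glp.GLP_OPT:
            return opt, "optimal"
        if status == _glp.GLP_NOFEAS:
            return np.nan, "infeasible"
        if status == _glp.GLP_UNBND:
            return np.nan, "unbounded"
        return np.nan, f"status_{status}"

    # -- public api ----------------------------------------------------------

    def capacities(
        self, bounds: BoundsSet
    ) -> tuple[np.ndarray, list[str]]:
        """Capacity of every function under one bounds set.

        Returns (values, statuses); values are clipped at ``CAPACITY_TOL``
        and set to NaN for non-optimal cells.
        """
        values = np.empty(len(self.ext.fns))
        statuses: list[str] = []
        if self.backend == "glpk":
            lower, upper = self.ext.full_bounds(bounds)
            self._set_glpk_bounds(lower[: self.ext.n_model], upper[: self.ext.n_model])
            for k, fn in enumerate(self.ext.fns):
                opt, status = self._glpk_maximize(self.ext.objective_col[fn.id])
                values[k] = opt
                statuses.append(status)
        else:
            lower, upper = self.ext.full_bounds(bounds)
            for k, fn in enumerate(self.ext.fns):
                c = np.zeros(self.ext.A.shape[1])
                c[self.ext.objective_col[fn.id]] = -1.0
                res = linprog(
                    c,
                    A_eq=self.ext.A,
                    b_eq=np.zeros(self.ext.A.shape[0]),
                    bounds=np.column_stack([lower, upper]),
                    method="highs",
                )
                if res.status == 0:
                    values[k] = -res.fun
                    statuses.append("optimal")
                else:
                    values[k] = np.nan
                    statuses.append(
                        {2: "infeasible", 3: "unbounded"}.get(res.status, "solver_failure")
                    )
        ok = ~np.isnan(values)
        values[ok & (np.abs(values) < CAPACITY_TOL)] = 0.0
        return values, statuses

    def __del__(self) -> None:  # pragma: no cover
        if self._lp is not None and _glp is not None:
            _glp.glp_delete_prob(self._lp)


# ---------------------------------------------------------------------------
# convenience single-shot ops
# ---------------------------------------------------------------------------

def function_capacity(
    model: MetabolicModel,
    bounds: BoundsSet,
    fn: MetabolicFunction,
    backend: str = "auto",
) -> float:
    """Maximum flux through one function's terminal reaction (never negative)."""
    solver = CapacitySolver(model, [fn], backend=backend)
    values, statuses = solver.capacities(bounds)
    if statuses[0] == "infeasible":
        raise InfeasibleProblemError(f"function {fn.id}: infeasible under these bounds")
    if statuses[0] == "unbounded":
        raise UnboundedProblemError(
            f"function {fn.id}: unbounded capacity; supply a finite v_cap"
        )
    if statuses[0] != "optimal":
        raise RuntimeError(f"function {fn.id}: solver failure ({statuses[0]})")
    return float(max(values[0], 0.0))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class CapacityProfile:
    """Flux capacities on a function x condition x time grid."""

    function_ids: list[str]
    conditions: list[str]
    timepoints: np.ndarray
    values: np.ndarray  # (fn, cond, time)
    status: np.ndarray  # object array, same shape

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, fid in enumerate(self.function_ids):
            for b, cond in enumerate(self.conditions):
                for c, t in enumerate(self.timepoints):
                    rows.append(
                        {
                            "function": fid,
                            "condition": cond,
                            "time": t,
                            "capacity": self.values[a, b, c],
                            "status": self.status[a, b, c],
                        }
                    )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CapacityProfile":
        df = pd.read_csv(path, sep="\t", comment="#")
        fids = list(pd.unique(df["function"]))
        conds = list(pd.unique(df["condition"]))
        times = np.array(sorted(pd.unique(df["time"])), dtype=float)
        values = np.full((len(fids), len(conds), len(times)), np.nan)
        status = np.full(values.shape, "missing", dtype=object)
        fi = {f: i for i, f in enumerate(fids)}
        ci = {c: i for i, c in enumerate(conds)}
        ti = {t: i for i, t in enumerate(times)}
        for row in df.itertuples():
            values[fi[row.function], ci[row.condition], ti[row.time]] = row.capacity
            status[fi[row.function], ci[row.condition], ti[row.time]] = row.status
        return cls(fids, conds, times, values, status)


def capacity_profiles(
    model: MetabolicModel,
    expr: ExpressionSeries,
    fns: Sequence[MetabolicFunction],
    v_cap: float,
    missing_gene_mode: str = "absent",
    backend: str = "auto",
) -> CapacityProfile:
    """One capacity LP per (function, condition, time point).

    Per-cell solver errors are recorded in the profile's status grid and do
    not abort the run.
    """
    solver = CapacitySolver(model, fns, backend=backend)
    conds = expr.conditions
    times = expr.timepoints
    values = np.full((len(fns), len(conds), len(times)), np.nan)
    status = np.full(values.shape, "missing", dtype=object)
    for b, cond in enumerate(conds):
        for c, t in enumerate(times):
            bounds = expression_to_bounds(
                model, expr.slice(cond, t), v_cap, missing_gene_mode
            )
            vals, stats = solver.capacities(bounds)
            values[:, b, c] = np.maximum(vals, 0.0, where=~np.isnan(vals), out=vals)
            status[:, b, c] = stats
        logger.info("capacity profiles: condition %s done (%d LPs)", cond, len(times) * len(fns))
    return CapacityProfile(
        [fn.id for fn in fns], list(conds), np.asarray(times, dtype=float), values, status
    )
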