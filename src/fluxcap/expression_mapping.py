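"""Expression integration: GPR scoring, E-flux bounds, metabolite mapping.

The integration follows the E-flux idea: the upper flux bound of an
enzyme-catalysed reaction is set proportional to the expression-derived
activity of its gene association, so transcript abundance caps — but never
forces — flux.  Activities are computed from GPR rules (AND = min of the
complex subunits, OR = sum over isozymes), normalized per condition x time
slice by the maximal activity, and scaled to a global flux cap ``v_cap``.
Reversible reactions receive symmetric bounds; exchange reactions and
reactions without expression evidence keep their model defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import GprNode, MetabolicModel

__all__ = [
    "ExpressionSeries",
    "BoundsSet",
    "MetaboliteMapping",
    "evaluate_gpr",
    "expression_to_bounds",
    "map_metabolites",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class ExpressionSeries:
    """Gene-expression values on a condition x time x gene grid.

    Backed by a wide DataFrame indexed by (condition, time) with one column
    per gene.  Values must be nonnegative; the time grid must be strictly
    increasing and identical across conditions.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if not isinstance(values.index, pd.MultiIndex) or values.index.nlevels != 2:
            raise ValueError("expression values need a (condition, time) MultiIndex")
        self.values = values.sort_index()
        self.values.index.names = ["condition", "time"]
        self.values.columns.name = None
        self.validate()

    @property
    def conditions(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def timepoints(self) -> np.ndarray:
        first = self.conditions[0]
        return self.values.loc[first].index.to_numpy(dtype=float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("expression series contains missing values")
        if (arr < 0).any():
            raise ValueError("expression series contains negative values")
        grids = {
            cond: tuple(self.values.loc[cond].index.to_numpy(dtype=float))
            for cond in self.conditions
        }
        ref = next(iter(grids.values()))
        if np.any(np.diff(ref) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        for cond, grid in grids.items():
            if grid != ref:
                raise ValueError(f"condition {cond} has a different time grid")

    def slice(self, condition: str, time: float) -> pd.Series:
        """Gene -> expression value for one condition and time point."""
        return self.values.loc[(condition, time)]

    # -- io ------------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionSeries":
        long = pd.read_csv(path, sep="\t", comment="#")
        wide = long.pivot_table(
            index=["condition", "time"], columns="feature", values="value"
        )
        return cls(wide)

    def to_tsv(self, path: str | Path) -> None:
        long = (
            self.values.stack()
            .rename("value")
            .rename_axis(["condition", "time", "feature"])
            .reset_index()
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class BoundsSet:
    """Flux bounds for every reaction at one condition x time point.

    ``constrained`` marks reactions whose upper bound derives from expression
    data; the rest keep model defaults.  ``reversible`` is carried along so a
    permutation of the expression-derived magnitudes can re-impose each
    reaction's thermodynamic (directionality) pattern.
    """

    reaction_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    constrained: np.ndarray  # bool
    reversible: np.ndarray  # bool

    def copy(self) -> "BoundsSet":
        return BoundsSet(
            self.reaction_ids,
            self.lower.copy(),
            self.upper.copy(),
            self.constrained.copy(),
            self.reversible.copy(),
        )

    def validate(self) -> None:
        if (self.lower > self.upper).any():
            raise ValueError("lower bound exceeds upper bound")


@dataclass(frozen=True)
class MetaboliteMapping:
    """Measurement name -> set of model base-compound identifiers."""

    pairs: Mapping[str, frozenset[str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaboliteMapping":
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = list(df.columns[:2])
        out: dict[str, set[str]] = {}
        for name, target in zip(df[cols[0]], df[cols[1]]):
            out.setdefault(str(name), set()).add(str(target))
        return cls({k: frozenset(v) for k, v in out.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"measurement": name, "base_id": base}
            for name in sorted(self.pairs)
            for base in sorted(self.pairs[name])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def validate(self, model: MetabolicModel) -> None:
        bases = {s.base_id for s in model.species}
        missing = {
            name: sorted(t - bases)
            for name, t in self.pairs.items()
            if t - bases
        }
        if missing:
            raise ValueError(
                f"mapping targets absent from the model: {missing}"
            )

    def mapped_bases(self) -> frozenset[str]:
        out: set[str] = set()
        for targets in self.pairs.values():
            out |= targets
        return frozenset(out)


# ---------------------------------------------------------------------------
# GPR evaluation
# ---------------------------------------------------------------------------

def evaluate_gpr(
    rule: GprNode | None,
    expr: Mapping[str, float],
    missing_gene_mode: str = "absent",
) -> float | None:
    """Expression-derived activity of a gene association.

    AND nodes take the minimum of their children (a complex is limited by its
    scarcest subunit), OR nodes the sum (isozymes act additively).  A gene
    absent from ``expr`` contributes no evidence: it is dropped from its
    parent node, and a node whose children are all absent is itself absent.
    With ``missing_gene_mode="zero"`` absent genes instead count as zero
    expression.  An empty rule evaluates to absent (``None``).
    """
    if rule is None:
        return None
    if rule.kind == "gene":
        if rule.gene in expr:
            return float(expr[rule.gene])
        return 0.0 if missing_gene_mode == "zero" else None
    vals = [
        v
        for v in (
            evaluate_gpr(ch, expr, missing_gene_mode) for ch in rule.children
        )
        if v is not None
    ]
    if not vals:
        return None
    return min(vals) if rule.kind == "and" else float(sum(vals))


# ---------------------------------------------------------------------------
# E-flux bounds
# ---------------------------------------------------------------------------

def expression_to_bounds(
    model: MetabolicModel,
    expr_slice: Mapping[str, float],
    v_cap: float,
    missing_gene_mode: str = "absent",
) -> BoundsSet:
    """Turn one expression slice into per-reaction flux bounds (E-flux).

    For each non-exchange reaction with a GPR activity ``a``, the upper bound
    is ``v_cap * a / a_max`` where ``a_max`` is the largest activity among
    constrained reactions in this slice; reversible reactions get
    ``lower = -upper``, irreversible ones ``lower = 0``.  Exchange reactions
    and reactions without activity keep model defaults.  Only upper bounds are
    restricted; no minimum flux is ever enforced.
    """
    if v_cap <= 0:
        raise ValueError("v_cap must be positive")
    n = len(model.reactions)
    lower, upper = model.default_bounds()
    constrained = np.zeros(n, dtype=bool)
    reversible = np.array([r.reversible for r in model.reactions], dtype=bool)

    activities = np.full(n, np.nan)
    for j, r in enumerate(model.reactions):
        if r.is_exchange or r.gpr is None:
            continue
        a = evaluate_gpr(r.gpr, expr_slice, missing_gene_mode)
        if a is not None:
            activities[j] = a
            constrained[j] = True

    if not constrained.any():
        warnings.warn(
            "no reaction activity could be derived from this expression slice; "
            "all bounds keep model defaults",
            stacklevel=2,
        )
        return BoundsSet(
            [r.id for r in model.reactions], lower, upper, constrained, reversible
        )

    a_max = np.nanmax(activities[constrained])
    if a_max <= 0:
        scale = np.zeros(n)
    else:
        scale = activities / a_max
    upper[constrained] = v_cap * scale[constrained]
    lower[constrained] = np.where(
        reversible[constrained], -upper[constrained], 0.0
    )
    return BoundsSet(
        [r.id for r in model.reactions], lower, upper, constrained, reversible
    )


# ---------------------------------------------------------------------------
# metabolite mapping
# ---------------------------------------------------------------------------

def map_metabolites(
    mapping: MetaboliteMapping,
    series: pd.DataFrame,
    model: MetabolicModel,
) -> tuple[pd.DataFrame, list[str]]:
    """Copy measured profiles onto every compartment instance of each compound.

    ``series`` is a wide table indexed by (condition, time) with one column
    per measurement.  The measured data are compartment-agnostic, so each
    compartment-specific instance of a mapped base compound receives an
    identical copy of the profile.  Returns the per-instance table and the
    list of measurements that could not be mapped.
    """
    cols: dict[str, pd.Series] = {}
    unmapped: list[str] = []
    for name in series.columns:
        targets = mapping.pairs.get(name)
        if not targets:
            unmapped.append(name)
            continue
        hit = False
        for base in sorted(targets):
            for inst in model.instances_of(base):
                cols[inst.id] = series[name]
                hit = True
        if not hit:
            unmapped.append(name)
    if not cols:
        return pd.DataFrame(index=series.index), unmapped
    return pd.DataFrame(cols, index=series.index), unmapped
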