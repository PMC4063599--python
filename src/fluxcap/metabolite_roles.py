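"""Pathway roles of metabolites and per-condition metabolite groupings.

Within one metabolic function, a metabolite consumed by some pathway reaction
but produced by none is a *substrate*; produced but never consumed, a
*product*; both, an *intermediate*.  Substrates of the declared first
reaction(s) are *initial substrates*, products of the terminal reaction
*final products*.  Roles are evaluated at the compartment-instance level
(stoichiometric signs as written) and lifted to base compounds by "any
instance qualifies"; cofactors are excluded throughout.

Groupings collect measured, mapped base compounds by the classification of
the pathways they participate in (modulator / sustainer / differential and
their complements), for three categorizations: any role, products only,
substrates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capacity_engine import MetabolicFunction
from .expression_mapping import MetaboliteMapping
from .model_core import CofactorList, MetabolicModel, metabolite_connectivity
from .null_classifier import ClassificationTable
from .variability_stats import RankSumResult, rank_sum_test

__all__ = [
    "RoleAssignment",
    "MetaboliteGrouping",
    "pathway_roles",
    "substrate_count_stats",
    "build_groupings",
    "connectivity_stats",
    "GROUP_NAMES",
    "CATEGORIZATIONS",
]

CATEGORIZATIONS = ("all", "products", "substrates")
GROUP_NAMES = (
    "in_modulator",
    "in_sustainer",
    "in_differential",
    "in_non_modulator",
    "in_non_sustainer",
    "in_non_differential",
    "all_measured",
)


@dataclass
class RoleAssignment:
    """Roles of one function's (non-cofactor) metabolites."""

    function_id: str
    roles: dict[str, str]  # species id -> substrate | intermediate | product
    initial_substrates: frozenset[str]
    final_products: frozenset[str]

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(s for s, r in self.roles.items() if r == "substrate")

    @property
    def intermediates(self) -> frozenset[str]:
        return frozenset(s for s, r in self.roles.items() if r == "intermediate")

    @property
    def products(self) -> frozenset[str]:
        return frozenset(s for s, r in self.roles.items() if r == "product")

    def bases_with_role(self, model: MetabolicModel, role: str) -> frozenset[str]:
        """Base compounds holding ``role`` ("any" accepts every role)."""
        out = set()
        for sid, r in self.roles.items():
            if role == "any" or r == role:
                out.add(model.species[model.species_index[sid]].base_id)
        return frozenset(out)

    def to_rows(self) -> list[dict]:
        return [
            {
                "function": self.function_id,
                "species": sid,
                "role": role,
                "initial_substrate": sid in self.initial_substrates,
                "final_product": sid in self.final_products,
            }
            for sid, role in sorted(self.roles.items())
        ]


def pathway_roles(
    fn: MetabolicFunction,
    model: MetabolicModel,
    cofactors: CofactorList | None = None,
) -> RoleAssignment:
    """Assign substrate/intermediate/product roles within one function.

    Consumption and production follow the stoichiometric signs of the pathway
    reactions as written (functions declare their catalytic direction).
    """
    fn.validate(model)
    cofactors = cofactors or CofactorList()
    consumed: set[str] = set()
    produced: set[str] = set()
    for rid in fn.reactions:
        rxn = model.reactions[model.reaction_index[rid]]
        for sid, coef in rxn.stoichiometry.items():
            if model.species[model.species_index[sid]].base_id in cofactors:
                continue
            if coef < 0:
                consumed.add(sid)
            else:
                produced.add(sid)
    roles: dict[str, str] = {}
    for sid in consumed | produced:
        if sid in consumed and sid in produced:
            roles[sid] = "intermediate"
        elif sid in consumed:
            roles[sid] = "substrate"
        else:
            roles[sid] = "product"

    initial: set[str] = set()
    for rid in fn.initial_reactions:
        rxn = model.reactions[model.reaction_index[rid]]
        for sid, coef in rxn.stoichiometry.items():
            if coef < 0 and roles.get(sid) == "substrate":
                initial.add(sid)
    final: set[str] = set()
    term = model.reactions[model.reaction_index[fn.terminal_reaction]]
    for sid, coef in term.stoichiometry.items():
        if coef > 0 and roles.get(sid) == "product":
            final.add(sid)
    return RoleAssignment(fn.id, roles, frozenset(initial), frozenset(final))


# ---------------------------------------------------------------------------
# substrate-count statistics
# ---------------------------------------------------------------------------

@dataclass
class SubstrateCountStats:
    """Substrate counts per pathway set with one-sided rank-sum tests."""

    mean_substrates: dict[str, float]  # differential / all / non_differential
    counts: dict[str, list[int]]
    fraction_two_initial: dict[str, float]
    p_differential_vs_all: RankSumResult
    p_differential_vs_non: RankSumResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in ("differential", "all", "non_differential"):
            rows.append(
                {
                    "group": group,
                    "n_pathways": len(self.counts[group]),
                    "mean_substrates": self.mean_substrates[group],
                    "fraction_two_initial_substrates": self.fraction_two_initial[group],
                }
            )
        return pd.DataFrame(rows)


def substrate_count_stats(
    fns: list[MetabolicFunction],
    roles: dict[str, RoleAssignment],
    classification: ClassificationTable,
) -> SubstrateCountStats:
    """Compare substrate counts of differential vs other pathways.

    Counts compartment-specific substrate instances per function (cofactors
    were already excluded during role assignment); reports group means, the
    fraction of pathways with exactly two initial substrates, and one-sided
    rank-sum p-values for "differential pathways have fewer substrates".
    """
    diff_ids = set(classification.differential[classification.differential].index)
    counts_all = [len(roles[fn.id].substrates) for fn in fns]
    counts_diff = [len(roles[fn.id].substrates) for fn in fns if fn.id in diff_ids]
    counts_non = [len(roles[fn.id].substrates) for fn in fns if fn.id not in diff_ids]
    init_all = [len(roles[fn.id].initial_substrates) for fn in fns]
    init_diff = [len(roles[fn.id].initial_substrates) for fn in fns if fn.id in diff_ids]
    init_non = [len(roles[fn.id].initial_substrates) for fn in fns if fn.id not in diff_ids]

    def frac_two(counts: list[int]) -> float:
        return float(np.mean([c == 2 for c in counts])) if counts else float("nan")

    def mean(counts: list[int]) -> float:
        return float(np.mean(counts)) if counts else float("nan")

    return SubstrateCountStats(
        mean_substrates={
            "differential": mean(counts_diff),
            "all": mean(counts_all),
            "non_differential": mean(counts_non),
        },
        counts={
            "differential": counts_diff,
            "all": counts_all,
            "non_differential": counts_non,
        },
        fraction_two_initial={
            "differential": frac_two(init_diff),
            "all": frac_two(init_all),
            "non_differential": frac_two(init_non),
        },
        p_differential_vs_all=rank_sum_test(counts_diff, counts_all),
        p_differential_vs_non=rank_sum_test(counts_diff, counts_non),
    )


# ---------------------------------------------------------------------------
# groupings
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteGrouping:
    """Measured-compound membership sets for one condition.

    ``sets[(categorization, group)]`` is a frozenset of base compounds;
    categorizations are any-role / products-only / substrates-only, groups the
    in-X / in-non-X memberships plus all measured compounds.  in-X and
    in-non-X are disjoint by construction: a compound participating in both an
    X and a non-X pathway counts for in-X only.
    """

    condition: str
    sets: dict[tuple[str, str], frozenset[str]]

    def sizes(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "categorization": cat, "group": grp,
             "n": len(members)}
            for (cat, grp), members in sorted(self.sets.items())
        ]
        return pd.DataFrame(rows)


def build_groupings(
    roles: dict[str, RoleAssignment],
    classification: ClassificationTable,
    mapping: MetaboliteMapping,
    condition: str,
    model: MetabolicModel,
    exclusive: bool = True,
) -> MetaboliteGrouping:
    """Membership sets of measured compounds for one condition.

    A pathway counts as modulator/sustainer in this condition when it carries
    that label here *and* passes the global differential filter; differential
    means either label.  With ``exclusive`` (default), in-non-X membership
    requires participating in no X pathway.
    """
    measured = mapping.mapped_bases() & {s.base_id for s in model.species}
    labels = classification.labels[condition]
    is_diff = classification.differential

    def fn_in_class(fid: str, cls: str) -> bool:
        if not bool(is_diff.get(fid, False)):
            return False
        lab = labels.get(fid, "none")
        if cls == "differential":
            return lab in ("modulator", "sustainer")
        return lab == cls

    role_for_cat = {"all": "any", "products": "product", "substrates": "substrate"}
    sets: dict[tuple[str, str], frozenset[str]] = {}
    for cat, role in role_for_cat.items():
        participants: dict[str, set[str]] = {}  # base -> set of fn ids w/ role
        for fid, ra in roles.items():
            for base in ra.bases_with_role(model, role):
                participants.setdefault(base, set()).add(fid)
        for cls in ("modulator", "sustainer", "differential"):
            in_x = {
                base
                for base, fids in participants.items()
                if base in measured and any(fn_in_class(f, cls) for f in fids)
            }
            non_x = {
                base
                for base, fids in participants.items()
                if base in measured and not any(fn_in_class(f, cls) for f in fids)
            }
            if not exclusive:
                non_x = {
                    base
                    for base, fids in participants.items()
                    if base in measured
                    and any(not fn_in_class(f, cls) for f in fids)
                }
            sets[(cat, f"in_{cls}")] = frozenset(in_x)
            sets[(cat, f"in_non_{cls}")] = frozenset(non_x)
        sets[(cat, "all_measured")] = frozenset(measured)
    return MetaboliteGrouping(condition, sets)


# ---------------------------------------------------------------------------
# topology statistics
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityStats:
    """Connectivity of measured substrates of differential pathways vs all."""

    mean_substrates_differential: float
    mean_all_metabolites: float
    n_substrates_differential: int
    n_all: int
    p_more_connected: RankSumResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": "substrates_differential",
                    "n": self.n_substrates_differential,
                    "mean_connectivity": self.mean_substrates_differential,
                    "p_more_connected": self.p_more_connected.p,
                    "na_reason": self.p_more_connected.na_reason,
                },
                {
                    "group": "all_metabolites",
                    "n": self.n_all,
                    "mean_connectivity": self.mean_all_metabolites,
                    "p_more_connected": np.nan,
                    "na_reason": None,
                },
            ]
        )


def connectivity_stats(
    model: MetabolicModel,
    cofactors: CofactorList,
    roles: dict[str, RoleAssignment],
    classification: ClassificationTable,
    mapping: MetaboliteMapping,
) -> ConnectivityStats:
    """Are measured substrates of differential pathways more connected?

    Connectivity counts reactions per compartment-specific instance (cofactors
    excluded).  The substrate group pools, over all conditions, the instances
    of measured base compounds acting as substrates in a pathway that is
    differential and classified in that condition; the reference group is
    every non-cofactor instance in the model.  The one-sided rank-sum test
    asks whether the substrate group is *more* connected.
    """
    conn = metabolite_connectivity(model, cofactors)
    measured = mapping.mapped_bases()
    diff_ids = set(classification.differential[classification.differential].index)
    active_bases: set[str] = set()
    for cond in classification.labels.columns:
        labels = classification.labels[cond]
        for fid, ra in roles.items():
            if fid in diff_ids and labels.get(fid, "none") != "none":
                active_bases |= set(ra.bases_with_role(model, "substrate")) & measured
    group = [
        conn[s.id]
        for s in model.species
        if s.base_id in active_bases and s.id in conn
    ]
    universe = list(conn.values())
    # one-sided: group MORE connected than all -> test all < group
    res = rank_sum_test(universe, group, alternative="a_less")
    return ConnectivityStats(
        mean_substrates_differential=float(np.mean(group)) if group else float("nan"),
        mean_all_metabolites=float(np.mean(universe)) if universe else float("nan"),
        n_substrates_differential=len(group),
        n_all=len(universe),
        p_more_connected=res,
    )
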