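"""Metabolic model container, io, and topology services.

A :class:`MetabolicModel` is a compartmentalized stoichiometric model: rows of
the stoichiometric matrix ``S`` are compartment-specific species (the same base
compound in two compartments is two distinct rows), columns are reactions.
Reactions carry flux bounds, a reversibility flag, an exchange flag, and an
optional gene-protein-reaction (GPR) boolean rule over gene identifiers.

Two on-disk dialects are supported: SBML Level 3 with the FBC package (read and
written through cobrapy) and a plain JSON dialect documented in
``docs/methods.md``.  Topology services (metabolite connectivity, compartment
multiplicity) operate directly on ``S``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GprNode",
    "parse_gpr",
    "Species",
    "Reaction",
    "CofactorList",
    "MetabolicModel",
    "ModelFormatError",
    "ModelValidationError",
    "load_model",
    "save_model",
    "metabolite_connectivity",
    "multicompartment_count",
]


class ModelFormatError(ValueError):
    """A model file could not be parsed under the requested dialect."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprNode:
    """Node of a boolean gene-association tree.

    ``kind`` is ``"gene"`` (leaf, ``gene`` set) or ``"and"``/``"or"`` with two
    or more ``children``.
    """

    kind: str
    gene: str | None = None
    children: tuple["GprNode", ...] = ()

    def genes(self) -> frozenset[str]:
        if self.kind == "gene":
            return frozenset({self.gene})
        out: set[str] = set()
        for ch in self.children:
            out |= ch.genes()
        return frozenset(out)

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for ch in self.children:
            s = ch.to_string()
            if ch.kind != "gene" and ch.kind != self.kind:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def _tokenize_gpr(text: str) -> list[str]:
    tokens: list[str] = []
    cur = ""
    for ch in text:
        if ch in "()":
            if cur:
                tokens.append(cur)
                cur = ""
            tokens.append(ch)
        elif ch.isspace():
            if cur:
                tokens.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    return tokens


def parse_gpr(text: str | None) -> GprNode | None:
    """Parse a GPR string like ``"g1 and (g2 or g3)"`` into a tree.

    ``and``/``or`` are case-insensitive keywords; any other token is a gene
    identifier (dots, colons etc. are allowed).  Returns ``None`` for an
    empty rule.  ``or`` binds looser than ``and``.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize_gpr(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprNode:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return GprNode("or", children=tuple(parts))

    def parse_and() -> GprNode:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GprNode("and", children=tuple(parts))

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise ModelFormatError(f"truncated GPR rule: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR rule: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"malformed GPR rule near {tok!r}: {text!r}")
        return GprNode("gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise ModelFormatError(f"trailing tokens in GPR rule: {text!r}")
    return node


# ---------------------------------------------------------------------------
# Species / reactions / model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A compartment-specific metabolite instance (one row of S)."""

    id: str
    base_id: str
    compartment: str


@dataclass
class Reaction:
    """One column of S with bounds, reversibility, exchange flag and GPR."""

    id: str
    stoichiometry: dict[str, float]  # species id -> coefficient
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    reversible: bool = False
    is_exchange: bool = False
    gpr: GprNode | None = None


@dataclass(frozen=True)
class CofactorList:
    """Base-compound identifiers excluded from topology and role statistics.

    Matching is compartment-agnostic: ``atp`` excludes ``atp_c`` and ``atp_p``.
    """

    excluded_ids: frozenset[str] = frozenset()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CofactorList":
        ids = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
        return cls(frozenset(ids))

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{c}\n" for c in sorted(self.excluded_ids)))

    def __contains__(self, base_id: str) -> bool:
        return base_id in self.excluded_ids


class MetabolicModel:
    """Compartmentalized stoichiometric model.

    Parameters
    ----------
    species : list of Species
        Rows of S, in order.
    reactions : list of Reaction
        Columns of S, in order.
    gene_ids : optional list of gene identifiers; inferred from GPRs if absent.
    """

    def __init__(
        self,
        species: list[Species],
        reactions: list[Reaction],
        gene_ids: list[str] | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        self.reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        if gene_ids is None:
            genes: set[str] = set()
            for r in self.reactions:
                if r.gpr is not None:
                    genes |= r.gpr.genes()
            gene_ids = sorted(genes)
        self.gene_ids = list(gene_ids)
        self._S: sp.csr_matrix | None = None
        self.validate()

    # -- structure ----------------------------------------------------------

    @property
    def S(self) -> sp.csr_matrix:
        """Stoichiometric matrix, species x reactions (CSR)."""
        if self._S is None:
            rows, cols, data = [], [], []
            for j, r in enumerate(self.reactions):
                for sid, coef in r.stoichiometry.items():
                    rows.append(self.species_index[sid])
                    cols.append(j)
                    data.append(float(coef))
            self._S = sp.csr_matrix(
                (data, (rows, cols)), shape=(len(self.species), len(self.reactions))
            )
        return self._S

    def validate(self) -> None:
        if len(self.species_index) != len(self.species):
            raise ModelValidationError("duplicate species identifiers")
        if len(self.reaction_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction identifiers")
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id} has empty stoichiometry")
            for sid, coef in r.stoichiometry.items():
                if sid not in self.species_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown species {sid}"
                    )
                if coef == 0:
                    raise ModelValidationError(
                        f"reaction {r.id} carries a zero coefficient for {sid}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not r.reversible and r.lower_bound < 0:
                raise ModelValidationError(
                    f"reaction {r.id} is irreversible but lower_bound < 0"
                )

    def flag_structural_exchanges(self) -> None:
        """Mark single-species reactions as exchanges when none are flagged.

        SBML files vary in annotation; a reaction touching a single species is
        structurally a boundary (import/export/demand) reaction.
        """
        if any(r.is_exchange for r in self.reactions):
            return
        for r in self.reactions:
            if len(r.stoichiometry) == 1:
                r.is_exchange = True

    def instances_of(self, base_id: str) -> list[Species]:
        return [s for s in self.species if s.base_id == base_id]

    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lower = np.array([r.lower_bound for r in self.reactions], dtype=float)
        upper = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lower, upper

    def canonical_matrix(self) -> tuple[list[str], list[str], np.ndarray]:
        """S with rows/columns sorted by identifier (for cross-dialect checks)."""
        s_order = np.argsort([s.id for s in self.species])
        r_order = np.argsort([r.id for r in self.reactions])
        dense = self.S.toarray()[np.ix_(s_order, r_order)]
        return (
            [self.species[i].id for i in s_order],
            [self.reactions[j].id for j in r_order],
            dense,
        )


# ---------------------------------------------------------------------------
# io: JSON dialect
# ---------------------------------------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": s.id, "base_id": s.base_id, "compartment": s.compartment}
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": {k: v for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "reversible": r.reversible,
                "is_exchange": r.is_exchange,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
            }
            for r in model.reactions
        ],
        "genes": list(model.gene_ids),
    }


def _strip_compartment(species_id: str, compartment: str) -> str:
    suffix = f"_{compartment}"
    if compartment and species_id.endswith(suffix):
        return species_id[: -len(suffix)]
    return species_id


def _model_from_json_dict(doc: dict, name: str = "model") -> MetabolicModel:
    try:
        species = []
        for m in doc["metabolites"]:
            comp = m.get("compartment", "")
            species.append(
                Species(
                    id=m["id"],
                    base_id=m.get("base_id") or _strip_compartment(m["id"], comp),
                    compartment=comp,
                )
            )
        reactions = []
        for r in doc["reactions"]:
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                    reversible=bool(r.get("reversible", r.get("lower_bound", 0) < 0)),
                    is_exchange=bool(r.get("is_exchange", False)),
                    gpr=parse_gpr(r.get("gpr", "")),
                )
            )
        genes = doc.get("genes")
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed JSON model: missing element {exc}") from exc
    model = MetabolicModel(species, reactions, gene_ids=genes, id=doc.get("id", name))
    model.flag_structural_exchanges()
    return model


# ---------------------------------------------------------------------------
# io: SBML via cobrapy
# ---------------------------------------------------------------------------

def _model_from_cobra(cmodel) -> MetabolicModel:
    species = [
        Species(
            id=m.id,
            base_id=_strip_compartment(m.id, m.compartment or ""),
            compartment=m.compartment or "",
        )
        for m in cmodel.metabolites
    ]
    reactions = []
    for rxn in cmodel.reactions:
        gpr_str = rxn.gene_reaction_rule or ""
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                reversible=rxn.lower_bound < 0,
                is_exchange=bool(rxn.boundary),
                gpr=parse_gpr(gpr_str),
            )
        )
    model = MetabolicModel(
        species, reactions, gene_ids=sorted(g.id for g in cmodel.genes), id=cmodel.id
    )
    model.flag_structural_exchanges()
    return model


def _model_to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    mets = {}
    compartments = sorted({s.compartment for s in model.species if s.compartment})
    cmodel.compartments = {c: c for c in compartments}
    for s in model.species:
        met = cobra.Metabolite(s.id, compartment=s.compartment or None)
        mets[s.id] = met
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(rxn)
    cmodel.add_reactions(rxns)
    for r, rxn in zip(model.reactions, rxns):
        rxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr is not None:
            rxn.gene_reaction_rule = r.gpr.to_string()
    return cmodel


# ---------------------------------------------------------------------------
# public io
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    if path.suffix.lower() == ".json":
        return "json"
    raise ModelFormatError(f"cannot infer model dialect from {path.name}")


def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load and validate a metabolic model from SBML or the JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid JSON in {path.name}: {exc}") from exc
        return _model_from_json_dict(doc, name=path.stem)
    if dialect == "sbml":
        import logging

        import cobra

        cobra_logger = logging.getLogger("cobra")
        old_level = cobra_logger.level
        cobra_logger.setLevel(logging.ERROR)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cmodel = cobra.io.read_sbml_model(str(path))
                except Exception as exc:  # cobra raises CobraSBMLError
                    raise ModelFormatError(
                        f"SBML parse failure in {path.name}: {exc}"
                    ) from exc
        finally:
            cobra_logger.setLevel(old_level)
        return _model_from_cobra(cmodel)
    raise ModelFormatError(f"unknown dialect {dialect!r}")


def save_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> None:
    """Write a model as SBML (via cobrapy/FBC) or as the JSON dialect."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, sort_keys=True))
    elif dialect == "sbml":
        import cobra

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(_model_to_cobra(model), str(path))
    else:
        raise ModelFormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def metabolite_connectivity(
    model: MetabolicModel, cofactors: CofactorList | None = None
) -> dict[str, int]:
    """Number of reactions each compartment-specific metabolite participates in.

    A metabolite participates in a reaction if its stoichiometric coefficient
    is nonzero, counted once per reaction regardless of coefficient magnitude.
    Compartment instances of the same base compound are separate entries.
    Compounds on the cofactor list are omitted from the result.
    """
    cofactors = cofactors or CofactorList()
    counts = np.diff(model.S.tocsr().indptr)
    return {
        s.id: int(c)
        for s, c in zip(model.species, counts)
        if s.base_id not in cofactors
    }


def multicompartment_count(model: MetabolicModel, mapped_ids: set[str]) -> int:
    """Number of base compounds with >= 2 compartment-specific instances.

    Unknown identifiers are skipped with a warning.
    """
    if not mapped_ids:
        return 0
    by_base: dict[str, int] = {}
    for s in model.species:
        by_base[s.base_id] = by_base.get(s.base_id, 0) + 1
    unknown = sorted(b for b in mapped_ids if b not in by_base)
    if unknown:
        warnings.warn(
            f"{len(unknown)} mapped compound(s) absent from the model and skipped: "
            + ", ".join(unknown[:10]),
            stacklevel=2,
        )
    return sum(1 for b in mapped_ids if by_base.get(b, 0) >= 2)
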