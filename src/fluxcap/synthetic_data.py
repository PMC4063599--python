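"""Synthetic models, pathways and time series with planted ground truth.

The generator emulates the structure of the study design this pipeline
targets: a compartmentalized metabolic network probed through a catalogue of
linear metabolic functions, gene expression sampled over 8 environmental
conditions x 22 time points (0-24 h, densely in the first hour), and
compartment-agnostic metabolite measurements of which a known fraction maps
onto the model.  Planted truths - up/down-regulated pathways on the
expression side, low-variability substrates on the metabolite side - make
classifier sensitivity, false-positive rate and the comparison grid testable
without any external data.

Design notes
------------
* Every pathway is a linear chain with its own import exchange and terminal
  demand, an ATP/ADP couple on the first step (the cofactor exclusion list),
  a shared hub substrate on the second step (connectivity contrast), an
  occasional side substrate on the first step (so some pathways have two
  initial substrates) and an occasional byproduct (products variety).
* A constrained background network (independent gene-associated chains)
  brings the expression-constrainable reaction pool to ~620 reactions, the
  scale of a genome-scale mapping.  The pool size matters: permuting bounds
  mixes the planted down-regulated magnitudes into the null, and in a small
  pool that contamination widens the null enough to mask the planted signal.
* Metabolite series are generated at the base-compound level; the realized CV
  on the retained window (after the first six points) equals the per-compound
  target exactly by construction, up to a mild per-compound jitter.  The
  first six points carry a transient excursion, deterministic in shape and
  random in sign, so the exclusion rule has teeth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .capacity_engine import MetabolicFunction, save_functions
from .expression_mapping import ExpressionSeries, MetaboliteMapping
from .model_core import CofactorList, MetabolicModel, Reaction, Species, parse_gpr, save_model
from .null_classifier import ClassificationTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_model",
    "generate_expression",
    "generate_metabolite_series",
    "generate_all",
    "pseudo_classification",
]

CONDITIONS = ("21C-HL", "21C-NL", "21C-LL", "21C-D", "32C-L", "32C-D", "4C-L", "4C-D")
AFFECTED = ("32C-L", "32C-D", "4C-L", "4C-D")  # the temperature-stress arm


def _default_timepoints() -> tuple[float, ...]:
    # 22 points over 0-24 h; six points within the first hour
    return tuple(np.concatenate([np.linspace(0.0, 1.0, 6), np.linspace(2.0, 24.0, 16)]))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_pathways: int = 20
    pathway_length: int = 4
    n_conditions: int = 8
    n_timepoints: int = 22
    n_planted_up: int = 4
    n_planted_down: int = 4
    expression_effect: float = 5.0
    baseline_noise_sd: float = 0.3
    substrate_cv_low: float = 0.05
    other_cv: float = 0.3
    cv_jitter_sd: float = 0.15
    unmappable_fraction: float = 0.2
    n_background_chains: int = 90
    background_chain_length: int = 6
    n_hubs: int = 3
    default_flux_bound: float = 1000.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.n_planted_up + self.n_planted_down > self.n_pathways:
            raise ValueError("planted sets exceed the pathway count")
        if self.expression_effect <= 1 and not (
            self.n_planted_up == self.n_planted_down == 0 or self.expression_effect == 1
        ):
            raise ValueError("expression_effect must be >= 1")
        if self.substrate_cv_low <= 0 or self.other_cv <= 0:
            raise ValueError("CV targets must be positive")
        if not 1 <= len(self.affected_conditions) < self.n_conditions:
            raise ValueError("affected conditions must cover >=1 but not all conditions")

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.n_conditions <= len(CONDITIONS):
            return CONDITIONS[: self.n_conditions]
        return tuple(f"cond{i:02d}" for i in range(self.n_conditions))

    @property
    def affected_conditions(self) -> tuple[str, ...]:
        conds = self.conditions
        hits = tuple(c for c in conds if c in AFFECTED)
        if hits:
            return hits
        # fall back: second half of the condition list, never all of it
        half = max(1, len(conds) // 2)
        return conds[-half:] if half < len(conds) else conds[1:]

    @property
    def timepoints(self) -> tuple[float, ...]:
        if self.n_timepoints == 22:
            return _default_timepoints()
        return tuple(np.linspace(0.0, 24.0, self.n_timepoints))

    def pathway_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pathways)]

    def planted_up(self) -> frozenset[str]:
        return frozenset(self.pathway_ids()[: self.n_planted_up])

    def planted_down(self) -> frozenset[str]:
        ids = self.pathway_ids()
        return frozenset(ids[self.n_planted_up : self.n_planted_up + self.n_planted_down])


@dataclass
class GroundTruth:
    """What was planted: pathway classes and compound variability tiers."""

    pathway_class: dict[str, str]  # fn id -> up | down | none
    affected_conditions: tuple[str, ...]
    low_cv_bases: frozenset[str]
    cv_target: dict[str, float]  # base compound -> realized-CV target
    measured_bases: tuple[str, ...]

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"kind": "pathway", "id": fid, "attribute": "planted_class", "value": cls}
            for fid, cls in sorted(self.pathway_class.items())
        ]
        rows += [
            {"kind": "condition", "id": c, "attribute": "affected", "value": "true"}
            for c in self.affected_conditions
        ]
        rows += [
            {
                "kind": "compound",
                "id": base,
                "attribute": "cv_target",
                "value": f"{self.cv_target[base]:.6g}",
            }
            for base in sorted(self.cv_target)
        ]
        rows += [
            {"kind": "compound", "id": base, "attribute": "tier", "value": "low"}
            for base in sorted(self.low_cv_bases)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------

def generate_model(
    spec: SyntheticSpec,
) -> tuple[MetabolicModel, list[MetabolicFunction], CofactorList]:
    """Deterministic synthetic network + function catalogue + cofactor list."""
    L = spec.pathway_length
    species: dict[str, Species] = {}
    reactions: list[Reaction] = []
    ub = spec.default_flux_bound

    def sp(base: str, comp: str) -> str:
        sid = f"{base}_{comp}"
        if sid not in species:
            species[sid] = Species(sid, base, comp)
        return sid

    def exchange(rid: str, sid: str, direction: int) -> None:
        reactions.append(
            Reaction(rid, {sid: float(direction)}, 0.0, ub, is_exchange=True)
        )

    comps = ("c", "p")
    for comp in comps:
        exchange(f"EX_atp_{comp}", sp("atp", comp), +1)
        exchange(f"EX_adp_{comp}", sp("adp", comp), -1)
        for k in range(spec.n_hubs):
            exchange(f"EX_hub{k}_{comp}", sp(f"hub{k}", comp), +1)

    fns: list[MetabolicFunction] = []
    for i, fid in enumerate(spec.pathway_ids()):
        comp = comps[i % 2]
        chain = [sp(f"sub{i}", comp)]
        for j in range(1, L):
            chain.append(sp(f"mid{i}_{j}", comp))
        chain.append(sp(f"prod{i}", comp))
        exchange(f"EX_sub{i}", chain[0], +1)
        rids = []
        for j in range(1, L + 1):
            rid = f"R{i}_{j}"
            stoich = {chain[j - 1]: -1.0, chain[j]: 1.0}
            gpr = f"g_{rid}"
            if j == 1:
                stoich[sp("atp", comp)] = -1.0
                stoich[sp("adp", comp)] = 1.0
                if i % 4 == 1:
                    side = sp(f"side{i}", comp)
                    stoich[side] = -1.0
                    exchange(f"EX_side{i}", side, +1)
            elif j == 2:
                stoich[sp(f"hub{i % spec.n_hubs}", comp)] = -1.0
                gpr = f"g_{rid}a or g_{rid}b"
            elif j == 3:
                if i % 2 == 0:
                    gpr = f"g_{rid}a and g_{rid}b"
                if i % 3 == 0:
                    byp = sp(f"byp{i}", comp)
                    stoich[byp] = 1.0
                    exchange(f"EX_byp{i}", byp, -1)
            reactions.append(Reaction(rid, stoich, 0.0, ub, gpr=parse_gpr(gpr)))
            rids.append(rid)
        reactions.append(
            Reaction(f"DM_{fid}", {chain[-1]: -1.0}, 0.0, ub, is_exchange=True)
        )
        fns.append(
            MetabolicFunction(
                id=fid,
                reactions=tuple(rids),
                initial_reactions=(rids[0],),
                terminal_reaction=rids[-1],
                description=f"synthetic linear pathway {fid} in compartment {comp}",
            )
        )

    # constrained background chains: bring the expression-constrainable pool
    # to genome-scale proportions
    Lb = spec.background_chain_length
    for k in range(spec.n_background_chains):
        comp = comps[k % 2]
        chain = [sp(f"bg{k}_{j}", comp) for j in range(Lb + 1)]
        exchange(f"EX_bg{k}", chain[0], +1)
        for j in range(1, Lb + 1):
            rid = f"B{k}_{j}"
            reactions.append(
                Reaction(
                    rid,
                    {chain[j - 1]: -1.0, chain[j]: 1.0},
                    0.0,
                    ub,
                    gpr=parse_gpr(f"g_{rid}"),
                )
            )
        reactions.append(
            Reaction(f"DM_bg{k}", {chain[-1]: -1.0}, 0.0, ub, is_exchange=True)
        )

    model = MetabolicModel(
        list(species.values()), reactions, id=f"synthetic_{spec.n_pathways}p_{spec.seed}"
    )
    cofactors = CofactorList(frozenset({"atp", "adp"}))
    return model, fns, cofactors


def _pathway_genes(model: MetabolicModel, fn: MetabolicFunction) -> frozenset[str]:
    genes: set[str] = set()
    for rid in fn.reactions:
        rxn = model.reactions[model.reaction_index[rid]]
        if rxn.gpr is not None:
            genes |= rxn.gpr.genes()
    return frozenset(genes)


def _truth_skeleton(spec: SyntheticSpec) -> GroundTruth:
    cls = {fid: "none" for fid in spec.pathway_ids()}
    for fid in spec.planted_up():
        cls[fid] = "up"
    for fid in spec.planted_down():
        cls[fid] = "down"
    return GroundTruth(
        pathway_class=cls,
        affected_conditions=spec.affected_conditions,
        low_cv_bases=frozenset(),
        cv_target={},
        measured_bases=(),
    )


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def generate_expression(
    spec: SyntheticSpec,
    model: MetabolicModel,
    fns: list[MetabolicFunction],
    truth: GroundTruth,
) -> ExpressionSeries:
    """Log-normal expression with the planted pathway effects applied.

    Baseline values are ``exp(N(0, baseline_noise_sd))`` independently per
    gene, condition and time point; all genes of a planted-up pathway are
    multiplied (planted-down: divided) by ``expression_effect`` in the
    affected conditions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    genes = list(model.gene_ids)
    conds = spec.conditions
    times = spec.timepoints
    n = len(conds) * len(times)
    values = np.exp(rng.normal(0.0, spec.baseline_noise_sd, size=(n, len(genes))))
    index = pd.MultiIndex.from_product([conds, times], names=["condition", "time"])
    df = pd.DataFrame(values, index=index, columns=genes)

    gene_idx = {g: k for k, g in enumerate(genes)}
    affected_rows = df.index.get_level_values(0).isin(truth.affected_conditions)
    for fn in fns:
        cls = truth.pathway_class.get(fn.id, "none")
        if cls == "none":
            continue
        factor = spec.expression_effect if cls == "up" else 1.0 / spec.expression_effect
        cols = [gene_idx[g] for g in sorted(_pathway_genes(model, fn))]
        df.iloc[affected_rows, cols] *= factor
    return ExpressionSeries(df)


# ---------------------------------------------------------------------------
# metabolite series generation
# ---------------------------------------------------------------------------

def _standardized(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    return (z - z.mean()) / z.std(ddof=1)


def generate_metabolite_series(
    spec: SyntheticSpec,
    model: MetabolicModel,
    fns: list[MetabolicFunction],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, MetaboliteMapping, GroundTruth]:
    """Measured metabolite table + mapping dictionary + completed truth.

    Substrates of planted pathways receive the low-CV tier, every other
    measured compound the high tier; on the retained window (after the first
    six points) the realized CV matches each compound's jittered target
    exactly by construction.  A configurable fraction of measurements is
    unmappable (absent from the dictionary).
    """
    from .metabolite_roles import pathway_roles  # deferred: avoids import cycle

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    cofactors = CofactorList(frozenset({"atp", "adp"}))
    roles = {fn.id: pathway_roles(fn, model, cofactors) for fn in fns}

    planted = {f for f, c in truth.pathway_class.items() if c != "none"}
    low_bases: set[str] = set()
    for fid in planted:
        low_bases |= set(roles[fid].bases_with_role(model, "substrate"))

    measured: list[str] = []
    seen: set[str] = set()

    def add(base: str) -> None:
        if base not in seen:
            seen.add(base)
            measured.append(base)

    for fid in sorted(roles):
        ra = roles[fid]
        for base in sorted(ra.bases_with_role(model, "substrate")):
            add(base)
        for base in sorted(ra.bases_with_role(model, "product")):
            add(base)
    for i in range(0, spec.n_pathways, 4):  # a sample of intermediates
        ra = roles[f"P{i + 1:02d}"]
        for base in sorted(ra.bases_with_role(model, "intermediate"))[:2]:
            add(base)

    n_mapped = len(measured)
    n_unmappable = int(round(
        spec.unmappable_fraction / (1.0 - spec.unmappable_fraction) * n_mapped
    )) if spec.unmappable_fraction > 0 else 0

    conds = spec.conditions
    times = np.asarray(spec.timepoints)
    n_t = len(times)
    k_trans = min(6, n_t - 2)  # transient window = first hour
    index = pd.MultiIndex.from_product([conds, times], names=["condition", "time"])

    cv_target: dict[str, float] = {}
    cols: dict[str, np.ndarray] = {}

    def make_series(cv: float) -> np.ndarray:
        mu = float(np.exp(rng.normal(0.0, 0.5)))
        out = np.empty(len(conds) * n_t)
        for ci in range(len(conds)):
            block = np.empty(n_t)
            zr = _standardized(rng, n_t - k_trans)
            block[k_trans:] = mu * (1.0 + cv * zr)
            sign = rng.choice([-1.0, 1.0])
            excursion = 0.5 * np.exp(-np.arange(k_trans) / 1.5)
            block[:k_trans] = mu * (
                1.0 + cv * rng.standard_normal(k_trans) + sign * excursion
            )
            out[ci * n_t : (ci + 1) * n_t] = block
        return np.maximum(out, 0.05 * mu)

    mapping_pairs: dict[str, frozenset[str]] = {}
    for base in measured:
        tier = spec.substrate_cv_low if base in low_bases else spec.other_cv
        cv = tier * float(np.exp(rng.normal(0.0, spec.cv_jitter_sd)))
        cv_target[base] = cv
        name = f"m_{base}"
        cols[name] = make_series(cv)
        mapping_pairs[name] = frozenset({base})
    for k in range(n_unmappable):
        cv = spec.other_cv * float(np.exp(rng.normal(0.0, spec.cv_jitter_sd)))
        cols[f"x_unknown{k}"] = make_series(cv)

    series = pd.DataFrame(cols, index=index)
    mapping = MetaboliteMapping(mapping_pairs)
    completed = GroundTruth(
        pathway_class=truth.pathway_class,
        affected_conditions=truth.affected_conditions,
        low_cv_bases=frozenset(low_bases & seen),
        cv_target=cv_target,
        measured_bases=tuple(measured),
    )
    return series, mapping, completed


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    model: MetabolicModel
    functions: list[MetabolicFunction]
    cofactors: CofactorList
    expression: ExpressionSeries
    metabolites: pd.DataFrame
    mapping: MetaboliteMapping
    truth: GroundTruth

    def write(self, outdir: str | Path, sbml: bool = False) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": outdir / "model.json",
            "functions": outdir / "functions.yaml",
            "expression": outdir / "expression.tsv",
            "metabolites": outdir / "metabolites.tsv",
            "mapping": outdir / "mapping.tsv",
            "cofactors": outdir / "cofactors.tsv",
            "truth": outdir / "truth.tsv",
        }
        save_model(self.model, paths["model"], dialect="json")
        if sbml:
            paths["model_sbml"] = outdir / "model.xml"
            save_model(self.model, paths["model_sbml"], dialect="sbml")
        save_functions(self.functions, paths["functions"])
        self.expression.to_tsv(paths["expression"])
        long = (
            self.metabolites.stack()
            .rename("value")
            .rename_axis(["condition", "time", "feature"])
            .reset_index()
        )
        long.to_csv(paths["metabolites"], sep="\t", index=False, float_format="%.10g")
        self.mapping.to_tsv(paths["mapping"])
        self.cofactors.to_tsv(paths["cofactors"])
        self.truth.to_tsv(paths["truth"])
        return paths


def generate_all(spec: SyntheticSpec) -> SyntheticDataset:
    """Model, functions, expression and metabolite data from one seed."""
    model, fns, cofactors = generate_model(spec)
    truth = _truth_skeleton(spec)
    expr = generate_expression(spec, model, fns, truth)
    series, mapping, truth = generate_metabolite_series(spec, model, fns, truth)
    return SyntheticDataset(spec, model, fns, cofactors, expr, series, mapping, truth)


# ---------------------------------------------------------------------------
# calibration harness
# ---------------------------------------------------------------------------

def pseudo_classification(
    fns: list[MetabolicFunction],
    conditions: tuple[str, ...],
    rng: np.random.Generator,
    rate: float = 0.25,
) -> ClassificationTable:
    """Random pathway labels for null-calibration studies of the grid.

    Each (pathway, condition) cell is independently labelled modulator or
    sustainer with probability ``rate/2`` each; the standard differential
    filter is applied.  Under data with no planted variability structure the
    grid's significance rate against such labels estimates the test size.
    """
    fids = [fn.id for fn in fns]
    draws = rng.random((len(fids), len(conditions)))
    labels = np.where(
        draws < rate / 2, "modulator", np.where(draws < rate, "sustainer", "none")
    )
    label_df = pd.DataFrame(labels, index=fids, columns=list(conditions))
    mean_z = pd.DataFrame(0.0, index=fids, columns=list(conditions))
    n_hit = (label_df != "none").sum(axis=1)
    differential = (n_hit >= 1) & (n_hit < len(conditions))
    return ClassificationTable(label_df, mean_z, differential)
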