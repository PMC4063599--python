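"""End-to-end runs: configuration, artifact emission, provenance, sensitivity.

A run executes capacity computation -> permutation null + classification ->
role assignment -> CV comparison grid -> topology statistics, writing every
table as TSV with a header comment carrying the config hash and seed, plus a
JSON provenance manifest.  Re-running with an identical configuration
reproduces identical outputs (all stochastic stages are seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity_engine import CapacityProfile, load_functions
from .expression_mapping import ExpressionSeries, MetaboliteMapping
from .metabolite_roles import (
    build_groupings,
    connectivity_stats,
    pathway_roles,
    substrate_count_stats,
)
from .model_core import CofactorList, load_model
from .null_classifier import NullConfig, classify, run_null_classification
from .variability_stats import (
    capacity_cv_comparison,
    cv_comparison_grid,
    cv_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "sensitivity_exclusion"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    model: str
    functions: str
    expression: str
    metabolites: str
    mapping: str
    cofactors: str
    output_dir: str = "fluxcap_run"
    seed: int = 0
    v_cap: float = 1000.0
    exclude_first_k: int = 6
    repetitions: int = 100
    z_threshold: float = 2.0
    classification_exclude_k: int = 0
    missing_gene_mode: str = "absent"  # or "zero"
    summary: str = "signed_mean"  # or "mean_abs"
    strict_threshold: bool = True
    exclusive_groups: bool = True
    paired_capacity_test: bool = False
    backend: str = "auto"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def null_config(self) -> NullConfig:
        return NullConfig(
            repetitions=self.repetitions,
            seed=self.seed,
            z_threshold=self.z_threshold,
            summary=self.summary,
            strict=self.strict_threshold,
        )

    def validate(self) -> None:
        for key in ("model", "functions", "expression", "metabolites", "mapping", "cofactors"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise PipelineError(f"config: {key} path does not exist: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the artifact set.

    Returns the in-memory results keyed by artifact name.  A stage failure
    raises :class:`PipelineError` naming the stage; artifacts written before
    the failure are retained and a ``FAILED`` marker file records the stage.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"fluxcap {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}"
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()

    stage = "load"
    t0 = time.time()
    try:
        model = load_model(cfg.model)
        fns = load_functions(cfg.functions)
        for fn in fns:
            fn.validate(model)
        expr = ExpressionSeries.from_tsv(cfg.expression)
        metab = pd.read_csv(cfg.metabolites, sep="\t", comment="#")
        metab = metab.pivot_table(
            index=["condition", "time"], columns="feature", values="value"
        )
        mapping = MetaboliteMapping.from_tsv(cfg.mapping)
        cofactors = CofactorList.from_tsv(cfg.cofactors)

        stage = "capacities_and_classification"
        observed, ztab, classification = run_null_classification(
            model,
            expr,
            fns,
            cfg.null_config(),
            cfg.v_cap,
            missing_gene_mode=cfg.missing_gene_mode,
            exclude_first_k=cfg.classification_exclude_k,
            backend=cfg.backend,
        )
        observed.to_tsv(outdir / "capacities.tsv", header_comment=header)
        _write_tsv(ztab.to_frame(), outdir / "zscores.tsv", header)
        _write_tsv(classification.to_frame(), outdir / "classification.tsv", header)
        logger.info("classification done in %.1f s", time.time() - t0)

        stage = "roles"
        roles = {fn.id: pathway_roles(fn, model, cofactors) for fn in fns}
        role_rows = [row for ra in roles.values() for row in ra.to_rows()]
        _write_tsv(pd.DataFrame(role_rows), outdir / "roles.tsv", header)
        substrate_stats = substrate_count_stats(fns, roles, classification)
        _write_tsv(substrate_stats.to_frame(), outdir / "substrate_stats.tsv", header)

        stage = "cv_grid"
        cvs = cv_table(metab, exclude_first_k=cfg.exclude_first_k)
        _write_tsv(cvs, outdir / "cv_metabolites.tsv", header)
        groupings = {
            cond: build_groupings(
                roles, classification, mapping, cond, model,
                exclusive=cfg.exclusive_groups,
            )
            for cond in expr.conditions
        }
        sizes = pd.concat([g.sizes() for g in groupings.values()], ignore_index=True)
        _write_tsv(sizes, outdir / "group_sizes.tsv", header)
        grid = cv_comparison_grid(cvs, groupings, mapping)
        _write_tsv(grid, outdir / "cv_grid.tsv", header)
        cap_cmp = capacity_cv_comparison(
            observed,
            classification,
            roles,
            cvs,
            mapping,
            model,
            exclude_first_k=cfg.exclude_first_k,
            paired=cfg.paired_capacity_test,
        )
        _write_tsv(cap_cmp, outdir / "capacity_cv_comparison.tsv", header)

        stage = "topology"
        topo = connectivity_stats(model, cofactors, roles, classification, mapping)
        _write_tsv(topo.to_frame(), outdir / "topology.tsv", header)

        stage = "manifest"
        manifest = {
            "package": "fluxcap",
            "version": __version__,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "wall_time_s": round(time.time() - t0, 2),
            "artifacts": sorted(
                p.name for p in outdir.iterdir() if p.suffix in (".tsv",)
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except PipelineError:
        marker.write_text(stage)
        raise
    except Exception as exc:
        marker.write_text(stage)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "model": model,
        "functions": fns,
        "observed": observed,
        "zscores": ztab,
        "classification": classification,
        "roles": roles,
        "substrate_stats": substrate_stats,
        "cv_table": cvs,
        "groupings": groupings,
        "grid": grid,
        "capacity_cv_comparison": cap_cmp,
        "topology": topo,
    }


def sensitivity_exclusion(
    ztab, cfg: NullConfig, k_values: list[int]
) -> pd.DataFrame:
    """Classification agreement as the leading exclusion window varies.

    Re-labels from the same z-score grid with each ``k`` and reports, against
    the k = 0 labelling, the fraction of identical pathway x condition labels.
    The z-scores themselves do not depend on k, so no LP is re-solved.
    """
    n_t = len(ztab.timepoints)
    for k in k_values:
        if k >= n_t - 1:
            raise ValueError(f"k={k} leaves fewer than 2 of {n_t} time points")
    base = classify(ztab, cfg, exclude_first_k=0)
    rows = []
    for k in sorted(set(k_values)):
        alt = classify(ztab, cfg, exclude_first_k=k)
        agree = float((alt.labels.values == base.labels.values).mean())
        rows.append(
            {
                "exclude_first_k": k,
                "agreement_vs_k0": agree,
                "n_differential": int(alt.differential.sum()),
            }
        )
    return pd.DataFrame(rows)
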