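"""Boundary-permutation null model, z-scores, modulator/sustainer calls.

The null model permutes the expression-derived upper-bound magnitudes
uniformly at random among the constrained reactions while leaving exchange
reactions and unconstrained reactions untouched; each reaction re-imposes its
own directionality pattern on the magnitude it receives (irreversible: lower
stays 0; reversible: lower = -upper).  This keeps thermodynamic and exchange
constraints unaltered and asks how much of an observed capacity is explained
by the multiset of bounds alone rather than by their placement on the network.

Observed capacities are scored as z = (observed - null mean) / null sd per
function, condition and time point (null summaries over ``repetitions``
independent permutations, default 100).  A function is a *sustainer* in a
condition when its signed mean z over retained time points exceeds the
threshold (+2 by default), a *modulator* below -threshold, and *differential*
when classified in at least one but not all conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capacity_engine import CapacityProfile, CapacitySolver, MetabolicFunction
from .expression_mapping import BoundsSet, ExpressionSeries, expression_to_bounds
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "ZScoreTable",
    "ClassificationTable",
    "permute_bounds",
    "null_distribution",
    "z_scores",
    "classify",
    "run_null_classification",
]

LABELS = ("none", "sustainer", "modulator")


@dataclass(frozen=True)
class NullConfig:
    """Null-model and classification settings.

    ``repetitions`` permutations per condition x time point (>= 2 so a sample
    standard deviation exists); one master ``seed`` with per-(condition, time)
    substreams.  ``summary`` selects the per-condition statistic: the signed
    mean of z over retained time points (default; sign distinguishes sustainer
    from modulator) or ``"mean_abs"`` (mean |z|, direction taken from the
    signed mean).  The threshold comparison is strict by default.
    """

    repetitions: int = 100
    seed: int = 0
    permutation_scope: str = "constrained_only"
    z_threshold: float = 2.0
    summary: str = "signed_mean"
    strict: bool = True

    def __post_init__(self) -> None:
        if self.repetitions < 2:
            raise ValueError("repetitions must be >= 2 (a standard deviation must exist)")
        if self.permutation_scope != "constrained_only":
            raise ValueError(f"unknown permutation scope {self.permutation_scope!r}")
        if self.summary not in ("signed_mean", "mean_abs"):
            raise ValueError(f"unknown summary statistic {self.summary!r}")


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG substream for a (condition, time) cell.

    Derived by counter from the master seed so cell results do not depend on
    evaluation order.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# permutation
# ---------------------------------------------------------------------------

def permute_bounds(bounds: BoundsSet, rng: np.random.Generator) -> BoundsSet:
    """Permute expression-derived upper-bound magnitudes among constrained reactions.

    The multiset of constrained upper bounds is conserved exactly; every
    reaction keeps its own reversibility pattern (exchange and unconstrained
    reactions are untouched).
    """
    idx = np.flatnonzero(bounds.constrained)
    if idx.size == 0:
        raise ValueError("no constrained reactions: nothing to permute")
    out = bounds.copy()
    mags = out.upper[idx]
    perm = rng.permutation(idx.size)
    out.upper[idx] = mags[perm]
    out.lower[idx] = np.where(bounds.reversible[idx], -out.upper[idx], 0.0)
    return out


def null_distribution(
    model: MetabolicModel,
    bounds: BoundsSet,
    fns: list[MetabolicFunction],
    cfg: NullConfig,
    rng: np.random.Generator,
    solver: CapacitySolver | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null mean/sd of each function's capacity for one condition x time slice.

    Draws ``cfg.repetitions`` independent permutations and recomputes all
    function capacities for each.  Returns (mean, sd, n_success) per function;
    per-repetition LP errors are logged and the affected repetition is dropped
    for that function.  A function with fewer than 2 successful repetitions
    gets NaN summaries (degenerate).
    """
    solver = solver or CapacitySolver(model, fns)
    samples = np.full((cfg.repetitions, len(fns)), np.nan)
    for r in range(cfg.repetitions):
        permuted = permute_bounds(bounds, rng)
        vals, stats = solver.capacities(permuted)
        bad = [s for s in stats if s != "optimal"]
        if bad:
            logger.warning("null repetition %d: %d non-optimal cells", r, len(bad))
        samples[r] = vals
    n_success = np.sum(~np.isnan(samples), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(samples, axis=0)
        sd = np.nanstd(samples, axis=0, ddof=1)
    mean[n_success < 2] = np.nan
    sd[n_success < 2] = np.nan
    return mean, sd, n_success


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

@dataclass
class ZScoreTable:
    """z-scores plus null summaries on a function x condition x time grid."""

    function_ids: list[str]
    conditions: list[str]
    timepoints: np.ndarray
    z: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    degenerate: np.ndarray  # bool

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
                            "z": self.z[a, b, c],
                            "null_mean": self.null_mean[a, b, c],
                            "null_sd": self.null_sd[a, b, c],
                            "degenerate": bool(self.degenerate[a, b, c]),
                        }
                    )
        return pd.DataFrame(rows)


def z_scores(
    observed: CapacityProfile,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    sd_floor_rel: float = 1e-8,
) -> ZScoreTable:
    """z = (observed - null mean) / max(null sd, floor) per cell.

    The floor is ``sd_floor_rel * (1 + |null mean|)``; it prevents infinite z
    on permutation-invariant cells.  Cells where the null sd sits at or below
    the floor are flagged degenerate; such a cell additionally gets z = 0 when
    the observed value equals the null mean to within the floor.
    """
    if null_mean.shape != observed.values.shape or null_sd.shape != observed.values.shape:
        raise ValueError("null summary grids do not match the observed capacity grid")
    floor = sd_floor_rel * (1.0 + np.abs(null_mean))
    degenerate = ~(null_sd > floor)
    denom = np.maximum(null_sd, floor)
    diff = observed.values - null_mean
    with np.errstate(invalid="ignore"):
        z = diff / denom
    z = np.where(degenerate & (np.abs(diff) <= floor), 0.0, z)
    return ZScoreTable(
        observed.function_ids,
        observed.conditions,
        observed.timepoints,
        z,
        null_mean,
        null_sd,
        degenerate,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationTable:
    """Per-(function, condition) labels and the global differential filter."""

    labels: pd.DataFrame  # function x condition, values in LABELS
    mean_z: pd.DataFrame  # function x condition
    differential: pd.Series  # function -> bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid in self.labels.index:
            for cond in self.labels.columns:
                rows.append(
                    {
                        "function": fid,
                        "condition": cond,
                        "label": self.labels.loc[fid, cond],
                        "mean_z": self.mean_z.loc[fid, cond],
                        "differential": bool(self.differential[fid]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClassificationTable":
        labels = df.pivot(index="function", columns="condition", values="label")
        mean_z = df.pivot(index="function", columns="condition", values="mean_z")
        differential = df.groupby("function")["differential"].first().astype(bool)
        return cls(labels, mean_z, differential.reindex(labels.index))


def classify(
    z: ZScoreTable, cfg: NullConfig, exclude_first_k: int = 0
) -> ClassificationTable:
    """Label each function per condition and apply the global differential filter.

    The per-condition statistic m is the mean of z over retained time points
    (the first ``exclude_first_k`` dropped).  m above the threshold marks a
    sustainer, below -threshold a modulator, else none; a function is
    *differential* when labelled non-none in at least one but not all
    conditions.
    """
    n_t = len(z.timepoints)
    if exclude_first_k >= n_t - 1:
        raise ValueError(
            f"exclude_first_k={exclude_first_k} leaves fewer than 2 of {n_t} time points"
        )
    zz = z.z[:, :, exclude_first_k:]
    with np.errstate(invalid="ignore"):
        m = np.nanmean(zz, axis=2)
        m_abs = np.nanmean(np.abs(zz), axis=2)
    thr = cfg.z_threshold
    if cfg.summary == "signed_mean":
        magnitude = np.abs(m)
    else:
        magnitude = m_abs
    if cfg.strict:
        hit = magnitude > thr
    else:
        hit = magnitude >= thr
    up = hit & (m > 0)
    down = hit & (m < 0)
    labels = np.where(up, "sustainer", np.where(down, "modulator", "none"))
    label_df = pd.DataFrame(labels, index=z.function_ids, columns=z.conditions)
    mean_df = pd.DataFrame(m, index=z.function_ids, columns=z.conditions)
    n_hit = (label_df != "none").sum(axis=1)
    differential = (n_hit >= 1) & (n_hit < len(z.conditions))
    return ClassificationTable(label_df, mean_df, differential)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_null_classification(
    model: MetabolicModel,
    expr: ExpressionSeries,
    fns: list[MetabolicFunction],
    cfg: NullConfig,
    v_cap: float,
    missing_gene_mode: str = "absent",
    exclude_first_k: int = 0,
    backend: str = "auto",
) -> tuple[CapacityProfile, ZScoreTable, ClassificationTable]:
    """Observed capacities, permutation null, z-scores and labels in one pass.

    Permutations are drawn independently per condition and time point from
    substreams of ``cfg.seed``, so any cell can be recomputed in isolation.
    """
    solver = CapacitySolver(model, fns, backend=backend)
    conds, times = expr.conditions, expr.timepoints
    shape = (len(fns), len(conds), len(times))
    obs_values = np.full(shape, np.nan)
    obs_status = np.full(shape, "missing", dtype=object)
    nmean = np.full(shape, np.nan)
    nsd = np.full(shape, np.nan)
    for b, cond in enumerate(conds):
        for c, t in enumerate(times):
            bounds = expression_to_bounds(
                model, expr.slice(cond, t), v_cap, missing_gene_mode
            )
            vals, stats = solver.capacities(bounds)
            obs_values[:, b, c] = vals
            obs_status[:, b, c] = stats
            rng = substream(cfg.seed, b, c)
            mu, sd, _ = null_distribution(model, bounds, fns, cfg, rng, solver=solver)
            nmean[:, b, c] = mu
            nsd[:, b, c] = sd
        logger.info(
            "null model: condition %s done (%d permutations x %d time points)",
            cond,
            cfg.repetitions,
            len(times),
        )
    observed = CapacityProfile(
        [fn.id for fn in fns], list(conds), np.asarray(times, dtype=float),
        obs_values, obs_status,
    )
    ztab = z_scores(observed, nmean, nsd)
    table = classify(ztab, cfg, exclude_first_k=exclude_first_k)
    return observed, ztab, table
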