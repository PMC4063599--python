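"""Temporal coefficients of variation and the Wilcoxon comparison grid.

Temporal variability of a profile is its coefficient of variation
CV = sigma/mu (sample standard deviation over mean), computed per condition
after dropping the first ``exclude_first_k`` time points (the immediate
perturbation response; six points = the first hour on the study's sampling
grid).  Group differences in CV are assessed with one-sided Wilcoxon rank-sum
tests at alpha = 0.05, with no multiple-testing correction for the headline
calls (a Benjamini-Hochberg column is emitted alongside for transparency).

The comparison grid crosses three metabolite categorizations (any role,
products only, substrates only) with six group comparisons (modulator /
sustainer / differential, each vs all measured metabolites and vs its
complement) under every condition: 3 x 6 x 8 = 144 tests for an
eight-condition design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .capacity_engine import CapacityProfile
    from .metabolite_roles import MetaboliteGrouping, RoleAssignment
    from .null_classifier import ClassificationTable

__all__ = [
    "CVResult",
    "RankSumResult",
    "coefficient_of_variation",
    "cv_table",
    "rank_sum_test",
    "COMPARISONS",
    "cv_comparison_grid",
    "capacity_cv_table",
    "capacity_cv_comparison",
    "benjamini_hochberg",
]

ALPHA = 0.05

COMPARISONS = (
    ("in_modulator", "all_measured"),
    ("in_sustainer", "all_measured"),
    ("in_differential", "all_measured"),
    ("in_modulator", "in_non_modulator"),
    ("in_sustainer", "in_non_sustainer"),
    ("in_differential", "in_non_differential"),
)


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    value: float  # NaN when undefined
    n_used: int
    mean: float
    sd: float
    reason: str | None = None  # why undefined


def coefficient_of_variation(
    series: Sequence[float], exclude_first_k: int = 0
) -> CVResult:
    """CV = sample sd / mean after dropping the first ``exclude_first_k`` points.

    Undefined (NaN value with a reason) when fewer than 2 points remain or the
    retained mean is not positive; undefined cells are flagged, never silently
    dropped by callers.
    """
    vals = np.asarray(series, dtype=float)[exclude_first_k:]
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n < 2:
        return CVResult(float("nan"), n, float("nan"), float("nan"), "too_few_points")
    mu = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if mu <= 0:
        return CVResult(float("nan"), n, mu, sd, "nonpositive_mean")
    if sd <= 1e-12 * abs(mu):  # constant series up to round-off
        return CVResult(0.0, n, mu, sd, None)
    return CVResult(sd / mu, n, mu, sd, None)


def cv_table(series: pd.DataFrame, exclude_first_k: int = 0) -> pd.DataFrame:
    """Per-(feature, condition) CV of a (condition, time)-indexed wide table."""
    rows = []
    for cond in series.index.get_level_values(0).unique():
        block = series.loc[cond]
        for feature in series.columns:
            res = coefficient_of_variation(block[feature].to_numpy(), exclude_first_k)
            rows.append(
                {
                    "feature": feature,
                    "condition": cond,
                    "cv": res.value,
                    "n_timepoints_used": res.n_used,
                    "mean": res.mean,
                    "sd": res.sd,
                    "reason": res.reason,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    p: float  # NaN when not applicable
    n_a: int
    n_b: int
    na_reason: str | None = None


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], alternative: str = "a_less"
) -> RankSumResult:
    """One-sided Wilcoxon rank-sum p-value for "a stochastically smaller than b".

    Exact null distribution when the smaller sample has <= 8 members and the
    data are tie-free; otherwise the normal approximation with tie correction.
    Samples with fewer than 2 members yield NA (the grid's too-small rule).
    ``alternative="two_sided"`` is available behind the flag.
    """
    a = np.asarray([x for x in a if not np.isnan(x)], dtype=float)
    b = np.asarray([x for x in b if not np.isnan(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        return RankSumResult(float("nan"), len(a), len(b), "sample_too_small")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(a), len(b)) <= 8) and not has_ties
    alt = {"a_less": "less", "two_sided": "two-sided"}[alternative]
    res = sps.mannwhitneyu(
        a, b, alternative=alt, method="exact" if exact else "asymptotic"
    )
    return RankSumResult(float(res.pvalue), len(a), len(b), None)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values; NaNs pass through unadjusted."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# the comparison grid
# ---------------------------------------------------------------------------

def _cv_lookup(
    cvs: pd.DataFrame, mapping, condition: str
) -> tuple[dict[str, float], dict[str, set[str]]]:
    """Measurement-level CVs for one condition plus a base->measurements index."""
    block = cvs[cvs["condition"] == condition]
    cv_by_meas = {
        row.feature: row.cv for row in block.itertuples() if not np.isnan(row.cv)
    }
    by_base: dict[str, set[str]] = {}
    for name, bases in mapping.pairs.items():
        for base in bases:
            by_base.setdefault(base, set()).add(name)
    return cv_by_meas, by_base


def cv_comparison_grid(
    cvs: pd.DataFrame,
    groupings: "dict[str, MetaboliteGrouping]",
    mapping,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One-sided rank-sum tests of group CVs across the full grid.

    ``cvs`` is a :func:`cv_table` result over the measured metabolite series;
    ``groupings`` maps condition -> membership sets (base-compound level).  A
    base compound's CV sample is the CVs of the measurements mapped to it.
    Rows: categorization x comparison x condition, with group sizes, p-value,
    significance at ``alpha``, NA reason codes and a BH column.
    """
    from .metabolite_roles import CATEGORIZATIONS

    rows = []
    for cond, grouping in groupings.items():
        cv_by_meas, by_base = _cv_lookup(cvs, mapping, cond)

        def group_cvs(members: frozenset[str]) -> list[float]:
            out = []
            for base in sorted(members):
                for meas in sorted(by_base.get(base, ())):
                    if meas in cv_by_meas:
                        out.append(cv_by_meas[meas])
            return out

        for cat in CATEGORIZATIONS:
            for group_name, ref_name in COMPARISONS:
                gvals = group_cvs(grouping.sets[(cat, group_name)])
                rvals = group_cvs(grouping.sets[(cat, ref_name)])
                res = rank_sum_test(gvals, rvals, alternative="a_less")
                rows.append(
                    {
                        "categorization": cat,
                        "comparison": f"{group_name}_vs_{ref_name}",
                        "condition": cond,
                        "n_group": res.n_a,
                        "n_reference": res.n_b,
                        "p": res.p,
                        "significant": bool(res.p < alpha) if not np.isnan(res.p) else False,
                        "na_reason": res.na_reason,
                    }
                )
    grid = pd.DataFrame(rows)
    grid["bh_q"] = benjamini_hochberg(grid["p"])
    return grid


# ---------------------------------------------------------------------------
# capacity-profile CVs
# ---------------------------------------------------------------------------

def capacity_cv_table(
    capacities: "CapacityProfile", exclude_first_k: int = 0
) -> pd.DataFrame:
    """Per-(function, condition) CV of the flux-capacity time profiles.

    The same exclusion window is applied to capacity series as to metabolite
    series, for comparability.
    """
    rows = []
    for a, fid in enumerate(capacities.function_ids):
        for b, cond in enumerate(capacities.conditions):
            res = coefficient_of_variation(
                capacities.values[a, b, :], exclude_first_k
            )
            rows.append(
                {
                    "feature": fid,
                    "condition": cond,
                    "cv": res.value,
                    "n_timepoints_used": res.n_used,
                    "mean": res.mean,
                    "sd": res.sd,
                    "reason": res.reason,
                }
            )
    return pd.DataFrame(rows)


def capacity_cv_comparison(
    capacities: "CapacityProfile",
    classification: "ClassificationTable",
    roles: "dict[str, RoleAssignment]",
    metabolite_cvs: pd.DataFrame,
    mapping,
    model,
    exclude_first_k: int = 0,
    alpha: float = ALPHA,
    paired: bool = False,
) -> pd.DataFrame:
    """Capacity-CV contrasts per condition.

    (i) capacity-profile CVs of differential vs non-differential pathways
    (one-sided: differential lower); (ii) CVs of measured substrates vs the
    capacity-profile CVs of the pathways they feed (one-sided: substrates
    lower; rank-sum by default, signed-rank on pairs with ``paired=True``).
    """
    cap_cvs = capacity_cv_table(capacities, exclude_first_k)
    diff_ids = set(classification.differential[classification.differential].index)
    rows = []
    for cond in capacities.conditions:
        block = cap_cvs[cap_cvs["condition"] == cond]
        cap_by_fn = {
            row.feature: row.cv for row in block.itertuples() if not np.isnan(row.cv)
        }
        diff_vals = [v for f, v in cap_by_fn.items() if f in diff_ids]
        non_vals = [v for f, v in cap_by_fn.items() if f not in diff_ids]
        res_i = rank_sum_test(diff_vals, non_vals, alternative="a_less")

        cv_by_meas, by_base = _cv_lookup(metabolite_cvs, mapping, cond)
        sub_vals: list[float] = []
        fn_vals: list[float] = []
        for fid, ra in roles.items():
            if fid not in cap_by_fn:
                continue
            measured_subs = []
            for base in sorted(ra.bases_with_role(model, "substrate")):
                for meas in sorted(by_base.get(base, ())):
                    if meas in cv_by_meas:
                        measured_subs.append(cv_by_meas[meas])
            for v in measured_subs:
                sub_vals.append(v)
                fn_vals.append(cap_by_fn[fid])
        if paired and len(sub_vals) >= 2:
            diffs = np.asarray(sub_vals) - np.asarray(fn_vals)
            if np.all(diffs == 0):
                res_ii = RankSumResult(float("nan"), len(sub_vals), len(fn_vals), "all_ties")
            else:
                p = float(sps.wilcoxon(sub_vals, fn_vals, alternative="less").pvalue)
                res_ii = RankSumResult(p, len(sub_vals), len(fn_vals), None)
        else:
            res_ii = rank_sum_test(sub_vals, fn_vals, alternative="a_less")
        rows.append(
            {
                "condition": cond,
                "n_differential": res_i.n_a,
                "n_non_differential": res_i.n_b,
                "p_capacity_cv_diff_lower": res_i.p,
                "na_reason_i": res_i.na_reason,
                "n_substrate_cvs": res_ii.n_a,
                "p_substrate_cv_lower_than_capacity": res_ii.p,
                "na_reason_ii": res_ii.na_reason,
                "significant_i": bool(res_i.p < alpha) if not np.isnan(res_i.p) else False,
                "significant_ii": bool(res_ii.p < alpha) if not np.isnan(res_ii.p) else False,
            }
        )
    return pd.DataFrame(rows)
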