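"""Boundary-permutation null model, z-scores and modulator/sustainer calls."""

import numpy as np
import pandas as pd
import pytest

from fluxcap.capacity_engine import CapacityProfile
from fluxcap.expression_mapping import BoundsSet, expression_to_bounds
from fluxcap.null_classifier import (
    NullConfig,
    ZScoreTable,
    classify,
    null_distribution,
    permute_bounds,
    run_null_classification,
    substream,
    z_scores,
)
from fluxcap.synthetic_data import SyntheticSpec, generate_all


def make_bounds(n=10, n_constrained=6, seed=0, reversible_every=3):
    rng = np.random.default_rng(seed)
    upper = rng.uniform(1, 10, n)
    constrained = np.zeros(n, dtype=bool)
    constrained[:n_constrained] = True
    reversible = np.arange(n) % reversible_every == 0
    lower = np.where(reversible, -upper, 0.0)
    return BoundsSet([f"R{i}" for i in range(n)], lower, upper, constrained, reversible)


class _IdentityRng:
    """Stub rng whose permutation is always the identity."""

    def permutation(self, n):
        return np.arange(n)


class TestPermuteBounds:
    def test_identity_permutation_is_noop(self):
        bounds = make_bounds()
        out = permute_bounds(bounds, _IdentityRng())
        assert np.array_equal(out.upper, bounds.upper)
        assert np.array_equal(out.lower, bounds.lower)

    def test_conserves_bound_multiset(self):
        bounds = make_bounds()
        rng = np.random.default_rng(42)
        out = permute_bounds(bounds, rng)
        idx = bounds.constrained
        assert np.array_equal(np.sort(out.upper[idx]), np.sort(bounds.upper[idx]))
        # untouched elsewhere
        assert np.array_equal(out.upper[~idx], bounds.upper[~idx])
        assert np.array_equal(out.lower[~idx], bounds.lower[~idx])

    def test_reversibility_pattern_reimposed(self):
        bounds = make_bounds()
        out = permute_bounds(bounds, np.random.default_rng(1))
        idx = np.flatnonzero(bounds.constrained)
        for j in idx:
            if bounds.reversible[j]:
                assert out.lower[j] == -out.upper[j]
            else:
                assert out.lower[j] == 0.0

    def test_no_constrained_reactions_raises(self):
        bounds = make_bounds(n_constrained=0)
        with pytest.raises(ValueError, match="nothing to permute"):
            permute_bounds(bounds, np.random.default_rng(0))


class TestNullDistribution:
    def test_equal_bounds_are_permutation_invariant(self, small_dataset):
        """All constrained bounds equal -> null sd 0, mean = observed."""
        model, fns = small_dataset.model, small_dataset.functions
        lower, upper = model.default_bounds()
        constrained = np.array(
            [r.gpr is not None and not r.is_exchange for r in model.reactions]
        )
        upper[constrained] = 7.0
        lower[constrained] = 0.0
        bounds = BoundsSet(
            [r.id for r in model.reactions], lower, upper, constrained,
            np.array([r.reversible for r in model.reactions]),
        )
        cfg = NullConfig(repetitions=5, seed=0)
        mean, sd, n = null_distribution(model, bounds, fns, cfg, np.random.default_rng(0))
        from fluxcap.capacity_engine import CapacitySolver

        obs, _ = CapacitySolver(model, fns).capacities(bounds)
        assert np.allclose(sd, 0.0, atol=1e-9)
        assert np.allclose(mean, obs, rtol=1e-9)

    def test_reproducible_from_seed(self, small_dataset):
        model, fns = small_dataset.model, small_dataset.functions[:3]
        expr = small_dataset.expression
        bounds = expression_to_bounds(
            model, expr.slice(expr.conditions[0], expr.timepoints[0]), 1000
        )
        cfg = NullConfig(repetitions=4, seed=9)
        m1, s1, _ = null_distribution(model, bounds, fns, cfg, substream(9, 0, 0))
        m2, s2, _ = null_distribution(model, bounds, fns, cfg, substream(9, 0, 0))
        assert np.array_equal(m1, m2) and np.array_equal(s1, s2)

    def test_two_seed_stability(self, small_dataset):
        """Independent seeds agree to O(sd/sqrt(n)) at n = 100."""
        model, fns = small_dataset.model, small_dataset.functions[:3]
        expr = small_dataset.expression
        bounds = expression_to_bounds(
            model, expr.slice(expr.conditions[0], expr.timepoints[0]), 1000
        )
        cfg = NullConfig(repetitions=100, seed=0)
        m1, s1, _ = null_distribution(model, bounds, fns, cfg, np.random.default_rng(1))
        m2, s2, _ = null_distribution(model, bounds, fns, cfg, np.random.default_rng(2))
        se = np.maximum(s1, s2) / np.sqrt(cfg.repetitions)
        assert np.all(np.abs(m1 - m2) <= 6 * se + 1e-12)

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError, match="repetitions"):
            NullConfig(repetitions=1, seed=0)


def profile_from_values(values):
    values = np.asarray(values, dtype=float)
    nf, nc, nt = values.shape
    return CapacityProfile(
        [f"P{i}" for i in range(nf)],
        [f"c{i}" for i in range(nc)],
        np.arange(nt, dtype=float),
        values,
        np.full(values.shape, "optimal", dtype=object),
    )


class TestZScores:
    def test_basic_value(self):
        obs = profile_from_values(np.full((1, 1, 1), 10.0))
        tab = z_scores(obs, np.full((1, 1, 1), 4.0), np.full((1, 1, 1), 2.0))
        assert tab.z[0, 0, 0] == pytest.approx(3.0)
        assert not tab.degenerate[0, 0, 0]

    def test_observed_equal_mean_is_zero(self):
        obs = profile_from_values(np.full((1, 1, 1), 4.0))
        tab = z_scores(obs, np.full((1, 1, 1), 4.0), np.full((1, 1, 1), 0.0))
        assert tab.z[0, 0, 0] == 0.0
        assert tab.degenerate[0, 0, 0]

    def test_floor_rule_for_degenerate_sd(self):
        obs = profile_from_values(np.full((1, 1, 1), 5.0))
        mean = np.full((1, 1, 1), 4.0)
        tab = z_scores(obs, mean, np.full((1, 1, 1), 0.0), sd_floor_rel=1e-8)
        floor = 1e-8 * (1 + 4.0)
        assert tab.degenerate[0, 0, 0]
        assert tab.z[0, 0, 0] == pytest.approx(1.0 / floor)

    def test_grid_mismatch_rejected(self):
        obs = profile_from_values(np.zeros((2, 1, 1)))
        with pytest.raises(ValueError, match="grid"):
            z_scores(obs, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)))


class TestClassify:
    def _table(self, z):
        z = np.asarray(z, dtype=float)
        return ZScoreTable(
            [f"P{i}" for i in range(z.shape[0])],
            [f"c{i}" for i in range(z.shape[1])],
            np.arange(z.shape[2], dtype=float),
            z,
            np.zeros_like(z),
            np.ones_like(z),
            np.zeros(z.shape, dtype=bool),
        )

    def test_sustainer_in_one_condition_is_differential(self):
        z = np.zeros((1, 8, 4))
        z[0, 2, :] = 2.5
        table = classify(self._table(z), NullConfig(seed=0))
        assert table.labels.iloc[0, 2] == "sustainer"
        assert (table.labels.iloc[0].drop(table.labels.columns[2]) == "none").all()
        assert bool(table.differential.iloc[0])

    def test_modulator_in_all_conditions_not_differential(self):
        z = np.full((1, 8, 4), -2.5)
        table = classify(self._table(z), NullConfig(seed=0))
        assert (table.labels.iloc[0] == "modulator").all()
        assert not bool(table.differential.iloc[0])

    def test_subthreshold_everywhere_is_none(self):
        z = np.full((1, 8, 4), 1.9)
        table = classify(self._table(z), NullConfig(seed=0))
        assert (table.labels.iloc[0] == "none").all()
        assert not bool(table.differential.iloc[0])

    def test_threshold_is_strict_by_default(self):
        z = np.full((1, 2, 4), 2.0)
        strict = classify(self._table(z), NullConfig(seed=0))
        assert (strict.labels.iloc[0] == "none").all()
        loose = classify(self._table(z), NullConfig(seed=0, strict=False))
        assert (loose.labels.iloc[0] == "sustainer").all()

    def test_exclusion_window(self):
        z = np.zeros((1, 2, 8))
        z[0, 0, :4] = 8.0  # early-only signal
        cfg = NullConfig(seed=0)
        with_early = classify(self._table(z), cfg, exclude_first_k=0)
        without = classify(self._table(z), cfg, exclude_first_k=4)
        assert with_early.labels.iloc[0, 0] == "sustainer"
        assert without.labels.iloc[0, 0] == "none"
        with pytest.raises(ValueError, match="fewer than 2"):
            classify(self._table(z), cfg, exclude_first_k=7)

    def test_scale_invariance(self):
        """Rescaling capacities and null summaries together leaves calls unchanged."""
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 10, size=(4, 3, 5))
        mean = values + rng.normal(0, 2, values.shape)
        sd = rng.uniform(0.5, 2, values.shape)
        for k in (1.0, 17.3):
            obs = profile_from_values(values * k)
            tab = z_scores(obs, mean * k, sd * k)
            table = classify(tab, NullConfig(seed=0))
            if k == 1.0:
                ref = table.labels
            else:
                pd.testing.assert_frame_equal(table.labels, ref)


class TestEndToEnd:
    def test_no_effect_no_differential_calls(self):
        """With effect = 1 no pathway should be called differential."""
        spec = SyntheticSpec(
            n_pathways=8,
            pathway_length=3,
            n_conditions=3,
            n_timepoints=8,
            n_planted_up=2,
            n_planted_down=2,
            expression_effect=1.0,
            n_background_chains=12,
            background_chain_length=4,
            seed=101,
        )
        ds = generate_all(spec)
        cfg = NullConfig(repetitions=30, seed=7)
        _, _, table = run_null_classification(
            ds.model, ds.expression, ds.functions, cfg, v_cap=1000
        )
        assert int(table.differential.sum()) == 0

    def test_planted_signal_recovered_small(self, small_dataset):
        ds = small_dataset
        cfg = NullConfig(repetitions=40, seed=11)
        _, ztab, table = run_null_classification(
            ds.model, ds.expression, ds.functions, cfg, v_cap=1000
        )
        truth = ds.truth.pathway_class
        for fid, cls in truth.items():
            if cls == "none":
                assert not bool(table.differential[fid])
            else:
                assert bool(table.differential[fid])
                affected = list(ds.truth.affected_conditions)
                expected = "sustainer" if cls == "up" else "modulator"
                assert (table.labels.loc[fid, affected] == expected).any()
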