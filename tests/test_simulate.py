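"""Tests for the block-correlated expression generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fdrsim import (
    NoiseParams,
    SimulationConfig,
    apply_noise,
    build_block_correlation,
    draw_theta,
    inject_de,
    partition_blocks,
    sample_correlated_block,
    simulate_experiment,
)
from fdrsim.exceptions import DegenerateInputError, InvalidParameterError
from fdrsim.simulate import BlockSpec


class TestPartitionBlocks:
    def test_unit_mean_forces_singletons(self, rng):
        sizes = partition_blocks(10, 1.0, rng)
        assert list(sizes) == [1] * 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n_genes=st.integers(min_value=1, max_value=3000),
        xi=st.floats(min_value=1.0, max_value=80.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_sizes_are_positive_and_conserve_gene_count(self, n_genes, xi, seed):
        sizes = partition_blocks(n_genes, xi, np.random.default_rng(seed))
        assert sizes.sum() == n_genes
        assert (sizes >= 1).all()

    def test_long_run_mean_matches_xi(self):
        # mean of 1 + Poisson(xi - 1) is xi; Monte-Carlo check over 50 seeds
        means = [
            np.mean(partition_blocks(10_000, 10.0, np.random.default_rng(s)))
            for s in range(50)
        ]
        assert 9.0 <= np.mean(means) <= 11.0

    @pytest.mark.parametrize("n_genes,xi", [(0, 5.0), (10, 0.5), (-3, 1.0)])
    def test_invalid_inputs_raise(self, n_genes, xi, rng):
        with pytest.raises(InvalidParameterError):
            partition_blocks(n_genes, xi, rng)


class TestDrawTheta:
    def test_fixed_scenario_returns_its_constant(self, rng):
        assert all(draw_theta(0.0, rng) == 0.0 for _ in range(20))
        assert draw_theta(0.3, rng) == 0.3

    def test_tent_is_uniform_on_half_interval(self):
        rng = np.random.default_rng(5)
        draws = np.array([draw_theta("tent", rng) for _ in range(100_000)])
        assert draws.min() >= 0.0 and draws.max() <= 0.5
        assert abs(draws.mean() - 0.25) < 0.005

    def test_fixed_value_outside_range_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            draw_theta(0.7, rng)
        with pytest.raises(InvalidParameterError):
            draw_theta("triangle", rng)


class TestBlockCorrelation:
    def test_zero_rho_gives_identity(self):
        corr = build_block_correlation(3, 0.0, [1, -1, 1])
        assert np.array_equal(corr, np.eye(3))

    def test_opposite_signs_give_negative_offdiagonal(self):
        corr = build_block_correlation(2, 0.8, [1, -1])
        assert corr[0, 1] == pytest.approx(-0.8)
        assert corr[1, 0] == pytest.approx(-0.8)
        assert np.all(np.diag(corr) == 1.0)

    def test_positive_semidefinite_at_high_rho(self, rng):
        signs = np.where(rng.random(200) < 0.5, -1.0, 1.0)
        corr = build_block_correlation(200, 0.95, signs)
        assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_invalid_rho_raises(self):
        with pytest.raises(InvalidParameterError):
            build_block_correlation(2, 1.5, [1, 1])


def _make_plain_blocks(n_blocks, size, active=True):
    return [
        BlockSpec(
            block_id=b, size=size, rho=0.5, signs=np.ones(size),
            active=active, de=False, deltas=np.zeros(size), theta=0.0,
        )
        for b in range(n_blocks)
    ]


class TestInjectDE:
    def test_psi_zero_flags_nothing(self, rng):
        out = inject_de(_make_plain_blocks(10, 5), 0.0, 10, 10, rng)
        assert not any(b.de for b in out)
        assert all(np.all(b.deltas == 0) for b in out)

    def test_gamma_magnitudes_center_on_unit_fold_change(self):
        # shape = rate = 10 gives mean |Delta| = 1 on the log2 scale
        rng = np.random.default_rng(11)
        out = inject_de(_make_plain_blocks(1000, 100), 1.0, 10, 10, rng)
        deltas = np.concatenate([b.deltas for b in out])
        assert abs(np.mean(np.abs(deltas)) - 1.0) < 0.01

    def test_direction_coin_is_fair(self):
        rng = np.random.default_rng(12)
        out = inject_de(_make_plain_blocks(1000, 100), 1.0, 10, 10, rng)
        deltas = np.concatenate([b.deltas for b in out])
        assert 0.49 <= np.mean(deltas > 0) <= 0.51

    def test_inactive_blocks_never_flagged(self, rng):
        blocks = _make_plain_blocks(4, 5, active=True) + [
            BlockSpec(block_id=4, size=5, rho=0.5, signs=np.ones(5),
                      active=False, de=False, deltas=np.zeros(5), theta=0.0)
        ]
        out = inject_de(blocks, 1.0, 10, 10, rng)
        assert not out[-1].de
        assert all(b.de for b in out[:-1])

    def test_psi_without_active_blocks_raises(self, rng):
        with pytest.raises(DegenerateInputError):
            inject_de(_make_plain_blocks(3, 5, active=False), 0.5, 10, 10, rng)


class TestApplyNoise:
    def test_noiseless_case_is_floor_clipped_identity(self, rng):
        raw = np.array([[0.0, 5.0, 100.0]])
        noise = NoiseParams(mult_sd=0.0, add_mean=0.0, add_sd=0.0, floor=1.0)
        out = apply_noise(raw, noise, rng)
        assert np.array_equal(out, np.maximum(raw, 1.0))

    def test_output_never_below_floor(self, rng):
        raw = rng.gamma(1.0, 10.0, size=(50, 20))
        out = apply_noise(raw, NoiseParams(floor=1.0), rng)
        assert out.min() >= 1.0

    def test_log_variance_grows_with_multiplicative_noise(self):
        raw = np.full((1, 20_000), 100.0)
        spreads = []
        for mult_sd in (0.05, 0.2):
            out = apply_noise(
                raw, NoiseParams(mult_sd=mult_sd, add_mean=0, add_sd=0.1),
                np.random.default_rng(3),
            )
            spreads.append(np.var(np.log2(out)))
        assert spreads[1] > spreads[0]

    def test_negative_signal_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            apply_noise(np.array([[-1.0]]), NoiseParams(), rng)


class TestSimulateExperiment:
    def test_matrix_shape_and_group_balance(self):
        cfg = SimulationConfig(n_genes=1000, n_per_group=25, seed=1)
        exp = simulate_experiment(cfg)
        assert exp.log2_matrix.shape == (1000, 50)
        assert np.sum(exp.group_labels == "normal") == 25
        assert np.sum(exp.group_labels == "cancer") == 25
        assert np.isfinite(exp.log2_matrix).all()

    def test_psi_zero_yields_no_de_genes(self):
        cfg = SimulationConfig(n_genes=500, n_per_group=10, psi=0.0, seed=2)
        exp = simulate_experiment(cfg)
        assert not exp.truth["is_de"].any()
        assert np.all(exp.truth["delta"] == 0)

    def test_identical_config_is_bit_identical(self):
        cfg = SimulationConfig(
            n_genes=400, n_per_group=10, mean_block_size=20, psi=0.2, seed=99
        )
        a, b = simulate_experiment(cfg), simulate_experiment(cfg)
        assert np.array_equal(a.log2_matrix, b.log2_matrix)
        assert a.truth.equals(b.truth)

    def test_de_genes_match_flagged_block_sizes(self):
        cfg = SimulationConfig(
            n_genes=2000, n_per_group=5, mean_block_size=25, psi=0.3,
            active_fraction=0.7, seed=4,
        )
        exp = simulate_experiment(cfg)
        truth = exp.truth
        de_blocks = truth.loc[truth["is_de"], "block_id"].unique()
        block_sizes = truth.groupby("block_id").size()
        assert truth["is_de"].sum() == block_sizes.loc[de_blocks].sum()
        # DE genes sit only in active blocks and carry nonzero shifts
        assert truth.loc[truth["is_de"], "active"].all()
        assert (truth.loc[truth["is_de"], "delta"] != 0).all()

    def test_changing_psi_preserves_block_layout(self):
        kwargs = dict(n_genes=800, n_per_group=5, mean_block_size=15, seed=13)
        low = simulate_experiment(SimulationConfig(psi=0.05, **kwargs))
        high = simulate_experiment(SimulationConfig(psi=0.40, **kwargs))
        assert low.truth["block_id"].equals(high.truth["block_id"])
        assert low.truth["active"].equals(high.truth["active"])

    def test_opposite_signs_yield_negative_sample_correlation(self):
        # one-factor construction: mean sample correlation between +/- genes < 0
        rng = np.random.default_rng(8)
        mean_corrs = []
        for _ in range(100):
            signs = np.array([1.0, -1.0] * 5)
            x = sample_correlated_block(10, 0.9, signs, 50, rng)
            corr = np.corrcoef(x)
            pos, neg = signs > 0, signs < 0
            mean_corrs.append(corr[np.ix_(pos, neg)].mean())
        assert np.mean(mean_corrs) < 0

    def test_singleton_blocks_make_genes_independent(self, null_experiment):
        # pairwise correlations of independent genes: centred at 0 with
        # sd about 1/sqrt(2N - 1)
        x = null_experiment.log2_matrix[:400]
        corr = np.corrcoef(x)
        vals = corr[np.triu_indices_from(corr, k=1)]
        n = x.shape[1]
        assert abs(vals.mean()) < 0.01
        assert abs(vals.std() - 1 / np.sqrt(n - 1)) / (1 / np.sqrt(n - 1)) < 0.2

    def test_null_pvalues_are_uniform(self, null_pvalues):
        res = stats.kstest(null_pvalues.p_values, "uniform")
        assert res.pvalue > 0.01
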