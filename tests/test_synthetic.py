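"""Ground-truth generator: profiles, kinetics, counts, operons."""

import numpy as np
import pytest
from scipy.stats import binomtest

from profilefit.classify import call_member_behavior
from profilefit.profile_model import evaluate_piecewise
from profilefit.regulation import cumulative_integral
from profilefit.synthetic import (
    SyntheticConfig,
    build_operon_structure,
    generate_dataset,
    sample_true_profiles,
    simulate_counts,
    simulate_protein_dynamics,
    simulate_replicate_levels,
)


class TestConfig:
    def test_mixes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="category_mix"):
            SyntheticConfig(category_mix={"up": 0.5, "down": 0.4})

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            SyntheticConfig(time_grid=(3.0, 2.0, 5.0, 6.0))

    def test_min_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            SyntheticConfig(n_replicates=1)


class TestTrueProfiles:
    def test_flat_category_has_equal_amplitudes(self):
        cfg = SyntheticConfig(n_genes=40, seed=0, category_mix={"flat": 1.0})
        params, cats = sample_true_profiles(cfg)
        for p in params:
            assert p.A1 == p.A2 == p.A3

    def test_transient_up_amplitude_ordering(self):
        cfg = SyntheticConfig(n_genes=40, seed=0, category_mix={"transient_up": 1.0})
        params, _ = sample_true_profiles(cfg)
        for p in params:
            assert p.A2 > p.A1 and p.A3 < p.A2

    def test_member_call_with_zero_delta_recovers_category(self):
        """Every drawn parameter set classifies as its intended category in
        the delta -> 0 limit."""
        cfg = SyntheticConfig(n_genes=300, seed=6)
        params, cats = sample_true_profiles(cfg)
        for p, c in zip(params, cats):
            assert call_member_behavior(p, 0.0) == c

    def test_knots_inside_observation_window(self, grid):
        cfg = SyntheticConfig(n_genes=100, seed=2)
        params, _ = sample_true_profiles(cfg)
        for p in params:
            assert np.all(p.knots >= grid[0]) and np.all(p.knots <= grid[-1])

    def test_category_frequencies_within_binomial_ci(self):
        """Empirical frequencies are consistent with the mix (exact binomial
        test, alpha=0.01, n=600)."""
        cfg = SyntheticConfig(n_genes=600, seed=1)
        _, cats = sample_true_profiles(cfg)
        for cat, prob in cfg.category_mix.items():
            k = sum(c == cat for c in cats)
            assert binomtest(k, 600, prob).pvalue > 0.01


class TestProteinDynamics:
    def test_no_degradation_equals_cumulative_integral(self, transient_params, grid):
        m = np.asarray(evaluate_piecewise(transient_params, grid))
        p = simulate_protein_dynamics(transient_params, 2.0, 0.0, 0.5, grid)
        expected = 0.5 + 2.0 * cumulative_integral(m, grid)
        assert np.allclose(p, expected, rtol=1e-12)

    def test_constant_transcript_approaches_fixed_point(self):
        from profilefit.profile_model import PiecewiseParams

        flat = PiecewiseParams(0.0, 1, 1, 1, 1, 2.0, 2.0, 2.0)
        t = np.array([0.0, 1.0, 10.0, 1000.0])
        p = simulate_protein_dynamics(flat, 3.0, 0.5, 0.0, t)
        assert p[-1] == pytest.approx(3.0 * 2.0 / 0.5, rel=1e-6)

    def test_matches_rk4_integrator_on_ramp(self):
        """Ramp m from 1 to 2 over [3, 8] h, k_s=1, k_d=0.5, p0=0: closed
        form matches a 4th-order fixed-step integrator at h=0.001."""
        from profilefit.profile_model import PiecewiseParams

        p_m = PiecewiseParams(3.0, 0.0, 5.0, 0.0, 0.0, 1.0, 2.0, 2.0)
        times = np.array([3.0, 4.0, 5.0, 6.0, 8.0])
        got = simulate_protein_dynamics(p_m, 1.0, 0.5, 0.0, times)

        def m(t):
            return 1.0 + (min(t, 8.0) - 3.0) / 5.0

        h = 0.001
        p, t = 0.0, 3.0
        oracle = {3.0: 0.0}
        while t < 8.0 - 1e-12:
            f = lambda tt, pp: 1.0 * m(tt) - 0.5 * pp
            k1 = f(t, p)
            k2 = f(t + h / 2, p + h * k1 / 2)
            k3 = f(t + h / 2, p + h * k2 / 2)
            k4 = f(t + h, p + h * k3)
            p += (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            for tj in times:
                if abs(t - tj) < h / 2:
                    oracle[float(tj)] = p
        for tj, val in zip(times, got):
            assert val == pytest.approx(oracle[float(tj)], rel=1e-6, abs=1e-9)

    def test_nonnegativity(self, grid, rng):
        cfg = SyntheticConfig(n_genes=30, seed=9)
        params, _ = sample_true_profiles(cfg)
        for p_m in params:
            k_s, k_d = rng.uniform(0, 5), rng.uniform(0, 5)
            p = simulate_protein_dynamics(p_m, k_s, k_d, rng.uniform(0, 3), grid)
            assert np.all(p >= 0)

    def test_negative_rates_rejected(self, transient_params, grid):
        with pytest.raises(ValueError):
            simulate_protein_dynamics(transient_params, -1.0, 0.1, 0.0, grid)


class TestSimulateCounts:
    def test_same_seed_identical(self, rng):
        cfg = SyntheticConfig(n_genes=20, seed=5)
        levels = rng.uniform(0, 2, size=(20, 9))
        a = simulate_counts(levels, cfg)
        b = simulate_counts(levels, cfg)
        assert np.array_equal(a, b)

    def test_adding_genes_preserves_existing_streams(self, rng):
        """Per-gene random streams are independent of the gene count (the
        appended genes here carry zero level so the pool normalization is
        unchanged and only stream stability is probed)."""
        cfg = SyntheticConfig(n_genes=10, seed=5)
        levels = rng.uniform(0.5, 2, size=(10, 9))
        base = simulate_counts(levels, cfg)
        more = simulate_counts(np.vstack([levels, np.zeros((5, 9))]), cfg)
        assert np.array_equal(more[:10], base)

    def test_all_zero_gene_yields_zero_counts(self):
        cfg = SyntheticConfig(n_genes=3, seed=0)
        levels = np.array([[1.0] * 9, [0.0] * 9, [2.0] * 9])
        counts = simulate_counts(levels, cfg)
        assert counts[1].sum() == 0

    def test_poisson_limit_replicate_cv_small(self):
        """dispersion -> 0 at high depth: replicate CV below 2% for genes
        holding >= 1e-3 of the pool (Poisson CV = 1/sqrt(mean))."""
        cfg = SyntheticConfig(n_genes=100, seed=3, depth=1e7, dispersion=0.0,
                              n_replicates=3)
        levels = np.ones((100, 9))  # each gene 1% of pool -> mean 1e5
        counts = simulate_counts(levels, cfg).astype(float)
        cv = counts.std(axis=2, ddof=1) / counts.mean(axis=2)
        assert np.median(cv) < 0.02

    def test_replicate_means_converge_to_relative_levels(self):
        cfg = SyntheticConfig(n_genes=50, seed=8, depth=1e7, dispersion=0.0)
        rng = np.random.default_rng(0)
        levels = rng.uniform(0.5, 3, size=(50, 9))
        counts = simulate_counts(levels, cfg).astype(float)
        rel = levels / levels.sum(axis=0)
        est = counts.mean(axis=2) / counts.mean(axis=2).sum(axis=0)
        assert np.allclose(est, rel, rtol=0.02)


class TestOperonStructure:
    def test_all_genes_assigned_and_ordered(self):
        cfg = SyntheticConfig(n_genes=57, seed=4)
        ops = build_operon_structure(cfg)
        assert len(ops) == 57
        for _, sub in ops.groupby("operon_id"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert np.all(starts[1:] > ends[:-1])  # non-overlapping, ordered

    def test_gaps_within_configured_range(self):
        cfg = SyntheticConfig(n_genes=200, seed=4)
        ops = build_operon_structure(cfg)
        inner = ops[ops["position"] > 0]
        assert inner["gap_prev_bp"].between(0, 2000).all()

    def test_operon_members_share_scaled_shape(self):
        cfg = SyntheticConfig(
            n_genes=30, seed=7, operon_size_dist={3: 1.0},
            class_mix={"mRNA": 1.0, "tRNA": 0.0, "rRNA": 0.0, "ncRNA": 0.0},
        )
        ds = generate_dataset(cfg)
        levels = ds.rna_levels
        for _, sub in ds.operons.groupby("operon_id"):
            ref = levels.loc[sub["gene"].iloc[0]].to_numpy()
            for g in sub["gene"].iloc[1:]:
                x = levels.loc[g].to_numpy()
                ratio = x[ref > 0] / ref[ref > 0]
                assert ratio.min() == pytest.approx(ratio.max(), rel=1e-9)
                assert ratio.min() > 0

    def test_zero_distance_noise_gives_perfect_protein_correlation(self):
        from scipy.stats import spearmanr

        cfg = SyntheticConfig(
            n_genes=30, seed=7, operon_size_dist={3: 1.0},
            distance_noise_sd_at_1kb=0.0,
            regulation_mix={"proportional": 1.0, "integral": 0.0, "intermediate": 0.0},
            category_mix={"down": 1.0},
            class_mix={"mRNA": 1.0, "tRNA": 0.0, "rRNA": 0.0, "ncRNA": 0.0},
        )
        ds = generate_dataset(cfg)
        # same regime and shared shape: noiseless protein profiles within an
        # operon are monotone transforms of each other
        for _, sub in ds.operons.groupby("operon_id"):
            genes = list(sub["gene"])
            base = ds.protein_levels.loc[genes[0]]
            for g in genes[1:]:
                rho = spearmanr(base, ds.protein_levels.loc[g]).statistic
                assert rho > 0.95


class TestReplicateLevels:
    def test_zero_cv_returns_copies(self, rng):
        levels = rng.uniform(0, 2, size=(5, 9))
        out = simulate_replicate_levels(levels, 0.0, 3, rng)
        assert np.array_equal(out[:, :, 0], levels)

    def test_noise_is_unit_mean(self, rng):
        levels = np.full((200, 9), 10.0)
        out = simulate_replicate_levels(levels, 0.2, 3, rng)
        assert out.mean() == pytest.approx(10.0, rel=0.02)


class TestGeneSetsAndDataset:
    def test_category_module_sets_exist(self):
        cfg = SyntheticConfig(n_genes=200, seed=1)
        ds = generate_dataset(cfg)
        assert any(name.endswith("_module") for name in ds.gene_sets)
        for members in ds.gene_sets.values():
            assert len(members) >= 3

    def test_dataset_is_seed_reproducible(self):
        a = generate_dataset(SyntheticConfig(n_genes=40, seed=13))
        b = generate_dataset(SyntheticConfig(n_genes=40, seed=13))
        assert np.array_equal(a.rna.counts, b.rna.counts)
        assert np.array_equal(a.protein.counts, b.protein.counts)
        assert a.truth.table.equals(b.truth.table)

    def test_non_mrna_genes_have_no_protein(self):
        cfg = SyntheticConfig(n_genes=150, seed=2)
        ds = generate_dataset(cfg)
        non_mrna = ds.truth.table.index[ds.truth.table["rna_class"] != "mRNA"]
        assert len(non_mrna) > 0
        assert not set(non_mrna) & set(ds.protein.genes)

    def test_truth_rates_nonnegative(self):
        ds = generate_dataset(SyntheticConfig(n_genes=80, seed=3))
        t = ds.truth.table
        for col in ("k_s", "k_d", "p0"):
            assert (t[col].dropna() >= 0).all()
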