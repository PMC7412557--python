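"""Adjacency, TOM, soft-threshold, eigengene, kME, and module detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aphidnet import (
    ConfigError,
    detect_modules,
    kme,
    module_eigengene,
    pick_soft_threshold,
    signed_adjacency,
    tom,
)
from aphidnet.network import UNASSIGNED, scale_free_fit


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def _profiles(rows, n_samples=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestSignedAdjacency:
    def test_closed_form_values(self):
        t = np.arange(6, dtype=float)
        data = _profiles([t, t, -t, 0.5 * t + 3], n_samples=6)
        a = signed_adjacency(data, beta=12.0).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)  # r = 1
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # r = -1
        assert a[0, 3] == pytest.approx(1.0)  # affine with positive slope

    def test_uncorrelated_pair_at_beta12(self):
        # orthogonal zero-mean profiles with exactly zero correlation
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.dot(x, y) == pytest.approx(0)
        a = signed_adjacency(_profiles([x, y], n_samples=4), beta=12.0)
        assert a.to_numpy()[0, 1] == pytest.approx(0.5 ** 12, rel=1e-12)

    def test_monotone_decreasing_in_beta(self):
        rng = np.random.default_rng(4)
        data = _profiles(rng.normal(size=(5, 10)), n_samples=10)
        a6 = signed_adjacency(data, 6.0).to_numpy()
        a12 = signed_adjacency(data, 12.0).to_numpy()
        off = ~np.eye(5, dtype=bool)
        assert (a12[off] < a6[off]).all()

    def test_too_few_samples_rejected(self):
        data = _profiles(np.random.default_rng(0).normal(size=(3, 3)), n_samples=3)
        with pytest.raises(ConfigError):
            signed_adjacency(data, 6.0)

    def test_zero_variance_gene_dropped(self, caplog):
        rng = np.random.default_rng(5)
        rows = list(rng.normal(size=(3, 8))) + [np.full(8, 2.0)]
        with caplog.at_level("WARNING"):
            a = signed_adjacency(_profiles(rows, n_samples=8), 6.0)
        assert a.shape == (3, 3)
        assert "zero-variance" in caplog.text


class TestTom:
    def test_two_gene_identity(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        t = tom(a)
        assert t[0, 1] == pytest.approx(0.37, abs=1e-14)

    def test_perfect_block_is_all_ones(self):
        a = np.ones((5, 5))
        assert np.allclose(tom(a), 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            a = random_adjacency(rng, n)
            assert np.max(np.abs(tom(a) - brute_force_tom(a))) < 1e-12

    def test_range_symmetry_diagonal(self):
        rng = np.random.default_rng(7)
        a = random_adjacency(rng, 15)
        t = tom(a)
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)
        assert t.min() >= 0.0 and t.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ConfigError, match="symmetric"):
            tom(a)


class TestSoftThreshold:
    def test_noise_matrix_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(8)
        data = _profiles(rng.normal(size=(300, 20)), n_samples=20)
        with caplog.at_level("WARNING"):
            beta = pick_soft_threshold(data)
        assert beta == 12.0
        assert "no candidate power" in caplog.text

    def test_modular_data_returns_at_most_fallback(self, default_network):
        beta = pick_soft_threshold(default_network["data"])
        assert beta <= 12.0

    def test_single_candidate_meeting_fit_is_returned(self):
        # strongly hub-like data: one gene correlated with many, rest sparse
        rng = np.random.default_rng(9)
        hub = rng.normal(size=30)
        rows = [hub + rng.normal(0, s, size=30) for s in np.linspace(0.1, 8, 120)]
        data = _profiles(rows, n_samples=30)
        beta = pick_soft_threshold(data, candidate_betas=(6,), rsq_threshold=0.5)
        assert beta in (6.0, 12.0)

    def test_scale_free_fit_flat_distribution_scores_zero(self):
        assert scale_free_fit(np.full(100, 3.0))[0] == 0.0


class TestEigengeneAndKme:
    def test_identical_genes_recover_standardized_profile(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        data = _profiles([v, v, v], n_samples=6)
        e = module_eigengene(data, data.index)
        z = (v - v.mean()) / v.std()
        z = z / np.linalg.norm(z)
        assert np.allclose(e.to_numpy(), z, atol=1e-12)
        scores = kme(data, pd.DataFrame({1: e}))
        assert np.allclose(scores[1], 1.0)

    def test_single_gene_module(self):
        v = np.array([2.0, 4.0, 8.0, 1.0, 0.0, 3.0])
        data = _profiles([v], n_samples=6)
        e = module_eigengene(data, data.index)
        z = (v - v.mean()) / v.std()
        assert np.allclose(np.abs(e.to_numpy()), np.abs(z / np.linalg.norm(z)))

    def test_sign_convention_majority_positive(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=10)
        rows = [base + rng.normal(0, 0.1, 10) for _ in range(9)]
        rows.append(-base)
        data = _profiles(rows, n_samples=10)
        e = module_eigengene(data, data.index)
        scores = kme(data, pd.DataFrame({1: e}))
        assert (scores[1].iloc[:9] > 0).all()

    def test_negated_eigengene_gives_minus_one(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=12)
        data = _profiles([base, -base], n_samples=12)
        e = module_eigengene(data, data.index[:1])
        scores = kme(data, pd.DataFrame({1: e}))
        assert scores[1]["g0"] == pytest.approx(1.0)
        assert scores[1]["g1"] == pytest.approx(-1.0)

    def test_kme_matches_direct_pearson(self):
        rng = np.random.default_rng(12)
        data = _profiles(rng.normal(size=(8, 15)), n_samples=15)
        e = module_eigengene(data, data.index[:4])
        scores = kme(data, pd.DataFrame({1: e}))
        for g in data.index:
            expected = np.corrcoef(data.loc[g], e)[0, 1]
            assert scores[1][g] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_gets_zero_kme(self):
        rng = np.random.default_rng(13)
        rows = [rng.normal(size=10), np.full(10, 4.0)]
        data = _profiles(rows, n_samples=10)
        e = module_eigengene(data, data.index[:1])
        scores = kme(data, pd.DataFrame({1: e}))
        assert scores[1]["g1"] == 0.0

    def test_constant_module_is_error(self):
        data = _profiles([np.full(8, 1.0)], n_samples=8)
        from aphidnet import PipelineError

        with pytest.raises(PipelineError):
            module_eigengene(data, data.index)


def _block_data(sizes, correlations, n_samples=30, seed=20, noise=0.1):
    """Planted blocks driven by independent latent profiles."""
    rng = np.random.default_rng(seed)
    rows = []
    for size, latent in zip(sizes, correlations):
        for _ in range(size):
            rows.append(latent + rng.normal(0, noise, n_samples))
    return _profiles(rows, n_samples=n_samples, seed=seed)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(21)
        l1, l2 = rng.normal(size=30), rng.normal(size=30)
        data = _block_data([60, 60], [l1, l2], seed=22)
        t = tom(signed_adjacency(data, 6.0).to_numpy())
        asg = detect_modules(t, data, min_module_size=30)
        assert len(asg.labels) == 2
        first = asg.modules.iloc[:60]
        second = asg.modules.iloc[60:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_independent_noise_unassigned(self):
        rng = np.random.default_rng(23)
        data = _profiles(rng.normal(size=(50, 30)), n_samples=30)
        t = tom(signed_adjacency(data, 12.0).to_numpy())
        asg = detect_modules(t, data, min_module_size=30)
        assert len(asg.labels) == 0
        assert (asg.modules == UNASSIGNED).all()

    def test_blocks_from_same_profile_are_merged(self):
        rng = np.random.default_rng(24)
        latent = rng.normal(size=30)
        data = _block_data([60, 60], [latent, latent], seed=25)
        t = tom(signed_adjacency(data, 6.0).to_numpy())
        asg = detect_modules(t, data, min_module_size=30)
        assert len(asg.labels) == 1

    def test_labels_ranked_by_size(self):
        rng = np.random.default_rng(26)
        l1, l2 = rng.normal(size=30), rng.normal(size=30)
        data = _block_data([40, 90], [l1, l2], seed=27)
        t = tom(signed_adjacency(data, 6.0).to_numpy())
        asg = detect_modules(t, data, min_module_size=30)
        sizes = asg.modules[asg.modules != UNASSIGNED].value_counts()
        assert sizes.loc[1] >= sizes.loc[2]

    def test_eigengene_unit_norm_and_kme_range(self, default_network):
        asg = default_network["assignment"]
        norms = np.linalg.norm(asg.eigengenes.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0)
        assert asg.kme.to_numpy().min() >= -1 - 1e-9
        assert asg.kme.to_numpy().max() <= 1 + 1e-9
        for label in asg.labels:
            assert asg.kme.loc[asg.members(label), label].mean() > 0


class TestSamplePermutationInvariance:
    def test_tom_and_modules_unchanged_by_sample_order(self):
        rng = np.random.default_rng(28)
        l1, l2 = rng.normal(size=20), rng.normal(size=20)
        data = _block_data([35, 35], [l1, l2], n_samples=20, seed=29)
        perm = rng.permutation(data.columns)
        shuffled = data[perm]
        t1 = tom(signed_adjacency(data, 6.0).to_numpy())
        t2 = tom(signed_adjacency(shuffled, 6.0).to_numpy())
        assert np.allclose(t1, t2, atol=1e-10)
        a1 = detect_modules(t1, data, min_module_size=30)
        a2 = detect_modules(t2, shuffled, min_module_size=30)
        assert a1.modules.equals(a2.modules)


class TestPlantedRecovery:
    def test_default_simulation_modules_recover_planted_labels(
        self, default_sim, default_network
    ):
        """Adjusted Rand index vs planted modules (unassigned excluded)."""
        from sklearn.metrics import adjusted_rand_score

        _, truth, _, _ = default_sim
        asg = default_network["assignment"]
        planted = pd.Series(truth.module_of)
        mask = asg.modules != UNASSIGNED
        ari = adjusted_rand_score(
            planted.loc[asg.modules.index[mask]], asg.modules[mask]
        )
        assert ari >= 0.8

    def test_eigengene_tracks_planted_profile(self, default_sim, default_network):
        """|cor(eigengene, planted condition signal)| is high for the module
        holding each planted label."""
        from aphidnet import table1_profiles

        counts, truth, _, _ = default_sim
        asg = default_network["assignment"]
        design_cols = default_network["norm"].samples
        profiles = {p.label: p for p in table1_profiles()}
        planted = pd.Series(truth.module_of)
        for label in truth.modules:
            members = [g for g in truth.members(label) if g in asg.modules.index]
            detected = asg.modules.loc[members].mode().iloc[0]
            if detected == UNASSIGNED:
                continue
            eigen = asg.eigengenes[detected]
            signal = np.array(
                [
                    profiles[label].at(s.split("_")[0], int(s.split("_d")[1][:2]))
                    for s in design_cols
                ]
            )
            corr = abs(np.corrcoef(eigen, signal)[0, 1])
            assert corr >= 0.9, (label, corr)
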