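import math

import numpy as np
import pytest
from scipy import special, stats

from finet.background_model import (
    ClusterAssignment,
    cluster_genes,
    fit_cluster_nulls,
    fit_gamma,
    n_clusters_for,
    truncate_and_shift,
)
from finet.feature_space import N_FEATURES, NORMALIZED, FeatureMatrix

from oracles import gamma_loglik


def _normalized_matrix(values):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    return FeatureMatrix(genes=genes, values=values,
                         missing_mask=np.zeros_like(values, dtype=bool),
                         state=NORMALIZED)


class TestClusterCount:
    @pytest.mark.parametrize("G,N,expected", [
        (6000, 3000, 2), (3001, 3000, 2), (3000, 3000, 1), (1, 3000, 1),
        (2999, 3000, 1), (9001, 3000, 4), (100, 10, 10),
    ])
    def test_ceiling_arithmetic(self, G, N, expected):
        assert n_clusters_for(G, N) == expected


class TestClusterGenes:
    def test_separated_blobs_are_recovered(self, rng):
        centers = np.array([[-6.0], [0.0], [6.0]])
        labels_true = rng.integers(0, 3, size=90)
        values = centers[labels_true] + rng.normal(scale=0.3, size=(90, 1))
        values = np.tile(values, (1, N_FEATURES))
        m = _normalized_matrix(values)
        assign = cluster_genes(m, genes_per_cluster=30)
        assert assign.n_clusters == 3
        # every found cluster must be pure w.r.t. the true blob
        for c in range(1, 4):
            members = [int(g[1:]) for g in assign.members(c)]
            assert len(set(labels_true[members])) == 1

    def test_single_cluster_shortcut(self, rng):
        m = _normalized_matrix(rng.normal(size=(10, N_FEATURES)))
        assign = cluster_genes(m, genes_per_cluster=3000)
        assert assign.n_clusters == 1
        assert set(assign.labels.values()) == {1}

    def test_deterministic(self, rng):
        values = rng.normal(size=(50, N_FEATURES))
        a1 = cluster_genes(_normalized_matrix(values), genes_per_cluster=10)
        a2 = cluster_genes(_normalized_matrix(values), genes_per_cluster=10)
        assert a1.labels == a2.labels


class TestTruncateAndShift:
    def _assign(self, n, cluster=1):
        return ClusterAssignment(labels={f"G{i}": cluster for i in range(n)},
                                 n_clusters=cluster,
                                 genes_per_cluster_target=3000)

    def test_drops_floor_q_n_smallest(self):
        estimated = {f"G{i}": float(i + 1) for i in range(100)}  # 1..100
        out = truncate_and_shift(estimated, self._assign(100), 0.05)
        tv = out[1]
        assert tv.values.size == 95
        assert tv.values.min() == 6.0  # 1..5 dropped
        assert tv.shift == 0.0

    def test_shift_applied_when_nonpositive(self):
        estimated = {"G0": -0.5, "G1": 1.0, "G2": 2.0, "G3": 3.0}
        out = truncate_and_shift(estimated, self._assign(4), 0.0)
        tv = out[1]
        assert tv.shift == pytest.approx(0.51)
        assert tv.values.min() == pytest.approx(0.01)

    def test_small_cluster_marked_unfittable(self):
        estimated = {"G0": 1.0, "G1": 2.0}
        out = truncate_and_shift(estimated, self._assign(2), 0.05)
        assert not out[1].fittable

    def test_floor_not_round(self):
        # 0.05 * 19 = 0.95 -> drop 0, not 1
        estimated = {f"G{i}": float(i + 1) for i in range(19)}
        out = truncate_and_shift(estimated, self._assign(19), 0.05)
        assert out[1].values.size == 19


class TestFitGamma:
    def test_recovers_known_parameters(self, rng):
        x = stats.gamma.rvs(3.0, scale=1.0 / 1.5, size=20000,
                            random_state=np.random.RandomState(7))
        fit = fit_gamma(x)
        assert fit.alpha_hat == pytest.approx(3.0, rel=0.05)
        assert fit.beta_hat == pytest.approx(1.5, rel=0.05)

    def test_stationarity_conditions_hold(self, rng):
        x = stats.gamma.rvs(2.0, scale=2.0, size=500,
                            random_state=np.random.RandomState(3))
        fit = fit_gamma(x)
        a, b = fit.alpha_hat, fit.beta_hat
        # rate condition: beta = alpha / mean
        assert b == pytest.approx(a / x.mean(), abs=1e-10)
        # profile shape equation satisfied to the Newton tolerance
        lhs = math.log(a) - special.digamma(a)
        rhs = math.log(x.mean()) - float(np.mean(np.log(x)))
        assert lhs == pytest.approx(rhs, abs=1e-7)

    def test_mle_beats_method_of_moments(self, rng):
        x = stats.gamma.rvs(4.0, scale=0.5, size=400,
                            random_state=np.random.RandomState(11))
        fit = fit_gamma(x)
        a_mom = x.mean() ** 2 / x.var(ddof=1)
        b_mom = x.mean() / x.var(ddof=1)
        assert gamma_loglik(x, fit.alpha_hat, fit.beta_hat) >= \
            gamma_loglik(x, a_mom, b_mom) - 1e-9

    def test_nonpositive_values_fatal(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gamma(np.array([1.0, 2.0, 0.0]))

    def test_too_few_values_fatal(self):
        with pytest.raises(ValueError, match="at least"):
            fit_gamma(np.array([1.0, 2.0]))

    def test_degenerate_identical_values_fatal(self):
        with pytest.raises(ValueError, match="identical"):
            fit_gamma(np.array([2.0, 2.0, 2.0, 2.0]))


class TestFitClusterNulls:
    def test_per_cluster_fits(self, rng):
        labels = {}
        estimated = {}
        rs = np.random.RandomState(5)
        for c, (shape, rate) in enumerate([(2.0, 1.0), (6.0, 0.5)], start=1):
            draws = stats.gamma.rvs(shape, scale=1.0 / rate, size=800,
                                    random_state=rs)
            for i, v in enumerate(draws):
                g = f"C{c}G{i}"
                labels[g] = c
                estimated[g] = float(v)
        clusters = ClusterAssignment(labels=labels, n_clusters=2,
                                     genes_per_cluster_target=800)
        fits = fit_cluster_nulls(estimated, clusters)
        assert set(fits) == {1, 2}
        # truncation biases the fit upward a little; loose sanity bands
        assert fits[1].alpha_hat == pytest.approx(2.0, rel=0.5)
        assert fits[2].alpha_hat == pytest.approx(6.0, rel=0.5)
        assert fits[1].n_used == 800 - 40  # floor(0.05 * 800)

    def test_unfittable_cluster_omitted(self):
        labels = {"G0": 1, "G1": 1, "G2": 2, "G3": 2, "G4": 2, "G5": 2}
        estimated = {"G0": 1.0, "G1": 2.0, "G2": 1.0, "G3": 2.0, "G4": 3.0,
                     "G5": 4.0}
        clusters = ClusterAssignment(labels=labels, n_clusters=2,
                                     genes_per_cluster_target=3)
        fits = fit_cluster_nulls(estimated, clusters)
        assert 1 not in fits and 2 in fits
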