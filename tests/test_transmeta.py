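"""Partition model, marginal likelihoods and Bayes factors."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from transmap import (
    ArgumentError,
    CapacityError,
    DataError,
    PriorSpec,
    RelatednessMatrix,
    cluster_clades,
    cluster_marginal_loglik,
    enumerate_centre_partitions,
    freq_distance_matrix,
    log10bf_association,
    log10bf_heterogeneity,
)
from transmap.transmeta import null_loglik, single_cluster_partition
from conftest import make_assoc


def quad_cluster_ml(betas, ses, tau):
    """Independent 1-D quadrature oracle for the cluster marginal likelihood."""

    def integrand(b):
        return math.exp(
            sum(norm.logpdf(x, loc=b, scale=s) for x, s in zip(betas, ses))
            + norm.logpdf(b, loc=0.0, scale=tau)
        )

    val, _ = quad(integrand, -10, 10, limit=200)
    return math.log(val)


def uniform_matrix(names, d=0.1):
    k = len(names)
    m = np.full((k, k), d)
    np.fill_diagonal(m, 0.0)
    return RelatednessMatrix(tuple(names), m)


class TestRelatedness:
    def test_hand_distance(self):
        eafs = {
            "a": pd.Series([0.1, 0.5], index=["v1", "v2"]),
            "b": pd.Series([0.2, 0.4], index=["v1", "v2"]),
        }
        m = freq_distance_matrix(eafs)
        assert m.distance("a", "b") == pytest.approx(0.1)

    def test_identical_studies_distance_zero(self):
        s = pd.Series([0.1, 0.5], index=["v1", "v2"])
        m = freq_distance_matrix({"a": s, "b": s.copy()})
        assert m.distance("a", "b") == 0.0

    def test_no_shared_variants(self):
        eafs = {
            "a": pd.Series([0.1], index=["v1"]),
            "b": pd.Series([0.2], index=["v2"]),
        }
        with pytest.raises(DataError):
            freq_distance_matrix(eafs)

    def test_drift_orders_distances(self, ancestral_pool):
        """Two low-drift populations are closer to each other than to a
        high-drift one."""
        from transmap import derive_population_pool

        pops = [
            derive_population_pool(ancestral_pool, n, f, 1e-4, 800, seed=s)
            for n, f, s in [("p1", 0.01, 1), ("p2", 0.01, 2), ("p3", 0.2, 3)]
        ]
        eafs = {
            p.ancestry: pd.Series(p.frequencies, index=list(p.variant_ids))
            for p in pops
        }
        m = freq_distance_matrix(eafs)
        assert m.distance("p1", "p2") < m.distance("p1", "p3")
        assert m.distance("p1", "p2") < m.distance("p2", "p3")


class TestClades:
    def test_forced_by_distances(self):
        m = RelatednessMatrix(
            ("s1", "s2", "s3"),
            np.array([[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]]),
        )
        clades = cluster_clades(m, cut_height=0.1).clades()
        groups = {frozenset(v) for v in clades.values()}
        assert groups == {frozenset({"s1", "s2"}), frozenset({"s3"})}

    def test_single_clade(self):
        m = uniform_matrix(["a", "b", "c"])
        assert len(cluster_clades(m, n_clades=1).clades()) == 1

    def test_singleton_clades(self):
        m = uniform_matrix(["a", "b", "c"])
        assert len(cluster_clades(m, n_clades=3).clades()) == 3

    def test_too_many_clades(self):
        with pytest.raises(ArgumentError):
            cluster_clades(uniform_matrix(["a", "b"]), n_clades=3)


class TestPartitionEnumeration:
    def test_two_study_enumeration(self):
        parts = enumerate_centre_partitions(["a", "b"], uniform_matrix(["a", "b"]))
        by_clusters = {p.clusters: p.prior for p in parts}
        assert by_clusters == {
            (("a", "b"),): pytest.approx(0.5),
            (("a",), ("b",)): pytest.approx(0.5),
        }

    @pytest.mark.parametrize("n", range(2, 9))
    def test_priors_sum_to_one(self, n):
        names = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(n)
        d = rng.uniform(0.01, 0.3, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        parts = enumerate_centre_partitions(names, RelatednessMatrix(tuple(names), d))
        assert sum(p.prior for p in parts) == pytest.approx(1.0, abs=1e-12)
        for p in parts:  # each partition covers every study exactly once
            members = [s for c in p.clusters for s in c]
            assert sorted(members) == sorted(names)

    def test_capacity_bound(self):
        names = [f"s{i}" for i in range(21)]
        with pytest.raises(CapacityError):
            enumerate_centre_partitions(names, uniform_matrix(names))


class TestClusterMarginal:
    def test_single_study_closed_form(self):
        """BF for one study (beta=0.2, SE=0.1, tau=0.2) is 2.2151."""
        alt = cluster_marginal_loglik([0.2], [0.1], 0.2)
        null = null_loglik([0.2], [0.1])
        assert math.exp(alt - null) == pytest.approx(2.2151, abs=1e-4)
        assert (alt - null) / math.log(10) == pytest.approx(0.3454, abs=1e-4)

    def test_zero_estimate_closed_form(self):
        alt = cluster_marginal_loglik([0.0], [0.1], 0.2)
        null = null_loglik([0.0], [0.1])
        assert math.exp(alt - null) == pytest.approx(math.sqrt(0.01 / 0.05), abs=1e-9)

    def test_vanishing_tau_gives_unit_bf(self):
        alt = cluster_marginal_loglik([0.37, -0.2], [0.1, 0.2], 1e-6)
        null = null_loglik([0.37, -0.2], [0.1, 0.2])
        assert math.exp(alt - null) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "betas,ses",
        [
            ([0.2], [0.1]),
            ([0.1, 0.3], [0.1, 0.2]),
            ([0.0, 0.05, -0.1], [0.08, 0.12, 0.2]),
            ([0.25, 0.2, 0.31, 0.15], [0.05, 0.07, 0.06, 0.1]),
        ],
    )
    def test_matches_quadrature(self, betas, ses):
        closed = cluster_marginal_loglik(betas, ses, 0.2)
        numeric = quad_cluster_ml(betas, ses, 0.2)
        assert closed == pytest.approx(numeric, rel=1e-6, abs=1e-8)

    def test_bad_tau(self):
        with pytest.raises(ArgumentError):
            cluster_marginal_loglik([0.1], [0.1], 0.0)


class TestAssociationBF:
    def test_worked_two_study_value(self):
        m = uniform_matrix(["a", "b"])
        parts = enumerate_centre_partitions(["a", "b"], m)
        results = [make_assoc(beta=0.2, se=0.1)] * 2
        bf, weights = log10bf_association(results, parts, 0.2, ["a", "b"])
        assert bf == pytest.approx(0.9185, abs=1e-4)
        assert sum(weights) == pytest.approx(1.0)

    def test_null_estimates_give_negative_log10bf(self):
        m = uniform_matrix(["a", "b", "c"])
        parts = enumerate_centre_partitions(["a", "b", "c"], m)
        results = [make_assoc(beta=0.0, se=0.1)] * 3
        bf, _ = log10bf_association(results, parts, 0.2, ["a", "b", "c"])
        assert bf < 0

    def test_study_order_invariance(self):
        names = ["a", "b", "c"]
        m = uniform_matrix(names)
        parts = enumerate_centre_partitions(names, m)
        results = [
            make_assoc(beta=0.1, se=0.1),
            make_assoc(beta=0.25, se=0.08),
            make_assoc(beta=0.18, se=0.12),
        ]
        bf1, _ = log10bf_association(results, parts, 0.2, names)
        perm = [2, 0, 1]
        bf2, _ = log10bf_association(
            [results[i] for i in perm], parts, 0.2, [names[i] for i in perm]
        )
        assert bf2 == pytest.approx(bf1, rel=1e-12)


class TestHeterogeneityBF:
    def test_worked_identical_studies_value(self):
        m = uniform_matrix(["a", "b"])
        parts = enumerate_centre_partitions(["a", "b"], m)
        results = [make_assoc(beta=0.2, se=0.1)] * 2
        assert log10bf_heterogeneity(results, parts, 0.2, ["a", "b"]) == pytest.approx(
            -0.1486, abs=1e-4
        )

    def test_opposed_effects_favour_heterogeneity(self):
        m = uniform_matrix(["a", "b"])
        parts = enumerate_centre_partitions(["a", "b"], m)
        results = [make_assoc(beta=0.5, se=0.05), make_assoc(beta=-0.5, se=0.05)]
        assert log10bf_heterogeneity(results, parts, 0.2, ["a", "b"]) > 0

    def test_single_study_convention(self):
        assert log10bf_heterogeneity([make_assoc()], [], 0.2) == 0.0
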