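"""Generator contracts: determinism, drift, LD divergence, ascertainment."""

import numpy as np
import pytest

from transmap import (
    ArgumentError,
    CausalModel,
    SimulationError,
    degrade_dosages,
    derive_population_pool,
    fit_additive,
    measure_info,
    qc_variants,
    sim_ancestral_pool,
    sim_annotation,
    simulate_study,
)
from transmap.assoc import VariantRecord
from transmap.simdata import read_study_tsv, write_study_tsv


class TestAncestralPool:
    def test_contract(self, ancestral_pool):
        p = ancestral_pool
        assert p.n_variants == 60
        assert np.all(np.diff(p.positions) > 0)
        assert np.all((p.frequencies > 0) & (p.frequencies < 1))
        assert set(np.unique(p.haplotypes)) <= {0, 1}

    def test_seeded_determinism(self):
        a = sim_ancestral_pool(60, 100_000, 1000, seed=1)
        b = sim_ancestral_pool(60, 100_000, 1000, seed=1)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_seed_changes_output(self):
        a = sim_ancestral_pool(60, 100_000, 1000, seed=1)
        b = sim_ancestral_pool(60, 100_000, 1000, seed=2)
        assert not np.array_equal(a.haplotypes, b.haplotypes)

    def test_blockwise_ld_exists(self, ancestral_pool):
        h = ancestral_pool.haplotypes.astype(float)
        r = np.corrcoef(h, rowvar=False)
        adjacent = np.abs(np.diag(r, k=1))
        assert np.max(adjacent) > 0.5  # nontrivial LD between some neighbours

    @pytest.mark.parametrize("bad", [dict(n_variants=1), dict(n_haplotypes=0),
                                     dict(region_length=10)])
    def test_argument_errors(self, bad):
        kwargs = dict(n_variants=60, region_length=100_000, n_haplotypes=100, seed=1)
        kwargs.update(bad)
        with pytest.raises(ArgumentError):
            sim_ancestral_pool(**kwargs)


class TestPopulationPool:
    def test_no_drift_identity(self, ancestral_pool):
        pop = derive_population_pool(ancestral_pool, "X", F=0.0, switch_rate=0.0,
                                     n_haplotypes=1000, seed=3)
        assert np.allclose(pop.frequencies, ancestral_pool.realized_frequencies)

    def test_drift_scales_with_F(self, ancestral_pool):
        p = ancestral_pool.realized_frequencies
        lo = derive_population_pool(ancestral_pool, "lo", 0.01, 1e-4, 1000, seed=5)
        hi = derive_population_pool(ancestral_pool, "hi", 0.15, 1e-4, 1000, seed=5)
        assert (np.abs(hi.frequencies - p).mean()
                > np.abs(lo.frequencies - p).mean())

    def test_ld_structure_diverges(self, population_pools):
        a, b = population_pools[0], population_pools[2]
        ra = np.corrcoef(a.haplotypes.astype(float), rowvar=False) ** 2
        rb = np.corrcoef(b.haplotypes.astype(float), rowvar=False) ** 2
        assert np.nanmax(np.abs(ra - rb)) > 0

    def test_realized_frequency_is_column_mean(self, population_pools):
        pop = population_pools[0]
        assert np.allclose(pop.frequencies, pop.haplotypes.mean(axis=0))

    def test_negative_F_rejected(self, ancestral_pool):
        with pytest.raises(ArgumentError):
            derive_population_pool(ancestral_pool, "X", -0.1, 0.0, 100, seed=1)


class TestSimulateStudy:
    def test_contract(self, small_study):
        study, _ = small_study
        assert study.n_cases == 1500
        assert study.n_individuals == 3000
        assert study.dosages.min() >= 0 and study.dosages.max() <= 2
        assert set(np.unique(study.phenotype)) == {0, 1}
        assert study.covariates.shape == (3000, 2)

    def test_frequency_conservation(self, population_pools):
        """Study EAF within 4 binomial SEs of the population frequency."""
        pool = population_pools[0]
        causal = CausalModel((), np.array([]), alpha=0.0)
        study = simulate_study(pool, causal, 1000, 1000, 0, seed=9)
        p = pool.frequencies
        se = np.sqrt(p * (1 - p) / (2 * study.n_individuals))
        assert np.all(np.abs(study.eaf - p) <= 4 * se)

    def test_null_effects_give_null_association(self, population_pools):
        """With beta = 0 everywhere, |z| < 4 in at least 99% of seeds."""
        pool = population_pools[0]
        causal = CausalModel((), np.array([]), alpha=0.0)
        j = int(np.argmin(np.abs(pool.frequencies - 0.5)))
        hits = 0
        for seed in range(200):
            st = simulate_study(pool, causal, 500, 500, 0, seed=seed)
            r = fit_additive(st.dosages[:, j], st.phenotype)
            if abs(r.beta / r.se) < 4:
                hits += 1
        assert hits >= 198

    def test_effect_recovery(self, population_pools):
        """A planted OR of 1.3 is recovered within 3 SEs in >= 99% of seeds."""
        pool = population_pools[0]
        j = int(np.argmin(np.abs(pool.frequencies - 0.5)))
        beta_true = np.log(1.3)
        causal = CausalModel((pool.variant_ids[j],), np.array([beta_true]), alpha=-1.0)
        hits = 0
        for seed in range(200):
            st = simulate_study(pool, causal, 3000, 3000, 0, seed=seed)
            r = fit_additive(st.dosages[:, j], st.phenotype)
            if abs(r.beta - beta_true) <= 3 * r.se:
                hits += 1
        assert hits >= 198

    def test_zero_cases_rejected(self, population_pools):
        causal = CausalModel((), np.array([]), alpha=0.0)
        with pytest.raises(ArgumentError):
            simulate_study(population_pools[0], causal, 0, 100, 0, seed=1)

    def test_unknown_causal_rejected(self, population_pools):
        causal = CausalModel(("nope",), np.array([0.1]), alpha=0.0)
        with pytest.raises(ArgumentError):
            simulate_study(population_pools[0], causal, 10, 10, 0, seed=1)


class TestDegradeDosages:
    def test_identity_at_full_info(self, small_study):
        study, _ = small_study
        out = degrade_dosages(study, 1.0)
        assert np.array_equal(out.dosages, study.dosages)
        assert np.allclose(out.info, 1.0)

    def test_target_info_achieved(self, small_study):
        study, _ = small_study
        out = degrade_dosages(study, 0.5)
        common = study.eaf > 0.1
        assert np.all(out.info[common] >= 0.4)
        assert np.all(out.info[common] <= 0.6)

    def test_low_info_fails_qc(self, small_study):
        """A variant degraded to info 0.2 is dropped by the default filter."""
        study, _ = small_study
        out = degrade_dosages(study, 0.2)
        j = int(np.argmax(study.eaf * (1 - study.eaf)))
        rec = VariantRecord(
            snpid="v", chrom="chr1", pos=1, ea="A", oa="G",
            eaf=float(out.eaf[j]), info=float(out.info[j]), n=out.n_individuals,
        )
        assert qc_variants([rec]) == []

    def test_eaf_preserved(self, small_study):
        study, _ = small_study
        out = degrade_dosages(study, 0.6)
        assert np.allclose(out.eaf, study.eaf, atol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_target_rejected(self, small_study, bad):
        with pytest.raises(ArgumentError):
            degrade_dosages(small_study[0], bad)


class TestMeasureInfo:
    def test_hard_genotypes_near_one(self, small_study):
        study, _ = small_study
        common = study.eaf > 0.1
        assert np.all(measure_info(study.dosages)[common] > 0.9)


class TestSimAnnotation:
    def test_enrichment_forces_coverage(self):
        track = sim_annotation(10_000, 1, 400, [500], enrichment=1.0, seed=1)
        iv = track.intervals[0]
        assert iv.start <= 499 < iv.end

    def test_no_enrichment_rarely_covers(self):
        """Elements on <= 2% of the region cover the causal in <= 5% of seeds."""
        covered = 0
        for seed in range(1000):
            track = sim_annotation(100_000, 2, 800, [500], enrichment=0.0, seed=seed)
            covered += any(iv.start <= 499 < iv.end for iv in track.intervals)
        assert covered <= 50

    def test_zero_elements(self):
        assert len(sim_annotation(10_000, 0, 100, [], 0.5, seed=1)) == 0

    def test_intervals_disjoint(self):
        track = sim_annotation(5_000, 8, 300, [100, 900], enrichment=1.0, seed=2)
        ivs = sorted(track.intervals, key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_impossible_packing_raises(self):
        with pytest.raises(SimulationError):
            sim_annotation(1_000, 10, 400, [], enrichment=0.0, seed=1)


def test_study_tsv_round_trip(tmp_path, small_study):
    study, _ = small_study
    d, s = tmp_path / "d.tsv", tmp_path / "s.tsv"
    write_study_tsv(study, d, s)
    back = read_study_tsv(d, s, study.positions, ancestry=study.ancestry)
    assert back.variant_ids == study.variant_ids
    assert np.array_equal(back.phenotype, study.phenotype)
    assert np.allclose(back.dosages, study.dosages, atol=1e-5)
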