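"""Synthetic multi-ancestry case-control GWAS data.

Generates the statistical structure that transancestral fine-mapping
exploits: several populations descended from one ancestral haplotype pool,
with allele-frequency drift (Balding-Nichols) and divergent LD (haplotype
mosaics with population-specific template switching), shared causal variants
whose allelic effects are identical in every ancestry, case-control
ascertainment by rejection sampling, and imputation-quality degradation of
dosages.  Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .annotate import AnnotationTrack, Interval
from .exceptions import ArgumentError, SimulationError

# Cap on total individuals drawn while filling case/control quotas.
MAX_REJECTION_DRAWS = 10_000_000

# Latent-Gaussian autocorrelation within an LD block of the ancestral pool.
_BLOCK_RHO = 0.92
# Variants per LD block are drawn uniformly from this range.
_BLOCK_SIZE_RANGE = (4, 10)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralPool:
    """Ancestral variant panel: positions, frequencies and base haplotypes.

    Positions are 1-based bp within a region of ``region_length`` bp and
    strictly increasing.  ``frequencies`` are the latent allele frequencies
    the haplotypes were drawn around; the realized (empirical) frequencies
    are the column means of ``haplotypes``.
    """

    variant_ids: tuple[str, ...]
    positions: np.ndarray          # int, 1-based, strictly increasing
    frequencies: np.ndarray        # float in (0, 1)
    haplotypes: np.ndarray         # uint8, n_haplotypes x n_variants
    region_length: int

    @property
    def n_variants(self) -> int:
        return self.positions.size

    @property
    def realized_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class PopulationPool:
    """Population-level haplotype pool derived from an ancestral pool."""

    ancestry: str
    F: float                       # FST-like drift parameter, >= 0
    switch_rate: float             # per-bp mosaic template switch rate
    variant_ids: tuple[str, ...]
    positions: np.ndarray
    haplotypes: np.ndarray         # uint8, n_haplotypes x n_variants
    frequencies: np.ndarray        # realized column means of `haplotypes`

    @property
    def n_variants(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class CausalModel:
    """Shared-effect disease model: logit P(case) = alpha + sum(beta * g).

    The same log-odds-ratio ``beta`` applies in every ancestry; the model of
    homogeneous allelic effects across populations is the working assumption
    of the whole analysis.
    """

    variant_ids: tuple[str, ...]
    betas: np.ndarray              # log-OR per effect-allele copy
    alpha: float                   # baseline log-odds of disease

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        if betas.shape != (len(self.variant_ids),):
            raise ArgumentError("one beta per causal variant required")
        if not np.all(np.isfinite(betas)):
            raise ArgumentError("causal effects must be finite")
        object.__setattr__(self, "betas", betas)


@dataclass(frozen=True)
class StudyDataset:
    """One simulated case-control study."""

    ancestry: str
    variant_ids: tuple[str, ...]
    positions: np.ndarray
    dosages: np.ndarray            # float, individuals x variants, in [0, 2]
    phenotype: np.ndarray          # int, case=1 / control=0
    covariates: np.ndarray         # float, individuals x n_covariates
    info: np.ndarray               # per-variant imputation quality in [0, 1]

    @property
    def n_individuals(self) -> int:
        return self.phenotype.size

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def eaf(self) -> np.ndarray:
        """Realized effect-allele frequency of each variant."""
        return self.dosages.mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sim_ancestral_pool(
    n_variants: int,
    region_length: int,
    n_haplotypes: int,
    seed: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> AncestralPool:
    """Simulate the ancestral variant panel with block-wise LD.

    Haplotypes come from a latent Gaussian AR(1) process restarted at LD
    block boundaries and thresholded at each variant's frequency quantile, so
    nearby variants within a block are strongly correlated while blocks are
    independent.
    """
    if n_variants < 2 or n_haplotypes <= 0:
        raise ArgumentError("n_variants >= 2 and n_haplotypes > 0 required")
    if region_length < n_variants:
        raise ArgumentError("region_length must be >= n_variants")
    rng = np.random.default_rng(seed)

    positions = np.sort(rng.choice(region_length, size=n_variants, replace=False) + 1)
    freqs = rng.uniform(*freq_range, size=n_variants)

    # assign variants to LD blocks
    block_start = np.zeros(n_variants, dtype=bool)
    j = 0
    while j < n_variants:
        block_start[j] = True
        j += int(rng.integers(*_BLOCK_SIZE_RANGE, endpoint=True))

    z = np.empty((n_haplotypes, n_variants))
    eps = rng.standard_normal((n_haplotypes, n_variants))
    for j in range(n_variants):
        if block_start[j]:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = _BLOCK_RHO * z[:, j - 1] + np.sqrt(1 - _BLOCK_RHO**2) * eps[:, j]
    haplotypes = (z < ndtri(freqs)).astype(np.uint8)

    ids = tuple(f"var{j:04d}" for j in range(n_variants))
    return AncestralPool(ids, positions, freqs, haplotypes, int(region_length))


def derive_population_pool(
    ancestral: AncestralPool,
    ancestry: str,
    F: float,
    switch_rate: float,
    n_haplotypes: int,
    seed: int,
) -> PopulationPool:
    """Derive a drifted population from the ancestral pool.

    Per-variant target frequencies follow the Balding-Nichols model
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p (taken as
    the ancestral pool's realized frequency; target = p exactly when F = 0).
    Haplotypes are mosaics of ancestral templates with switches at the given
    per-bp rate, then a minimal number of alleles is flipped per variant so
    the realized frequency matches the drifted target.
    """
    if F < 0:
        raise ArgumentError("drift parameter F must be >= 0")
    if switch_rate < 0:
        raise ArgumentError("switch_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n_var = ancestral.n_variants
    p = ancestral.realized_frequencies

    if F > 0:
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        target = rng.beta(a, b)
    else:
        target = p.copy()

    # mosaic copying with per-gap switch probability 1 - exp(-rate * gap)
    gaps = np.diff(ancestral.positions)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    n_templates = ancestral.haplotypes.shape[0]
    haps = np.empty((n_haplotypes, n_var), dtype=np.uint8)
    templates = rng.integers(0, n_templates, size=n_haplotypes)
    haps[:, 0] = ancestral.haplotypes[templates, 0]
    for j in range(1, n_var):
        switch = rng.random(n_haplotypes) < p_switch[j - 1]
        if switch.any():
            templates = np.where(
                switch, rng.integers(0, n_templates, size=n_haplotypes), templates
            )
        haps[:, j] = ancestral.haplotypes[templates, j]

    # flip a minimal set of alleles to hit the drifted target count
    want = np.clip(np.rint(target * n_haplotypes).astype(int), 1, n_haplotypes - 1)
    for j in range(n_var):
        have = int(haps[:, j].sum())
        if have < want[j]:
            zeros = np.flatnonzero(haps[:, j] == 0)
            flip = rng.choice(zeros, size=want[j] - have, replace=False)
            haps[flip, j] = 1
        elif have > want[j]:
            ones = np.flatnonzero(haps[:, j] == 1)
            flip = rng.choice(ones, size=have - want[j], replace=False)
            haps[flip, j] = 0

    return PopulationPool(
        ancestry=ancestry,
        F=float(F),
        switch_rate=float(switch_rate),
        variant_ids=ancestral.variant_ids,
        positions=ancestral.positions,
        haplotypes=haps,
        frequencies=haps.mean(axis=0),
    )


def simulate_study(
    pool: PopulationPool,
    causal: CausalModel,
    n_case: int,
    n_control: int,
    n_covariates: int,
    seed: int,
) -> StudyDataset:
    """Simulate a case-control study from a population pool.

    Individuals pair two haplotypes drawn with replacement; disease status
    follows logistic(alpha + sum beta*g); rejection sampling accumulates
    cases and controls until both quotas are met (hard cap on total draws).
    Covariates are null: standard normal, independent of genotype and
    phenotype, standing in for the principal components and study covariates
    a real analysis adjusts for.
    """
    if n_case <= 0 or n_control <= 0:
        raise ArgumentError("n_case and n_control must be positive")
    if n_covariates < 0:
        raise ArgumentError("n_covariates must be >= 0")
    idx = []
    for vid in causal.variant_ids:
        if vid not in pool.variant_ids:
            raise ArgumentError(f"causal variant {vid!r} not in pool")
        idx.append(pool.variant_ids.index(vid))
    causal_idx = np.asarray(idx, dtype=int)

    rng = np.random.default_rng(seed)
    n_hap, n_var = pool.haplotypes.shape
    need = n_case + n_control
    cases, controls = [], []
    got_case = got_control = 0
    drawn = 0
    batch = max(2048, need)
    while got_case < n_case or got_control < n_control:
        if drawn >= MAX_REJECTION_DRAWS:
            raise SimulationError(
                f"case/control quota ({n_case}/{n_control}) unreachable within "
                f"{MAX_REJECTION_DRAWS} draws: have {got_case}/{got_control}"
            )
        b = min(batch, MAX_REJECTION_DRAWS - drawn)
        h1 = rng.integers(0, n_hap, size=b)
        h2 = rng.integers(0, n_hap, size=b)
        geno = (pool.haplotypes[h1] + pool.haplotypes[h2]).astype(np.float64)
        lp = causal.alpha + geno[:, causal_idx] @ causal.betas
        y = rng.random(b) < expit(lp)
        drawn += b
        if got_case < n_case:
            take = geno[y][: n_case - got_case]
            cases.append(take)
            got_case += take.shape[0]
        if got_control < n_control:
            take = geno[~y][: n_control - got_control]
            controls.append(take)
            got_control += take.shape[0]

    dosages = np.vstack([np.vstack(cases), np.vstack(controls)])
    phenotype = np.concatenate(
        [np.ones(n_case, dtype=np.int8), np.zeros(n_control, dtype=np.int8)]
    )
    covariates = rng.standard_normal((need, n_covariates))
    return StudyDataset(
        ancestry=pool.ancestry,
        variant_ids=pool.variant_ids,
        positions=pool.positions,
        dosages=dosages,
        phenotype=phenotype,
        covariates=covariates,
        info=np.ones(n_var),
    )


def measure_info(dosages: np.ndarray) -> np.ndarray:
    """Imputation quality as the ratio of observed dosage variance to the
    Hardy-Weinberg expectation 2*EAF*(1-EAF), clamped to [0, 1]."""
    eaf = dosages.mean(axis=0) / 2.0
    expected = 2.0 * eaf * (1.0 - eaf)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, dosages.var(axis=0) / expected, 0.0)
    return np.clip(ratio, 0.0, 1.0)


def degrade_dosages(
    study: StudyDataset,
    target_info: float | np.ndarray,
    seed: int = 0,
) -> StudyDataset:
    """Degrade hard genotypes to mimic imputation at a target info score.

    Dosages are shrunk toward the variant mean 2*EAF by sqrt(target_info),
    which scales the dosage variance by target_info while preserving the
    allele frequency and the [0, 2] bounds; the realized variance-ratio info
    then matches the target up to Hardy-Weinberg sampling noise.  The
    transform is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    target = np.broadcast_to(
        np.asarray(target_info, dtype=float), (len(study.variant_ids),)
    ).copy()
    if np.any(target <= 0) or np.any(target > 1):
        raise ArgumentError("target_info must lie in (0, 1]")
    lam = np.sqrt(target)
    mean = study.dosages.mean(axis=0)
    dosages = mean + lam * (study.dosages - mean)
    full = target == 1.0
    if full.all():
        dosages = study.dosages
    else:
        dosages[:, full] = study.dosages[:, full]
    # undegraded hard genotypes count as perfect quality by definition
    info = np.where(full, 1.0, measure_info(dosages))
    return replace(study, dosages=dosages, info=info)


def sim_annotation(
    region_length: int,
    n_elements: int,
    element_length: int,
    causal_positions: list[int],
    enrichment: float,
    seed: int,
    chrom: str = "chr1",
    max_tries: int = 10_000,
) -> AnnotationTrack:
    """Simulate a regulatory-element track (0-based half-open intervals).

    With probability ``enrichment`` each causal position (1-based) is covered
    by an element; remaining elements are placed uniformly.  Elements never
    overlap; placement failure after ``max_tries`` rejections raises.
    """
    if n_elements < 0 or element_length <= 0:
        raise ArgumentError("n_elements >= 0 and element_length > 0 required")
    if not 0.0 <= enrichment <= 1.0:
        raise ArgumentError("enrichment must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []

    def overlaps(a: int, b: int) -> bool:
        return any(a < e and s < b for s, e in placed)

    n_left = n_elements
    for pos in causal_positions:
        if n_left == 0:
            break
        if rng.random() < enrichment:
            pos0 = pos - 1  # 1-based variant position -> 0-based coordinate
            lo = max(0, pos0 - element_length + 1)
            hi = min(pos0, region_length - element_length)
            for _ in range(max_tries):
                start = int(rng.integers(lo, hi + 1))
                if not overlaps(start, start + element_length):
                    placed.append((start, start + element_length))
                    n_left -= 1
                    break
            else:
                raise SimulationError("cannot place causal-covering element")
    for _ in range(n_left):
        for _ in range(max_tries):
            start = int(rng.integers(0, region_length - element_length + 1))
            if not overlaps(start, start + element_length):
                placed.append((start, start + element_length))
                break
        else:
            raise SimulationError(
                f"cannot place {n_elements} non-overlapping elements "
                f"of {element_length} bp in {region_length} bp"
            )

    placed.sort()
    intervals = [
        Interval(chrom, s, e, state=f"enh{k}", tissue="islet")
        for k, (s, e) in enumerate(placed)
    ]
    return AnnotationTrack(intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_study_tsv(study: StudyDataset, dosage_path, sample_path) -> None:
    """Write a study as a documented TSV pair.

    ``dosage_path``: one row per individual, one column per variant id.
    ``sample_path``: PHENOTYPE column plus COV1..COVk columns.
    """
    pd.DataFrame(study.dosages, columns=list(study.variant_ids)).to_csv(
        dosage_path, sep="\t", index=False, float_format="%.6g"
    )
    samples = pd.DataFrame({"PHENOTYPE": study.phenotype})
    for k in range(study.covariates.shape[1]):
        samples[f"COV{k + 1}"] = study.covariates[:, k]
    samples.to_csv(sample_path, sep="\t", index=False, float_format="%.6g")


def read_study_tsv(
    dosage_path, sample_path, positions: np.ndarray, ancestry: str = "NA"
) -> StudyDataset:
    """Read back a study written by :func:`write_study_tsv`."""
    dos = pd.read_csv(dosage_path, sep="\t")
    samples = pd.read_csv(sample_path, sep="\t")
    cov_cols = [c for c in samples.columns if c.startswith("COV")]
    dosages = dos.to_numpy(dtype=float)
    return StudyDataset(
        ancestry=ancestry,
        variant_ids=tuple(dos.columns),
        positions=np.asarray(positions),
        dosages=dosages,
        phenotype=samples["PHENOTYPE"].to_numpy(dtype=np.int8),
        covariates=samples[cov_cols].to_numpy(dtype=float),
        info=measure_info(dosages),
    )
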