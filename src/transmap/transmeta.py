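"""Bayesian transancestral meta-analysis.

A Bayesian hybrid of fixed- and random-effects meta-analysis in the style of
MANTRA: studies are grouped into clusters by a centre-based Bayesian
partition model of study relatedness (pairwise mean absolute allele-
frequency difference), all studies within a cluster share one allelic
log-OR drawn from a N(0, tau^2) prior, and distinct clusters have
independent effects.  Averaging the marginal likelihood over all partitions
yields a Bayes factor for association that tolerates between-ancestry
heterogeneity in allelic effects arising from LD differences with a shared
causal variant, and a second Bayes factor for heterogeneity that compares
the unconstrained clustering against the single-cluster (fixed-effect-like)
model.

Per-study likelihoods are the usual summary-statistic normal approximation
N(beta_hat_s; b, SE_s^2), so every cluster marginal likelihood has the
closed form of a zero-mean multivariate normal with covariance
diag(SE^2) + tau^2 * J, evaluated here via the Sherman-Morrison identity.
All Bayes-factor arithmetic is carried in natural-log space.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .assoc import AssocResult
from .exceptions import ArgumentError, CapacityError, DataError
from .fixedmeta import FixedMetaResult, ivw_combine

logger = logging.getLogger(__name__)

LOG10 = math.log(10.0)
ENUMERATION_LIMIT = 20  # exhaustive centre-set enumeration bound

# genome-wide significance on the Bayesian scale
GENOME_WIDE_LOG10BF = 6.0


# ---------------------------------------------------------------------------
# study relatedness and clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelatednessMatrix:
    """Pairwise mean absolute effect-allele-frequency differences."""

    studies: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.studies),) * 2:
            raise ArgumentError("matrix shape must match the study list")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ArgumentError("matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "matrix", m)

    def distance(self, a: str, b: str) -> float:
        i, j = self.studies.index(a), self.studies.index(b)
        return float(self.matrix[i, j])


@dataclass(frozen=True)
class CladeAssignment:
    assignment: dict[str, int]  # study -> clade label
    method: str
    cut: float

    def clades(self) -> dict[int, tuple[str, ...]]:
        out: dict[int, list[str]] = {}
        for study, label in self.assignment.items():
            out.setdefault(label, []).append(study)
        return {k: tuple(v) for k, v in out.items()}


def freq_distance_matrix(study_eafs: dict[str, pd.Series]) -> RelatednessMatrix:
    """Relatedness between studies from post-QC allele frequencies.

    d(s, t) = mean over shared variants of |EAF_s - EAF_t|, with effect
    alleles harmonized upstream.  A pair with no shared variant is an error.
    """
    names = tuple(study_eafs)
    if len(names) < 2:
        raise ArgumentError("at least two studies required")
    k = len(names)
    m = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        a, b = study_eafs[names[i]], study_eafs[names[j]]
        shared = a.index.intersection(b.index)
        if shared.empty:
            raise DataError(f"no shared variants between {names[i]} and {names[j]}")
        d = float((a.loc[shared] - b.loc[shared]).abs().mean())
        m[i, j] = m[j, i] = d
    return RelatednessMatrix(studies=names, matrix=m)


def cluster_clades(
    matrix: RelatednessMatrix,
    n_clades: int | None = None,
    cut_height: float | None = None,
) -> CladeAssignment:
    """Average-linkage hierarchical clustering of studies into clades."""
    k = len(matrix.studies)
    if (n_clades is None) == (cut_height is None):
        raise ArgumentError("give exactly one of n_clades or cut_height")
    if n_clades is not None and not 1 <= n_clades <= k:
        raise ArgumentError(f"n_clades must lie in [1, {k}]")
    if k == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(matrix.matrix, checks=False), method="average")
        if n_clades is not None:
            labels = fcluster(z, t=n_clades, criterion="maxclust")
            cut = float(n_clades)
        else:
            labels = fcluster(z, t=cut_height, criterion="distance")
            cut = float(cut_height)
    if n_clades is not None:
        cut = float(n_clades)
    elif k == 1:
        cut = float(cut_height if cut_height is not None else 0.0)
    return CladeAssignment(
        assignment=dict(zip(matrix.studies, (int(x) for x in labels))),
        method="average",
        cut=cut,
    )


# ---------------------------------------------------------------------------
# the Bayesian partition model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors of the partition model.

    ``tau`` is the standard deviation of the N(0, tau^2) prior on the
    cluster-level allelic log-OR (default 0.2, spanning typical complex-
    trait effect sizes).  The partition prior is uniform over the number of
    centres T, and uniform over centre sets of a given T.
    """

    tau: float = 0.2

    def __post_init__(self):
        if self.tau <= 0:
            raise ArgumentError("tau must be positive")


@dataclass(frozen=True)
class Partition:
    """A clustering of studies induced by a set of centres.

    Each study is assigned to its nearest centre under the relatedness
    distance (ties to the lowest-index centre); centre sets that induce the
    same grouping have their prior mass aggregated.
    """

    clusters: tuple[tuple[str, ...], ...]
    prior: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def enumerate_centre_partitions(
    studies: list[str],
    matrix: RelatednessMatrix,
    prior: PriorSpec | None = None,
) -> list[Partition]:
    """Enumerate every centre-induced partition with its prior mass.

    All 2^N - 1 non-empty centre sets are enumerated; a centre set of size T
    carries prior (1/N) * (1 / C(N, T)), so the prior is uniform over T and,
    given T, uniform over centre sets.  Centre sets inducing the same
    partition pool their mass; the returned priors sum to 1.
    """
    n = len(studies)
    if n == 0:
        raise ArgumentError("no studies")
    if n > ENUMERATION_LIMIT:
        raise CapacityError(
            f"{n} studies exceeds the exhaustive enumeration bound of "
            f"{ENUMERATION_LIMIT}; a sampling mode is not provided"
        )
    order = {s: i for i, s in enumerate(studies)}
    midx = [matrix.studies.index(s) for s in studies]
    d = matrix.matrix[np.ix_(midx, midx)]

    masses: dict[tuple[tuple[str, ...], ...], float] = {}
    for t in range(1, n + 1):
        w = (1.0 / n) / math.comb(n, t)
        for centres in itertools.combinations(range(n), t):
            # nearest-centre assignment, ties to the lowest-index centre
            groups: dict[int, list[str]] = {c: [] for c in centres}
            for i in range(n):
                best = min(centres, key=lambda c: (d[i, c], c))
                groups[best].append(studies[i])
            key = tuple(
                sorted(
                    (tuple(sorted(g, key=order.get)) for g in groups.values() if g),
                    key=lambda g: order[g[0]],
                )
            )
            masses[key] = masses.get(key, 0.0) + w
    return [Partition(clusters=k, prior=v) for k, v in masses.items()]


def single_cluster_partition(studies: list[str]) -> Partition:
    """The homogeneity reference: every study in one cluster, prior 1."""
    return Partition(clusters=(tuple(studies),), prior=1.0)


# ---------------------------------------------------------------------------
# marginal likelihoods and Bayes factors
# ---------------------------------------------------------------------------

def cluster_marginal_loglik(betas, ses, tau: float) -> float:
    """Log marginal likelihood of one cluster's estimates under a shared
    effect b ~ N(0, tau^2):

        log integral prod_s N(beta_s; b, SE_s^2) N(b; 0, tau^2) db,

    i.e. the zero-mean multivariate normal log-density with covariance
    diag(SE^2) + tau^2 * J, evaluated by Sherman-Morrison.
    """
    if tau <= 0:
        raise ArgumentError("tau must be positive")
    x = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se <= 0):
        raise ArgumentError("standard errors must be positive")
    prec = 1.0 / se**2
    s = float(np.sum(prec))
    quad = float(np.sum(x**2 * prec)) - tau**2 / (1.0 + tau**2 * s) * float(
        np.sum(x * prec)
    ) ** 2
    logdet = float(np.sum(np.log(se**2))) + math.log1p(tau**2 * s)
    k = x.size
    return -0.5 * (k * math.log(2 * math.pi) + logdet + quad)


def null_loglik(betas, ses) -> float:
    """Log likelihood with every effect fixed at zero."""
    x = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    return float(np.sum(norm.logpdf(x, loc=0.0, scale=se)))


def _partition_logml(
    partition: Partition,
    est: dict[str, tuple[float, float]],
    tau: float,
) -> float:
    total = 0.0
    for cluster in partition.clusters:
        b = [est[s][0] for s in cluster]
        se = [est[s][1] for s in cluster]
        total += cluster_marginal_loglik(b, se, tau)
    return total


@dataclass(frozen=True)
class BayesMetaResult:
    """Transancestral meta-analysis result for one variant."""

    snpid: str
    pos: int
    log10_bf: float
    log10_bf_het: float
    partition_weights: tuple[float, ...]  # posterior over enumerated partitions
    fixed: FixedMetaResult
    shadow: bool = False

    @property
    def genome_wide(self) -> bool:
        """Dual significance rule: Bayesian and frequentist thresholds both met."""
        from .fixedmeta import GENOME_WIDE_P

        return (
            self.log10_bf >= GENOME_WIDE_LOG10BF and self.fixed.p < GENOME_WIDE_P
        )


def log10bf_association(
    per_study_results: list[AssocResult],
    partitions: list[Partition],
    tau: float = 0.2,
    study_names: list[str] | None = None,
) -> tuple[float, tuple[float, ...]]:
    """Bayes factor for association, averaged over partitions.

    Alternative marginal likelihood: sum over partitions of prior times the
    product of cluster marginal likelihoods; null: every study effect fixed
    at zero.  Returns (log10 BF, posterior partition weights).
    """
    if study_names is None:
        study_names = [f"s{i}" for i in range(len(per_study_results))]
    est = _estimates(per_study_results, study_names, partitions)

    log_terms = np.array(
        [math.log(p.prior) + _partition_logml(p, est, tau) for p in partitions]
    )
    m = float(np.max(log_terms))
    log_alt = m + math.log(float(np.sum(np.exp(log_terms - m))))
    weights = np.exp(log_terms - log_alt)

    betas = [est[s][0] for s in est]
    ses = [est[s][1] for s in est]
    log_null = null_loglik(betas, ses)
    return (log_alt - log_null) / LOG10, tuple(float(w) for w in weights)


def log10bf_heterogeneity(
    per_study_results: list[AssocResult],
    partitions: list[Partition],
    tau: float = 0.2,
    study_names: list[str] | None = None,
) -> float:
    """Bayes factor for heterogeneity in allelic effects.

    Compares the partition-averaged (unconstrained-clustering) marginal
    likelihood against the single-cluster model in which every study shares
    one effect; values above zero favour between-study heterogeneity.  A
    single study returns 0 by convention.
    """
    if len(per_study_results) < 2:
        return 0.0
    if study_names is None:
        study_names = [f"s{i}" for i in range(len(per_study_results))]
    est = _estimates(per_study_results, study_names, partitions)

    log_terms = np.array(
        [math.log(p.prior) + _partition_logml(p, est, tau) for p in partitions]
    )
    m = float(np.max(log_terms))
    log_alt = m + math.log(float(np.sum(np.exp(log_terms - m))))
    single = single_cluster_partition(list(est))
    log_single = _partition_logml(single, est, tau)
    return (log_alt - log_single) / LOG10


def _estimates(
    results: list[AssocResult],
    study_names: list[str],
    partitions: list[Partition],
) -> dict[str, tuple[float, float]]:
    if len(results) != len(study_names):
        raise ArgumentError("study_names and results lengths differ")
    est = {
        name: (r.beta, r.se)
        for name, r in zip(study_names, results)
        if r.converged and np.isfinite(r.se) and r.se > 0
    }
    if not est:
        raise ArgumentError("no converged study results")
    needed = {s for p in partitions for c in p.clusters for s in c}
    if needed - set(est):
        raise ArgumentError(
            f"partitions reference studies without results: {sorted(needed - set(est))}"
        )
    if set(est) - needed:
        raise ArgumentError(
            f"results for studies absent from partitions: {sorted(set(est) - needed)}"
        )
    return est


def meta_analyse_variant(
    per_study_results: list[AssocResult],
    partitions: list[Partition],
    tau: float = 0.2,
    study_names: list[str] | None = None,
) -> BayesMetaResult:
    """Full transancestral meta-analysis of one variant: association BF,
    heterogeneity BF and the fixed-effects companion."""
    usable = [r for r in per_study_results if r.converged]
    l10, weights = log10bf_association(per_study_results, partitions, tau, study_names)
    l10_het = log10bf_heterogeneity(per_study_results, partitions, tau, study_names)
    fixed = ivw_combine(per_study_results)
    first = usable[0]
    return BayesMetaResult(
        snpid=first.snpid,
        pos=first.pos,
        log10_bf=l10,
        log10_bf_het=l10_het,
        partition_weights=weights,
        fixed=fixed,
        shadow=any(r.shadow for r in usable),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_transmeta_tsv(results: list[BayesMetaResult], path) -> None:
    rows = [
        {
            "SNPID": r.snpid, "POS": r.pos,
            "LOG10BF": r.log10_bf, "LOG10BF_HET": r.log10_bf_het,
            "BETA": r.fixed.beta, "SE": r.fixed.se, "OR": r.fixed.or_,
            "CI_L": r.fixed.ci_low, "CI_U": r.fixed.ci_high, "P": r.fixed.p,
            "Q": r.fixed.q, "Q_DF": r.fixed.q_df, "Q_P": r.fixed.q_p,
            "N_STUDIES": r.fixed.n_studies,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_relatedness(matrix: RelatednessMatrix, clades: CladeAssignment,
                      tsv_path, json_path) -> None:
    import json

    pd.DataFrame(
        matrix.matrix, index=list(matrix.studies), columns=list(matrix.studies)
    ).to_csv(tsv_path, sep="\t")
    with open(json_path, "w") as fh:
        json.dump(
            {
                "studies": list(matrix.studies),
                "clades": {s: int(c) for s, c in clades.assignment.items()},
                "method": clades.method,
                "cut": clades.cut,
            },
            fh,
            indent=2,
        )
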