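"""Credible sets for distinct association signals.

Under the assumption of a single causal variant per signal and a uniform
prior over which locus variant it is, the posterior probability that
variant j drives the signal is its Bayes factor divided by the locus sum,

    pi_j = BF_j / sum_k BF_k,

with the BFs taken from the (conditional) transancestral meta-analysis.
The 99% credible set is the minimal prefix of variants, ranked by
descending BF, whose cumulative posterior mass reaches the level; under
model correctness it contains the causal variant with that probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ArgumentError

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class CredibleVariant:
    snpid: str
    position: int
    log10_bf: float
    pi: float
    cumulative: float


@dataclass(frozen=True)
class CredibleSet:
    signal: str
    variants: tuple[CredibleVariant, ...]
    level: float

    @property
    def total_mass(self) -> float:
        return self.variants[-1].cumulative if self.variants else 0.0

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def interval(self) -> tuple[int, int]:
        pos = [v.position for v in self.variants]
        return (min(pos), max(pos))

    @property
    def distance_bp(self) -> int:
        """Inclusive genomic span of the set: max - min + 1."""
        lo, hi = self.interval
        return hi - lo + 1

    def contains(self, snpid: str) -> bool:
        return any(v.snpid == snpid for v in self.variants)


def posterior_probs(log10_bfs: dict[str, float]) -> dict[str, float]:
    """Per-variant posterior masses pi_j = BF_j / sum_k BF_k.

    Computed in log space with max-subtraction so that very large log10 BFs
    (the interesting case) never overflow.
    """
    if not log10_bfs:
        raise ArgumentError("no Bayes factors supplied")
    ids = list(log10_bfs)
    lam = np.array([log10_bfs[i] for i in ids], dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ArgumentError("Bayes factors must be finite")
    m = lam.max()
    w = np.power(10.0, lam - m)
    w /= w.sum()
    return dict(zip(ids, (float(x) for x in w)))


def build_credible_set(
    probs: dict[str, float],
    positions: dict[str, int],
    level: float = 0.99,
    log10_bfs: dict[str, float] | None = None,
    signal: str = ".",
) -> CredibleSet:
    """Minimal credible set at the given level.

    Variants are ranked by descending posterior mass (equivalently BF),
    ties broken by smaller position then lexicographic identifier, and the
    shortest prefix whose cumulative mass reaches ``level`` (inclusive) is
    kept.
    """
    if not 0.0 < level < 1.0:
        raise ArgumentError("level must lie in (0, 1)")
    if not probs:
        raise ArgumentError("empty posterior")
    total = sum(probs.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ArgumentError(f"posterior masses sum to {total}, not 1")
    ranked = sorted(probs, key=lambda v: (-probs[v], positions[v], v))
    variants = []
    cum = 0.0
    for vid in ranked:
        cum += probs[vid]
        variants.append(
            CredibleVariant(
                snpid=vid,
                position=int(positions[vid]),
                log10_bf=(log10_bfs or {}).get(vid, float("nan")),
                pi=probs[vid],
                cumulative=cum,
            )
        )
        if cum >= level:
            break
    return CredibleSet(signal=signal, variants=tuple(variants), level=level)


def credset_summary(cs: CredibleSet) -> tuple[int, tuple[int, int], int]:
    """(variant count, (min, max) positions, inclusive span in bp)."""
    if not cs.variants:
        raise ArgumentError("empty credible set")
    return cs.n_variants, cs.interval, cs.distance_bp


def credible_set_from_log10bfs(
    log10_bfs: dict[str, float],
    positions: dict[str, int],
    level: float = 0.99,
    signal: str = ".",
) -> CredibleSet:
    """Convenience: posterior masses then the credible set in one step."""
    probs = posterior_probs(log10_bfs)
    return build_credible_set(
        probs, positions, level=level, log10_bfs=log10_bfs, signal=signal
    )


def write_credset_tsv(cs: CredibleSet, path) -> None:
    rows = [
        {
            "SNPID": v.snpid, "POS": v.position, "LOG10BF": v.log10_bf,
            "PI": v.pi, "CUM_PI": v.cumulative,
        }
        for v in cs.variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_comparison_tsv(sets_by_analysis: dict[str, dict[str, CredibleSet]], path) -> None:
    """Summary table comparing credible sets across analyses.

    ``sets_by_analysis`` maps analysis label (a clade subset or the full
    transancestral analysis) to {signal -> CredibleSet}; one row per signal
    and analysis with the set size, span and interval.
    """
    rows = []
    for analysis, by_signal in sets_by_analysis.items():
        for signal, cs in by_signal.items():
            lo, hi = cs.interval
            rows.append(
                {
                    "ANALYSIS": analysis, "SIGNAL": signal,
                    "N_SNPS": cs.n_variants, "DISTANCE_BP": cs.distance_bp,
                    "INTERVAL_LO": lo, "INTERVAL_HI": hi,
                    "TOTAL_MASS": cs.total_mass,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
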