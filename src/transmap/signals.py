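"""Delineation of distinct association signals by conditional analysis.

A locus may harbour several causal variants; each gives rise to a distinct
association signal represented by an index variant.  Signals are separated
by stepwise conditioning: at each round every study is refit with the
dosages of the current index variants as extra covariates, the conditional
results are meta-analysed transancestrally, and the strongest remaining
variant becomes a new index if it still attains genome-wide significance on
BOTH scales (log10 BF >= 6 and fixed-effects P < 5e-8).  Index variants
are then refined by leave-one-out conditioning: each signal's index is
re-scanned while conditioning on all the other indexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocResult, qc_variants, study_scan, VariantRecord, completeness_filter
from .exceptions import ArgumentError
from .fixedmeta import GENOME_WIDE_P
from .simdata import StudyDataset
from .transmeta import (
    GENOME_WIDE_LOG10BF,
    BayesMetaResult,
    Partition,
    PriorSpec,
    RelatednessMatrix,
    enumerate_centre_partitions,
    freq_distance_matrix,
    meta_analyse_variant,
)

logger = logging.getLogger(__name__)

MAX_ROUNDS = 10
MAX_REFINE_ITERATIONS = 10


@dataclass(frozen=True)
class Signal:
    """One distinct association signal at a locus."""

    index: str
    conditioned_on: tuple[str, ...]
    result: BayesMetaResult

    def __post_init__(self):
        if self.index in self.conditioned_on:
            raise ArgumentError("a signal's index cannot condition on itself")


@dataclass(frozen=True)
class TraceRow:
    round: int
    lead: str
    log10_bf: float
    p: float
    decision: str  # "accept" | "stop" | "cap"


@dataclass(frozen=True)
class DelineationTrace:
    rows: tuple[TraceRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ROUND": r.round, "LEAD": r.lead,
                    "LOG10BF": r.log10_bf, "P": r.p, "DECISION": r.decision,
                }
                for r in self.rows
            ]
        )


class Locus:
    """All per-study genotype-level data for one locus, with the QC
    settings and partition model needed for conditional meta-analysis.

    Partitions are enumerated lazily per contributing-study subset (a
    variant may be missing from a study after QC) and cached.
    """

    def __init__(
        self,
        studies: list[StudyDataset],
        study_names: list[str] | None = None,
        prior: PriorSpec | None = None,
        maf_min: float = 0.01,
        info_min: float = 0.4,
        min_fraction: float = 0.8,
        chrom: str = "chr1",
    ):
        if not studies:
            raise ArgumentError("a locus needs at least one study")
        self.studies = studies
        self.study_names = study_names or [
            f"{s.ancestry}_{i}" for i, s in enumerate(studies)
        ]
        self.prior = prior or PriorSpec()
        self.maf_min = maf_min
        self.info_min = info_min
        self.min_fraction = min_fraction
        self.chrom = chrom
        self._partition_cache: dict[frozenset, list[Partition]] = {}

        # per-study post-QC variant sets
        self.qc_ids: dict[str, set[str]] = {}
        for name, st in zip(self.study_names, studies):
            recs = [
                VariantRecord(
                    snpid=vid, chrom=chrom, pos=int(st.positions[j]),
                    ea="A", oa="G", eaf=float(st.eaf[j]),
                    info=float(st.info[j]), n=st.n_individuals,
                )
                for j, vid in enumerate(st.variant_ids)
            ]
            self.qc_ids[name] = {r.snpid for r in qc_variants(recs, maf_min, info_min)}

        self.total_n = sum(s.n_individuals for s in studies)
        per_variant_n: dict[str, int] = {}
        for name, st in zip(self.study_names, studies):
            for vid in self.qc_ids[name]:
                per_variant_n[vid] = per_variant_n.get(vid, 0) + st.n_individuals
        self.meta_ids = set(
            completeness_filter(per_variant_n, self.total_n, min_fraction)
        )

        if len(studies) >= 2:
            eafs = {
                name: pd.Series(st.eaf, index=list(st.variant_ids)).loc[
                    sorted(self.qc_ids[name])
                ]
                for name, st in zip(self.study_names, studies)
            }
            self.relatedness: RelatednessMatrix | None = freq_distance_matrix(eafs)
        else:
            self.relatedness = None

        self.positions = {
            vid: int(studies[0].positions[j])
            for j, vid in enumerate(studies[0].variant_ids)
        }

    def partitions_for(self, names: list[str]) -> list[Partition]:
        key = frozenset(names)
        if key not in self._partition_cache:
            if len(names) == 1:
                parts = [Partition(clusters=((names[0],),), prior=1.0)]
            else:
                parts = enumerate_centre_partitions(
                    sorted(names, key=self.study_names.index),
                    self.relatedness,
                    self.prior,
                )
            self._partition_cache[key] = parts
        return self._partition_cache[key]

    def conditional_scan(
        self,
        condition_on: tuple[str, ...] = (),
        variant_ids: list[str] | None = None,
    ) -> list[BayesMetaResult]:
        """Conditional transancestral meta-analysis of the locus.

        Every study is refit with the conditioning dosages as covariates;
        per-variant results are combined under the partition model for the
        studies actually contributing that variant.
        """
        targets = (
            [v for v in variant_ids if v in self.meta_ids]
            if variant_ids is not None
            else [v for v in self.studies[0].variant_ids if v in self.meta_ids]
        )
        by_variant: dict[str, list[tuple[str, AssocResult]]] = {v: [] for v in targets}
        for name, st in zip(self.study_names, self.studies):
            ids = [v for v in targets if v in self.qc_ids[name]]
            if not ids:
                continue
            for r in study_scan(st, ids, conditioned_on=condition_on):
                by_variant[r.snpid].append((name, r))

        out = []
        for vid in targets:
            contrib = [
                (n, r)
                for n, r in by_variant[vid]
                if r.converged and np.isfinite(r.se) and r.se > 0
            ]
            if not contrib:
                continue
            names = [n for n, _ in contrib]
            results = [r for _, r in contrib]
            parts = self.partitions_for(names)
            out.append(
                meta_analyse_variant(
                    results, parts, tau=self.prior.tau, study_names=names
                )
            )
        return out

    def conditional_result(
        self, snpid: str, condition_on: tuple[str, ...]
    ) -> BayesMetaResult:
        """Meta-analysis result at one variant under given conditioning."""
        res = self.conditional_scan(condition_on, variant_ids=[snpid])
        if not res:
            raise ArgumentError(f"no converged result at {snpid}")
        return res[0]


def scan_lead(meta_results: list[BayesMetaResult]) -> BayesMetaResult:
    """The lead variant: maximal log10 BF, ties broken by smaller position
    then lexicographic identifier.  Shadow-flagged variants (near-collinear
    with a conditioning index) never lead."""
    eligible = [r for r in meta_results if not r.shadow]
    if not eligible:
        raise ArgumentError("no eligible meta-analysis results")
    return min(eligible, key=lambda r: (-r.log10_bf, r.pos, r.snpid))


def stepwise_delineate(
    locus: Locus,
    threshold_bf: float = GENOME_WIDE_LOG10BF,
    threshold_p: float = GENOME_WIDE_P,
    max_rounds: int = MAX_ROUNDS,
) -> tuple[list[Signal], DelineationTrace]:
    """Stepwise conditional delineation of distinct signals.

    Round r re-runs the conditional meta-analysis conditioning on all
    current indexes and takes the lead; the lead must pass BOTH thresholds
    to become a new index, otherwise delineation stops.  Signals are
    returned with leave-one-out conditional results.
    """
    indexes: list[str] = []
    rows: list[TraceRow] = []
    for rnd in range(1, max_rounds + 1):
        results = locus.conditional_scan(tuple(indexes))
        if not results:
            break
        lead = scan_lead(results)
        passes = lead.log10_bf >= threshold_bf and lead.fixed.p < threshold_p
        if passes:
            decision = "accept" if rnd < max_rounds else "cap"
            indexes.append(lead.snpid)
        else:
            decision = "stop"
        rows.append(
            TraceRow(rnd, lead.snpid, lead.log10_bf, lead.fixed.p, decision)
        )
        logger.info(
            "delineation round %d: lead=%s log10BF=%.2f P=%.3g -> %s",
            rnd, lead.snpid, lead.log10_bf, lead.fixed.p, decision,
        )
        if not passes:
            break

    signals = [
        Signal(
            index=vid,
            conditioned_on=tuple(v for v in indexes if v != vid),
            result=locus.conditional_result(
                vid, tuple(v for v in indexes if v != vid)
            ),
        )
        for vid in indexes
    ]
    return signals, DelineationTrace(rows=tuple(rows))


def refine_indexes(
    signals: list[Signal],
    locus: Locus,
    threshold_bf: float = GENOME_WIDE_LOG10BF,
    threshold_p: float = GENOME_WIDE_P,
    max_iterations: int = MAX_REFINE_ITERATIONS,
) -> list[Signal]:
    """Leave-one-out refinement of the index variants.

    Each signal's index is replaced by the lead of a conditional scan
    conditioning on all OTHER indexes; iteration continues until the index
    set is stable (or the iteration cap, with a warning).
    """
    if not signals:
        raise ArgumentError("refine_indexes requires at least one signal")
    indexes = [s.index for s in signals]
    for _ in range(max_iterations):
        changed = False
        for k in range(len(indexes)):
            others = tuple(v for i, v in enumerate(indexes) if i != k)
            lead = scan_lead(locus.conditional_scan(others))
            if lead.snpid != indexes[k]:
                logger.info(
                    "refine: signal %d index %s -> %s", k, indexes[k], lead.snpid
                )
                indexes[k] = lead.snpid
                changed = True
        if not changed:
            break
    else:
        logger.warning(
            "index refinement did not stabilize within %d iterations; "
            "returning the last state", max_iterations,
        )
    return [
        Signal(
            index=vid,
            conditioned_on=tuple(v for i, v in enumerate(indexes) if i != k),
            result=locus.conditional_result(
                vid, tuple(v for i, v in enumerate(indexes) if i != k)
            ),
        )
        for k, vid in enumerate(indexes)
    ]


def write_signals_tsv(signals: list[Signal], path) -> None:
    rows = [
        {
            "SIGNAL_ID": f"sig{k + 1}",
            "INDEX_SNP": s.index,
            "CONDITIONED_ON": ";".join(s.conditioned_on) if s.conditioned_on else ".",
            "LOG10BF": s.result.log10_bf,
            "P": s.result.fixed.p,
        }
        for k, s in enumerate(signals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
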