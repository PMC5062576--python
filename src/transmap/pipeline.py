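"""End-to-end pipeline: simulate -> associate -> meta-analyse -> delineate
-> credible sets -> annotate, from one seeded configuration.

The default configuration is the package's demonstration scenario: three
ancestry groups drifted from one ancestral pool with divergent LD, two
planted causal variants of modest effect shared across ancestries,
case-control studies of equal size per ancestry, and a synthetic islet-
enhancer track enriched at the causal positions.  Identical configuration
and seed reproduce the whole report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationTrack, overlap_credible, write_bed
from .assoc import AssocResult, study_scan, write_summary_stats
from .credsets import (
    CredibleSet,
    credible_set_from_log10bfs,
    write_comparison_tsv,
    write_credset_tsv,
)
from .exceptions import ArgumentError, FormatError
from .signals import Locus, Signal, refine_indexes, stepwise_delineate, write_signals_tsv
from .simdata import (
    CausalModel,
    StudyDataset,
    degrade_dosages,
    derive_population_pool,
    sim_ancestral_pool,
    sim_annotation,
    simulate_study,
    write_study_tsv,
)
from .transmeta import (
    PriorSpec,
    cluster_clades,
    write_relatedness,
    write_transmeta_tsv,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, with the canonical default values
    (QC: MAF >= 1%, info >= 0.4, completeness 80%; significance:
    log10 BF >= 6 and P < 5e-8; credible level 99%; effect prior tau 0.2)."""

    seed: int = 1
    # simulation
    n_variants: int = 60
    region_length: int = 100_000
    n_ancestral_haplotypes: int = 1000
    ancestries: tuple[str, ...] = ("EAsia", "Eur", "Afr")
    drift_F: tuple[float, ...] = (0.05, 0.10, 0.15)
    switch_rates: tuple[float, ...] = (1e-4, 2e-4, 4e-4)
    n_pop_haplotypes: int = 1000
    n_cases: int = 3000
    n_controls: int = 3000
    n_covariates: int = 2
    causal_odds_ratios: tuple[float, ...] = (1.3, 1.3)
    n_causal: int = 2
    baseline_alpha: float = -2.197224577336219  # logit(0.10)
    target_info: float = 0.95
    # annotation
    n_elements: int = 5
    element_length: int = 800
    enrichment: float = 1.0
    chrom: str = "chr1"
    # QC
    maf_min: float = 0.01
    info_min: float = 0.4
    min_fraction: float = 0.8
    # inference
    tau: float = 0.2
    threshold_bf: float = 6.0
    threshold_p: float = 5e-8
    credible_level: float = 0.99
    n_clades: int = 2
    # output
    out_dir: str = "transmap_out"

    def __post_init__(self):
        if self.n_variants <= 0:
            raise ArgumentError("n_variants must be positive")
        if len(self.drift_F) != len(self.ancestries):
            raise ArgumentError("one drift F per ancestry required")
        if len(self.switch_rates) != len(self.ancestries):
            raise ArgumentError("one switch rate per ancestry required")
        if not 0 < self.credible_level < 1:
            raise ArgumentError("credible_level must lie in (0, 1)")
        if not 0 < self.min_fraction <= 1:
            raise ArgumentError("min_fraction must lie in (0, 1]")
        if self.tau <= 0:
            raise ArgumentError("tau must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ancestries", "drift_F", "switch_rates", "causal_odds_ratios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class SimulatedLocus:
    """Simulation output consumed by the analysis stages."""

    studies: list[StudyDataset]
    study_names: list[str]
    causal: CausalModel
    track: AnnotationTrack
    positions: dict[str, int]


@dataclass
class ReportBundle:
    """Everything the pipeline reports for one locus."""

    signals: list[Signal]
    signal_table: pd.DataFrame          # index, OR, CI, P, log10 BF, BF_het, Q P
    credible_sets: dict[str, dict[str, CredibleSet]]  # analysis -> signal -> set
    credset_table: pd.DataFrame         # clade-vs-transancestral comparison
    overlap_table: pd.DataFrame
    clade_assignment: dict[str, int]
    provenance: dict


def _pick_causals(pool, populations, config: PipelineConfig, rng) -> tuple[str, ...]:
    """Choose causal variants for the planted signals.

    Candidates must be common (MAF >= 0.05) in EVERY derived population --
    the scenario transancestral fine-mapping addresses is a causal variant
    shared across ancestry groups and analysable in each of them; a variant
    drifted to rarity in one ancestry would be removed by the per-study MAF
    filter and could never be fine-mapped.  Multiple causals are additionally
    required to be in weak mutual LD (ancestral r^2 <= 0.05).
    """
    if config.n_causal == 0:
        return ()
    n_var = len(pool.variant_ids)
    common = [
        j
        for j in range(n_var)
        if all(0.05 <= p.frequencies[j] <= 0.95 for p in populations)
    ]
    chosen: list[int] = []
    hap = pool.haplotypes.astype(float)
    for j in rng.permutation(common):
        ok = True
        for c in chosen:
            r = np.corrcoef(hap[:, j], hap[:, c])[0, 1]
            if r * r > 0.05:
                ok = False
                break
        if ok:
            chosen.append(int(j))
        if len(chosen) == config.n_causal:
            break
    if len(chosen) < config.n_causal:
        raise ArgumentError(
            "could not find enough weakly linked variants common in every "
            "population to plant"
        )
    chosen.sort()
    return tuple(pool.variant_ids[j] for j in chosen)


def simulate_locus(config: PipelineConfig) -> SimulatedLocus:
    """Run the generative stage of the pipeline."""
    rng = np.random.default_rng(config.seed)
    ancestral = sim_ancestral_pool(
        config.n_variants,
        config.region_length,
        config.n_ancestral_haplotypes,
        seed=int(rng.integers(2**31)),
    )
    pools = [
        derive_population_pool(
            ancestral, anc, f, sw, config.n_pop_haplotypes,
            seed=int(rng.integers(2**31)),
        )
        for anc, f, sw in zip(config.ancestries, config.drift_F, config.switch_rates)
    ]
    causal_ids = _pick_causals(ancestral, pools, config, rng)
    betas = np.log(np.asarray(config.causal_odds_ratios, dtype=float))
    if betas.size != len(causal_ids):
        raise ArgumentError("causal_odds_ratios length must equal n_causal")
    causal = CausalModel(causal_ids, betas, alpha=config.baseline_alpha)

    studies, names = [], []
    for pool in pools:
        st = simulate_study(
            pool, causal, config.n_cases, config.n_controls,
            config.n_covariates, seed=int(rng.integers(2**31)),
        )
        if config.target_info < 1.0:
            st = degrade_dosages(st, config.target_info)
        studies.append(st)
        names.append(pool.ancestry)
        logger.info(
            "simulate: study %s, %d cases / %d controls, %d variants",
            pool.ancestry, st.n_cases, st.n_individuals - st.n_cases,
            len(st.variant_ids),
        )

    positions = {
        vid: int(ancestral.positions[j])
        for j, vid in enumerate(ancestral.variant_ids)
    }
    track = sim_annotation(
        config.region_length, config.n_elements, config.element_length,
        [positions[v] for v in causal_ids], config.enrichment,
        seed=int(rng.integers(2**31)), chrom=config.chrom,
    )
    return SimulatedLocus(studies, names, causal, track, positions)


def read_summary_stats(path, reference: pd.DataFrame | None = None) -> list[AssocResult]:
    """Load a per-study summary-statistics TSV.

    ``reference``, when given, is a variant table with SNPID/EA/OA columns;
    rows whose alleles are swapped relative to it are harmonized (beta
    negated, EAF complemented).  Missing required columns and duplicate
    SNPIDs are format errors.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["SNPID", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    dup = df["SNPID"][df["SNPID"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated SNPID {dup.iloc[0]!r}")

    if reference is not None:
        ref = reference.set_index("SNPID")
        for i, row in df.iterrows():
            if row["SNPID"] not in ref.index:
                continue
            r = ref.loc[row["SNPID"]]
            if row["EA"] == r["OA"] and row["OA"] == r["EA"]:
                df.loc[i, "BETA"] = -row["BETA"]
                df.loc[i, "EAF"] = 1.0 - row["EAF"]
                df.loc[i, ["EA", "OA"]] = [r["EA"], r["OA"]]
            elif row["EA"] != r["EA"] or row["OA"] != r["OA"]:
                raise FormatError(
                    f"{row['SNPID']}: alleles {row['EA']}/{row['OA']} do not "
                    f"match reference {r['EA']}/{r['OA']}"
                )

    out = []
    for _, row in df.iterrows():
        cond = row.get("CONDITIONED_ON", ".")
        conditioned = tuple(str(cond).split(";")) if str(cond) not in (".", "nan") else ()
        out.append(
            AssocResult(
                snpid=str(row["SNPID"]), pos=int(row["POS"]),
                beta=float(row["BETA"]), se=float(row["SE"]), p=float(row["P"]),
                eaf=float(row["EAF"]), n=int(row["N"]), info=float(row["INFO"]),
                conditioned_on=conditioned,
                converged=bool(np.isfinite(row["SE"]) and row["SE"] > 0),
            )
        )
    return out


def fine_map_unconditional(
    config: PipelineConfig,
) -> tuple[CredibleSet, tuple[str, ...]]:
    """Simulate one locus and fine-map it without conditional delineation.

    Returns the credible set from the unconditional transancestral
    meta-analysis together with the planted causal variant ids; the
    workhorse of coverage-calibration experiments for single-signal loci.
    """
    sim = simulate_locus(config)
    locus = Locus(
        sim.studies, sim.study_names, prior=PriorSpec(tau=config.tau),
        maf_min=config.maf_min, info_min=config.info_min,
        min_fraction=config.min_fraction, chrom=config.chrom,
    )
    results = locus.conditional_scan(())
    bfs = {r.snpid: r.log10_bf for r in results}
    cs = credible_set_from_log10bfs(
        bfs, locus.positions, level=config.credible_level, signal="unconditional"
    )
    return cs, sim.causal.variant_ids


def _clade_subsets(locus: Locus, config: PipelineConfig) -> dict[str, list[int]]:
    """Analysis subsets mirroring the clade-wise vs all-studies comparison."""
    subsets: dict[str, list[int]] = {}
    if locus.relatedness is not None and len(locus.study_names) > 2:
        clades = cluster_clades(locus.relatedness, n_clades=config.n_clades)
        for label, members in sorted(clades.clades().items()):
            name = "clade_" + "-".join(members)
            subsets[name] = [locus.study_names.index(s) for s in members]
        assignment = clades.assignment
    else:
        assignment = {s: 1 for s in locus.study_names}
    subsets["all_studies"] = list(range(len(locus.study_names)))
    _clade_subsets.last_assignment = assignment  # type: ignore[attr-defined]
    return subsets


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full analysis chain and (optionally) write all outputs."""
    sim = simulate_locus(config)
    prior = PriorSpec(tau=config.tau)
    locus = Locus(
        sim.studies, sim.study_names, prior=prior,
        maf_min=config.maf_min, info_min=config.info_min,
        min_fraction=config.min_fraction, chrom=config.chrom,
    )

    signals, trace = stepwise_delineate(
        locus, config.threshold_bf, config.threshold_p
    )
    if signals:
        signals = refine_indexes(
            signals, locus, config.threshold_bf, config.threshold_p
        )
    logger.info("delineation: %d distinct signal(s)", len(signals))

    # per-signal credible sets for each clade subset and for all studies
    subsets = _clade_subsets(locus, config)
    clade_assignment = _clade_subsets.last_assignment  # type: ignore[attr-defined]
    credible_sets: dict[str, dict[str, CredibleSet]] = {}
    for analysis, idxs in subsets.items():
        sub_locus = (
            locus
            if len(idxs) == len(locus.study_names)
            else Locus(
                [locus.studies[i] for i in idxs],
                [locus.study_names[i] for i in idxs],
                prior=prior, maf_min=config.maf_min, info_min=config.info_min,
                min_fraction=config.min_fraction, chrom=config.chrom,
            )
        )
        by_signal = {}
        for s in signals:
            results = sub_locus.conditional_scan(s.conditioned_on)
            bfs = {r.snpid: r.log10_bf for r in results if not r.shadow}
            if not bfs:
                continue
            by_signal[s.index] = credible_set_from_log10bfs(
                bfs, locus.positions, level=config.credible_level, signal=s.index
            )
        credible_sets[analysis] = by_signal

    signal_table = pd.DataFrame(
        [
            {
                "SIGNAL_ID": f"sig{k + 1}",
                "INDEX_SNP": s.index,
                "CONDITIONED_ON": ";".join(s.conditioned_on) or ".",
                "OR": s.result.fixed.or_,
                "CI_L": s.result.fixed.ci_low,
                "CI_U": s.result.fixed.ci_high,
                "P": s.result.fixed.p,
                "LOG10BF": s.result.log10_bf,
                "LOG10BF_HET": s.result.log10_bf_het,
                "Q_P": s.result.fixed.q_p,
            }
            for k, s in enumerate(signals)
        ]
    )

    credset_rows = []
    for analysis, by_signal in credible_sets.items():
        for sig, cs in by_signal.items():
            lo, hi = cs.interval
            credset_rows.append(
                {
                    "ANALYSIS": analysis, "SIGNAL": sig, "N_SNPS": cs.n_variants,
                    "DISTANCE_BP": cs.distance_bp, "INTERVAL_LO": lo,
                    "INTERVAL_HI": hi, "TOTAL_MASS": cs.total_mass,
                }
            )
    credset_table = pd.DataFrame(credset_rows)

    overlap_rows = []
    for sig, cs in credible_sets.get("all_studies", {}).items():
        report = overlap_credible(cs, sim.track, chrom=config.chrom)
        for element, hits in sorted(report.element_variants.items()):
            for snpid, pi in hits:
                overlap_rows.append(
                    {"SIGNAL": sig, "ELEMENT": element, "SNPID": snpid, "PI": pi}
                )
        for element, mass in sorted(report.element_mass.items()):
            overlap_rows.append(
                {"SIGNAL": sig, "ELEMENT": element, "SNPID": "__TOTAL__", "PI": mass}
            )
    overlap_table = pd.DataFrame(overlap_rows)

    bundle = ReportBundle(
        signals=signals,
        signal_table=signal_table,
        credible_sets=credible_sets,
        credset_table=credset_table,
        overlap_table=overlap_table,
        clade_assignment=clade_assignment,
        provenance={
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
            "causal_variants": list(sim.causal.variant_ids),
        },
    )
    if out_dir is not None:
        write_bundle(bundle, sim, locus, config, Path(out_dir))
    return bundle


def write_bundle(
    bundle: ReportBundle,
    sim: SimulatedLocus,
    locus: Locus,
    config: PipelineConfig,
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, st in zip(sim.study_names, sim.studies):
        write_study_tsv(st, out / f"{name}.dosages.tsv", out / f"{name}.samples.tsv")
        write_summary_stats(study_scan(st), out / f"{name}.assoc.tsv", chrom=config.chrom)
    write_bed(sim.track, out / "annotation.bed")
    if locus.relatedness is not None:
        clades = cluster_clades(locus.relatedness, n_clades=config.n_clades)
        write_relatedness(
            locus.relatedness, clades,
            out / "relatedness.tsv", out / "clades.json",
        )
    write_transmeta_tsv(locus.conditional_scan(()), out / "meta.tsv")
    write_signals_tsv(bundle.signals, out / "signals.tsv")
    for analysis, by_signal in bundle.credible_sets.items():
        for sig, cs in by_signal.items():
            write_credset_tsv(cs, out / f"credset.{analysis}.{sig}.tsv")
    write_comparison_tsv(bundle.credible_sets, out / "credset_comparison.tsv")
    bundle.signal_table.to_csv(out / "signal_table.tsv", sep="\t", index=False)
    if not bundle.overlap_table.empty:
        bundle.overlap_table.to_csv(out / "overlap.tsv", sep="\t", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
    logger.info("pipeline outputs written to %s", out)
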