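"""Overlap of credible-set variants with regulatory annotation intervals.

Annotation tracks use BED conventions: 0-based half-open intervals.  Variant
positions throughout the package are 1-based, so a variant at 1-based
position p overlaps an interval [a, b) iff a <= p-1 < b.  The per-element
summed posterior mass highlights regulatory elements that capture a large
share of a signal's credible set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

from intervaltree import IntervalTree

from .exceptions import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .credsets import CredibleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interval:
    """One annotation element, 0-based half-open."""

    chrom: str
    start: int
    end: int
    state: str = "."
    tissue: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"interval start {self.start} >= end {self.end}"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.state}"


@dataclass(frozen=True)
class AnnotationTrack:
    """A sorted collection of non-degenerate annotation intervals."""

    intervals: tuple[Interval, ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "intervals",
            tuple(sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))),
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class OverlapReport:
    """Credible-set variants intersected with annotation elements."""

    # variant id -> tuple of element names it falls in
    variant_elements: dict[str, tuple[str, ...]]
    # element name -> tuple of (variant id, posterior mass)
    element_variants: dict[str, tuple[tuple[str, float], ...]]

    @property
    def element_mass(self) -> dict[str, float]:
        return {
            name: sum(pi for _, pi in hits)
            for name, hits in self.element_variants.items()
        }


def read_bed(path) -> AnnotationTrack:
    """Parse a standard BED file (>= 3 tab-separated columns, 0-based
    half-open).  Column 4 is kept as the element's state label; further
    columns are ignored.  Malformed lines raise with their line number."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("fewer than 3 columns", line=lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"non-numeric coordinates {parts[1]!r}/{parts[2]!r}",
                    line=lineno,
                ) from None
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", line=lineno)
            state = parts[3] if len(parts) > 3 else "."
            intervals.append(Interval(chrom, start, end, state=state))
    return AnnotationTrack(intervals=tuple(intervals))


def write_bed(track: AnnotationTrack, path) -> None:
    """Write a track as 4-column BED (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.state}\n")


def overlap_credible(
    credible_set: "CredibleSet",
    track: AnnotationTrack,
    chrom: str = "chr1",
) -> OverlapReport:
    """Intersect a credible set's variants with an annotation track.

    ``chrom`` names the chromosome the credible-set positions live on; track
    intervals on other chromosomes never match.  If no track interval shares
    the chromosome at all, a warning is logged and the report is empty.
    """
    same_chrom = [iv for iv in track.intervals if iv.chrom == chrom]
    if track.intervals and not same_chrom:
        logger.warning(
            "no annotation intervals on chromosome %r; empty overlap report", chrom
        )
        return OverlapReport({}, {})

    tree = IntervalTree()
    for iv in same_chrom:
        tree[iv.start: iv.end] = iv

    variant_elements: dict[str, tuple[str, ...]] = {}
    element_variants: dict[str, list[tuple[str, float]]] = {}
    for cv in credible_set.variants:
        hits = sorted(
            (h.data for h in tree[cv.position - 1]),
            key=lambda iv: (iv.start, iv.end),
        )
        if hits:
            variant_elements[cv.snpid] = tuple(h.name for h in hits)
            for h in hits:
                element_variants.setdefault(h.name, []).append((cv.snpid, cv.pi))
    return OverlapReport(
        variant_elements=variant_elements,
        element_variants={k: tuple(v) for k, v in element_variants.items()},
    )


def element_mass(report: OverlapReport) -> dict[str, float]:
    """Summed credible-set posterior mass captured by each element."""
    return report.element_mass
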