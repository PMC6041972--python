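"""Genome-coverage accounting and cross-tissue MQTL overlap regions.

Two coverage conventions coexist deliberately: QTL coverage merges
overlapping intervals per chromosome before summing (a union length), while
MQTL coverage is the raw sum of CI widths without overlap correction —
matching how the per-tissue coverage panels of published meta-analyses are
tabulated.  Both are explicit functions so callers choose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import MQTLError
from .io import GeneticMap, PhysicalAnchor
from .meta import MQTL, flanking_markers

#: Genetic length (cM) of the IBM2 2008 Neighbors consensus map (16681 markers).
REFERENCE_MAP_LENGTH_CM = 7980.637
#: Physical length (bp) of the maize B73 reference assembly, version 2.
B73V2_GENOME_BP = 2_066_432_718


def merged_length(intervals: Iterable[tuple[str, float, float]]) -> float:
    """Total union length of (chromosome, start, end) intervals in cM."""
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for chrom, start, end in intervals:
        if end < start:
            start, end = end, start
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0.0
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
    return total


def qtl_coverage(projected) -> float:
    """Overlap-merged genetic coverage (cM) of projected QTL 95% CIs."""
    return merged_length(
        (q.chromosome, q.ref_ci_start, q.ref_ci_end) for q in projected
    )


def mqtl_coverage(mqtls: Sequence[MQTL]) -> float:
    """Raw sum of MQTL CI widths (cM), no overlap correction."""
    return sum(m.ci_width for m in mqtls)


def coverage_percent(length_cM: float,
                     map_length_cM: float = REFERENCE_MAP_LENGTH_CM) -> float:
    """Genetic coverage as a percentage of the reference map length."""
    if map_length_cM <= 0:
        raise MQTLError("map length must be positive")
    return length_cM / map_length_cM * 100.0


def reduction_percent(qtl_cov: float, mqtl_cov: float) -> float:
    """Percent coverage reduction achieved by the meta-analysis."""
    if qtl_cov <= 0:
        raise MQTLError("QTL coverage must be positive")
    return (qtl_cov - mqtl_cov) / qtl_cov * 100.0


@dataclass
class CoverageReport:
    """Per-tissue genetic (and optionally physical) coverage summary."""

    tissue_class: str
    qtl_coverage_cM: float
    mqtl_coverage_cM: float
    qtl_pct: float
    mqtl_pct: float
    reduction_pct: float
    physical_coverage_bp: float | None = None
    physical_pct: float | None = None


def coverage_report(projected, mqtls: Sequence[MQTL], tissue_class: str,
                    map_length_cM: float = REFERENCE_MAP_LENGTH_CM,
                    genome_bp: int | None = None) -> CoverageReport:
    """Assemble the per-tissue coverage panel from projected QTL and MQTL."""
    qcov = qtl_coverage(q for q in projected if q.tissue_class == tissue_class)
    tissue_mqtls = [m for m in mqtls if m.tissue_class == tissue_class]
    mcov = mqtl_coverage(tissue_mqtls)
    phys_bp = phys_pct = None
    if genome_bp is not None:
        closed = [m for m in tissue_mqtls
                  if m.phys_start_bp is not None and m.phys_end_bp is not None]
        if closed:
            phys_pct = physical_coverage(closed, genome_bp)
            phys_bp = phys_pct / 100.0 * genome_bp
    return CoverageReport(
        tissue_class=tissue_class,
        qtl_coverage_cM=qcov, mqtl_coverage_cM=mcov,
        qtl_pct=coverage_percent(qcov, map_length_cM),
        mqtl_pct=coverage_percent(mcov, map_length_cM),
        reduction_pct=reduction_percent(qcov, mcov),
        physical_coverage_bp=phys_bp, physical_pct=phys_pct,
    )


@dataclass
class PhysicalInterval:
    """bp interval for an MQTL; an open end means the chromosome's mapped
    markers were exhausted before an anchored marker was found."""

    chromosome: str
    start_bp: float | None
    end_bp: float | None
    start_open: bool = False
    end_open: bool = False


def anchor_physical(mqtl: MQTL, reference: GeneticMap,
                    anchors: Sequence[PhysicalAnchor]) -> PhysicalInterval:
    """Physical interval of an MQTL from the anchors of its flanking markers.

    Takes the flanking markers of the genetic CI (computing them from the
    reference when absent); if a flank has no physical anchor, walks outward
    along the reference marker order to the next anchored marker.  A side
    that exhausts the chromosome without an anchored marker is flagged open.
    """
    chrom = mqtl.chromosome
    anchored = {a.marker_name: a.position_bp for a in anchors
                if a.chromosome == chrom}
    left, right = mqtl.flank_left, mqtl.flank_right
    if left is None or right is None:
        left, right = flanking_markers(reference, chrom, mqtl.ci95_start,
                                       mqtl.ci95_end)
    names = reference.marker_names(chrom)

    def walk(start_name: str | None, step: int) -> float | None:
        if start_name is None or start_name not in names:
            return None
        i = names.index(start_name)
        while 0 <= i < len(names):
            if names[i] in anchored:
                return float(anchored[names[i]])
            i += step
        return None

    start_bp = walk(left, -1)
    end_bp = walk(right, +1)
    if start_bp is not None and end_bp is not None and start_bp > end_bp:
        start_bp, end_bp = end_bp, start_bp
    return PhysicalInterval(
        chromosome=chrom, start_bp=start_bp, end_bp=end_bp,
        start_open=start_bp is None, end_open=end_bp is None,
    )


def physical_coverage(mqtls: Sequence[MQTL], genome_bp: int = B73V2_GENOME_BP,
                      chromosome_lengths_bp: dict[str, float] | None = None) -> float:
    """Percent of the genome spanned by the MQTL physical intervals.

    Raw sum of (end - start), no overlap merging.  An open-ended interval is
    closed at the chromosome's physical length, which must then be supplied.
    """
    total = 0.0
    for m in mqtls:
        start, end = m.phys_start_bp, m.phys_end_bp
        if m.phys_end_open or end is None:
            if chromosome_lengths_bp is None or m.chromosome not in chromosome_lengths_bp:
                raise MQTLError(
                    f"{m.mqtl_id}: open-ended physical interval and no "
                    f"chromosome length supplied for chromosome {m.chromosome}"
                )
            end = chromosome_lengths_bp[m.chromosome]
        if m.phys_start_open or start is None:
            raise MQTLError(f"{m.mqtl_id}: physical interval start is missing")
        total += end - start
    return total / genome_bp * 100.0


@dataclass
class OverlapRegion:
    """A chromosome region where MQTL CIs from >= 2 tissue classes chain
    together by pairwise overlap."""

    chromosome: str
    span: tuple[float, float]
    members: list[str]
    tissue_classes: frozenset[str]

    @property
    def all_three(self) -> bool:
        return len(self.tissue_classes) >= 3


def cross_tissue_overlaps(mqtls: Sequence[MQTL],
                          mode: str = "genetic") -> list[OverlapRegion]:
    """Connected components of the MQTL interval-overlap graph, restricted
    to components that mix >= 2 tissue classes.

    ``mode`` selects the coordinates: genetic CIs (cM) or physical intervals
    (bp; MQTL without a closed physical interval are skipped).
    """
    items: list[tuple[str, float, float, str, str]] = []
    for m in mqtls:
        if mode == "genetic":
            items.append((m.chromosome, m.ci95_start, m.ci95_end,
                          m.mqtl_id, m.tissue_class))
        elif mode == "physical":
            if m.phys_start_bp is None or m.phys_end_bp is None:
                continue
            items.append((m.chromosome, m.phys_start_bp, m.phys_end_bp,
                          m.mqtl_id, m.tissue_class))
        else:
            raise ValueError(f"unknown overlap mode {mode!r}")

    by_chrom: dict[str, list] = {}
    for item in items:
        by_chrom.setdefault(item[0], []).append(item)
    regions = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom], key=lambda t: (t[1], t[2], t[3]))
        component: list = []
        comp_end = -float("inf")

        def close(component):
            classes = frozenset(t[4] for t in component)
            if len(component) >= 2 and len(classes) >= 2:
                regions.append(OverlapRegion(
                    chromosome=chrom,
                    span=(min(t[1] for t in component),
                          max(t[2] for t in component)),
                    members=sorted(t[3] for t in component),
                    tissue_classes=classes,
                ))

        for item in spans:
            if component and item[1] > comp_end:
                close(component)
                component = []
                comp_end = -float("inf")
            component.append(item)
            comp_end = max(comp_end, item[2])
        if component:
            close(component)
    return regions
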