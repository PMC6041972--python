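"""Project component genetic maps and QTL onto a reference map.

Different mapping studies use different marker panels and the same markers
can sit at locally different distances, so positions are carried over with a
piecewise-linear (homothetic) transform anchored at markers shared between
the two maps: inside an interval flanked by shared markers the local
interval ratio applies, and beyond the terminal shared markers a
chromosome-wide global ratio extrapolates from the nearest anchor.  Shared
markers whose order disagrees between maps (inverted markers) are discarded
by keeping the maximum-cardinality order-consistent subset.

A consensus map is built by iteratively projecting component maps onto the
reference, most-similar component first, and inserting each component's
non-shared markers at their projected positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import GeneticMap, MarkerLocus
from .standardize import StandardizedQTL


@dataclass
class AnchorSet:
    """Order-consistent shared markers between one component chromosome and
    the reference, plus the global extrapolation ratio."""

    chromosome: str
    pairs: list[tuple[str, float, float]]  # (marker, component cM, reference cM)
    global_ratio: float

    @property
    def component_positions(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])

    @property
    def reference_positions(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    @property
    def marker_names(self) -> list[str]:
        return [p[0] for p in self.pairs]


@dataclass
class ProjectedQTL(StandardizedQTL):
    """A standardized QTL re-expressed in reference-map coordinates."""

    ref_position: float = float("nan")
    ref_ci_start: float = float("nan")
    ref_ci_end: float = float("nan")
    projection_status: str = "projected"  # projected | discarded_negative | no_anchors


@dataclass
class ProjectionLogEntry:
    map_id: str
    chromosome: str
    item: str  # marker or QTL id
    event: str  # inserted | discarded_negative | no_anchors | skipped_component
    detail: str = ""


def _max_order_consistent(pairs: list[tuple[str, float, float]]):
    """Maximum subset of anchor pairs with strictly increasing reference
    positions when ordered by component position (longest increasing
    subsequence on reference rank); ties broken toward the subset spanning
    the larger reference interval."""
    n = len(pairs)
    if n == 0:
        return []
    ref = [p[2] for p in pairs]
    # dp over pairs sorted by component position (input order)
    best_len = [1] * n
    best_span = [0.0] * n  # reference span of the chain ending at i
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ref[j] < ref[i]:
                cand_len = best_len[j] + 1
                cand_span = best_span[j] + (ref[i] - ref[j])
                if cand_len > best_len[i] or (
                    cand_len == best_len[i] and cand_span > best_span[i]
                ):
                    best_len[i] = cand_len
                    best_span[i] = cand_span
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], best_span[i]))
    chain = []
    while end != -1:
        chain.append(pairs[end])
        end = prev[end]
    return chain[::-1]


def shared_markers(component: GeneticMap, reference: GeneticMap,
                   chromosome: str) -> AnchorSet | None:
    """Anchor pairs for one chromosome, or None when fewer than two
    order-consistent shared markers exist (the no-anchors signal)."""
    if chromosome not in component.markers or chromosome not in reference.markers:
        return None
    ref_pos = {m.name: m.position for m in reference.loci(chromosome)}
    pairs = [
        (m.name, m.position, ref_pos[m.name])
        for m in component.loci(chromosome)
        if m.name in ref_pos
    ]
    pairs = _max_order_consistent(pairs)
    # collapse degenerate component intervals (identical component positions)
    deduped: list[tuple[str, float, float]] = []
    for p in pairs:
        if deduped and p[1] == deduped[-1][1]:
            continue
        deduped.append(p)
    if len(deduped) < 2:
        return None
    comp_span = deduped[-1][1] - deduped[0][1]
    ref_span = deduped[-1][2] - deduped[0][2]
    global_ratio = ref_span / comp_span if comp_span > 0 else 1.0
    return AnchorSet(chromosome=chromosome, pairs=deduped, global_ratio=global_ratio)


def project_position(pos: float, anchors: AnchorSet) -> float:
    """Map a component-coordinate cM position into reference coordinates.

    Piecewise-linear between consecutive anchors; beyond the terminal anchors
    the chromosome-wide global ratio extrapolates from the nearest anchor.
    Monotone non-decreasing in ``pos``.
    """
    c = anchors.component_positions
    r = anchors.reference_positions
    if pos <= c[0]:
        return float(r[0] + (pos - c[0]) * anchors.global_ratio)
    if pos >= c[-1]:
        return float(r[-1] + (pos - c[-1]) * anchors.global_ratio)
    i = int(np.searchsorted(c, pos, side="right") - 1)
    frac = (pos - c[i]) / (c[i + 1] - c[i])
    return float(r[i] + frac * (r[i + 1] - r[i]))


def project_qtl(q: StandardizedQTL, anchors: AnchorSet | None) -> ProjectedQTL:
    """Project a QTL's position and CI bounds; discard anything below zero.

    Each CI bound is projected independently; bounds are re-ordered if the
    transform locally reverses them and clamped so the projected position
    stays inside the projected interval.
    """
    base = vars(q).copy()
    if anchors is None:
        return ProjectedQTL(**base, projection_status="no_anchors")
    pos = project_position(q.position, anchors)
    lo = project_position(q.ci95_start, anchors)
    hi = project_position(q.ci95_end, anchors)
    lo, hi = min(lo, hi), max(lo, hi)
    lo, hi = min(lo, pos), max(hi, pos)
    status = "discarded_negative" if min(lo, hi, pos) < 0 else "projected"
    return ProjectedQTL(**base, ref_position=pos, ref_ci_start=lo,
                        ref_ci_end=hi, projection_status=status)


def project_qtls(qtls: Sequence[StandardizedQTL], component: GeneticMap,
                 reference: GeneticMap) -> tuple[list[ProjectedQTL], list[ProjectionLogEntry]]:
    """Project a study's QTL using per-chromosome anchors against the reference."""
    out, logbook = [], []
    anchor_cache: dict[str, AnchorSet | None] = {}
    for q in qtls:
        if q.chromosome not in anchor_cache:
            anchor_cache[q.chromosome] = shared_markers(component, reference, q.chromosome)
        p = project_qtl(q, anchor_cache[q.chromosome])
        if p.projection_status != "projected":
            logbook.append(ProjectionLogEntry(
                map_id=component.map_id, chromosome=q.chromosome,
                item=q.qtl_id, event=p.projection_status))
        out.append(p)
    return out, logbook


def build_consensus(reference: GeneticMap, components: Sequence[GeneticMap],
                    ) -> tuple[GeneticMap, list[ProjectionLogEntry]]:
    """Iteratively merge component maps into the reference.

    Components are processed in descending order of shared-marker count with
    the reference (a proxy for map similarity), ties broken by map_id.  Each
    component's non-shared markers are inserted at their projected positions
    on the growing consensus; reference marker positions are never moved.
    Projections below zero are discarded and logged.  Duplicate submission of
    the same component is a no-op after the first pass.
    """
    logbook: list[ProjectionLogEntry] = []

    def shared_count(component: GeneticMap) -> int:
        total = 0
        for chrom in component.markers:
            if chrom in reference.markers:
                ref_names = set(reference.marker_names(chrom))
                total += sum(1 for m in component.loci(chrom) if m.name in ref_names)
        return total

    ordered = sorted(components, key=lambda g: (-shared_count(g), g.map_id))
    consensus = GeneticMap.from_loci(
        reference.map_id + "_consensus",
        [m for c in reference.chromosomes for m in reference.loci(c)],
        population_type="reference",
    )
    for component in ordered:
        inserted_any = False
        usable = False
        for chrom in component.markers:
            anchors = shared_markers(component, consensus, chrom)
            if anchors is None:
                for m in component.loci(chrom):
                    logbook.append(ProjectionLogEntry(
                        map_id=component.map_id, chromosome=chrom,
                        item=m.name, event="no_anchors"))
                continue
            usable = True
            consensus_names = set(consensus.marker_names(chrom)) if chrom in consensus.markers else set()
            new_loci = []
            for m in component.loci(chrom):
                if m.name in consensus_names:
                    continue
                pos = project_position(m.position, anchors)
                if pos < 0:
                    logbook.append(ProjectionLogEntry(
                        map_id=component.map_id, chromosome=chrom,
                        item=m.name, event="discarded_negative",
                        detail=f"projected to {pos:.3f}"))
                    continue
                new_loci.append(MarkerLocus(name=m.name, chromosome=chrom, position=pos))
                logbook.append(ProjectionLogEntry(
                    map_id=component.map_id, chromosome=chrom,
                    item=m.name, event="inserted", detail=f"{pos:.3f}"))
            if new_loci:
                inserted_any = True
                merged = list(consensus.markers.get(chrom, [])) + new_loci
                consensus.markers[chrom] = sorted(merged, key=lambda m: (m.position, m.name))
        if not usable:
            logbook.append(ProjectionLogEntry(
                map_id=component.map_id, chromosome="*",
                item="*", event="skipped_component",
                detail="no chromosome with >= 2 order-consistent shared markers"))
        del inserted_any
    return consensus, logbook
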