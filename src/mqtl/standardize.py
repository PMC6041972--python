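"""Convert heterogeneous reported QTL statistics to a uniform (LOD, R2, 95% CI).

Published QTL tables rarely report the same statistics: some give a LOD
score, some only a likelihood-ratio statistic (LRS), some the fraction of
phenotypic variance explained (R2).  This module fills the gaps with the
standard conversions

    LOD = LRS / 4.6
    R2  = 1 - 10^(-2 LOD / N)

and replaces every reported support interval with the empirical 95%
confidence-interval width

    CI95 = k / (N * R2)

where k = 530 for F2/F3 populations and k = 163 for RILs/IRILs
(Darvasi-Soller approximation).  The standardized CI is centered on the
reported most-likely position; the original interval is kept as provenance.

Overlapping QTL within one (study, trait, chromosome) group are reduced to
the member with the highest R2 so a single underlying QTL reported several
times does not dominate the meta-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import StandardizationError
from .io import QTLRecord

#: Darvasi-Soller proportionality constant per mapping-population type.
K_CONSTANTS: Mapping[str, float] = {"F2": 530.0, "F3": 530.0, "RIL": 163.0, "IRIL": 163.0}


def lod_from_lrs(lrs: float) -> float:
    """LOD score from a likelihood-ratio statistic: LOD = LRS / 4.6."""
    if not math.isfinite(lrs) or lrs < 0:
        raise StandardizationError(f"lrs must be finite and >= 0, got {lrs}")
    return lrs / 4.6


def r2_from_lod(lod: float, n: int) -> float:
    """Variance explained from a LOD score: R2 = 1 - 10^(-2 LOD / N)."""
    if lod < 0 or not math.isfinite(lod):
        raise StandardizationError(f"lod must be finite and >= 0, got {lod}")
    if n < 2:
        raise StandardizationError(f"population size must be >= 2, got {n}")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def ci95_width(n: int, r2: float, population_type: str,
               k_constants: Mapping[str, float] = K_CONSTANTS) -> float:
    """Empirical 95% CI width (cM): k / (N * R2), k chosen by population type."""
    if n <= 0:
        raise StandardizationError(f"population size must be positive, got {n}")
    if not (0 < r2 <= 1):
        raise StandardizationError(f"r2 must be in (0, 1], got {r2}")
    try:
        k = k_constants[population_type]
    except KeyError:
        raise StandardizationError(
            f"no CI constant configured for population type {population_type!r}; "
            f"known types: {sorted(k_constants)}"
        ) from None
    return k / (n * r2)


@dataclass
class StandardizedQTL:
    """A QTL with LOD, R2 and a 95% CI filled in and centered on its position.

    ``lod_source``/``r2_source`` record whether each statistic was reported
    or derived (``reported`` | ``from_lrs`` | ``from_lod`` | ``absent``).
    The reported interval, if any, is retained in ``reported_ci``.
    """

    qtl_id: str
    study_id: str
    trait: str
    tissue_class: str
    trait_category: str
    chromosome: str
    position: float
    lod: float | None
    r2: float
    lod_source: str
    r2_source: str
    k_constant: float
    ci95_width: float
    ci95_start: float
    ci95_end: float
    population_size: int
    population_type: str
    reported_ci: tuple[float, float] | None = None


def standardize_record(q: QTLRecord,
                       k_constants: Mapping[str, float] = K_CONSTANTS) -> StandardizedQTL:
    """Fill missing LOD/R2 and attach the standardized 95% CI.

    Reported values take precedence: a published R2 is never recomputed from
    the LOD.  Missing LOD is taken from the LRS; missing R2 from the LOD.
    """
    lod, lod_source = q.lod, "reported"
    if lod is None and q.lrs is not None:
        lod, lod_source = lod_from_lrs(q.lrs), "from_lrs"
    elif lod is None:
        lod_source = "absent"

    r2, r2_source = q.r2, "reported"
    if r2 is None:
        if lod is None:
            raise StandardizationError(
                f"{q.qtl_id}: cannot fill r2 (no lod and no lrs reported)"
            )
        r2, r2_source = r2_from_lod(lod, q.population_size), "from_lod"
    if r2 <= 0:
        raise StandardizationError(
            f"{q.qtl_id}: derived r2 is {r2}; CI width would be infinite"
        )

    width = ci95_width(q.population_size, r2, q.population_type, k_constants)
    reported_ci = None
    if q.ci_start is not None and q.ci_end is not None:
        reported_ci = (q.ci_start, q.ci_end)
    return StandardizedQTL(
        qtl_id=q.qtl_id, study_id=q.study_id, trait=q.trait,
        tissue_class=q.tissue_class, trait_category=q.trait_category,
        chromosome=q.chromosome, position=q.position,
        lod=lod, r2=r2, lod_source=lod_source, r2_source=r2_source,
        k_constant=k_constants[q.population_type],
        ci95_width=width,
        ci95_start=q.position - width / 2.0,
        ci95_end=q.position + width / 2.0,
        population_size=q.population_size, population_type=q.population_type,
        reported_ci=reported_ci,
    )


def _interval(q: StandardizedQTL, use_reported: bool) -> tuple[float, float]:
    if use_reported and q.reported_ci is not None:
        return q.reported_ci
    return (q.ci95_start, q.ci95_end)


def dedupe_overlapping(records: Sequence[StandardizedQTL],
                       use_reported_ci: bool = False) -> list[StandardizedQTL]:
    """Drop same-study same-trait QTL whose CIs overlap, keeping the top R2.

    Within each (study_id, trait, chromosome) group, QTL are chained into
    connected components by closed-interval overlap of their 95% CIs and only
    the component member with the highest R2 survives.  Ties go to the
    narrower reported CI, then to the lexicographically smallest qtl_id, so
    the output is deterministic.  Idempotent; the input order of survivors is
    preserved.
    """
    groups: dict[tuple[str, str, str], list[StandardizedQTL]] = {}
    for q in records:
        groups.setdefault((q.study_id, q.trait, q.chromosome), []).append(q)

    survivors: set[int] = set()
    for members in groups.values():
        ordered = sorted(members, key=lambda q: _interval(q, use_reported_ci))
        component: list[StandardizedQTL] = []
        comp_end = -math.inf

        def close(component):
            def rank(q):
                reported_width = (
                    q.reported_ci[1] - q.reported_ci[0]
                    if q.reported_ci is not None else math.inf
                )
                return (-q.r2, reported_width, q.qtl_id)
            survivors.add(id(min(component, key=rank)))

        for q in ordered:
            start, end = _interval(q, use_reported_ci)
            if component and start > comp_end:
                close(component)
                component = []
                comp_end = -math.inf
            component.append(q)
            comp_end = max(comp_end, end)
        if component:
            close(component)
    return [q for q in records if id(q) in survivors]
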