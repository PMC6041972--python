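"""Synthetic multi-study QTL datasets with known ground truth.

The generator emulates the ingredients of a literature-based QTL
meta-analysis at the summary-statistic level (no genotypes or phenotypes):

* a dense reference map with markers at sorted uniform positions;
* per-study component maps that keep a random subset of the reference
  markers and locally distort inter-marker distances by positive
  log-normal factors (so marker order is preserved);
* latent "planted" meta-QTL, each observed by several studies as a QTL
  whose reported position scatters around the true location with the
  standard deviation implied by its own Darvasi-Soller 95% CI,
  CI95 = k / (N * R2), sd = CI95 / 3.92;
* per-study population types and sizes spanning the F2/F3/RIL/IRIL range
  typical of published bi-parental maize studies (N ~ 100-472), and R2
  drawn from a right-skewed Beta(1.2, 8) truncated to [0.005, 0.47],
  matching the span of variance fractions such studies report.

All randomness flows from the single config seed; per-study streams are
split with ``numpy.random.SeedSequence`` so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MQTLError
from .io import (GeneticMap, MarkerLocus, QTLRecord, write_map,
                 write_qtl_table)
from .standardize import K_CONSTANTS

_TRAITS = {
    "leaf": ["ECB-LFD", "SCB-LDR", "SWCB-LFD", "ADL", "NDF"],
    "stem": ["ECB-TL", "MCB-STL", "ECB-SDR", "p-CA", "ADF"],
    "kernel": ["MW-GWL", "MCB-KR", "MW-DI", "trans-FA", "Gal"],
}
_POP_TYPES = ("F2", "F3", "RIL", "IRIL")


@dataclass
class PlantedMQTL:
    chromosome: str
    position: float
    tissue_class: str


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror a typical multi-study corpus."""

    seed: int = 0
    n_chromosomes: int = 3
    markers_per_chromosome: int = 40
    chromosome_length_cM: float = 200.0
    n_studies: int = 10
    population_sizes: tuple[int, int] = (100, 472)
    shared_marker_fraction: float = 0.8
    distortion_sd: float = 0.1  # per-interval log-ratio scale
    planted_mqtl: list[PlantedMQTL] = field(default_factory=list)
    qtl_per_mqtl_range: tuple[int, int] = (4, 8)
    r2_beta: tuple[float, float] = (1.2, 8.0)
    r2_bounds: tuple[float, float] = (0.005, 0.47)

    def validate(self) -> None:
        if self.markers_per_chromosome < 1:
            raise MQTLError("markers_per_chromosome must be positive")
        if self.n_chromosomes < 1 or self.n_studies < 1:
            raise MQTLError("counts must be positive")
        if not (0 < self.shared_marker_fraction <= 1):
            raise MQTLError("shared_marker_fraction must be in (0, 1]")
        for p in self.planted_mqtl:
            if not (0 <= p.position <= self.chromosome_length_cM):
                raise MQTLError(
                    f"planted MQTL at {p.position} outside chromosome "
                    f"length {self.chromosome_length_cM}"
                )


@dataclass
class TrueQTL:
    """Generative parameters behind one emitted QTL record."""

    qtl_id: str
    mqtl_index: int
    study_id: str
    true_position: float  # on the reference scale
    component_position: float  # the same locus on the component scale
    r2: float
    sd: float


@dataclass
class GroundTruth:
    planted: list[PlantedMQTL]
    qtls: list[TrueQTL]

    def members_of(self, mqtl_index: int) -> list[str]:
        return [q.qtl_id for q in self.qtls if q.mqtl_index == mqtl_index]


def _study_rng(config: SimulationConfig, study_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(study_index + 1,))
    )


def _assignments(config: SimulationConfig) -> list[list[int]]:
    """Per-study list of planted-MQTL indices observed by that study
    (derived deterministically from the config seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    lo, hi = config.qtl_per_mqtl_range
    per_study: list[list[int]] = [[] for _ in range(config.n_studies)]
    for idx in range(len(config.planted_mqtl)):
        m = int(rng.integers(lo, hi + 1))
        m = min(m, config.n_studies)
        chosen = rng.choice(config.n_studies, size=m, replace=False)
        for s in sorted(chosen):
            per_study[s].append(idx)
    return per_study


def simulate_reference(config: SimulationConfig) -> GeneticMap:
    """Reference map with markers at sorted uniform positions per chromosome."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10 ** 6,)))
    loci = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(rng.uniform(0, config.chromosome_length_cM,
                                  config.markers_per_chromosome))
        for i, p in enumerate(pos, start=1):
            loci.append(MarkerLocus(name=f"c{c}m{i}", chromosome=str(c),
                                    position=float(p)))
    return GeneticMap.from_loci("reference_sim", loci)


def _distort_map(reference: GeneticMap, config: SimulationConfig,
                 rng: np.random.Generator, map_id: str,
                 population_size: int, population_type: str) -> GeneticMap:
    """Subset the reference markers and rescale each inter-marker interval
    by a positive log-normal factor; order is preserved."""
    loci: list[MarkerLocus] = []
    for chrom in reference.chromosomes:
        ref_loci = reference.loci(chrom)
        for _attempt in range(2):
            keep = [m for m in ref_loci
                    if rng.random() < config.shared_marker_fraction]
            if len(keep) >= 2:
                break
        else:
            raise MQTLError(
                f"chromosome {chrom}: fewer than 2 markers kept after resampling; "
                f"raise shared_marker_fraction or markers_per_chromosome"
            )
        gaps = np.diff([m.position for m in keep])
        factors = np.exp(rng.normal(0.0, config.distortion_sd, len(gaps)))
        pos = np.concatenate([[keep[0].position], keep[0].position + np.cumsum(gaps * factors)])
        loci.extend(
            MarkerLocus(name=m.name, chromosome=chrom, position=float(p))
            for m, p in zip(keep, pos)
        )
    return GeneticMap.from_loci(map_id, loci, population_size=population_size,
                                population_type=population_type)


def _component_scale(reference_pos: float, component: GeneticMap,
                     reference: GeneticMap, chromosome: str) -> float:
    """Re-express a reference-scale position on the component map's scale
    (piecewise-linear through the markers the component kept)."""
    names = component.marker_names(chromosome)
    ref_pos = np.array([reference.position_of(n, chromosome) for n in names])
    comp_pos = np.array(component.positions(chromosome))
    if reference_pos <= ref_pos[0]:
        slope = (comp_pos[-1] - comp_pos[0]) / max(ref_pos[-1] - ref_pos[0], 1e-12)
        return float(comp_pos[0] + (reference_pos - ref_pos[0]) * slope)
    if reference_pos >= ref_pos[-1]:
        slope = (comp_pos[-1] - comp_pos[0]) / max(ref_pos[-1] - ref_pos[0], 1e-12)
        return float(comp_pos[-1] + (reference_pos - ref_pos[-1]) * slope)
    return float(np.interp(reference_pos, ref_pos, comp_pos))


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float) -> float:
    while True:
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)


def simulate_study(reference: GeneticMap, config: SimulationConfig,
                   study_index: int) -> tuple[GeneticMap, list[QTLRecord], list[TrueQTL]]:
    """One study: a distorted component map plus its reported QTL.

    Each planted MQTL assigned to this study yields one QTL: R2 is drawn
    from the truncated beta, the 95% CI width follows CI95 = k / (N * R2)
    exactly, and the reported position scatters around the true locus (on
    the component scale) with sd = CI95 / 3.92.
    """
    config.validate()
    rng = _study_rng(config, study_index)
    study_id = f"study{study_index + 1:02d}"
    population_type = _POP_TYPES[int(rng.integers(len(_POP_TYPES)))]
    population_size = int(rng.integers(config.population_sizes[0],
                                       config.population_sizes[1] + 1))
    component = _distort_map(reference, config, rng, map_id=study_id,
                             population_size=population_size,
                             population_type=population_type)
    records: list[QTLRecord] = []
    truths: list[TrueQTL] = []
    for mqtl_index in _assignments(config)[study_index]:
        planted = config.planted_mqtl[mqtl_index]
        comp_center = _component_scale(planted.position, component, reference,
                                       planted.chromosome)
        r2 = _truncated_beta(rng, *config.r2_beta, *config.r2_bounds)
        width = K_CONSTANTS[population_type] / (population_size * r2)
        sd = width / 3.92
        position = float(rng.normal(comp_center, sd))
        qtl_id = f"{study_id}_m{mqtl_index + 1}"
        tissue = planted.tissue_class
        trait = _TRAITS[tissue][int(rng.integers(len(_TRAITS[tissue])))]
        records.append(QTLRecord(
            qtl_id=qtl_id, study_id=study_id, trait=trait,
            tissue_class=tissue,
            trait_category="CWC" if trait in {"ADL", "NDF", "p-CA", "ADF",
                                              "trans-FA", "Gal"} else "insect_resistance",
            chromosome=planted.chromosome, position=position,
            ci_start=position - width / 2.0, ci_end=position + width / 2.0,
            r2=r2, population_size=population_size,
            population_type=population_type,
        ))
        truths.append(TrueQTL(
            qtl_id=qtl_id, mqtl_index=mqtl_index, study_id=study_id,
            true_position=planted.position, component_position=comp_center,
            r2=r2, sd=sd,
        ))
    return component, records, truths


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[GeneticMap, list[tuple[GeneticMap, list[QTLRecord]]], GroundTruth]:
    """Full bundle: reference map, per-study (map, QTL) pairs, ground truth."""
    reference = simulate_reference(config)
    studies = []
    all_truths: list[TrueQTL] = []
    for s in range(config.n_studies):
        component, records, truths = simulate_study(reference, config, s)
        studies.append((component, records))
        all_truths.extend(truths)
    return reference, studies, GroundTruth(planted=list(config.planted_mqtl),
                                           qtls=all_truths)


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> None:
    """Write the bundle as the package's TSV formats plus a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, studies, truth = simulate_dataset(config)
    write_map(reference, out / "reference_map.tsv")
    records = []
    for component, qtls in studies:
        write_map(component, out / f"map_{component.map_id}.tsv")
        records.extend(qtls)
    write_qtl_table(records, out / "qtl.tsv")
    pd.DataFrame([{
        "qtl_id": t.qtl_id, "mqtl_index": t.mqtl_index, "study_id": t.study_id,
        "true_position_cM": t.true_position,
        "component_position_cM": t.component_position,
        "r2": t.r2, "sd_cM": t.sd,
    } for t in truth.qtls]).to_csv(out / "truth.tsv", sep="\t", index=False)
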