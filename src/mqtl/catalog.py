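"""Bundled catalog of published maize tissue-specific insect-resistance MQTL.

The package ships the curated table of 86 declared meta-QTL (24 leaf LIR,
42 stem SIR, 20 kernel KIR) for maize resistance to stem borers and storage
pests, with their genetic 95% CIs on the IBM2 2008 Neighbors reference map
and the physical intervals of their flanking markers on the B73 v2
assembly.  It serves as a real-data fixture for the coverage accounting and
the worked examples.

The CI(95%) column is kept as reported (``reported_ci_width``) because the
published per-tissue coverage totals are sums of that column, which for a
few rows differs slightly from end - start of the printed bounds.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import MQTL

#: Published per-tissue genetic coverage (cM) of the projected QTL 95% CIs
#: on the reference map (overlap-merged), from the same coverage panel.
QTL_GENETIC_COVERAGE_CM = {"kernel": 2702.35, "leaf": 4024.24, "stem": 5558.27}

_MBP = 1e6


def load_catalog_frame() -> pd.DataFrame:
    """The catalog as a DataFrame (one row per MQTL, Mbp physical columns)."""
    with (resources.files("mqtl") / "data" / "tissue_mqtl_catalog.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def load_catalog() -> list[MQTL]:
    """The catalog as :class:`~mqtl.meta.MQTL` records (bp physical units).

    An ``END`` physical end (flanking marker outward walk exhausted the
    chromosome) becomes an open-ended interval.
    """
    out = []
    for row in load_catalog_frame().itertuples(index=False):
        end_open = str(row.phys_end_mbp) == "END"
        out.append(MQTL(
            mqtl_id=row.mqtl_id,
            tissue_class=row.tissue_class,
            chromosome=str(row.chromosome),
            position=row.position_cM,
            ci95_start=row.ci_start_cM,
            ci95_end=row.ci_end_cM,
            sd=row.ci95_width_cM / (2 * 1.96),
            flank_left=row.flank_left,
            flank_right=row.flank_right,
            phys_start_bp=float(row.phys_start_mbp) * _MBP,
            phys_end_bp=None if end_open else float(row.phys_end_mbp) * _MBP,
            phys_end_open=end_open,
            reported_ci_width=row.ci95_width_cM,
        ))
    return out
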