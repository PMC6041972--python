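import pytest

from mqtl.io import GeneticMap, MarkerLocus, QTLRecord


def make_map(map_id, chrom_markers, **kw):
    """Build a GeneticMap from {chrom: [(name, pos), ...]}."""
    loci = [MarkerLocus(name=n, chromosome=c, position=p)
            for c, items in chrom_markers.items() for n, p in items]
    return GeneticMap.from_loci(map_id, loci, **kw)


def make_qtl(qtl_id="q1", study_id="s1", trait="ECB-TL", tissue="stem",
             chrom="1", position=50.0, ci=(45.0, 55.0), r2=0.1, lod=None,
             lrs=None, n=200, pop_type="F2", category="insect_resistance"):
    return QTLRecord(
        qtl_id=qtl_id, study_id=study_id, trait=trait, tissue_class=tissue,
        trait_category=category, chromosome=chrom, position=position,
        ci_start=ci[0] if ci else None, ci_end=ci[1] if ci else None,
        lod=lod, lrs=lrs, r2=r2, population_size=n, population_type=pop_type,
    )


@pytest.fixture
def reference_map():
    return make_map("ref", {
        "1": [("a", 0.0), ("b", 20.0), ("c", 40.0), ("d", 60.0), ("e", 100.0)],
        "2": [("f", 0.0), ("g", 30.0), ("h", 80.0)],
    })
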