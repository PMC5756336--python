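import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from auxoactivity.models import (
    Community,
    GeneRecord,
    GenomeBin,
    PathwayDefinition,
)


def make_bin(bin_id="bin001", genes=(), size=2_000_000, transporters=None,
             completeness=0.95, contamination=0.01, taxonomy="Archaeoglobus-like"):
    return GenomeBin(
        bin_id=bin_id,
        taxonomy_label=taxonomy,
        genome_size=size,
        completeness=completeness,
        contamination=contamination,
        genes=frozenset(genes),
        transporters=dict(transporters or {}),
    )


def make_pathway(compound="histidine", steps=(("g1",), ("g2", "g3")),
                 compound_class="amino_acid", transporter_relevant=True, rank=0):
    return PathwayDefinition(
        compound_id=compound,
        compound_class=compound_class,
        steps=tuple(frozenset(s) for s in steps),
        transporter_relevant=transporter_relevant,
        biosynthetic_cost_rank=rank,
    )


@pytest.fixture
def tiny_community():
    """Three bins, two pathways, ten gene records."""
    pathways = (
        make_pathway("histidine", steps=(("hisA", "hisA2"), ("hisB",)), rank=0),
        make_pathway("B2", steps=(("ribA",), ("ribB",)),
                     compound_class="vitamin", transporter_relevant=False, rank=1),
    )
    inventories = {
        "bin001": ("hisA", "hisB", "ribA", "ribB"),
        "bin002": ("hisA2", "hisB", "ribA"),
        "bin003": ("hisB", "ribA", "ribB"),
    }
    bins = tuple(
        make_bin(bid, genes=genes, size=1_000_000 * (i + 1),
                 transporters={"histidine": True} if i == 0 else {})
        for i, (bid, genes) in enumerate(sorted(inventories.items()))
    )
    genes = tuple(
        GeneRecord(gene_id=g, bin_id=bid, length=500 + 100 * j)
        for bid, inv in sorted(inventories.items())
        for j, g in enumerate(inv)
    )
    return Community(bins=bins, genes=genes, pathways=pathways)
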