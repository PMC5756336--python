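"""FPKM computation and the top-quartile "highly transcribed" rule.

FPKM = fragments / ((gene length / 1000) * (total mapped fragments / 1e6)).

A gene counts as highly transcribed when its FPKM is strictly above the
sample-wide 75th-percentile threshold, i.e. it ranks in the top 25% of
all genes in the metatranscriptome.  The quantile uses the lower
nearest-rank convention (no interpolation), computed over the union of
all genes across bins: the cumulative FPKM distribution is a property of
the whole sample, not of one genome.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .models import ExpressionTable, GeneRecord, ValidationError

#: Fraction of genes below the "highly transcribed" cutoff.
DEFAULT_QUANTILE = 0.75


@dataclass(frozen=True)
class TranscriptionClass:
    bin_id: str
    gene_id: str
    fpkm: float
    highly_transcribed: bool


def fpkm(
    fragments: Mapping[tuple[str, str], float],
    genes: Sequence[GeneRecord],
    total_mapped_fragments: int,
    sample_id: str = "sample",
) -> ExpressionTable:
    """Length- and depth-normalise fragment counts into FPKM.

    Every counted (bin, gene) pair must have a :class:`GeneRecord`
    supplying its length; zero counts give FPKM 0 exactly.
    """
    if total_mapped_fragments <= 0:
        raise ValidationError("total_mapped_fragments must be > 0")
    lengths = {(g.bin_id, g.gene_id): g.length for g in genes}
    table: dict[tuple[str, str], float] = {}
    per_million = total_mapped_fragments / 1e6
    for key, count in fragments.items():
        if key not in lengths:
            raise ValidationError(
                f"fragment count for unknown gene {key[1]!r} in bin {key[0]!r}"
            )
        if count < 0:
            raise ValidationError(f"negative fragment count for {key}")
        kb = lengths[key] / 1000.0
        table[key] = count / (kb * per_million)
    return ExpressionTable(
        sample_id=sample_id,
        fpkm=table,
        total_mapped_fragments=total_mapped_fragments,
    )


def expression_threshold(table: ExpressionTable, quantile: float = DEFAULT_QUANTILE) -> float:
    """Empirical quantile of all FPKM values, lower nearest-rank.

    With n sorted values the threshold is the ceil(q*n)-th smallest, so
    on ranks 1..100 at q = 0.75 the threshold is exactly 75 and the top
    25 values sit strictly above it.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValidationError(f"quantile {quantile} outside [0, 1]")
    values = sorted(table.fpkm.values())
    if not values:
        raise ValidationError("empty expression table")
    rank = max(1, math.ceil(quantile * len(values)))
    return values[rank - 1]


def classify_highly_transcribed(
    table: ExpressionTable, threshold: float
) -> list[TranscriptionClass]:
    """Flag genes with FPKM strictly above ``threshold``.

    Ties at the threshold are not flagged, matching the strict cutoff
    used for the top-quartile rule (FPKM > threshold).
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return [
        TranscriptionClass(
            bin_id=bin_id,
            gene_id=gene_id,
            fpkm=value,
            highly_transcribed=value > threshold,
        )
        for (bin_id, gene_id), value in sorted(table.fpkm.items())
    ]
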