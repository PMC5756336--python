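"""Relative abundance and cDNA/DNA transcriptional activity ratios.

Relative abundance divides each bin's mapped metagenomic reads by its
genome size before normalising, so that a large genome does not inflate
the apparent abundance of its organism.  Transcriptional activity is the
per-bin cDNA mapping rate divided by the DNA mapping rate; a community
member is called active when that ratio exceeds 0.5 (strictly), which
separates organisms transcribing above their DNA-abundance expectation
from the inactive background carried in by injection water.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .models import (
    CDNA,
    DNA,
    GenomeBin,
    ReadMappingSummary,
    ValidationError,
)

#: Default activity cutoff on the cDNA/DNA ratio (strict >).
ACTIVITY_THRESHOLD = 0.5


@dataclass
class ActivityProfile:
    """Mapping rates and activity classification for one bin."""

    bin_id: str
    dna_mapping_rate: float
    cdna_mapping_rate: float
    ratio: Optional[float]
    active: bool = False


def relative_abundance(
    dna: ReadMappingSummary, bins: Sequence[GenomeBin]
) -> dict[str, float]:
    """Genome-size-normalised relative abundance from a DNA library.

    abundance_i = (mapped_i / size_i) / sum_j (mapped_j / size_j)

    Bins with zero mapped reads get abundance 0; the result sums to 1
    over all bins in the summary.
    """
    sizes = {b.bin_id: b.genome_size for b in bins}
    unknown = sorted(set(dna.mapped_reads) - set(sizes))
    if unknown:
        raise ValidationError(
            f"mapping references bins without a genome size: {', '.join(unknown)}"
        )
    if dna.total_reads <= 0:
        raise ValidationError("total_reads must be > 0")
    weights = {
        bin_id: count / sizes[bin_id] for bin_id, count in dna.mapped_reads.items()
    }
    denom = sum(weights.values())
    if denom == 0:
        raise ValidationError("no mapped reads: all per-bin counts are zero")
    return {bin_id: w / denom for bin_id, w in weights.items()}


def cdna_dna_ratio(
    cdna: ReadMappingSummary, dna: ReadMappingSummary
) -> list[ActivityProfile]:
    """Per-bin cDNA/DNA mapping-rate ratios.

    Both summaries must describe the same bin set.  A bin with DNA
    mapping rate 0 gets an undefined ratio (None) and stays inactive:
    its transcription has no abundance baseline to be compared against.
    """
    if dna.library_type != DNA:
        raise ValidationError(f"expected a DNA summary, got {dna.library_type}")
    if cdna.library_type != CDNA:
        raise ValidationError(f"expected a cDNA summary, got {cdna.library_type}")
    only_dna = sorted(set(dna.mapped_reads) - set(cdna.mapped_reads))
    only_cdna = sorted(set(cdna.mapped_reads) - set(dna.mapped_reads))
    if only_dna or only_cdna:
        raise ValidationError(
            "mismatched bin sets between libraries; "
            f"DNA-only: {only_dna}; cDNA-only: {only_cdna}"
        )
    if dna.total_reads <= 0 or cdna.total_reads <= 0:
        raise ValidationError("library totals must be > 0")
    profiles = []
    for bin_id in sorted(dna.mapped_reads):
        dna_rate = dna.mapped_reads[bin_id] / dna.total_reads
        cdna_rate = cdna.mapped_reads[bin_id] / cdna.total_reads
        ratio = cdna_rate / dna_rate if dna_rate > 0 else None
        profiles.append(
            ActivityProfile(
                bin_id=bin_id,
                dna_mapping_rate=dna_rate,
                cdna_mapping_rate=cdna_rate,
                ratio=ratio,
            )
        )
    return profiles


def classify_active(
    profiles: Sequence[ActivityProfile], threshold: float = ACTIVITY_THRESHOLD
) -> set[str]:
    """Flag bins whose ratio is strictly above ``threshold``.

    Sets each profile's ``active`` field in place and returns the active
    bin ids.  Ties at the threshold are inactive, and undefined ratios
    never classify as active.
    """
    active = set()
    for p in profiles:
        p.active = p.ratio is not None and p.ratio > threshold
        if p.active:
            active.add(p.bin_id)
    return active
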