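"""Synthetic communities with planted ground truth.

Sequencing-scale inputs for this kind of analysis (binned genomes,
read-mapping summaries, per-gene fragment counts) cannot be regenerated
at desk scale, so this module fabricates the tabular products of the
upstream workflow with known truth planted in them:

* per bin x compound, a planted prototroph/auxotroph status — auxotrophs
  lack all alternatives of >= 2 pathway steps (or, optionally, of exactly
  one step with the pathway transcribed at a low level); "annotation-gap"
  prototrophs lack exactly one step but transcribe the rest of the
  pathway like complete bins, exercising the expression-rescue rule;
* per bin, a relative abundance (Dirichlet) and a transcriptional
  activity multiplier (log-normal) that drive multinomial DNA and cDNA
  read-mapping draws;
* per (bin, gene), an expected FPKM: each pathway has one log-normal
  mean shared by its genes, each bin also carries log-normal background
  genes, and Poisson fragment noise plus optional log-normal
  between-replicate noise sit on top.

Every stage draws from its own seeded stream, so regenerating one stage
never perturbs another, and identical (config, seed) give byte-identical
serialized outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import expression as expr
from .models import (
    AMINO_ACID,
    CDNA,
    DNA,
    VITAMIN,
    Community,
    ExpressionTable,
    GeneRecord,
    GenomeBin,
    PathwayDefinition,
    ReadMappingSummary,
    ValidationError,
)

# Amino acids ordered by increasing biosynthetic cost (Akashi-Gojobori-like
# ordering), then vitamins; synthetic compound names continue beyond these.
AMINO_ACIDS = (
    "glycine", "alanine", "serine", "aspartate", "asparagine", "glutamate",
    "glutamine", "threonine", "proline", "valine", "cysteine", "arginine",
    "leucine", "lysine", "isoleucine", "histidine", "methionine",
    "phenylalanine", "tyrosine", "tryptophan",
)
VITAMINS = ("B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12", "K2")
#: Vitamins taken up without a dedicated transport system.
TRANSPORTER_EXEMPT = frozenset({"B2", "B3"})

_TAXA = (
    "Acinetobacter-like", "Marinobacter-like", "Sulfurimonas-like",
    "Thermodesulfobacterium-like", "Archaeoglobus-like", "Methanosaeta-like",
    "Pseudomonas-like", "Clostridia-like",
)

# planted status categories
_FULL = "full_prototroph"
_GAP = "single_missing_prototroph"
_AUX = "auxotroph"
_LOWEXPR_AUX = "low_expression_auxotroph"

#: expression multiplier for pathways planted as transcribed-but-gapped vs low
_LOW_EXPRESSION_FACTOR = 0.1

_STREAM_COMMUNITY = 1
_STREAM_DNA = 2
_STREAM_CDNA = 3
_STREAM_EXPRESSION = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic community; defaults are the study conditions."""

    n_bins: int = 20
    n_compounds: int = 20
    steps_per_pathway: tuple[int, int] = (3, 6)
    or_group_size: tuple[int, int] = (1, 3)
    auxotroph_rate: float = 0.3
    single_missing_prototroph_rate: float = 0.1
    low_expression_auxotroph_rate: float = 0.0
    expression_noise_sd: float = 0.5
    dna_depth: int = 1_000_000
    cdna_depth: int = 1_000_000
    unmapped_fraction: float = 0.3
    n_background_genes: int = 30
    expectation_counts: bool = False  # replace Poisson/log-normal noise by the mean
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.auxotroph_rate,
            self.single_missing_prototroph_rate,
            self.low_expression_auxotroph_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValidationError("rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ValidationError("status rates must sum to <= 1")
        if self.dna_depth <= 0 or self.cdna_depth <= 0:
            raise ValidationError("sequencing depths must be > 0")
        if not 0.0 <= self.unmapped_fraction < 1.0:
            raise ValidationError("unmapped_fraction must lie in [0, 1)")
        if self.n_bins < 1 or self.n_compounds < 1:
            raise ValidationError("n_bins and n_compounds must be >= 1")
        if self.n_bins < 2 and self.single_missing_prototroph_rate > 0:
            raise ValidationError(
                "single_missing_prototroph_rate > 0 needs n_bins >= 2: the "
                "rescue rule compares against complete-pathway reference bins"
            )
        if self.steps_per_pathway[0] < 2:
            raise ValidationError("pathways need >= 2 steps")
        if self.steps_per_pathway[0] > self.steps_per_pathway[1]:
            raise ValidationError("steps_per_pathway range is inverted")
        if self.or_group_size[0] < 1 or self.or_group_size[0] > self.or_group_size[1]:
            raise ValidationError("or_group_size range is invalid")
        if self.expression_noise_sd < 0:
            raise ValidationError("expression_noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    status_truth: dict[tuple[str, str], str]  # (bin, compound) -> prototroph/auxotroph
    activity_truth: dict[str, float]
    abundance_truth: dict[str, float]
    expressed_mean: dict[tuple[str, str], float]  # (bin, gene) -> expected FPKM
    category: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundance_truth.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"abundance_truth sums to {total}, not 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def compound_names(n: int) -> list[str]:
    names = list(AMINO_ACIDS) + list(VITAMINS)
    while len(names) < n:
        names.append(f"compound{len(names) + 1:02d}")
    return names[:n]


def generate_community(
    config: GeneratorConfig,
) -> tuple[Community, SyntheticTruth]:
    """Draw a community with planted auxotrophies and expression means."""
    rng = _rng(config.seed, _STREAM_COMMUNITY)
    compounds = compound_names(config.n_compounds)

    pathways = []
    pathway_mean: dict[str, float] = {}
    for rank, compound in enumerate(compounds):
        n_steps = int(rng.integers(config.steps_per_pathway[0],
                                   config.steps_per_pathway[1] + 1))
        steps = []
        for si in range(n_steps):
            n_alt = int(rng.integers(config.or_group_size[0],
                                     config.or_group_size[1] + 1))
            steps.append(frozenset(
                f"{compound}_s{si:02d}g{ai}" for ai in range(n_alt)
            ))
        pathways.append(
            PathwayDefinition(
                compound_id=compound,
                compound_class=VITAMIN if compound in VITAMINS else AMINO_ACID,
                transporter_relevant=compound not in TRANSPORTER_EXEMPT,
                biosynthetic_cost_rank=rank,
                steps=tuple(steps),
            )
        )
        # one shared mean per pathway keeps rescue comparisons exact at
        # zero noise: a gapped-but-transcribed pathway scores what a
        # complete one does
        pathway_mean[compound] = float(rng.lognormal(math.log(30.0), 0.8))

    gene_length: dict[str, int] = {}

    def length_of(gene_id: str) -> int:
        if gene_id not in gene_length:
            gene_length[gene_id] = int(rng.integers(300, 3001))
        return gene_length[gene_id]

    bins: list[GenomeBin] = []
    gene_records: list[GeneRecord] = []
    status_truth: dict[tuple[str, str], str] = {}
    category: dict[tuple[str, str], str] = {}
    expressed_mean: dict[tuple[str, str], float] = {}

    p_aux = config.auxotroph_rate
    p_gap = config.single_missing_prototroph_rate
    p_low = config.low_expression_auxotroph_rate

    for i in range(config.n_bins):
        bin_id = f"bin{i + 1:03d}"
        taxonomy = _TAXA[i % len(_TAXA)]
        genome_size = int(rng.integers(1_000_000, 6_000_001))
        # drawn on the 4-decimal percentage grid the TSV format stores
        completeness = round(float(rng.uniform(85.0, 100.0)), 4) / 100.0
        contamination = round(float(rng.uniform(0.0, 3.0)), 4) / 100.0
        genes: set[str] = set()
        transporters: dict[str, bool] = {}

        for pathway in pathways:
            compound = pathway.compound_id
            u = float(rng.uniform())
            if u < p_aux:
                cat = _AUX
            elif u < p_aux + p_gap:
                cat = _GAP
            elif u < p_aux + p_gap + p_low:
                cat = _LOWEXPR_AUX
            else:
                cat = _FULL
            n_steps = len(pathway.steps)
            if cat == _AUX:
                k_missing = int(rng.integers(2, n_steps + 1))
                missing = set(rng.choice(n_steps, size=k_missing, replace=False).tolist())
            elif cat in (_GAP, _LOWEXPR_AUX):
                missing = {int(rng.integers(n_steps))}
            else:
                missing = set()

            factor = {
                _FULL: 1.0, _GAP: 1.0,
                _AUX: 0.0, _LOWEXPR_AUX: _LOW_EXPRESSION_FACTOR,
            }[cat]
            for si, step in enumerate(pathway.steps):
                if si in missing:
                    continue
                alts = sorted(step)
                keep = [a for a in alts if rng.uniform() < 0.7]
                if not keep:
                    keep = [alts[int(rng.integers(len(alts)))]]
                for gene in keep:
                    genes.add(gene)
                    expressed_mean[(bin_id, gene)] = factor * pathway_mean[compound]

            status_truth[(bin_id, compound)] = (
                "auxotroph" if cat in (_AUX, _LOWEXPR_AUX) else "prototroph"
            )
            category[(bin_id, compound)] = cat
            if pathway.transporter_relevant and rng.uniform() < 0.5:
                transporters[compound] = True

        for j in range(config.n_background_genes):
            gene = f"{bin_id}_bg{j:03d}"
            genes.add(gene)
            expressed_mean[(bin_id, gene)] = float(rng.lognormal(math.log(10.0), 1.0))

        for gene in sorted(genes):
            gene_records.append(
                GeneRecord(gene_id=gene, bin_id=bin_id, length=length_of(gene))
            )
        bins.append(
            GenomeBin(
                bin_id=bin_id,
                taxonomy_label=taxonomy,
                genome_size=genome_size,
                completeness=completeness,
                contamination=contamination,
                genes=frozenset(genes),
                transporters=transporters,
            )
        )

    raw_abundance = rng.dirichlet(np.ones(config.n_bins))
    # renormalise so the planted vector sums to 1 at float precision
    raw_abundance = raw_abundance / raw_abundance.sum()
    abundance_truth = {b.bin_id: float(a) for b, a in zip(bins, raw_abundance)}
    activity_truth = {
        b.bin_id: float(rng.lognormal(0.0, 0.7)) for b in bins
    }

    community = Community(
        bins=tuple(bins), genes=tuple(gene_records), pathways=tuple(pathways)
    )
    truth = SyntheticTruth(
        status_truth=status_truth,
        activity_truth=activity_truth,
        abundance_truth=abundance_truth,
        expressed_mean=expressed_mean,
        category=category,
    )
    return community, truth


def _multinomial_summary(
    rng: np.random.Generator,
    sample_id: str,
    library_type: str,
    depth: int,
    weights: dict[str, float],
    unmapped_fraction: float,
) -> ReadMappingSummary:
    bin_ids = sorted(weights)
    w = np.array([weights[b] for b in bin_ids], dtype=float)
    p = (1.0 - unmapped_fraction) * w / w.sum()
    p = np.append(p, 1.0 - p.sum())  # unmapped remainder category
    counts = rng.multinomial(depth, p)
    return ReadMappingSummary(
        sample_id=sample_id,
        library_type=library_type,
        total_reads=depth,
        mapped_reads={b: int(c) for b, c in zip(bin_ids, counts[:-1])},
    )


def simulate_mapping(
    truth: SyntheticTruth, community: Community, config: GeneratorConfig
) -> tuple[ReadMappingSummary, ReadMappingSummary]:
    """Draw DNA and cDNA read-mapping summaries.

    DNA reads land on a bin in proportion to abundance x genome size
    (more DNA per cell for bigger genomes); cDNA reads in proportion to
    abundance x activity multiplier.  A configurable fraction of each
    library stays unmapped, emulating community members that never made
    it into a bin.
    """
    sizes = {b.bin_id: b.genome_size for b in community.bins}
    dna_weights = {
        bid: truth.abundance_truth[bid] * sizes[bid] for bid in sizes
    }
    cdna_weights = {
        bid: truth.abundance_truth[bid] * truth.activity_truth[bid] for bid in sizes
    }
    dna = _multinomial_summary(
        _rng(config.seed, _STREAM_DNA), "synthetic", DNA, config.dna_depth,
        dna_weights, config.unmapped_fraction,
    )
    cdna = _multinomial_summary(
        _rng(config.seed, _STREAM_CDNA), "synthetic", CDNA, config.cdna_depth,
        cdna_weights, config.unmapped_fraction,
    )
    return dna, cdna


def simulate_expression(
    truth: SyntheticTruth, community: Community, config: GeneratorConfig
) -> ExpressionTable:
    """Draw per-gene fragment counts and convert them to FPKM.

    The expected fragment count of a gene is its planted FPKM times
    (length/1000) x (library depth/1e6), so that the FPKM computed back
    from the counts is centred on the planted value.  Log-normal noise
    (sd on the natural-log scale) multiplies the mean, then Poisson
    counting noise applies.  With ``expectation_counts`` set — or at
    ``expression_noise_sd = 0``, the fully noiseless condition — every
    count equals its expectation exactly.
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    per_kb_per_million = config.cdna_depth / 1e6
    deterministic = config.expectation_counts or config.expression_noise_sd == 0
    fragments: dict[tuple[str, str], float] = {}
    for record in sorted(community.genes, key=lambda g: (g.bin_id, g.gene_id)):
        key = (record.bin_id, record.gene_id)
        mean_fpkm = truth.expressed_mean.get(key, 0.0)
        mean_frags = mean_fpkm * (record.length / 1000.0) * per_kb_per_million
        if deterministic:
            fragments[key] = mean_frags
        else:
            if mean_frags > 0:
                mean_frags *= rng.lognormal(0.0, config.expression_noise_sd)
            fragments[key] = float(rng.poisson(mean_frags))
    return expr.fpkm(
        fragments,
        community.genes,
        total_mapped_fragments=config.cdna_depth,
        sample_id="synthetic",
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize planted truth as JSON (sorted keys; byte-stable)."""
    import json

    payload = {
        "status_truth": {f"{b}\t{c}": s for (b, c), s in truth.status_truth.items()},
        "category": {f"{b}\t{c}": s for (b, c), s in truth.category.items()},
        "activity_truth": truth.activity_truth,
        "abundance_truth": truth.abundance_truth,
        "expressed_mean": {
            f"{b}\t{g}": m for (b, g), m in truth.expressed_mean.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    import json

    with open(path) as fh:
        payload = json.load(fh)

    def unkey(d):
        return {tuple(k.split("\t")): v for k, v in d.items()}

    return SyntheticTruth(
        status_truth=unkey(payload["status_truth"]),
        category=unkey(payload.get("category", {})),
        activity_truth=payload["activity_truth"],
        abundance_truth=payload["abundance_truth"],
        expressed_mean=unkey(payload["expressed_mean"]),
    )


def generate_all(
    config: GeneratorConfig,
) -> tuple[Community, SyntheticTruth, ReadMappingSummary, ReadMappingSummary, ExpressionTable]:
    """Convenience wrapper running all three stages."""
    community, truth = generate_community(config)
    dna, cdna = simulate_mapping(truth, community, config)
    table = simulate_expression(truth, community, config)
    return community, truth, dna, cdna, table
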