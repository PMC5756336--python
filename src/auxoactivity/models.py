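"""Domain types shared by every analysis stage.

The objects here mirror the tabular products of a genome-resolved
metagenomics/metatranscriptomics workflow: genome bins with orthology-gene
inventories, biosynthetic pathway definitions, read-mapping summaries for
DNA and cDNA libraries, per-gene expression tables, auxotrophy calls, and
the reaction/conditions pair used for Gibbs-energy evaluation.

All types validate their invariants on construction and raise
:class:`ValidationError` on violation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence


class ValidationError(ValueError):
    """An object or file violates a structural invariant."""


AMINO_ACID = "amino_acid"
VITAMIN = "vitamin"

PROTOTROPH = "prototroph"
AUXOTROPH = "auxotroph"
INDETERMINATE = "indeterminate"
STATUSES = (PROTOTROPH, AUXOTROPH, INDETERMINATE)

DNA = "DNA"
CDNA = "cDNA"

AQUEOUS = "aqueous"
GAS = "gas"
PURE_LIQUID = "pure_liquid"
WATER = "water"
PHASES = (AQUEOUS, GAS, PURE_LIQUID, WATER)

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Reference temperature (K) of the bundled formation energies.
T_STANDARD = 298.15


@dataclass
class GenomeBin:
    """A draft genome recovered by binning, with its gene inventory.

    Completeness and contamination are stored as fractions in [0, 1];
    the file readers accept CheckM-style percentages and convert.
    """

    bin_id: str
    taxonomy_label: str
    genome_size: int
    completeness: float
    contamination: float
    genes: frozenset[str] = field(default_factory=frozenset)
    transporters: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bin_id:
            raise ValidationError("bin_id must be non-empty")
        if self.genome_size <= 0:
            raise ValidationError(
                f"bin {self.bin_id}: genome_size must be > 0, got {self.genome_size}"
            )
        if not 0.0 <= self.completeness <= 1.0:
            raise ValidationError(
                f"bin {self.bin_id}: completeness {self.completeness} outside [0, 1]"
            )
        if not 0.0 <= self.contamination <= 1.0:
            raise ValidationError(
                f"bin {self.bin_id}: contamination {self.contamination} outside [0, 1]"
            )
        self.genes = frozenset(self.genes)


@dataclass(frozen=True)
class PathwayDefinition:
    """A compound's biosynthetic route as an ordered list of OR-group steps.

    Each step is a set of alternative genes (isoenzymes); the step is
    satisfied if any member is present.  ``transporter_relevant`` is False
    for compounds whose uptake needs no dedicated transport system
    (vitamins B2 and B3), in which case transporter presence is reported
    as not applicable.
    """

    compound_id: str
    compound_class: str
    steps: tuple[frozenset[str], ...]
    transporter_relevant: bool = True
    biosynthetic_cost_rank: int = 0

    def __post_init__(self) -> None:
        if self.compound_class not in (AMINO_ACID, VITAMIN):
            raise ValidationError(
                f"pathway {self.compound_id}: unknown compound_class "
                f"{self.compound_class!r}"
            )
        if not self.steps:
            raise ValidationError(f"pathway {self.compound_id}: steps must be non-empty")
        steps = tuple(frozenset(s) for s in self.steps)
        for i, step in enumerate(steps):
            if not step:
                raise ValidationError(
                    f"pathway {self.compound_id}: step {i} OR-group is empty"
                )
        object.__setattr__(self, "steps", steps)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= step
        return frozenset(out)


@dataclass(frozen=True)
class GeneRecord:
    """One gene instance in one bin; length feeds the FPKM denominator."""

    gene_id: str
    bin_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(
                f"gene {self.gene_id} in {self.bin_id}: length must be > 0"
            )


@dataclass
class ReadMappingSummary:
    """Per-sample mapped-read counts per bin for one library type."""

    sample_id: str
    library_type: str
    total_reads: int
    mapped_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_type not in (DNA, CDNA):
            raise ValidationError(
                f"library_type must be 'DNA' or 'cDNA', got {self.library_type!r}"
            )
        if any(v < 0 for v in self.mapped_reads.values()):
            raise ValidationError("mapped read counts must be non-negative")
        mapped = sum(self.mapped_reads.values())
        if self.total_reads < mapped:
            raise ValidationError(
                f"sample {self.sample_id} ({self.library_type}): total_reads "
                f"{self.total_reads} < sum of mapped reads {mapped}"
            )


@dataclass
class ExpressionTable:
    """Per-(bin, gene) FPKM values with the library total they came from."""

    sample_id: str
    fpkm: dict[tuple[str, str], float] = field(default_factory=dict)
    total_mapped_fragments: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped_fragments <= 0:
            raise ValidationError("total_mapped_fragments must be > 0")
        for key, value in self.fpkm.items():
            if value < 0:
                raise ValidationError(f"negative FPKM for {key}")

    def values(self) -> list[float]:
        return list(self.fpkm.values())


@dataclass
class AuxotrophyCall:
    """The status of one bin for one compound.

    ``transporter_present`` is None when the compound needs no transport
    system, otherwise a boolean copied from the bin annotation.
    """

    bin_id: str
    compound_id: str
    status: str
    n_missing_steps: int
    rescue_applied: bool = False
    pathway_expression_score: Optional[float] = None
    transporter_present: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == PROTOTROPH and self.n_missing_steps > 1:
            raise ValidationError(
                f"{self.bin_id}/{self.compound_id}: prototroph with "
                f"{self.n_missing_steps} missing steps"
            )
        if self.n_missing_steps >= 2 and self.status != AUXOTROPH:
            raise ValidationError(
                f"{self.bin_id}/{self.compound_id}: >= 2 missing steps requires "
                f"auxotroph status"
            )
        if self.rescue_applied and self.n_missing_steps != 1:
            raise ValidationError("rescue_applied requires exactly 1 missing step")
        if (
            self.pathway_expression_score is not None
            and self.pathway_expression_score < 0
        ):
            raise ValidationError("pathway_expression_score must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction; products carry positive coefficients.

    Coefficients are kept as :class:`fractions.Fraction` so that rational
    combinations (e.g. coupling a fermentation to 17/4 acetogenesis) stay
    exact.  Elemental/charge balance is checked against the species table
    at evaluation time, not construction time, because composition lives
    in the formation-energy table.
    """

    name: str
    stoichiometry: Mapping[str, Fraction]
    species_phase: Mapping[str, str]
    reference: str = ""

    def __post_init__(self) -> None:
        stoich = {s: Fraction(v) for s, v in self.stoichiometry.items() if v != 0}
        phases = dict(self.species_phase)
        for species in stoich:
            phase = phases.get(species)
            if phase is None:
                raise ValidationError(
                    f"reaction {self.name}: no phase for species {species!r}"
                )
            if phase not in PHASES:
                raise ValidationError(
                    f"reaction {self.name}: unknown phase {phase!r} for {species!r}"
                )
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "species_phase", phases)

    @staticmethod
    def linear_combination(
        terms: Sequence[tuple[Fraction | int, "Reaction"]], name: str
    ) -> "Reaction":
        """Build the net reaction Σ c_k R_k with exact rational arithmetic."""
        stoich: dict[str, Fraction] = {}
        phases: dict[str, str] = {}
        refs = []
        for coef, rxn in terms:
            coef = Fraction(coef)
            refs.append(f"{coef} x {rxn.name}")
            for sp, nu in rxn.stoichiometry.items():
                stoich[sp] = stoich.get(sp, Fraction(0)) + coef * nu
                if sp in phases and phases[sp] != rxn.species_phase[sp]:
                    raise ValidationError(
                        f"species {sp!r} has conflicting phases in combination"
                    )
                phases[sp] = rxn.species_phase[sp]
        stoich = {s: v for s, v in stoich.items() if v != 0}
        phases = {s: p for s, p in phases.items() if s in stoich}
        return Reaction(
            name=name, stoichiometry=stoich, species_phase=phases,
            reference=" + ".join(refs),
        )


@dataclass
class Conditions:
    """Physicochemical state for in-situ Gibbs-energy evaluation.

    Aqueous activities are molar concentrations (activity coefficient 1),
    gases partial pressures in atm, water and pure liquids activity 1,
    and the proton activity is 10^-pH.
    """

    temperature: float
    pH: float
    concentrations: dict[str, float] = field(default_factory=dict)
    partial_pressures: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        for name, c in self.concentrations.items():
            if c <= 0:
                raise ValidationError(f"concentration of {name!r} must be > 0")
        for name, p in self.partial_pressures.items():
            if p <= 0:
                raise ValidationError(f"partial pressure of {name!r} must be > 0")

    def replace(self, **updates) -> "Conditions":
        """Return a copy with scalar fields and/or single activities changed."""
        conc = dict(self.concentrations)
        pres = dict(self.partial_pressures)
        conc.update(updates.pop("concentrations", {}))
        pres.update(updates.pop("partial_pressures", {}))
        return Conditions(
            temperature=updates.get("temperature", self.temperature),
            pH=updates.get("pH", self.pH),
            concentrations=conc,
            partial_pressures=pres,
        )


@dataclass(frozen=True)
class Community:
    """Cross-referenced bundle of bins, gene records, and pathways."""

    bins: tuple[GenomeBin, ...]
    genes: tuple[GeneRecord, ...]
    pathways: tuple[PathwayDefinition, ...]

    def __post_init__(self) -> None:
        bin_ids = [b.bin_id for b in self.bins]
        if len(bin_ids) != len(set(bin_ids)):
            dupes = sorted({b for b in bin_ids if bin_ids.count(b) > 1})
            raise ValidationError(f"duplicate bin_id(s): {', '.join(dupes)}")
        compound_ids = [p.compound_id for p in self.pathways]
        if len(compound_ids) != len(set(compound_ids)):
            raise ValidationError("duplicate compound_id in pathways")
        known = set(bin_ids)
        for g in self.genes:
            if g.bin_id not in known:
                raise ValidationError(
                    f"gene {g.gene_id} references unknown bin {g.bin_id!r}"
                )

    @property
    def bin_index(self) -> dict[str, GenomeBin]:
        return {b.bin_id: b for b in self.bins}

    def gene_length(self, gene_id: str, bin_id: str) -> int:
        for g in self.genes:
            if g.gene_id == gene_id and g.bin_id == bin_id:
                return g.length
        raise KeyError((bin_id, gene_id))
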