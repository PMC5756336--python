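"""Auxotrophy calling from pathway completeness plus expression rescue.

A biosynthetic pathway is a list of steps, each an OR-group of
alternative genes (isoenzymes).  Counting is step-level: a step with any
member present is satisfied, so alternative enzymes for one reaction
never create a false auxotrophy.  The calling rule:

* 0 missing steps  -> prototroph;
* >= 2 missing steps -> auxotroph, regardless of expression;
* exactly 1 missing step -> decided by the expression-rescue rule: the
  pathway counts as complete (the single absence is treated as an
  annotation/assembly gap) when its overall transcription is similar to
  or higher than in genomes carrying the complete pathway; low
  transcription confirms the auxotrophy; when no expression data or no
  complete-pathway reference genome exists the call is indeterminate.

"Overall transcription" is operationalised as the median FPKM over the
pathway genes present in the bin, and "similar or higher" as
score >= alpha * median(reference scores) with alpha = 0.75 by default.
Transporter presence is recorded alongside the call but never changes
it (it is displayed, not required); compounds needing no transport
system (vitamins B2 and B3) record it as not applicable.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import (
    AUXOTROPH,
    INDETERMINATE,
    PROTOTROPH,
    AuxotrophyCall,
    ExpressionTable,
    GenomeBin,
    PathwayDefinition,
    ValidationError,
)

#: "Similar or higher" tolerance on the pathway expression score.
DEFAULT_ALPHA = 0.75

COVERED = "covered"
UNCOVERED = "uncovered"


@dataclass
class PathwayEvaluation:
    """Completeness and expression evidence for one bin x pathway."""

    bin_id: str
    compound_id: str
    missing_steps: list[int]
    expression_score: Optional[float] = None
    reference_scores: list[float] = field(default_factory=list)

    @property
    def n_missing(self) -> int:
        return len(self.missing_steps)


@dataclass(frozen=True)
class CompoundCoverage:
    """Whether at least one community member can synthesise a compound."""

    covered: bool
    data_limited: bool  # only indeterminate calls stood between it and coverage


def pathway_completeness(
    bin: GenomeBin, pathway: PathwayDefinition
) -> PathwayEvaluation:
    """List the pathway steps with no present alternative in the bin."""
    missing = [
        idx
        for idx, step in enumerate(pathway.steps)
        if not (step & bin.genes)
    ]
    return PathwayEvaluation(
        bin_id=bin.bin_id, compound_id=pathway.compound_id, missing_steps=missing
    )


def pathway_expression_score(
    bin: GenomeBin, pathway: PathwayDefinition, expression: ExpressionTable
) -> Optional[float]:
    """Median FPKM over the pathway genes present in the bin.

    Present genes without an FPKM entry count as 0 (no mapped
    fragments).  Returns None when the bin carries no gene of the
    pathway at all.
    """
    present = sorted(pathway.all_genes & bin.genes)
    if not present:
        return None
    values = [expression.fpkm.get((bin.bin_id, g), 0.0) for g in present]
    return float(statistics.median(values))


def expression_rescue(eval: PathwayEvaluation, alpha: float = DEFAULT_ALPHA) -> bool:
    """Decide whether a single-missing-gene pathway counts as complete.

    True iff reference scores from complete-pathway bins exist and the
    bin's pathway expression score is >= alpha * median(references).
    Raises on pathways that do not have exactly one missing step — the
    rule is only defined there.
    """
    if eval.n_missing != 1:
        raise ValidationError(
            f"expression_rescue applies only to pathways with exactly 1 missing "
            f"step, got {eval.n_missing} for {eval.bin_id}/{eval.compound_id}"
        )
    if eval.expression_score is None or not eval.reference_scores:
        return False
    return eval.expression_score >= alpha * statistics.median(eval.reference_scores)


def call_auxotrophy(
    eval: PathwayEvaluation,
    pathway: PathwayDefinition,
    bin: GenomeBin,
    expression_available: bool,
    alpha: float = DEFAULT_ALPHA,
) -> AuxotrophyCall:
    """Apply the calling rule to one evaluated bin x pathway pair."""
    rescue_applied = False
    if eval.n_missing == 0:
        status = PROTOTROPH
    elif eval.n_missing >= 2:
        status = AUXOTROPH
    else:
        if (
            not expression_available
            or eval.expression_score is None
            or not eval.reference_scores
        ):
            status = INDETERMINATE
        elif expression_rescue(eval, alpha):
            status = PROTOTROPH
            rescue_applied = True
        else:
            status = AUXOTROPH
    if pathway.transporter_relevant:
        transporter: Optional[bool] = bool(
            bin.transporters.get(pathway.compound_id, False)
        )
    else:
        transporter = None
    return AuxotrophyCall(
        bin_id=bin.bin_id,
        compound_id=pathway.compound_id,
        status=status,
        n_missing_steps=eval.n_missing,
        rescue_applied=rescue_applied,
        pathway_expression_score=eval.expression_score,
        transporter_present=transporter,
    )


def auxotrophy_matrix(
    bins: Sequence[GenomeBin],
    pathways: Sequence[PathwayDefinition],
    expression: Optional[ExpressionTable] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[AuxotrophyCall]:
    """Call every bin for every compound.

    For each pathway, bins with zero missing steps define the reference
    expression scores the rescue rule compares against.  Output order is
    canonical — compounds by (cost rank, id), bins by id — regardless of
    input order.
    """
    ordered_pathways = sorted(
        pathways, key=lambda p: (p.biosynthetic_cost_rank, p.compound_id)
    )
    ordered_bins = sorted(bins, key=lambda b: b.bin_id)
    calls: list[AuxotrophyCall] = []
    for pathway in ordered_pathways:
        evals = {b.bin_id: pathway_completeness(b, pathway) for b in ordered_bins}
        if expression is not None:
            scores = {
                b.bin_id: pathway_expression_score(b, pathway, expression)
                for b in ordered_bins
            }
            references = [
                scores[bid]
                for bid, ev in evals.items()
                if ev.n_missing == 0 and scores[bid] is not None
            ]
            for b in ordered_bins:
                evals[b.bin_id].expression_score = scores[b.bin_id]
                evals[b.bin_id].reference_scores = list(references)
        for b in ordered_bins:
            calls.append(
                call_auxotrophy(
                    evals[b.bin_id],
                    pathway,
                    b,
                    expression_available=expression is not None,
                    alpha=alpha,
                )
            )
    return calls


def community_complementarity(
    calls: Sequence[AuxotrophyCall],
) -> dict[str, CompoundCoverage]:
    """Per compound: can the community, taken as a unit, synthesise it?

    A compound is covered iff at least one bin is a prototroph for it.
    Compounds where no bin is prototroph but at least one call is
    indeterminate are uncovered yet flagged data-limited: more expression
    data could still rescue them.
    """
    by_compound: dict[str, list[AuxotrophyCall]] = {}
    for call in calls:
        by_compound.setdefault(call.compound_id, []).append(call)
    out = {}
    for compound, compound_calls in by_compound.items():
        covered = any(c.status == PROTOTROPH for c in compound_calls)
        data_limited = not covered and any(
            c.status == INDETERMINATE for c in compound_calls
        )
        out[compound] = CompoundCoverage(covered=covered, data_limited=data_limited)
    return out
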