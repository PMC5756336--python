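"""Readers and writers for the plain-text community file formats.

Formats (all TSV except the pathway/truth JSON):

* ``bins.tsv`` — bin_id, taxonomy, genome_size_bp, completeness_pct,
  contamination_pct, gene_ids (comma-joined), transporter_compounds
  (comma-joined compounds with a transporter present).
* ``genes.tsv`` — gene_id, bin_id, length_bp.
* ``pathways.json`` — list of ``{compound_id, compound_class,
  transporter_relevant, cost_rank, steps: [[gene, ...], ...]}``.
* ``mapping.tsv`` — sample_id, library_type, total_reads, bin_id,
  mapped_reads (long format; one summary per sample x library).
* ``expression.tsv`` + ``totals.tsv`` — fragment counts per (sample,
  bin, gene) and per-sample totals of mapped fragments.

Completeness/contamination are percentages on disk (the CheckM
convention) and fractions in memory.  All writers emit rows in a
canonical sort order so that identical objects give byte-identical
files regardless of input order.
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import (
    AuxotrophyCall,
    Community,
    ExpressionTable,
    GeneRecord,
    GenomeBin,
    PathwayDefinition,
    ReadMappingSummary,
    ValidationError,
    AUXOTROPH,
    INDETERMINATE,
    PROTOTROPH,
)

BINS_FILE = "bins.tsv"
GENES_FILE = "genes.tsv"
PATHWAYS_FILE = "pathways.json"
MAPPING_FILE = "mapping.tsv"
EXPRESSION_FILE = "expression.tsv"
TOTALS_FILE = "totals.tsv"
TRUTH_FILE = "truth.json"

_BIN_COLUMNS = [
    "bin_id", "taxonomy", "genome_size_bp", "completeness_pct",
    "contamination_pct", "gene_ids", "transporter_compounds",
]
_GENE_COLUMNS = ["gene_id", "bin_id", "length_bp"]
_MAPPING_COLUMNS = ["sample_id", "library_type", "total_reads", "bin_id", "mapped_reads"]
_EXPRESSION_COLUMNS = ["sample_id", "bin_id", "gene_id", "fragments"]
_TOTALS_COLUMNS = ["sample_id", "total_mapped_fragments"]


def _read_tsv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing file: {path.name} (looked in {path.parent})")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path.name}: cannot parse ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return df


def _row_int(path: Path, row_idx: int, field: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ValidationError(
            f"{path.name} line {row_idx + 2}: {field} is not an integer ({raw!r})"
        ) from None


def _row_float(path: Path, row_idx: int, field: str, raw: str) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise ValidationError(
            f"{path.name} line {row_idx + 2}: {field} is not a number ({raw!r})"
        ) from None
    if math.isnan(value):
        raise ValidationError(f"{path.name} line {row_idx + 2}: {field} is NaN")
    return value


def _split_list(raw: str) -> list[str]:
    return [item for item in raw.split(",") if item]


# ---------------------------------------------------------------------------
# community (bins + genes + pathways)
# ---------------------------------------------------------------------------

def read_community(dir_path: str | Path) -> Community:
    """Load and cross-reference a community directory.

    Raises :class:`ValidationError` with the offending file name / line
    number on any missing file, malformed row, duplicate bin, or gene row
    that references an unknown bin.
    """
    dir_path = Path(dir_path)
    bins = _read_bins(dir_path / BINS_FILE)
    genes = _read_genes(dir_path / GENES_FILE)
    pathways = read_pathways(dir_path / PATHWAYS_FILE)
    return Community(bins=tuple(bins), genes=tuple(genes), pathways=tuple(pathways))


def _read_bins(path: Path) -> list[GenomeBin]:
    df = _read_tsv(path, _BIN_COLUMNS)
    bins: list[GenomeBin] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        bin_id = row["bin_id"]
        if bin_id in seen:
            raise ValidationError(f"{path.name} line {idx + 2}: duplicate bin_id {bin_id!r}")
        seen.add(bin_id)
        try:
            bins.append(
                GenomeBin(
                    bin_id=bin_id,
                    taxonomy_label=row["taxonomy"],
                    genome_size=_row_int(path, idx, "genome_size_bp", row["genome_size_bp"]),
                    completeness=_row_float(path, idx, "completeness_pct", row["completeness_pct"]) / 100.0,
                    contamination=_row_float(path, idx, "contamination_pct", row["contamination_pct"]) / 100.0,
                    genes=frozenset(_split_list(row["gene_ids"])),
                    transporters={c: True for c in _split_list(row["transporter_compounds"])},
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} line {idx + 2}: {exc}") from None
    return bins


def _read_genes(path: Path) -> list[GeneRecord]:
    df = _read_tsv(path, _GENE_COLUMNS)
    genes = []
    for idx, row in df.iterrows():
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                bin_id=row["bin_id"],
                length=_row_int(path, idx, "length_bp", row["length_bp"]),
            )
        )
    return genes


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path.name} (looked in {path.parent})")
    with open(path) as fh:
        raw = json.load(fh)
    pathways = []
    for entry in raw:
        pathways.append(
            PathwayDefinition(
                compound_id=entry["compound_id"],
                compound_class=entry["compound_class"],
                transporter_relevant=bool(entry.get("transporter_relevant", True)),
                biosynthetic_cost_rank=int(entry.get("cost_rank", 0)),
                steps=tuple(frozenset(step) for step in entry["steps"]),
            )
        )
    ids = [p.compound_id for p in pathways]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path.name}: duplicate compound_id")
    return pathways


def write_community(community: Community, dir_path: str | Path) -> Path:
    """Write bins.tsv / genes.tsv / pathways.json with canonical row order."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    rows = []
    for b in sorted(community.bins, key=lambda b: b.bin_id):
        rows.append(
            {
                "bin_id": b.bin_id,
                "taxonomy": b.taxonomy_label,
                "genome_size_bp": b.genome_size,
                # 4 decimal places of a percentage: write(read(x)) is the
                # identity for any value that originated as pct/100
                "completeness_pct": f"{b.completeness * 100.0:.4f}",
                "contamination_pct": f"{b.contamination * 100.0:.4f}",
                "gene_ids": ",".join(sorted(b.genes)),
                "transporter_compounds": ",".join(
                    sorted(c for c, present in b.transporters.items() if present)
                ),
            }
        )
    pd.DataFrame(rows, columns=_BIN_COLUMNS).to_csv(
        dir_path / BINS_FILE, sep="\t", index=False
    )

    gene_rows = [
        {"gene_id": g.gene_id, "bin_id": g.bin_id, "length_bp": g.length}
        for g in sorted(community.genes, key=lambda g: (g.bin_id, g.gene_id))
    ]
    pd.DataFrame(gene_rows, columns=_GENE_COLUMNS).to_csv(
        dir_path / GENES_FILE, sep="\t", index=False
    )

    write_pathways(community.pathways, dir_path / PATHWAYS_FILE)
    return dir_path


def write_pathways(pathways: Iterable[PathwayDefinition], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "compound_id": p.compound_id,
            "compound_class": p.compound_class,
            "transporter_relevant": p.transporter_relevant,
            "cost_rank": p.biosynthetic_cost_rank,
            "steps": [sorted(step) for step in p.steps],
        }
        for p in sorted(
            pathways, key=lambda p: (p.biosynthetic_cost_rank, p.compound_id)
        )
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# mapping summaries
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> list[ReadMappingSummary]:
    path = Path(path)
    df = _read_tsv(path, _MAPPING_COLUMNS)
    summaries: dict[tuple[str, str], ReadMappingSummary] = {}
    for idx, row in df.iterrows():
        key = (row["sample_id"], row["library_type"])
        total = _row_int(path, idx, "total_reads", row["total_reads"])
        mapped = _row_int(path, idx, "mapped_reads", row["mapped_reads"])
        if key not in summaries:
            summaries[key] = ReadMappingSummary(
                sample_id=key[0], library_type=key[1], total_reads=total,
                mapped_reads={},
            )
        summary = summaries[key]
        if summary.total_reads != total:
            raise ValidationError(
                f"{path.name} line {idx + 2}: inconsistent total_reads for "
                f"{key[0]}/{key[1]}"
            )
        if row["bin_id"] in summary.mapped_reads:
            raise ValidationError(
                f"{path.name} line {idx + 2}: duplicate bin {row['bin_id']!r} "
                f"for {key[0]}/{key[1]}"
            )
        summary.mapped_reads[row["bin_id"]] = mapped
    out = []
    for summary in summaries.values():
        # re-validate now that all rows are in
        out.append(
            ReadMappingSummary(
                sample_id=summary.sample_id,
                library_type=summary.library_type,
                total_reads=summary.total_reads,
                mapped_reads=dict(sorted(summary.mapped_reads.items())),
            )
        )
    out.sort(key=lambda s: (s.sample_id, s.library_type))
    return out


def write_mapping(summaries: Iterable[ReadMappingSummary], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in sorted(summaries, key=lambda s: (s.sample_id, s.library_type)):
        for bin_id in sorted(s.mapped_reads):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "library_type": s.library_type,
                    "total_reads": s.total_reads,
                    "bin_id": bin_id,
                    "mapped_reads": s.mapped_reads[bin_id],
                }
            )
    pd.DataFrame(rows, columns=_MAPPING_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# fragment counts and FPKM tables
# ---------------------------------------------------------------------------

def read_fragments(
    expression_path: str | Path, totals_path: str | Path
) -> dict[str, tuple[dict[tuple[str, str], float], int]]:
    """Return ``{sample_id: (fragments by (bin, gene), total)}``."""
    expression_path = Path(expression_path)
    totals_path = Path(totals_path)
    df = _read_tsv(expression_path, _EXPRESSION_COLUMNS)
    totals_df = _read_tsv(totals_path, _TOTALS_COLUMNS)
    totals = {
        row["sample_id"]: _row_int(totals_path, idx, "total_mapped_fragments",
                                   row["total_mapped_fragments"])
        for idx, row in totals_df.iterrows()
    }
    out: dict[str, tuple[dict[tuple[str, str], float], int]] = {}
    for idx, row in df.iterrows():
        sample = row["sample_id"]
        if sample not in totals:
            raise ValidationError(
                f"{expression_path.name} line {idx + 2}: sample {sample!r} has "
                f"no entry in {totals_path.name}"
            )
        frags = _row_float(expression_path, idx, "fragments", row["fragments"])
        if frags < 0:
            raise ValidationError(
                f"{expression_path.name} line {idx + 2}: negative fragment count"
            )
        out.setdefault(sample, ({}, totals[sample]))[0][
            (row["bin_id"], row["gene_id"])
        ] = frags
    for sample, total in totals.items():
        out.setdefault(sample, ({}, total))
    return out


def write_fragments(
    fragments: dict[str, tuple[dict[tuple[str, str], float], int]],
    expression_path: str | Path,
    totals_path: str | Path,
) -> None:
    rows = []
    totals_rows = []
    for sample in sorted(fragments):
        counts, total = fragments[sample]
        totals_rows.append({"sample_id": sample, "total_mapped_fragments": total})
        for (bin_id, gene_id) in sorted(counts):
            value = counts[(bin_id, gene_id)]
            rows.append(
                {
                    "sample_id": sample,
                    "bin_id": bin_id,
                    "gene_id": gene_id,
                    "fragments": f"{value:.10g}",
                }
            )
    pd.DataFrame(rows, columns=_EXPRESSION_COLUMNS).to_csv(
        Path(expression_path), sep="\t", index=False
    )
    pd.DataFrame(totals_rows, columns=_TOTALS_COLUMNS).to_csv(
        Path(totals_path), sep="\t", index=False
    )


def write_expression_table(table: ExpressionTable, path: str | Path,
                           flags: Optional[dict[tuple[str, str], bool]] = None) -> Path:
    """Write per-gene FPKM (and optional highly-transcribed flags) as TSV."""
    path = Path(path)
    rows = []
    for (bin_id, gene_id) in sorted(table.fpkm):
        row = {
            "sample_id": table.sample_id,
            "bin_id": bin_id,
            "gene_id": gene_id,
            "fpkm": f"{table.fpkm[(bin_id, gene_id)]:.10g}",
        }
        if flags is not None:
            row["highly_transcribed"] = str(flags[(bin_id, gene_id)])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# auxotrophy matrix
# ---------------------------------------------------------------------------

def _encode_cell(call: AuxotrophyCall) -> str:
    if call.transporter_present is None:
        flag = "NA"
    else:
        flag = "T" if call.transporter_present else "F"
    return f"{call.status};{flag}"


def write_auxotrophy_matrix(
    calls: Sequence[AuxotrophyCall],
    path: str | Path,
    pathways: Optional[Sequence[PathwayDefinition]] = None,
) -> Path:
    """Write the compounds x bins status matrix.

    Rows are compounds ordered by biosynthetic cost rank when pathway
    definitions are supplied (alphabetically otherwise), columns are bins
    in lexicographic order; output is byte-identical for identical call
    sets regardless of input order.  Cells are ``status;T|F|NA`` where the
    flag records transporter presence (NA = no transport system required).
    """
    path = Path(path)
    by_key = {(c.compound_id, c.bin_id): c for c in calls}
    if len(by_key) != len(calls):
        raise ValidationError("duplicate (compound, bin) pairs in calls")
    compounds = sorted({c.compound_id for c in calls})
    bins = sorted({c.bin_id for c in calls})
    missing = [
        (comp, b) for comp in compounds for b in bins if (comp, b) not in by_key
    ]
    if missing:
        listing = ", ".join(f"{c}/{b}" for c, b in missing[:10])
        raise ValidationError(
            f"incomplete bins x compounds grid; missing pairs: {listing}"
        )
    if pathways is not None:
        rank = {p.compound_id: p.biosynthetic_cost_rank for p in pathways}
        compounds.sort(key=lambda c: (rank.get(c, 0), c))
    lines = ["compound\t" + "\t".join(bins)]
    for comp in compounds:
        cells = [_encode_cell(by_key[(comp, b)]) for b in bins]
        lines.append(comp + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_auxotrophy_matrix(path: str | Path) -> list[AuxotrophyCall]:
    """Read a status matrix back into calls.

    The matrix stores only status and transporter flag, so the returned
    calls carry a minimal consistent ``n_missing_steps`` (0 for
    prototroph, 1 for indeterminate, 2 for auxotroph) and no expression
    score.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path.name}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path.name}: empty matrix")
    header = lines[0].split("\t")
    if header[0] != "compound":
        raise ValidationError(f"{path.name}: bad header")
    bins = header[1:]
    n_missing = {PROTOTROPH: 0, INDETERMINATE: 1, AUXOTROPH: 2}
    calls = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(bins) + 1:
            raise ValidationError(f"{path.name} line {lineno}: wrong column count")
        compound = parts[0]
        for bin_id, cell in zip(bins, parts[1:]):
            try:
                status, flag = cell.split(";")
            except ValueError:
                raise ValidationError(
                    f"{path.name} line {lineno}: malformed cell {cell!r}"
                ) from None
            transporter = {"T": True, "F": False, "NA": None}.get(flag, "bad")
            if transporter == "bad" or status not in n_missing:
                raise ValidationError(
                    f"{path.name} line {lineno}: malformed cell {cell!r}"
                )
            calls.append(
                AuxotrophyCall(
                    bin_id=bin_id,
                    compound_id=compound,
                    status=status,
                    n_missing_steps=n_missing[status],
                    transporter_present=transporter,
                )
            )
    return calls
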