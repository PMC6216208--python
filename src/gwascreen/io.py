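"""TSV readers and writers for all pipeline inputs and outputs.

One dialect throughout: tab-separated values, ``#``-prefixed comment and
metadata lines, UTF-8.  Readers validate row by row and report the file,
row number and column of the first problem; writers emit deterministic
column order and print precision (p-values in scientific notation with 3
significant digits, fractions to 4 decimals), so identical inputs always
produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence, Union

from .assoc import AssocResult, GenotypeCounts
from .screen import (
    DrugTargetRecord,
    DrugTargetTable,
    GeneSet,
    PPINetwork,
    ScreenReport,
)

__all__ = [
    "read_genotype_counts",
    "write_genotype_counts",
    "read_gene_list",
    "write_gene_list",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_drug_targets",
    "write_drug_targets",
    "write_assoc_tsv",
    "write_screen_tsv",
    "write_plotdata_tsv",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

GENOTYPE_COLUMNS = [
    "snp_id", "chrom", "pos", "minor_allele", "major_allele",
    "case_hom_minor", "case_het", "case_hom_major",
    "control_hom_minor", "control_het", "control_hom_major",
    "case_missing", "control_missing",
]

ASSOC_COLUMNS = [
    "snp_id", "maf_case", "maf_control",
    "trend_stat", "p_trend", "genotypic_stat", "genotypic_df", "p_genotypic",
    "p_hwe_case", "p_hwe_control",
    "or_allelic", "ci_low", "ci_high",
    "call_rate_case", "call_rate_control",
]


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"  # 3 significant digits


def _fmt_frac(x: float) -> str:
    return f"{x:.4f}"


def _data_lines(path: PathLike) -> list[tuple[int, list[str]]]:
    """Non-comment, non-blank lines of a TSV file with 1-based line numbers."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    return out


def _parse_int(cell: str, path: PathLike, lineno: int, column: str, minimum: int = 0) -> int:
    try:
        v = int(cell)
    except ValueError:
        raise ValueError(
            f"{path}: line {lineno}, column {column!r}: expected an integer, got {cell!r}"
        ) from None
    if v < minimum:
        raise ValueError(
            f"{path}: line {lineno}, column {column!r}: value {v} below minimum {minimum}"
        )
    return v


def read_genotype_counts(path: PathLike) -> list[GenotypeCounts]:
    """Read a genotype-count table (one SNP per row).

    Columns: ``snp_id chrom pos minor_allele major_allele case_hom_minor
    case_het case_hom_major control_hom_minor control_het control_hom_major
    [case_missing control_missing]``.  A header row repeating the column
    names is accepted and skipped.
    """
    rows = _data_lines(path)
    if rows and rows[0][1][0] == "snp_id":
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no genotype-count rows found")
    out: list[GenotypeCounts] = []
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) not in (11, 13):
            raise ValueError(
                f"{path}: line {lineno}: expected 11 or 13 tab-separated columns, "
                f"got {len(cells)}"
            )
        snp_id = cells[0].strip()
        if not snp_id:
            raise ValueError(f"{path}: line {lineno}: empty snp_id")
        if snp_id in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        pos = _parse_int(cells[2], path, lineno, "pos", minimum=1)
        ints = [
            _parse_int(cells[5 + k], path, lineno, GENOTYPE_COLUMNS[5 + k]) for k in range(6)
        ]
        missing = (0, 0)
        if len(cells) == 13:
            missing = (
                _parse_int(cells[11], path, lineno, "case_missing"),
                _parse_int(cells[12], path, lineno, "control_missing"),
            )
        try:
            gc = GenotypeCounts(
                snp_id=snp_id,
                chrom=cells[1].strip(),
                pos=pos,
                minor_allele=cells[3].strip(),
                major_allele=cells[4].strip(),
                case_counts=tuple(ints[:3]),
                control_counts=tuple(ints[3:]),
                case_missing=missing[0],
                control_missing=missing[1],
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        out.append(gc)
    return out


def write_genotype_counts(rows: Sequence[GenotypeCounts], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(GENOTYPE_COLUMNS) + "\n")
        for gc in rows:
            cells = [
                gc.snp_id, gc.chrom, str(gc.pos), gc.minor_allele, gc.major_allele,
                *(str(c) for c in gc.case_counts),
                *(str(c) for c in gc.control_counts),
                str(gc.case_missing), str(gc.control_missing),
            ]
            fh.write("\t".join(cells) + "\n")


def read_gene_list(path: PathLike, name: str | None = None) -> GeneSet:
    """Read a gene list: one symbol per line, '#' comments allowed."""
    symbols = []
    for lineno, cells in _data_lines(path):
        sym = cells[0].strip()
        if not sym:
            raise ValueError(f"{path}: line {lineno}: empty gene symbol")
        symbols.append(sym)
    if not symbols:
        raise ValueError(f"{path}: no gene symbols found")
    return GeneSet.from_symbols(name or Path(path).stem, symbols)


def write_gene_list(genes: GeneSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_ppi_edges(path: PathLike) -> PPINetwork:
    """Read an undirected PPI edge list: two symbol columns, extras ignored.

    Reversed duplicates and self-loops are normalized away; their counts are
    logged.
    """
    net = PPINetwork()
    n_rows = 0
    for lineno, cells in _data_lines(path):
        if len(cells) < 2:
            raise ValueError(
                f"{path}: line {lineno}: expected at least 2 tab-separated columns, "
                f"got {len(cells)}"
            )
        a, b = cells[0].strip(), cells[1].strip()
        if not a or not b:
            raise ValueError(f"{path}: line {lineno}: empty gene symbol in edge")
        net.add_edge(a, b)
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no edges found")
    if net.n_self_loops_dropped or net.n_duplicates_dropped:
        logger.info(
            "%s: normalized away %d self-loop(s) and %d duplicate edge(s)",
            path, net.n_self_loops_dropped, net.n_duplicates_dropped,
        )
    return net


def write_ppi_edges(net: PPINetwork, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path: PathLike) -> DrugTargetTable:
    """Read a drug-target table: drug_id, drug_name, target_gene,
    approval_status, optional family_id (empty allowed)."""
    rows = _data_lines(path)
    if rows and rows[0][1][0] == "drug_id":
        rows = rows[1:]
    table = DrugTargetTable()
    n_rows = 0
    for lineno, cells in rows:
        if len(cells) not in (4, 5):
            raise ValueError(
                f"{path}: line {lineno}: expected 4 or 5 tab-separated columns, "
                f"got {len(cells)}"
            )
        family = cells[4].strip() if len(cells) == 5 and cells[4].strip() else None
        try:
            table.add(
                DrugTargetRecord(
                    drug_id=cells[0].strip(),
                    drug_name=cells[1].strip(),
                    target_gene=cells[2].strip(),
                    approval_status=cells[3].strip(),
                    family_id=family,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no drug-target rows found")
    if table.n_duplicates_dropped:
        logger.info("%s: dropped %d duplicate (drug, target) pair(s)",
                    path, table.n_duplicates_dropped)
    return table


def write_drug_targets(table: DrugTargetTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdrug_name\ttarget_gene\tapproval_status\tfamily_id\n")
        for r in table:
            fh.write(
                f"{r.drug_id}\t{r.drug_name}\t{r.target_gene}\t"
                f"{r.approval_status}\t{r.family_id or ''}\n"
            )


def write_assoc_tsv(results: Sequence[AssocResult], path: PathLike) -> None:
    """Write the association table: locus-report-shaped columns plus the
    trend statistic, OR and CI bounds.

    P-values print in scientific notation (3 significant digits, lower-case
    'e'); MAFs and call rates to 4 decimals.
    """
    if not results:
        raise ValueError("no association results to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSOC_COLUMNS) + "\n")
        for r in results:
            cells = [
                r.snp_id,
                _fmt_frac(r.maf_case), _fmt_frac(r.maf_control),
                f"{r.trend_stat:.4f}", _fmt_p(r.p_trend),
                f"{r.genotypic_stat:.4f}", str(r.genotypic_df), _fmt_p(r.p_genotypic),
                _fmt_frac(r.p_hwe_case), _fmt_frac(r.p_hwe_control),
                f"{r.or_allelic:.4f}", f"{r.ci_low:.4f}", f"{r.ci_high:.4f}",
                _fmt_frac(r.call_rate_case), _fmt_frac(r.call_rate_control),
            ]
            fh.write("\t".join(cells) + "\n")


def write_screen_tsv(report: ScreenReport, path: PathLike) -> None:
    """Write a screen report: '#'-prefixed count header, then candidate rows."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in report.counts().items():
            fh.write(f"# {key}\t{value}\n")
        if report.missing_seeds:
            fh.write(f"# missing_seeds\t{','.join(report.missing_seeds)}\n")
        fh.write("drug_id\tdrug_name\tfamily_id\thit_genes\tprovenance\n")
        for c in report.candidates:
            fh.write(
                f"{c.drug_id}\t{c.drug_name}\t{c.family_id}\t"
                f"{','.join(c.hit_genes)}\t{','.join(c.provenance)}\n"
            )


def write_plotdata_tsv(
    rows: Sequence[GenotypeCounts],
    results: Sequence[AssocResult],
    path: PathLike,
    r2_to_index: dict[str, float] | None = None,
) -> None:
    """Write regional-plot data: snp_id, pos, -log10 trend p, r^2 to the
    index SNP; rows sorted by position.  No graphics are produced."""
    import math

    if not results:
        raise ValueError("no results to write")
    by_id = {r.snp_id: r for r in results}
    ordered = sorted(rows, key=lambda gc: gc.pos)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tpos\tminus_log10_p_trend\tr2_to_index\n")
        for gc in ordered:
            res = by_id.get(gc.snp_id)
            if res is None:
                continue
            mlp = -math.log10(res.p_trend) if res.p_trend > 0 else float("inf")
            r2 = (r2_to_index or {}).get(gc.snp_id)
            r2_cell = f"{r2:.4f}" if r2 is not None else "NA"
            fh.write(f"{gc.snp_id}\t{gc.pos}\t{mlp:.4f}\t{r2_cell}\n")
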