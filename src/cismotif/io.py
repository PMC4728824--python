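"""Tab-delimited result export, BED export, config files, provenance.

Every output file starts with comment lines recording the tool version, the
full configuration, and a checksum of each input file, so a result can
always be traced to what produced it; re-running with identical inputs and
settings yields byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .expression import ExpressionResult
from .genome import GeneModel
from .network import InteractionStore
from .pipeline import ScanResult
from .scoring import significance_stars

__all__ = [
    "sha256_of",
    "provenance_lines",
    "write_hits_tsv",
    "write_hits_bed",
    "write_expression_tsv",
    "parse_key_value_file",
]

HIT_COLUMNS = (
    "AGI Code", "Name", "Description", "Sequence", "Length", "Region",
    "Direction", "Position", "Motif Score", "p-Value", "Significance",
    "EC Number", "Interaction", "Annotation",
)

EXPR_COLUMNS = (
    "AGI Code", "Name", "Description", "Number of Sites", "Fold Change",
    "Regions", "Binding Score", "Significance", "Target Class", "Note",
)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_lines(
    config: Mapping[str, str], inputs: Mapping[str, str | Path]
) -> list[str]:
    lines = [f"# cismotif_version={__version__}"]
    for key in sorted(config):
        lines.append(f"# config {key}={config[key]}")
    for name in sorted(inputs):
        lines.append(f"# input {name}={Path(inputs[name]).name} sha256={sha256_of(inputs[name])}")
    return lines


def parse_key_value_file(path: str | Path) -> dict[str, str]:
    """Read a plain ``key = value`` config file (# comments allowed)."""
    out: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def _fmt_score(x: float) -> str:
    return f"{x:.4f}"


def _interaction_summary(store: InteractionStore | None, gene_id: str) -> str:
    if store is None or gene_id not in store.graph:
        return ""
    return ";".join(sorted(store.graph.neighbors(gene_id)))


def write_hits_tsv(
    result: ScanResult,
    genes: Sequence[GeneModel],
    path: str | Path,
    interactions: InteractionStore | None = None,
    provenance: Iterable[str] = (),
) -> None:
    """The scan results table: one row per (transcript, hit), positions as
    signed start-codon-relative integers, plus per-locus score columns."""
    lookup = {g.gene_id: g for g in genes}
    lines = list(provenance)
    lines.append("\t".join(HIT_COLUMNS))
    ordered = sorted(
        result.hits,
        key=lambda h: (h.gene_id, h.transcript_id, h.unit_offset, h.strand),
    )
    for h in ordered:
        gene = lookup[h.gene_id]
        report = result.reports.get(h.gene_id)
        lines.append(
            "\t".join(
                (
                    h.gene_id,
                    gene.name,
                    gene.description,
                    h.matched_sequence,
                    str(h.length),
                    "|".join(h.region_labels),
                    h.strand,
                    str(h.atg_position),
                    _fmt_score(report.motif_score) if report else "",
                    _fmt_p(report.p_value) if report else "",
                    report.significance if report else "",
                    ",".join(gene.ec_numbers),
                    _interaction_summary(interactions, h.gene_id),
                    gene.annotation,
                )
            )
        )
    lines.append(f"# total_motifs={result.total_hits}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hits_bed(
    result: ScanResult,
    genes: Sequence[GeneModel],
    path: str | Path,
) -> None:
    """BED6 export (0-based half-open, genome-strand orientation); the score
    column is the locus Motif Score scaled ×100 and clamped to [0, 1000]."""
    lookup = {g.gene_id: g for g in genes}
    rows = []
    for h in sorted(
        result.hits, key=lambda h: (h.genomic_interval, h.gene_id, h.strand)
    ):
        chrom, start, end = h.genomic_interval
        gene = lookup[h.gene_id]
        genome_strand = "+" if (gene.strand == "+") == (h.strand == "forward") else "-"
        report = result.reports.get(h.gene_id)
        score = 0
        if report is not None:
            score = max(0, min(1000, int(round(report.motif_score * 100))))
        rows.append(
            f"{chrom}\t{start - 1}\t{end}\t{h.gene_id}\t{score}\t{genome_strand}"
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def write_expression_tsv(
    expr_result: ExpressionResult,
    result: ScanResult,
    genes: Sequence[GeneModel],
    path: str | Path,
    provenance: Iterable[str] = (),
) -> None:
    """Per-gene expression-integration report: primary targets first, sorted
    by Binding Score; the dataset chi-squared goes in the header lines."""
    lookup = {g.gene_id: g for g in genes}
    chi2 = expr_result.chi2
    lines = list(provenance)
    lines.append(f"# specific_word={expr_result.specific_word}")
    if chi2.valid:
        lines.append(
            f"# chi2_stat={chi2.statistic:.4f} chi2_p={_fmt_p(chi2.p_value)} df=1"
        )
    else:
        lines.append(f"# chi2=not_computed reason={chi2.reason}")
    lines.append(
        f"# B_FC={expr_result.counts.b_fc} B_Tot={expr_result.counts.b_tot}"
    )
    lines.append("\t".join(EXPR_COLUMNS))
    class_order = {"primary": 0, "secondary": 1, "unchanged": 2}
    ordered = sorted(
        expr_result.reports,
        key=lambda r: (class_order[r.target_class], -r.binding_score, r.gene_id),
    )
    for r in ordered:
        gene = lookup.get(r.gene_id)
        report = result.reports.get(r.gene_id)
        lines.append(
            "\t".join(
                (
                    r.gene_id,
                    gene.name if gene else "",
                    gene.description if gene else "",
                    str(r.n_sites),
                    "" if r.fold_change is None else f"{r.fold_change:.4f}",
                    "|".join(r.regions),
                    _fmt_score(r.binding_score),
                    report.significance if report else "na",
                    r.target_class,
                    r.note,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
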