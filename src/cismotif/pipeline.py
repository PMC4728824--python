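"""End-to-end scan orchestration: gene models → scan units → hits → scores.

This is the library face of the whole-genome motif search: one call builds
a scan unit per transcript (all splice forms are scanned and reported),
runs the pattern over it, applies the Contain/Devoid filter, and assembles
a per-locus score report (observed vs expected counts, Motif Score,
binomial p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .genome import (
    ALL_REGION_KINDS,
    GeneModel,
    GenomeIndex,
    RegionKind,
    ScanUnit,
    build_scan_unit,
    flanking_cds_bounds,
)
from .motif import (
    PWM,
    FilterSpec,
    MotifError,
    MotifHit,
    MotifPattern,
    apply_filters,
    compile_iupac,
    dedupe_palindromic,
    pwm_to_pattern,
    scan_unit,
)
from .scoring import BackgroundModel, DEFAULT_BACKGROUND, ScoreReport, score_locus

__all__ = ["ScanConfig", "ScanResult", "scan_genes", "MIN_MOTIF_LENGTH_SUGGESTED"]

logger = logging.getLogger("cismotif")

#: Shorter motifs produce unwieldy hit lists; a warning is logged below this.
MIN_MOTIF_LENGTH_SUGGESTED = 7


@dataclass
class ScanConfig:
    """Everything that defines one scan run."""

    motif: str | None = None
    pwm: PWM | None = None
    min_prob: float = 0.05
    strand_mode: str = "forward"
    selected_kinds: frozenset[RegionKind] = ALL_REGION_KINDS
    intergenic5_len: int | None = None
    intergenic3_len: int | None = None
    background: BackgroundModel = DEFAULT_BACKGROUND
    filters: FilterSpec | None = None
    measure_from: str = "transcript"
    dedupe_palindromes: bool = False
    min_motif_length_warning: int = MIN_MOTIF_LENGTH_SUGGESTED

    def __post_init__(self) -> None:
        if self.motif is None and self.pwm is None:
            raise MotifError("a scan needs a motif string or a PWM")
        self.selected_kinds = frozenset(
            RegionKind(k) for k in self.selected_kinds
        )

    def pattern(self) -> MotifPattern:
        if self.pwm is not None:
            return pwm_to_pattern(self.pwm, self.min_prob, self.strand_mode)
        pat = compile_iupac(self.motif, self.strand_mode)
        return pat

    def as_dict(self) -> dict[str, str]:
        """Flat, deterministic key=value view for provenance headers."""
        return {
            "motif": self.motif or f"PWM:{self.pwm.consensus}",
            "min_prob": str(self.min_prob),
            "strand_mode": self.strand_mode,
            "regions": ",".join(
                sorted(k.value for k in self.selected_kinds)
            ),
            "intergenic5_len": str(self.intergenic5_len),
            "intergenic3_len": str(self.intergenic3_len),
            "background": ",".join(
                f"{b}={self.background.freqs[b]}" for b in "ACGT"
            ),
            "contain": str(self.filters.contain if self.filters else None),
            "devoid": str(self.filters.devoid if self.filters else None),
            "filter_mode": str(self.filters.mode if self.filters else None),
            "measure_from": self.measure_from,
            "dedupe_palindromes": str(self.dedupe_palindromes),
        }


@dataclass
class ScanResult:
    """Hits for every (gene, transcript), per-locus score reports, and the
    units they were measured on."""

    hits: list[MotifHit]
    reports: dict[str, ScoreReport]
    units: dict[tuple[str, str], ScanUnit]
    pattern: MotifPattern
    config: ScanConfig

    @property
    def total_hits(self) -> int:
        return len(self.hits)

    def hits_of_gene(self, gene_id: str) -> list[MotifHit]:
        return [h for h in self.hits if h.gene_id == gene_id]


def scan_genes(
    genome: GenomeIndex,
    genes: Sequence[GeneModel],
    config: ScanConfig,
) -> ScanResult:
    """Scan every transcript of every gene and score each locus.

    The per-locus binomial model uses the locus's own scan unit (the longest
    one across isoforms) as the sequence whose R_L defines the number of
    possible positions T, and counts one success per distinct genomic
    position (strand and isoform duplicates collapse).
    """
    pattern = config.pattern()
    if pattern.length < config.min_motif_length_warning:
        logger.warning(
            "motif length %d is below the suggested minimum of %d bp; "
            "expect a large, noisy hit list",
            pattern.length,
            config.min_motif_length_warning,
        )
    bounds = flanking_cds_bounds(genes)
    all_hits: list[MotifHit] = []
    units: dict[tuple[str, str], ScanUnit] = {}
    for gene in genes:
        for t in gene.transcripts:
            unit = build_scan_unit(
                gene,
                t.transcript_id,
                genome,
                selected_kinds=config.selected_kinds,
                intergenic5_len=config.intergenic5_len,
                intergenic3_len=config.intergenic3_len,
                neighbors=bounds[gene.gene_id],
                measure_from=config.measure_from,
            )
            units[(gene.gene_id, t.transcript_id)] = unit
            hits = scan_unit(unit, pattern, pwm=config.pwm)
            if config.dedupe_palindromes:
                hits = dedupe_palindromic(hits)
            all_hits.extend(hits)

    gene_lookup = {g.gene_id: g for g in genes}
    all_hits = apply_filters(all_hits, config.filters, gene_lookup)

    reports: dict[str, ScoreReport] = {}
    for gene in genes:
        gene_hits = [h for h in all_hits if h.gene_id == gene.gene_id]
        if not gene_hits:
            continue
        rep_unit = max(
            (units[(gene.gene_id, t.transcript_id)] for t in gene.transcripts),
            key=lambda u: (u.length, u.transcript_id),
        )
        report = score_locus(rep_unit, gene_hits, pattern, config.background)
        if report is not None:
            reports[gene.gene_id] = report
    return ScanResult(
        hits=all_hits, reports=reports, units=units, pattern=pattern, config=config
    )
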