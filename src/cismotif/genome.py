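"""Genome sequences, gene models and scan units.

A locus is partitioned into six selectable region classes — 5' intergenic,
5' UTR, coding exon, intron, 3' UTR, 3' intergenic — per transcript isoform.
The regions a user selects are concatenated (5'→3' on the gene strand,
without separators, so a motif may span a region boundary) into a
:class:`ScanUnit`, which carries the coordinate maps needed to report every
hit both in genomic coordinates and as a signed position relative to the A
of the start codon (ATG = +1; the base immediately upstream = −1; there is
no position 0).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

__all__ = [
    "RegionKind",
    "Region",
    "TranscriptModel",
    "GeneModel",
    "GenomeIndex",
    "Segment",
    "ScanUnit",
    "GenomeError",
    "AnnotationError",
    "reverse_complement",
    "load_genome",
    "load_gene_models",
    "flanking_cds_bounds",
    "build_scan_unit",
    "atg_relative_position",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"[^ACGTN]")


class GenomeError(ValueError):
    """Malformed genome sequence input."""


class AnnotationError(ValueError):
    """Malformed or inconsistent gene-model annotation."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionKind(str, enum.Enum):
    """The six selectable gene-region classes."""

    INTERGENIC5 = "intergenic5"
    UTR5 = "utr5"
    CDS = "exon_cds"
    INTRON = "intron"
    UTR3 = "utr3"
    INTERGENIC3 = "intergenic3"


ALL_REGION_KINDS: frozenset[RegionKind] = frozenset(RegionKind)


@dataclass(frozen=True)
class Region:
    """A contiguous genomic interval of one region class.

    Coordinates are 1-based closed intervals in the GFF3 frame.
    """

    kind: RegionKind
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One splice form: its regions in 5'→3' gene-strand order.

    ``atg_genomic`` is the genomic coordinate of the A of the start codon
    (the 5'-most CDS base on the gene strand).
    """

    transcript_id: str
    regions: list[Region]
    atg_genomic: int

    @property
    def span(self) -> tuple[int, int]:
        return (min(r.start for r in self.regions), max(r.end for r in self.regions))

    @property
    def cds_span(self) -> tuple[int, int]:
        cds = [r for r in self.regions if r.kind is RegionKind.CDS]
        return (min(r.start for r in cds), max(r.end for r in cds))


@dataclass
class GeneModel:
    """A locus: one or more transcript isoforms on one chromosome strand."""

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel]
    name: str = ""
    description: str = ""
    annotation: str = ""
    ec_numbers: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def cds_span(self) -> tuple[int, int]:
        return (
            min(t.cds_span[0] for t in self.transcripts),
            max(t.cds_span[1] for t in self.transcripts),
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"gene {self.gene_id} has no transcript {transcript_id!r}")


@dataclass
class GenomeIndex:
    """Chromosome id → uppercase sequence over the {A,C,G,T,N} alphabet."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            bad = _VALID_SEQ.search(seq)
            if bad is not None:
                raise GenomeError(
                    f"record {name!r}: invalid character {bad.group()!r} "
                    f"at position {bad.start() + 1}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Sequence of a 1-based closed interval on the forward strand."""
        return self.chromosomes[chromosome][start - 1 : end]


def load_genome(fasta_path: str | Path) -> GenomeIndex:
    """Read a (multi-record) FASTA into a :class:`GenomeIndex`.

    Soft-masked lowercase input is uppercased; characters outside
    {A,C,G,T,N} raise :class:`GenomeError` naming the record and position.
    """
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in records:
                raise GenomeError(f"duplicate FASTA record id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    except GenomeError:
        raise
    except Exception as exc:  # Biopython parse failure
        raise GenomeError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    if not records:
        raise GenomeError(f"no FASTA records found in {fasta_path}")
    return GenomeIndex(records)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _attr(feature, key: str) -> str:
    vals = feature.attributes.get(key, [])
    return vals[0] if vals else ""


def _partition_exons(
    exons: list[tuple[int, int]], cds_lo: int, cds_hi: int, strand: str
) -> list[Region]:
    """Split ascending exon intervals into UTR5/CDS/UTR3 around the CDS span
    and insert introns in the gaps; returned in 5'→3' gene-strand order."""
    regions: list[Region] = []
    prev_end: int | None = None
    for s, e in exons:
        if prev_end is not None:
            if s <= prev_end:
                raise AnnotationError(f"overlapping exons near position {s}")
            if s > prev_end + 1:
                regions.append(Region(RegionKind.INTRON, prev_end + 1, s - 1))
        if s < cds_lo:
            kind = RegionKind.UTR5 if strand == "+" else RegionKind.UTR3
            regions.append(Region(kind, s, min(e, cds_lo - 1)))
        mid_lo, mid_hi = max(s, cds_lo), min(e, cds_hi)
        if mid_lo <= mid_hi:
            regions.append(Region(RegionKind.CDS, mid_lo, mid_hi))
        if e > cds_hi:
            kind = RegionKind.UTR3 if strand == "+" else RegionKind.UTR5
            regions.append(Region(kind, max(s, cds_hi + 1), e))
        prev_end = e
    if strand == "-":
        regions.reverse()
    return regions


def load_gene_models(
    gff3_path: str | Path, genome: GenomeIndex | None = None
) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects.

    Introns are always derived as the gaps between consecutive exons of a
    transcript, and UTRs from the exon-vs-CDS partition, so that the region
    model is identical across GFF3 dialects. Explicit UTR / intron features
    are tolerated but ignored. Transcripts must carry at least one CDS
    feature (the ATG-relative coordinate frame needs a start codon).
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    lengths = genome.lengths if genome is not None else {}

    for t in db.features_of_type(_TRANSCRIPT_TYPES):
        parent = _attr(t, "Parent")
        if parent not in gene_ids:
            raise AnnotationError(
                f"transcript {t.id!r} references unknown gene Parent {parent!r}"
            )

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if lengths:
            if g.seqid not in lengths:
                raise AnnotationError(
                    f"gene {g.id!r} on unknown chromosome {g.seqid!r}"
                )
            if g.end > lengths[g.seqid]:
                raise AnnotationError(
                    f"gene {g.id!r} extends to {g.end}, beyond chromosome "
                    f"{g.seqid!r} length {lengths[g.seqid]}"
                )
        transcripts: list[TranscriptModel] = []
        for t in db.children(g, featuretype=_TRANSCRIPT_TYPES, order_by="start"):
            exons = [
                (f.start, f.end)
                for f in db.children(t, featuretype="exon", order_by="start")
            ]
            cds = [
                (f.start, f.end)
                for f in db.children(t, featuretype="CDS", order_by="start")
            ]
            if not cds:
                raise AnnotationError(
                    f"transcript {t.id!r} has no CDS feature; cannot anchor "
                    "ATG-relative coordinates"
                )
            if not exons:
                # CDS/UTR-only dialect: synthesize exons by merging adjacent
                # CDS and UTR features.
                parts = sorted(
                    cds
                    + [
                        (f.start, f.end)
                        for f in db.children(
                            t,
                            featuretype=("five_prime_UTR", "three_prime_UTR"),
                            order_by="start",
                        )
                    ]
                )
                exons = []
                for s, e in parts:
                    if exons and s <= exons[-1][1] + 1:
                        exons[-1] = (exons[-1][0], max(exons[-1][1], e))
                    else:
                        exons.append((s, e))
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            regions = _partition_exons(exons, cds_lo, cds_hi, g.strand)
            atg = cds_lo if g.strand == "+" else cds_hi
            transcripts.append(TranscriptModel(t.id, regions, atg))
        if not transcripts:
            raise AnnotationError(f"gene {g.id!r} has no transcript children")
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                strand=g.strand,
                transcripts=transcripts,
                name=_attr(g, "Name"),
                description=_attr(g, "description") or _attr(g, "Note"),
                annotation=_attr(g, "annotation"),
                ec_numbers=[x for x in g.attributes.get("ec_number", []) if x],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Scan units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One region's slice of a scan unit: genomic interval + unit offset."""

    kind: RegionKind
    start: int
    end: int
    unit_offset: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScanUnit:
    """Concatenation of a transcript's selected regions, 5'→3' on the gene
    strand, with the maps from unit offsets back to genomic coordinates."""

    gene_id: str
    transcript_id: str
    chromosome: str
    gene_strand: str
    sequence: str
    segments: list[Segment]
    atg_genomic: int

    @property
    def length(self) -> int:
        """Total selected-region length R_L in bp."""
        return len(self.sequence)

    def _segment_at(self, unit_offset: int) -> Segment:
        if not 0 <= unit_offset < self.length:
            raise IndexError(
                f"unit offset {unit_offset} outside [0, {self.length})"
            )
        for seg in self.segments:
            if seg.unit_offset <= unit_offset < seg.unit_offset + seg.length:
                return seg
        raise AssertionError("segment map does not cover the unit")  # pragma: no cover

    def genomic_position(self, unit_offset: int) -> int:
        """Genomic coordinate (1-based) of the base at a unit offset."""
        seg = self._segment_at(unit_offset)
        d = unit_offset - seg.unit_offset
        return seg.start + d if self.gene_strand == "+" else seg.end - d

    def unit_offset_at(self, genomic: int) -> int:
        """Inverse of :meth:`genomic_position` (round-trip partner)."""
        for seg in self.segments:
            if seg.start <= genomic <= seg.end:
                d = genomic - seg.start if self.gene_strand == "+" else seg.end - genomic
                return seg.unit_offset + d
        raise IndexError(f"genomic position {genomic} not covered by unit")

    def region_kinds_at(self, unit_offset: int, length: int = 1) -> list[RegionKind]:
        """Region classes overlapped by a window, in 5'→3' order, deduplicated."""
        kinds: list[RegionKind] = []
        for off in range(unit_offset, unit_offset + length):
            kind = self._segment_at(off).kind
            if not kinds or kinds[-1] is not kind:
                kinds.append(kind)
        # collapse repeats while preserving first-occurrence order
        seen: list[RegionKind] = []
        for k in kinds:
            if k not in seen:
                seen.append(k)
        return seen


def flanking_cds_bounds(
    genes: Sequence[GeneModel],
) -> dict[str, tuple[int | None, int | None]]:
    """For every gene, the genomic coordinates of the nearest flanking
    coding sequence on each side: (highest CDS end of a gene starting to the
    left, lowest CDS start of a gene ending to the right); ``None`` where no
    such gene exists. Intergenic regions are truncated at these bounds."""
    bounds: dict[str, tuple[int | None, int | None]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        for g in chrom_genes:
            span = g.span
            left = [
                o.cds_span[1]
                for o in chrom_genes
                if o.gene_id != g.gene_id and o.cds_span[0] < span[0]
            ]
            right = [
                o.cds_span[0]
                for o in chrom_genes
                if o.gene_id != g.gene_id and o.cds_span[1] > span[1]
            ]
            bounds[g.gene_id] = (max(left) if left else None, min(right) if right else None)
    return bounds


def _clip_gap(
    gap: tuple[int, int], length: int | None, anchored: str
) -> tuple[int, int] | None:
    """Take up to ``length`` bases of a gap interval adjacent to the
    transcript (``anchored`` = which side of the gap touches it)."""
    lo, hi = gap
    if hi < lo:
        return None  # overlapping neighbour: empty intergenic region
    if length is not None and length <= 0:
        return None
    if length is None:
        return (lo, hi)
    if anchored == "right":  # gap lies 5'/left of the transcript
        return (max(lo, hi - length + 1), hi)
    return (lo, min(hi, lo + length - 1))


def build_scan_unit(
    gene: GeneModel,
    transcript_id: str,
    genome: GenomeIndex,
    selected_kinds: Iterable[RegionKind] = ALL_REGION_KINDS,
    intergenic5_len: int | None = None,
    intergenic3_len: int | None = None,
    neighbors: tuple[int | None, int | None] = (None, None),
    measure_from: str = "transcript",
) -> ScanUnit:
    """Assemble the scan unit for one transcript.

    ``intergenic5_len`` / ``intergenic3_len`` bound the intergenic flanks;
    when ``None`` (the blank length box) the full gap between genes is used.
    Either way the flank is truncated at the nearest flanking gene's coding
    sequence (``neighbors``, genomic frame: left bound, right bound — see
    :func:`flanking_cds_bounds`) and clamped at the chromosome ends.
    ``measure_from`` selects whether the flanks extend from the transcript's
    outermost annotated base (default) or from its CDS span.
    """
    selected = set()
    for k in selected_kinds:
        if not isinstance(k, RegionKind):
            try:
                k = RegionKind(k)
            except ValueError:
                raise ValueError(f"unknown region kind {k!r}") from None
        selected.add(k)
    if intergenic5_len is not None and intergenic5_len < 0:
        raise ValueError("intergenic5_len must be >= 0")
    if intergenic3_len is not None and intergenic3_len < 0:
        raise ValueError("intergenic3_len must be >= 0")

    t = gene.transcript(transcript_id)
    span = t.span if measure_from == "transcript" else t.cds_span
    chrom_len = genome.lengths[gene.chromosome]
    left_bound, right_bound = neighbors

    left_gap = ((left_bound + 1) if left_bound is not None else 1, span[0] - 1)
    right_gap = (span[1] + 1, (right_bound - 1) if right_bound is not None else chrom_len)
    # clamp at chromosome ends (requesting beyond the start is not an error)
    left_gap = (max(1, left_gap[0]), left_gap[1])
    right_gap = (right_gap[0], min(chrom_len, right_gap[1]))

    if gene.strand == "+":
        i5 = _clip_gap(left_gap, intergenic5_len, anchored="right")
        i3 = _clip_gap(right_gap, intergenic3_len, anchored="left")
    else:
        i5 = _clip_gap(right_gap, intergenic5_len, anchored="left")
        i3 = _clip_gap(left_gap, intergenic3_len, anchored="right")

    ordered: list[Region] = []
    if i5 is not None:
        ordered.append(Region(RegionKind.INTERGENIC5, *i5))
    ordered.extend(t.regions)
    if i3 is not None:
        ordered.append(Region(RegionKind.INTERGENIC3, *i3))

    segments: list[Segment] = []
    parts: list[str] = []
    offset = 0
    for r in ordered:
        if r.kind not in selected:
            continue
        seq = genome.fetch(gene.chromosome, r.start, r.end)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        segments.append(Segment(r.kind, r.start, r.end, offset))
        parts.append(seq)
        offset += r.length
    return ScanUnit(
        gene_id=gene.gene_id,
        transcript_id=transcript_id,
        chromosome=gene.chromosome,
        gene_strand=gene.strand,
        sequence="".join(parts),
        segments=segments,
        atg_genomic=t.atg_genomic,
    )


def atg_relative_position(unit: ScanUnit, unit_offset: int) -> int:
    """Signed position of a unit base relative to the A of the start codon.

    The A of ATG is +1 and the base immediately 5' of it is −1; there is no
    position 0.
    """
    g = unit.genomic_position(unit_offset)
    d = g - unit.atg_genomic if unit.gene_strand == "+" else unit.atg_genomic - g
    return d + 1 if d >= 0 else d
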