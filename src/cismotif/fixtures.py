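"""Deterministic synthetic genomes with planted motif and expression structure.

The generator emits everything the scanner and the expression analysis
consume — genome FASTA, GFF3 gene models, a fold-change table, an
interaction table — plus a truth table listing every planted site (gene,
region, strand, start-codon-relative position, word) and every
differential-expression label, so recovery can be checked exactly.

Background sequence is sampled i.i.d. from the nucleotide background model;
windows that happen to match the planted pattern (either orientation) are
rejected and resampled, so the truth counts are exact rather than
statistical. Gene structures are parametric and minimal: they are not meant
to reproduce real intron/exon length statistics, only to exercise all six
region classes with known coordinates.

``enrichment_odds`` biases the gene choice for *specific-word* sites toward
differentially expressed genes (odds 1 = no association, the null); sites
of the other words derived from the pattern are placed uniformly, so the
specific-vs-family contrast that the Binding Score and the chi-squared test
measure is the quantity being planted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import (
    GeneModel,
    GenomeIndex,
    Region,
    RegionKind,
    TranscriptModel,
    reverse_complement,
)
from .motif import MotifError, MotifPattern, compile_iupac
from .scoring import DEFAULT_BACKGROUND, BackgroundModel

__all__ = ["FixtureSpec", "PlantedSite", "Fixture", "generate_fixture"]

_BASES = "ACGT"

_DESCRIPTIONS = (
    "protein kinase",
    "receptor-like kinase",
    "MYB transcription factor",
    "ABC transporter family protein",
    "cytochrome P450 monooxygenase",
    "unknown protein",
)
_EC_FOR = {"protein kinase": "2.7.11.1", "cytochrome P450 monooxygenase": "1.14.14.1"}
_BIOCHEM_METHODS = (
    "Yeast Two-Hybrid",
    "Pull-Down",
    "Co-Immunoprecipitation",
    "Affinity Capture-MS",
)

_DEFAULT_REGION_DIST = {
    RegionKind.INTERGENIC5: 0.5,
    RegionKind.UTR5: 0.1,
    RegionKind.CDS: 0.1,
    RegionKind.INTRON: 0.1,
    RegionKind.UTR3: 0.1,
    RegionKind.INTERGENIC3: 0.1,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed fixes every output."""

    seed: int = 0
    n_chromosomes: int = 1
    n_genes: int = 50
    background: BackgroundModel = DEFAULT_BACKGROUND
    motif: str = "GRTACT"
    specific_word: str | None = None
    n_planted_sites: int = 20
    site_region_distribution: dict[RegionKind, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_DIST)
    )
    reverse_site_fraction: float = 0.25
    de_fraction: float = 0.3
    enrichment_odds: float = 1.0
    fc_de_mean: float = 2.5
    fc_de_sd: float = 0.5
    fc_null_sd: float = 0.3
    fct: float = 1.0
    n_interactions: int = 30
    scan_intergenic_len: int = 100
    # gene geometry (bp)
    utr5_range: tuple[int, int] = (20, 60)
    utr3_range: tuple[int, int] = (20, 60)
    exon_range: tuple[int, int] = (90, 180)
    intron_range: tuple[int, int] = (50, 90)
    max_introns: int = 2
    gap_range: tuple[int, int] = (230, 330)

    def __post_init__(self) -> None:
        total = sum(self.site_region_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("site_region_distribution must sum to 1")
        if self.gap_range[0] < 2 * self.scan_intergenic_len + len(self.motif):
            raise ValueError(
                "minimum gene gap must exceed twice the scan intergenic length "
                "plus the motif length, so every intergenic site belongs to "
                "exactly one gene's scan window"
            )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted motif instance."""

    gene_id: str
    transcript_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # forward/reverse relative to the gene strand
    region: RegionKind
    atg_position: int
    word: str


@dataclass
class Fixture:
    """In-memory synthetic dataset plus writers for the standard formats."""

    spec: FixtureSpec
    genome: GenomeIndex
    genes: list[GeneModel]
    expression: dict[str, float]
    de_genes: set[str]
    interactions: list[tuple[str, str, str, str]]
    truth: list[PlantedSite]

    @property
    def specific_word(self) -> str:
        if self.spec.specific_word is not None:
            return self.spec.specific_word
        return compile_iupac(self.spec.motif).words()[0]

    def scan_kwargs(self) -> dict:
        """Scan-unit settings under which the truth table is exact."""
        return {
            "intergenic5_len": self.spec.scan_intergenic_len,
            "intergenic3_len": self.spec.scan_intergenic_len,
        }

    # -- writers ------------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "expression": outdir / "expression.tsv",
            "interactions": outdir / "interactions.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.write_fasta(paths["fasta"])
        self.write_gff3(paths["gff3"])
        self.write_expression(paths["expression"])
        self.write_interactions(paths["interactions"])
        self.write_truth(paths["truth"])
        return paths

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.genome.chromosomes):
                fh.write(f">{name}\n")
                seq = self.genome.chromosomes[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        rows: list[str] = ["##gff-version 3"]
        for g in self.genes:
            t = g.transcripts[0]
            span = g.span
            attrs = f"ID={g.gene_id};Name={g.name};description={g.description}"
            if g.ec_numbers:
                attrs += ";ec_number=" + ",".join(g.ec_numbers)
            rows.append(
                "\t".join(
                    (g.chromosome, "cismotif", "gene", str(span[0]), str(span[1]),
                     ".", g.strand, ".", attrs)
                )
            )
            rows.append(
                "\t".join(
                    (g.chromosome, "cismotif", "mRNA", str(span[0]), str(span[1]),
                     ".", g.strand, ".",
                     f"ID={t.transcript_id};Parent={g.gene_id}")
                )
            )
            feature_of = {
                RegionKind.UTR5: "five_prime_UTR",
                RegionKind.CDS: "CDS",
                RegionKind.UTR3: "three_prime_UTR",
            }
            # exons: merge adjacent non-intron regions in ascending order
            exonic = sorted(
                (r for r in t.regions if r.kind is not RegionKind.INTRON),
                key=lambda r: r.start,
            )
            exons: list[list[int]] = []
            for r in exonic:
                if exons and r.start <= exons[-1][1] + 1:
                    exons[-1][1] = max(exons[-1][1], r.end)
                else:
                    exons.append([r.start, r.end])
            for i, (s, e) in enumerate(exons, start=1):
                rows.append(
                    "\t".join(
                        (g.chromosome, "cismotif", "exon", str(s), str(e), ".",
                         g.strand, ".",
                         f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}")
                    )
                )
            counters = {k: 0 for k in feature_of}
            for r in sorted(t.regions, key=lambda r: r.start):
                ftype = feature_of.get(r.kind)
                if ftype is None:
                    continue
                counters[r.kind] += 1
                phase = "0" if r.kind is RegionKind.CDS else "."
                rows.append(
                    "\t".join(
                        (g.chromosome, "cismotif", ftype, str(r.start), str(r.end),
                         ".", g.strand, phase,
                         f"ID={t.transcript_id}.{ftype}{counters[r.kind]};"
                         f"Parent={t.transcript_id}")
                    )
                )
        Path(path).write_text("\n".join(rows) + "\n")

    def write_expression(self, path: str | Path) -> None:
        lines = ["gene\tfold_change"]
        for gid in sorted(self.expression):
            lines.append(f"{gid}\t{self.expression[gid]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_interactions(self, path: str | Path) -> None:
        lines = ["gene_a\tgene_b\tevidence\tmethod"]
        for a, b, ev, method in self.interactions:
            lines.append(f"{a}\t{b}\t{ev}\t{method}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth(self, path: str | Path) -> None:
        lines = [
            "gene_id\ttranscript_id\tchromosome\tstart\tend\tstrand\tregion"
            "\tatg_position\tword\tde"
        ]
        for s in self.truth:
            lines.append(
                f"{s.gene_id}\t{s.transcript_id}\t{s.chromosome}\t{s.start}"
                f"\t{s.end}\t{s.strand}\t{s.region.value}\t{s.atg_position}"
                f"\t{s.word}\t{int(s.gene_id in self.de_genes)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _sample_bases(rng: np.random.Generator, n: int, bg: BackgroundModel) -> list[str]:
    probs = [bg.freqs[b] for b in _BASES]
    return list(rng.choice(list(_BASES), size=n, p=probs))


def _gene_region_lengths(rng: np.random.Generator, spec: FixtureSpec) -> list[tuple[RegionKind, int]]:
    """Region lengths in 5'→3' gene order: UTR5, CDS/intron alternation, UTR3."""
    u5 = int(rng.integers(*spec.utr5_range, endpoint=True))
    u3 = int(rng.integers(*spec.utr3_range, endpoint=True))
    n_introns = int(rng.integers(0, spec.max_introns, endpoint=True))
    exons = [
        int(rng.integers(*spec.exon_range, endpoint=True))
        for _ in range(n_introns + 1)
    ]
    excess = sum(exons) % 3  # keep the CDS a whole number of codons
    exons[-1] -= excess
    introns = [
        int(rng.integers(*spec.intron_range, endpoint=True)) for _ in range(n_introns)
    ]
    parts: list[tuple[RegionKind, int]] = [(RegionKind.UTR5, u5)]
    for i, e in enumerate(exons):
        parts.append((RegionKind.CDS, e))
        if i < n_introns:
            parts.append((RegionKind.INTRON, introns[i]))
    parts.append((RegionKind.UTR3, u3))
    return parts


def _planting_intervals(
    gene: GeneModel, kind: RegionKind, flank: int
) -> list[tuple[int, int]]:
    """Genomic intervals of one region class available for planting."""
    t = gene.transcripts[0]
    if kind is RegionKind.INTERGENIC5:
        span = t.span
        if gene.strand == "+":
            return [(span[0] - flank, span[0] - 1)]
        return [(span[1] + 1, span[1] + flank)]
    if kind is RegionKind.INTERGENIC3:
        span = t.span
        if gene.strand == "+":
            return [(span[1] + 1, span[1] + flank)]
        return [(span[0] - flank, span[0] - 1)]
    return [(r.start, r.end) for r in t.regions if r.kind is kind]


def _atg_relative(gene: GeneModel, g_start: int, g_end: int) -> int:
    atg = gene.transcripts[0].atg_genomic
    g_first = g_start if gene.strand == "+" else g_end
    d = g_first - atg if gene.strand == "+" else atg - g_first
    return d + 1 if d >= 0 else d


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one synthetic dataset; identical spec → identical output."""
    rng = np.random.default_rng(spec.seed)
    pattern = compile_iupac(spec.motif)
    words = pattern.words()
    specific = spec.specific_word if spec.specific_word is not None else words[0]
    if specific not in words:
        raise MotifError(
            f"specific word {specific!r} is not derived from motif {spec.motif!r}"
        )
    for w in words:
        if pattern.matches(reverse_complement(w)):
            raise MotifError(
                f"motif {spec.motif!r} is orientation-ambiguous "
                f"(reverse complement of {w} also matches); planted strand "
                "truth would be ill-defined"
            )
    m_l = pattern.length
    margin = spec.scan_intergenic_len + 2 * m_l + 10

    # --- lay out genes -----------------------------------------------------
    per_chrom = [
        [i for i in range(spec.n_genes) if i * spec.n_chromosomes // spec.n_genes == c]
        for c in range(spec.n_chromosomes)
    ]
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    for c, idxs in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        cursor = margin + 1
        for i in idxs:
            strand = "+" if rng.random() < 0.5 else "-"
            parts = _gene_region_lengths(rng, spec)
            ascending = parts if strand == "+" else list(reversed(parts))
            regions_asc: list[Region] = []
            pos = cursor
            for kind, length in ascending:
                regions_asc.append(Region(kind, pos, pos + length - 1))
                pos += length
            regions = regions_asc if strand == "+" else list(reversed(regions_asc))
            cds = [r for r in regions if r.kind is RegionKind.CDS]
            atg = min(r.start for r in cds) if strand == "+" else max(r.end for r in cds)
            gene_id = f"AT{c}G{(i + 1) * 10:05d}"
            desc = _DESCRIPTIONS[i % len(_DESCRIPTIONS)]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    transcripts=[TranscriptModel(f"{gene_id}.1", regions, atg)],
                    name=f"GEN{i + 1}",
                    description=desc,
                    annotation=f"synthetic locus {i + 1}",
                    ec_numbers=[_EC_FOR[desc]] if desc in _EC_FOR else [],
                )
            )
            cursor = pos + int(rng.integers(*spec.gap_range, endpoint=True))
        chrom_lengths[chrom] = cursor + margin

    seqs = {
        chrom: _sample_bases(rng, n, spec.background)
        for chrom, n in chrom_lengths.items()
    }

    # --- expression labels -------------------------------------------------
    de_flags = rng.random(spec.n_genes) < spec.de_fraction
    de_genes: set[str] = set()
    expression: dict[str, float] = {}
    for g, de in zip(genes, de_flags):
        if de:
            mag = -1.0
            while mag < spec.fct:
                mag = rng.normal(spec.fc_de_mean, spec.fc_de_sd)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            expression[g.gene_id] = sign * mag
            de_genes.add(g.gene_id)
        else:
            mag = spec.fct
            while abs(mag) >= spec.fct:
                mag = rng.normal(0.0, spec.fc_null_sd)
            expression[g.gene_id] = mag

    # --- plant sites -------------------------------------------------------
    kinds = list(spec.site_region_distribution)
    kind_probs = [spec.site_region_distribution[k] for k in kinds]
    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    truth: list[PlantedSite] = []
    de_mask = np.array([g.gene_id in de_genes for g in genes])
    for _ in range(spec.n_planted_sites):
        word = words[int(rng.integers(len(words)))]
        if word == specific and spec.enrichment_odds != 1.0:
            weights = np.where(de_mask, spec.enrichment_odds, 1.0)
        else:
            weights = np.ones(len(genes))
        weights = weights / weights.sum()
        placed = False
        for _attempt in range(300):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            kind = kinds[int(rng.choice(len(kinds), p=kind_probs))]
            intervals = [
                iv
                for iv in _planting_intervals(gene, kind, spec.scan_intergenic_len)
                if iv[1] - iv[0] + 1 >= m_l
            ]
            if not intervals:
                continue
            lo, hi = intervals[int(rng.integers(len(intervals)))]
            start = int(rng.integers(lo, hi - m_l + 1, endpoint=True))
            end = start + m_l - 1
            # keep >=1 bp clearance so decontamination always has a free base
            if any(
                start <= e + 1 and end >= s - 1
                for s, e in planted[gene.chromosome]
            ):
                continue
            site_strand = (
                "reverse" if rng.random() < spec.reverse_site_fraction else "forward"
            )
            text_gene = word if site_strand == "forward" else reverse_complement(word)
            text_genome = text_gene if gene.strand == "+" else reverse_complement(text_gene)
            seq = seqs[gene.chromosome]
            seq[start - 1 : end] = list(text_genome)
            planted[gene.chromosome].append((start, end))
            truth.append(
                PlantedSite(
                    gene_id=gene.gene_id,
                    transcript_id=gene.transcripts[0].transcript_id,
                    chromosome=gene.chromosome,
                    start=start,
                    end=end,
                    strand=site_strand,
                    region=kind,
                    atg_position=_atg_relative(gene, start, end),
                    word=word,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "motif cannot fit the requested region distribution; "
                "enlarge the regions or reduce n_planted_sites"
            )

    # --- decontaminate chance matches --------------------------------------
    fwd_body = "".join("[" + "".join(sorted(s)) + "]" for s in pattern.allowed_sets)
    rc_sets = [
        frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in s)
        for s in reversed(pattern.allowed_sets)
    ]
    rc_body = "".join("[" + "".join(sorted(s)) + "]" for s in rc_sets)
    regexes = [re.compile(f"(?=({fwd_body}))"), re.compile(f"(?=({rc_body}))")]
    probs = [spec.background.freqs[b] for b in _BASES]
    for chrom, seq in seqs.items():
        protected = np.zeros(len(seq), dtype=bool)
        for s, e in planted[chrom]:
            protected[s - 1 : e] = True
        planted_set = set(planted[chrom])
        for _round in range(200):
            text = "".join(seq)
            dirty = False
            for rx in regexes:
                for m in rx.finditer(text):
                    s0 = m.start() + 1
                    iv = (s0, s0 + m_l - 1)
                    if iv in planted_set:
                        continue
                    free = [
                        j for j in range(m.start(), m.start() + m_l) if not protected[j]
                    ]
                    for j in free:
                        seq[j] = str(rng.choice(list(_BASES), p=probs))
                    dirty = True
            if not dirty:
                break
        else:  # pragma: no cover - pathological spec
            raise RuntimeError("background decontamination did not converge")

    genome = GenomeIndex({c: "".join(s) for c, s in seqs.items()})

    # --- interactions ------------------------------------------------------
    interactions: list[tuple[str, str, str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    gene_ids = [g.gene_id for g in genes]
    attempts = 0
    while len(interactions) < spec.n_interactions and attempts < spec.n_interactions * 20:
        attempts += 1
        a, b = rng.choice(len(gene_ids), size=2, replace=False)
        pair = tuple(sorted((gene_ids[a], gene_ids[b])))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        if rng.random() < 0.6:
            ev = "biochemical"
            method = _BIOCHEM_METHODS[int(rng.integers(len(_BIOCHEM_METHODS)))]
        else:
            ev, method = "computational", ""
        interactions.append((pair[0], pair[1], ev, method))

    return Fixture(
        spec=spec,
        genome=genome,
        genes=genes,
        expression=expression,
        de_genes=de_genes,
        interactions=interactions,
        truth=truth,
    )
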