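import numpy as np
import pytest

from cismotif.genome import (
    GeneModel,
    GenomeIndex,
    Region,
    RegionKind,
    ScanUnit,
    Segment,
    TranscriptModel,
)


def make_unit(sequence: str, gene_strand: str = "+", atg_genomic: int = 1) -> ScanUnit:
    """Single-segment scan unit over a literal sequence (plus-strand frame)."""
    segments = []
    if sequence:
        segments = [Segment(RegionKind.CDS, 1, len(sequence), 0)]
        if gene_strand == "-":
            segments = [Segment(RegionKind.CDS, 1, len(sequence), 0)]
    return ScanUnit(
        gene_id="G1",
        transcript_id="G1.1",
        chromosome="chr1",
        gene_strand=gene_strand,
        sequence=sequence,
        segments=segments,
        atg_genomic=atg_genomic,
    )


def make_multi_unit(parts: list[tuple[RegionKind, str]]) -> ScanUnit:
    """Plus-strand unit built from contiguous segments of given kinds."""
    segments = []
    seq = []
    pos = 1
    off = 0
    for kind, s in parts:
        segments.append(Segment(kind, pos, pos + len(s) - 1, off))
        seq.append(s)
        pos += len(s)
        off += len(s)
    return ScanUnit(
        gene_id="G1",
        transcript_id="G1.1",
        chromosome="chr1",
        gene_strand="+",
        sequence="".join(seq),
        segments=segments,
        atg_genomic=1,
    )


@pytest.fixture
def toy_genome() -> GenomeIndex:
    """1 kb chromosome of background sequence with a known plus-strand gene."""
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=1000, p=[0.32, 0.18, 0.18, 0.32]))
    return GenomeIndex({"chr1": seq})


def plus_gene(
    utr5=(201, 210), cds=(211, 240), utr3=(241, 250), gene_id="GENE1"
) -> GeneModel:
    regions = [
        Region(RegionKind.UTR5, *utr5),
        Region(RegionKind.CDS, *cds),
        Region(RegionKind.UTR3, *utr3),
    ]
    return GeneModel(
        gene_id=gene_id,
        chromosome="chr1",
        strand="+",
        transcripts=[TranscriptModel(f"{gene_id}.1", regions, cds[0])],
        name="TOY1",
        description="toy gene",
    )


def minus_gene(
    utr3=(301, 310), cds=(311, 340), utr5=(341, 350), gene_id="GENE2"
) -> GeneModel:
    # 5'→3' on the minus strand runs from high to low genomic coordinates
    regions = [
        Region(RegionKind.UTR5, *utr5),
        Region(RegionKind.CDS, *cds),
        Region(RegionKind.UTR3, *utr3),
    ]
    return GeneModel(
        gene_id=gene_id,
        chromosome="chr1",
        strand="-",
        transcripts=[TranscriptModel(f"{gene_id}.1", regions, cds[1])],
        name="TOY2",
        description="toy minus gene",
    )
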