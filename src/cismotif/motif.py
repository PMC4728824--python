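"""IUPAC-degenerate and PWM motif compilation, scanning, and hit filtering.

Patterns are compiled position-wise into sets of concrete bases; a PWM can
be projected onto such a pattern by keeping, at each column, the bases whose
probability clears a floor (default 0.05). Scanning slides every window of a
:class:`~cismotif.genome.ScanUnit` and reports all (including overlapping)
matches; genome N bases never match any code, N in the pattern included, so
unknown sequence cannot inflate counts. Matching is case-insensitive.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GeneModel, ScanUnit, atg_relative_position, reverse_complement

__all__ = [
    "IUPAC_SETS",
    "MotifPattern",
    "PWM",
    "MotifHit",
    "FilterSpec",
    "MotifError",
    "compile_iupac",
    "reverse_complement_pattern",
    "scan_unit",
    "scan_unit_naive",
    "pwm_match_prob",
    "pwm_to_pattern",
    "load_pwm",
    "apply_filters",
    "dedupe_palindromic",
]

# The 15-letter degenerate nucleotide alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


class MotifError(ValueError):
    """Invalid motif input."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: per-position sets of concrete bases."""

    text: str
    allowed_sets: tuple[frozenset[str], ...]
    strand_mode: str = "forward"

    @property
    def length(self) -> int:
        """Motif length M_L in bp."""
        return len(self.allowed_sets)

    def matches(self, window: str) -> bool:
        window = window.upper()
        if len(window) != self.length:
            return False
        return all(b in s for b, s in zip(window, self.allowed_sets))

    def words(self) -> list[str]:
        """All concrete words the pattern matches (lexicographic order)."""
        return [
            "".join(w)
            for w in itertools.product(*[sorted(s) for s in self.allowed_sets])
        ]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


def compile_iupac(text: str, strand_mode: str = "forward") -> MotifPattern:
    """Compile an IUPAC string into a :class:`MotifPattern` (case-insensitive)."""
    if not text:
        raise MotifError("empty motif string")
    if strand_mode not in ("forward", "reverse", "both"):
        raise MotifError(f"unknown strand mode {strand_mode!r}")
    sets = []
    for i, ch in enumerate(text.upper()):
        if ch not in IUPAC_SETS:
            raise MotifError(f"invalid IUPAC character {ch!r} at position {i + 1}")
        sets.append(IUPAC_SETS[ch])
    return MotifPattern(text.upper(), tuple(sets), strand_mode)


def reverse_complement_pattern(pattern: MotifPattern) -> MotifPattern:
    """Reverse the position order and complement every allowed set
    (R↔Y, K↔M, S↔S, W↔W, B↔V, D↔H, N↔N). Applying twice is the identity."""
    sets = tuple(
        frozenset(_BASE_COMPLEMENT[b] for b in s)
        for s in reversed(pattern.allowed_sets)
    )
    text = "".join(_SET_TO_CODE[s] for s in sets)
    return MotifPattern(text, sets, pattern.strand_mode)


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-column probabilities over A, C, G, T.

    ``matrix`` has shape (4, L) with rows in A, C, G, T order.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise MotifError("PWM must be a 4 x L matrix (rows A, C, G, T)")
        if (m < 0).any():
            raise MotifError("PWM entries must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise MotifError("every PWM column must sum to 1 (within 1e-9)")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


def load_pwm(path: str | Path) -> PWM:
    """Read a whitespace-delimited PWM: 4 labelled rows (A/C/G/T) × L columns.

    Count matrices (rows summing column-wise to a common integer) are
    normalised to probabilities.
    """
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(":", " ").split()
            label = parts[0].upper().strip("|[]")
            if label not in _BASES:
                raise MotifError(f"unexpected PWM row label {parts[0]!r}")
            try:
                rows[label] = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise MotifError(f"non-numeric PWM entry in row {label}: {exc}")
    missing = [b for b in _BASES if b not in rows]
    if missing:
        raise MotifError(f"PWM file lacks rows for {', '.join(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise MotifError("PWM rows have unequal lengths")
    m = np.array([rows[b] for b in _BASES], dtype=float)
    sums = m.sum(axis=0)
    if (sums <= 0).any():
        raise MotifError("PWM column sums to zero")
    if not np.allclose(sums, 1.0, atol=1e-6):
        m = m / sums  # counts → probabilities
    return PWM(m)


def pwm_match_prob(pwm: PWM, window: str) -> float:
    """V_PWM for a concrete window: the product over positions of the column
    probability of the observed base — the probability that the factor binds
    that exact sequence under the matrix."""
    window = window.upper()
    if len(window) != pwm.length:
        raise MotifError(
            f"window length {len(window)} != PWM length {pwm.length}"
        )
    prob = 1.0
    for j, base in enumerate(window):
        if base not in _BASES:
            return 0.0
        prob *= float(pwm.matrix[_BASES.index(base), j])
    return prob


def pwm_to_pattern(
    pwm: PWM, min_prob: float = 0.05, strand_mode: str = "forward"
) -> MotifPattern:
    """Project a PWM onto a degenerate pattern: at each column keep the bases
    with probability ≥ ``min_prob``. This defines the set of "motifs derived
    from the PWM" used both for scanning and for enrichment counts."""
    if not 0 < min_prob <= 1:
        raise MotifError("min_prob must lie in (0, 1]")
    sets = []
    for j in range(pwm.length):
        allowed = frozenset(
            _BASES[i] for i in range(4) if pwm.matrix[i, j] >= min_prob
        )
        if not allowed:
            raise MotifError(
                f"PWM column {j + 1}: no base reaches probability {min_prob}; "
                "lower the threshold"
            )
        sets.append(allowed)
    text = "".join(_SET_TO_CODE[s] for s in sets)
    return MotifPattern(text, tuple(sets), strand_mode)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    """One motif match in one transcript's scan unit.

    ``matched_sequence`` holds the bases as they read on the gene strand;
    ``strand`` is the match orientation relative to the gene strand.
    ``atg_position`` is the signed start-codon-relative position of the
    window's first gene-strand base.
    """

    gene_id: str
    transcript_id: str
    matched_sequence: str
    unit_offset: int
    atg_position: int
    genomic_interval: tuple[str, int, int]
    strand: str
    region_labels: tuple[str, ...]
    length: int
    v_pwm: float = 1.0

    @property
    def motif_word(self) -> str:
        """The matched word read on the motif's own strand."""
        if self.strand == "forward":
            return self.matched_sequence
        return reverse_complement(self.matched_sequence)


def _pattern_regex(pattern: MotifPattern) -> re.Pattern[str]:
    # character classes contain concrete bases only, so genome N never matches
    body = "".join("[" + "".join(sorted(s)) + "]" for s in pattern.allowed_sets)
    return re.compile(f"(?=({body}))")


def _make_hit(
    unit: ScanUnit,
    offset: int,
    length: int,
    strand: str,
    pwm: PWM | None,
) -> MotifHit:
    window = unit.sequence[offset : offset + length]
    g_first = unit.genomic_position(offset)
    g_last = unit.genomic_position(offset + length - 1)
    v = 1.0
    if pwm is not None:
        word = window if strand == "forward" else reverse_complement(window)
        v = pwm_match_prob(pwm, word)
    return MotifHit(
        gene_id=unit.gene_id,
        transcript_id=unit.transcript_id,
        matched_sequence=window,
        unit_offset=offset,
        atg_position=atg_relative_position(unit, offset),
        genomic_interval=(unit.chromosome, min(g_first, g_last), max(g_first, g_last)),
        strand=strand,
        region_labels=tuple(k.value for k in unit.region_kinds_at(offset, length)),
        length=length,
        v_pwm=v,
    )


def scan_unit(
    unit: ScanUnit, pattern: MotifPattern, pwm: PWM | None = None
) -> list[MotifHit]:
    """All matches of a pattern in a scan unit.

    ``strand_mode='reverse'`` scans with the reverse-complement pattern and
    reports strand='reverse'; ``'both'`` scans both orientations and reports
    each match separately (a palindromic site therefore yields two hits).
    Overlapping matches are all reported. A motif longer than the unit gives
    an empty result. When a ``pwm`` is supplied, each hit carries its V_PWM.
    """
    hits: list[MotifHit] = []
    m_l = pattern.length
    if m_l > unit.length:
        return hits
    seq = unit.sequence
    if pattern.strand_mode in ("forward", "both"):
        for m in _pattern_regex(pattern).finditer(seq):
            hits.append(_make_hit(unit, m.start(), m_l, "forward", pwm))
    if pattern.strand_mode in ("reverse", "both"):
        rc = reverse_complement_pattern(pattern)
        for m in _pattern_regex(rc).finditer(seq):
            hits.append(_make_hit(unit, m.start(), m_l, "reverse", pwm))
    hits.sort(key=lambda h: (h.unit_offset, h.strand))
    return hits


def scan_unit_naive(
    unit: ScanUnit, pattern: MotifPattern, pwm: PWM | None = None
) -> list[MotifHit]:
    """Reference scanner: the plainest window-by-window set-membership loop.

    Same contract as :func:`scan_unit`; kept as an independent oracle for
    equivalence testing and never used on real workloads.
    """
    hits: list[MotifHit] = []
    m_l = pattern.length
    seq = unit.sequence
    orientations: list[tuple[str, MotifPattern]] = []
    if pattern.strand_mode in ("forward", "both"):
        orientations.append(("forward", pattern))
    if pattern.strand_mode in ("reverse", "both"):
        orientations.append(("reverse", reverse_complement_pattern(pattern)))
    for off in range(0, unit.length - m_l + 1):
        window = seq[off : off + m_l]
        for strand, pat in orientations:
            ok = all(base in s for base, s in zip(window, pat.allowed_sets))
            if ok:
                hits.append(_make_hit(unit, off, m_l, strand, pwm))
    hits.sort(key=lambda h: (h.unit_offset, h.strand))
    return hits


def dedupe_palindromic(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Optionally collapse the two-strand double report of a palindromic site
    to a single (forward-first) hit per genomic interval and transcript."""
    seen: set[tuple] = set()
    out: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (h.transcript_id, h.unit_offset, h.strand)):
        key = (h.transcript_id, h.genomic_interval)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Contain / Devoid filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterSpec:
    """Gene-level annotation-text filter.

    ``contain`` passes genes whose name/description/annotation holds the
    substring; ``devoid`` passes genes where it does not; ``mode`` combines
    the two ('and' = both must pass, 'or' = either).
    """

    contain: str | None = None
    devoid: str | None = None
    mode: str = "and"

    def __post_init__(self) -> None:
        if self.contain is None and self.devoid is None:
            raise MotifError("FilterSpec needs at least one of contain/devoid")
        if self.mode not in ("and", "or"):
            raise MotifError(f"filter mode must be 'and' or 'or', got {self.mode!r}")

    def passes(self, gene: GeneModel) -> bool:
        text = " ".join((gene.name, gene.description, gene.annotation)).lower()
        checks = []
        if self.contain is not None:
            checks.append(self.contain.lower() in text)
        if self.devoid is not None:
            checks.append(self.devoid.lower() not in text)
        return all(checks) if self.mode == "and" else any(checks)


def apply_filters(
    hits: Iterable[MotifHit],
    spec: FilterSpec | None,
    gene_lookup: Mapping[str, GeneModel],
) -> list[MotifHit]:
    """Drop hits belonging to genes that fail the Contain/Devoid filter."""
    hits = list(hits)
    if spec is None:
        return hits
    passing = {
        gid for gid, gene in gene_lookup.items() if spec.passes(gene)
    }
    return [h for h in hits if h.gene_id in passing]
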