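"""Motif enrichment scoring: background model, Motif Score, binomial p-value.

Per locus, the number of observed binding sites ``B_O`` is compared with the
expectation under an i.i.d. background model::

    B_E = M_P * T            T = 2 * (R_L - M_L + 1)
    MS  = V_PWM * B_O * ln(B_O / B_E)

where ``M_P`` is the probability of the motif at one position (product of
the background frequencies of the allowed bases, column by column), ``T``
the number of possible matching positions across both strands of the
selected regions (length ``R_L``), and ``V_PWM`` the PWM binding
probability (1 for a plain IUPAC search). The p-value is the upper tail of
the Binomial(T, M_P) count: the probability of at least ``n`` motifs.

The default background is the Arabidopsis nucleotide composition
A = T = 0.32, C = G = 0.18.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .genome import ScanUnit
from .motif import MotifHit, MotifPattern

__all__ = [
    "BackgroundModel",
    "DEFAULT_BACKGROUND",
    "ScoreReport",
    "motif_background_prob",
    "possible_positions",
    "motif_score",
    "binomial_pvalue",
    "significance_stars",
    "unique_site_count",
    "score_locus",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Genome-wide single-nucleotide frequencies."""

    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freqs) != set("ACGT"):
            raise ValueError("background must give frequencies for A, C, G, T")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freqs.values()):
            raise ValueError("background frequencies must be non-negative")
        object.__setattr__(self, "freqs", dict(self.freqs))


#: Arabidopsis nucleotide composition.
DEFAULT_BACKGROUND = BackgroundModel({"A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32})


def motif_background_prob(
    pattern: MotifPattern, background: BackgroundModel = DEFAULT_BACKGROUND
) -> float:
    """M_P: probability that one background-drawn window matches the motif.

    Product over positions of the summed background frequencies of the
    allowed bases; singleton positions reduce to the plain per-nucleotide
    product (e.g. ATCCG → 0.32·0.32·0.18·0.18·0.18).
    """
    prob = 1.0
    for allowed in pattern.allowed_sets:
        prob *= sum(background.freqs[b] for b in allowed)
    return prob


def possible_positions(region_length: int, motif_length: int) -> int:
    """T = 2 (R_L − M_L + 1): matching positions across both strands."""
    if region_length < 1 or motif_length < 1:
        raise ValueError("lengths must be >= 1")
    if region_length < motif_length:
        return 0
    return 2 * (region_length - motif_length + 1)


def motif_score(v_pwm: float, b_observed: float, b_expected: float) -> float:
    """MS = V_PWM · B_O · ln(B_O / B_E); negative when B_O < B_E."""
    if b_observed < 1:
        raise ValueError("motif score is undefined for zero observed sites")
    if b_expected <= 0:
        raise ValueError("expected count must be positive")
    return v_pwm * b_observed * math.log(b_observed / b_expected)


def binomial_pvalue(n: int, t: int, m_p: float) -> float:
    """Probability of observing at least ``n`` motifs among ``t`` possible
    positions, each matching with probability ``m_p`` (upper binomial tail).

    Computed through the binomial survival function, stable for large ``t``.
    """
    if not 0 <= m_p <= 1:
        raise ValueError("m_p must lie in [0, 1]")
    if n < 0 or n > t:
        raise ValueError(f"need 0 <= n <= T, got n={n}, T={t}")
    if n == 0:
        return 1.0
    return float(stats.binom.sf(n - 1, t, m_p))


def significance_stars(p_value: float) -> str:
    """Conventional star coding: *** <0.001, ** <0.01, * <0.05, else ns."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ScoreReport:
    """Per-locus motif enrichment summary (one Bernoulli model per locus)."""

    gene_id: str
    transcript_id: str
    motif_text: str
    b_observed: int
    b_expected: float
    n: int
    t: int
    m_p: float
    v_pwm: float
    motif_score: float
    p_value: float
    significance: str


def unique_site_count(hits: Iterable[MotifHit]) -> int:
    """B_O: distinct genomic positions hit, pooling strands and isoforms.

    T already carries the two-strand factor, so a both-strand palindromic
    pair at one position is a single success; duplicates across splice forms
    collapse for the same reason.
    """
    return len({h.genomic_interval for h in hits})


def score_locus(
    unit: ScanUnit,
    hits: Sequence[MotifHit],
    pattern: MotifPattern,
    background: BackgroundModel = DEFAULT_BACKGROUND,
) -> ScoreReport | None:
    """Assemble the per-locus score report; ``None`` when there are no hits.

    ``hits`` should be the locus's pooled hits (all isoforms); ``unit`` is
    the representative scan unit supplying R_L. V_PWM is averaged over the
    deduplicated positions (1.0 throughout for plain IUPAC searches).
    """
    by_pos: dict[tuple, MotifHit] = {}
    for h in sorted(hits, key=lambda h: (h.unit_offset, h.strand, h.transcript_id)):
        by_pos.setdefault(h.genomic_interval, h)
    b_o = len(by_pos)
    if b_o == 0:
        return None
    m_p = motif_background_prob(pattern, background)
    t = possible_positions(unit.length, pattern.length)
    b_e = m_p * t
    v = sum(h.v_pwm for h in by_pos.values()) / b_o
    ms = motif_score(v, b_o, b_e)
    p = binomial_pvalue(b_o, t, m_p)
    return ScoreReport(
        gene_id=unit.gene_id,
        transcript_id=unit.transcript_id,
        motif_text=pattern.text,
        b_observed=b_o,
        b_expected=b_e,
        n=b_o,
        t=t,
        m_p=m_p,
        v_pwm=v,
        motif_score=ms,
        p_value=p,
        significance=significance_stars(p),
    )
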