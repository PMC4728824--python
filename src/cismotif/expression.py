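"""Expression integration: fold-change thresholding, Binding Score,
chi-squared enrichment, primary/secondary target classification.

A two-column tab-delimited table (gene id, fold change) is combined with
motif sites. A gene above the fold-change threshold (FCT) that carries at
least one binding site in the selected regions is called a *primary* target
(directly bound); one above threshold with no site is *secondary*
(downstream effect); everything else is *unchanged*.

Per locus the Binding Score sums, over its ``n`` binding sites::

    BS = sum_i  V_PWM(i) * B_FC_Spec(w_i) * ln( (B_FC_Spec(w_i) / B_Tot_Spec(w_i))
                                                / (B_FC / B_Tot) )

where for the concrete word ``w_i`` matched by site ``i``, ``B_FC_Spec`` /
``B_Tot_Spec`` count its sites in differentially expressed genes / in the
whole scanned gene set, and ``B_FC`` / ``B_Tot`` are the same counts pooled
over all words derived from the PWM. A positive BS means the locus's words
concentrate in differentially expressed genes more than the motif family at
large. Terms whose counts vanish contribute 0 (the information-less limit).

The accompanying chi-squared test (2×2, 1 df, no continuity correction)
asks whether genes holding the one specific word are differentially
expressed more often than genes holding only the other words of the family.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel
from .motif import MotifHit

__all__ = [
    "ExpressionTable",
    "ExpressionError",
    "EnrichmentCounts",
    "Chi2Result",
    "BindingScoreReport",
    "ExpressionResult",
    "load_expression",
    "is_above_threshold",
    "unique_sites",
    "site_counts",
    "binding_score",
    "chi_square_enrichment",
    "classify_targets",
    "expression_analysis",
]


class ExpressionError(ValueError):
    """Malformed expression input."""


@dataclass
class ExpressionTable:
    """Gene id → fold change, plus the user's threshold and scale.

    ``scale`` declares how fold changes are encoded: 'log2' (|fc| ≥ FCT is
    differential) or 'linear' (max(fc, 1/fc) ≥ FCT, so 4-fold down at
    fc = 0.25 passes FCT = 2).
    """

    records: dict[str, float]
    fct: float = 1.0
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.fct <= 0:
            raise ExpressionError("FCT must be positive")
        if self.scale not in ("log2", "linear"):
            raise ExpressionError(f"unknown fold-change scale {self.scale!r}")

    def is_differential(self, gene_id: str) -> bool:
        fc = self.records.get(gene_id)
        if fc is None:
            return False
        return is_above_threshold(fc, self.fct, self.scale)


def is_above_threshold(fold_change: float, fct: float, scale: str = "log2") -> bool:
    """Whether a fold change clears the threshold on its declared scale."""
    if fct <= 0:
        raise ExpressionError("FCT must be positive")
    if scale == "log2":
        return abs(fold_change) >= fct
    if scale == "linear":
        if fold_change <= 0:
            raise ExpressionError(
                f"linear-scale fold change must be positive, got {fold_change}"
            )
        return max(fold_change, 1.0 / fold_change) >= fct
    raise ExpressionError(f"unknown fold-change scale {scale!r}")


def load_expression(
    tsv_path: str | Path, fct: float = 1.0, scale: str = "log2"
) -> ExpressionTable:
    """Read the two-column tab-delimited (gene id, fold change) table.

    A header row is sniffed (non-numeric second field) and skipped.
    Duplicate gene ids and non-numeric fold changes are row-level errors.
    """
    try:
        df = pd.read_csv(
            tsv_path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise ExpressionError(f"expression file {tsv_path} is empty") from None
    if df.empty:
        raise ExpressionError(f"expression file {tsv_path} is empty")
    if df.shape[1] < 2:
        raise ExpressionError("expression file needs two tab-delimited columns")
    first_val = str(df.iloc[0, 1])
    try:
        float(first_val)
    except ValueError:
        df = df.iloc[1:]  # header row
        if df.empty:
            raise ExpressionError(f"expression file {tsv_path} has no data rows")
    records: dict[str, float] = {}
    for row_no, (gene, fc) in enumerate(
        zip(df.iloc[:, 0], df.iloc[:, 1]), start=1
    ):
        gene = str(gene).strip()
        if gene in records:
            raise ExpressionError(f"duplicate gene id {gene!r} in expression file")
        try:
            records[gene] = float(fc)
        except (TypeError, ValueError):
            raise ExpressionError(
                f"row {row_no}: non-numeric fold change {fc!r} for gene {gene!r}"
            )
    return ExpressionTable(records, fct=fct, scale=scale)


# ---------------------------------------------------------------------------
# Site bookkeeping
# ---------------------------------------------------------------------------


def unique_sites(hits: Iterable[MotifHit]) -> dict[str, list[MotifHit]]:
    """Deduplicate hits to one site per (gene, genomic position), pooling
    isoforms and strands (forward representative preferred), grouped by gene."""
    chosen: dict[tuple, MotifHit] = {}
    for h in sorted(
        hits, key=lambda h: (h.gene_id, h.genomic_interval, h.strand, h.transcript_id)
    ):
        chosen.setdefault((h.gene_id, h.genomic_interval), h)
    by_gene: dict[str, list[MotifHit]] = {}
    for (gene_id, _), h in sorted(chosen.items()):
        by_gene.setdefault(gene_id, []).append(h)
    return by_gene


@dataclass(frozen=True)
class EnrichmentCounts:
    """The four B symbols of the Binding Score, per concrete word and pooled.

    ``per_word`` maps each word to (B_FC_Spec, B_Tot_Spec); ``b_fc`` /
    ``b_tot`` pool every word derived from the PWM.
    """

    b_fc: int
    b_tot: int
    per_word: dict[str, tuple[int, int]]

    def spec(self, word: str) -> tuple[int, int]:
        return self.per_word.get(word, (0, 0))


def site_counts(
    sites_by_gene: Mapping[str, Sequence[MotifHit]],
    expr: ExpressionTable,
    gene_weighted: bool = False,
) -> EnrichmentCounts:
    """Count sites genome-wide and above the fold-change threshold.

    Default is site-weighted (every site in a differential gene counts
    toward B_FC); ``gene_weighted=True`` counts each gene at most once per
    word instead.
    """
    b_fc = b_tot = 0
    per_word: dict[str, list[int]] = {}
    for gene_id, sites in sites_by_gene.items():
        de = expr.is_differential(gene_id)
        words = [s.motif_word for s in sites]
        if gene_weighted:
            words = sorted(set(words))
        for w in words:
            entry = per_word.setdefault(w, [0, 0])
            entry[1] += 1
            b_tot += 1
            if de:
                entry[0] += 1
                b_fc += 1
    return EnrichmentCounts(
        b_fc=b_fc,
        b_tot=b_tot,
        per_word={w: (fc, tot) for w, (fc, tot) in sorted(per_word.items())},
    )


def binding_score(
    locus_sites: Sequence[MotifHit], counts: EnrichmentCounts
) -> float:
    """BS of one locus: sum over its sites of the word-specific enrichment
    term; a locus with no sites scores 0; any zero count zeroes its term."""
    if counts.b_tot == 0 or counts.b_fc == 0:
        return 0.0
    family_rate = counts.b_fc / counts.b_tot
    score = 0.0
    for site in locus_sites:
        b_fc_spec, b_tot_spec = counts.spec(site.motif_word)
        if b_fc_spec == 0 or b_tot_spec == 0:
            continue
        ratio = (b_fc_spec / b_tot_spec) / family_rate
        score += site.v_pwm * b_fc_spec * math.log(ratio)
    return score


# ---------------------------------------------------------------------------
# Chi-squared enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    valid: bool
    table: tuple[tuple[int, int], tuple[int, int]]
    reason: str = ""


def chi_square_enrichment(
    genes_with_sites_all: int,
    genes_with_sites_and_de_all: int,
    genes_with_sites_spec: int,
    genes_with_sites_and_de_spec: int,
    exclusive: bool = True,
) -> Chi2Result:
    """2×2 chi-squared (1 df, no continuity correction) comparing the
    differential-expression rate of genes holding the specific word against
    genes holding (other) words of the PWM family.

    With ``exclusive`` (default) the comparison group is the family minus
    the specific word, so the two rows are disjoint; ``exclusive=False``
    keeps the family group inclusive. Inputs are the inclusive counts. A
    zero expected cell flags the result invalid instead of raising.
    """
    if genes_with_sites_and_de_all > genes_with_sites_all:
        raise ExpressionError("DE-and-sites count exceeds sites count (all)")
    if genes_with_sites_and_de_spec > genes_with_sites_spec:
        raise ExpressionError("DE-and-sites count exceeds sites count (specific)")
    if genes_with_sites_spec > genes_with_sites_all:
        raise ExpressionError("specific-word gene count exceeds family count")
    if exclusive:
        rest = genes_with_sites_all - genes_with_sites_spec
        rest_de = genes_with_sites_and_de_all - genes_with_sites_and_de_spec
    else:
        rest = genes_with_sites_all
        rest_de = genes_with_sites_and_de_all
    table = (
        (genes_with_sites_and_de_spec, genes_with_sites_spec - genes_with_sites_and_de_spec),
        (rest_de, rest - rest_de),
    )
    arr = np.array(table, dtype=float)
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return Chi2Result(
            float("nan"), float("nan"), False, table,
            reason="zero expected cell; test not computed",
        )
    stat, p, _, expected = stats.chi2_contingency(arr, correction=False)
    if (expected == 0).any():  # pragma: no cover - caught by margin check
        return Chi2Result(
            float("nan"), float("nan"), False, table,
            reason="zero expected cell; test not computed",
        )
    return Chi2Result(float(stat), float(p), True, table)


# ---------------------------------------------------------------------------
# Target classification and full analysis
# ---------------------------------------------------------------------------


@dataclass
class BindingScoreReport:
    """Per-gene expression-integration summary."""

    gene_id: str
    n_sites: int
    fold_change: float | None
    regions: tuple[str, ...]
    binding_score: float
    b_fc: int
    b_tot: int
    b_fc_spec: int
    b_tot_spec: int
    chi2_stat: float
    chi2_p: float
    target_class: str
    note: str = ""


@dataclass
class ExpressionResult:
    reports: list[BindingScoreReport]
    chi2: Chi2Result
    counts: EnrichmentCounts
    specific_word: str


def classify_targets(
    has_sites: bool, fold_change: float | None, expr: ExpressionTable
) -> tuple[str, str]:
    """Target class of one gene: primary (differential, with sites),
    secondary (differential, no sites), unchanged otherwise. A gene with
    hits but no expression record is unchanged, flagged."""
    if fold_change is None:
        return ("unchanged", "no expression data")
    if is_above_threshold(fold_change, expr.fct, expr.scale):
        return ("primary" if has_sites else "secondary", "")
    return ("unchanged", "")


def expression_analysis(
    hits: Iterable[MotifHit],
    expr: ExpressionTable,
    specific_word: str | None = None,
    exclusive: bool = True,
    gene_weighted: bool = False,
) -> ExpressionResult:
    """Full expression integration over a scan's hits.

    ``specific_word`` is "the one specific motif considered"; when omitted it
    defaults to the most frequent concrete word among the sites (ties break
    lexicographically). Every gene in the expression table and every gene
    with sites receives a report.
    """
    sites_by_gene = unique_sites(hits)
    counts = site_counts(sites_by_gene, expr, gene_weighted=gene_weighted)
    if specific_word is None:
        tally = Counter()
        for sites in sites_by_gene.values():
            tally.update(s.motif_word for s in sites)
        specific_word = min(
            tally, key=lambda w: (-tally[w], w), default=""
        )

    genes_sites_all = genes_sites_de_all = 0
    genes_sites_spec = genes_sites_de_spec = 0
    for gene_id, sites in sites_by_gene.items():
        de = expr.is_differential(gene_id)
        genes_sites_all += 1
        genes_sites_de_all += de
        if any(s.motif_word == specific_word for s in sites):
            genes_sites_spec += 1
            genes_sites_de_spec += de
    chi2 = chi_square_enrichment(
        genes_sites_all,
        genes_sites_de_all,
        genes_sites_spec,
        genes_sites_de_spec,
        exclusive=exclusive,
    )

    spec_fc, spec_tot = counts.spec(specific_word)
    reports: list[BindingScoreReport] = []
    gene_ids = sorted(set(sites_by_gene) | set(expr.records))
    for gene_id in gene_ids:
        sites = sites_by_gene.get(gene_id, [])
        fc = expr.records.get(gene_id)
        target_class, note = classify_targets(bool(sites), fc, expr)
        regions: list[str] = []
        for s in sites:
            for r in s.region_labels:
                if r not in regions:
                    regions.append(r)
        reports.append(
            BindingScoreReport(
                gene_id=gene_id,
                n_sites=len(sites),
                fold_change=fc,
                regions=tuple(regions),
                binding_score=binding_score(sites, counts),
                b_fc=counts.b_fc,
                b_tot=counts.b_tot,
                b_fc_spec=spec_fc,
                b_tot_spec=spec_tot,
                chi2_stat=chi2.statistic,
                chi2_p=chi2.p_value,
                target_class=target_class,
                note=note,
            )
        )
    return ExpressionResult(reports, chi2, counts, specific_word)
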