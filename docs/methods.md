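# Methods

## Coordinate model

Gene models are read from GFF3 (1-based closed intervals; features `gene`,
`mRNA`/`transcript`, `exon`, `CDS`; `ID`/`Parent` attributes required).
Internally, unit offsets are 0-based half-open; every user-facing position
is the signed distance to the A of the start codon, with ATG = +1, the base
immediately 5′ of it = −1 and no position 0, so promoter sites read as
negative numbers.

Introns are always derived as the gaps between consecutive exons, and UTRs
from the partition of each exon against the transcript's CDS span;
explicit `five_prime_UTR`/`three_prime_UTR`/intron features are tolerated
but ignored. This keeps the region model identical across GFF3 dialects
and avoids double counting. Transcripts without a CDS feature are rejected:
the ATG-relative frame is undefined for them. When only CDS/UTR features
are present, exons are synthesized by merging adjacent features.

Each transcript is partitioned into six region classes — `intergenic5`,
`utr5`, `exon_cds`, `intron`, `utr3`, `intergenic3` — and the selected
classes are concatenated 5′→3′ on the gene strand without separators, so a
motif can span a region boundary (such hits carry both region labels).
Intergenic flanks extend outward from the transcript's outermost annotated
base (configurable to the CDS span instead, `measure_from="cds"`), for the
requested length; they are truncated at the nearest flanking gene's
outermost **coding** coordinate (UTRs of the neighbour do not stop the
flank) and clamped at chromosome ends. A blank length means the full gap.
Overlapping neighbours yield an empty intergenic region, not an error.
Genes without annotated UTRs simply have their intergenic flanks abut the
CDS.

## Motif model

IUPAC-degenerate patterns are compiled position-wise into sets of concrete
bases (R={A,G}, Y={C,T}, S={G,C}, W={A,T}, K={G,T}, M={A,C}, B={C,G,T},
D={A,G,T}, H={A,C,T}, V={A,C,G}, N={A,C,G,T}); matching is
case-insensitive. Genome `N` bases never match any code, including a
pattern `N`, so unknown sequence cannot inflate counts. Reverse-strand
search uses the reverse-complement pattern and reports hits with
`strand=reverse` and the window as it reads on the gene strand; in `both`
mode a palindromic site is reported once per orientation (an optional
dedup collapses the pair). All overlapping matches are reported. The
production scanner is a compiled-regex lookahead sweep; a deliberately
plain window-by-window loop (`scan_unit_naive`) is kept as the test oracle.

A PWM is a 4×L column-stochastic matrix (rows A, C, G, T; count matrices
are normalised on load). `V_PWM` of a concrete window is the product of the
column probabilities of its bases — the probability the factor binds that
exact word. Because no enumeration rule for "the motifs derived from the
PWM" is forced by the formulas, the package defines the family as all
words matching the projection of the PWM onto a degenerate pattern with a
per-column probability floor (default 0.05, configurable): deterministic,
cheap, and the same rule serves both scanning and the enrichment counts.
PWM scans report every window matching that projection, with its `V_PWM`
attached; `V_PWM` is the raw product, not normalised to the consensus.

## Enrichment scoring

Per locus, with R_L the concatenated selected-region length and M_L the
motif length,

    M_P = ∏_j Σ_{b ∈ allowed_j} f(b)        (background frequencies f)
    T   = 2 (R_L − M_L + 1),  0 if R_L < M_L
    B_E = M_P · T
    MS  = V_PWM · B_O · ln(B_O / B_E)
    p   = P[Binomial(T, M_P) ≥ B_O]          (scipy survival function)

The default background is the Arabidopsis composition A = T = 0.32,
C = G = 0.18, overridable by a four-frequency config file. B_O counts
**distinct genomic positions**, pooling strands and splice forms: T already
carries the factor 2 for strands, so a both-strand palindromic pair at one
position is one Bernoulli success (slightly conservative, since T still
counts two trials there). The locus's own scan unit defines T — a
genome-wide T would make every per-gene p-value meaningless; with several
isoforms the longest unit is the representative. For PWM scans the single
V_PWM factor in MS is the mean V_PWM over the deduplicated positions
(exactly 1 for plain IUPAC searches). Significance stars use the
conventional 0.05/0.01/0.001 thresholds. The binomial model ignores
overlap dependence between windows and self-overlapping-motif clumping; no
multiple-testing correction across loci is applied. scipy's survival
function agrees with exact summation to ~3×10⁻¹⁴ relative error for tails
down to 10⁻²⁵⁰; beyond that, double precision only supports "astronomically
small".

## Expression integration

Fold changes come from a two-column tab-delimited table; the scale is
declared in config — `log2` (default, threshold FCT = 1, i.e. 2-fold:
|fc| ≥ FCT) or `linear` (max(fc, 1/fc) ≥ FCT, so 4-fold down at fc = 0.25
clears FCT = 2). Both microarray and RNA-seq pipelines emit one or the
other, which is why the scale is explicit rather than guessed.

Sites are deduplicated to one per (gene, genomic position) before
counting. `B_Tot` / `B_FC` count sites in all scanned genes / in genes
above threshold for the whole motif family; `B_Tot_Spec` / `B_FC_Spec` the
same for one concrete word ("site-weighted"; a gene-weighted variant is a
flag). Counts are genome-wide (the whole scanned gene set), matching the
symbol definitions. The Binding Score of a locus sums, over its sites i
with word w_i,

    V_PWM(i) · B_FC_Spec(w_i) · ln[ (B_FC_Spec(w_i)/B_Tot_Spec(w_i)) / (B_FC/B_Tot) ]

Any term whose counts vanish contributes 0 — the formula is undefined
there and 0 is the information-less limit. BS is therefore additive over
any partition of a locus's site list, and monotone in B_FC_Spec wherever
the inner ratio is ≥ 1 (in the depleted regime x·ln(x·c) is not monotone;
no claim is made there).

The chi-squared test (2×2, 1 df, no continuity correction) compares the
differential-expression rate of genes holding the specific word against
genes holding only the *other* family words — the exclusive contrast keeps
the rows disjoint; an inclusive variant is available by flag. "The one
specific motif considered" defaults to the most frequent matched word and
is settable. A zero expected cell flags the test "not computed" rather
than raising. Target classes: above threshold with ≥1 site → primary;
above threshold with none → secondary; otherwise unchanged; genes with
sites but no expression record are unchanged and flagged "no expression
data".

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes: i.i.d. background sequence at the configured composition;
parametric gene structures (UTR 20–60 bp, 1–3 coding exons of 90–180 bp,
introns 50–90 bp, inter-gene gaps 230–330 bp by default) laid out with
known coordinates on one or more chromosomes; planted sites with recorded
gene, region, strand and ATG-relative position; fold changes drawn on the
log2 scale (differential genes: |N(2.5, 0.5)| with random sign, resampled
to clear FCT; others: N(0, 0.3) resampled to stay below), so the recorded
labels and the realized fold changes agree exactly; and a random
interaction table. Background windows that happen to match the planted
pattern in either orientation are resampled until none remain, so truth
counts are exact rather than statistical. Orientation-ambiguous motifs
(a word whose reverse complement also matches the pattern) are rejected,
because planted strand truth would be ill-defined. The recommended scan
flank (`scan_kwargs()`, 100 bp intergenic) together with the minimum gap
guard guarantees each intergenic site falls in exactly one gene's window.

`enrichment_odds` biases the gene choice of **specific-word** sites toward
differentially expressed genes; the other family words are placed
uniformly. This is deliberate: the Binding Score and the chi-squared test
measure a specific-vs-family contrast, so an enrichment applied equally to
every word would be invisible to them by construction. Odds 1 is the null.

What the generator does **not** emulate: realistic intron/exon length
statistics, GC heterogeneity, repeat structure, nested or overlapping
loci, alternative isoforms, or dependence between neighbouring windows.
Passing tests therefore demonstrate correctness of the coordinate
bookkeeping and the statistics under the model's own assumptions, not
robustness to the full messiness of real annotation.

## Calibration experiments

`cismotif.calibration` runs the two simulation experiments: replicates of
120 genes, 80 planted sites of the two-word pattern GRTACT (specific word
GGTACT), 35 % of genes differential. These sizes keep every expected cell
of the 2×2 table around 8 or more, where the 1-df chi-squared
approximation is trustworthy, while thousands of replicates stay cheap
(the acceptance run uses 2,000 null and 200 enriched datasets; the
acceptance script 1,000 and 200). Replicates with a zero-margin table
count as non-rejections.

## Numerical and formatting choices

* p-values via the binomial survival function (stable to T ~ 10⁸).
* Exported numbers: MS/BS to 4 decimals, p-values in scientific notation
  with 3 significant digits; every output starts with provenance comments
  (tool version, full config, input SHA-256) and re-runs are
  byte-identical.
* BED export is 0-based half-open, strand converted to the genome frame;
  the results TSV keeps ATG-relative positions.
* Deterministic orderings throughout: hits by (gene, transcript, offset,
  strand); neighbourhood edges lexicographic by (depth, ids).

## Known limitations

No compound-Poisson correction for self-overlapping motifs; no FDR across
loci; the per-gene "Significance" column of the expression report reflects
the scan-stage binomial test (the dataset chi-squared sits in the file
header); interaction evidence conflicts resolve in favour of
"biochemical"; no FASTA index or BAM/binary support — inputs are plain
text by design.
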