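# Methods

## The assay being modelled

Digital gene expression (DGE) tag profiling measures transcript
abundance by sequencing one short tag per cDNA molecule.  NlaIII cuts
the cDNA at its recognition site CATG, keeping the fragment between
the 3'-most CATG and the poly(A) tail; MmeI then cuts 17 bp downstream
of the site.  Every read is therefore a 21-mer `CATG + 17 nt` taken
from the 3'-most CATG of a polyadenylated transcript, and a tag's read
count is proportional to the transcript's abundance.  The package
analyses three libraries from FACS-sorted planarian cell fractions —
X1 (proliferating stem cells, S/G2/M), X2 (stem-cell progeny plus some
proliferating cells, G0/G1) and Xin (differentiated cells) — but the
machinery is generic over any set of named libraries.

## Virtual digestion and tag indexing (`digest`)

A reference set (transcriptome, EST set, genome) is digested in
silico: every CATG occurrence with a full 17-nt suffix yields one
theoretical tag; `strand_mode="both"` also scans the reverse
complement, which is what lets strand-specific DGE data expose
antisense transcription.  Coordinates are 1-based and inclusive;
`position` is the first base of CATG on the indexed strand, and
minus-strand occurrences also carry the equivalent forward-strand
interval (GFF3 convention).  Windows containing non-ACGT characters
are disqualified rather than expanded: expanding ambiguity codes would
inflate the index, and mapping is exact-match.

A transcript whose 3'-most CATG lies closer than 17 nt to its end
produces a tag that reads into the poly(A) tail.  The *simulator*
always completes such tags with A's (that is what the sequencer
observes); the *index* does not by default, so those tags surface as
orphans — a deliberate, biologically motivated orphan source.  The
`polyA_pad` flag adds the A-completed terminal tags to an index; the
pipeline enables it only for the transcript-quantification stage
(candidate calling), keeping the default index for the mapping
accounting and cutoff scan so the orphan fraction remains visible.

## Mapping (`mapping`)

Exact mapping is hash lookup of each observed tag against the index.
The 3'-most rule — when several distinct observed tags hit the same
(transcript, strand), only those at the maximal position keep the hit —
removes upstream artefacts of incomplete NlaIII digestion.  Ties from
duplicated sequence keep all tied tags (discarding would silently lose
counts).  The rule only demotes hits; a tag that loses all hits
becomes an orphan for that reference set.  It is switched off for
genome contigs, where many transcripts share one record and positional
competition is meaningless.

Genome rescue of orphans tolerates up to two mismatches.  The search
is pigeonhole-seeded: a 21-mer within Hamming distance 2 of a genomic
window must match one of its three 7-mer thirds exactly, so exact
7-mer seeding (sorted integer-coded k-mer array, binary search)
followed by full Hamming verification is lossless.  Mismatches are
allowed at all 21 positions, including the CATG anchor.  The test
suite holds an independent all-window Hamming-scan oracle against it.

Per-reference summaries count mapped / one-match / multi-match /
orphan tags and the mean distinct references hit per mapped tag
("contigs per tag"); with no mapped tag the mean is reported as 0 with
a degenerate flag.  Multi-reference overlaps are reported as
subset counts (which combination of reference sets each tag hits),
sorted descending with percentages, optionally truncated to the top k.

## Normalization and the comparison test (`stats`)

Counts are scaled to counts per million (cpm).  The denominator is the
*pre-filter* library depth (normalization precedes reliability
filtering in the workflow); a `denominator="post"` switch exists
because the convention is not universal.  When two libraries are
compared, the tag universe is the set of tags passing the occurrence
cutoff in at least one library, but cpm values are taken from the
unfiltered counts — treating a count-4 tag as absent would manufacture
spurious zero-against-large splits and inflate the false-positive
rate.

The comparison test models the two libraries as equally likely sources
of each read of a tag.  With pseudo-counts x = round(max(cpm_a,
cpm_b)) and y = round(min(...)) (half-up rounding), the p-value is the
one-sided binomial tail

    p = P(X >= x),   X ~ Binomial(n = x + y, p = 1/2),

computed through the regularized incomplete beta function; the y = 0
case is returned as the exact closed form 2^-x, and x = y = 0 gives
p = 1 (no evidence).  The statistic is symmetric in its arguments and
ignores overdispersion by design — the point of the package is this
tag-count test, not a negative-binomial GLM.  No multiple-testing
correction is applied by default (candidate selection uses raw
p < 0.001); Benjamini–Hochberg is available behind a flag.

Splashplot coordinates summarise three-way comparisons: x =
sign(X1−Xin)·log2|X1−Xin| and likewise y for X2, with |Δ| ≤ 1 cpm
collapsed to 0 — the log2 of a sub-unit difference would be negative
while the change itself is upward, inverting the sign semantics.
Quadrants classify fraction specificity (upper right: overexpressed in
both X1 and X2 relative to Xin).  Fraction correlations are plain
Pearson and Spearman matrices over shared tags.

## Occurrence-cutoff calibration (`noise`)

How many times must a tag be seen to be trusted?  The scan maps the
library at cutoffs 1, 5, 10, 15, 20 and, for each cutoff, reports
observed mapped tags, observed unmapped (noise) tags, and the mean ±
SD of mapped tags over randomized library replicates.  Randomization
preserves the exact count vector (rank-abundance structure) and
redraws tag sequences i.i.d. from the library's empirical base
composition, isolating sequence specificity from abundance structure.
Reference sets can be randomized analogously (same lengths, i.i.d.
bases from pooled composition).

The recommendation applies a one-order-of-magnitude criterion: the
recommended cutoff ends the last step along the cutoff ladder at which
the noise level drops at least tenfold.  The noise series is the
randomized-hit mean when the randomization produces hits at all;
otherwise it is the observed unmapped-tag series.  The fallback
matters in practice: the probability that an i.i.d.
composition-matched random 21-mer equals any particular indexed tag is
of order 1e-12, so the expected number of exact random hits is far
below one for any index that fits in memory, and the randomized means
are zero at every cutoff.  The unmapped series carries the same
signal — singleton sequencing-error tags collapse between cutoffs 1
and 5 and the series is flat afterwards, while genuine transcripts
recur well above 5.

Saturation curves subsample reads without replacement (a tag with
count c contributes c draws; prefix subsets of a random read
permutation give exact hypergeometric marginals) and record distinct
mapped tags at each multiple of the step (200,000 reads by default)
plus the full depth.  Analytic rarefaction closed forms are
deliberately not used; the empirical curve is the object of interest.

## Term enrichment (`enrichment`)

Annotations are propagated over ontology ancestors (is_a parent edges;
cycles rejected with the offending path).  Each (fraction, term) pair
is tested with the exact two-tailed hypergeometric test in its
minimum-likelihood form: sum of all point probabilities no larger than
the observed one, clamped to 1.  Effect size is the Haldane-corrected
(+0.5 on each cell) log2 odds ratio of the 2×2 table.  The default
background is every sequence with at least one propagated annotation —
unannotated sequences carry no information in a term test — and can be
overridden.  A transcript belongs to a fraction's study set when that
fraction has its maximal cpm and the binomial comparison against at
least one other fraction is significant at 0.001.  The significance
threshold for enrichment itself is 1e-5.

## 3'-UTR proximity (`utr`)

Genome-mapped tags that hit no transcript may come from unannotated
3'-UTR sequence.  Transcripts are oriented by their longest
ATG-to-stop ORF over six frames (ties: forward strand, then smallest
start), placed on the genome by exact substring search on both strands
(or imported placements), and flipped when the ORF strand disagrees
with the placement strand.  Each genome-mapped tag within ±1,000 bp of
a strand-consistent transcript 3' end is binned by signed distance
(positive = downstream in transcript orientation, bin width 50 nt),
assigned to the *nearest* 3' end only to avoid double counting.  The
coverage fraction is the share of CATG targets inside the downstream
windows that carry a sequenced tag (window-restricted denominator).
Poly(A) sites are not predicted, and projection is not splice-aware.

## The synthetic study generator (`synthetic`)

The generator emulates the statistical structure the analysis relies
on, with known ground truth:

- 500 random transcripts, length ~ N(500, 150²) nt, 35% GC (AT-rich,
  planarian-like); sequences lacking a full-suffix CATG site are
  redrawn until at least 95% carry one.  Canonical (poly-A padded)
  tags are kept collision-free so each emitted tag traces to exactly
  one transcript.
- Expression: a shared log-normal baseline (meanlog 1.0, sdlog 1.5 —
  heavy-tailed rank-abundance as DGE libraries show) times a
  per-fraction log-normal deviation (sdlog 0.4), because real sorted
  fractions are globally distinct states, not copies differing in a
  handful of genes.  X2 is rebuilt as 0.6·X1 + 0.4·Xin before its own
  planted transcripts are applied, reflecting its mixed composition;
  this makes X1–X2 the most-correlated pair by construction.
  Fraction-specific overexpression is planted at 8-fold on 30 (X1), 8
  (X2) and 20 (Xin) transcripts; columns renormalize to one million.
- Libraries: X1/X2/Xin depths 1,000,000 / 960,000 / 320,000 reads
  (the study design's unequal-depth shape at reduced scale, chosen to
  keep the default analysis and test suite fast while leaving
  per-transcript counts deep enough for the planted effects to be
  unambiguous).  Reads are multinomial in the expression column; 5% of
  a transcript's reads emit the reverse-complement strand's own
  3'-most tag (antisense transcription at lower level than sense); 2%
  of reads come from transcripts withheld from the reference (novel
  transcripts, the orphan source); each emitted 21-mer suffers one
  uniformly placed substitution with probability 0.5% (an artifact
  choice — the platform's post-filter error rate is not published).
  Tag counts sum exactly to the configured depth.
- Genome: transcripts (including withheld ones) embedded verbatim on a
  random strand, ten per contig, separated by Poisson-length spacers.
- Annotations: a three-level toy ontology; one leaf term planted on
  X1-specific transcripts at 4× the background rate.

What the generator does **not** model: read qualities, PCR duplicates,
splice variants, repeat families, assembly errors, composition bias
along transcripts, and any real sequence homology.  Passing tests
therefore demonstrate that the pipeline's logic and statistics behave
as designed under the stated generative model — not that the
biological conclusions of any particular dataset are correct.

## Numerical choices

- Half-up rounding for cpm pseudo-counts (5.73 → 6, 5.22 → 5).
- The y = 0 binomial tail is the exact closed form 2^-x; the general
  case uses `scipy.stats.binom.sf`, cross-checked against explicit
  enumeration up to n = 60 in the tests.
- Minimum-likelihood two-tailed sums use a 1 + 1e-9 relative tolerance
  when comparing point probabilities, guarding floating-point ties.
- The mismatch mapper caps at 2 mismatches (the pigeonhole guarantee
  of 7-mer thirds); degenerate inputs (empty genome, empty sequence)
  yield empty results rather than errors.
- All randomness flows through `numpy.random.Generator` seeded from a
  single study seed (child streams via `SeedSequence.spawn`); equal
  seeds give byte-identical pipeline outputs.

## Problem sizes

Default analyses run on the 500-transcript, ~2.3-million-read
scenario; the test suite uses the same scale for acceptance-style
checks (five seeds) and smaller configurations (120 transcripts,
~10^5 reads) for pipeline smoke tests.  Randomization uses 20–50
replicates in tests and scripts; the full calibration depth of
500 library / 100 reference replicates is available through
`n_rand`.

## Known limitations

- The comparison test reproduces printed reference p-values exactly
  only when the smaller cpm rounds to zero; for two positive cpm the
  original study's internal algorithm (unpublished, possibly
  continuous-valued) deviates from the rounded-count binomial tail by
  up to ~50%, and this package makes no attempt to reverse-engineer
  it.
- Orphan accounting depends on the poly-A padding convention; both
  conventions are exposed and the pipeline's choice per stage is
  stated above.
- The cutoff recommendation's randomized-hit branch is informative
  only for reference sets large enough for chance 21-mer collisions;
  at realistic index sizes the unmapped-tag series is the operative
  signal (see above).
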