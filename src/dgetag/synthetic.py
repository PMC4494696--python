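"""Synthetic DGE study generator with known ground truth.

Emulates the structure of a three-fraction tag-profiling experiment on
FACS-sorted cell populations: a reference transcriptome of AT-rich
random transcripts, a genome with the transcripts embedded between
random spacers, per-fraction expression with a shared log-normal
baseline plus planted fraction-specific overexpression, and tag
libraries of 21-nt CATG-anchored tags drawn multinomially from the
expression profile.  Reads are simulated at tag level only — the
downstream analysis consumes tag counts, so no read-length, quality or
PCR-duplicate model is included.

The three default fractions are named X1 (proliferating stem cells),
X2 (stem-cell progeny plus proliferating cells) and Xin (differentiated
cells); X2 is built as a mixture of X1-like and Xin-like expression,
reflecting its heterogeneous composition.  Library depths are unequal,
with the differentiated fraction sequenced shallowest.

Ground truth (planted expression, DE labels, antisense capability,
withheld "novel" transcripts absent from the reference) is returned in
a :class:`SyntheticTruth` and is what every downstream acceptance check
measures recovery against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import TAG_LENGTH, canonical_3prime_tag, reverse_complement
from .stats import MILLION, TagLibrary

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe the reduced-scale default scenario: 500
    transcripts of mean length 500 nt at 35% GC, three libraries with
    unequal depths, 8-fold overexpression planted per fraction, 5%
    antisense reads, 0.5% per-read substitution error and 2% of reads
    from transcripts withheld from the reference (orphan source).
    """

    n_transcripts: int = 500
    length_mean: float = 500.0
    length_sd: float = 150.0
    gc_fraction: float = 0.35
    library_depths: Mapping[str, int] = field(
        default_factory=lambda: {"X1": 1_000_000, "X2": 960_000, "Xin": 320_000})
    de_spec: Sequence[tuple[str, int, float]] = field(
        default_factory=lambda: [("X1", 30, 8.0), ("X2", 8, 8.0), ("Xin", 20, 8.0)])
    antisense_rate: float = 0.05
    error_rate: float = 0.005
    novel_rate: float = 0.02
    seed: int = 0
    # log-normal baseline: heavy-tailed rank-abundance like real DGE libraries
    log_mean: float = 1.0
    log_sd: float = 1.5
    # per-fraction log-normal deviation from the shared baseline: fractions
    # are globally distinct transcriptional states, not copies with a few
    # planted outliers
    fraction_dispersion: float = 0.4
    # X2 = 0.6 * X1-like + 0.4 * Xin-like (None disables the mixture)
    x2_mixture: tuple[float, float] | None = (0.6, 0.4)
    withheld_fraction: float = 0.05
    min_length: int = 25

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if self.length_mean < TAG_LENGTH:
            raise ValueError(
                f"length_mean {self.length_mean} is shorter than a {TAG_LENGTH} nt tag")
        for name, val in [("gc_fraction", self.gc_fraction),
                          ("antisense_rate", self.antisense_rate),
                          ("error_rate", self.error_rate),
                          ("novel_rate", self.novel_rate),
                          ("withheld_fraction", self.withheld_fraction)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if not self.library_depths:
            raise ValueError("library_depths must name at least one sample")
        for sample, depth in self.library_depths.items():
            if depth <= 0:
                raise ValueError(f"depth for {sample!r} must be positive")
        for sample, n_de, fold in self.de_spec:
            if sample not in self.library_depths:
                raise ValueError(f"de_spec names unknown sample {sample!r}")
            if fold < 1.0:
                raise ValueError("fold changes must be >= 1")
            if n_de < 0 or n_de > self.n_transcripts:
                raise ValueError("de_spec transcript counts out of range")
        if sum(n for _, n, _ in self.de_spec) > self.n_transcripts:
            raise ValueError("de_spec assigns more transcripts than exist")
        if self.fraction_dispersion < 0:
            raise ValueError("fraction_dispersion must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.library_depths)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study (plumbing for validation)."""

    expression: pd.DataFrame | None  # transcripts x samples, expected cpm
    de_labels: dict[str, tuple[str, float]]
    antisense_flags: dict[str, bool]
    withheld_ids: set[str]
    canonical_tags: dict[str, str]  # transcript -> sense 3'-most tag (poly-A padded)
    antisense_tags: dict[str, str]  # transcript -> reverse-strand 3'-most tag
    tagless_ids: set[str]
    withheld_records: list[tuple[str, str]]
    seed: int


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _has_full_tag_site(seq: str) -> bool:
    return canonical_3prime_tag(seq, polyA_pad=False) is not None


def generate_transcriptome(config: SyntheticConfig,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Random transcripts plus ground-truth tag bookkeeping.

    Sequences lacking a full-suffix CATG site are regenerated until at
    least 95% of transcripts carry a valid 3'-most tag site (skipped
    when the base composition makes CATG impossible, e.g. gc=0, in
    which case all transcripts are flagged tagless).  Canonical poly-A
    padded tags are kept collision-free across the whole study so that
    each emitted tag traces to exactly one transcript.

    Returns the *emitted* reference records (withheld novel transcripts
    are carried only inside the truth object).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_ref = config.n_transcripts
    n_novel = (round(config.withheld_fraction * n_ref) if config.novel_rate > 0 else 0)
    n_total = n_ref + n_novel
    ids = [f"tr_{i + 1:04d}" for i in range(n_ref)] + \
          [f"nov_{i + 1:03d}" for i in range(n_novel)]

    lengths = np.maximum(config.min_length,
                         np.round(rng.normal(config.length_mean, config.length_sd,
                                             n_total)).astype(int))
    seqs = [_random_sequence(rng, int(L), config.gc_fraction) for L in lengths]

    catg_possible = 0.0 < config.gc_fraction < 1.0
    if catg_possible:
        for _ in range(100):
            missing = [i for i, s in enumerate(seqs) if not _has_full_tag_site(s)]
            if len(missing) <= 0.05 * n_total:
                break
            for i in missing:
                seqs[i] = _random_sequence(rng, int(lengths[i]), config.gc_fraction)

    # keep canonical (poly-A padded) tags unique across the study
    canonical: dict[str, str] = {}
    seen_tags: set[str] = set()
    tagless: set[str] = set()
    for i, tid in enumerate(ids):
        for _ in range(100):
            tag = canonical_3prime_tag(seqs[i], polyA_pad=True)
            if tag is None:
                tagless.add(tid)
                break
            if tag.sequence not in seen_tags:
                seen_tags.add(tag.sequence)
                canonical[tid] = tag.sequence
                break
            if not catg_possible:  # cannot resolve the collision by redrawing
                tagless.add(tid)
                break
            seqs[i] = _random_sequence(rng, int(lengths[i]), config.gc_fraction)
        else:
            tagless.add(tid)

    antisense_tags: dict[str, str] = {}
    antisense_flags: dict[str, bool] = {}
    for i, tid in enumerate(ids):
        anti = canonical_3prime_tag(reverse_complement(seqs[i]), polyA_pad=True)
        antisense_flags[tid] = anti is not None and tid not in tagless
        if anti is not None:
            antisense_tags[tid] = anti.sequence

    records = list(zip(ids[:n_ref], seqs[:n_ref]))
    withheld_records = list(zip(ids[n_ref:], seqs[n_ref:]))
    truth = SyntheticTruth(
        expression=None,
        de_labels={},
        antisense_flags=antisense_flags,
        withheld_ids=set(ids[n_ref:]),
        canonical_tags=canonical,
        antisense_tags=antisense_tags,
        tagless_ids=tagless,
        withheld_records=withheld_records,
        seed=config.seed,
    )
    if tagless:
        logger.info("%d/%d transcripts carry no CATG site", len(tagless), n_total)
    return records, truth


def simulate_expression(config: SyntheticConfig,
                        rng: np.random.Generator | None = None,
                        transcript_ids: Sequence[str] | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, tuple[str, float]]]:
    """Expected-cpm matrix with planted fraction-specific overexpression.

    A log-normal baseline is shared across fractions, with a
    per-fraction log-normal deviation (``fraction_dispersion``) on top
    so each fraction is a globally distinct state; each ``de_spec``
    entry then multiplies a disjoint random subset of transcripts by
    its fold change in its target sample.  When the X2 mixture is
    configured, the X2 column is rebuilt as a weighted blend of the X1
    and Xin columns (X2 receives no dispersion of its own) before X2's
    own planted transcripts are applied.  All columns are renormalized
    to sum to one million (cpm scale).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = list(transcript_ids) if transcript_ids is not None else \
        [f"tr_{i + 1:04d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("transcript_ids length must equal n_transcripts")

    base = rng.lognormal(config.log_mean, config.log_sd, n)
    mixture = config.x2_mixture
    mix_applies = mixture is not None and {"X1", "X2", "Xin"} <= set(config.samples)
    expr = pd.DataFrame({s: base.copy() for s in config.samples}, index=ids)
    if config.fraction_dispersion > 0:
        for s in config.samples:
            if mix_applies and s == "X2":
                continue  # X2 inherits its deviation through the mixture
            expr[s] *= rng.lognormal(0.0, config.fraction_dispersion, n)

    total_de = sum(n_de for _, n_de, _ in config.de_spec)
    chosen = rng.choice(n, size=total_de, replace=False) if total_de else np.array([], int)
    de_labels: dict[str, tuple[str, float]] = {}
    offset = 0
    assignments: dict[str, list[tuple[np.ndarray, float]]] = {}
    for sample, n_de, fold in config.de_spec:
        idx = chosen[offset:offset + n_de]
        offset += n_de
        assignments.setdefault(sample, []).append((idx, fold))
        for i in idx:
            tid = ids[int(i)]
            if tid in de_labels:
                raise ValueError(f"transcript {tid} assigned to multiple de_spec entries")
            de_labels[tid] = (sample, fold)

    for sample, entries in assignments.items():
        if mix_applies and sample == "X2":
            continue  # planted after the mixture below
        for idx, fold in entries:
            expr.iloc[idx, expr.columns.get_loc(sample)] *= fold
    if mix_applies:
        w1, win = mixture
        expr["X2"] = w1 * expr["X1"] + win * expr["Xin"]
        for idx, fold in assignments.get("X2", []):
            expr.iloc[idx, expr.columns.get_loc("X2")] *= fold

    expr = expr / expr.sum(axis=0) * MILLION
    return expr, de_labels


def simulate_dge_library(transcriptome: Sequence[tuple[str, str]],
                         expression: pd.DataFrame,
                         config: SyntheticConfig,
                         sample_id: str,
                         rng: np.random.Generator | None = None,
                         truth: SyntheticTruth | None = None) -> TagLibrary:
    """Draw one tag library of the configured depth for one fraction.

    Reads are drawn multinomially in proportion to the expression
    column; each read emits its transcript's canonical 3'-most tag
    (poly-A padded when the terminal CATG sits closer than 17 nt to the
    transcript end).  A read is diverted to the reverse-complement
    strand's own 3'-most tag with probability ``antisense_rate``, and
    with probability ``novel_rate`` it is drawn instead from a
    transcript withheld from the reference.  Finally each emitted
    21-mer suffers a single uniformly placed substitution with
    probability ``error_rate``.  Tag counts always sum exactly to the
    configured depth.  Transcripts without any CATG site contribute no
    reads (logged).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if sample_id not in expression.columns:
        raise ValueError(f"expression has no column {sample_id!r}")
    depth = config.library_depths[sample_id]

    if truth is not None:
        canonical = truth.canonical_tags
        anti = truth.antisense_tags
        withheld = [tid for tid, _ in truth.withheld_records if tid in canonical]
    else:
        canonical, anti = {}, {}
        for tid, seq in transcriptome:
            tag = canonical_3prime_tag(seq, polyA_pad=True)
            if tag is not None:
                canonical[tid] = tag.sequence
            rc = canonical_3prime_tag(reverse_complement(seq), polyA_pad=True)
            if rc is not None:
                anti[tid] = rc.sequence
        withheld = []

    ids = [tid for tid, _ in transcriptome]
    weights = expression.loc[ids, sample_id].to_numpy(dtype=float).copy()
    tagged = np.array([tid in canonical for tid in ids])
    n_tagless = int((~tagged).sum())
    if n_tagless:
        logger.info("%s: %d tagless transcripts contribute no reads",
                    sample_id, n_tagless)
    weights[~tagged] = 0.0
    if weights.sum() <= 0:
        raise ValueError("no taggable transcript has positive expression")

    n_novel = rng.binomial(depth, config.novel_rate) if withheld else 0
    counts = rng.multinomial(depth - n_novel, weights / weights.sum())

    tag_counts: dict[str, int] = {}

    def _emit(tid: str, c: int) -> None:
        if c <= 0:
            return
        a = rng.binomial(c, config.antisense_rate) if tid in anti else 0
        if c - a > 0:
            t = canonical[tid]
            tag_counts[t] = tag_counts.get(t, 0) + (c - a)
        if a > 0:
            t = anti[tid]
            tag_counts[t] = tag_counts.get(t, 0) + a

    for tid, c in zip(ids, counts):
        _emit(tid, int(c))
    if n_novel:
        novel_counts = rng.multinomial(n_novel, np.full(len(withheld), 1.0 / len(withheld)))
        for tid, c in zip(withheld, novel_counts):
            _emit(tid, int(c))

    if config.error_rate > 0:
        base_index = {b: i for i, b in enumerate("ACGT")}
        mutated: dict[str, int] = {}
        for tag in list(tag_counts):
            e = rng.binomial(tag_counts[tag], config.error_rate)
            if e == 0:
                continue
            tag_counts[tag] -= e
            positions = rng.integers(0, TAG_LENGTH, e)
            shifts = rng.integers(1, 4, e)
            for pos, shift in zip(positions, shifts):
                new_base = "ACGT"[(base_index[tag[pos]] + shift) % 4]
                mut = tag[:pos] + new_base + tag[pos + 1:]
                mutated[mut] = mutated.get(mut, 0) + 1
            if tag_counts[tag] == 0:
                del tag_counts[tag]
        for tag, c in mutated.items():
            tag_counts[tag] = tag_counts.get(tag, 0) + c

    return TagLibrary(sample_id, tag_counts, depth)


@dataclass(frozen=True)
class Placement:
    """Verbatim embedding of a transcript in a genome contig (1-based, inclusive)."""

    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str


def generate_genome(transcriptome: Sequence[tuple[str, str]],
                    spacer_mean: float = 500.0,
                    rng: np.random.Generator | None = None,
                    gc_fraction: float = 0.35,
                    transcripts_per_contig: int = 10,
                    seed: int | None = None,
                    ) -> tuple[list[tuple[str, str]], list[Placement]]:
    """Embed transcripts verbatim in contigs separated by random spacers.

    Each transcript is placed once, on a random strand (reverse
    complement inserted when minus), with Poisson-length spacers of the
    given mean flanking it.  A spacer mean of zero produces back-to-back
    transcripts and no flanks.
    """
    if not transcriptome:
        raise ValueError("transcriptome is empty")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)

    def spacer() -> str:
        if spacer_mean <= 0:
            return ""
        return _random_sequence(rng, int(rng.poisson(spacer_mean)), gc_fraction)

    contigs: list[tuple[str, str]] = []
    placements: list[Placement] = []
    chunks = [transcriptome[i:i + transcripts_per_contig]
              for i in range(0, len(transcriptome), transcripts_per_contig)]
    for ci, chunk in enumerate(chunks):
        contig_id = f"contig_{ci + 1:03d}"
        parts = [spacer()]
        offset = len(parts[0])
        for tid, seq in chunk:
            strand = "+" if rng.random() < 0.5 else "-"
            insert = seq if strand == "+" else reverse_complement(seq)
            placements.append(Placement(tid, contig_id, offset + 1,
                                        offset + len(insert), strand))
            parts.append(insert)
            offset += len(insert)
            sp = spacer()
            parts.append(sp)
            offset += len(sp)
        contigs.append((contig_id, "".join(parts)))
    return contigs, placements


@dataclass
class SyntheticScenario:
    """One fully generated study: reference, genome, libraries and truth."""

    config: SyntheticConfig
    reference: list[tuple[str, str]]
    truth: SyntheticTruth
    genome: list[tuple[str, str]]
    placements: list[Placement]
    libraries: dict[str, TagLibrary]


def simulate_study(config: SyntheticConfig | None = None,
                   spacer_mean: float = 500.0) -> SyntheticScenario:
    """Generate the whole default scenario deterministically from one seed."""
    config = config if config is not None else SyntheticConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_seq = np.random.default_rng(seeds[0])
    rng_expr = np.random.default_rng(seeds[1])
    rng_gen = np.random.default_rng(seeds[2])
    rng_lib = np.random.default_rng(seeds[3])

    reference, truth = generate_transcriptome(config, rng_seq)
    expr, de_labels = simulate_expression(
        config, rng_expr, transcript_ids=[tid for tid, _ in reference])
    truth.expression = expr
    truth.de_labels = de_labels

    genome, placements = generate_genome(reference + truth.withheld_records,
                                         spacer_mean=spacer_mean, rng=rng_gen,
                                         gc_fraction=config.gc_fraction)
    libraries = {
        sample: simulate_dge_library(reference, expr, config, sample,
                                     rng=rng_lib, truth=truth)
        for sample in config.samples
    }
    return SyntheticScenario(config, reference, truth, genome, placements, libraries)


def simulate_annotations(transcript_ids: Sequence[str],
                         planted_ids: set[str],
                         rng: np.random.Generator | None = None,
                         seed: int | None = None,
                         n_leaf_terms: int = 12,
                         base_rate: float = 0.15,
                         planted_rate: float = 0.6,
                         ) -> tuple[dict[str, set[str]], dict[str, set[str]], str]:
    """Synthetic GO-like annotation with one term planted on a target set.

    Builds a small three-level ontology (root, three mid-level terms,
    ``n_leaf_terms`` leaves) and annotates every transcript with leaves
    at ``base_rate``; the first leaf (the planted term) is assigned to
    transcripts in ``planted_ids`` at ``planted_rate`` instead —
    a 4x enrichment under the defaults.  Returns (direct annotations,
    parent edges, planted term id).
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    root = "T:0000"
    mids = [f"T:{m:02d}00" for m in (1, 2, 3)]
    leaves = [f"T:{(m % 3) + 1:02d}{m // 3 + 1:02d}" for m in range(n_leaf_terms)]
    edges: dict[str, set[str]] = {m: {root} for m in mids}
    for i, leaf in enumerate(leaves):
        edges[leaf] = {mids[i % 3]}
    planted_term = leaves[0]

    direct: dict[str, set[str]] = {}
    for tid in transcript_ids:
        terms = set()
        for leaf in leaves:
            rate = planted_rate if (leaf == planted_term and tid in planted_ids) \
                else base_rate
            if rng.random() < rate:
                terms.add(leaf)
        if not terms:
            terms.add(leaves[int(rng.integers(len(leaves)))])
        direct[tid] = terms
    return direct, edges, planted_term
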