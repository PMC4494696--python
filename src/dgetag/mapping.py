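"""Mapping observed tag libraries against theoretical tag indexes.

Exact (hash) lookup against transcriptome indexes with 3'-most
resolution, mismatch-tolerant search against genome sequences, Table-1
style per-reference summaries and multi-reference overlap counting.

The 3'-most rule: when several distinct observed tags hit the same
(reference, strand), only the tag(s) at the maximal position keep that
hit — sequencing reads only the 3'-most CATG of a transcript, so
upstream matches are artefacts.  The rule demotes individual hits but
never deletes a tag's record; a tag losing all its hits becomes an
orphan for that reference set.  Position ties (duplicated sequence)
keep all tied tags rather than discarding counts silently.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import numpy as np
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digest import TAG_LENGTH, TagIndex, reverse_complement
from .stats import TagLibrary

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass
class MappingRecord:
    tag: str
    reference_set: str
    hits: list[tuple[str, int, str, int]]  # (reference_id, position, strand, mismatches)
    status: str  # 'one_match', 'multi_match' or 'orphan'
    sense: str  # 'sense', 'antisense', 'both' or 'none'

    @property
    def references_hit(self) -> set[str]:
        return {h[0] for h in self.hits}


@dataclass
class MappingSummary:
    """Per-reference mapping accounting (mapped = one_match + multi_match)."""

    reference_set: str
    mapped: int
    one_match: int
    multi_match: int
    orphan: int
    contigs_per_tag: float
    degenerate: bool = False  # no mapped tag at all; contigs_per_tag reported as 0


def _classify_sense(hits: Sequence[tuple[str, int, str, int]]) -> str:
    strands = {h[2] for h in hits}
    if not strands:
        return "none"
    if strands == {"+"}:
        return "sense"
    if strands == {"-"}:
        return "antisense"
    return "both"


def map_tags_exact(library: TagLibrary, index: TagIndex,
                   three_prime_rule: bool = True) -> list[MappingRecord]:
    """Exact-match every library tag against an index, with 3'-most resolution.

    Malformed tags (wrong length or alphabet) are skipped with a warning
    count; every well-formed tag gets exactly one record.  The 3'-most
    rule assumes each reference record is one transcript; disable it
    (``three_prime_rule=False``) when mapping against genome contigs,
    where many transcripts share a record and positional competition is
    meaningless.
    """
    raw_hits: dict[str, list] = {}
    skipped = 0
    for tag in library.counts:
        if len(tag) != TAG_LENGTH or set(tag) - _VALID:
            skipped += 1
            continue
        raw_hits[tag] = index.lookup(tag)
    if skipped:
        logger.warning("%d malformed tags skipped during mapping", skipped)

    # 3'-most resolution: maximal position per (reference_id, strand)
    best: dict[tuple[str, str], int] = {}
    if three_prime_rule:
        for occs in raw_hits.values():
            for occ in occs:
                key = (occ.reference_id, occ.strand)
                if occ.position > best.get(key, 0):
                    best[key] = occ.position

    records = []
    for tag, occs in raw_hits.items():
        kept = [(o.reference_id, o.position, o.strand, 0) for o in occs
                if not three_prime_rule
                or o.position == best[(o.reference_id, o.strand)]]
        refs = {h[0] for h in kept}
        status = "orphan" if not kept else ("one_match" if len(refs) == 1 else "multi_match")
        records.append(MappingRecord(tag, index.name, kept, status, _classify_sense(kept)))
    return records


def summarize_mapping(records: Sequence[MappingRecord],
                      library: TagLibrary | None = None) -> MappingSummary:
    """Count mapped / one-match / multi-match / orphan tags for one reference."""
    if not records:
        return MappingSummary("", 0, 0, 0, 0, 0.0, degenerate=True)
    name = records[0].reference_set
    mapped = one = multi = orphan = 0
    refs_total = 0
    for rec in records:
        if rec.status == "orphan":
            orphan += 1
            continue
        mapped += 1
        n_refs = len(rec.references_hit)
        refs_total += n_refs
        if n_refs == 1:
            one += 1
        else:
            multi += 1
    degenerate = mapped == 0
    cpt = 0.0 if degenerate else refs_total / mapped
    return MappingSummary(name, mapped, one, multi, orphan, cpt, degenerate)


def reference_overlap(records_by_set: Mapping[str, Sequence[MappingRecord]],
                      top_k: int | None = None) -> list[tuple[tuple[str, ...], int, float]]:
    """Venn-stave subset counts: which reference-set combination each tag hits.

    Every tag mapped in at least one set contributes to exactly one
    subset (the full combination of sets where it has >= 1 hit).
    Returns (subset, count, percent-of-mapped) sorted descending, with
    optional top-k truncation.
    """
    membership: dict[str, set[str]] = defaultdict(set)
    for set_name, records in records_by_set.items():
        for rec in records:
            if rec.status != "orphan":
                membership[rec.tag].add(set_name)
    counts = Counter(tuple(sorted(sets)) for sets in membership.values())
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[:top_k]
    return [(subset, n, 100.0 * n / total if total else 0.0) for subset, n in ranked]


# ---------------------------------------------------------------------------
# mismatch mapping against genome sequences


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    """Hamming distance, or limit+1 as soon as it is exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


class GenomeSeedIndex:
    """Pigeonhole seed index over genome 7-mers for <=2-mismatch tag search.

    A 21-mer with at most two mismatches must match at least one of its
    three 7-nt thirds exactly, so exact 7-mer seeding followed by full
    Hamming verification is lossless for the mismatch budget used here.
    Mismatches are allowed at any of the 21 positions, including the
    CATG anchor.  Seeds are stored as a sorted integer-coded k-mer
    array queried by binary search; windows containing non-ACGT bases
    never seed.
    """

    PART = 7

    def __init__(self, genome: Sequence[tuple[str, str]]):
        self.contigs = [(cid, seq.upper()) for cid, seq in genome]
        seqs = [seq for _, seq in self.contigs]
        # concatenate with N spacers so no seed spans a contig boundary
        joined = ("N" * self.PART).join(seqs)
        offsets = []
        off = 0
        for s in seqs:
            offsets.append(off)
            off += len(s) + self.PART
        self._offsets = np.asarray(offsets, dtype=np.int64)
        self._lengths = np.asarray([len(s) for s in seqs], dtype=np.int64)

        lut = np.full(256, 4, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        codes = lut[np.frombuffer(joined.encode(), dtype=np.uint8)]
        n_windows = len(codes) - self.PART + 1
        if n_windows <= 0:
            self._kmers = np.empty(0, dtype=np.int64)
            self._positions = np.empty(0, dtype=np.int64)
            return
        kmers = np.zeros(n_windows, dtype=np.int64)
        bad = np.zeros(n_windows, dtype=bool)
        for j in range(self.PART):
            col = codes[j:j + n_windows]
            kmers = kmers * 4 + col
            bad |= col > 3
        positions = np.nonzero(~bad)[0]
        kmers = kmers[~bad]
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._positions = positions[order]

    def _seed_positions(self, seed: str):
        code = 0
        for ch in seed:
            v = "ACGT".find(ch)
            if v < 0:
                return np.empty(0, dtype=np.int64)
            code = code * 4 + v
        lo = np.searchsorted(self._kmers, code, "left")
        hi = np.searchsorted(self._kmers, code, "right")
        return self._positions[lo:hi]

    def search(self, tag: str, max_mismatches: int) -> list[tuple[str, int, str, int]]:
        """All genomic windows (both strands) within the Hamming budget.

        Hits are (contig, 1-based forward start of the 21-mer window,
        strand, mismatches); a minus-strand hit means the tag matches
        the reverse complement of that forward window.
        """
        if max_mismatches > 2:
            raise ValueError("pigeonhole seeding supports at most 2 mismatches")
        found: dict[tuple[int, int, str], int] = {}
        for query, strand in ((tag, "+"), (reverse_complement(tag), "-")):
            for part_start in range(0, TAG_LENGTH - self.PART + 1, self.PART):
                seed = query[part_start:part_start + self.PART]
                for gpos in self._seed_positions(seed):
                    ci = int(np.searchsorted(self._offsets, gpos, "right")) - 1
                    start = int(gpos) - int(self._offsets[ci]) - part_start
                    if start < 0 or start + TAG_LENGTH > int(self._lengths[ci]):
                        continue
                    key = (ci, start, strand)
                    if key in found:
                        continue
                    seq = self.contigs[ci][1]
                    d = _hamming_at_most(query, seq[start:start + TAG_LENGTH],
                                         max_mismatches)
                    if d <= max_mismatches:
                        found[key] = d
        return sorted((self.contigs[ci][0], start + 1, strand, d)
                      for (ci, start, strand), d in found.items())


def map_tags_mismatch(tags: Iterable[str],
                      genome: Sequence[tuple[str, str]],
                      max_mismatches: int = 2,
                      seed_index: GenomeSeedIndex | None = None,
                      ) -> dict[str, list[tuple[str, int, str, int]]]:
    """Hamming-tolerant search of tags against genome contigs (both strands).

    Intended for tags orphaned by exact transcriptome mapping; with
    ``max_mismatches=0`` it reduces to exact genome mapping.  An empty
    genome leaves every tag an orphan (empty hit list).
    """
    if not 0 <= max_mismatches <= 2:
        raise ValueError("max_mismatches must be 0, 1 or 2")
    if seed_index is None:
        seed_index = GenomeSeedIndex(genome)
    return {tag: seed_index.search(tag.upper(), max_mismatches) for tag in tags}
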