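"""3'-UTR tag proximity: do genome-only tags cluster near transcript ends?

Tags that map to the genome but to no transcript may come from
unannotated 3'-UTR sequence — DGE libraries are built from the 3' end,
so such tags should sit just downstream of annotated transcript
termini.  Transcripts are oriented by their longest ORF, placed on the
genome by exact substring search (or imported placements), and
genome-mapped tags are histogrammed by signed distance to the nearest
3' terminus within a +/-1,000 bp window.  Poly(A) sites are not
predicted.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digest import ANCHOR, TAG_LENGTH, reverse_complement

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> tuple[str, int, int, int] | None:
    """Longest ATG-to-stop open reading frame over all six frames.

    Returns (strand, frame, start, length): start is the 1-based
    position of the ATG on the reported strand, length in nucleotides
    including the stop codon.  Ties prefer the forward strand, then the
    smallest start.  Returns None when no complete ORF exists.
    """
    sequence = sequence.upper()
    if len(sequence) < 6:
        raise ValueError("sequence shorter than 6 nt cannot hold an ORF")
    best: tuple[int, int, str, int, int] | None = None  # (-len, strand_rank, ...)

    for strand_rank, (strand, seq) in enumerate(
            (("+", sequence), ("-", reverse_complement(sequence)))):
        for frame in range(3):
            i = frame
            open_start: int | None = None
            while i + 3 <= len(seq):
                codon = seq[i:i + 3]
                if open_start is None and codon == "ATG":
                    open_start = i
                elif open_start is not None and codon in _STOPS:
                    length = i + 3 - open_start
                    key = (-length, strand_rank, open_start)
                    if best is None or key < best[:3]:
                        best = (-length, strand_rank, open_start, frame, length)
                    open_start = None
                i += 3
    if best is None:
        return None
    _, strand_rank, start0, frame, length = best
    return ("+" if strand_rank == 0 else "-", frame, start0 + 1, length)


@dataclass
class TranscriptPlacement:
    """A transcript located on the genome, oriented by its longest ORF.

    ``strand`` is the effective transcript orientation on the genome:
    the placement strand, flipped when the longest ORF lies on the
    transcript's reverse strand.  ``three_prime_pos`` is the genomic
    coordinate of the transcript 3' end under that orientation (the
    placement end on '+', the start on '-').
    """

    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str
    orf_strand: str
    three_prime_pos: int
    ambiguous: bool = False


def _orient(transcript_id: str, contig: str, start: int, end: int,
            placement_strand: str, orf_strand: str, ambiguous: bool,
            ) -> TranscriptPlacement:
    flip = orf_strand == "-"
    strand = placement_strand if not flip else ("-" if placement_strand == "+" else "+")
    three_prime = end if strand == "+" else start
    return TranscriptPlacement(transcript_id, contig, start, end, strand,
                               orf_strand, three_prime, ambiguous)


def place_transcripts(transcripts: Sequence[tuple[str, str]],
                      genome: Sequence[tuple[str, str]],
                      external_placements: Sequence | None = None,
                      ) -> tuple[list[TranscriptPlacement], list[str]]:
    """Locate transcripts on the genome and orient them by longest ORF.

    Placements are found by exact substring search on both strands
    (the synthetic path embeds transcripts verbatim); alternatively
    pre-computed placements with (transcript_id, contig, start, end,
    strand) attributes can be supplied.  Multiple exact placements are
    all reported, flagged ambiguous.  Returns (placements, ids of
    unplaceable transcripts).
    """
    orf_strands: dict[str, str] = {}
    for tid, seq in transcripts:
        orf = longest_orf(seq) if len(seq) >= 6 else None
        orf_strands[tid] = orf[0] if orf is not None else "+"

    placements: list[TranscriptPlacement] = []
    unplaced: list[str] = []

    if external_placements is not None:
        placed_ids = set()
        for p in external_placements:
            placements.append(_orient(p.transcript_id, p.contig, p.start, p.end,
                                      p.strand, orf_strands.get(p.transcript_id, "+"),
                                      False))
            placed_ids.add(p.transcript_id)
        unplaced = [tid for tid, _ in transcripts if tid not in placed_ids]
        return placements, unplaced

    contigs = [(cid, seq.upper()) for cid, seq in genome]
    for tid, seq in transcripts:
        seq = seq.upper()
        rc = reverse_complement(seq)
        found: list[tuple[str, int, int, str]] = []
        for cid, contig_seq in contigs:
            for query, strand in ((seq, "+"), (rc, "-")):
                start = contig_seq.find(query)
                while start != -1:
                    found.append((cid, start + 1, start + len(query), strand))
                    start = contig_seq.find(query, start + 1)
        if not found:
            unplaced.append(tid)
            continue
        ambiguous = len(found) > 1
        for cid, start, end, strand in found:
            placements.append(_orient(tid, cid, start, end, strand,
                                      orf_strands[tid], ambiguous))
    return placements, unplaced


@dataclass
class ProximityProfile:
    """Histogram of genome-tag positions relative to transcript 3' ends.

    Bins are keyed by their left edge in signed distance (negative =
    upstream of the 3' end in transcript orientation); ``fraction_covered``
    is the share of CATG targets in the downstream windows that carry a
    sequenced tag.
    """

    window: int
    bin_width: int
    histogram: dict[int, int] = field(default_factory=dict)
    n_assigned: int = 0
    fraction_covered: float = 0.0


def _tag_anchor_position(position: int, strand: str) -> int:
    """Forward-genome coordinate of the CATG start of a mapped tag.

    ``position`` is the forward start of the 21-mer window; on the minus
    strand the CATG anchor sits at the window's forward end.
    """
    return position if strand == "+" else position + TAG_LENGTH - 1


def proximity_profile(placements: Sequence[TranscriptPlacement],
                      genome_hits: Iterable[tuple[str, str, int, str]],
                      genome: Sequence[tuple[str, str]],
                      window: int = 1000,
                      bin_width: int = 50) -> ProximityProfile:
    """Bin genome-mapped tags by signed distance to the nearest 3' end.

    ``genome_hits`` are (tag, contig, forward-start, strand) records.
    Only strand-consistent placements count (the tag must lie on the
    transcript's oriented strand); each tag is assigned to the nearest
    3' end only, and distances beyond ``window`` are excluded.
    Positive distance = downstream of the 3' end in transcript
    orientation.
    """
    by_contig: dict[tuple[str, str], list[TranscriptPlacement]] = defaultdict(list)
    for p in placements:
        by_contig[(p.contig, p.strand)].append(p)

    profile = ProximityProfile(window, bin_width)
    for tag, contig, position, strand in genome_hits:
        anchor = _tag_anchor_position(position, strand)
        best_d: int | None = None
        for p in by_contig.get((contig, strand), ()):
            d = anchor - p.three_prime_pos if p.strand == "+" \
                else p.three_prime_pos - anchor
            if abs(d) <= window and (best_d is None or abs(d) < abs(best_d)):
                best_d = d
        if best_d is None:
            continue
        bin_start = int(math.floor(best_d / bin_width)) * bin_width
        profile.histogram[bin_start] = profile.histogram.get(bin_start, 0) + 1
        profile.n_assigned += 1

    # CATG-target coverage of the downstream windows
    hit_anchors = {(contig, strand, _tag_anchor_position(pos, strand))
                   for _, contig, pos, strand in genome_hits}
    contig_seqs = dict((cid, seq.upper()) for cid, seq in genome)
    total_sites = covered = 0
    for p in placements:
        seq = contig_seqs.get(p.contig)
        if seq is None:
            continue
        if p.strand == "+":
            lo, hi = p.three_prime_pos, min(len(seq), p.three_prime_pos + window)
            region = seq[lo - 1:hi]
            sites = [lo + i for i in range(len(region))
                     if region[i:i + len(ANCHOR)] == ANCHOR]
        else:
            lo, hi = max(1, p.three_prime_pos - window), p.three_prime_pos
            region = seq[lo - 1:hi]
            # CATG on the minus strand reads CATG in forward sequence too
            sites = [lo + i + len(ANCHOR) - 1 for i in range(len(region))
                     if region[i:i + len(ANCHOR)] == ANCHOR]
        for site in sites:
            total_sites += 1
            if (p.contig, p.strand, site) in hit_anchors:
                covered += 1
    profile.fraction_covered = covered / total_sites if total_sites else 0.0
    return profile
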