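"""Virtual NlaIII/MmeI digestion of reference sequence sets.

DGE tag profiling reads a fixed-length sequence tag from each
polyadenylated transcript: NlaIII cuts at its recognition site CATG,
retaining the fragment from the 3'-most CATG to the poly(A) tail, and
MmeI then cuts 17 bp downstream of the site, so every tag is a 21-mer
``CATG + 17 nt``.  This module performs the *virtual* digestion: it
enumerates every theoretical tag a reference sequence could produce
(one per CATG occurrence with a full-length suffix), identifies the
canonical 3'-most tag of a transcript, and builds an exact-lookup tag
index over a whole reference set.

Coordinates are 1-based and inclusive; ``position`` is the first base
of the CATG site on the indexed strand.  Reverse-strand occurrences
also carry the equivalent forward-strand interval so they can be
projected onto genome annotation.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

TAG_LENGTH = 21
ANCHOR = "CATG"
SUFFIX_LENGTH = TAG_LENGTH - len(ANCHOR)  # 17 nt cut off by MmeI

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGT")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TheoreticalTag:
    """One CATG-anchored 21-mer a reference sequence can produce.

    ``position`` is 1-based on the indexed strand (for ``strand == '-'``
    it runs along the reverse complement); ``fwd_start``/``fwd_end``
    give the same window in forward-strand coordinates.
    """

    sequence: str
    reference_id: str
    position: int
    strand: str
    is_3prime_most: bool = False
    fwd_start: int = 0
    fwd_end: int = 0

    def __post_init__(self) -> None:
        if not self.sequence.startswith(ANCHOR):
            raise ValueError(f"tag does not start with {ANCHOR}: {self.sequence}")
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag length != {TAG_LENGTH}: {self.sequence}")


def _scan_one_strand(sequence: str, reference_id: str, strand: str,
                     seq_length: int) -> list[TheoreticalTag]:
    """All full-suffix CATG windows of one strand (sequence given 5'->3')."""
    tags = []
    start = sequence.find(ANCHOR)
    while start != -1:
        window = sequence[start:start + TAG_LENGTH]
        if len(window) == TAG_LENGTH and not (set(window) - _VALID):
            pos = start + 1
            if strand == "+":
                fwd_start, fwd_end = pos, pos + TAG_LENGTH - 1
            else:
                fwd_end = seq_length - pos + 1
                fwd_start = fwd_end - TAG_LENGTH + 1
            tags.append(TheoreticalTag(window, reference_id, pos, strand,
                                       fwd_start=fwd_start, fwd_end=fwd_end))
        start = sequence.find(ANCHOR, start + 1)
    return tags


def _mark_3prime_most(tags: list[TheoreticalTag]) -> list[TheoreticalTag]:
    best: dict[tuple[str, str], int] = {}
    for t in tags:
        key = (t.reference_id, t.strand)
        if t.position > best.get(key, 0):
            best[key] = t.position
    return [dataclasses.replace(t, is_3prime_most=(t.position == best[(t.reference_id, t.strand)]))
            for t in tags]


def extract_theoretical_tags(sequence: str, reference_id: str = "",
                             strand_mode: str = "forward") -> list[TheoreticalTag]:
    """Enumerate every theoretical CATG+17 tag of a sequence.

    Windows containing non-ACGT characters (N, ambiguity codes) are
    disqualified rather than expanded.  ``strand_mode='both'`` also
    scans the reverse complement, which is what allows strand-specific
    DGE data to reveal antisense transcription.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    sequence = sequence.upper()
    n = len(sequence)
    tags = _scan_one_strand(sequence, reference_id, "+", n)
    if strand_mode == "both":
        tags += _scan_one_strand(reverse_complement(sequence), reference_id, "-", n)
    return _mark_3prime_most(tags)


def canonical_3prime_tag(sequence: str, reference_id: str = "",
                         polyA_pad: bool = False) -> TheoreticalTag | None:
    """The tag sequencing would observe: the 3'-most CATG of the transcript.

    Without ``polyA_pad`` the 3'-most CATG carrying a full 17-nt suffix is
    returned (falling back past terminal sites with short suffixes).  With
    ``polyA_pad`` a terminal CATG with fewer than 17 following bases is
    completed with A's — the poly(A) tail the sequenced cDNA actually has.
    Returns None when no qualifying site exists.
    """
    sequence = sequence.upper()
    n = len(sequence)
    positions = []
    start = sequence.find(ANCHOR)
    while start != -1:
        positions.append(start)
        start = sequence.find(ANCHOR, start + 1)
    for start in reversed(positions):
        window = sequence[start:start + TAG_LENGTH]
        if set(window) - _VALID:
            continue
        if len(window) == TAG_LENGTH:
            return TheoreticalTag(window, reference_id, start + 1, "+", True,
                                  fwd_start=start + 1, fwd_end=start + TAG_LENGTH)
        if polyA_pad:
            padded = window + "A" * (TAG_LENGTH - len(window))
            return TheoreticalTag(padded, reference_id, start + 1, "+", True,
                                  fwd_start=start + 1, fwd_end=n)
    return None


@dataclass
class TagIndex:
    """Exact-lookup database of the theoretical tags of one reference set."""

    name: str
    tags: dict[str, list[TheoreticalTag]] = field(default_factory=dict)
    n_references: int = 0
    strand_mode: str = "both"

    def lookup(self, tag: str) -> list[TheoreticalTag]:
        return self.tags.get(tag, [])

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.tags.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# tag\treference_id\tposition\tstrand\tis_3prime_most\n")
            for tag in sorted(self.tags):
                for occ in self.tags[tag]:
                    fh.write(f"{tag}\t{occ.reference_id}\t{occ.position}\t"
                             f"{occ.strand}\t{int(occ.is_3prime_most)}\n")


def _iter_records(reference: str | Path | Iterable) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA path, SeqRecords, or (id, seq) pairs."""
    if isinstance(reference, (str, Path)):
        for rec in SeqIO.parse(str(reference), "fasta"):
            yield rec.id, str(rec.seq)
        return
    for item in reference:
        if hasattr(item, "id") and hasattr(item, "seq"):
            yield item.id, str(item.seq)
        else:
            name, seq = item
            yield name, str(seq)


def build_tag_index(reference: str | Path | Iterable, name: str,
                    strand_mode: str = "both",
                    polyA_pad: bool = False) -> TagIndex:
    """Virtually digest a whole reference set into a :class:`TagIndex`.

    Duplicate record ids are rejected; duplicate tag *sequences* across
    references simply accumulate occurrences, which is what drives the
    one-match / multi-match accounting downstream.

    With ``polyA_pad`` (off by default) the A-completed tag of a
    terminal CATG closer than 17 nt to a sequence end is also indexed;
    without it such transcripts are represented by the next full-suffix
    site upstream, so libraries from poly(A)-padded cDNA leave a small
    orphan fraction.
    """
    index = TagIndex(name=name, strand_mode=strand_mode)
    seen_ids: set[str] = set()
    for ref_id, seq in _iter_records(reference):
        if ref_id in seen_ids:
            raise ValueError(f"duplicate FASTA id in reference {name!r}: {ref_id}")
        seen_ids.add(ref_id)
        for tag in extract_theoretical_tags(seq, ref_id, strand_mode):
            index.tags.setdefault(tag.sequence, []).append(tag)
        if polyA_pad:
            strands = [(seq, "+")]
            if strand_mode == "both":
                strands.append((reverse_complement(seq.upper()), "-"))
            for oriented, strand in strands:
                padded = canonical_3prime_tag(oriented, ref_id, polyA_pad=True)
                if padded is None:
                    continue
                occ = dataclasses.replace(padded, strand=strand)
                existing = index.tags.get(occ.sequence, [])
                if not any(o.reference_id == ref_id and o.strand == strand
                           and o.position == occ.position for o in existing):
                    index.tags.setdefault(occ.sequence, []).append(occ)
    index.n_references = len(seen_ids)
    return index
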