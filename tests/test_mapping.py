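"""Exact and mismatch tag mapping, 3'-most resolution, summaries, overlaps."""

import numpy as np
import pytest

from dgetag.digest import build_tag_index, reverse_complement
from dgetag.mapping import (GenomeSeedIndex, MappingRecord, map_tags_exact,
                            map_tags_mismatch, reference_overlap,
                            summarize_mapping)
from dgetag.stats import filter_by_cutoff, make_library


def _transcript_with_two_sites():
    """One transcript with CATG sites at positions 21 and 61 (full suffixes)."""
    filler = "ACCGTTACCGTTACCGTTAC"  # 20 nt, no CATG
    seq = filler + "CATG" + "ACGTACGTACGTACGTA" + filler[:19] + \
        "CATG" + "TTGGCCAATTGGCCAAT" + filler
    return seq


def naive_hamming_hits(tag, genome, max_mm):
    """Oracle: score every 21-mer window on both strands with numpy."""
    hits = []
    for cid, seq in genome:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for query, strand in ((tag, "+"), (reverse_complement(tag), "-")):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            if len(arr) < 21:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, 21)
            dists = (windows != q).sum(axis=1)
            for pos in np.nonzero(dists <= max_mm)[0]:
                hits.append((cid, int(pos) + 1, strand, int(dists[pos])))
    return sorted(hits)


class TestExactMapping:
    def test_canonical_tag_is_one_match_sense(self):
        seq = "AACATGACGTACGTACGTACGTACC"
        index = build_tag_index([("t1", seq)], "ref", "forward")
        lib = make_library("s", {"CATGACGTACGTACGTACGTA": 10})
        (rec,) = map_tags_exact(lib, index)
        assert rec.status == "one_match" and rec.sense == "sense"

    def test_3prime_most_rule_demotes_upstream_tag(self):
        seq = _transcript_with_two_sites()
        index = build_tag_index([("t1", seq)], "ref", "forward")
        up_tag = seq[20:41]
        down_tag = seq[60:81]
        lib = make_library("s", {up_tag: 5, down_tag: 5})
        records = {r.tag: r for r in map_tags_exact(lib, index)}
        assert records[down_tag].status == "one_match"
        assert records[up_tag].status == "orphan"

    def test_upstream_tag_maps_when_alone(self):
        """The 3'-most rule compares observed tags, not theoretical sites."""
        seq = _transcript_with_two_sites()
        index = build_tag_index([("t1", seq)], "ref", "forward")
        up_tag = seq[20:41]
        (rec,) = map_tags_exact(make_library("s", {up_tag: 5}), index)
        assert rec.status == "one_match"

    def test_genome_contigs_mapped_without_positional_competition(self):
        """Many transcripts share a contig: the 3'-most rule must be off."""
        seq = _transcript_with_two_sites()
        up_tag, down_tag = seq[20:41], seq[60:81]
        index = build_tag_index([("contig", seq)], "genome", "forward")
        lib = make_library("s", {up_tag: 5, down_tag: 5})
        with_rule = {r.tag: r.status for r in map_tags_exact(lib, index)}
        without = {r.tag: r.status
                   for r in map_tags_exact(lib, index, three_prime_rule=False)}
        assert with_rule[up_tag] == "orphan"
        assert without[up_tag] == without[down_tag] == "one_match"

    def test_zero_noise_library_has_no_orphans(self, clean_scenario):
        index = build_tag_index(clean_scenario.reference, "ref", "both",
                                polyA_pad=True)
        for lib in clean_scenario.libraries.values():
            records = map_tags_exact(filter_by_cutoff(lib, 5), index)
            assert all(r.status != "orphan" for r in records)
            # poly-A padded tags of different transcripts can coincide across
            # strands, so a stray 'both' is possible; pure antisense is not
            assert all(r.sense != "antisense" for r in records)
            sense = sum(r.sense == "sense" for r in records)
            assert sense >= 0.99 * len(records)

    def test_indexed_canonicals_always_map(self, clean_scenario):
        """Exact mapping is symmetric to index construction."""
        index = build_tag_index(clean_scenario.reference, "ref", "both")
        tags = {t: 10 for t in list(index.tags)[:200]}
        records = map_tags_exact(make_library("s", tags), index)
        # a theoretical tag can only be demoted by a more-3' observed tag,
        # and here every observed tag is itself theoretical
        orphans = [r for r in records if r.status == "orphan"]
        for r in orphans:
            occs = index.lookup(r.tag)
            assert all(not o.is_3prime_most for o in occs)


class TestSummary:
    def _records(self):
        return [
            MappingRecord("A" * 21, "ref", [("c1", 5, "+", 0)], "one_match", "sense"),
            MappingRecord("C" * 21, "ref", [("c1", 9, "+", 0), ("c2", 3, "+", 0)],
                          "multi_match", "sense"),
            MappingRecord("G" * 21, "ref", [], "orphan", "none"),
        ]

    def test_counts_and_contigs_per_tag(self):
        s = summarize_mapping(self._records())
        assert (s.mapped, s.one_match, s.multi_match, s.orphan) == (2, 1, 1, 1)
        assert s.contigs_per_tag == pytest.approx(1.5)
        assert s.mapped == s.one_match + s.multi_match

    def test_all_orphan_is_degenerate(self):
        records = [MappingRecord("G" * 21, "ref", [], "orphan", "none")]
        s = summarize_mapping(records)
        assert s.degenerate and s.contigs_per_tag == 0.0

    def test_summary_matches_independent_tally(self, default_scenario):
        index = build_tag_index(default_scenario.reference, "ref", "both")
        lib = filter_by_cutoff(default_scenario.libraries["X1"], 5)
        records = map_tags_exact(lib, index)
        s = summarize_mapping(records)
        mapped = sum(1 for r in records if r.hits)
        orphan = sum(1 for r in records if not r.hits)
        assert (s.mapped, s.orphan) == (mapped, orphan)
        assert s.mapped + s.orphan == len(records)


class TestReferenceOverlap:
    def _rec(self, tag, name, hit):
        hits = [(hit, 1, "+", 0)] if hit else []
        return MappingRecord(tag, name, hits,
                             "one_match" if hit else "orphan",
                             "sense" if hit else "none")

    def test_three_equal_subsets(self):
        t1, t2, t3 = "A" * 21, "C" * 21, "G" * 21
        by_set = {
            "A": [self._rec(t1, "A", "x"), self._rec(t2, "A", None),
                  self._rec(t3, "A", "x")],
            "B": [self._rec(t1, "B", None), self._rec(t2, "B", "y"),
                  self._rec(t3, "B", "y")],
        }
        result = dict((subset, (n, pct)) for subset, n, pct in
                      reference_overlap(by_set))
        assert result[("A",)][0] == result[("B",)][0] == result[("A", "B")][0] == 1
        assert result[("A",)][1] == pytest.approx(33.33, abs=0.01)

    def test_full_intersection_membership_only(self):
        tag = "A" * 21
        by_set = {name: [self._rec(tag, name, "x")] for name in "ABC"}
        result = reference_overlap(by_set)
        assert result == [(("A", "B", "C"), 1, 100.0)]

    def test_subset_counts_match_set_algebra(self, clean_scenario):
        """A reference missing 20% of transcripts: counts equal brute-force algebra."""
        full = clean_scenario.reference
        partial = full[: int(0.8 * len(full))]
        idx_full = build_tag_index(full, "full", "both", polyA_pad=True)
        idx_part = build_tag_index(partial, "part", "both", polyA_pad=True)
        lib = filter_by_cutoff(clean_scenario.libraries["X1"], 5)
        by_set = {"full": map_tags_exact(lib, idx_full),
                  "part": map_tags_exact(lib, idx_part)}
        got = dict((s, n) for s, n, _ in reference_overlap(by_set))
        in_full = {r.tag for r in by_set["full"] if r.status != "orphan"}
        in_part = {r.tag for r in by_set["part"] if r.status != "orphan"}
        expected = {("full",): len(in_full - in_part),
                    ("full", "part"): len(in_full & in_part),
                    ("part",): len(in_part - in_full)}
        expected = {k: v for k, v in expected.items() if v}
        assert got == expected

    def test_orphan_fraction_shrinks_under_reference_union(self, clean_scenario):
        full = clean_scenario.reference
        half = full[: len(full) // 2]
        lib = filter_by_cutoff(clean_scenario.libraries["Xin"], 5)
        orphans = []
        for records in (map_tags_exact(lib, build_tag_index(half, "h", "both")),
                        map_tags_exact(lib, build_tag_index(full, "f", "both"))):
            orphans.append(sum(1 for r in records if r.status == "orphan"))
        assert orphans[1] <= orphans[0]


class TestMismatchMapping:
    def _genome(self, rng, n=20_000):
        bases = np.array(list("ACGT"))
        return [("g1", "".join(rng.choice(bases, n, p=[0.325, 0.175, 0.175, 0.325])))]

    def test_planted_single_substitution_found_at_distance_one(self, rng):
        genome = self._genome(rng)
        window = genome[0][1][5000:5021]
        tag = "A" + window[1:] if window[0] != "A" else "C" + window[1:]
        hits = map_tags_mismatch([tag], genome, 2)[tag]
        assert ("g1", 5001, "+", 1) in hits
        assert ("g1", 5001, "+", 0) not in hits

    def test_distance_three_stays_orphan(self, rng):
        genome = [("g1", "A" * 1000)]
        tag = "CATG" + "C" * 17  # 20 mismatches from any all-A window
        assert map_tags_mismatch([tag], genome, 2)[tag] == []

    def test_empty_genome_leaves_orphans(self):
        assert map_tags_mismatch(["CATG" + "A" * 17], [], 2) == \
            {"CATG" + "A" * 17: []}

    def test_zero_mismatch_equals_exact_window_match(self, rng):
        genome = self._genome(rng)
        seq = genome[0][1]
        tags = [seq[i:i + 21] for i in (0, 777, 4004)]
        hits = map_tags_mismatch(tags, genome, 0)
        for tag in tags:
            assert all(d == 0 for *_, d in hits[tag])
            assert hits[tag] == naive_hamming_hits(tag, genome, 0)

    def test_matches_naive_hamming_scan(self, rng):
        """Seeded pigeonhole search is equivalent to the all-window oracle."""
        genome = self._genome(rng, 20_000)
        seq = genome[0][1]
        tags = []
        for start in rng.integers(0, len(seq) - 21, 15):
            window = list(seq[start:start + 21])
            for pos in rng.choice(21, size=int(rng.integers(0, 3)), replace=False):
                window[pos] = "ACGT"[(("ACGT".index(window[pos])) + 1) % 4]
            tags.append("".join(window))
        tags += ["".join(rng.choice(list("ACGT"), 21)) for _ in range(10)]
        index = GenomeSeedIndex(genome)
        for tag in tags:
            assert index.search(tag, 2) == naive_hamming_hits(tag, genome, 2)
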