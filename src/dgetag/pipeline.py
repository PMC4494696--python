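"""End-to-end orchestration of the tag-profiling analysis.

Mirrors the study workflow: digest the references, filter the
libraries at the occurrence cutoff, map against every reference set,
compare expression between fractions, calibrate the cutoff by
randomization, draw saturation curves, test term enrichment of
fraction-specific transcript sets and profile genome-only tags around
transcript 3' ends.  Every stage writes a TSV under the output
directory and the run closes with a YAML manifest recording versions,
seeds and parameters.  A stage failure aborts with the stage name
while preserving the outputs already written.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .digest import TagIndex, build_tag_index
from .enrichment import (assign_fractions, enrich_fraction_sets,
                         propagate_annotations)
from .io import (read_fasta, read_tag_library, write_fasta,
                 write_gff3_placements, write_tag_library, write_truth,
                 write_tsv, write_yaml)
from .mapping import (map_tags_exact, map_tags_mismatch, reference_overlap,
                      summarize_mapping)
from .noise import recommend_cutoff, saturation_curve, specificity_scan
from .stats import (TagLibrary, compare_cpm_maps, correlate_fractions,
                    filter_by_cutoff, normalize_cpm, splash_table)
from .synthetic import (SyntheticConfig, SyntheticScenario,
                        simulate_annotations, simulate_study)
from .utr import place_transcripts, proximity_profile

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run parameters; defaults trace the study's published choices."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    reference_fastas: dict[str, str] = field(default_factory=dict)
    library_paths: dict[str, str] = field(default_factory=dict)
    cutoff: int = 5
    de_alpha: float = 0.001
    go_alpha: float = 1e-5
    n_rand: int = 20
    saturation_step: int = 200_000
    window: int = 1000
    genome_mismatches: int = 2
    seed: int = 0
    outdir: str = "dgetag_run"


def _transcript_cpm(records, cpm: dict[str, float]) -> dict[str, float]:
    """Sum each tag's cpm into the transcripts its retained sense hits name."""
    out: dict[str, float] = {}
    for rec in records:
        if rec.status == "orphan":
            continue
        value = cpm.get(rec.tag, 0.0)
        for ref_id, _, strand, _ in rec.hits:
            if strand == "+":
                out[ref_id] = out.get(ref_id, 0.0) + value
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a bundle of in-memory results.

    When ``library_paths`` is empty a synthetic study is generated from
    ``config.synthetic`` (and its inputs are written next to the
    results); otherwise libraries and references are loaded from the
    configured paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    manifest: dict = {
        "dgetag_version": __version__,
        "seed": config.seed,
        "parameters": {
            "cutoff": config.cutoff, "de_alpha": config.de_alpha,
            "go_alpha": config.go_alpha, "n_rand": config.n_rand,
            "saturation_step": config.saturation_step, "window": config.window,
            "genome_mismatches": config.genome_mismatches,
        },
        "stages": {},
    }

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)}
                write_yaml(manifest, outdir / "manifest.yaml")
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
        return _Stage()

    scenario: SyntheticScenario | None = None
    with stage("inputs"):
        if config.library_paths:
            reference_sets = {name: read_fasta(p)
                              for name, p in config.reference_fastas.items()}
            libraries = {s: read_tag_library(p, s)
                         for s, p in config.library_paths.items()}
            genome = reference_sets.pop("genome", None)
            transcriptome = reference_sets.pop("transcriptome",
                                               next(iter(reference_sets.values()), None))
            if transcriptome is None:
                raise ValueError("no transcriptome reference configured")
        else:
            scenario = simulate_study(config.synthetic)
            transcriptome = scenario.reference
            genome = scenario.genome
            libraries = scenario.libraries
            write_fasta(transcriptome, outdir / "reference.fasta")
            write_fasta(genome, outdir / "genome.fasta")
            write_gff3_placements(scenario.placements, outdir / "placements.gff3")
            write_truth(scenario.truth, outdir / "truth.yaml")
            for sample, lib in libraries.items():
                write_tag_library(lib, outdir / f"library_{sample}.tsv")
        manifest["samples"] = {s: lib.total_reads for s, lib in libraries.items()}
        bundle["libraries"] = libraries
        bundle["scenario"] = scenario

    with stage("digest"):
        indexes: dict[str, TagIndex] = {
            "transcriptome": build_tag_index(transcriptome, "transcriptome", "both")}
        if genome is not None:
            indexes["genome"] = build_tag_index(genome, "genome", "both")
        bundle["indexes"] = indexes

    with stage("filter"):
        filtered = {s: filter_by_cutoff(lib, config.cutoff)
                    for s, lib in libraries.items()}
        bundle["filtered"] = filtered
        rows = [(s, lib.total_reads, lib.n_distinct, filtered[s].n_distinct)
                for s, lib in libraries.items()]
        write_tsv(pd.DataFrame(rows, columns=["sample", "total_reads",
                                              "distinct_tags", "tags_ge_cutoff"]),
                  outdir / "library_stats.tsv")

    with stage("map"):
        pooled: dict[str, int] = {}
        for lib in filtered.values():
            for t, c in lib.counts.items():
                pooled[t] = pooled.get(t, 0) + c
        pooled_lib = TagLibrary("pooled", pooled, sum(pooled.values()))
        records_by_set = {
            name: map_tags_exact(pooled_lib, idx,
                                 three_prime_rule=(name != "genome"))
            for name, idx in indexes.items()}
        summaries = [summarize_mapping(records_by_set[name])
                     for name in records_by_set]
        write_tsv(pd.DataFrame(
            [(s.reference_set, s.mapped, s.one_match, s.multi_match, s.orphan,
              round(s.contigs_per_tag, 3)) for s in summaries],
            columns=["reference_set", "mapped", "one_match", "multi_match",
                     "orphan", "contigs_per_tag"]),
            outdir / "mapping_summary.tsv")
        overlap = reference_overlap(records_by_set, top_k=20)
        write_tsv(pd.DataFrame(
            [("&".join(subset), n, round(pct, 2)) for subset, n, pct in overlap],
            columns=["reference_subset", "tags", "percent"]),
            outdir / "reference_overlap.tsv")
        bundle["records_by_set"] = records_by_set
        bundle["mapping_summaries"] = summaries

    with stage("genome_rescue"):
        genome_hits = {}
        if genome is not None:
            tr_records = {r.tag: r for r in records_by_set["transcriptome"]}
            orphans = [t for t, r in tr_records.items() if r.status == "orphan"]
            genome_hits = map_tags_mismatch(orphans, genome,
                                            config.genome_mismatches)
            rescued = sum(1 for hits in genome_hits.values() if hits)
            write_tsv(pd.DataFrame(
                [(t, len(h), min((d for *_, d in h), default=-1))
                 for t, h in sorted(genome_hits.items())],
                columns=["tag", "n_genome_hits", "best_mismatches"]),
                outdir / "genome_rescue.tsv")
            manifest["genome_rescue"] = {"orphans": len(orphans), "rescued": rescued}
        bundle["genome_hits"] = genome_hits

    with stage("compare"):
        # tag universe: reliable (cutoff-passing) in at least one library;
        # cpm values: from the unfiltered counts, so a tag just below the
        # cutoff in one library is not mistaken for absent
        universe: set[str] = set()
        for lib in filtered.values():
            universe |= set(lib.counts)
        full_cpm = {s: normalize_cpm(libraries[s]) for s in libraries}
        cpm = {s: {t: full_cpm[s].get(t, 0.0) for t in universe}
               for s in libraries}
        bundle["cpm"] = cpm
        samples = list(cpm)
        comparisons = {}
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                df = compare_cpm_maps(cpm[a], cpm[b], a, b)
                comparisons[(a, b)] = df
                write_tsv(df, outdir / f"comparison_{a}_vs_{b}.tsv")
        bundle["comparisons"] = comparisons
        if {"X1", "X2", "Xin"} <= set(samples):
            splash = splash_table(cpm["X1"], cpm["X2"], cpm["Xin"])
            write_tsv(splash, outdir / "splashplot.tsv")
            bundle["splash"] = splash
            shared = sorted(set(cpm["X1"]) & set(cpm["X2"]) & set(cpm["Xin"]))
            if len(shared) >= 3:
                matrix = pd.DataFrame({s: [cpm[s][t] for t in shared]
                                       for s in ("X1", "X2", "Xin")}, index=shared)
                pearson, spearman = correlate_fractions(matrix)
                write_tsv(pearson.round(4).reset_index(names="sample"),
                          outdir / "correlation_pearson.tsv")
                write_tsv(spearman.round(4).reset_index(names="sample"),
                          outdir / "correlation_spearman.tsv")
                bundle["correlations"] = (pearson, spearman)

    with stage("candidates"):
        # quantification index: poly-A padded, because the sequenced tag of a
        # transcript whose 3'-most CATG sits within 17 nt of its end reads
        # into the poly(A) tail (the plain index keeps those tags orphan on
        # purpose in the mapping accounting above)
        quant_index = build_tag_index(transcriptome, "transcriptome_quant",
                                      "both", polyA_pad=True)
        quant_records = map_tags_exact(
            TagLibrary("universe", {t: 1 for t in universe}, len(universe)),
            quant_index)
        tr_cpm = {s: _transcript_cpm(quant_records, cpm[s]) for s in cpm}
        fractions = assign_fractions(tr_cpm, alpha=config.de_alpha)
        bundle["transcript_cpm"] = tr_cpm
        bundle["fraction_sets"] = fractions
        rows = [(s, tid, round(tr_cpm[s].get(tid, 0.0), 3))
                for s in fractions for tid in sorted(fractions[s])]
        write_tsv(pd.DataFrame(rows, columns=["fraction", "transcript", "cpm"]),
                  outdir / "candidates.tsv")

    with stage("cutoff_scan"):
        scan_sample = max(libraries, key=lambda s: libraries[s].total_reads)
        results = specificity_scan(libraries[scan_sample],
                                   indexes["transcriptome"],
                                   n_rand=config.n_rand, seed=config.seed)
        recommended = recommend_cutoff(results)
        write_tsv(pd.DataFrame(
            [(r.cutoff, r.observed_hits, r.observed_orphans,
              round(r.random_hits_mean, 3), round(r.random_hits_sd, 3))
             for r in results],
            columns=["cutoff", "observed_hits", "observed_orphans",
                     "random_hits_mean", "random_hits_sd"]),
            outdir / "cutoff_scan.tsv")
        manifest["recommended_cutoff"] = recommended
        bundle["cutoff_results"] = results
        bundle["recommended_cutoff"] = recommended

    with stage("saturation"):
        sat_sample = max(libraries, key=lambda s: libraries[s].total_reads)
        curves = saturation_curve(libraries[sat_sample], indexes,
                                  step=config.saturation_step, seed=config.seed)
        rows = [(name, size, n) for name, curve in curves.items()
                for size, n in curve.points]
        write_tsv(pd.DataFrame(rows, columns=["reference_set", "subsample_size",
                                              "distinct_mapped"]),
                  outdir / "saturation.tsv")
        bundle["saturation"] = curves

    with stage("enrichment"):
        if scenario is not None:
            ids = [tid for tid, _ in scenario.reference]
            x1_planted = {t for t, (s, _) in scenario.truth.de_labels.items()
                          if s == "X1"}
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
            direct, edges, planted = simulate_annotations(ids, x1_planted, rng=rng)
            propagated = propagate_annotations(direct, edges)
            study_sets = {f: s & set(propagated) for f, s in fractions.items()}
            records = enrich_fraction_sets(study_sets, propagated,
                                           alpha=config.go_alpha)
            write_tsv(pd.DataFrame(
                [(r.fraction, r.term_id, r.k, r.n, r.K, r.N,
                  f"{r.p_two_tailed:.4g}", round(r.log_odds, 3),
                  r.direction, int(r.significant)) for r in records],
                columns=["fraction", "term", "k", "n", "K", "N", "p",
                         "log_odds", "direction", "significant"]),
                outdir / "enrichment.tsv")
            bundle["enrichment"] = records
            bundle["planted_term"] = planted

    with stage("utr3"):
        if scenario is not None and genome is not None:
            placements, unplaced = place_transcripts(
                scenario.reference, genome,
                external_placements=[p for p in scenario.placements
                                     if not p.transcript_id.startswith("nov_")])
            hits = []
            for tag, hit_list in genome_hits.items():
                for contig, pos, strand, d in hit_list:
                    if d == 0:
                        hits.append((tag, contig, pos, strand))
            profile = proximity_profile(placements, hits, genome,
                                        window=config.window)
            write_tsv(pd.DataFrame(sorted(profile.histogram.items()),
                                   columns=["bin_start", "tags"]),
                      outdir / "utr_proximity.tsv")
            manifest["utr3"] = {"assigned": profile.n_assigned,
                                "fraction_covered": round(profile.fraction_covered, 5),
                                "unplaced": len(unplaced)}
            bundle["utr_profile"] = profile

    write_yaml(manifest, outdir / "manifest.yaml")
    bundle["manifest"] = manifest
    return bundle
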