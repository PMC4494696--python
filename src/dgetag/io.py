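"""Readers and writers for the pipeline's file formats.

Tag libraries travel as two-column TSV (tag, count) with an optional
header; references and genomes as FASTA; transcript placements as
GFF3 (1-based, inclusive); configuration, truth and run manifests as
YAML.  Every TSV written here starts with a ``#`` comment line naming
its columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import TAG_LENGTH
from .stats import TagLibrary
from .synthetic import Placement, SyntheticTruth

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


def read_tag_library(path: str | Path, sample_id: str | None = None) -> TagLibrary:
    """Load a (tag, count) TSV; duplicate tag rows are aggregated.

    Tags must be 21 nt over ACGT; malformed rows are skipped with a
    warning naming their line numbers, and a file with no valid rows is
    rejected.  A single header row is tolerated.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    bad_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                bad_lines.append(lineno)
                continue
            tag, count_str = fields[0].upper(), fields[1]
            try:
                count = int(count_str)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                bad_lines.append(lineno)
                continue
            if len(tag) != TAG_LENGTH or set(tag) - _VALID or count < 0:
                bad_lines.append(lineno)
                continue
            counts[tag] = counts.get(tag, 0) + count
    if bad_lines:
        shown = ", ".join(map(str, bad_lines[:10]))
        logger.warning("%s: skipped %d malformed rows (lines %s%s)", path,
                       len(bad_lines), shown, "..." if len(bad_lines) > 10 else "")
    if not counts:
        raise ValueError(f"no valid tag rows in {path}")
    return TagLibrary(sample_id or path.stem, counts, sum(counts.values()))


def write_tag_library(library: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# tag\tcount\n")
        for tag in sorted(library.counts):
            fh.write(f"{tag}\t{library.counts[tag]}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 placements


def write_gff3_placements(placements: Sequence[Placement], path: str | Path,
                          source: str = "dgetag") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in placements:
            fh.write(f"{p.contig}\t{source}\ttranscript\t{p.start}\t{p.end}\t.\t"
                     f"{p.strand}\t.\tID={p.transcript_id}\n")


def read_gff3_placements(path: str | Path) -> list[Placement]:
    placements = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            placements.append(Placement(attrs.get("ID", ""), cols[0],
                                        int(cols[3]), int(cols[4]), cols[6]))
    return placements


# ---------------------------------------------------------------------------
# annotation TSVs (sequence_id -> term_id; child -> parent edges)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, term = line.split("\t")[:2]
            direct.setdefault(seq_id, set()).add(term)
    return direct


def write_annotations(direct: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sequence_id\tterm_id\n")
        for seq_id in sorted(direct):
            for term in sorted(direct[seq_id]):
                fh.write(f"{seq_id}\t{term}\n")


def read_ontology_edges(path: str | Path) -> dict[str, set[str]]:
    edges: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            edges.setdefault(child, set()).add(parent)
    return edges


def write_ontology_edges(edges: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# child\tparent\n")
        for child in sorted(edges):
            for parent in sorted(edges[child]):
                fh.write(f"{child}\t{parent}\n")


def read_obo_edges(path: str | Path,
                   keep: tuple[str, ...] = ("is_a",)) -> dict[str, set[str]]:
    """Minimal OBO-subset reader: [Term] stanzas reduced to parent edges.

    Only ``is_a`` lines are kept by default; pass relationship names in
    ``keep`` (e.g. ``("is_a", "part_of")``) to collapse further typed
    relationships onto plain parent edges.  Obsolete terms are skipped.
    Anything beyond id / is_a / relationship lines is ignored — this is
    not a general ontology parser.
    """
    edges: dict[str, set[str]] = {}
    term_id: str | None = None
    in_term = False
    obsolete = False
    pending: list[str] = []

    def flush() -> None:
        if term_id is not None and not obsolete:
            for parent in pending:
                edges.setdefault(term_id, set()).add(parent)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                term_id, obsolete, pending = None, False, []
                continue
            if not in_term or not line:
                continue
            if line.startswith("id:"):
                term_id = line[3:].strip()
            elif line.startswith("is_obsolete:") and "true" in line:
                obsolete = True
            elif line.startswith("is_a:") and "is_a" in keep:
                pending.append(line[5:].split("!")[0].strip())
            elif line.startswith("relationship:"):
                fields = line[len("relationship:"):].split("!")[0].split()
                if len(fields) == 2 and fields[0] in keep:
                    pending.append(fields[1])
    flush()
    return edges


# ---------------------------------------------------------------------------
# YAML (config, truth, manifest)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True, default_flow_style=False)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the ground truth of a synthetic study (expression inline)."""
    payload = {
        "seed": truth.seed,
        "de_labels": {t: list(v) for t, v in truth.de_labels.items()},
        "antisense_flags": {t: bool(v) for t, v in truth.antisense_flags.items()},
        "withheld_ids": sorted(truth.withheld_ids),
        "tagless_ids": sorted(truth.tagless_ids),
        "canonical_tags": dict(truth.canonical_tags),
        "expression": {
            "samples": list(truth.expression.columns),
            "transcripts": list(truth.expression.index),
            "cpm": [[round(float(v), 6) for v in row]
                    for row in truth.expression.to_numpy()],
        } if truth.expression is not None else None,
    }
    write_yaml(payload, path)


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as TSV with a '#'-prefixed column header."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
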