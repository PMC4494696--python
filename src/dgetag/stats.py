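"""Filtering, normalization and statistical comparison of tag libraries.

The comparison test treats the two libraries as a fair coin experiment:
after scaling both tag counts to counts per million (cpm) and rounding
to pseudo-counts x >= y, the chance of seeing a split at least as
lopsided as (x, y) under equal expression is the binomial tail
P(X >= x) with X ~ Binomial(x + y, 1/2).  When the smaller side is
zero this reduces to the closed form p = 2^-x, which is returned
exactly.  No dispersion model is fitted — each tag is tested on its
own counts, and no multiple-testing correction is applied by default
(candidate selection uses the raw p < 0.001 threshold; an optional
Benjamini-Hochberg adjustment is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

MILLION = 1_000_000


def round_half_up(value: float) -> int:
    """Round to the nearest integer, halves away from zero-ward (5.5 -> 6)."""
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class TagLibrary:
    """One sequenced library: a multiset of 21-nt tags with raw counts.

    ``total_reads`` is the library depth at load time and is kept as the
    cpm denominator even after cutoff filtering produces a smaller
    instance (filters never mutate, they return new libraries).
    """

    sample_id: str
    counts: Mapping[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_reads_retained(self) -> int:
        return sum(self.counts.values())


def make_library(sample_id: str, counts: Mapping[str, int]) -> TagLibrary:
    """Build a library whose depth is the sum of its counts (load-time state)."""
    return TagLibrary(sample_id, dict(counts), sum(counts.values()))


def filter_by_cutoff(library: TagLibrary, min_count: int = 5) -> TagLibrary:
    """Keep reliable tags: those sequenced ``min_count`` times or more.

    The parent's total_reads is retained so cpm stays on the original
    library scale.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {t: c for t, c in library.counts.items() if c >= min_count}
    return TagLibrary(library.sample_id, kept, library.total_reads)


def normalize_cpm(library: TagLibrary, denominator: str = "pre") -> dict[str, float]:
    """Tag counts scaled to counts per million.

    ``denominator='pre'`` (default) divides by the pre-filter library
    depth; ``'post'`` divides by the reads surviving the current filter.
    """
    if not library.counts:
        raise ValueError(f"empty library {library.sample_id!r}")
    if denominator == "pre":
        total = library.total_reads
    elif denominator == "post":
        total = library.n_reads_retained
    else:
        raise ValueError("denominator must be 'pre' or 'post'")
    scale = MILLION / total
    return {t: c * scale for t, c in library.counts.items()}


def mean_reads_per_tag(total_reads: int, distinct_tags: int) -> float:
    """Average sequencing redundancy: reads per distinct tag."""
    if distinct_tags <= 0:
        raise ValueError("distinct_tags must be positive")
    return total_reads / distinct_tags


# ---------------------------------------------------------------------------
# binomial comparison test


@dataclass(frozen=True)
class ComparisonRecord:
    tag: str
    cpm_a: float
    cpm_b: float
    pseudo_a: int
    pseudo_b: int
    p_value: float
    direction: str  # 'a>b', 'b>a' or 'equal'


def binomial_tail_p(cpm_a: float, cpm_b: float) -> float:
    """Equal-chance binomial tail on rounded cpm pseudo-counts.

    x = round(max), y = round(min); p = P(X >= x), X ~ Bin(x+y, 1/2).
    Symmetric in its arguments; (0, 0) carries no evidence and returns 1.
    """
    if cpm_a < 0 or cpm_b < 0:
        raise ValueError("cpm values must be non-negative")
    x = round_half_up(max(cpm_a, cpm_b))
    y = round_half_up(min(cpm_a, cpm_b))
    if x == 0:
        return 1.0
    if y == 0:
        return 2.0 ** (-x)  # closed form, exact
    return float(sps.binom.sf(x - 1, x + y, 0.5))


def compare_libraries(cpm_a: float, cpm_b: float, tag: str = "") -> ComparisonRecord:
    """Compare one tag's cpm between two libraries (see module docstring)."""
    p = binomial_tail_p(cpm_a, cpm_b)
    a, b = round_half_up(cpm_a), round_half_up(cpm_b)
    direction = "a>b" if a > b else ("b>a" if b > a else "equal")
    return ComparisonRecord(tag, cpm_a, cpm_b, a, b, p, direction)


def compare_cpm_maps(cpm_a: Mapping[str, float], cpm_b: Mapping[str, float],
                     name_a: str = "a", name_b: str = "b") -> pd.DataFrame:
    """Per-tag comparison over the union of two cpm maps (absent tag -> 0)."""
    tags = sorted(set(cpm_a) | set(cpm_b))
    rows = []
    for t in tags:
        rec = compare_libraries(cpm_a.get(t, 0.0), cpm_b.get(t, 0.0), t)
        rows.append((t, rec.cpm_a, rec.cpm_b, rec.p_value))
    return pd.DataFrame(rows, columns=["tag", f"cpm_{name_a}", f"cpm_{name_b}", "p_value"])


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Optional BH adjustment (off by default everywhere in the pipeline)."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# splashplot coordinates


@dataclass(frozen=True)
class SplashPoint:
    tag: str
    x: float  # signed log2 |X1 - Xin|
    y: float  # signed log2 |X2 - Xin|
    quadrant: str  # '++', '+-', '-+', '--' or 'axis'


def _signed_log2_diff(a: float, b: float) -> float:
    d = a - b
    if abs(d) <= 1.0:  # sub-unit cpm differences carry no usable sign
        return 0.0
    return math.copysign(math.log2(abs(d)), d)


def splash_coordinates(cpm_x1: float, cpm_x2: float, cpm_xin: float,
                       tag: str = "") -> SplashPoint:
    """Project a tag onto the splashplot plane.

    x and y are the log2 of the absolute cpm difference of X1 (resp. X2)
    versus Xin, signed by the direction of the change; differences of at
    most 1 cpm collapse to the axis.  The upper-right quadrant holds tags
    overexpressed in both X1 and X2 relative to Xin, the lower-left tags
    overexpressed in Xin.
    """
    if min(cpm_x1, cpm_x2, cpm_xin) < 0:
        raise ValueError("cpm values must be non-negative")
    x = _signed_log2_diff(cpm_x1, cpm_xin)
    y = _signed_log2_diff(cpm_x2, cpm_xin)
    if x == 0.0 or y == 0.0:
        quadrant = "axis"
    else:
        quadrant = ("+" if x > 0 else "-") + ("+" if y > 0 else "-")
    return SplashPoint(tag, x, y, quadrant)


def splash_table(cpm_x1: Mapping[str, float], cpm_x2: Mapping[str, float],
                 cpm_xin: Mapping[str, float]) -> pd.DataFrame:
    tags = sorted(set(cpm_x1) | set(cpm_x2) | set(cpm_xin))
    rows = []
    for t in tags:
        pt = splash_coordinates(cpm_x1.get(t, 0.0), cpm_x2.get(t, 0.0),
                                cpm_xin.get(t, 0.0), t)
        rows.append((t, pt.x, pt.y, pt.quadrant))
    return pd.DataFrame(rows, columns=["tag", "x", "y", "quadrant"])


# ---------------------------------------------------------------------------
# inter-fraction correlations


def correlate_fractions(cpm_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson and Spearman correlation of fraction cpm profiles.

    Expects a tags-x-samples DataFrame restricted to shared tags (missing
    values should already be 0-filled).  Constant columns make Pearson
    undefined; pandas reports those entries as NaN, which is propagated.
    """
    if len(cpm_matrix) < 3:
        raise ValueError("need at least 3 shared tags to correlate")
    pearson = cpm_matrix.corr(method="pearson")
    spearman = cpm_matrix.corr(method="spearman")
    return pearson, spearman
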