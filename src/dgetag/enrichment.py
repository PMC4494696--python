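"""Term enrichment of fraction-specific transcript sets.

Annotations are propagated up the ontology (a transcript annotated
with a term is implicitly annotated with every ancestor), then each
(fraction, term) pair is tested with an exact two-tailed
hypergeometric test on the 2x2 study-set / background table.  The
two-tailed p-value uses the minimum-likelihood construction: the sum
of all hypergeometric point probabilities no larger than the observed
one, which covers both over- and under-representation.  Effect size is
reported as the Haldane-corrected log2 odds ratio of the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as sps

from .stats import binomial_tail_p


def propagate_annotations(direct: Mapping[str, set[str]],
                          ontology_edges: Mapping[str, set[str]],
                          ) -> dict[str, set[str]]:
    """Close each sequence's annotation over ontology ancestors.

    ``ontology_edges`` maps a term to its parent terms (is_a).  Cycles
    are rejected with the offending path.  Idempotent: propagating an
    already propagated map changes nothing.
    """
    ancestors: dict[str, set[str]] = {}

    def _ancestors(term: str, path: tuple[str, ...]) -> set[str]:
        if term in path:
            cycle = " -> ".join(path[path.index(term):] + (term,))
            raise ValueError(f"ontology cycle detected: {cycle}")
        if term in ancestors:
            return ancestors[term]
        result: set[str] = set()
        for parent in ontology_edges.get(term, ()):
            result.add(parent)
            result |= _ancestors(parent, path + (term,))
        ancestors[term] = result
        return result

    propagated: dict[str, set[str]] = {}
    for seq_id, terms in direct.items():
        closure = set(terms)
        for term in terms:
            closure |= _ancestors(term, ())
        propagated[seq_id] = closure
    return propagated


def hypergeom_two_tailed(k: int, n: int, K: int, N: int) -> float:
    """Exact two-tailed hypergeometric p-value (minimum-likelihood sum).

    k annotated in a study set of n, K annotated in a background of N.
    All outcomes j with P(X = j) <= P(X = k) contribute; the sum is
    clamped to 1.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    if k < n + K - N:
        raise ValueError(f"k={k} below the support minimum {n + K - N}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    support = range(lo, hi + 1)
    pmf = sps.hypergeom.pmf(list(support), N, K, n)
    p_obs = pmf[k - lo]
    # tolerance guards against ties broken by floating-point noise
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(1.0, p)


def log_odds_ratio(k: int, n: int, K: int, N: int) -> float:
    """Haldane-corrected log2 odds ratio of the 2x2 enrichment table."""
    a, b = k + 0.5, n - k + 0.5
    c, d = K - k + 0.5, (N - n) - (K - k) + 0.5
    return math.log2((a / b) / (c / d))


@dataclass(frozen=True)
class EnrichmentRecord:
    fraction: str
    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_two_tailed: float
    log_odds: float
    direction: str  # 'over' or 'under'
    significant: bool


def enrich_fraction_sets(study_sets: Mapping[str, set[str]],
                         propagated: Mapping[str, set[str]],
                         background: set[str] | None = None,
                         alpha: float = 1e-5) -> list[EnrichmentRecord]:
    """Test every (fraction, term) pair against the background.

    The default background is every sequence with at least one
    propagated annotation — unannotated sequences carry no information
    in a term test (pass an explicit background to change this).  Study
    sets must be subsets of the background.
    """
    if background is None:
        background = {s for s, terms in propagated.items() if terms}
    N = len(background)
    term_members: dict[str, set[str]] = {}
    for seq_id in background:
        for term in propagated.get(seq_id, ()):
            term_members.setdefault(term, set()).add(seq_id)

    records: list[EnrichmentRecord] = []
    for fraction, study in study_sets.items():
        if not study:
            continue
        extra = study - background
        if extra:
            raise ValueError(
                f"study set {fraction!r} has {len(extra)} ids outside the background")
        n = len(study)
        for term, members in sorted(term_members.items()):
            K = len(members)
            k = len(study & members)
            if k == 0 and K == 0:
                continue
            p = hypergeom_two_tailed(k, n, K, N)
            lo = log_odds_ratio(k, n, K, N)
            records.append(EnrichmentRecord(
                fraction, term, k, n, K, N, p, lo,
                "over" if lo >= 0 else "under", p < alpha))
    return records


def assign_fractions(cpm_by_sample: Mapping[str, Mapping[str, float]],
                     alpha: float = 0.001) -> dict[str, set[str]]:
    """Classify sequences by the fraction where they are mostly expressed.

    A sequence is assigned to the fraction with its maximal cpm,
    provided the binomial comparison against at least one other
    fraction is significant at ``alpha`` (ties on the maximum leave the
    sequence unassigned).
    """
    samples = list(cpm_by_sample)
    ids: set[str] = set()
    for cpm in cpm_by_sample.values():
        ids |= set(cpm)
    out: dict[str, set[str]] = {s: set() for s in samples}
    for seq_id in ids:
        values = {s: cpm_by_sample[s].get(seq_id, 0.0) for s in samples}
        top = max(values, key=values.get)
        top_value = values[top]
        if sum(1 for v in values.values() if v == top_value) > 1:
            continue
        others = [values[s] for s in samples if s != top]
        if any(binomial_tail_p(top_value, v) < alpha for v in others):
            out[top].add(seq_id)
    return out
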