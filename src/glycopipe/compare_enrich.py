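"""Dataset-overlap statistics and exact hypergeometric enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom


def _normalize(ids) -> frozenset[str]:
    return frozenset(str(x).strip().lower() for x in ids if str(x).strip())


@dataclass
class OverlapResult:
    labels: tuple[str, ...]
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]       # unordered label pair -> |A∩B|
    triple: int | None                         # |A∩B∩C| when three sets given
    pct_in: dict[tuple[str, str], float]       # (A, B) -> 100*|A∩B|/|A|
    jaccard: dict[tuple[str, str], float]


def overlap_stats(sets: Mapping[str, Sequence[str]]) -> OverlapResult:
    """Exact intersection counts, asymmetric overlap percentages and Jaccard
    indices for two or three labelled accession sets.

    Identifiers are normalized case-insensitively with whitespace stripped.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_stats expects 2 or 3 labelled sets")
    norm = {label: _normalize(ids) for label, ids in sets.items()}
    for label, s in norm.items():
        if not s:
            raise ValueError(f"set {label!r} is empty after normalization")
    labels = tuple(norm)
    pairwise: dict[tuple[str, str], int] = {}
    pct_in: dict[tuple[str, str], float] = {}
    jaccard: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        inter = len(norm[a] & norm[b])
        union = len(norm[a] | norm[b])
        pairwise[(a, b)] = inter
        pct_in[(a, b)] = 100.0 * inter / len(norm[a])
        pct_in[(b, a)] = 100.0 * inter / len(norm[b])
        jaccard[(a, b)] = inter / union
    triple = None
    if len(labels) == 3:
        triple = len(norm[labels[0]] & norm[labels[1]] & norm[labels[2]])
    return OverlapResult(
        labels=labels,
        sizes={label: len(s) for label, s in norm.items()},
        pairwise=pairwise,
        triple=triple,
        pct_in=pct_in,
        jaccard=jaccard,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up, monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentRow:
    term: str
    query_hits: int
    background_hits: int
    query_size: int
    background_size: int
    fold: float
    p_value: float
    q_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


def hypergeom_enrichment(query_set: Sequence[str],
                         annotation_map: Mapping[str, Sequence[str]],
                         background_set: Sequence[str]) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of annotation terms in a query.

    ``annotation_map`` maps each accession to its terms.  The query must be
    a subset of the background.  Fold = (hits/query) / (term/background);
    p is the exact probability of >= the observed hit count; q is BH across
    all terms with annotated background members.
    """
    query = _normalize(query_set)
    background = _normalize(background_set)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query is not contained in the background (e.g. {extra})")
    ann = {str(acc).strip().lower(): set(terms) for acc, terms in annotation_map.items()}
    term_bg: dict[str, set[str]] = {}
    for acc in background:
        for term in ann.get(acc, ()):
            term_bg.setdefault(term, set()).add(acc)

    M, n = len(background), len(query)
    rows: list[EnrichmentRow] = []
    for term in sorted(term_bg):
        members = term_bg[term]
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / M) if k > 0 else 0.0
        rows.append(EnrichmentRow(term, k, K, n, M, fold, min(p, 1.0), 0.0))
    qvals = benjamini_hochberg([r.p_value for r in rows]) if rows else []
    for row, q in zip(rows, qvals):
        row.q_value = float(q)
    return rows
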