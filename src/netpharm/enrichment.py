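"""Pathway over-representation analysis on a screened target set.

For each pathway with members in the background universe, the overlap with
the query is scored with the one-sided hypergeometric upper tail
P(X >= k), the standard over-representation statistic for annotation sets.
Significance is called on the raw p-value at ``alpha`` (default 0.01) by
default; Benjamini–Hochberg adjustment is available by flag.

The tail probability is computed with exact big-integer combinatorics
(a single integer sum divided by C(N, n)), so it is exact to float
conversion at the problem sizes this package addresses (set sizes in the
hundreds).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable

import numpy as np

from .exceptions import DomainError
from .io_formats import PathwayCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation test."""

    pathway_id: str
    description: str
    overlap: int          # k: query proteins in the pathway
    pathway_size: int     # K: pathway members within the background
    query_size: int       # n
    background_size: int  # N
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "description": self.description,
            "overlap": self.overlap,
            "pathway_size": self.pathway_size,
            "query_size": self.query_size,
            "background_size": self.background_size,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def hypergeometric_tail(k: int, K: int, n: int, N_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_bg, K, n).

    X counts successes when drawing n items without replacement from a
    population of N_bg containing K successes. Computed as an exact
    big-integer sum Σ_{j>=k} C(K,j)·C(N_bg−K, n−j), divided by C(N_bg, n).
    Symmetric in K and n. Returns exactly 1.0 when k <= max(0, K+n-N_bg).
    """
    if N_bg < 0 or K < 0 or n < 0 or k < 0:
        raise DomainError("all counts must be nonnegative")
    if K > N_bg or n > N_bg:
        raise DomainError(
            f"K={K} and n={n} must not exceed the background size N_bg={N_bg}")
    if k > min(K, n):
        raise DomainError(f"overlap k={k} exceeds min(K={K}, n={n})")
    lo = max(k, 0)
    hi = min(K, n)
    numerator = sum(comb(K, j) * comb(N_bg - K, n - j) for j in range(lo, hi + 1))
    return numerator / comb(N_bg, n)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def enrich_pathways(query: Iterable[str], pathways: PathwayCollection,
                    background: Iterable[str] | None = None,
                    alpha: float = 0.01,
                    correction: str = "none") -> list[EnrichmentResult]:
    """Test every pathway for over-representation of *query* proteins.

    Pathway member sets are intersected with the background universe before
    testing; pathways emptied by that restriction are skipped. The default
    background is the union of all pathway members and the query. Results are
    sorted by ascending p-value (ties by pathway id). ``correction='none'``
    calls significance on raw p < alpha; ``'benjamini_hochberg'`` (or
    ``'bh'``) on adjusted p < alpha.
    """
    if correction not in ("none", "benjamini_hochberg", "bh"):
        raise DomainError(f"unknown correction {correction!r}")
    query = set(query)
    if background is None:
        background = pathways.all_members() | query
    background = set(background)
    if not background:
        raise DomainError("background universe is empty")
    if not query <= background:
        raise DomainError("query contains proteins outside the background universe")

    n = len(query)
    N_bg = len(background)
    results = []
    for pathway in pathways:
        members = pathway.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = hypergeometric_tail(k, K, n, N_bg)
        results.append((pathway, k, K, p))

    p_raw = np.array([r[3] for r in results], dtype=float)
    if correction in ("benjamini_hochberg", "bh") and len(p_raw):
        p_call = benjamini_hochberg(p_raw)
    else:
        p_call = p_raw

    out = [
        EnrichmentResult(
            pathway_id=pw.pathway_id,
            description=pw.description,
            overlap=k,
            pathway_size=K,
            query_size=n,
            background_size=N_bg,
            p_value=float(p),
            significant=bool(pc < alpha),
        )
        for (pw, k, K, p), pc in zip(results, p_call)
    ]
    out.sort(key=lambda r: (r.p_value, r.pathway_id))
    return out
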