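"""Gene-set over-representation analysis with FDR control.

Each query gene list (A, B, or the recurrent list C) is tested against a
GMT collection with the one-sided hypergeometric test: given a universe
of N genes of which K belong to the set, drawing the n query genes
without replacement, the p-value is P(X >= k) for the observed overlap
k.  Benjamini–Hochberg step-up adjustment is applied across all sets
tested for one query.  The top enriched sets feed the downstream
pathway bonus in candidate scoring.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "write_enrichment_tsv",
]

DEFAULT_TOP_N = 3


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe (upper-cased symbols)."""

    sets: list[GeneSet]
    universe: frozenset

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str, universe=None) -> GeneSetCollection:
    """Read a GMT file (set id TAB description TAB member...).

    If ``universe`` is None the background is the union of all set
    members; otherwise the given symbols (e.g. all genes in the variant
    annotation) are used.
    """
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            sets.append(GeneSet(fields[0], fields[1], members))
    if universe is None:
        uni: frozenset = frozenset().union(*(s.members for s in sets)) if sets else frozenset()
    else:
        uni = frozenset(g.upper() for g in universe)
    return GeneSetCollection(sets, uni)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1.
    """
    p = list(map(float, pvals))
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # set size (within universe)
    N: int  # universe size
    p: float
    q: float


def enrich(
    query, collection: GeneSetCollection, top_n: int = DEFAULT_TOP_N
) -> tuple[list[EnrichmentResult], frozenset]:
    """Test a gene list against every set in the collection.

    Returns results sorted ascending by p (ties by set id) together with
    the union of members of the ``top_n`` best-ranked sets — the genes
    eligible for the downstream pathway bonus.  Query symbols outside
    the universe are dropped with a warning.
    """
    qset = frozenset(g.upper() for g in query)
    if not qset:
        raise ValueError("empty query gene list")
    outside = qset - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    qset = qset & collection.universe
    if not qset:
        raise ValueError("no query genes remain within the universe")
    N = len(collection.universe)
    n = len(qset)
    raw = []
    for s in collection.sets:
        members = s.members & collection.universe
        if not members:
            continue
        K = len(members)
        k = len(qset & members)
        raw.append((s.set_id, k, K, hypergeom_upper_tail(k, n, K, N), members))
    qvals = bh_adjust([r[3] for r in raw])
    results = sorted(
        (
            EnrichmentResult(set_id, k, n, K, N, p, q)
            for (set_id, k, K, p, _), q in zip(raw, qvals)
        ),
        key=lambda r: (r.p, r.set_id),
    )
    member_lookup = {s.set_id: s.members for s in collection.sets}
    top: frozenset = frozenset()
    for r in results[:top_n]:
        top |= member_lookup[r.set_id]
    return results, top


def write_enrichment_tsv(results: list[EnrichmentResult], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set_id", "k", "n", "K", "N", "p", "q"])
        for r in results:
            w.writerow([r.set_id, r.k, r.n, r.K, r.N, f"{r.p:.6g}", f"{r.q:.6g}"])
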