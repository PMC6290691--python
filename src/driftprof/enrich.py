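"""Pathway over-representation analysis (ORA) of candidate gene lists.

One-sided hypergeometric (Fisher) test per gene set: with a universe of N
annotatable genes, a pathway of K genes and a query list of n genes, the
probability of observing k or more overlapping genes by chance is
P(X >= k) for X ~ Hypergeometric(N, K, n).  Rows are sorted by raw p-value
(the field's convention for over-representation output); Benjamini-Hochberg
q-values are reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .vardata import PathwayDB


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    k: int          # overlap count
    n: int          # query list size within the universe
    K: int          # pathway size
    N: int          # universe size
    p_value: float
    q_value: float

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n, self.K) <= self.N:
            raise ValueError("inconsistent overlap counts")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value outside (0,1]")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), accumulated in log space."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > N or n > N or k > min(n, K):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def ora(gene_list: Iterable[str], pathway_db: PathwayDB) -> list[EnrichmentRow]:
    """Test every pathway for over-representation of the query gene list.

    Genes outside the universe are dropped before testing; an empty
    intersection is an error that names the unmatched genes.  Output is
    sorted ascending by p-value, ties broken by pathway id.
    """
    genes = set(gene_list)
    query = genes & pathway_db.universe
    if not query:
        unmatched = ", ".join(sorted(genes)) or "<empty list>"
        raise ValueError(f"no query gene is in the universe: {unmatched}")
    N = len(pathway_db.universe)
    n = len(query)
    raw = []
    for pid in sorted(pathway_db.sets):
        members = pathway_db.sets[pid]
        k = len(query & members)
        raw.append((pid, k, len(members),
                    hypergeom_upper_tail(k, len(members), n, N)))
    q_values = benjamini_hochberg([r[3] for r in raw])
    rows = [EnrichmentRow(pathway_id=pid, k=k, n=n, K=K, N=N,
                          p_value=p, q_value=float(q))
            for (pid, k, K, p), q in zip(raw, q_values)]
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rows
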