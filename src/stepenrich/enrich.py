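"""Over-representation tests: gene-list and unweighted step-centric methods.

Both tests use the one-tailed hypergeometric distribution (one-tailed
Fisher's exact test): the probability that k or more of the n pathway items
appear in an input list of size N drawn without replacement from a background
of size M.  The traditional method counts genes; the step-centric method
counts step-enabling entities, so a set of interchangeable proteins counts
once towards both the pathway size n and the overlap k, no matter how many
members are differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Background, PathwayDB, normalize_gene_id

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_adjust",
    "map_genes_to_entities",
    "gene_list_enrichment",
    "step_enrichment",
    "compare_methods",
]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    title: str
    method: str  # gene | step | wstep
    k: int
    n: int
    N: int
    M: int
    p_raw: float
    p_adj: float
    member_hits: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.N)):
            raise ValueError(f"invalid overlap k={self.k} for n={self.n}, N={self.N}")
        if self.n > self.M or self.N > self.M:
            raise ValueError(f"n={self.n} or N={self.N} exceeds background M={self.M}")


def hypergeom_tail(k: int, n: int, N: int, M: int) -> float:
    """P(K >= k) for K ~ Hypergeometric(M, n, N).

    p = sum_{j=k}^{min(n,N)} C(n,j) C(M-n, N-j) / C(M,N), evaluated via the
    log-space survival function.
    """
    if M < 0 or not (0 <= n <= M) or not (0 <= N <= M):
        raise ValueError(f"invalid hypergeometric parameters n={n}, N={N}, M={M}")
    if not (0 <= k <= min(n, N)):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, N={N})]")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def map_genes_to_entities(
    genes: Iterable[str], background: Background
) -> dict[str, frozenset[str]]:
    """Map input genes to the background entities they activate.

    Returns ``{canonical_id: matched member genes}`` containing every
    background set with at least one member in the input plus every solo
    entity whose gene is in the input.  Each set appears once regardless of
    how many members matched.  Input genes are first intersected with the
    annotated background.
    """
    present = {normalize_gene_id(g) for g in genes} & set(background.genes)
    hits: dict[str, frozenset[str]] = {}
    for ent in background.entities:
        matched = ent.members & present
        if matched:
            hits[ent.canonical_id] = frozenset(matched)
    return hits


def _finalize(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-adjust across all tested pathways; sort by (p_raw, pathway_id)."""
    if not results:
        return results
    adj = bh_adjust([r.p_raw for r in results])
    out = [replace(r, p_adj=float(q)) for r, q in zip(results, adj)]
    out.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return out


def gene_list_enrichment(genes: Iterable[str], db: PathwayDB) -> list[EnrichmentResult]:
    """Traditional enrichment on expanded gene lists.

    Per pathway: k = |input ∩ gene_list|, n = |gene_list|, N = annotated
    input size, M = number of genes annotated to any pathway.
    """
    bg = db.background
    present = {normalize_gene_id(g) for g in genes} & set(bg.genes)
    N, M = len(present), bg.M_genes
    results = []
    for pw in db.pathways:
        overlap = present & pw.gene_list
        k, n = len(overlap), len(pw.gene_list)
        results.append(
            EnrichmentResult(
                pathway_id=pw.id,
                title=pw.title,
                method="gene",
                k=k,
                n=n,
                N=N,
                M=M,
                p_raw=hypergeom_tail(k, n, N, M),
                p_adj=1.0,
                member_hits=";".join(sorted(overlap)),
            )
        )
    return _finalize(results)


def step_enrichment(genes: Iterable[str], db: PathwayDB) -> list[EnrichmentResult]:
    """Step-centric enrichment on entity lists.

    The input is mapped to background entities once; per pathway k is the
    number of pathway entities hit, n the entity-list size, N the mapped
    entity count, M the background entity count.
    """
    bg = db.background
    hits = map_genes_to_entities(genes, bg)
    N, M = len(hits), bg.M_entities
    results = []
    for pw in db.pathways:
        matched = [e for e in pw.entities if e.canonical_id in hits]
        k, n = len(matched), pw.n
        member_hits = ";".join(
            ",".join(sorted(hits[e.canonical_id])) for e in matched
        )
        results.append(
            EnrichmentResult(
                pathway_id=pw.id,
                title=pw.title,
                method="step",
                k=k,
                n=n,
                N=N,
                M=M,
                p_raw=hypergeom_tail(k, n, N, M),
                p_adj=1.0,
                member_hits=member_hits,
            )
        )
    return _finalize(results)


def compare_methods(
    results_a: Sequence[EnrichmentResult] | pd.DataFrame,
    results_b: Sequence[EnrichmentResult] | pd.DataFrame,
    fdr_a: float = 0.10,
    fdr_b_grid: Sequence[float] = (0.10, 0.15, 0.20, 0.30, 0.40),
) -> pd.DataFrame:
    """Fraction of method-A significant pathways missed by B at each FDR.

    significant_A is fixed at ``fdr_a``; for each grid value g the unique
    fraction is |sig_A \\ sig_B(g)| / |sig_A| (0 when sig_A is empty).
    """

    def _frame(res) -> pd.DataFrame:
        if isinstance(res, pd.DataFrame):
            return res
        return pd.DataFrame(
            {"pathway_id": [r.pathway_id for r in res], "p_adj": [r.p_adj for r in res]}
        )

    a, b = _frame(results_a), _frame(results_b)
    sig_a = set(a.loc[a["p_adj"] <= fdr_a, "pathway_id"])
    rows = []
    for g in fdr_b_grid:
        sig_b = set(b.loc[b["p_adj"] <= g, "pathway_id"])
        unique = sig_a - sig_b
        rows.append(
            {
                "fdr_b": g,
                "n_sig_a": len(sig_a),
                "n_sig_b": len(sig_b),
                "n_unique_a": len(unique),
                "unique_fraction": (len(unique) / len(sig_a)) if sig_a else 0.0,
            }
        )
    return pd.DataFrame(rows)
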