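"""Weighted step enrichment via the multivariate Fisher's noncentral
hypergeometric distribution (mFNCHG).

The unweighted step test assumes every entity is equally likely to be
sampled, but a set of five interchangeable genes offers five chances for a
uniformly drawn gene to activate it.  To restore the gene-level uniform-draw
assumption while keeping the step-level test statistic, each entity is
weighted by its gene count and the composition of sampled entities is
modeled with the mFNCHG: items are drawn independently with odds
proportional to their weights, conditioned on the total number drawn, N.
(Fisher's conditioned-independent-draws model, not Wallenius's sequential
model, matches a differential-expression experiment where the number of
perturbed genes is itself random and only known afterwards.)

Urn parameterization
--------------------
Pathway entities are compressed into weight classes (identical weights merge
— exact by the Vandermonde identity, and it shrinks outcome enumeration).
The background is approximated as a single class holding the M - n entities
outside the pathway at their mean weight rounded to 2 decimal places, which
preserves the in-pathway vs out-of-pathway odds.

For outcome x (counts per class, sum = N):

    P(x) = [ prod_i C(m_i, x_i) w_i^{x_i} ] / Z

with Z summing the same product over every feasible outcome.  Z and the
tail masses are read off per-class generating polynomials
``sum_x C(m,x) w^x t^x`` convolved in log space (log-sum-exp), so no
simulation or explicit enumeration of the background is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .enrich import EnrichmentResult, _finalize, map_genes_to_entities
from .model import Background, Pathway, PathwayDB, entity_weight

__all__ = [
    "UrnSpec",
    "build_urn",
    "enumerate_outcomes",
    "mfnchg_pmf",
    "weighted_tail_p",
    "weighted_step_enrichment",
    "simulate_urn",
]

_NEG_INF = float("-inf")


def _log_comb(m: int, x) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    return gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)


@dataclass(frozen=True)
class UrnSpec:
    """Weight-class urn: pathway classes plus one mean-weight background class.

    ``classes`` is a tuple of (weight, count) pairs sorted by descending
    weight; ``bg_count = M_entities - n`` and ``N`` is the number of draws.
    """

    classes: tuple[tuple[float, int], ...]
    bg_weight: float
    bg_count: int
    N: int

    def __post_init__(self) -> None:
        for w, m in self.classes:
            if w <= 0 or m <= 0:
                raise ValueError(f"class weights and counts must be positive, got ({w}, {m})")
        if self.bg_weight <= 0:
            raise ValueError("background weight must be positive")
        if self.bg_count < 0:
            raise ValueError("background count must be >= 0")
        if not (0 <= self.N <= self.M):
            raise ValueError(f"draws N={self.N} outside [0, M={self.M}]")

    @property
    def n(self) -> int:
        return sum(m for _, m in self.classes)

    @property
    def M(self) -> int:
        return self.n + self.bg_count

    def scaled(self, c: float) -> "UrnSpec":
        """All weights multiplied by c > 0 (leaves every probability unchanged)."""
        return UrnSpec(
            tuple((w * c, m) for w, m in self.classes), self.bg_weight * c, self.bg_count, self.N
        )


def build_urn(pathway: Pathway, background: Background, N: int) -> UrnSpec:
    """Compress a pathway against its background into an UrnSpec.

    Pathway entities sharing a weight merge into one class; the remaining
    background entities (not in this pathway) collapse into a single class at
    their mean weight rounded to 2 decimal places.
    """
    if N > background.M_entities:
        raise ValueError(f"N={N} exceeds background size {background.M_entities}")
    path_ids = pathway.entity_ids
    counts: dict[int, int] = {}
    for ent in pathway.entities:
        w = entity_weight(ent)
        counts[w] = counts.get(w, 0) + 1
    classes = tuple(sorted(((float(w), m) for w, m in counts.items()), reverse=True))
    bg_entities = [e for e in background.entities if e.canonical_id not in path_ids]
    if bg_entities:
        bg_weight = round(sum(entity_weight(e) for e in bg_entities) / len(bg_entities), 2)
    else:
        bg_weight = 1.0
    return UrnSpec(classes=classes, bg_weight=bg_weight, bg_count=len(bg_entities), N=N)


def _class_log_poly(w: float, m: int, degree_cap: int | None = None) -> np.ndarray:
    hi = m if degree_cap is None else min(m, degree_cap)
    x = np.arange(hi + 1)
    return _log_comb(m, x) + x * math.log(w)


def _log_conv(a: np.ndarray, b: np.ndarray, degree_cap: int | None = None) -> np.ndarray:
    out_len = len(a) + len(b) - 1
    if degree_cap is not None:
        out_len = min(out_len, degree_cap + 1)
    out = np.full(out_len, _NEG_INF)
    for i, ai in enumerate(a):
        if ai == _NEG_INF or i >= out_len:
            continue
        hi = min(len(b), out_len - i)
        out[i : i + hi] = np.logaddexp(out[i : i + hi], ai + b[:hi])
    return out


@lru_cache(maxsize=8192)
def _pathway_log_poly(classes: tuple[tuple[float, int], ...]) -> np.ndarray:
    """log coefficients L[j] = log sum over pathway outcomes with total j of
    prod C(m_i, x_i) w_i^{x_i}; degree = n."""
    poly = np.zeros(1)
    for w, m in classes:
        poly = _log_conv(poly, _class_log_poly(w, m))
    poly.setflags(write=False)
    return poly


def _log_bg_term(urn: UrnSpec, j: int) -> float:
    """log weight-mass of drawing the remaining N - j items from the background."""
    r = urn.N - j
    if r < 0 or r > urn.bg_count:
        return _NEG_INF
    return float(_log_comb(urn.bg_count, r)) + r * math.log(urn.bg_weight)


@lru_cache(maxsize=8192)
def _log_partition(urn: UrnSpec) -> float:
    L = _pathway_log_poly(urn.classes)
    terms = [
        L[j] + _log_bg_term(urn, j)
        for j in range(0, min(urn.n, urn.N) + 1)
        if L[j] > _NEG_INF and _log_bg_term(urn, j) > _NEG_INF
    ]
    if not terms:
        raise ValueError("urn admits no feasible outcome")
    return float(logsumexp(terms))


def enumerate_outcomes(urn: UrnSpec, j: int) -> list[tuple[int, ...]]:
    """All pathway-class composition vectors with total j, in lexicographic
    order; empty when infeasible (including when the background cannot absorb
    the remaining N - j draws)."""
    if j < 0 or j > min(urn.n, urn.N):
        raise ValueError(f"pathway total j={j} outside [0, min(n, N)]")
    if urn.N - j > urn.bg_count:
        return []
    bounds = [m for _, m in urn.classes]
    out: list[tuple[int, ...]] = []

    def rec(idx: int, remaining: int, prefix: tuple[int, ...]) -> None:
        if idx == len(bounds):
            if remaining == 0:
                out.append(prefix)
            return
        tail_capacity = sum(bounds[idx + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(bounds[idx], remaining)
        for v in range(lo, hi + 1):
            rec(idx + 1, remaining - v, prefix + (v,))

    rec(0, j, ())
    return out


def mfnchg_pmf(x: Sequence[int], urn: UrnSpec) -> float:
    """Probability of outcome x = (pathway-class counts..., background count)."""
    x = tuple(int(v) for v in x)
    if len(x) != len(urn.classes) + 1:
        raise ValueError(f"outcome length {len(x)} != {len(urn.classes) + 1} classes")
    bounds = [m for _, m in urn.classes] + [urn.bg_count]
    if any(v < 0 or v > b for v, b in zip(x, bounds)) or sum(x) != urn.N:
        raise ValueError(f"infeasible outcome {x} for urn {urn}")
    weights = [w for w, _ in urn.classes] + [urn.bg_weight]
    log_term = sum(
        float(_log_comb(m, v)) + v * math.log(w) for v, m, w in zip(x, bounds, weights)
    )
    return float(math.exp(log_term - _log_partition(urn)))


def weighted_tail_p(k: int, urn: UrnSpec) -> float:
    """P(K >= k) where K is the number of pathway entities among the N draws.

    Equals ``sum_{j>=k} sum_{x in enumerate_outcomes(urn, j)} mfnchg_pmf(x)``;
    the per-j inner sums are read directly off the pathway generating
    polynomial, which is the same quantity without re-enumeration.
    """
    jmax = min(urn.n, urn.N)
    if not (0 <= k <= jmax):
        raise ValueError(f"k={k} outside [0, min(n={urn.n}, N={urn.N})]")
    if k == 0:
        return 1.0
    L = _pathway_log_poly(urn.classes)
    terms = [
        L[j] + _log_bg_term(urn, j)
        for j in range(k, jmax + 1)
        if L[j] > _NEG_INF and _log_bg_term(urn, j) > _NEG_INF
    ]
    if not terms:
        return 0.0
    p = math.exp(float(logsumexp(terms)) - _log_partition(urn))
    return min(max(p, 0.0), 1.0)


def weighted_step_enrichment(genes: Iterable[str], db: PathwayDB) -> list[EnrichmentResult]:
    """Step enrichment with set entities weighted by their gene counts.

    Entity mapping, k, n, N, and M are identical to the unweighted step
    method; only the tail probability changes (method tag ``wstep``).
    """
    bg = db.background
    hits = map_genes_to_entities(genes, bg)
    N, M = len(hits), bg.M_entities
    results = []
    for pw in db.pathways:
        matched = [e for e in pw.entities if e.canonical_id in hits]
        k, n = len(matched), pw.n
        urn = build_urn(pw, bg, N)
        member_hits = ";".join(",".join(sorted(hits[e.canonical_id])) for e in matched)
        results.append(
            EnrichmentResult(
                pathway_id=pw.id,
                title=pw.title,
                method="wstep",
                k=k,
                n=n,
                N=N,
                M=M,
                p_raw=weighted_tail_p(k, urn),
                p_adj=1.0,
                member_hits=member_hits,
            )
        )
    return _finalize(results)


def simulate_urn(urn: UrnSpec, reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo oracle: empirical P(K >= k) for k = 0..min(n, N).

    Draws reps outcomes from the exact conditional distribution by sequential
    conditional sampling: class by class, the count for class i given r
    remaining draws is categorical with probabilities proportional to
    ``classpoly_i[v] * suffixpoly_{i+1}[r - v]``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    N = urn.N
    kmax = min(urn.n, urn.N)
    if N == 0:
        tails = np.zeros(kmax + 1)
        tails[0] = 1.0
        return tails
    all_classes = list(urn.classes) + [(urn.bg_weight, urn.bg_count)]
    polys = [_class_log_poly(w, m, degree_cap=N) for w, m in all_classes]
    suffix: list[np.ndarray] = [np.zeros(1)] * (len(all_classes) + 1)
    for i in range(len(all_classes) - 1, -1, -1):
        suffix[i] = _log_conv(polys[i], suffix[i + 1], degree_cap=N)
    rng = np.random.default_rng(seed)
    remaining = np.full(reps, N, dtype=int)
    k_path = np.zeros(reps, dtype=int)
    for i, (w, m) in enumerate(all_classes):
        draws = np.zeros(reps, dtype=int)
        suf = suffix[i + 1]
        for r in np.unique(remaining):
            mask = remaining == r
            vmax = min(m, int(r))
            logp = np.array(
                [
                    polys[i][v] + (suf[r - v] if r - v < len(suf) else _NEG_INF)
                    for v in range(vmax + 1)
                ]
            )
            finite = logp > _NEG_INF
            if not finite.any():
                raise ValueError("urn admits no feasible outcome")
            probs = np.zeros(vmax + 1)
            probs[finite] = np.exp(logp[finite] - logsumexp(logp[finite]))
            probs /= probs.sum()
            draws[mask] = rng.choice(vmax + 1, size=int(mask.sum()), p=probs)
        if i < len(urn.classes):
            k_path += draws
        remaining -= draws
    assert (remaining == 0).all()
    return np.array([np.mean(k_path >= k) for k in range(kmax + 1)])
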