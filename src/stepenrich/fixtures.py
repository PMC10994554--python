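"""Synthetic pathway databases, perturbation gene lists, and brute-force
oracles.

The generator emulates the structural mix found in curated pathway models:
mostly solo-protein steps, some complexes (AND logic), some flat sets (OR
logic), and occasional sets-of-complexes sharing a common subunit.  Input
lists emulate the premise that a cell regulating a step perturbs one (or few)
members of a set, not all of them: for each perturbed pathway a chosen
fraction of entities is activated, each set contributing a fixed number of
randomly chosen members, optionally diluted with noise genes from the
unperturbed background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .io import export_gmt  # re-exported: GMT supports external cross-checks
from .model import (
    EntityNode,
    Pathway,
    PathwayDB,
    build_pathway,
)
from .weighted import UrnSpec

__all__ = [
    "ScenarioSpec",
    "gen_pathway_db",
    "gen_input_list",
    "brute_force_tail",
    "export_gmt",
]


class ConfigurationError(ValueError):
    """Raised for infeasible scenario specifications."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters for a synthetic pathway database and perturbation scenario.

    Entity-kind probabilities are (nested set-of-complexes, complex, flat
    set, solo = remainder).  Defaults lean towards solo steps, as curated
    databases do, with enough sets to exercise the set-aware statistics.
    """

    seed: int
    n_pathways: int = 15
    entities_per_pathway: tuple[int, int] = (4, 12)
    set_size: tuple[int, int] = (2, 6)
    complex_size: tuple[int, int] = (2, 4)
    complex_prob: float = 0.15
    set_prob: float = 0.20
    nested_prob: float = 0.05
    nesting_depth: int = 1
    n_genes: int = 400
    perturbed: tuple[str, ...] = ()
    fraction: float = 1.0
    members_per_set: int = 1
    noise_genes: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if self.n_pathways < 1 or self.n_genes < 1:
            raise ConfigurationError("n_pathways and n_genes must be positive")
        for name in ("entities_per_pathway", "set_size", "complex_size"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        total_p = self.complex_prob + self.set_prob + self.nested_prob
        if min(self.complex_prob, self.set_prob, self.nested_prob) < 0 or total_p > 1:
            raise ConfigurationError("entity-kind probabilities must be >= 0 and sum <= 1")
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigurationError("fraction must be in [0, 1]")
        if self.members_per_set < 1 or self.noise_genes < 0:
            raise ConfigurationError("members_per_set >= 1 and noise_genes >= 0 required")
        if self.nesting_depth < 1:
            raise ConfigurationError("nesting_depth must be >= 1")
        # worst case gene demand of one pathway must fit the pool
        worst_entity = max(self.set_size[1], self.complex_size[1], 1 + 3 * self.complex_size[1])
        if self.entities_per_pathway[1] * worst_entity > self.n_genes:
            raise ConfigurationError(
                "gene pool too small for the requested pathway sizes"
            )


def _gene_pool(spec: ScenarioSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def gen_pathway_db(spec: ScenarioSpec) -> PathwayDB:
    """Deterministically generate a pathway database from a scenario spec.

    Entities within one pathway use disjoint genes (drawn from a per-pathway
    shuffle of the shared pool); distinct pathways may overlap, as real
    databases do.
    """
    rng = np.random.default_rng(spec.seed)
    pool = _gene_pool(spec)
    lo, hi = spec.entities_per_pathway
    pathways: list[Pathway] = []
    for idx in range(spec.n_pathways):
        n_ent = int(rng.integers(lo, hi + 1))
        avail = [pool[i] for i in rng.permutation(spec.n_genes)]

        def take(count: int) -> list[str]:
            if count > len(avail):
                raise ConfigurationError("gene pool exhausted within a pathway")
            return [avail.pop() for _ in range(count)]

        enablers: list[EntityNode] = []
        for _ in range(n_ent):
            u = float(rng.random())
            if u < spec.nested_prob:
                # set of complexes sharing one common subunit
                n_alt = int(rng.integers(2, 4))
                common = take(1)[0]
                alts = take(n_alt)
                enablers.append(
                    EntityNode.set_of(
                        EntityNode.complex([EntityNode.protein(common), EntityNode.protein(a)])
                        for a in alts
                    )
                )
            elif u < spec.nested_prob + spec.complex_prob:
                size = int(rng.integers(spec.complex_size[0], spec.complex_size[1] + 1))
                enablers.append(
                    EntityNode.complex(EntityNode.protein(g) for g in take(size))
                )
            elif u < spec.nested_prob + spec.complex_prob + spec.set_prob:
                size = int(rng.integers(spec.set_size[0], spec.set_size[1] + 1))
                enablers.append(
                    EntityNode.set_of(EntityNode.protein(g) for g in take(size))
                )
            else:
                enablers.append(EntityNode.protein(take(1)[0]))
        pathways.append(build_pathway(f"PW{idx:03d}", f"Synthetic pathway {idx}", enablers))
    return PathwayDB.from_pathways(pathways)


def gen_input_list(db: PathwayDB, spec: ScenarioSpec) -> tuple[list[str], dict[str, list[str]]]:
    """Generate a differential-expression-style gene list plus truth labels.

    For each perturbed pathway, ceil(fraction * n) entities are chosen; solo
    entities emit their gene, sets emit ``members_per_set`` random members.
    Noise genes come from background genes outside every perturbed pathway.
    Returns (gene list, {pathway_id: perturbed entity canonical_ids}).
    """
    rng = np.random.default_rng([spec.seed, 7919])
    genes: dict[str, None] = {}
    truth: dict[str, list[str]] = {}
    perturbed_genes: set[str] = set()
    for pid in spec.perturbed:
        pw = db.get(pid)
        perturbed_genes |= pw.gene_list
        n_sel = math.ceil(spec.fraction * pw.n)
        chosen_idx = sorted(rng.choice(pw.n, size=n_sel, replace=False))
        chosen = [pw.entities[i] for i in chosen_idx]
        truth[pid] = [e.canonical_id for e in chosen]
        for ent in chosen:
            members = sorted(ent.members)
            take = min(spec.members_per_set, len(members))
            for i in rng.choice(len(members), size=take, replace=False):
                genes.setdefault(members[int(i)], None)
    if spec.noise_genes:
        noise_pool = sorted(set(db.background.genes) - perturbed_genes)
        if spec.noise_genes > len(noise_pool):
            raise ConfigurationError("not enough unperturbed background genes for noise")
        for i in rng.choice(len(noise_pool), size=spec.noise_genes, replace=False):
            genes.setdefault(noise_pool[int(i)], None)
    return list(genes), truth


def sample_urns(
    n_urns: int,
    seed: int,
    max_classes: int = 5,
    max_m: int = 4,
    max_bg: int = 6,
    max_n_draws: int = 8,
) -> list[UrnSpec]:
    """Random small urns (distinct integer pathway weights, 2-dp background
    weight) sized for brute-force verification."""
    rng = np.random.default_rng(seed)
    urns: list[UrnSpec] = []
    while len(urns) < n_urns:
        n_classes = int(rng.integers(1, max_classes + 1))
        weights = rng.choice(np.arange(1, 9), size=n_classes, replace=False)
        classes = tuple(
            sorted(
                ((float(w), int(rng.integers(1, max_m + 1))) for w in weights),
                reverse=True,
            )
        )
        bg_count = int(rng.integers(0, max_bg + 1))
        bg_weight = round(float(rng.uniform(0.5, 4.0)), 2)
        n = sum(m for _, m in classes)
        N = int(rng.integers(0, min(max_n_draws, n + bg_count) + 1))
        urns.append(UrnSpec(classes=classes, bg_weight=bg_weight, bg_count=bg_count, N=N))
    return urns


_MAX_BRUTE_SPACE = 10**6


def brute_force_tail(k: int, urn: UrnSpec) -> float:
    """Exact-rational oracle for :func:`stepenrich.weighted.weighted_tail_p`.

    Enumerates every feasible outcome over all classes (pathway classes and
    the background class, no compression shortcuts), accumulates unnormalized
    terms as exact fractions, and returns the normalized mass of outcomes
    whose pathway total is >= k.  Refuses outcome spaces above 10^6.
    """
    all_classes = list(urn.classes) + [(urn.bg_weight, urn.bg_count)]
    space = 1
    for _, m in all_classes:
        space *= min(m, urn.N) + 1
        if space > _MAX_BRUTE_SPACE:
            raise ConfigurationError("outcome space too large for brute-force enumeration")
    if not (0 <= k <= min(urn.n, urn.N)):
        raise ValueError(f"k={k} outside [0, min(n, N)]")
    weights = [Fraction(str(w)) for w, _ in all_classes]
    bounds = [m for _, m in all_classes]
    n_path = len(urn.classes)
    total = Fraction(0)
    tail = Fraction(0)

    def rec(idx: int, remaining: int, path_total: int, term: Fraction) -> None:
        nonlocal total, tail
        if idx == len(bounds):
            if remaining == 0:
                total += term
                if path_total >= k:
                    tail += term
            return
        for v in range(min(bounds[idx], remaining) + 1):
            rec(
                idx + 1,
                remaining - v,
                path_total + (v if idx < n_path else 0),
                term * math.comb(bounds[idx], v) * weights[idx] ** v,
            )

    rec(0, urn.N, 0, Fraction(1))
    if total == 0:
        raise ValueError("urn admits no feasible outcome")
    return float(tail / total)
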