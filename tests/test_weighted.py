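"""mFNCHG urn construction, pmf, tail p-values, simulation oracle."""

import itertools
import math

import numpy as np
import pytest

from stepenrich import (
    EntityNode,
    PathwayDB,
    UrnSpec,
    build_pathway,
    build_urn,
    enumerate_outcomes,
    hypergeom_tail,
    mfnchg_pmf,
    simulate_urn,
    step_enrichment,
    weighted_step_enrichment,
    weighted_tail_p,
)
from stepenrich.fixtures import ScenarioSpec, brute_force_tail, gen_pathway_db

_p = EntityNode.protein

TOY = UrnSpec(classes=((2.0, 1), (1.0, 1)), bg_weight=1.0, bg_count=2, N=2)


class TestBuildUrn:
    def test_grouping_by_weight(self, multi_db):
        pw = build_pathway(
            "w",
            "w",
            [
                EntityNode.set_of([_p(f"A{i}") for i in range(5)]),
                _p("B1"),
                _p("B2"),
                EntityNode.set_of([_p("C1"), _p("C2"), _p("C3")]),
                _p("B3"),
            ],
        )
        db = PathwayDB.from_pathways([pw] + multi_db.pathways)
        urn = build_urn(pw, db.background, N=3)
        assert urn.classes == ((5.0, 1), (3.0, 1), (1.0, 3))
        assert urn.n == 5
        assert urn.bg_count == db.background.M_entities - 5

    def test_mean_background_weight_rounded_two_dp(self):
        p1 = build_pathway("a", "a", [_p("X")])
        p2 = build_pathway(
            "b", "b", [_p("Y"), _p("Z"), EntityNode.set_of([_p("S1"), _p("S2")])]
        )
        db = PathwayDB.from_pathways([p1, p2])
        urn = build_urn(p1, db.background, N=1)
        # background entities: solo Y, solo Z, set{S1,S2} -> mean 4/3 -> 1.33
        assert urn.bg_weight == pytest.approx(1.33)

    def test_all_solo_everything_weight_one(self, multi_db):
        p = build_pathway("s", "s", [_p("U1"), _p("U2")])
        db = PathwayDB.from_pathways([p] + multi_db.pathways)
        urn = build_urn(p, db.background, N=2)
        assert urn.classes == ((1.0, 2),)

    def test_draws_exceeding_background_rejected(self, fig_db):
        with pytest.raises(ValueError):
            build_urn(fig_db.pathways[0], fig_db.background, N=99)


class TestPmf:
    def test_toy_urn_pmf(self):
        # outcomes over (set w2, solo w1, bg w1 x2), N=2: terms 2,4,2,1 -> Z=9
        assert mfnchg_pmf((1, 0, 1), TOY) == pytest.approx(4 / 9, abs=1e-12)
        assert mfnchg_pmf((1, 1, 0), TOY) == pytest.approx(2 / 9, abs=1e-12)
        assert mfnchg_pmf((0, 0, 2), TOY) == pytest.approx(1 / 9, abs=1e-12)

    def test_equal_weights_reduce_to_central(self):
        urn = UrnSpec(classes=((1.0, 2), (1.0, 1)), bg_weight=1.0, bg_count=3, N=3)
        for x in [(1, 0, 2), (2, 1, 0), (0, 0, 3)]:
            central = (
                math.comb(2, x[0]) * math.comb(1, x[1]) * math.comb(3, x[2])
            ) / math.comb(6, 3)
            assert mfnchg_pmf(x, urn) == pytest.approx(central, abs=1e-12)

    def test_pmf_sums_to_one(self):
        total = 0.0
        for x0 in range(2):
            for x1 in range(2):
                x2 = TOY.N - x0 - x1
                if 0 <= x2 <= TOY.bg_count:
                    total += mfnchg_pmf((x0, x1, x2), TOY)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_outcome_rejected(self):
        with pytest.raises(ValueError):
            mfnchg_pmf((2, 0, 0), TOY)
        with pytest.raises(ValueError):
            mfnchg_pmf((1, 1, 1), TOY)


class TestEnumerateOutcomes:
    def test_two_classes_total_one(self):
        assert enumerate_outcomes(TOY, 1) == [(0, 1), (1, 0)]

    def test_zero_total_feasibility(self):
        assert enumerate_outcomes(TOY, 0) == [(0, 0)]
        tight = UrnSpec(classes=((2.0, 1), (1.0, 1)), bg_weight=1.0, bg_count=1, N=2)
        assert enumerate_outcomes(tight, 0) == []

    def test_single_class(self):
        urn = UrnSpec(classes=((1.0, 3),), bg_weight=1.0, bg_count=5, N=4)
        assert enumerate_outcomes(urn, 2) == [(2,)]

    def test_matches_pmf_tail(self):
        """Summing mfnchg_pmf over enumerated outcomes equals weighted_tail_p."""
        urn = UrnSpec(classes=((3.0, 2), (1.0, 2)), bg_weight=1.5, bg_count=4, N=4)
        for k in range(min(urn.n, urn.N) + 1):
            total = 0.0
            for j in range(k, min(urn.n, urn.N) + 1):
                for x in enumerate_outcomes(urn, j):
                    total += mfnchg_pmf(x + (urn.N - j,), urn)
            assert weighted_tail_p(k, urn) == pytest.approx(total, abs=1e-12)


class TestWeightedTail:
    def test_toy_urn_tails(self):
        assert weighted_tail_p(0, TOY) == 1.0
        assert weighted_tail_p(1, TOY) == pytest.approx(8 / 9, abs=1e-12)
        assert weighted_tail_p(2, TOY) == pytest.approx(2 / 9, abs=1e-12)

    def test_unit_weight_matches_central_hypergeometric(self):
        urn = UrnSpec(classes=((1.0, 1), (1.0, 1)), bg_weight=1.0, bg_count=2, N=2)
        assert weighted_tail_p(2, urn) == pytest.approx(1 / 6, abs=1e-12)
        assert weighted_tail_p(2, urn) == pytest.approx(hypergeom_tail(2, 2, 2, 4), abs=1e-12)
        # upweighting the set increases the tail p (2/9 > 1/6)
        assert weighted_tail_p(2, TOY) > weighted_tail_p(2, urn)

    def test_non_increasing_in_k(self):
        urn = UrnSpec(classes=((4.0, 2), (2.0, 1), (1.0, 3)), bg_weight=1.2, bg_count=8, N=6)
        ps = [weighted_tail_p(k, urn) for k in range(min(urn.n, urn.N) + 1)]
        assert all(a >= b - 1e-14 for a, b in zip(ps, ps[1:]))

    def test_increasing_pathway_weight_does_not_decrease_tail(self):
        base = UrnSpec(classes=((2.0, 1), (1.0, 2)), bg_weight=1.0, bg_count=5, N=4)
        for k in range(1, 4):
            p0 = weighted_tail_p(k, base)
            boosted = UrnSpec(classes=((5.0, 1), (1.0, 2)), bg_weight=1.0, bg_count=5, N=4)
            assert weighted_tail_p(k, boosted) >= p0 - 1e-12

    def test_scaling_all_weights_is_invariant(self):
        urn = UrnSpec(classes=((3.0, 2), (1.0, 2)), bg_weight=1.37, bg_count=6, N=5)
        for c in (0.25, 2.0, 7.5):
            scaled = urn.scaled(c)
            for k in range(min(urn.n, urn.N) + 1):
                assert weighted_tail_p(k, scaled) == pytest.approx(
                    weighted_tail_p(k, urn), abs=1e-12
                )

    def test_splitting_weight_class_is_invariant(self):
        merged = UrnSpec(classes=((2.0, 4), (1.0, 2)), bg_weight=1.1, bg_count=6, N=5)
        split = UrnSpec(classes=((2.0, 1), (2.0, 3), (1.0, 2)), bg_weight=1.1, bg_count=6, N=5)
        for k in range(min(merged.n, merged.N) + 1):
            assert weighted_tail_p(k, split) == pytest.approx(
                weighted_tail_p(k, merged), abs=1e-12
            )

    def test_matches_brute_force_battery(self):
        urns = [
            TOY,
            UrnSpec(classes=((5.0, 1), (3.0, 1), (1.0, 3)), bg_weight=1.33, bg_count=6, N=5),
            UrnSpec(classes=((4.0, 2),), bg_weight=2.5, bg_count=4, N=3),
            UrnSpec(classes=((2.0, 2), (1.5, 1), (1.0, 2)), bg_weight=1.0, bg_count=5, N=6),
        ]
        for urn in urns:
            for k in range(min(urn.n, urn.N) + 1):
                assert weighted_tail_p(k, urn) == pytest.approx(
                    brute_force_tail(k, urn), abs=1e-10
                )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            weighted_tail_p(3, TOY)
        with pytest.raises(ValueError):
            weighted_tail_p(-1, TOY)


class TestWeightedEnrichment:
    def test_all_solo_db_equals_unweighted(self):
        spec = ScenarioSpec(seed=11, n_pathways=8, complex_prob=0.2, set_prob=0.0, nested_prob=0.0)
        db = gen_pathway_db(spec)
        genes = sorted(db.pathways[0].gene_list)[:5]
        w = {r.pathway_id: r for r in weighted_step_enrichment(genes, db)}
        s = {r.pathway_id: r for r in step_enrichment(genes, db)}
        for pid in w:
            assert w[pid].p_raw == pytest.approx(s[pid].p_raw, abs=1e-9)
            assert (w[pid].k, w[pid].n, w[pid].N, w[pid].M) == (
                s[pid].k, s[pid].n, s[pid].N, s[pid].M,
            )

    def test_worked_example_against_brute_force(self, fig_db):
        (res,) = weighted_step_enrichment(["P1", "P2", "P4"], fig_db)
        assert (res.k, res.n, res.N, res.M) == (2, 4, 2, 4)
        urn = build_urn(fig_db.pathways[0], fig_db.background, N=2)
        assert urn.classes == ((2.0, 1), (1.0, 3))
        assert res.p_raw == pytest.approx(brute_force_tail(2, urn), abs=1e-12)

    def test_large_set_raises_p_above_unweighted(self, multi_db):
        # pathway dominated by one large set, input hits one member per entity
        big_set = EntityNode.set_of([_p(f"PC{i:02d}") for i in range(44)])
        pw = build_pathway("collagen-like", "collagen-like", [big_set, _p("LOX1"), _p("LOX2")])
        db = PathwayDB.from_pathways([pw] + multi_db.pathways)
        genes = ["PC01", "LOX1", "LOX2"]
        w = next(r for r in weighted_step_enrichment(genes, db) if r.pathway_id == "collagen-like")
        s = next(r for r in step_enrichment(genes, db) if r.pathway_id == "collagen-like")
        assert w.k == s.k == 3
        assert w.p_raw > s.p_raw


class TestSimulateUrn:
    def test_same_seed_reproducible(self):
        a = simulate_urn(TOY, reps=2000, seed=5)
        b = simulate_urn(TOY, reps=2000, seed=5)
        assert np.array_equal(a, b)

    def test_zero_draws(self):
        urn = UrnSpec(classes=((2.0, 1),), bg_weight=1.0, bg_count=3, N=0)
        tails = simulate_urn(urn, reps=10, seed=1)
        assert tails[0] == 1.0

    def test_within_three_standard_errors_of_exact(self):
        reps = 20000
        for urn in (TOY, UrnSpec(classes=((3.0, 1), (1.0, 2)), bg_weight=1.5, bg_count=5, N=4)):
            tails = simulate_urn(urn, reps=reps, seed=42)
            for k in range(1, min(urn.n, urn.N) + 1):
                p = weighted_tail_p(k, urn)
                se = math.sqrt(p * (1 - p) / reps)
                assert abs(tails[k] - p) <= max(3 * se, 1e-3)
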