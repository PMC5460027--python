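"""Screen statistics: dropout hit calling, essentiality ranking,
preranked enrichment, overlap and pathway tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from misl import (
    call_dropout_hits,
    generate_screen,
    overlap_test,
    preranked_enrichment,
    same_pathway_enrichment,
    score_mutation_essentiality,
)
from misl.errors import MislError, ValidationError
from misl.screen import EssentialityRanking, _running_sum_es


def screen_frame(rows):
    return pd.DataFrame(rows, columns=["construct_id", "gene", "baseline", "treated"])


def constructs(gene, ratios, baseline=1000):
    return [
        (f"{gene}_sh{i}", gene, baseline, round(baseline * r))
        for i, r in enumerate(ratios, start=1)
    ]


class TestDropoutHits:
    def test_hand_enumerated_hit(self):
        # qualifying ratios {0.5, 0.55}, mean 0.525 < 0.6 -> hit
        screen = screen_frame(constructs("GA", [0.5, 0.55, 0.9]))
        assert call_dropout_hits(screen, "baseline", "treated") == {"GA"}

    def test_mean_ratio_gate_blocks(self):
        # qualifying {0.79, 0.78}, mean 0.785 >= 0.6 -> not a hit
        screen = screen_frame(constructs("GB", [0.79, 0.78, 0.9]))
        assert call_dropout_hits(screen, "baseline", "treated") == set()

    def test_fewer_than_three_constructs_excluded(self):
        screen = screen_frame(constructs("GC", [0.1, 0.1]))
        assert call_dropout_hits(screen, "baseline", "treated") == set()

    def test_read_floor_can_disqualify_gene(self):
        # third construct below 100 baseline reads -> only 2 survive -> excluded
        rows = constructs("GD", [0.1, 0.1]) + [("GD_sh3", "GD", 99, 10)]
        assert call_dropout_hits(screen_frame(rows), "baseline", "treated") == set()

    def test_single_qualifying_construct_not_enough(self):
        screen = screen_frame(constructs("GE", [0.1, 0.95, 0.95]))
        assert call_dropout_hits(screen, "baseline", "treated") == set()

    def test_invariant_to_construct_order_and_floor_noise(self):
        rows = constructs("GA", [0.5, 0.55, 0.9]) + constructs("GB", [1.0, 1.0, 1.0])
        shuffled = screen_frame(rows).sample(frac=1.0, random_state=0)
        with_junk = pd.concat(
            [shuffled, screen_frame([("junk", "GA", 50, 1)])], ignore_index=True
        )
        assert call_dropout_hits(with_junk, "baseline", "treated") == {"GA"}

    def test_twenty_construct_table_every_gate(self):
        """One table exercising the read floor, the redundancy rule, the
        per-construct reduction gate and the per-gene mean-ratio gate."""
        rows = (
            constructs("HIT1", [0.5, 0.55, 0.9])          # hit
            + constructs("HIT2", [0.3, 0.4, 0.5, 0.95])   # hit, 3 qualifying
            + constructs("MEAN", [0.79, 0.78, 0.9])       # fails mean gate
            + constructs("FEW", [0.1, 0.1])               # < 3 constructs
            + constructs("ONE", [0.1, 0.95, 0.95])        # 1 qualifying
            + [("FLOOR_sh1", "FLOOR", 10, 1),             # all below floor
               ("FLOOR_sh2", "FLOOR", 20, 2),
               ("FLOOR_sh3", "FLOOR", 30, 3)]
            + constructs("NULL", [1.0, 1.05])
        )
        assert len(rows) == 20
        assert call_dropout_hits(screen_frame(rows), "baseline", "treated") == {"HIT1", "HIT2"}

    def test_planted_screen_gene_called(self, standard_truth):
        screen = generate_screen(standard_truth)
        hits = call_dropout_hits(screen, "baseline", "treated")
        planted = {b for _, b in standard_truth.planted_hi_lo + standard_truth.planted_hi_hi}
        assert planted <= hits


def score_screen(genes_scores, mut_lines, wt_lines, constructs_per_gene=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gene, shift in genes_scores.items():
        for j in range(constructs_per_gene):
            row = {"construct_id": f"{gene}_{j}", "gene": gene}
            row.update({l: rng.normal(0, 0.2) - shift for l in mut_lines})
            row.update({l: rng.normal(0, 0.2) for l in wt_lines})
            rows.append(row)
    return pd.DataFrame(rows)


class TestEssentialityRanking:
    MUT = [f"M{i}" for i in range(8)]
    WT = [f"W{i}" for i in range(8)]

    def test_planted_essential_gene_ranks_first(self):
        screen = score_screen({"ESS": 1.0, **{f"N{i}": 0.0 for i in range(30)}}, self.MUT, self.WT)
        ranking = score_mutation_essentiality(screen, self.MUT, self.WT)
        assert ranking.ordering[0] == "ESS"
        assert ranking.scores["ESS"] > 0

    def test_identical_groups_score_near_zero(self):
        screen = score_screen({"FLAT": 0.0}, self.MUT, self.WT, seed=5)
        ranking = score_mutation_essentiality(screen, self.MUT, self.WT)
        assert abs(ranking.scores["FLAT"]) < 1.0

    def test_construct_filter_removes_gene(self):
        screen = score_screen({"A": 0.0, "B": 0.0}, self.MUT, self.WT)
        screen = screen[~screen["construct_id"].isin(["B_2"])]  # B down to 2 constructs
        ranking = score_mutation_essentiality(screen, self.MUT, self.WT)
        assert "B" not in ranking.scores.index and "A" in ranking.scores.index

    def test_sign_convention_by_perturbation(self):
        """Artificially depleting a gene's mutant scores strictly
        increases its rank."""
        base = score_screen({f"N{i}": 0.0 for i in range(20)}, self.MUT, self.WT, seed=2)
        r0 = score_mutation_essentiality(base, self.MUT, self.WT)
        target = "N7"
        before = r0.ordering.index(target)
        depleted = base.copy()
        depleted.loc[depleted["gene"] == target, self.MUT] -= 2.0
        r1 = score_mutation_essentiality(depleted, self.MUT, self.WT)
        assert r1.ordering.index(target) < before
        assert r1.ordering.index(target) == 0


def brute_force_es(scores, hit_genes, weight=1.0):
    """Independent running-sum maximum-deviation computation."""
    running, best = 0.0, 0.0
    hits = [g in hit_genes for g in scores.index]
    total_w = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    n_miss = len(scores) - sum(hits)
    for s, h in zip(scores, hits):
        running += (abs(s) ** weight) / total_w if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def make_ranking(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    return EssentialityRanking(pd.Series(scores, index=[f"G{i:03d}" for i in range(n)]))


class TestPrerankedEnrichment:
    def test_es_equals_brute_force_on_fixtures(self):
        for seed in range(5):
            ranking = make_ranking(150, seed)
            rng = np.random.default_rng(100 + seed)
            gene_set = set(rng.choice(ranking.ordering, size=40, replace=False))
            res = preranked_enrichment(ranking, gene_set, n_permutations=50, seed=1)
            assert res.es == pytest.approx(
                brute_force_es(ranking.scores, gene_set), abs=1e-12
            )

    def test_top_of_list_set_maxes_out(self):
        ranking = make_ranking(200)
        top = set(ranking.ordering[:30])
        res = preranked_enrichment(ranking, top, n_permutations=500, seed=3)
        assert res.es > 0.9
        assert res.p_value < 0.02  # permutation floor: no null reaches the ES
        assert res.nes > 1

    def test_bottom_of_list_set_negative(self):
        ranking = make_ranking(200)
        bottom = set(ranking.ordering[-30:])
        res = preranked_enrichment(ranking, bottom, n_permutations=200, seed=3)
        assert res.es < 0
        assert res.nes < 0

    def test_overlap_gate_names_requirement(self):
        ranking = make_ranking(100)
        with pytest.raises(MislError, match=">= 25"):
            preranked_enrichment(ranking, set(ranking.ordering[:10]))

    def test_null_pvalues_uniform(self):
        """Random gene sets produce uniform permutation p-values."""
        ranking = make_ranking(150, seed=9)
        rng = np.random.default_rng(77)
        pvals = []
        for i in range(120):
            gene_set = set(rng.choice(ranking.ordering, size=30, replace=False))
            res = preranked_enrichment(ranking, gene_set, n_permutations=99, seed=1000 + i)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestOverlapTest:
    def test_matches_hypergeometric_oracle_screen_dimensions(self):
        """At the dimensions of a genome-scale screen (universe 8189,
        lists of 61 and 776) the Fisher p equals the hypergeometric
        enumeration to 1e-10."""
        universe = {f"U{i}" for i in range(8189)}
        ordered = sorted(universe)
        a = set(ordered[:61])
        b = set(ordered[50:826])  # overlap 11
        overlap, p = overlap_test(a, b, universe)
        assert overlap == 11
        n, K, na = 8189, 776, 61
        pmf = hypergeom.pmf(np.arange(0, 62), n, K, na)
        expected = float(pmf[pmf <= hypergeom.pmf(11, n, K, na) * (1 + 1e-7)].sum())
        assert p == pytest.approx(expected, abs=1e-10)

    def test_symmetric_in_sets(self):
        universe = {f"U{i}" for i in range(200)}
        ordered = sorted(universe)
        a, b = set(ordered[:30]), set(ordered[20:80])
        assert overlap_test(a, b, universe) == overlap_test(b, a, universe)

    def test_identical_sets_minimal_p(self):
        universe = {f"U{i}" for i in range(100)}
        a = set(sorted(universe)[:10])
        _, p_same = overlap_test(a, a, universe)
        _, p_disjoint = overlap_test(a, set(sorted(universe)[10:20]), universe)
        assert p_same < p_disjoint

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_test(set(), set(), set())


class TestSamePathwayEnrichment:
    UNIVERSE = {f"U{i}" for i in range(100)} | {"MUT", "C1", "C2", "C3"}

    def test_identical_overlap_keeps_smaller_p(self):
        candidates = {"C1", "C2"}
        pathways = {
            "small": {"MUT", "C1", "C2"},               # tighter -> smaller p
            "large": {"MUT", "C1", "C2"} | {f"U{i}" for i in range(40)},
        }
        res = same_pathway_enrichment(candidates, "MUT", pathways, self.UNIVERSE)
        assert [r.pathway for r in res] == ["small"]

    def test_contained_overlap_removed(self):
        candidates = {"C1", "C2", "C3"}
        pathways = {
            "full": {"MUT", "C1", "C2", "C3"},
            "partial": {"MUT", "C1", "C2", "U0"},  # overlap strictly contained
        }
        res = same_pathway_enrichment(candidates, "MUT", pathways, self.UNIVERSE)
        assert [r.pathway for r in res] == ["full"]

    def test_oversized_pathway_excluded(self):
        big = {"MUT", "C1"} | {f"X{i}" for i in range(500)}  # 502 members
        res = same_pathway_enrichment({"C1"}, "MUT", {"big": big}, self.UNIVERSE | big)
        assert res == []

    def test_pathway_without_mutation_gene_never_tested(self):
        res = same_pathway_enrichment({"C1"}, "MUT", {"noMut": {"C1", "U1"}}, self.UNIVERSE)
        assert res == []

    def test_hypergeometric_value(self):
        candidates = {"C1", "C2"}
        pathways = {"p": {"MUT", "C1", "C2", "U0", "U1"}}
        res = same_pathway_enrichment(candidates, "MUT", pathways, self.UNIVERSE)
        n = len(self.UNIVERSE)
        expected = float(hypergeom.sf(1, n, 5, 2))
        assert res[0].p_value == pytest.approx(expected, abs=1e-12)
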