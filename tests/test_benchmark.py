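import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from orthonet import benchmark
from orthonet.benchmark import (
    compare_paired,
    derive_gold_standard,
    lls_score,
    partial_auroc,
    precision_coverage_curve,
    random_network_baseline,
    term_gene_ranking,
)
from orthonet.errors import DegenerateInputError, EmptyResultError
from orthonet.model import (
    AnnotationCatalog,
    GoldStandard,
    TermInfo,
    canonical_pair,
)
from orthonet.simulate import SynthConfig, make_source_network


# ---------------------------------------------------------------------------
# Gold standard
# ---------------------------------------------------------------------------

class TestGoldStandard:
    def test_single_term_enumerates_all_pairs(self):
        cat = AnnotationCatalog({"T": TermInfo("t", "other", {"g1", "g2", "g3"})})
        gold = derive_gold_standard(cat, 2, 10)
        assert gold.positives == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        assert gold.universe == {"g1", "g2", "g3"}

    def test_oversize_term_contributes_nothing(self):
        big = TermInfo("big", "other", {f"g{i}" for i in range(500)})
        small = TermInfo("small", "other", {"a", "b"})
        gold = derive_gold_standard(
            AnnotationCatalog({"B": big, "S": small}), 2, 300
        )
        assert gold.universe == {"a", "b"}

    def test_no_qualifying_term_is_an_error(self):
        cat = AnnotationCatalog({"T": TermInfo("t", "other", {"g1"})})
        with pytest.raises(EmptyResultError):
            derive_gold_standard(cat, 5, 300)

    def test_positive_count_matches_brute_force(self, rng):
        for _ in range(20):
            cat = AnnotationCatalog()
            genes = [f"g{i}" for i in range(25)]
            for t in range(int(rng.integers(1, 6))):
                members = {g for g in genes if rng.random() < 0.4}
                if members:
                    cat[f"T{t}"] = TermInfo(f"{t}", "other", members)
            if not cat:
                continue
            lo, hi = 2, 12
            try:
                gold = derive_gold_standard(cat, lo, hi)
            except EmptyResultError:
                continue
            expected = set()
            for info in cat.values():
                if lo <= len(info.genes) <= hi:
                    for a, b in itertools.combinations(sorted(info.genes), 2):
                        expected.add((a, b))
            assert gold.positives == expected


# ---------------------------------------------------------------------------
# LLS of an edge set
# ---------------------------------------------------------------------------

class TestLlsScore:
    def test_balanced_toy_scores_zero_for_any_pseudocount(self):
        # universe of 4 genes, one term over 3 of them: P'=3, N'=3;
        # one positive and one negative edge: P=1, N=1 -> ln 1 = 0
        gold = GoldStandard(
            universe={"g1", "g2", "g3", "g4"},
            positives={("g1", "g2"), ("g1", "g3"), ("g2", "g3")},
            term_size_bounds=(2, 10),
        )
        for c in (0.1, 1.0, 5.0):
            assert lls_score([("g1", "g2"), ("g1", "g4")], gold, c) == pytest.approx(0.0)

    def test_all_positive_edges_hit_closed_form_maximum(self):
        gold = GoldStandard(
            universe={"g1", "g2", "g3"},
            positives={("g1", "g2"), ("g1", "g3")},
            term_size_bounds=(2, 10),
        )
        c = 1.0
        # P=2, N=0; P'=2, N'=1
        expected = math.log(((2 + c) / c) / ((2 + c) / (1 + c)))
        assert lls_score([("g1", "g2"), ("g1", "g3")], gold, c) == pytest.approx(expected)

    def test_edges_outside_universe_do_not_count(self):
        gold = GoldStandard(
            universe={"g1", "g2"}, positives={("g1", "g2")},
            term_size_bounds=(2, 10),
        )
        with pytest.raises(EmptyResultError):
            lls_score([("zz", "g1")], gold)

    def test_uniform_edge_sample_scores_near_zero(self, rng):
        # prior odds cancel when edges are an unbiased sample of universe pairs
        genes = [f"g{i:03d}" for i in range(80)]
        cat = AnnotationCatalog()
        for t in range(8):
            cat[f"T{t}"] = TermInfo(f"{t}", "other",
                                    set(rng.choice(genes, size=10, replace=False)))
        gold = derive_gold_standard(cat, 5, 300)
        universe = sorted(gold.universe)
        pairs = []
        for _ in range(10_000):
            a, b = rng.choice(len(universe), size=2, replace=False)
            pairs.append((universe[a], universe[b]))
        assert abs(lls_score(pairs, gold)) < 0.1


# ---------------------------------------------------------------------------
# Precision–coverage curve
# ---------------------------------------------------------------------------

def _gold_from_terms(term_sets):
    cat = AnnotationCatalog(
        {f"T{i}": TermInfo(f"{i}", "other", set(s)) for i, s in enumerate(term_sets)}
    )
    return derive_gold_standard(cat, 2, 300)


class TestPrecisionCoverage:
    def test_all_positive_network_has_precision_one_everywhere(self):
        gold = _gold_from_terms([{"a", "b", "c", "d"}])
        net = {("a", "b"): 3.0, ("c", "d"): 2.0, ("a", "c"): 1.0}
        curve = precision_coverage_curve(net, gold, bin_size=1)
        assert all(p.cumulative_precision == 1.0 for p in curve)
        covs = [p.gene_coverage for p in curve]
        assert covs == sorted(covs)

    def test_single_bin_matches_direct_count(self, rng):
        genes = [f"g{i}" for i in range(20)]
        gold = _gold_from_terms([set(genes[:8]), set(genes[8:14])])
        net = {}
        while len(net) < 30:
            a, b = rng.choice(genes, size=2, replace=False)
            net[canonical_pair(a, b)] = float(rng.uniform(0, 5))
        (point,) = precision_coverage_curve(net, gold, bin_size=len(net))
        n_eval = sum(
            1 for (a, b) in net if a in gold.universe and b in gold.universe
        )
        n_pos = sum(1 for p in net if p in gold.positives)
        assert point.edges_considered == len(net)
        assert point.cumulative_precision == pytest.approx(n_pos / n_eval)

    def test_final_precision_equals_whole_network_positive_fraction(self, rng):
        genes = [f"g{i}" for i in range(15)]
        gold = _gold_from_terms([set(genes[:6])])
        net = {}
        while len(net) < 25:
            a, b = rng.choice(genes, size=2, replace=False)
            net[canonical_pair(a, b)] = float(rng.uniform(0, 5))
        curve = precision_coverage_curve(net, gold, bin_size=4)
        whole = precision_coverage_curve(net, gold, bin_size=len(net))
        assert curve[-1].cumulative_precision == whole[0].cumulative_precision

    def test_score_shuffled_network_tracks_background_rate(self, rng):
        # precision of a random-score ranking fluctuates around the
        # network-wide positive fraction (binomial sampling)
        genes = [f"g{i}" for i in range(40)]
        gold = _gold_from_terms([set(genes[:15]), set(genes[15:30])])
        net = {}
        while len(net) < 300:
            a, b = rng.choice(genes, size=2, replace=False)
            net[canonical_pair(a, b)] = float(rng.uniform(0, 5))
        background = precision_coverage_curve(net, gold, bin_size=len(net))[0]
        p = background.cumulative_precision
        curve = precision_coverage_curve(net, gold, bin_size=50)
        for point in curve:
            n = point.edges_considered  # upper bound on evaluable count
            se = math.sqrt(p * (1 - p) / n)
            assert abs(point.cumulative_precision - p) <= 3 * se + 1e-9

    def test_genome_scope_uses_total_gene_count(self):
        gold = _gold_from_terms([{"a", "b"}])
        net = {("a", "b"): 1.0}
        (point,) = precision_coverage_curve(
            net, gold, bin_size=1, coverage_scope="genome", n_total_genes=10
        )
        assert point.gene_coverage == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# Guilt-by-association ranking
# ---------------------------------------------------------------------------

class TestTermGeneRanking:
    def test_star_hub_ranks_first(self):
        net = {("hub", "m1"): 1.0, ("hub", "m2"): 1.0, ("hub", "m3"): 1.0,
               ("m1", "m2"): 1.0}
        ranking = term_gene_ranking(net, {"m1", "m2", "m3"})
        assert ranking[0] == ("hub", 3.0)

    def test_member_score_excludes_own_annotation(self):
        # m1's own membership contributes nothing; only edges to m2 count
        net = {("m1", "m2"): 2.0, ("m1", "x"): 5.0}
        ranking = dict(term_gene_ranking(net, {"m1", "m2"}))
        assert ranking["m1"] == pytest.approx(2.0)
        # x's edge to non-member m1... m1 IS a member, so x scores 5
        assert ranking["x"] == pytest.approx(5.0)

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(EmptyResultError):
            term_gene_ranking({("a", "b"): 1.0}, {"a", "zz"})

    def test_matches_brute_force_summation(self, rng):
        for _ in range(25):
            genes = [f"g{i}" for i in range(12)]
            net = {}
            while len(net) < 20:
                a, b = rng.choice(genes, size=2, replace=False)
                net[canonical_pair(a, b)] = float(rng.uniform(0.1, 4))
            members = set(rng.choice(genes, size=4, replace=False))
            got = dict(term_gene_ranking(net, members))
            for g in got:  # ranking covers network genes only
                expected = sum(
                    s for (a, b), s in net.items()
                    if (a == g and b in members and b != g)
                    or (b == g and a in members and a != g)
                )
                assert got[g] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Partial AUROC
# ---------------------------------------------------------------------------

class TestPartialAuroc:
    def test_perfect_ranking_scores_one(self):
        ranking = [("p1", 9.0), ("p2", 8.0), ("n1", 1.0), ("n2", 0.5)] + [
            (f"n{i}", 0.0) for i in range(2, 300)
        ]
        assert partial_auroc(ranking, {"p1", "p2"}, 0.01) == pytest.approx(1.0)

    def test_all_tied_scores_give_diagonal(self):
        ranking = [(f"g{i}", 1.0) for i in range(500)]
        pos = {f"g{i}" for i in range(50)}
        # normalized diagonal area up to c is c/2
        assert partial_auroc(ranking, pos, 0.01) == pytest.approx(0.005)

    def test_random_rankings_average_the_diagonal(self, rng):
        vals = []
        for _ in range(200):
            scores = rng.permutation(1000).astype(float)
            ranking = [(f"g{i}", s) for i, s in enumerate(scores)]
            pos = {f"g{i}" for i in range(50)}
            vals.append(partial_auroc(ranking, pos, 0.01))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - 0.005) <= 3 * se

    def test_invariant_under_monotone_score_transform(self, rng):
        scores = rng.uniform(0, 5, size=200)
        ranking = [(f"g{i}", s) for i, s in enumerate(scores)]
        pos = {f"g{i}" for i in range(0, 200, 7)}
        base = partial_auroc(ranking, pos, 0.05)
        warped = [(g, math.exp(s) + 3) for g, s in ranking]
        assert partial_auroc(warped, pos, 0.05) == pytest.approx(base)

    def test_full_window_equals_mann_whitney_auc(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            ranking = [(f"g{i}", s) for i, s in enumerate(scores)]
            pos = {f"g{i}" for i in range(30) if labels[i]}
            u = sps.mannwhitneyu(
                scores[labels], scores[~labels], alternative="two-sided"
            ).statistic
            auc = u / (labels.sum() * (~labels).sum())
            assert partial_auroc(ranking, pos, 1.0) == pytest.approx(auc)

    def test_degenerate_label_sets_rejected(self):
        ranking = [("a", 1.0), ("b", 0.5)]
        with pytest.raises(DegenerateInputError):
            partial_auroc(ranking, {"a", "b"}, 0.01)
        with pytest.raises(DegenerateInputError):
            partial_auroc(ranking, set(), 0.01)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------

def exact_signed_rank_p(diffs):
    """Sign-flip enumeration oracle with average ranks (two-sided)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


class TestComparePaired:
    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compare_paired([1.0] * 8, [1.0] * 8)

    def test_eight_uniform_signs_exact_tail(self):
        a = [float(i) for i in range(1, 9)]
        b = [0.0] * 8
        _stat, p = compare_paired(a, b)
        assert p == pytest.approx(2 / 256)

    def test_matches_enumeration_oracle(self, rng):
        checked = 0
        while checked < 100:
            n = int(rng.integers(6, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            if rng.random() < 0.5:
                # force tied absolute differences
                a = np.round(a, 0)
                b = np.round(b, 0)
            d = a - b
            if (d != 0).sum() < 6:
                continue
            _stat, p = compare_paired(a, b)
            assert p == pytest.approx(exact_signed_rank_p(d), abs=1e-8)
            checked += 1

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.normal(0.3, 1, size=60)
        b = rng.normal(0.0, 1, size=60)
        stat, p = compare_paired(a, b)
        ref = sps.wilcoxon(a - b, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Random-network baseline
# ---------------------------------------------------------------------------

def _planted_network(seed=3):
    config = SynthConfig(
        n_ancestral_genes=120, n_modules=4, seed=seed,
        background_edge_prob=0.01,
    )
    genes_by_idx = {i: f"g{i:03d}" for i in range(120)}
    modules = [list(range(m * 8, m * 8 + 8)) for m in range(4)]
    net, _ = make_source_network(genes_by_idx, modules, config, seed, "SP", "CX")
    return {(e.gene_a, e.gene_b): e.lls for e in net.edges}, [
        {genes_by_idx[i] for i in m} for m in modules
    ]


class TestRandomBaseline:
    def test_degree_sequence_preserved(self):
        net, _ = _planted_network()
        rand = random_network_baseline(net, seed=1)

        def degrees(edges):
            d = {}
            for a, b in edges:
                d[a] = d.get(a, 0) + 1
                d[b] = d.get(b, 0) + 1
            return d

        assert degrees(rand) == degrees(net)

    def test_seed_determinism(self):
        net, _ = _planted_network()
        assert random_network_baseline(net, seed=7) == random_network_baseline(
            net, seed=7
        )
        assert random_network_baseline(net, seed=7) != random_network_baseline(
            net, seed=8
        )

    def test_scores_are_a_permutation_of_the_original(self):
        net, _ = _planted_network()
        rand = random_network_baseline(net, seed=2)
        assert sorted(rand.values()) == pytest.approx(sorted(net.values()))

    def test_randomization_destroys_planted_signal(self):
        net, modules = _planted_network()
        rand = random_network_baseline(net, seed=4)
        for members in modules:
            ranking = term_gene_ranking(net, members)
            pauc_real = partial_auroc(ranking, members, 0.05)
            ranking_r = term_gene_ranking(rand, members)
            pauc_rand = partial_auroc(ranking_r, members, 0.05)
            assert pauc_real > pauc_rand
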