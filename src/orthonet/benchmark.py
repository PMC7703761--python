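"""Network benchmarking against co-annotation gold standards.

The evaluation machinery mirrors how co-functional networks are usually
judged:

* a gold standard of positive pairs — genes co-annotated to the same
  curated term, for terms within configurable size bounds;
* the log-likelihood score (LLS) of an edge set: the natural-log odds of
  finding a co-annotated pair among the evaluated edges relative to the
  background odds among all annotated-gene pairs,
  ``ln[(P/N) / (P'/N')]``, with additive smoothing on all four counts;
* cumulative precision–coverage curves over the score-ranked edge list;
* guilt-by-association gene ranking per term (sum of edge LLS to term
  members, leave-one-out for the members themselves) scored by partial
  AUROC on the low false-positive-rate window (FPR ≤ 0.01 by default),
  normalised so a perfect ranking scores 1 and a random one fpr_max/2;
* a paired Wilcoxon signed-rank comparison between two networks'
  per-term scores;
* a degree-preserving random-network baseline (double-edge swaps plus
  score permutation).

Ties in rankings are handled deterministically: tied scores are traversed
as a single diagonal ROC segment, equivalent to averaging over random tie
orders, with no RNG in evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .errors import DegenerateInputError, EmptyResultError
from .model import (
    AnnotationCatalog,
    GoldStandard,
    as_score_dict,
    canonical_pair,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gold standard
# ---------------------------------------------------------------------------

def derive_gold_standard(
    catalog: AnnotationCatalog,
    min_term_size: int = 5,
    max_term_size: int = 300,
) -> GoldStandard:
    """Build a co-annotation gold standard from a term catalog.

    Qualifying terms have between ``min_term_size`` and ``max_term_size``
    genes (tiny terms are statistically unstable, huge ones
    uninformative); positives are all unordered within-term pairs, the
    universe is the union of qualifying-term genes.
    """
    if not catalog:
        raise EmptyResultError("derive_gold_standard: empty catalog")
    if not (2 <= min_term_size <= max_term_size):
        raise ValueError("require 2 <= min_term_size <= max_term_size")
    universe: Set[str] = set()
    positives: Set[Tuple[str, str]] = set()
    n_terms = 0
    for term_id, info in catalog.items():
        size = len(info.genes)
        if not (min_term_size <= size <= max_term_size):
            continue
        n_terms += 1
        universe |= info.genes
        for a, b in combinations(sorted(info.genes), 2):
            positives.add(canonical_pair(a, b))
    if n_terms == 0:
        raise EmptyResultError(
            "derive_gold_standard: no term within size bounds "
            f"[{min_term_size}, {max_term_size}]"
        )
    return GoldStandard(
        universe=universe,
        positives=positives,
        term_size_bounds=(min_term_size, max_term_size),
    )


# ---------------------------------------------------------------------------
# LLS of an edge set
# ---------------------------------------------------------------------------

def lls_score(
    edge_pairs: Iterable[Tuple[str, str]],
    gold: GoldStandard,
    pseudocount: float = 1.0,
) -> float:
    """Log-likelihood score (natural log) of an edge set against a gold
    standard.

    Only pairs with both genes in the annotated universe are evaluable.
    With P/N the positive/negative counts among evaluable pairs and
    P'/N' the counts among all universe pairs, the score is
    ``ln[((P+c)/(N+c)) / ((P'+c)/(N'+c))]`` with pseudocount ``c``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    P = N = 0
    for a, b in edge_pairs:
        if a in gold.universe and b in gold.universe:
            if canonical_pair(a, b) in gold.positives:
                P += 1
            else:
                N += 1
    if P + N == 0:
        raise EmptyResultError(
            "lls_score: no edge with both genes in the annotated universe"
        )
    n_u = len(gold.universe)
    total_pairs = n_u * (n_u - 1) // 2
    P_prime = len(gold.positives)
    N_prime = total_pairs - P_prime
    c = pseudocount
    return math.log(((P + c) / (N + c)) / ((P_prime + c) / (N_prime + c)))


# ---------------------------------------------------------------------------
# Precision–coverage curve
# ---------------------------------------------------------------------------

@dataclass
class CurvePoint:
    edges_considered: int
    cumulative_precision: float
    gene_coverage: float


def precision_coverage_curve(
    network,
    gold: GoldStandard,
    bin_size: int = 1000,
    coverage_scope: str = "universe",
    n_total_genes: Optional[int] = None,
) -> List[CurvePoint]:
    """Cumulative precision and gene coverage along the score-ranked
    edge list.

    Edges are sorted by descending score (ties by canonical pair); after
    each bin the curve records the fraction of gold-evaluable edges so
    far that are positives, and the gene coverage.  With
    ``coverage_scope="universe"`` coverage counts annotated genes seen
    over the annotated universe; with ``"genome"`` it counts all genes
    seen over ``n_total_genes``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if coverage_scope not in ("universe", "genome"):
        raise ValueError(f"unknown coverage_scope {coverage_scope!r}")
    if coverage_scope == "genome" and not n_total_genes:
        raise ValueError("coverage_scope='genome' requires n_total_genes")
    scores = as_score_dict(network)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    points: List[CurvePoint] = []
    seen: Set[str] = set()
    n_pos = n_eval = 0
    for i, ((a, b), _score) in enumerate(ranked, 1):
        seen.add(a)
        seen.add(b)
        if a in gold.universe and b in gold.universe:
            n_eval += 1
            if canonical_pair(a, b) in gold.positives:
                n_pos += 1
        if i % bin_size == 0 or i == len(ranked):
            if coverage_scope == "universe":
                cov = len(seen & gold.universe) / len(gold.universe)
            else:
                cov = len(seen) / n_total_genes
            precision = n_pos / n_eval if n_eval else 0.0
            points.append(CurvePoint(i, precision, cov))
    return points


# ---------------------------------------------------------------------------
# Guilt-by-association ranking and partial AUROC
# ---------------------------------------------------------------------------

def term_gene_ranking(
    network, term_genes: Iterable[str]
) -> List[Tuple[str, float]]:
    """Rank every network gene by its summed edge LLS to term members.

    A member's own annotation never contributes to its score
    (leave-one-out): gene g is scored as the sum of lls(g, m) over term
    members m != g.  Result is sorted by descending score, ties by gene
    id; genes with no edge to any member share the bottom with score 0.
    """
    scores = as_score_dict(network)
    members = set(term_genes)
    nodes: Set[str] = set()
    for a, b in scores:
        nodes.add(a)
        nodes.add(b)
    if len(members & nodes) < 2:
        raise EmptyResultError(
            "term_gene_ranking: fewer than 2 term members in the network"
        )
    assoc: Dict[str, float] = {g: 0.0 for g in nodes}
    for (a, b), s in scores.items():
        if b in members:
            assoc[a] += s
        if a in members:
            assoc[b] += s
    return sorted(assoc.items(), key=lambda kv: (-kv[1], kv[0]))


def partial_auroc(
    ranking: Sequence[Tuple[str, float]],
    positives: Iterable[str],
    fpr_max: float = 0.01,
) -> float:
    """Partial AUROC over FPR in [0, fpr_max], normalised by fpr_max.

    The ROC is built tie-aware: candidates sharing a score are traversed
    as one diagonal segment (equivalent to averaging over random tie
    orders).  A perfect ranking scores 1; a random one fpr_max/2.
    """
    if not (0 < fpr_max <= 1):
        raise ValueError("fpr_max must be in (0, 1]")
    pos = set(positives)
    labels = np.array([1 if g in pos else 0 for g, _ in ranking])
    scores = np.array([s for _, s in ranking], dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            "partial_auroc: need at least one positive and one negative"
        )
    # group by descending score
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    # cumulative TP/FP at the end of each tie group
    boundaries = np.nonzero(np.diff(scores))[0]
    group_ends = np.append(boundaries, len(scores) - 1)
    tp = np.cumsum(labels)[group_ends] / n_pos
    fp = np.cumsum(1 - labels)[group_ends] / n_neg
    tpr = np.concatenate([[0.0], tp])
    fpr = np.concatenate([[0.0], fp])
    # trapezoid area over [0, fpr_max] with interpolation at the cut
    area = 0.0
    for i in range(1, len(fpr)):
        x0, x1 = fpr[i - 1], fpr[i]
        y0, y1 = tpr[i - 1], tpr[i]
        if x0 >= fpr_max:
            break
        if x1 > fpr_max:
            # linear interpolation inside the segment
            y1 = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            x1 = fpr_max
        area += (x1 - x0) * (y0 + y1) / 2.0
    return float(area / fpr_max)


@dataclass
class TermAUROC:
    term_id: str
    pauc: float
    n_pos: int
    n_neg: int


def per_term_paucs(
    network,
    catalog: AnnotationCatalog,
    fpr_max: float = 0.01,
) -> List[TermAUROC]:
    """Partial AUROC of the guilt-by-association ranking for every term
    with at least two members in the network."""
    out: List[TermAUROC] = []
    for term_id in sorted(catalog):
        genes = catalog[term_id].genes
        try:
            ranking = term_gene_ranking(network, genes)
            pauc = partial_auroc(ranking, genes, fpr_max)
        except (EmptyResultError, DegenerateInputError) as exc:
            logger.info("term %s skipped: %s", term_id, exc)
            continue
        n_pos = len(genes & {g for g, _ in ranking})
        out.append(
            TermAUROC(term_id, pauc, n_pos, len(ranking) - n_pos)
        )
    return out


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(d: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided signed-rank p conditional on the observed ranks.

    Average ranks are multiples of 1/2, so doubling them gives integers
    and the null distribution of 2*W+ is the convolution of (1 + x^(2r))
    over the ranks — exact even with ties, unlike plugging a tie-averaged
    statistic into the tie-free tables.
    """
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    doubled = np.rint(2 * ranks).astype(int)
    coeffs = np.zeros(doubled.sum() + 1)
    coeffs[0] = 1.0
    top = 0
    for r in doubled:
        nxt = coeffs.copy()
        nxt[r : top + r + 1] += coeffs[: top + 1]
        coeffs = nxt
        top += r
    coeffs /= 2.0 ** len(doubled)
    w2 = int(round(2 * w_plus))
    p_le = float(coeffs[: w2 + 1].sum())
    p_ge = float(coeffs[w2:].sum())
    return w_plus, min(1.0, 2.0 * min(p_le, p_ge))


def compare_paired(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-term scores.

    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute differences get average ranks; the null distribution is
    exact for n <= 25 (conditional on the observed ranks, so ties are
    handled exactly) and a normal approximation with continuity
    correction beyond that.  Returns (W+, two-sided p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("compare_paired: unequal lengths")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateInputError(
            "compare_paired: all paired differences are zero"
        )
    if d.size < 6:
        raise DegenerateInputError(
            "compare_paired: need >= 6 nonzero differences"
        )
    if d.size <= 25:
        return _exact_signed_rank_p(d)
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True,
        alternative="two-sided", method="approx",
    )
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), float(res.pvalue)


# ---------------------------------------------------------------------------
# Random-network baseline
# ---------------------------------------------------------------------------

def random_network_baseline(
    network, n_swaps_per_edge: int = 10, seed: int = 0
) -> Dict[Tuple[str, str], float]:
    """Degree-preserving randomised copy of a scored network.

    Applies ``n_swaps_per_edge * |E|`` attempted double-edge swaps
    (self-loops and duplicate edges rejected), then permutes the original
    scores over the surviving edges.  Returns ``{canonical pair: score}``;
    fully seeded and reproducible.
    """
    scores = as_score_dict(network)
    if len(scores) < 2:
        raise ValueError("random_network_baseline: need >= 2 edges")
    g = nx.Graph()
    g.add_edges_from(scores.keys())
    nswap = n_swaps_per_edge * g.number_of_edges()
    try:
        nx.double_edge_swap(
            g, nswap=nswap, max_tries=100 * nswap, seed=seed
        )
    except nx.NetworkXError as exc:  # too-small graphs can exhaust tries
        logger.warning("double_edge_swap stopped early: %s", exc)
    rng = np.random.default_rng(seed)
    values = np.array(list(scores.values()))
    rng.shuffle(values)
    pairs = sorted(canonical_pair(a, b) for a, b in g.edges())
    return {pair: float(v) for pair, v in zip(pairs, values)}
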