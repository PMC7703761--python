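"""Network analysis: term subnetworks and guide-gene prioritization.

Two workflows operate on a built network:

* **subnetwork extraction** — the induced subgraph of the network on a
  term's genes, keeping only connected components with at least three
  genes (an isolated annotated gene or a lone pair carries no network
  signal worth showing);
* **gene prioritization** — given user-supplied guide genes, every guide
  is ranked by its within-group connectivity (summed edge score to the
  other guides) and every other network gene by its summed edge score to
  the guides (guilt by association).  Candidates scoring 0 are omitted;
  the top-n cut retains all candidates tied at the boundary.

Plus the small arithmetic the workflows report: fold enrichment of an
annotated subset over a background probability, and genome coverage as a
percentage of coding genes.

All operations here are pure: same inputs, identical outputs, no RNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import EmptyResultError
from .model import (
    AnnotationCatalog,
    IntegratedNetwork,
    ProvenanceEntry,
    as_score_dict,
    canonical_pair,
)


@dataclass
class SubnetworkView:
    """A term-induced subnetwork after the >=3-connected-genes filter."""

    term_id: str
    nodes: List[str]
    edges: List[Tuple[str, str, float, List[ProvenanceEntry]]]
    dropped_components: int


@dataclass
class PrioritizationResult:
    """Ranked guide genes and candidate genes for one guide set."""

    guides_found: List[str]
    guides_missing: List[str]
    guide_ranking: List[Tuple[str, float]]
    candidate_ranking: List[Tuple[str, float]]
    threshold: Optional[float] = None


def extract_subnetwork(
    network, term_genes: Iterable[str], term_id: str
) -> SubnetworkView:
    """Induced subgraph of the network on a term's genes.

    Connected components with fewer than three genes are removed and
    counted in ``dropped_components``; the view may be empty.
    """
    term_genes = set(term_genes)
    if not term_genes:
        raise ValueError("extract_subnetwork: empty term gene set")
    scores = as_score_dict(network)
    prov: Dict[Tuple[str, str], List[ProvenanceEntry]] = {}
    if isinstance(network, IntegratedNetwork):
        prov = {pair: p for pair, (_s, p) in network.edges.items()}
    g = nx.Graph()
    for (a, b), s in scores.items():
        if a in term_genes and b in term_genes:
            g.add_edge(a, b, score=s)
    kept: Set[str] = set()
    dropped = 0
    for comp in nx.connected_components(g):
        if len(comp) >= 3:
            kept |= comp
        else:
            dropped += 1
    nodes = sorted(kept)
    edges = [
        (a, b, g.edges[a, b]["score"], prov.get((a, b), []))
        for a, b in sorted(
            canonical_pair(a, b) for a, b in g.edges() if a in kept
        )
    ]
    return SubnetworkView(
        term_id=term_id, nodes=nodes, edges=edges, dropped_components=dropped
    )


def prioritize(
    network,
    guide_genes: Iterable[str],
    top_n: int = 100,
    min_score: Optional[float] = None,
) -> PrioritizationResult:
    """Rank guide genes by within-group connectivity and other genes by
    their summed edge score to the guides.

    Guides absent from the network are reported in ``guides_missing``.
    Candidates with score 0 are omitted; the top-n cut keeps every
    candidate tied with the last retained one, so the result may exceed
    ``top_n``.  ``min_score`` optionally filters candidates below a
    score threshold.
    """
    scores = as_score_dict(network)
    nodes: Set[str] = set()
    for a, b in scores:
        nodes.add(a)
        nodes.add(b)
    guides = sorted(set(guide_genes))
    found = [g for g in guides if g in nodes]
    missing = [g for g in guides if g not in nodes]
    if not found:
        raise EmptyResultError("prioritize: no guide gene in the network")
    fset = set(found)
    within: Dict[str, float] = {g: 0.0 for g in found}
    neighbor: Dict[str, float] = {}
    for (a, b), s in scores.items():
        a_in, b_in = a in fset, b in fset
        if a_in and b_in:
            within[a] += s
            within[b] += s
        elif a_in:
            neighbor[b] = neighbor.get(b, 0.0) + s
        elif b_in:
            neighbor[a] = neighbor.get(a, 0.0) + s
    guide_ranking = sorted(within.items(), key=lambda kv: (-kv[1], kv[0]))
    candidates = sorted(
        ((g, s) for g, s in neighbor.items() if s > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if min_score is not None:
        candidates = [(g, s) for g, s in candidates if s >= min_score]
    if len(candidates) > top_n:
        cut_score = candidates[top_n - 1][1]
        candidates = [
            (g, s) for i, (g, s) in enumerate(candidates)
            if i < top_n or s == cut_score
        ]
    return PrioritizationResult(
        guides_found=found,
        guides_missing=missing,
        guide_ranking=guide_ranking,
        candidate_ranking=candidates,
        threshold=min_score,
    )


def fold_enrichment(
    k_annotated: int, n_selected: int, background_p: float
) -> float:
    """Fold enrichment of an annotated subset over a background
    probability: ``(k/n) / background_p``."""
    if background_p <= 0 or background_p > 1:
        raise ValueError("background_p must be in (0, 1]")
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    if not (0 <= k_annotated <= n_selected):
        raise ValueError("require 0 <= k_annotated <= n_selected")
    return (k_annotated / n_selected) / background_p


def genome_coverage(network, n_coding_genes: int) -> float:
    """Network genome coverage as a percentage of coding genes, to one
    decimal place."""
    scores = as_score_dict(network)
    genes: Set[str] = set()
    for a, b in scores:
        genes.add(a)
        genes.add(b)
    if n_coding_genes < len(genes):
        raise ValueError(
            "n_coding_genes must be >= number of network genes"
        )
    return round(100.0 * len(genes) / n_coding_genes, 1)


def term_search(catalog: AnnotationCatalog, keyword: str) -> List[str]:
    """Case-insensitive substring search over term ids and names,
    returned in term-id order.  An empty keyword matches every term."""
    kw = keyword.lower()
    return sorted(
        term_id
        for term_id, info in catalog.items()
        if kw in term_id.lower() or kw in info.name.lower()
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _prov_str(prov: Sequence[ProvenanceEntry]) -> str:
    return "|".join(
        f"{p.species_code}:{p.evidence_code}:{p.lls!r}"
        for p in sorted(prov, key=lambda p: -p.lls)
    )


def export_subnetwork(view: SubnetworkView, out_dir, stem: str) -> List[Path]:
    """Write a subnetwork as node TSV + edge TSV (with provenance) and a
    JSON document; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    node_path = out_dir / f"{stem}.nodes.tsv"
    edge_path = out_dir / f"{stem}.edges.tsv"
    json_path = out_dir / f"{stem}.json"
    node_path.write_text("gene\n" + "".join(f"{g}\n" for g in view.nodes))
    with open(edge_path, "w") as out:
        out.write("gene_a\tgene_b\tscore\tprovenance\n")
        for a, b, s, prov in view.edges:
            out.write(f"{a}\t{b}\t{s!r}\t{_prov_str(prov)}\n")
    json_path.write_text(
        json.dumps(
            {
                "term_id": view.term_id,
                "nodes": view.nodes,
                "edges": [
                    {"gene_a": a, "gene_b": b, "score": s,
                     "provenance": _prov_str(prov)}
                    for a, b, s, prov in view.edges
                ],
                "dropped_components": view.dropped_components,
            },
            indent=2,
        )
        + "\n"
    )
    return [node_path, edge_path, json_path]


def export_prioritization(
    result: PrioritizationResult, out_dir, stem: str = "prioritization"
) -> List[Path]:
    """Write guide and candidate tables as TSV plus a JSON document."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    guide_path = out_dir / f"{stem}.guides.tsv"
    cand_path = out_dir / f"{stem}.candidates.tsv"
    json_path = out_dir / f"{stem}.json"
    with open(guide_path, "w") as out:
        out.write("gene\twithin_group_score\n")
        for g, s in result.guide_ranking:
            out.write(f"{g}\t{s!r}\n")
    with open(cand_path, "w") as out:
        out.write("gene\tneighbor_score\n")
        for g, s in result.candidate_ranking:
            out.write(f"{g}\t{s!r}\n")
    json_path.write_text(
        json.dumps(
            {
                "guides_found": result.guides_found,
                "guides_missing": result.guides_missing,
                "guide_ranking": result.guide_ranking,
                "candidate_ranking": result.candidate_ranking,
                "threshold": result.threshold,
            },
            indent=2,
        )
        + "\n"
    )
    return [guide_path, cand_path, json_path]
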