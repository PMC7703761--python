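"""Interolog transfer and multi-source score integration.

A source edge (a, b, LLS) maps onto the target genome when both of its
endpoints have one-to-one orthologs there; the transferred edge inherits
the source LLS and records its provenance (source species, evidence code,
original gene pair).  When several source networks support the same
target pair, their scores are integrated either by taking the single
highest LLS (``method="max"``, the default — multiple sources are treated
as fully correlated) or by summing each source network's best LLS
(``method="sum"``, naive-Bayes independence).  Within one source network,
multiple interologs landing on the same target pair collapse to that
network's maximum before integration, which keeps max-integration
idempotent and prevents double counting under sum.

Term annotations transfer the same way: a target gene inherits every term
carried by any of its ortholog images in the source catalogs.

:func:`build_network` is the end-to-end builder: isoform selection →
per-source BBH → edge mapping → integration (+ annotation transfer),
driven by a YAML manifest describing the source bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import homology, io_formats
from .errors import IntegrityError, OrthonetError
from .homology import AlignParams
from .model import (
    AnnotationCatalog,
    IntegratedNetwork,
    OrthologMap,
    Proteome,
    ProvenanceEntry,
    SourceNetwork,
    TermInfo,
    canonical_pair,
)

logger = logging.getLogger(__name__)

MappedEdge = Tuple[Tuple[str, str], ProvenanceEntry]


def _check_one_to_one(gene_map: Mapping[str, str]) -> None:
    values = list(gene_map.values())
    if len(set(values)) != len(values):
        raise IntegrityError("ortholog gene map is not one-to-one")


def map_edges(
    source_network: SourceNetwork, gene_map: Mapping[str, str]
) -> Tuple[List[MappedEdge], int]:
    """Map source edges onto target genes through an ortholog gene map.

    ``gene_map`` maps source gene -> target gene and must be one-to-one.
    Returns the mapped edges (canonical target pair + provenance) and the
    count of source edges dropped for lack of an ortholog on either side.
    """
    _check_one_to_one(gene_map)
    mapped: List[MappedEdge] = []
    dropped = 0
    for edge in source_network.edges:
        ta = gene_map.get(edge.gene_a)
        tb = gene_map.get(edge.gene_b)
        if ta is None or tb is None:
            dropped += 1
            continue
        if ta == tb:  # impossible under one-to-one; guard anyway
            raise IntegrityError(
                f"edge ({edge.gene_a}, {edge.gene_b}) mapped onto a "
                f"self-pair {ta!r}"
            )
        mapped.append(
            (
                canonical_pair(ta, tb),
                ProvenanceEntry(
                    species_code=source_network.species_code,
                    evidence_code=source_network.evidence_code,
                    lls=edge.lls,
                    source_gene_a=edge.gene_a,
                    source_gene_b=edge.gene_b,
                ),
            )
        )
    return mapped, dropped


def integrate(
    mapped_edge_sets: Sequence[Iterable[MappedEdge]],
    method: str = "max",
    target_species: str = "target",
) -> IntegratedNetwork:
    """Integrate mapped edges from one or more source networks.

    Provenance entries are grouped by canonical target pair; within one
    source network (species_code, evidence_code) multiple entries for the
    same pair count only through that network's maximum LLS; the edge
    score is then the max (or sum) of the per-network maxima.  All
    provenance entries are retained.
    """
    if method not in ("max", "sum"):
        raise ValueError(f"unknown integration method {method!r}")
    if not mapped_edge_sets:
        raise ValueError("integrate: need at least one mapped edge set")
    prov_by_pair: Dict[Tuple[str, str], List[ProvenanceEntry]] = {}
    for mapped in mapped_edge_sets:
        for pair, entry in mapped:
            prov_by_pair.setdefault(pair, []).append(entry)
    edges: Dict[Tuple[str, str], Tuple[float, List[ProvenanceEntry]]] = {}
    for pair, entries in prov_by_pair.items():
        per_source: Dict[Tuple[str, str], float] = {}
        for e in entries:
            key = (e.species_code, e.evidence_code)
            per_source[key] = max(per_source.get(key, float("-inf")), e.lls)
        if method == "max":
            score = max(per_source.values())
        else:
            score = sum(per_source.values())
        edges[pair] = (score, entries)
    return IntegratedNetwork(
        target_species=target_species, edges=edges, integration_method=method
    )


def transfer_annotations(
    catalogs_by_source_species: Mapping[str, AnnotationCatalog],
    gene_maps_by_species: Mapping[str, Mapping[str, str]],
) -> AnnotationCatalog:
    """Transfer term annotations from source catalogs to target genes.

    A target gene inherits a term iff one of its source ortholog images
    carries it; gene sets union across sources.  Sources are processed in
    species-code order, and the first source contributing a term supplies
    its name and namespace.
    """
    out = AnnotationCatalog()
    for species in sorted(catalogs_by_source_species):
        catalog = catalogs_by_source_species[species]
        gene_map = gene_maps_by_species.get(species)
        if gene_map is None:
            raise OrthonetError(
                f"no ortholog map for source species {species!r}"
            )
        for term_id in sorted(catalog):
            info = catalog[term_id]
            inherited = {
                gene_map[g] for g in info.genes if g in gene_map
            }
            if not inherited:
                continue
            if term_id in out:
                out[term_id].genes |= inherited
            else:
                out[term_id] = TermInfo(
                    name=info.name, namespace=info.namespace, genes=set(inherited)
                )
    return out


# ---------------------------------------------------------------------------
# End-to-end builder
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """One source species in a bundle: its proteome and scored networks."""

    species_code: str
    proteome_path: Path
    network_paths: List[Tuple[Path, Optional[str]]]  # (path, evidence_code)
    gmt_path: Optional[Path] = None


@dataclass
class BuildReport:
    """Per-source and global statistics of one network build."""

    target_species: str = "target"
    n_input_genes: int = 0
    per_source: Dict[str, Dict[str, int]] = field(default_factory=dict)
    n_edges: int = 0
    n_nodes: int = 0
    coverage: float = 0.0
    integration_method: str = "max"

    def to_dict(self) -> dict:
        return {
            "target_species": self.target_species,
            "n_input_genes": self.n_input_genes,
            "per_source": self.per_source,
            "n_edges": self.n_edges,
            "n_nodes": self.n_nodes,
            "coverage": self.coverage,
            "integration_method": self.integration_method,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class BuildResult:
    network: IntegratedNetwork
    report: BuildReport
    annotations: AnnotationCatalog
    ortholog_maps: Dict[str, OrthologMap]


def load_manifest(manifest_path) -> Tuple[List[SourceSpec], dict]:
    """Load a YAML bundle manifest.

    Layout::

        target_species: TGT
        sources:
          - species_code: SP1
            proteome: sp1/proteome.fasta
            networks:
              - {path: sp1/net_CX.tsv, evidence_code: CX}
            gmt: sp1/annotations.gmt

    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    data = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    sources: List[SourceSpec] = []
    for entry in data.get("sources", []):
        nets: List[Tuple[Path, Optional[str]]] = []
        for net in entry.get("networks", []):
            if isinstance(net, str):
                nets.append((base / net, None))
            else:
                nets.append((base / net["path"], net.get("evidence_code")))
        gmt = entry.get("gmt")
        sources.append(
            SourceSpec(
                species_code=entry["species_code"],
                proteome_path=base / entry["proteome"],
                network_paths=nets,
                gmt_path=(base / gmt) if gmt else None,
            )
        )
    return sources, data


def build_network(
    target_fasta,
    manifest_path,
    method: str = "max",
    params: Optional[AlignParams] = None,
    isoform_table_path=None,
    target_species: Optional[str] = None,
    species_filter: Optional[Iterable[str]] = None,
) -> BuildResult:
    """Build an integrated co-functional network for a target proteome.

    Pipeline: read the target FASTA (and reduce it to one protein per
    gene when a cross-reference table is given) → for each source
    species, find BBH orthologs with the built-in aligner → map every
    source edge through the ortholog pairs → integrate scores across
    sources (``max`` by default) → transfer any source annotations.

    Genome coverage in the report is the fraction of input target genes
    that end up as network nodes.
    """
    sources, data = load_manifest(manifest_path)
    if species_filter is not None:
        allowed = set(species_filter)
        sources = [s for s in sources if s.species_code in allowed]
    if not sources:
        raise ValueError("build_network: no source species selected")
    target_species = target_species or data.get("target_species", "target")

    records = io_formats.read_fasta(target_fasta)
    table = (
        io_formats.read_isoform_table(isoform_table_path)
        if isoform_table_path
        else None
    )
    target = io_formats.select_longest_isoform(
        records, table, species_code=target_species
    )
    target_gene_of = target.gene_of()

    report = BuildReport(
        target_species=target_species,
        n_input_genes=len(target),
        integration_method=method,
    )
    mapped_sets: List[List[MappedEdge]] = []
    catalogs: Dict[str, AnnotationCatalog] = {}
    gene_maps: Dict[str, Mapping[str, str]] = {}
    ortho_maps: Dict[str, OrthologMap] = {}

    for spec in sorted(sources, key=lambda s: s.species_code):
        if not spec.network_paths:
            logger.warning(
                "source %s has a proteome but no networks; skipped",
                spec.species_code,
            )
            continue
        source_records = io_formats.read_fasta(spec.proteome_path)
        source = Proteome(
            species_code=spec.species_code,
            records=[
                # sources are expected pre-reduced; treat each protein as a gene
                type(r)(r.protein_id, r.seq, r.gene_id or r.protein_id, r.description)
                for r in source_records
            ],
        )
        omap = homology.bbh_from_proteomes(target, source, params)
        ortho_maps[spec.species_code] = omap
        source_gene_of = source.gene_of()
        gene_map = {
            source_gene_of[s]: target_gene_of[t] for t, s in omap.pairs
        }
        gene_maps[spec.species_code] = gene_map
        stats = {"orthologs": len(omap), "transferred": 0, "dropped": 0}
        for net_path, evidence in spec.network_paths:
            edges, sp_hdr, ev_hdr = io_formats.read_edge_list(net_path)
            net = SourceNetwork(
                species_code=sp_hdr or spec.species_code,
                evidence_code=evidence or ev_hdr or Path(net_path).stem,
                edges=edges,
            )
            mapped, dropped = map_edges(net, gene_map)
            stats["transferred"] += len(mapped)
            stats["dropped"] += dropped
            mapped_sets.append(mapped)
        report.per_source[spec.species_code] = stats
        if spec.gmt_path is not None:
            catalogs[spec.species_code] = io_formats.read_gmt(spec.gmt_path)

    if not any(mapped_sets):
        network = IntegratedNetwork(
            target_species=target_species, integration_method=method
        )
    else:
        network = integrate(
            mapped_sets, method=method, target_species=target_species
        )
    report.n_edges = len(network)
    report.n_nodes = len(network.nodes())
    report.coverage = (
        report.n_nodes / report.n_input_genes if report.n_input_genes else 0.0
    )
    annotations = (
        transfer_annotations(catalogs, gene_maps)
        if catalogs
        else AnnotationCatalog()
    )
    return BuildResult(
        network=network,
        report=report,
        annotations=annotations,
        ortholog_maps=ortho_maps,
    )
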