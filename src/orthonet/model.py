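"""Shared domain types.

The package moves a handful of objects between its stages: amino-acid
sequence records and proteomes, undirected LLS-weighted edge lists,
term -> gene-set annotation catalogs, tabular homology hits, one-to-one
ortholog maps, and the integrated target network with per-source
provenance.  They are plain dataclasses; the functional surface lives in
the operation modules (:mod:`orthonet.io_formats`, :mod:`orthonet.homology`,
:mod:`orthonet.transfer`, ...).

Edges are always undirected and stored once, under the canonical
(lexicographically sorted) gene pair; :func:`canonical_pair` is the single
normalisation used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Set, Tuple

from .errors import FormatError

__all__ = [
    "canonical_pair",
    "SequenceRecord",
    "Proteome",
    "EdgeRecord",
    "TermInfo",
    "AnnotationCatalog",
    "AlignmentHit",
    "OrthologMap",
    "SourceNetwork",
    "ProvenanceEntry",
    "IntegratedNetwork",
    "GoldStandard",
]


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Return the unordered gene pair in its canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class SequenceRecord:
    """One amino-acid sequence.

    ``protein_id`` is the first whitespace-delimited token of the FASTA
    header; the remainder of the header is kept as ``description`` but is
    never used as a key.  ``gene_id`` is attached during isoform selection.
    """

    protein_id: str
    seq: str
    gene_id: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("sequence record with empty protein_id")
        if not self.seq:
            raise FormatError(
                f"empty sequence for record {self.protein_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Proteome:
    """A collection of sequence records for one species, unique by
    ``protein_id`` (and, after isoform selection, at most one per gene)."""

    species_code: str
    records: List[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise FormatError(
                    f"duplicate protein_id {rec.protein_id!r} in proteome "
                    f"{self.species_code!r}"
                )
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, protein_id: str) -> Optional[SequenceRecord]:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        return None

    def by_id(self) -> Dict[str, SequenceRecord]:
        return {rec.protein_id: rec for rec in self.records}

    def gene_of(self) -> Dict[str, str]:
        """protein_id -> gene_id map (protein_id itself when unset)."""
        return {
            rec.protein_id: rec.gene_id or rec.protein_id
            for rec in self.records
        }


class EdgeRecord(NamedTuple):
    """One undirected, LLS-weighted edge in canonical pair order."""

    gene_a: str
    gene_b: str
    lls: float


@dataclass
class TermInfo:
    """One annotation term: display name, namespace and member genes."""

    name: str
    namespace: str  # "GO-BP", "KEGG" or "other"
    genes: Set[str]


class AnnotationCatalog(Dict[str, TermInfo]):
    """Mapping term_id -> :class:`TermInfo`.

    A thin dict subclass so catalogs stay directly indexable while giving
    the type a name the rest of the code can refer to.
    """

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for info in self.values():
            out |= info.genes
        return out


@dataclass
class AlignmentHit:
    """One row of 12-column tabular homology output (BLAST/DIAMOND
    ``outfmt 6`` column order; 1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass
class OrthologMap:
    """One-to-one (bidirectional best hit) ortholog pairs between a target
    and one source species."""

    target_species: str
    source_species: str
    pairs: Set[Tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        targets = [t for t, _ in self.pairs]
        sources = [s for _, s in self.pairs]
        if len(set(targets)) != len(targets) or len(set(sources)) != len(sources):
            from .errors import IntegrityError

            raise IntegrityError(
                "ortholog map is not one-to-one between "
                f"{self.target_species!r} and {self.source_species!r}"
            )

    def source_to_target(self) -> Dict[str, str]:
        return {s: t for t, s in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SourceNetwork:
    """A scored network for one source species and one evidence type."""

    species_code: str
    evidence_code: str
    edges: List[EdgeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ProvenanceEntry:
    """Where a transferred edge came from: the source network and the
    original gene pair and score."""

    species_code: str
    evidence_code: str
    lls: float
    source_gene_a: str = ""
    source_gene_b: str = ""


@dataclass
class IntegratedNetwork:
    """The built target network.

    ``edges`` maps each canonical target gene pair to its integrated score
    and the full list of supporting provenance entries.  Under
    ``integration_method == "max"`` the score is the largest supporting
    LLS; under ``"sum"`` it is the sum over distinct source networks of
    each network's largest supporting LLS.
    """

    target_species: str
    edges: Dict[Tuple[str, str], Tuple[float, List[ProvenanceEntry]]] = field(
        default_factory=dict
    )
    integration_method: str = "max"

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def scores(self) -> Dict[Tuple[str, str], float]:
        return {pair: sc for pair, (sc, _) in self.edges.items()}


@dataclass
class GoldStandard:
    """Co-annotation gold standard: annotated universe and the set of
    positive (co-annotated) canonical gene pairs."""

    universe: Set[str]
    positives: Set[Tuple[str, str]]
    term_size_bounds: Tuple[int, int]


def as_score_dict(network) -> Dict[Tuple[str, str], float]:
    """Normalise a network argument to ``{canonical pair: score}``.

    Accepts an :class:`IntegratedNetwork`, a mapping pair -> score, or an
    iterable of :class:`EdgeRecord`.
    """
    if isinstance(network, IntegratedNetwork):
        return network.scores()
    if isinstance(network, dict):
        return {canonical_pair(a, b): float(s) for (a, b), s in network.items()}
    out: Dict[Tuple[str, str], float] = {}
    for rec in network:
        out[canonical_pair(rec.gene_a, rec.gene_b)] = float(rec.lls)
    return out
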