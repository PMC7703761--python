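"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* FASTA proteomes (via Bio.SeqIO); the record id is the first whitespace
  token of the header.
* 2-column TSV gene/isoform cross-reference tables (gene_id, protein_id).
* 3-column TSV scored edge lists (gene_a, gene_b, lls) with optional
  ``#key=value`` header lines carrying ``species_code`` / ``evidence_code``.
* GMT annotation catalogs (term_id, term_name, genes...).
* 12-column tabular homology hits (BLAST/DIAMOND ``outfmt 6``).
* The integrated-network TSV with a per-edge provenance column.

All paths may end in ``.gz`` (plain gzip).  Edge lists are canonicalised on
read: pairs sorted lexicographically, duplicates collapsed to the maximum
score, self-edges dropped — so reading a written file is a no-op.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

from .errors import FormatError
from .model import (
    AlignmentHit,
    AnnotationCatalog,
    EdgeRecord,
    IntegratedNetwork,
    Proteome,
    ProvenanceEntry,
    SequenceRecord,
    TermInfo,
    canonical_pair,
)

logger = logging.getLogger(__name__)

NETWORK_HEADER = ["gene_a", "gene_b", "score", "provenance"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[SequenceRecord]:
    """Parse a protein FASTA file into sequence records.

    The protein id is the first whitespace-delimited token of the header;
    the rest of the header is retained as the description.  Sequences are
    uppercased.  An empty sequence under a header or a duplicate id is a
    :class:`FormatError`.
    """
    records: List[SequenceRecord] = []
    seen = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(
                    f"{path}: empty sequence under header {rec.id!r}"
                )
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate protein_id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(protein_id=rec.id, seq=seq, description=desc)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = rec.protein_id
            if rec.description:
                header += " " + rec.description
            out.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Isoform selection
# ---------------------------------------------------------------------------

def read_isoform_table(path) -> Dict[str, List[str]]:
    """Read a 2-column TSV cross-reference (gene_id, protein_id).

    Returns gene_id -> list of protein ids.  A protein listed under two
    genes is a :class:`FormatError`.
    """
    table: Dict[str, List[str]] = {}
    owner: Dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            gene, prot = parts[0], parts[1]
            if prot in owner and owner[prot] != gene:
                raise FormatError(
                    f"{path}:{lineno}: protein {prot!r} listed under both "
                    f"{owner[prot]!r} and {gene!r}"
                )
            owner[prot] = gene
            table.setdefault(gene, []).append(prot)
    return table


def select_longest_isoform(
    records: Iterable[SequenceRecord],
    isoform_table: Optional[Dict[str, List[str]]] = None,
    species_code: str = "target",
) -> Proteome:
    """Reduce a proteome to one protein per gene.

    For each gene in the cross-reference table, the longest listed isoform
    present in ``records`` is kept (ties broken by lexicographically
    smallest protein id).  Proteins absent from the table are kept as
    single-isoform genes with ``gene_id == protein_id``.  Table entries
    with no matching record are ignored with a warning.
    """
    records = list(records)
    if not records:
        raise FormatError("select_longest_isoform: no input records")
    if isoform_table is None:
        isoform_table = {}
    by_id = {rec.protein_id: rec for rec in records}
    claimed = set()
    kept: List[SequenceRecord] = []
    for gene in sorted(isoform_table):
        candidates = []
        for prot in isoform_table[gene]:
            rec = by_id.get(prot)
            if rec is None:
                logger.warning(
                    "isoform table lists %r under gene %r but no such "
                    "record exists; ignored", prot, gene,
                )
                continue
            candidates.append(rec)
            claimed.add(prot)
        if not candidates:
            continue
        best = max(candidates, key=lambda r: (r.length, _neg_lex(r.protein_id)))
        kept.append(
            SequenceRecord(
                protein_id=best.protein_id,
                seq=best.seq,
                gene_id=gene,
                description=best.description,
            )
        )
    for rec in records:
        if rec.protein_id not in claimed:
            kept.append(
                SequenceRecord(
                    protein_id=rec.protein_id,
                    seq=rec.seq,
                    gene_id=rec.protein_id,
                    description=rec.description,
                )
            )
    kept.sort(key=lambda r: r.protein_id)
    return Proteome(species_code=species_code, records=kept)


class _neg_lex(str):
    """Inverts lexicographic comparison, so max() prefers the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> Tuple[List[EdgeRecord], Optional[str], Optional[str]]:
    """Read a 3-column scored edge list.

    ``#key=value`` header lines may declare ``species_code`` and
    ``evidence_code``.  Pairs are canonicalised; duplicate pairs collapse
    to the maximum score (warning); self-edges are dropped (warning);
    a non-numeric score is a :class:`FormatError` naming the line.
    """
    meta: Dict[str, str] = {}
    best: Dict[Tuple[str, str], float] = {}
    order: List[Tuple[str, str]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            a, b = parts[0], parts[1]
            try:
                lls = float(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                ) from None
            if a == b:
                logger.warning("%s:%d: self-edge %r dropped", path, lineno, a)
                continue
            pair = canonical_pair(a, b)
            if pair in best:
                logger.warning(
                    "%s:%d: duplicate pair %s collapsed to max score",
                    path, lineno, pair,
                )
                best[pair] = max(best[pair], lls)
            else:
                best[pair] = lls
                order.append(pair)
    edges = [EdgeRecord(a, b, best[(a, b)]) for a, b in order]
    return edges, meta.get("species_code"), meta.get("evidence_code")


def write_edge_list(
    edges: Iterable[EdgeRecord],
    path,
    species_code: Optional[str] = None,
    evidence_code: Optional[str] = None,
) -> None:
    with _open_text(path, "wt") as out:
        if species_code is not None:
            out.write(f"#species_code={species_code}\n")
        if evidence_code is not None:
            out.write(f"#evidence_code={evidence_code}\n")
        for rec in edges:
            a, b = canonical_pair(rec.gene_a, rec.gene_b)
            out.write(f"{a}\t{b}\t{rec.lls!r}\n")


# ---------------------------------------------------------------------------
# GMT annotation catalogs
# ---------------------------------------------------------------------------

def _infer_namespace(term_id: str) -> str:
    tid = term_id.upper()
    if tid.startswith("GO"):
        return "GO-BP"
    if tid.startswith(("KEGG", "KO", "MAP", "PATH")):
        return "KEGG"
    return "other"


def read_gmt(path) -> AnnotationCatalog:
    """Read a GMT file (term_id <TAB> term_name <TAB> gene...).

    Duplicate genes within a line are deduplicated; lines with no genes
    are skipped with a warning; a duplicate term_id is an error.
    """
    catalog = AnnotationCatalog()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least term_id and name"
                )
            term_id, name = parts[0], parts[1]
            genes = {g for g in parts[2:] if g}
            if not genes:
                logger.warning(
                    "%s:%d: term %r has no genes; skipped", path, lineno, term_id
                )
                continue
            if term_id in catalog:
                raise FormatError(f"{path}:{lineno}: duplicate term {term_id!r}")
            catalog[term_id] = TermInfo(
                name=name, namespace=_infer_namespace(term_id), genes=genes
            )
    return catalog


def write_gmt(catalog: AnnotationCatalog, path) -> None:
    with _open_text(path, "wt") as out:
        for term_id in sorted(catalog):
            info = catalog[term_id]
            genes = "\t".join(sorted(info.genes))
            out.write(f"{term_id}\t{info.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# Tabular homology hits
# ---------------------------------------------------------------------------

def read_tabular_hits(path) -> List[AlignmentHit]:
    """Read 12-column tabular alignment hits (``outfmt 6`` column order).

    No filtering is applied at read time; a wrong column count is a
    :class:`FormatError` naming the line.
    """
    hits: List[AlignmentHit] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path) -> None:
    with _open_text(path, "wt") as out:
        for h in hits:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.percent_identity,
                        h.aln_length, h.mismatches, h.gap_opens,
                        h.q_start, h.q_end, h.s_start, h.s_end,
                        h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Integrated network
# ---------------------------------------------------------------------------

def write_network(network: IntegratedNetwork, path) -> None:
    """Write an integrated network as TSV.

    Columns: gene_a, gene_b, score, provenance.  The provenance column
    holds ``species:evidence:lls`` triplets joined by ``|``, sorted by
    descending lls.  Rows are sorted by descending score, then by
    canonical pair.
    """
    rows = sorted(
        network.edges.items(), key=lambda kv: (-kv[1][0], kv[0])
    )
    with _open_text(path, "wt") as out:
        out.write(f"#target_species={network.target_species}\n")
        out.write(f"#integration_method={network.integration_method}\n")
        out.write("\t".join(NETWORK_HEADER) + "\n")
        for (a, b), (score, prov) in rows:
            prov_sorted = sorted(prov, key=lambda p: -p.lls)
            prov_str = "|".join(
                f"{p.species_code}:{p.evidence_code}:{p.lls!r}"
                for p in prov_sorted
            )
            out.write(f"{a}\t{b}\t{score!r}\t{prov_str}\n")


def read_network(path) -> IntegratedNetwork:
    meta: Dict[str, str] = {}
    edges: Dict[Tuple[str, str], Tuple[float, List[ProvenanceEntry]]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if parts[:3] == NETWORK_HEADER[:3]:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 columns")
            a, b = canonical_pair(parts[0], parts[1])
            try:
                score = float(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                ) from None
            prov: List[ProvenanceEntry] = []
            if len(parts) > 3 and parts[3]:
                for trip in parts[3].split("|"):
                    fields = trip.split(":")
                    if len(fields) != 3:
                        raise FormatError(
                            f"{path}:{lineno}: bad provenance triplet {trip!r}"
                        )
                    prov.append(
                        ProvenanceEntry(
                            species_code=fields[0],
                            evidence_code=fields[1],
                            lls=float(fields[2]),
                        )
                    )
            edges[(a, b)] = (score, prov)
    return IntegratedNetwork(
        target_species=meta.get("target_species", "target"),
        edges=edges,
        integration_method=meta.get("integration_method", "max"),
    )
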