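"""Homology search and bidirectional-best-hit (BBH) orthology.

Orthologs between the target proteome and each source proteome are the
pairs of proteins that are each other's highest-scoring homology hit —
the classical one-to-one BBH criterion.  Scores come from one of two
engines:

* the built-in engine: optimal Smith–Waterman local alignment under an
  affine gap model (a gap of length k costs ``gap_open + (k-1) *
  gap_extend``), scored with a named substitution matrix (BLOSUM62 by
  default) via Biopython's ``PairwiseAligner``.  It reports the raw
  alignment score in the ``bitscore`` field and 0 in ``evalue`` — BBH
  needs a consistent ranking, not calibrated significance;
* externally produced tabular hits (DIAMOND / BLAST ``outfmt 6``),
  ingested through :func:`orthonet.io_formats.read_tabular_hits` and
  filtered by E-value (:func:`filter_hits`, default 1e-5).

Best-hit ties are broken by minimal E-value, then by lexicographically
smallest subject id, so results are deterministic.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError, OrthonetError
from .model import AlignmentHit, OrthologMap, Proteome

logger = logging.getLogger(__name__)

#: residues mapped to 'X' when absent from the substitution matrix
_AMBIGUOUS_FALLBACK = {"U", "O", "J"}


@dataclass
class AlignParams:
    """Built-in aligner parameters.

    Defaults (BLOSUM62, gap open 11, gap extend 1) follow common protein
    search practice.  ``min_score`` is the reporting threshold for
    all-vs-all hits.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = params.matrix()
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each additional one: exactly the affine model
    # gap_open + (k-1) * gap_extend.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def sanitize_sequence(seq: str, alphabet: str) -> str:
    """Uppercase ``seq`` and map residues missing from the matrix to 'X'.

    Only the recognised ambiguity letters (U, O, J) fall back to 'X';
    any other unknown character is an error naming the residue.
    """
    seq = seq.upper()
    known = set(alphabet)
    out = []
    for ch in seq:
        if ch in known:
            out.append(ch)
        elif ch in _AMBIGUOUS_FALLBACK and "X" in known:
            out.append("X")
        else:
            raise FormatError(
                f"residue {ch!r} is not in the substitution matrix and has "
                "no 'X' fallback"
            )
    return "".join(out)


def local_align_score(
    seq_q: str, seq_s: str, params: Optional[AlignParams] = None
) -> float:
    """Optimal Smith–Waterman local alignment score under affine gaps.

    The empty local alignment floors the score at 0.
    """
    params = params or AlignParams()
    if not seq_q or not seq_s:
        raise FormatError("local_align_score: empty sequence")
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q = sanitize_sequence(seq_q, alphabet)
    s = sanitize_sequence(seq_s, alphabet)
    return float(aligner.score(q, s))


def _placeholder_hit(query_id: str, subject_id: str, score: float) -> AlignmentHit:
    # The built-in engine reports the score only; positional columns are
    # placeholders (the downstream BBH logic never reads them).
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=0.0,
        aln_length=0,
        mismatches=0,
        gap_opens=0,
        q_start=1,
        q_end=1,
        s_start=1,
        s_end=1,
        evalue=0.0,
        bitscore=score,
    )


def all_vs_all_hits(
    proteome_q: Proteome,
    proteome_s: Proteome,
    params: Optional[AlignParams] = None,
) -> List[AlignmentHit]:
    """Score every (query, subject) pair with the built-in engine.

    A hit is reported when the local alignment score reaches
    ``params.min_score``.  When the two proteomes are the same object,
    self-pairs are excluded.
    """
    params = params or AlignParams()
    if len(proteome_q) == 0 or len(proteome_s) == 0:
        raise FormatError("all_vs_all_hits: empty proteome")
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    same = proteome_q is proteome_s
    subjects = [
        (rec.protein_id, sanitize_sequence(rec.seq, alphabet))
        for rec in proteome_s
    ]
    hits: List[AlignmentHit] = []
    for qrec in proteome_q:
        qseq = sanitize_sequence(qrec.seq, alphabet)
        for sid, sseq in subjects:
            if same and sid == qrec.protein_id:
                continue
            score = float(aligner.score(qseq, sseq))
            if score >= params.min_score:
                hits.append(_placeholder_hit(qrec.protein_id, sid, score))
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit], max_evalue: float = 1e-5
) -> List[AlignmentHit]:
    """Keep hits with ``evalue <= max_evalue`` (for externally produced
    hits; the built-in engine reports evalue 0, which always passes)."""
    return [h for h in hits if h.evalue <= max_evalue]


def best_hit(hits: Iterable[AlignmentHit], query_id: str) -> Optional[str]:
    """Subject with maximal bitscore for ``query_id``.

    Ties break by minimal evalue, then lexicographically smallest
    subject id; ``None`` when the query has no hits.
    """
    best: Optional[AlignmentHit] = None
    for h in hits:
        if h.query_id != query_id:
            continue
        if best is None or _hit_key(h) > _hit_key(best):
            best = h
    return best.subject_id if best is not None else None


def _hit_key(h: AlignmentHit) -> Tuple[float, float, Tuple[int, ...]]:
    # larger is better: bitscore desc, evalue asc, subject_id asc
    return (h.bitscore, -h.evalue, _lex_desc(h.subject_id))


def _lex_desc(s: str) -> Tuple[int, ...]:
    # invert lexicographic order so max() prefers the smallest id
    return tuple(-ord(c) for c in s)


def _best_per_query(hits: Iterable[AlignmentHit]) -> Dict[str, str]:
    best: Dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) > _hit_key(cur):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def bbh_orthologs(
    hits_q_to_s: Iterable[AlignmentHit],
    hits_s_to_q: Iterable[AlignmentHit],
    target_species: str = "target",
    source_species: str = "source",
) -> OrthologMap:
    """One-to-one orthologs by bidirectional best hit.

    A pair (t, s) is included iff t's best hit in the forward direction is
    s and s's best hit in the reverse direction is t.  The construction
    guarantees the one-to-one property.
    """
    fwd = _best_per_query(hits_q_to_s)
    rev = _best_per_query(hits_s_to_q)
    pairs = {(t, s) for t, s in fwd.items() if rev.get(s) == t}
    return OrthologMap(
        target_species=target_species,
        source_species=source_species,
        pairs=pairs,
    )


def transpose_hits(hits: Iterable[AlignmentHit]) -> List[AlignmentHit]:
    """Swap query and subject in every hit.

    Valid as the reverse search direction for the built-in engine, whose
    score is symmetric under a symmetric substitution matrix.
    """
    out = []
    for h in hits:
        out.append(
            AlignmentHit(
                query_id=h.subject_id,
                subject_id=h.query_id,
                percent_identity=h.percent_identity,
                aln_length=h.aln_length,
                mismatches=h.mismatches,
                gap_opens=h.gap_opens,
                q_start=h.s_start,
                q_end=h.s_end,
                s_start=h.q_start,
                s_end=h.q_end,
                evalue=h.evalue,
                bitscore=h.bitscore,
            )
        )
    return out


def bbh_from_proteomes(
    proteome_q: Proteome,
    proteome_s: Proteome,
    params: Optional[AlignParams] = None,
) -> OrthologMap:
    """BBH ortholog map computed with the built-in engine.

    Computes one direction of all-vs-all scores and transposes it for the
    reverse direction (the Smith–Waterman score is symmetric), halving
    the alignment work.
    """
    fwd = all_vs_all_hits(proteome_q, proteome_s, params)
    rev = transpose_hits(fwd)
    return bbh_orthologs(
        fwd,
        rev,
        target_species=proteome_q.species_code,
        source_species=proteome_s.species_code,
    )


# ---------------------------------------------------------------------------
# External aligner adapter
# ---------------------------------------------------------------------------

@dataclass
class ToolConfig:
    """Configuration for an external homology search engine."""

    engine: str = "diamond"  # "diamond" or "blast"
    binary: Optional[str] = None  # defaults to the engine name on PATH
    sensitive: bool = True
    threads: int = 1
    extra_args: List[str] = field(default_factory=list)


def run_external_search(
    proteome_q_path, proteome_s_path, tool_config: ToolConfig, out_path=None
) -> Path:
    """Run DIAMOND or BLAST to produce 12-column tabular hits.

    The adapter is engine-agnostic downstream: whatever produced the hits,
    they are read back with :func:`orthonet.io_formats.read_tabular_hits`.
    A missing binary raises an actionable error and leaves no partial
    output behind.
    """
    binary = tool_config.binary or tool_config.engine
    resolved = shutil.which(binary)
    if resolved is None:
        raise OrthonetError(
            f"external aligner {binary!r} not found on PATH; install it or "
            "use the built-in alignment engine"
        )
    q = Path(proteome_q_path)
    s = Path(proteome_s_path)
    out = Path(out_path) if out_path else q.with_suffix(".hits.tsv")
    if tool_config.engine == "diamond":
        db = s.with_suffix(".dmnd")
        cmds = [
            [resolved, "makedb", "--in", str(s), "-d", str(db)],
            [resolved, "blastp", "-q", str(q), "-d", str(db), "-o", str(out),
             "--outfmt", "6", "-p", str(tool_config.threads)]
            + (["--sensitive"] if tool_config.sensitive else [])
            + list(tool_config.extra_args),
        ]
    elif tool_config.engine == "blast":
        cmds = [
            ["makeblastdb", "-in", str(s), "-dbtype", "prot"],
            [resolved, "-query", str(q), "-db", str(s), "-out", str(out),
             "-outfmt", "6", "-num_threads", str(tool_config.threads)]
            + list(tool_config.extra_args),
        ]
    else:
        raise OrthonetError(f"unknown external engine {tool_config.engine!r}")
    try:
        for cmd in cmds:
            subprocess.run(cmd, check=True, capture_output=True)
    except (subprocess.CalledProcessError, OSError) as exc:
        if out.exists():
            out.unlink()
        raise OrthonetError(f"external search failed: {exc}") from exc
    return out
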