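"""Synthetic proteomes and source networks with known ground truth.

The generator emulates the inputs the builder consumes in the wild: an
ancestral proteome radiates into a target species and several source
species (each gene independently retained, retained sequences mutated by
per-residue substitution — no indels, which keeps the built-in aligner's
recovery behaviour analyzable); functional modules are planted as groups
of ancestral genes, and each source species gets scored networks whose
within-module pairs carry high LLS ("signal") and whose remaining pairs
carry low LLS ("background"); each source also gets a one-term-per-module
annotation catalog.  Everything is written in exactly the formats
:mod:`orthonet.io_formats` reads, together with a machine-readable ground
truth (ortholog pairs, module membership, per-edge labels), so recovery
properties can be tested end to end without external data.

All randomness flows from the single ``seed`` in :class:`SynthConfig`
through named substreams; a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import yaml

from . import io_formats
from .model import (
    AnnotationCatalog,
    EdgeRecord,
    Proteome,
    SequenceRecord,
    SourceNetwork,
    TermInfo,
    canonical_pair,
)

#: BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff).
BLOSUM62_FREQS: Dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_MIN_LEN = 30


@dataclass
class SynthConfig:
    """Parameters of the synthetic study system.

    Defaults are a desk-scale ecosystem: three source species descended
    from a 300-gene ancestor at 90% gene retention and 5% per-residue
    divergence, six planted modules of 5–10 genes, dense within-module
    edges with clearly higher LLS than the background, and up to three
    isoforms per target gene.  The background edge probability (0.001
    per network) keeps the integrated network at the sub-percent density
    real co-functional networks exhibit.
    """

    n_source_species: int = 3
    n_ancestral_genes: int = 300
    conservation_rate: float = 0.9
    substitution_rate: float = 0.05
    mean_protein_length: int = 150
    n_modules: int = 6
    module_size_range: Tuple[int, int] = (5, 10)
    within_module_edge_prob: float = 0.8
    background_edge_prob: float = 0.001
    lls_signal: Tuple[float, float] = (4.0, 0.5)
    lls_noise: Tuple[float, float] = (0.8, 0.3)
    isoforms_per_gene_max: int = 3
    networks_per_species: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("conservation_rate", "substitution_rate",
                     "within_module_edge_prob", "background_edge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.lls_signal[0] > self.lls_noise[0]:
            raise ValueError("lls_signal mean must exceed lls_noise mean")


def _rng(seed: int, *salts: int) -> np.random.Generator:
    """Named substream of the master seed (deterministic, collision-free)."""
    return np.random.default_rng(np.random.SeedSequence([seed, *salts]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(BLOSUM62_FREQS))
    probs = np.array(list(BLOSUM62_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def make_ancestral_proteome(config: SynthConfig) -> Proteome:
    """Sample the ancestral proteome.

    Sequences are i.i.d. residues from the BLOSUM62 background
    frequencies; lengths are geometric around ``mean_protein_length``
    with a floor of 30 residues.
    """
    rng = _rng(config.seed, 1)
    records: List[SequenceRecord] = []
    mean_extra = max(config.mean_protein_length - (_MIN_LEN - 1), 1)
    for i in range(config.n_ancestral_genes):
        length = (_MIN_LEN - 1) + int(rng.geometric(1.0 / mean_extra))
        records.append(
            SequenceRecord(
                protein_id=f"anc{i:04d}",
                seq=_random_seq(rng, length),
                gene_id=f"anc{i:04d}",
            )
        )
    return Proteome(species_code="ANC", records=records)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    letters = np.array(list(BLOSUM62_FREQS))
    probs = np.array(list(BLOSUM62_FREQS.values()))
    probs = probs / probs.sum()
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # substitutions only; a draw may coincide with the original residue
        chars[hit] = rng.choice(letters, size=n_hit, p=probs)
    return "".join(chars)


def derive_species(
    ancestral: Proteome,
    conservation_rate: float,
    substitution_rate: float,
    species_code: str,
    seed: int,
    isoforms_per_gene_max: int = 1,
) -> Tuple[List[SequenceRecord], Dict[str, List[str]], Dict[str, str]]:
    """Evolve a species from the ancestor.

    Each ancestral gene is retained with probability
    ``conservation_rate``; retained sequences receive per-residue
    substitutions at ``substitution_rate``.  Each retained gene emits 1
    to ``isoforms_per_gene_max`` isoforms; the first is the full-length
    protein, the others are C-terminal truncations.

    Returns (records, isoform table, ortholog truth) where the truth maps
    ancestral gene id -> this species' gene id.
    """
    rng = _rng(seed, 2)
    records: List[SequenceRecord] = []
    table: Dict[str, List[str]] = {}
    truth: Dict[str, str] = {}
    for idx, anc in enumerate(ancestral.records):
        if rng.random() >= conservation_rate:
            continue
        gene = f"{species_code}_g{idx:04d}"
        truth[anc.gene_id or anc.protein_id] = gene
        seq = _mutate(rng, anc.seq, substitution_rate)
        if isoforms_per_gene_max == 1:
            # pre-reduced proteome: the protein carries the gene's own id
            records.append(SequenceRecord(gene, seq, gene_id=gene))
            table[gene] = [gene]
            continue
        n_iso = int(rng.integers(1, isoforms_per_gene_max + 1))
        prots: List[str] = []
        for j in range(1, n_iso + 1):
            pid = f"{gene}.p{j}"
            if j == 1:
                records.append(SequenceRecord(pid, seq, gene_id=gene))
            else:
                cut = max(_MIN_LEN, int(len(seq) * rng.uniform(0.4, 0.8)))
                records.append(SequenceRecord(pid, seq[:cut], gene_id=gene))
            prots.append(pid)
        table[gene] = prots
    return records, table, truth


def assign_modules(config: SynthConfig) -> List[List[int]]:
    """Plant disjoint functional modules as sets of ancestral gene
    indices (sizes uniform within ``module_size_range``)."""
    rng = _rng(config.seed, 3)
    lo, hi = config.module_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_modules)]
    if sum(sizes) > config.n_ancestral_genes:
        raise ValueError("modules do not fit into the ancestral gene set")
    pool = rng.permutation(config.n_ancestral_genes)
    modules: List[List[int]] = []
    start = 0
    for size in sizes:
        modules.append(sorted(int(i) for i in pool[start : start + size]))
        start += size
    return modules


def make_source_network(
    genes_by_idx: Dict[int, str],
    modules: Sequence[Sequence[int]],
    config: SynthConfig,
    seed: int,
    species_code: str,
    evidence_code: str,
) -> Tuple[SourceNetwork, Dict[Tuple[str, str], str]]:
    """Sample one scored network over a species' genes.

    Within-module pairs become edges with probability
    ``within_module_edge_prob`` and LLS ~ Normal(*lls_signal*); all other
    pairs with probability ``background_edge_prob`` and LLS ~
    Normal(*lls_noise*); scores are floored at 0.01.  Returns the network
    and a per-edge label ("signal" / "background")."""
    rng = _rng(seed, 4)
    module_of: Dict[int, int] = {}
    for m, members in enumerate(modules):
        for idx in members:
            module_of[idx] = m
    indices = sorted(genes_by_idx)
    edges: List[EdgeRecord] = []
    labels: Dict[Tuple[str, str], str] = {}
    for i, ia in enumerate(indices):
        for ib in indices[i + 1 :]:
            same_module = (
                ia in module_of and module_of.get(ib) == module_of[ia]
            )
            if same_module:
                p, (mu, sd) = config.within_module_edge_prob, config.lls_signal
                label = "signal"
            else:
                p, (mu, sd) = config.background_edge_prob, config.lls_noise
                label = "background"
            if rng.random() < p:
                lls = max(0.01, float(rng.normal(mu, sd)))
                pair = canonical_pair(genes_by_idx[ia], genes_by_idx[ib])
                edges.append(EdgeRecord(pair[0], pair[1], lls))
                labels[pair] = label
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return (
        SourceNetwork(
            species_code=species_code, evidence_code=evidence_code, edges=edges
        ),
        labels,
    )


def make_annotations(
    modules: Sequence[Sequence[int]], genes_by_idx: Dict[int, str]
) -> AnnotationCatalog:
    """One term per planted module, restricted to the genes this species
    retained; term names are synthesized deterministically."""
    catalog = AnnotationCatalog()
    for m, members in enumerate(modules, 1):
        genes = {genes_by_idx[i] for i in members if i in genes_by_idx}
        if not genes:
            continue
        catalog[f"SYN:{m:04d}"] = TermInfo(
            name=f"planted functional module {m} process",
            namespace="other",
            genes=genes,
        )
    return catalog


@dataclass
class BundleTruth:
    """Ground truth emitted alongside a synthetic bundle."""

    target_species: str
    target_fasta: Path
    isoform_table: Path
    manifest: Path
    truth_json: Path
    orthologs: Dict[str, List[Tuple[str, str]]]  # species -> (target, source) gene pairs
    modules_target: Dict[str, List[str]]  # term -> target genes
    modules_by_species: Dict[str, Dict[str, List[str]]]
    edge_labels: Dict[str, Dict[Tuple[str, str], str]]  # "sp/ev" -> labels
    expected_interologs: Dict[str, Set[Tuple[str, str]]]  # "sp/ev" -> target pairs


_EVIDENCE_CODES = ["CX", "PP", "GN", "DP", "PG", "CC"]


def make_bundle(config: SynthConfig, out_dir) -> BundleTruth:
    """Generate a complete on-disk input bundle plus ground truth.

    Writes the target FASTA (with isoforms and a gene/isoform table),
    per-source directories with proteome, scored edge lists and a GMT
    catalog, a YAML manifest for :func:`orthonet.transfer.build_network`,
    and a ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ancestral = make_ancestral_proteome(config)
    modules = assign_modules(config)

    # --- target species (with isoforms) ---
    t_records, t_table, t_truth = derive_species(
        ancestral,
        config.conservation_rate,
        config.substitution_rate,
        "TGT",
        seed=_sub_seed(config.seed, 0),
        isoforms_per_gene_max=config.isoforms_per_gene_max,
    )
    target_fasta = out / "target.fasta"
    io_formats.write_fasta(t_records, target_fasta)
    isoform_table = out / "target.isoforms.tsv"
    with open(isoform_table, "w") as fh:
        for gene in sorted(t_table):
            for prot in t_table[gene]:
                fh.write(f"{gene}\t{prot}\n")

    anc_to_target = t_truth  # ancestral gene -> target gene
    idx_of = {f"anc{i:04d}": i for i in range(config.n_ancestral_genes)}

    orthologs: Dict[str, List[Tuple[str, str]]] = {}
    modules_by_species: Dict[str, Dict[str, List[str]]] = {}
    edge_labels: Dict[str, Dict[Tuple[str, str], str]] = {}
    expected: Dict[str, Set[Tuple[str, str]]] = {}
    manifest_sources = []

    for s in range(config.n_source_species):
        sp = f"SP{s + 1}"
        sp_dir = out / sp
        sp_dir.mkdir(exist_ok=True)
        s_records, _s_table, s_truth = derive_species(
            ancestral,
            config.conservation_rate,
            config.substitution_rate,
            sp,
            seed=_sub_seed(config.seed, s + 1),
            isoforms_per_gene_max=1,
        )
        io_formats.write_fasta(s_records, sp_dir / "proteome.fasta")
        genes_by_idx = {
            idx_of[anc]: gene for anc, gene in s_truth.items()
        }
        orthologs[sp] = sorted(
            (anc_to_target[anc], s_truth[anc])
            for anc in s_truth
            if anc in anc_to_target
        )
        target_of = dict((src, tgt) for tgt, src in orthologs[sp])
        modules_by_species[sp] = {
            f"SYN:{m + 1:04d}": sorted(
                genes_by_idx[i] for i in members if i in genes_by_idx
            )
            for m, members in enumerate(modules)
        }
        nets = []
        for k in range(config.networks_per_species):
            ev = _EVIDENCE_CODES[k % len(_EVIDENCE_CODES)]
            net, labels = make_source_network(
                genes_by_idx,
                modules,
                config,
                seed=_sub_seed(config.seed, 100 + s * 10 + k),
                species_code=sp,
                evidence_code=ev,
            )
            path = sp_dir / f"net_{ev}.tsv"
            io_formats.write_edge_list(
                net.edges, path, species_code=sp, evidence_code=ev
            )
            key = f"{sp}/{ev}"
            edge_labels[key] = labels
            expected[key] = {
                canonical_pair(target_of[e.gene_a], target_of[e.gene_b])
                for e in net.edges
                if e.gene_a in target_of and e.gene_b in target_of
            }
            nets.append({"path": f"{sp}/net_{ev}.tsv", "evidence_code": ev})
        catalog = make_annotations(modules, genes_by_idx)
        io_formats.write_gmt(catalog, sp_dir / "annotations.gmt")
        manifest_sources.append(
            {
                "species_code": sp,
                "proteome": f"{sp}/proteome.fasta",
                "networks": nets,
                "gmt": f"{sp}/annotations.gmt",
            }
        )

    manifest = out / "manifest.yaml"
    manifest.write_text(
        yaml.safe_dump(
            {"target_species": "TGT", "sources": manifest_sources},
            sort_keys=True,
        )
    )

    modules_target = {
        f"SYN:{m + 1:04d}": sorted(
            anc_to_target[f"anc{i:04d}"]
            for i in members
            if f"anc{i:04d}" in anc_to_target
        )
        for m, members in enumerate(modules)
    }
    truth_json = out / "ground_truth.json"
    truth_json.write_text(
        json.dumps(
            {
                "config": asdict(config),
                "target_species": "TGT",
                "orthologs": {
                    sp: [list(p) for p in pairs]
                    for sp, pairs in orthologs.items()
                },
                "modules_target": modules_target,
                "modules_by_species": modules_by_species,
                "edge_labels": {
                    key: {f"{a}|{b}": lab for (a, b), lab in labels.items()}
                    for key, labels in edge_labels.items()
                },
                "expected_interologs": {
                    key: sorted(f"{a}|{b}" for a, b in pairs)
                    for key, pairs in expected.items()
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return BundleTruth(
        target_species="TGT",
        target_fasta=target_fasta,
        isoform_table=isoform_table,
        manifest=manifest,
        truth_json=truth_json,
        orthologs=orthologs,
        modules_target=modules_target,
        modules_by_species=modules_by_species,
        edge_labels=edge_labels,
        expected_interologs=expected,
    )


def _sub_seed(seed: int, salt: int) -> int:
    """Derive a child seed below 2**31 from the master seed."""
    return int(
        np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31)
    )
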