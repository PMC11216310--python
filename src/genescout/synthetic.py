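"""Self-contained synthetic fixtures: genomes with planted genes.

The generator emulates the study design the pipeline is meant for: a
multi-contig nucleotide genome carrying complete protein-coding ORFs at
known loci, query proteins that are controlled-divergence orthologs of the
planted genes, decoy paralogs (diverged copies planted elsewhere),
pseudogenes (copies with an internal frameshift), and absent queries —
random proteins with no planted counterpart — for specificity testing.
Divergence is substitution-only so the ungapped validation aligner remains
a faithful stage; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import GenescoutError
from .formats_io import (
    AnnotationGene,
    ProteinQuery,
    write_fasta,
    write_gff3,
    write_paralog_tsv,
    write_presence_tsv,
)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# codons per residue, for back-translation of mutated paralog proteins
_CODONS_FOR: dict[str, tuple[str, ...]] = {}
for codon in _SENSE_CODONS:
    _CODONS_FOR.setdefault(str(Seq(codon).translate()), tuple())
_CODONS_FOR = {
    aa: tuple(c for c in _SENSE_CODONS if str(Seq(c).translate()) == aa)
    for aa in _CODONS_FOR
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic fixture.

    ``divergence`` is the fraction of query residues substituted relative
    to the planted gene's translation; ``spacing`` is the minimum
    intergenic distance between planted elements (twice the default region
    margin, so candidate regions of distinct genes stay disjoint).
    """

    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 200_000
    n_genes: int = 5
    gene_codons: tuple[int, int] = (100, 200)
    intronless: bool = True
    divergence: float = 0.1
    n_isoforms: int = 1
    n_paralogs: int = 0
    paralog_divergence: float = 0.25
    n_pseudogenes: int = 0
    n_absent_queries: int = 0
    gc: float = 0.5
    spacing: int = 20_000

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if not 0 <= self.paralog_divergence < 1:
            raise ValueError("paralog_divergence must be in [0, 1)")


@dataclass
class Fixture:
    """In-memory fixture; ``write`` materializes the standard files."""

    config: SimConfig
    genome: dict[str, str]
    queries: list[ProteinQuery]
    truth: list[AnnotationGene]
    presence: dict[str, bool]
    paralog_map: dict[str, list[str]]
    proteins: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fna",
            "queries": outdir / "queries.faa",
            "truth": outdir / "truth.gff3",
            "orthologs": outdir / "orthologs.tsv",
            "paralogs": outdir / "paralogs.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_fasta({q.qid: q.sequence for q in self.queries}, paths["queries"])
        write_gff3(self.truth, paths["truth"])
        write_presence_tsv(self.presence, paths["orthologs"])
        write_paralog_tsv(self.paralog_map, paths["paralogs"])
        return paths


def mutate_protein(seq: str, divergence: float, seed: int) -> str:
    """Substitute exactly ``round(divergence * len)`` residues.

    Replacement residues are drawn from the 19 standard alternatives
    (never the original, never an ambiguous letter).  Deterministic given
    ``seed``.
    """
    if not seq:
        raise GenescoutError("cannot mutate an empty protein")
    if not 0 <= divergence < 1:
        raise GenescoutError("divergence must be in [0, 1)")
    n_sub = round(divergence * len(seq))
    if n_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in sorted(positions):
        alternatives = [r for r in _RESIDUES if r != out[pos]]
        out[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A complete ORF of ``n_codons`` codons, stop codon included."""
    body = [
        _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
        for _ in range(n_codons - 2)
    ]
    return "ATG" + "".join(body) + _STOPS[rng.integers(0, 3)]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(
        _RESIDUES[rng.integers(0, len(_RESIDUES))] for _ in range(length - 1)
    )


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length == 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def generate_fixture(config: SimConfig) -> Fixture:
    """Generate a complete fixture from ``config`` (see module docstring).

    Raises when the planted elements cannot fit with the configured
    spacing ("reduce n_genes or raise contig_length").
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_codons

    # --- design the planted elements -----------------------------------
    elements: list[dict] = []  # kind, id, cds, biotype, (source)
    proteins: dict[str, str] = {}
    for i in range(config.n_genes):
        gid = f"g{i + 1}"
        cds = _random_cds(rng, int(rng.integers(lo, hi + 1)))
        proteins[gid] = str(Seq(cds).translate()).rstrip("*")
        elements.append({"kind": "gene", "id": gid, "cds": cds,
                         "biotype": "protein_coding"})
    paralog_map: dict[str, list[str]] = {}
    for j in range(config.n_paralogs):
        src = f"g{int(rng.integers(0, config.n_genes)) + 1}"
        pid = f"{src}_par{j + 1}"
        mutated = mutate_protein(
            proteins[src], config.paralog_divergence,
            seed=int(rng.integers(0, 2**31)),
        )
        mutated = "M" + mutated[1:]  # keep a translatable ATG start
        cds = "ATG" + _back_translate(rng, mutated[1:]) + _STOPS[rng.integers(0, 3)]
        paralog_map.setdefault(src, []).append(pid)
        elements.append({"kind": "paralog", "id": pid, "cds": cds,
                         "biotype": "protein_coding"})
    for j in range(config.n_pseudogenes):
        src = f"g{int(rng.integers(0, config.n_genes)) + 1}"
        pid = f"{src}_ps{j + 1}"
        cds = elements[int(src[1:]) - 1]["cds"]
        cut = len(cds) // 2
        elements.append({"kind": "pseudogene", "id": pid,
                         "cds": cds[:cut] + cds[cut + 1:],  # frameshift
                         "biotype": "pseudogene"})

    # --- place them on contigs ------------------------------------------
    contigs = [f"ctg{c + 1}" for c in range(config.n_contigs)]
    per_contig: dict[str, list[dict]] = {c: [] for c in contigs}
    for idx, elem in enumerate(elements):
        per_contig[contigs[idx % config.n_contigs]].append(elem)
    genome: dict[str, str] = {}
    truth: list[AnnotationGene] = []
    for contig in contigs:
        elems = per_contig[contig]
        order = rng.permutation(len(elems))
        elems = [elems[i] for i in order]
        total_len = sum(len(e["cds"]) for e in elems)
        slack = config.contig_length - total_len - (len(elems) + 1) * config.spacing
        if slack < 0:
            raise GenescoutError(
                "planted elements do not fit: reduce n_genes or raise contig_length"
            )
        extras = (
            rng.multinomial(slack, [1.0 / (len(elems) + 1)] * (len(elems) + 1))
            if elems
            else np.array([slack])
        )
        parts: list[str] = []
        cursor = 0
        for k, elem in enumerate(elems):
            gap = config.spacing + int(extras[k])
            parts.append(_random_dna(rng, gap, config.gc))
            cursor += gap
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            cds = elem["cds"]
            planted = cds if strand == "+" else str(Seq(cds).reverse_complement())
            parts.append(planted)
            truth.append(
                AnnotationGene(
                    gene_id=elem["id"],
                    contig=contig,
                    strand=strand,
                    start=cursor,
                    end=cursor + len(cds),
                    cds_intervals=(
                        [(cursor, cursor + len(cds))]
                        if elem["biotype"] == "protein_coding"
                        else []
                    ),
                    biotype=elem["biotype"],
                )
            )
            cursor += len(cds)
        tail = config.contig_length - cursor
        parts.append(_random_dna(rng, tail, config.gc))
        genome[contig] = "".join(parts)

    # --- queries and bookkeeping ----------------------------------------
    queries: list[ProteinQuery] = []
    presence: dict[str, bool] = {}
    for i in range(config.n_genes):
        gid = f"g{i + 1}"
        presence[gid] = True
        for j in range(config.n_isoforms):
            seq = mutate_protein(
                proteins[gid], config.divergence, seed=int(rng.integers(0, 2**31))
            )
            queries.append(ProteinQuery(gid, f"i{j + 1}", seq))
    for j in range(config.n_absent_queries):
        gid = f"absent{j + 1}"
        presence[gid] = False
        length = int(rng.integers(lo, hi + 1))
        queries.append(ProteinQuery(gid, "i1", _random_protein(rng, length)))
    truth.sort(key=lambda g: (g.contig, g.start))
    return Fixture(
        config=config,
        genome=genome,
        queries=queries,
        truth=truth,
        presence=presence,
        paralog_map=paralog_map,
        proteins=proteins,
    )


def label_candidates(candidates, truth: Sequence[AnnotationGene]) -> None:
    """Label each candidate 1 iff its CDS span overlaps its own query
    gene's true locus by >=1 bp (in place)."""
    loci: Mapping[str, AnnotationGene] = {g.gene_id: g for g in truth}
    for c in candidates:
        g = loci.get(c.gene_id)
        span = c.model.span
        c.label = int(
            g is not None
            and g.contig == c.model.contig
            and max(span[0], g.start) < min(span[1], g.end)
        )
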