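"""Readers/writers for FASTA, GFF3, BLAST tabular HSPs and hint records.

Coordinate convention: everything held in memory is 0-based, half-open, on
the forward strand.  Files honor their own standards — GFF3 and BLAST
tabular are 1-based inclusive, BED is 0-based half-open.  FASTA query
headers encode identity as ``gene_id|isoform_id`` (anything after the first
whitespace is ignored; a header without ``|`` is used as both ids).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .errors import InputParseError, NoUsableQueriesError
from .seeding import Hsp

#: Residues the paper-stage quality control removes queries for.
AMBIGUOUS_RESIDUES = frozenset("BJOUZ")


@dataclass(frozen=True)
class ProteinQuery:
    """One query protein isoform.

    ``gene_id`` groups isoforms of the same gene; ``sequence`` is uppercase
    amino acids (standard 20 letters plus X after quality control).
    """

    gene_id: str
    isoform_id: str
    sequence: str

    @property
    def qid(self) -> str:
        return f"{self.gene_id}|{self.isoform_id}"


@dataclass
class AnnotationGene:
    """A gene from a reference annotation, reduced to its evaluated region.

    ``start``/``end`` delimit the region from the start codon through the
    stop codon of the representative transcript (largest total CDS length).
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path_or_stream) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(path_or_stream, "fasta"):
        if record.id in seqs:
            raise InputParseError(f"duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_query_fasta(path_or_stream) -> list[ProteinQuery]:
    """Parse query proteins, splitting ``gene|isoform`` headers."""
    queries = []
    for name, seq in read_fasta(path_or_stream).items():
        gene_id, _, isoform_id = name.partition("|")
        queries.append(ProteinQuery(gene_id, isoform_id or gene_id, seq.upper()))
    return queries


def qc_queries(raw: Sequence[ProteinQuery]) -> list[ProteinQuery]:
    """Quality-control query proteins.

    Removes sequences containing ambiguous residues (B, J, O, U, Z) and
    collapses exact duplicate sequences to their first occurrence.  Input
    order is preserved, so the result is deterministic.
    """
    seen: set[str] = set()
    kept: list[ProteinQuery] = []
    for q in raw:
        if not q.sequence:
            continue
        if set(q.sequence) & AMBIGUOUS_RESIDUES:
            continue
        if q.sequence in seen:
            continue
        seen.add(q.sequence)
        kept.append(q)
    if not kept:
        raise NoUsableQueriesError("no usable queries after quality control")
    return kept


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def parse_blast_tab(
    stream, query_lengths: Mapping[str, int] | None = None
) -> list[Hsp]:
    """Parse 12-column BLAST tabular output into :class:`Hsp` records.

    Target coordinates in the file are 1-based inclusive with
    ``tstart > tend`` encoding the minus strand; they are converted to
    0-based half-open forward-strand intervals.  ``query_lengths`` (keyed by
    the full query id) makes ``query_cov`` exact; without it the aligned
    query end is used as a lower bound on the query length.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hsps: list[Hsp] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate runs of spaces as separators
            fields = line.split()
        if len(fields) != 12:
            raise InputParseError(
                f"line {lineno}: expected 12 columns, got {len(fields)}"
            )
        qid, tid = fields[0], fields[1]
        try:
            pident = float(fields[2])
            alnlen = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            tstart, tend = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            bits = float(fields[11])
        except ValueError as exc:
            raise InputParseError(f"line {lineno}: {exc}") from None
        if tstart < tend:
            strand, start, end = "+", tstart - 1, tend
        elif tstart > tend:
            strand, start, end = "-", tend - 1, tstart
        else:
            strand, start, end = "+", tstart - 1, tend  # single-base segment
        gene_id, _, isoform_id = qid.partition("|")
        qlen = (query_lengths or {}).get(qid)
        denom = qlen if qlen else max(qend, 1)
        cov = min(1.0, (qend - qstart + 1) / denom)
        hsps.append(
            Hsp(
                gene_id=gene_id,
                isoform_id=isoform_id or gene_id,
                contig=tid,
                strand=strand,
                start=start,
                end=end,
                pident=pident,
                aln_len=alnlen,
                query_cov=cov,
                evalue=evalue,
                bits=bits,
            )
        )
    return hsps


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene", "pseudogene"}


def _biotype_of(feature) -> str:
    for key in ("biotype", "gene_biotype"):
        if key in feature.attributes:
            value = feature.attributes[key][0]
            if value == "protein_coding":
                return "protein_coding"
            if "pseudogene" in value:
                return "pseudogene"
            return "other"
    if feature.featuretype == "pseudogene":
        return "pseudogene"
    return "protein_coding"


def parse_gff3_annotation(path_or_stream) -> list[AnnotationGene]:
    """Reduce a GFF3 annotation to one :class:`AnnotationGene` per gene.

    For protein-coding genes the representative transcript is the one with
    the largest total CDS length (ties broken by lexicographically smallest
    transcript id); its CDS extent defines the gene region.  CDS features
    without a resolvable parent gene are skipped with a warning.
    """
    if isinstance(path_or_stream, (str, Path)):
        data = Path(path_or_stream).read_text()
    else:
        data = path_or_stream.read()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    genes: list[AnnotationGene] = []
    claimed_cds = set()
    for gene in db.all_features():
        if gene.featuretype not in _GENE_TYPES:
            continue
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        biotype = _biotype_of(gene)
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for tx in db.children(gene, level=1):
            tx_id = tx.attributes.get("ID", [tx.id])[0]
            cds = [
                (c.start - 1, c.end)
                for c in db.children(tx, featuretype="CDS")
            ]
            if cds:
                transcripts[tx_id] = sorted(cds)
                claimed_cds.update((gene.seqid, s, e) for s, e in cds)
        if transcripts:
            rep_id = max(
                sorted(transcripts),
                key=lambda t: sum(e - s for s, e in transcripts[t]),
            )
            # max() keeps the first of equal keys; sorting first makes the
            # tie-break the lexicographically smallest id.
            best_len = max(
                sum(e - s for s, e in iv) for iv in transcripts.values()
            )
            candidates = [
                t
                for t, iv in transcripts.items()
                if sum(e - s for s, e in iv) == best_len
            ]
            rep_id = min(candidates)
            cds = transcripts[rep_id]
            genes.append(
                AnnotationGene(
                    gene_id=gene_id,
                    contig=gene.seqid,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    start=cds[0][0],
                    end=cds[-1][1],
                    cds_intervals=cds,
                    biotype=biotype,
                )
            )
        else:
            genes.append(
                AnnotationGene(
                    gene_id=gene_id,
                    contig=gene.seqid,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    start=gene.start - 1,
                    end=gene.end,
                    cds_intervals=[],
                    biotype=biotype,
                )
            )
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds))
        if not parents:
            warnings.warn(
                f"CDS feature at {cds.seqid}:{cds.start}-{cds.end} has no "
                "parent gene; skipped"
            )
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


def _phases(cds: Sequence[tuple[int, int]], strand: str) -> list[int]:
    order = list(cds) if strand == "+" else list(reversed(cds))
    phases, cum = {}, 0
    for s, e in order:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    return [phases[(s, e)] for s, e in cds]


def write_gff3(genes: Iterable[AnnotationGene], path, source: str = "genescout") -> None:
    """Write genes as GFF3 gene/mRNA/CDS rows (1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            ftype = "pseudogene" if g.biotype == "pseudogene" and not g.cds_intervals else "gene"
            out.write(
                f"{g.contig}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            if not g.cds_intervals:
                continue
            tx_id = f"{g.gene_id}.t1"
            out.write(
                f"{g.contig}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tx_id};Parent={g.gene_id}\n"
            )
            for (s, e), phase in zip(g.cds_intervals, _phases(g.cds_intervals, g.strand)):
                out.write(
                    f"{g.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tID={tx_id}.cds;Parent={tx_id}\n"
                )


# ---------------------------------------------------------------------------
# Hints, BED, TSV tables
# ---------------------------------------------------------------------------

def write_hints(hints, contig: str, path) -> None:
    """Write hint records in the GFF-style CDSpart dialect (``src=P``)."""
    with open(path, "w") as out:
        for h in hints:
            out.write(
                f"{contig}\thint\tCDSpart\t{h.start + 1}\t{h.end}\t{h.score:g}\t"
                f"{h.strand}\t.\tsrc={h.source}\n"
            )


def write_regions_bed(regions, path) -> None:
    with open(path, "w") as out:
        for r in regions:
            out.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.gene_id}\t{r.strand}\n"
            )


def read_presence_tsv(path) -> dict[str, bool]:
    """Read an ortholog-presence table: ``gene_id<TAB>present`` (0/1)."""
    presence: dict[str, bool] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise InputParseError(f"presence table line {lineno}: {line!r}")
            presence[parts[0]] = parts[1] == "1"
    return presence


def write_presence_tsv(presence: Mapping[str, bool], path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tpresent\n")
        for gene_id in presence:
            out.write(f"{gene_id}\t{int(presence[gene_id])}\n")


def read_paralog_tsv(path) -> dict[str, list[str]]:
    """Read a paralog map: ``gene_id<TAB>paralog_id`` rows."""
    paralogs: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputParseError(f"paralog table row {line!r}")
            paralogs.setdefault(parts[0], []).append(parts[1])
    return paralogs


def write_paralog_tsv(paralogs: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tparalog_id\n")
        for gene_id, ids in paralogs.items():
            for pid in ids:
                out.write(f"{gene_id}\t{pid}\n")
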