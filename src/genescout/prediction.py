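"""Protein hints and homology-guided gene prediction within candidate regions.

The ``external`` backends wrap a protein-to-genome aligner (Exonerate
protein2genome style) for hints and a hint-aware gene predictor (AUGUSTUS
style) for models.  The ``builtin`` backends keep the pipeline runnable
without external binaries: hints are the matched blocks of the seeding
aligner applied to the region sequence, and the predictor reports every
complete single-exon ORF (ATG through stop, both strands) of at least
``min_codons`` codons.  The synthetic fixtures plant intronless genes, so
the builtin path exercises the full pipeline honestly.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .errors import ConfigurationError, StageError
from .regions import CandidateRegion
from .seeding import builtin_search

MIN_ORF_CODONS = 60
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class HintRecord:
    """One CDSpart evidence interval, region-local forward coordinates."""

    start: int
    end: int
    strand: str
    kind: str = "CDSpart"
    source: str = "P"
    score: float = 0.0


@dataclass
class GeneModel:
    """A predicted gene: CDS intervals (genomic, forward coordinates,
    stop codon included), the encoded protein, and hint support."""

    model_id: str
    region_id: str
    gene_id: str
    contig: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    protein: str = ""
    hint_support: float | None = None
    has_start: bool = True
    has_stop: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


# ---------------------------------------------------------------------------
# Hints
# ---------------------------------------------------------------------------

def build_hints(
    region: CandidateRegion,
    region_seq: str,
    queries,
    backend: str = "builtin",
    min_bits: float = 25.0,
    command_template: str | None = None,
) -> list[HintRecord]:
    """Produce CDSpart hints for a region from its retained query proteins.

    The builtin backend reuses the translated seed-and-extend aligner on
    the region sequence; a lower bit threshold than the genome-wide search
    is used because the search space is tiny.  An empty result is not an
    error — it simply leaves predictions unsupported.
    """
    if backend == "external":
        return _external_hints(region, region_seq, queries, command_template)
    hsps = builtin_search(queries, {"region": region_seq}, min_bits=min_bits)
    hints = [
        HintRecord(start=h.start, end=h.end, strand=h.strand, score=h.bits)
        for h in hsps
    ]
    hints.sort(key=lambda h: (h.start, h.end, h.strand))
    return hints


def _external_hints(region, region_seq, queries, command_template):
    from .formats_io import write_fasta

    if not command_template:
        raise ConfigurationError("external hint backend requires a command template")
    tool = command_template.split()[0]
    if shutil.which(tool) is None:
        raise ConfigurationError(f"hint aligner {tool!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "queries.faa"
        rpath = Path(tmp) / "region.fna"
        opath = Path(tmp) / "hints.gff"
        write_fasta({q.qid: q.sequence for q in queries}, qpath)
        write_fasta({"region": region_seq}, rpath)
        cmd = command_template.format(queries=qpath, region=rpath, output=opath)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ConfigurationError(
                f"hint aligner failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        hints = []
        for line in opath.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8 or f[2] != "CDSpart":
                continue
            hints.append(
                HintRecord(
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    score=float(f[5]) if f[5] not in ".," else 0.0,
                )
            )
    hints.sort(key=lambda h: (h.start, h.end, h.strand))
    return hints


# ---------------------------------------------------------------------------
# Builtin ORF predictor
# ---------------------------------------------------------------------------

def scan_orfs(seq: str, min_codons: int = MIN_ORF_CODONS) -> list[tuple[str, int, int]]:
    """Find complete ORFs (ATG..stop, stop included) on both strands.

    Returns (strand, start, end) with coordinates on the scanned strand's
    own sequence: forward ORFs on ``seq``, minus ORFs on its reverse
    complement.  Per (frame, stop) only the ORF from the first in-frame ATG
    is reported (the longest complete ORF ending at that stop); the codon
    count includes the stop codon.
    """
    seq = seq.upper()
    orfs: list[tuple[str, int, int]] = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        n = len(s)
        for f in range(3):
            atg = None
            for pos in range(f, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    if atg is not None and (pos + 3 - atg) // 3 >= min_codons:
                        orfs.append((strand, atg, pos + 3))
                    atg = None
                elif codon == "ATG" and atg is None:
                    atg = pos
    return orfs


def lift_to_genome(
    strand: str, local_intervals: Sequence[tuple[int, int]], region: CandidateRegion
) -> list[tuple[int, int]]:
    """Lift region-local CDS intervals to genomic forward coordinates.

    Plus-strand intervals are offsets into the forward region sequence;
    minus-strand intervals are offsets into the region's reverse
    complement and are mapped through the reverse-complement coordinate
    flip.  Intervals escaping the region raise :class:`StageError`.
    """
    length = region.length
    lifted = []
    for s, e in local_intervals:
        if s < 0 or e > length or s >= e:
            raise StageError(
                f"local interval [{s},{e}) escapes region of length {length}"
            )
        if strand == "+":
            lifted.append((region.start + s, region.start + e))
        else:
            lifted.append((region.start + length - e, region.start + length - s))
    return sorted(lifted)


def hint_support_percent(
    cds_fwd_local: Sequence[tuple[int, int]], strand: str, hints: Sequence[HintRecord]
) -> float:
    """Percent of CDS bases covered by at least one same-strand hint.

    Invariant under hint fragmentation: splitting a hint into adjacent
    pieces does not change coverage.
    """
    total = sum(e - s for s, e in cds_fwd_local)
    if total == 0:
        raise StageError("gene model has zero CDS length")
    strand_hints = sorted(
        (h.start, h.end) for h in hints if h.strand == strand
    )
    merged: list[list[int]] = []
    for s, e in strand_hints:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = 0
    for cs, ce in cds_fwd_local:
        for hs, he in merged:
            lo, hi = max(cs, hs), min(ce, he)
            if lo < hi:
                covered += hi - lo
    return 100.0 * covered / total


def _external_predict(region, region_seq, hints, command_template):
    """Run a configured hint-aware gene predictor on the region sequence.

    The command template is formatted with ``{region}`` (FASTA), ``{hints}``
    (CDSpart GFF) and ``{output}`` (GFF with CDS rows, region-local 1-based
    coordinates).  Models are lifted to genomic coordinates; hint support is
    recomputed from the hints when the predictor does not report it.
    """
    from .formats_io import write_fasta, write_hints

    if not command_template:
        raise ConfigurationError("external predictor requires a command template")
    tool = command_template.split()[0]
    if shutil.which(tool) is None:
        raise ConfigurationError(f"gene predictor {tool!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        rpath = Path(tmp) / "region.fna"
        hpath = Path(tmp) / "hints.gff"
        opath = Path(tmp) / "predictions.gff"
        write_fasta({"region": region_seq}, rpath)
        write_hints(hints, "region", hpath)
        cmd = command_template.format(region=rpath, hints=hpath, output=opath)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ConfigurationError(
                f"gene predictor failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        by_tx: dict[str, dict] = {}
        for line in opath.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            tx = f[8].split("Parent=")[-1].split(";")[0] if "Parent=" in f[8] else f[8]
            rec = by_tx.setdefault(tx, {"strand": f[6], "cds": []})
            rec["cds"].append((int(f[3]) - 1, int(f[4])))
        models = []
        for tx in sorted(by_tx):
            rec = by_tx[tx]
            strand = rec["strand"]
            fwd_local = sorted(rec["cds"])
            if strand == "+":
                local = fwd_local
            else:
                n = region.length
                local = sorted((n - e, n - s) for s, e in fwd_local)
            genomic = lift_to_genome(strand, local, region)
            parts = [region_seq[s:e] for s, e in fwd_local]
            cds_seq = "".join(parts)
            if strand == "-":
                cds_seq = str(Seq(cds_seq).reverse_complement())
            protein = str(Seq(cds_seq).translate()).rstrip("*")
            has_start = cds_seq[:3] == "ATG"
            has_stop = cds_seq[-3:] in _STOPS
            if not (has_start and has_stop):
                continue
            models.append(
                GeneModel(
                    model_id="",
                    region_id=region.region_id,
                    gene_id=region.gene_id,
                    contig=region.contig,
                    strand=strand,
                    cds_intervals=genomic,
                    protein=protein,
                    hint_support=hint_support_percent(fwd_local, strand, hints),
                )
            )
    models.sort(key=lambda m: (m.span, m.strand))
    for i, m in enumerate(models, start=1):
        m.model_id = f"{region.region_id}.m{i}"
    return models


def predict_genes(
    region: CandidateRegion,
    region_seq: str,
    hints: Sequence[HintRecord],
    backend: str = "builtin",
    min_codons: int = MIN_ORF_CODONS,
    command_template: str | None = None,
) -> list[GeneModel]:
    """Predict complete gene models within a region and lift them to the genome.

    Models lacking either a start or a stop codon are never emitted.  The
    builtin backend returns an empty list for regions shorter than
    ``3 * min_codons`` nucleotides.
    """
    if backend == "external":
        return _external_predict(region, region_seq, hints, command_template)
    if len(region_seq) < 3 * min_codons:
        return []
    models: list[GeneModel] = []
    for strand, s, e in scan_orfs(region_seq, min_codons=min_codons):
        genomic = lift_to_genome(strand, [(s, e)], region)
        if strand == "+":
            cds_seq = region_seq[s:e]
        else:
            cds_seq = str(Seq(region_seq).reverse_complement())[s:e]
        protein = str(Seq(cds_seq).translate()).rstrip("*")
        fwd_local = [(gs - region.start, ge - region.start) for gs, ge in genomic]
        support = hint_support_percent(fwd_local, strand, hints)
        models.append(
            GeneModel(
                model_id="",
                region_id=region.region_id,
                gene_id=region.gene_id,
                contig=region.contig,
                strand=strand,
                cds_intervals=genomic,
                protein=protein,
                hint_support=support,
                has_start=True,
                has_stop=True,
            )
        )
    models.sort(key=lambda m: (m.span, m.strand))
    for i, m in enumerate(models, start=1):
        m.model_id = f"{region.region_id}.m{i}"
    return models
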