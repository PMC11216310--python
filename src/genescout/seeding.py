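"""Translated similarity search: query proteins vs. genome nucleotides.

Two backends produce the same :class:`Hsp` records.  The ``external``
backend shells out to a user-configured search tool (an MMseqs2/TBLASTN
style command) and parses its BLAST tabular output.  The ``builtin``
backend is a self-contained seed-and-extend translated search: exact
5-mer seeds on six-frame translations, ungapped X-drop extension under
BLOSUM62, one reported HSP per (query, frame, diagonal).  It exists so the
whole pipeline runs and is testable without any external binaries.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import scoring
from .errors import ConfigurationError, InputParseError

if TYPE_CHECKING:  # pragma: no cover
    from .formats_io import ProteinQuery

SEED_K = 5
XDROP = 20
DEFAULT_MIN_BITS = 40.0

_VALID_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class Hsp:
    """One high-scoring pair: a query isoform aligned to a genomic interval.

    ``start``/``end`` are 0-based half-open forward-strand genomic
    coordinates; ``strand`` records which strand the protein is encoded on.
    ``query_cov`` is the aligned fraction of the query length.
    """

    gene_id: str
    isoform_id: str
    contig: str
    strand: str
    start: int
    end: int
    pident: float
    aln_len: int
    query_cov: float
    evalue: float
    bits: float
    frame: int | None = None  # builtin backend bookkeeping: 0..5

    @property
    def qid(self) -> str:
        return f"{self.gene_id}|{self.isoform_id}"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def translate_six_frames(dna: str) -> dict[str, str]:
    """Translate ``dna`` in all six reading frames.

    Returns a mapping with keys ``+1,+2,+3,-1,-2,-3``.  Frames ``-f`` read
    from the reverse complement with the same offset convention.  Stops are
    ``*``; codons containing N translate to X; trailing partial codons are
    dropped.  Characters outside ``{A,C,G,T,N}`` raise ``ValueError``.
    """
    dna = dna.upper()
    bad = set(dna) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    rc = str(Seq(dna).reverse_complement())
    frames: dict[str, str] = {}
    for label, seq in (("+", dna), ("-", rc)):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                aa = str(Seq(sub).translate())
                # Biopython emits X for N-containing codons already.
            else:
                aa = ""
            frames[f"{label}{f + 1}"] = aa
    return frames


def _frame_to_genomic(
    frame_key: str, aa_start: int, aa_end: int, contig_len: int
) -> tuple[str, int, int]:
    """Map an amino-acid interval in a frame back to genomic nucleotides."""
    strand, f = frame_key[0], int(frame_key[1]) - 1
    nt_start = f + 3 * aa_start
    nt_end = f + 3 * aa_end
    if strand == "+":
        return "+", nt_start, nt_end
    return "-", contig_len - nt_end, contig_len - nt_start


def genomic_to_frame(
    frame_key: str, start: int, end: int, contig_len: int
) -> tuple[int, int]:
    """Inverse of the frame→genome mapping (amino-acid coordinates)."""
    strand, f = frame_key[0], int(frame_key[1]) - 1
    if strand == "+":
        nt_start, nt_end = start, end
    else:
        nt_start, nt_end = contig_len - end, contig_len - start
    return (nt_start - f) // 3, (nt_end - f) // 3


def _extend_xdrop(
    q: np.ndarray, t: np.ndarray, qpos: int, tpos: int, k: int, xdrop: int
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a seed at (qpos, tpos) of length k.

    Returns (q_start, q_end, raw_score, matches) with q_end exclusive;
    target coordinates follow on the same diagonal.
    """
    pair = scoring.SCORE
    score = int(pair[q[qpos : qpos + k], t[tpos : tpos + k]].sum())
    # extend right
    best_r, run = 0, 0
    i, j = qpos + k, tpos + k
    r_off = 0
    while i < len(q) and j < len(t):
        run += int(pair[q[i], t[j]])
        if run > best_r:
            best_r, r_off = run, i - (qpos + k) + 1
        elif run < best_r - xdrop:
            break
        i += 1
        j += 1
    # extend left
    best_l, run = 0, 0
    i, j = qpos - 1, tpos - 1
    l_off = 0
    while i >= 0 and j >= 0:
        run += int(pair[q[i], t[j]])
        if run > best_l:
            best_l, l_off = run, qpos - i
        elif run < best_l - xdrop:
            break
        i -= 1
        j -= 1
    qs = qpos - l_off
    qe = qpos + k + r_off
    total = score + best_l + best_r
    matches = int((q[qs:qe] == t[qs - qpos + tpos : qe - qpos + tpos]).sum())
    return qs, qe, total, matches


def _kmer_index(queries: Sequence["ProteinQuery"], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for qi, query in enumerate(queries):
        seq = query.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((qi, pos))
    return index


def builtin_search(
    queries: Sequence["ProteinQuery"],
    genome: Mapping[str, str],
    min_bits: float = DEFAULT_MIN_BITS,
    k: int = SEED_K,
    xdrop: int = XDROP,
) -> list[Hsp]:
    """Seed-and-extend translated search of ``queries`` against ``genome``.

    Deterministic given its inputs.  Contigs shorter than one codon are
    skipped with a warning.
    """
    index = _kmer_index(queries, k)
    encoded_q = [scoring.encode(q.sequence) for q in queries]
    hsps: list[Hsp] = []
    frame_order = ["+1", "+2", "+3", "-1", "-2", "-3"]
    for contig in genome:
        dna = genome[contig].upper()
        if len(dna) < 3:
            warnings.warn(f"contig {contig!r} shorter than 3 nt; skipped")
            continue
        frames = translate_six_frames(dna)
        for fi, fkey in enumerate(frame_order):
            aa = frames[fkey]
            if len(aa) < k:
                continue
            t = scoring.encode(aa)
            # diagonal -> (best_score, qs, qe, matches, qi); one HSP per
            # (query, diagonal), extensions skip seeds inside prior spans
            seeds: dict[tuple[int, int], list[int]] = {}
            for tpos in range(len(aa) - k + 1):
                hits = index.get(aa[tpos : tpos + k])
                if not hits:
                    continue
                for qi, qpos in hits:
                    seeds.setdefault((qi, tpos - qpos), []).append(qpos)
            for (qi, diag), qpositions in sorted(seeds.items()):
                q = encoded_q[qi]
                best = None
                covered_end = -1
                for qpos in qpositions:
                    if qpos < covered_end:
                        continue
                    qs, qe, raw, matches = _extend_xdrop(
                        q, t, qpos, qpos + diag, k, xdrop
                    )
                    covered_end = qe
                    if best is None or raw > best[0]:
                        best = (raw, qs, qe, matches)
                raw, qs, qe, matches = best[0], best[1], best[2], best[3]
                bits = scoring.bit_score(raw)
                if bits < min_bits:
                    continue
                ts, te = qs + diag, qe + diag
                strand, g_start, g_end = _frame_to_genomic(fkey, ts, te, len(dna))
                aln_len = qe - qs
                query = queries[qi]
                hsps.append(
                    Hsp(
                        gene_id=query.gene_id,
                        isoform_id=query.isoform_id,
                        contig=contig,
                        strand=strand,
                        start=g_start,
                        end=g_end,
                        pident=100.0 * matches / aln_len,
                        aln_len=aln_len,
                        query_cov=aln_len / len(query.sequence),
                        evalue=float(len(dna)) * len(query.sequence) * 2.0 ** (-bits),
                        bits=bits,
                        frame=fi,
                    )
                )
    hsps.sort(key=lambda h: (h.contig, h.start, h.end, h.strand, h.qid))
    return hsps


def external_search(
    queries: Sequence["ProteinQuery"],
    genome: Mapping[str, str],
    command_template: str,
    min_bits: float = DEFAULT_MIN_BITS,
) -> list[Hsp]:
    """Run a configured external translated-search tool.

    ``command_template`` is formatted with ``{queries}``, ``{genome}`` and
    ``{output}`` placeholders and must produce 12-column BLAST tabular
    output at ``{output}``.
    """
    from .formats_io import parse_blast_tab, write_fasta

    tool = command_template.split()[0]
    if shutil.which(tool) is None:
        raise ConfigurationError(
            f"external search tool {tool!r} not found on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "queries.faa"
        gpath = Path(tmp) / "genome.fna"
        opath = Path(tmp) / "hits.tsv"
        write_fasta({q.qid: q.sequence for q in queries}, qpath)
        write_fasta(dict(genome), gpath)
        cmd = command_template.format(queries=qpath, genome=gpath, output=opath)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ConfigurationError(
                f"external search failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        if not opath.exists():
            raise InputParseError("external search produced no output file")
        qlens = {q.qid: len(q.sequence) for q in queries}
        with open(opath) as handle:
            hsps = parse_blast_tab(handle, query_lengths=qlens)
    return [h for h in hsps if h.bits >= min_bits]


def search_translated(
    queries: Sequence["ProteinQuery"],
    genome: Mapping[str, str],
    backend: str = "builtin",
    min_bits: float = DEFAULT_MIN_BITS,
    command_template: str | None = None,
) -> list[Hsp]:
    """Dispatch the translated search to the selected backend."""
    if backend == "builtin":
        return builtin_search(queries, genome, min_bits=min_bits)
    if backend == "external":
        if not command_template:
            raise ConfigurationError(
                "external backend requires a search command template"
            )
        return external_search(queries, genome, command_template, min_bits=min_bits)
    raise ConfigurationError(f"unknown search backend {backend!r}")
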