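"""Ungapped re-alignment of query proteins to predicted proteins.

Validation statistics feed the result filter: the best-scoring ungapped
alignment over all relative offsets of the two sequences, scored under
BLOSUM62 (X and stop score 0).  The aligned length is the full overlap
window at the best offset — the ungapped model has no internal gaps by
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import scoring
from .errors import StageError
from .formats_io import ProteinQuery
from .prediction import GeneModel


@dataclass(frozen=True)
class AlignmentStats:
    """Validation alignment statistics.

    ``aln_pident``/``aln_psim`` are percentages of the aligned window;
    ``aln_gene_cov`` is the aligned fraction of the *query* length.
    ``score`` is the raw BLOSUM62 alignment score used for ranking.
    """

    aln_pident: float
    aln_psim: float
    aln_gene_cov: float
    score: int = 0


def align_validate(query: ProteinQuery | str, predicted: str) -> AlignmentStats:
    """Best ungapped alignment of ``query`` against ``predicted``.

    Offsets place the query at every possible shift relative to the
    predicted protein; ties in score resolve to the smallest offset.  A
    pair is counted similar when its substitution score is positive or the
    residues are identical (identical X/stop pairs score 0 but remain
    matches, keeping percent similarity >= percent identity).
    """
    qseq = query.sequence if isinstance(query, ProteinQuery) else query
    if not qseq:
        raise StageError("empty query protein")
    if not predicted:
        raise StageError("nothing to validate: empty predicted protein")
    q = scoring.encode(qseq)
    p = scoring.encode(predicted)
    n, m = len(q), len(p)
    best = None  # (score, offset)
    for offset in range(-(n - 1), m):
        qs = max(0, -offset)
        ps = max(0, offset)
        length = min(n - qs, m - ps)
        window_scores = scoring.SCORE[q[qs : qs + length], p[ps : ps + length]]
        total = int(window_scores.sum())
        if best is None or total > best[0]:
            best = (total, offset)
    score, offset = best
    qs = max(0, -offset)
    ps = max(0, offset)
    length = min(n - qs, m - ps)
    qw = q[qs : qs + length]
    pw = p[ps : ps + length]
    pair = scoring.SCORE[qw, pw]
    matches = int((qw == pw).sum())
    similar = int(((pair > 0) | (qw == pw)).sum())
    return AlignmentStats(
        aln_pident=100.0 * matches / length,
        aln_psim=100.0 * similar / length,
        aln_gene_cov=length / n,
        score=score,
    )


def best_query_for_model(
    model: GeneModel, queries_of_gene: Sequence[ProteinQuery]
) -> tuple[str, AlignmentStats]:
    """Pick the query isoform whose ungapped alignment scores highest.

    Ties break to the lexicographically smallest isoform id.
    """
    if not queries_of_gene:
        raise StageError(f"no query isoforms available for model {model.model_id}")
    best: tuple[str, AlignmentStats] | None = None
    for q in sorted(queries_of_gene, key=lambda q: q.isoform_id):
        stats = align_validate(q, model.protein)
        if best is None or stats.score > best[1].score:
            best = (q.isoform_id, stats)
    return best
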