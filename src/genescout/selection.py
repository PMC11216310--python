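"""Reduce scored candidates to the final report.

Rule order is fixed: overlap dedup within a genomic region, then per-gene
dedup with near-tie retention (probabilities above ``tie_ratio`` times the
gene's best are kept), then the calibrated probability threshold.  All
ties break on identifiers so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .prediction import GeneModel


@dataclass
class Candidate:
    """A gene model joined to its feature vector and filter probability."""

    model: GeneModel
    features: np.ndarray | None = None
    probability: float | None = None
    isoform_id: str | None = None
    label: int | None = None

    @property
    def gene_id(self) -> str:
        return self.model.gene_id

    @property
    def sort_key(self):
        return (self.model.contig, self.model.span[0], self.model.span[1],
                self.model.model_id)


def _overlap_components(candidates: Sequence[Candidate]) -> list[list[Candidate]]:
    """Connected components under >=1 bp same-strand CDS-span overlap."""
    order = sorted(
        candidates,
        key=lambda c: (c.model.contig, c.model.strand, c.model.span),
    )
    comps: list[list[Candidate]] = []
    cur_key = None
    cur_end = -1
    for c in order:
        key = (c.model.contig, c.model.strand)
        s, e = c.model.span
        if key == cur_key and s < cur_end:
            comps[-1].append(c)
            cur_end = max(cur_end, e)
        else:
            comps.append([c])
            cur_key, cur_end = key, e
    return comps


def _best(component: Sequence[Candidate]) -> Candidate:
    return min(
        component,
        key=lambda c: (-(c.probability if c.probability is not None else 0.0),
                       c.gene_id, c.model.model_id),
    )


def dedup_by_region(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Keep only the highest-probability candidate per overlapping locus."""
    kept = [_best(comp) for comp in _overlap_components(candidates)]
    kept.sort(key=lambda c: c.sort_key)
    return kept


def dedup_by_gene(
    candidates: Sequence[Candidate], tie_ratio: float = 0.95
) -> list[Candidate]:
    """Per gene, keep candidates within the near-tie band of the best.

    A candidate survives when its probability exceeds ``tie_ratio`` times
    the gene's maximum probability, so near-equal multi-locus predictions
    are all reported.
    """
    best: dict[str, float] = {}
    for c in candidates:
        p = c.probability or 0.0
        if c.gene_id not in best or p > best[c.gene_id]:
            best[c.gene_id] = p
    kept = [
        c
        for c in candidates
        if (c.probability or 0.0) >= best[c.gene_id]
        or (c.probability or 0.0) > tie_ratio * best[c.gene_id]
    ]
    kept.sort(key=lambda c: c.sort_key)
    return kept


def pick_isoform_model(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Among same-gene models at one locus (overlapping spans), keep the
    highest-probability one regardless of which isoform validated it."""
    kept: list[Candidate] = []
    by_gene: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gene_id in sorted(by_gene):
        for comp in _overlap_components(by_gene[gene_id]):
            kept.append(_best(comp))
    kept.sort(key=lambda c: c.sort_key)
    return kept


def apply_threshold(
    candidates: Sequence[Candidate], threshold: float
) -> list[Candidate]:
    """Keep candidates with probability >= threshold, position-sorted."""
    kept = [c for c in candidates if (c.probability or 0.0) >= threshold]
    kept.sort(key=lambda c: c.sort_key)
    return kept


def select(
    candidates: Sequence[Candidate],
    threshold: float,
    tie_ratio: float = 0.95,
) -> list[Candidate]:
    """Full selection chain: region dedup, gene dedup, isoform pick, threshold."""
    step = dedup_by_region(candidates)
    step = dedup_by_gene(step, tie_ratio=tie_ratio)
    step = pick_isoform_model(step)
    return apply_threshold(step, threshold)
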