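"""Score a final report against a truth annotation.

Confusion cells are defined over query genes, with negatives supplied by
an explicit ortholog-presence table: a query gene with no ortholog in the
searched genome is a true negative when it is absent from the report and a
false positive when reported.  A present query gene is a true positive
when some reported locus overlaps its annotated region (start codon
through stop codon) by at least one base; reporting it only elsewhere
yields both a false positive and a false negative.  Coverage statistics
are computed for true-positive pairs only; every reported locus is also
placed into one of five annotation categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import StageError
from .formats_io import AnnotationGene
from .prediction import GeneModel

CATEGORIES = ("correct", "paralog", "other_gene", "pseudogene", "intergenic")


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    gene_coverage: list[float] = field(default_factory=list)
    exon_coverage: list[float] = field(default_factory=list)
    category_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mean_gene_coverage": (
                sum(self.gene_coverage) / len(self.gene_coverage)
                if self.gene_coverage
                else None
            ),
            "mean_exon_coverage": (
                sum(self.exon_coverage) / len(self.exon_coverage)
                if self.exon_coverage
                else None
            ),
            "category_counts": dict(self.category_counts),
        }


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def confusion(
    report: Sequence[GeneModel],
    annotation: Sequence[AnnotationGene],
    ortholog_presence: Mapping[str, bool],
    mode: str = "overlap",
) -> tuple[int, int, int, int]:
    """Count (tp, fp, fn, tn) over query genes.

    ``mode='overlap'`` requires a reported locus to overlap the truth gene
    region; ``mode='presence'`` counts a present gene reported anywhere as
    a true positive (the assembly-level evaluation convention).
    """
    truth = {g.gene_id: g for g in annotation}
    reported: dict[str, list[GeneModel]] = {}
    for m in report:
        reported.setdefault(m.gene_id, []).append(m)
    for gene_id in reported:
        if gene_id not in ortholog_presence:
            raise StageError(f"gene {gene_id!r} missing from ortholog presence table")
    tp = fp = fn = tn = 0
    for gene_id, present in ortholog_presence.items():
        models = reported.get(gene_id, [])
        if present:
            if mode == "presence":
                hit = bool(models)
            else:
                g = truth.get(gene_id)
                if g is None:
                    raise StageError(
                        f"present gene {gene_id!r} has no truth annotation"
                    )
                hit = any(
                    m.contig == g.contig and _overlaps(m.span, g.interval)
                    for m in models
                )
            if hit:
                tp += 1
            else:
                fn += 1
                if models:  # reported, but only at wrong loci
                    fp += 1
        else:
            if models:
                fp += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def metrics(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[float | None, float | None, float | None, float | None]:
    """Sensitivity, specificity, PPV, NPV; ``None`` on a zero denominator."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return (
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
        ratio(tp, tp + fp),
        ratio(tn, tn + fn),
    )


def coverage(
    pred_model: GeneModel, truth_gene: AnnotationGene
) -> tuple[float, float]:
    """Fraction of the truth gene span / truth CDS bases covered by the model."""
    gs, ge = truth_gene.interval
    if ge <= gs:
        raise StageError(f"truth gene {truth_gene.gene_id} has zero-length region")
    ps, pe = pred_model.span
    gene_cov = max(0, min(ge, pe) - max(gs, ps)) / (ge - gs)
    total_cds = sum(e - s for s, e in truth_gene.cds_intervals)
    if total_cds == 0:
        return gene_cov, 0.0
    covered = 0
    for ts, te in truth_gene.cds_intervals:
        for cs, ce in pred_model.cds_intervals:
            covered += max(0, min(te, ce) - max(ts, cs))
    return gene_cov, covered / total_cds


def categorize(
    pred_model: GeneModel,
    annotation: Sequence[AnnotationGene],
    query_gene_ids: set[str],
    paralog_map: Mapping[str, Sequence[str]],
) -> str:
    """Annotate a reported locus: correct > paralog > other_gene >
    pseudogene > intergenic, first >=1 bp overlap in precedence order."""
    span = pred_model.span
    overlapping = [
        g
        for g in annotation
        if g.contig == pred_model.contig and _overlaps(span, g.interval)
    ]
    own_paralogs = set(paralog_map.get(pred_model.gene_id, []))
    if any(g.gene_id == pred_model.gene_id for g in overlapping):
        return "correct"
    if any(g.gene_id in own_paralogs for g in overlapping):
        return "paralog"
    if any(
        g.biotype == "protein_coding"
        and g.gene_id not in query_gene_ids
        and g.gene_id not in own_paralogs
        for g in overlapping
    ):
        return "other_gene"
    if any(g.biotype == "pseudogene" for g in overlapping):
        return "pseudogene"
    return "intergenic"


def evaluate(
    report: Sequence[GeneModel],
    annotation: Sequence[AnnotationGene],
    ortholog_presence: Mapping[str, bool],
    paralog_map: Mapping[str, Sequence[str]] | None = None,
    mode: str = "overlap",
) -> EvalReport:
    """Full evaluation: confusion matrix, rates, coverage, categories."""
    paralog_map = paralog_map or {}
    tp, fp, fn, tn = confusion(report, annotation, ortholog_presence, mode=mode)
    sens, spec, ppv, npv = metrics(tp, fp, fn, tn)
    out = EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        category_counts={c: 0 for c in CATEGORIES},
    )
    truth = {g.gene_id: g for g in annotation}
    query_ids = set(ortholog_presence)
    for m in report:
        g = truth.get(m.gene_id)
        if (
            mode == "overlap"
            and g is not None
            and m.contig == g.contig
            and _overlaps(m.span, g.interval)
        ):
            gene_cov, exon_cov = coverage(m, g)
            out.gene_coverage.append(gene_cov)
            out.exon_coverage.append(exon_cov)
        out.category_counts[categorize(m, annotation, query_ids, paralog_map)] += 1
    return out
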