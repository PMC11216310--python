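"""Evaluation: confusion cells, rates, coverage and locus categories."""

import numpy as np
import pytest

from genescout.errors import StageError
from genescout.evaluation import (
    categorize,
    confusion,
    coverage,
    evaluate,
    metrics,
)
from genescout.formats_io import AnnotationGene
from genescout.prediction import GeneModel


def _gene(gene_id, start, end, contig="c", biotype="protein_coding", cds=None):
    return AnnotationGene(
        gene_id=gene_id, contig=contig, strand="+", start=start, end=end,
        cds_intervals=cds if cds is not None else [(start, end)], biotype=biotype,
    )


def _model(gene_id, start, end, contig="c", cds=None, mid=None):
    return GeneModel(
        model_id=mid or f"{gene_id}.m", region_id="R", gene_id=gene_id,
        contig=contig, strand="+",
        cds_intervals=cds if cds is not None else [(start, end)],
        hint_support=100.0,
    )


ANNOTATION = [_gene("A", 100, 400), _gene("B", 1000, 1400)]
PRESENCE = {"A": True, "B": True, "C": False}


class TestConfusion:
    def test_found_missed_and_true_negative(self):
        report = [_model("A", 150, 350)]
        assert confusion(report, ANNOTATION, PRESENCE) == (1, 0, 1, 1)

    def test_wrong_locus_counts_fp_and_fn(self):
        report = [_model("A", 5000, 5300)]
        tp, fp, fn, tn = confusion(report, ANNOTATION, PRESENCE)
        assert (tp, fp) == (0, 1) and fn == 2 and tn == 1

    def test_reported_absent_gene_is_fp(self):
        report = [_model("A", 150, 350), _model("C", 9000, 9300)]
        assert confusion(report, ANNOTATION, PRESENCE) == (1, 1, 1, 0)

    def test_unknown_gene_rejected(self):
        with pytest.raises(StageError):
            confusion([_model("Z", 0, 10)], ANNOTATION, PRESENCE)

    def test_presence_mode_ignores_location(self):
        report = [_model("A", 5000, 5300)]
        tp, fp, fn, tn = confusion(report, ANNOTATION, PRESENCE, mode="presence")
        assert (tp, fp, fn, tn) == (1, 0, 1, 1)

    def test_accounting_closes(self):
        """tp+fn equals the number of present query genes."""
        report = [_model("A", 150, 350), _model("B", 9000, 9300), _model("C", 50, 80)]
        tp, fp, fn, tn = confusion(report, ANNOTATION, PRESENCE)
        present = sum(PRESENCE.values())
        assert tp + fn == present
        assert tn + fp >= len(PRESENCE) - present


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((9, 1, 1, 9), (0.9, 0.9, 0.9, 0.9)),
            ((0, 0, 5, 5), (0.0, 1.0, None, 0.5)),
            ((1, 0, 1, 1), (0.5, 1.0, 1.0, 0.5)),
        ],
    )
    def test_rates_and_undefined(self, counts, expected):
        assert metrics(*counts) == expected


class TestCoverage:
    def test_gene_coverage_half(self):
        gene = _gene("A", 100, 200)
        model = _model("A", 150, 250)
        gene_cov, _ = coverage(model, gene)
        assert gene_cov == pytest.approx(0.5)

    def test_exon_coverage(self):
        gene = _gene("A", 100, 200, cds=[(100, 160), (180, 200)])
        model = _model("A", 100, 160, cds=[(100, 160)])
        _, exon_cov = coverage(model, gene)
        assert exon_cov == pytest.approx(0.75)

    def test_identical_structures(self):
        gene = _gene("A", 100, 400, cds=[(100, 250), (300, 400)])
        model = _model("A", 100, 400, cds=[(100, 250), (300, 400)])
        assert coverage(model, gene) == (1.0, 1.0)

    def test_zero_length_truth_rejected(self):
        with pytest.raises(StageError):
            coverage(_model("A", 0, 10), _gene("A", 100, 100))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_counter(self, seed):
        rng = np.random.default_rng(seed)

        def non_overlapping(k, max_len):
            out, cursor = [], 0
            for _ in range(k):
                s = cursor + int(rng.integers(0, 200))
                e = s + int(rng.integers(10, max_len))
                out.append((s, e))
                cursor = e + 1
            return out

        truth_cds = non_overlapping(4, 50)
        pred_cds = non_overlapping(3, 60)
        gene = _gene("A", truth_cds[0][0], truth_cds[-1][1], cds=truth_cds)
        model = _model("A", pred_cds[0][0], pred_cds[-1][1], cds=pred_cds)
        gene_cov, exon_cov = coverage(model, gene)
        base = np.zeros(2000, dtype=bool)
        for s, e in truth_cds:
            base[s:e] = True
        pred = np.zeros(2000, dtype=bool)
        for s, e in pred_cds:
            pred[s:e] = True
        expected_exon = (base & pred).sum() / base.sum()
        span = np.zeros(2000, dtype=bool)
        span[model.span[0]:model.span[1]] = True
        region = np.zeros(2000, dtype=bool)
        region[gene.start:gene.end] = True
        expected_gene = (span & region).sum() / region.sum()
        assert exon_cov == pytest.approx(expected_exon)
        assert gene_cov == pytest.approx(expected_gene)


class TestCategorize:
    ANNOT = [
        _gene("A", 100, 400),
        _gene("A_par1", 1000, 1400),
        _gene("other", 2000, 2400),
        _gene("ps", 3000, 3400, biotype="pseudogene", cds=[]),
    ]
    PARALOGS = {"A": ["A_par1"]}
    QUERIES = {"A", "B"}

    def _cat(self, start, end):
        return categorize(_model("A", start, end), self.ANNOT, self.QUERIES, self.PARALOGS)

    def test_correct(self):
        assert self._cat(150, 350) == "correct"

    def test_paralog(self):
        assert self._cat(1100, 1300) == "paralog"

    def test_other_gene(self):
        assert self._cat(2100, 2300) == "other_gene"

    def test_pseudogene(self):
        assert self._cat(3100, 3300) == "pseudogene"

    def test_intergenic(self):
        assert self._cat(9000, 9300) == "intergenic"

    def test_precedence_correct_beats_paralog(self):
        # span covering both the true gene and the paralog
        assert self._cat(150, 1300) == "correct"

    def test_lower_precedence_overlap_never_changes_category(self):
        for hi in (400, 1400, 2400, 3400):
            assert self._cat(150, hi) == "correct"


class TestEvaluate:
    def test_full_report_on_micro_example(self):
        report = [_model("A", 150, 350), _model("C", 9000, 9300)]
        presence = {"A": True, "B": True, "C": False}
        out = evaluate(report, ANNOTATION, presence, {"A": []})
        assert (out.tp, out.fp, out.fn, out.tn) == (1, 1, 1, 0)
        assert out.sensitivity == 0.5 and out.ppv == 0.5
        assert out.category_counts["correct"] == 1
        assert out.category_counts["intergenic"] == 1
        assert out.gene_coverage == [pytest.approx(200 / 300)]

    def test_identical_pred_and_truth(self):
        report = [_model("A", 100, 400), _model("B", 1000, 1400)]
        out = evaluate(report, ANNOTATION, {"A": True, "B": True})
        assert out.sensitivity == 1.0
        assert out.category_counts["correct"] == 2
        assert out.gene_coverage == [1.0, 1.0]

    def test_presence_vs_overlap_mode(self):
        report = [_model("A", 5000, 5300)]
        presence = {"A": True}
        overlap = evaluate(report, ANNOTATION, presence)
        pres = evaluate(report, ANNOTATION, presence, mode="presence")
        assert (overlap.tp, overlap.fp, overlap.fn) == (0, 1, 1)
        assert (pres.tp, pres.fp, pres.fn) == (1, 0, 0)
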