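"""End-to-end orchestration of the gene-list search pipeline.

Stage order: query QC -> translated search -> region grouping/extension ->
protein hints -> gene prediction -> validation re-alignment -> feature
assembly -> filter scoring -> selection.  Every stage logs its input and
output counts; with an output directory all intermediates are persisted.
Runs with identical inputs, seeds and builtin backends are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats_io, proteoval, seeding, selection
from .errors import ConfigurationError, StageError
from .filter_model import FilterModel, assemble_features, calibrate_threshold, smote_balance, train_filter
from .formats_io import ProteinQuery
from .prediction import GeneModel, build_hints, predict_genes
from .regions import CandidateRegion, PipelineConfig, group_and_extend, region_similarity_summary, retain_top_queries
from .selection import Candidate
from .synthetic import label_candidates

logger = logging.getLogger("genescout")


@dataclass
class PipelineResult:
    hsps: list = field(default_factory=list)
    regions: list[CandidateRegion] = field(default_factory=list)
    candidates: list[Candidate] = field(default_factory=list)
    report: list[Candidate] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    status: str = "ok"


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        return {k: v.upper() for k, v in formats_io.read_fasta(genome).items()}
    return {k: v.upper() for k, v in genome.items()}


def _load_queries(queries) -> list[ProteinQuery]:
    if isinstance(queries, (str, Path)):
        return formats_io.read_query_fasta(queries)
    return list(queries)


def run_search(
    genome,
    queries,
    config: PipelineConfig | None = None,
    filter_model: FilterModel | None = None,
    no_filter: bool = False,
    backend: str = "builtin",
    search_command: str | None = None,
    hint_command: str | None = None,
    predict_command: str | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full search.

    With ``no_filter`` the raw scored candidates (features, no selection)
    are reported — the mode used to produce filter training data.
    Otherwise ``filter_model`` must be trained and calibrated.
    """
    config = config or PipelineConfig()
    if not no_filter:
        if filter_model is None:
            raise ConfigurationError("a trained filter model is required (or no_filter)")
        if filter_model.calibrated_threshold is None:
            raise ConfigurationError("filter model has no calibrated threshold")
    t0 = time.time()
    genome = _load_genome(genome)
    raw_queries = _load_queries(queries)
    clean = formats_io.qc_queries(raw_queries)
    _log("qc_queries", len(raw_queries), len(clean), t0)

    t0 = time.time()
    hsps = seeding.search_translated(
        clean, genome, backend=backend, min_bits=config.min_bits,
        command_template=search_command,
    )
    _log("search", len(clean), len(hsps), t0)

    result = PipelineResult(hsps=hsps)
    if not hsps:
        result.status = "no seeds"
        result.stage_counts = {"queries": len(clean), "hsps": 0, "regions": 0,
                               "models": 0, "candidates": 0, "reported": 0}
        if out_dir is not None:
            _persist(result, genome, out_dir, config)
        return result

    t0 = time.time()
    contig_lengths = {c: len(s) for c, s in genome.items()}
    regions = group_and_extend(hsps, config, contig_lengths)
    regions = [retain_top_queries(r, config.top_k) for r in regions]
    for r in regions:
        region_similarity_summary(r)
    _log("group_and_extend", len(hsps), len(regions), t0)
    result.regions = regions

    by_gene: dict[str, list[ProteinQuery]] = {}
    for q in clean:
        by_gene.setdefault(q.gene_id, []).append(q)

    t0 = time.time()
    candidates: list[Candidate] = []
    n_models = 0
    for region in regions:
        region_seq = genome[region.contig][region.start : region.end]
        retained_ids = {iso for iso, _ in region.retained_queries}
        region_queries = [
            q for q in by_gene.get(region.gene_id, []) if q.isoform_id in retained_ids
        ] or by_gene.get(region.gene_id, [])
        hints = build_hints(
            region, region_seq, region_queries,
            backend=backend, command_template=hint_command,
        )
        models = predict_genes(
            region, region_seq, hints, backend=backend,
            min_codons=config.min_orf_codons, command_template=predict_command,
        )
        n_models += len(models)
        for model in models:
            isoform_id, stats = proteoval.best_query_for_model(model, region_queries)
            features = assemble_features(
                region.sim_pident,
                region.sim_gene_cov,
                model.hint_support,
                stats.aln_pident,
                stats.aln_psim,
                stats.aln_gene_cov,
            )
            candidates.append(
                Candidate(model=model, features=features, isoform_id=isoform_id)
            )
    candidates.sort(key=lambda c: c.sort_key)
    _log("predict+validate", len(regions), len(candidates), t0)
    result.candidates = candidates

    if filter_model is not None:
        X = np.array([c.features for c in candidates]) if candidates else np.empty((0, 6))
        if len(candidates):
            probs = filter_model.predict_proba(X)
            for c, p in zip(candidates, probs):
                c.probability = float(p)
    if no_filter:
        result.report = list(candidates)
    else:
        t0 = time.time()
        result.report = selection.select(
            candidates, filter_model.calibrated_threshold, config.tie_ratio
        )
        _log("select", len(candidates), len(result.report), t0)
    result.stage_counts = {
        "queries": len(clean),
        "hsps": len(hsps),
        "regions": len(regions),
        "models": n_models,
        "candidates": len(candidates),
        "reported": len(result.report),
    }
    if out_dir is not None:
        _persist(result, genome, out_dir, config)
    return result


def _log(stage: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info("stage=%s in=%d out=%d wall=%.2fs", stage, n_in, n_out, time.time() - t0)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_prediction_gff3(candidates: Sequence[Candidate], path) -> None:
    """Write candidates as GFF3 with model/gene ids, hint support and
    probability attributes (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for c in candidates:
            m = c.model
            prob = "" if c.probability is None else f";probability={c.probability:.6f}"
            s, e = m.span
            out.write(
                f"{m.contig}\tgenescout\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.model_id};gene_id={m.gene_id};"
                f"hint_support={m.hint_support:.2f}{prob}\n"
            )
            out.write(
                f"{m.contig}\tgenescout\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.model_id}.t;Parent={m.model_id}\n"
            )
            for cs, ce in m.cds_intervals:
                out.write(
                    f"{m.contig}\tgenescout\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t"
                    f"0\tID={m.model_id}.cds;Parent={m.model_id}.t\n"
                )


def parse_prediction_gff3(path) -> list[GeneModel]:
    """Read back the prediction GFF3 dialect written by this package."""
    models: dict[str, GeneModel] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        if f[2] == "gene":
            mid = attrs["ID"]
            models[mid] = GeneModel(
                model_id=mid,
                region_id="",
                gene_id=attrs.get("gene_id", mid),
                contig=f[0],
                strand=f[6],
                cds_intervals=[],
                hint_support=float(attrs.get("hint_support", "0")),
            )
        elif f[2] == "CDS":
            mid = attrs.get("Parent", "").removesuffix(".t")
            if mid in models:
                models[mid].cds_intervals.append((int(f[3]) - 1, int(f[4])))
    for m in models.values():
        m.cds_intervals.sort()
    return sorted(models.values(), key=lambda m: (m.contig, m.span))


def _write_candidate_tsv(candidates: Sequence[Candidate], path) -> None:
    from .filter_model import FEATURE_NAMES

    with open(path, "w") as out:
        cols = ["model_id", "gene_id", "contig", "start", "end", "strand",
                "isoform_id", *FEATURE_NAMES, "probability", "label"]
        out.write("\t".join(cols) + "\n")
        for c in candidates:
            m = c.model
            feats = "\t".join(f"{v:.6g}" for v in c.features)
            prob = "" if c.probability is None else f"{c.probability:.6f}"
            label = "" if c.label is None else str(c.label)
            out.write(
                f"{m.model_id}\t{m.gene_id}\t{m.contig}\t{m.span[0]}\t{m.span[1]}\t"
                f"{m.strand}\t{c.isoform_id}\t{feats}\t{prob}\t{label}\n"
            )


def _write_summary_tsv(result: PipelineResult, path) -> None:
    found: dict[str, Candidate] = {}
    for c in result.report:
        cur = found.get(c.gene_id)
        if cur is None or (c.probability or 0) > (cur.probability or 0):
            found[c.gene_id] = c
    gene_ids = sorted({h.gene_id for h in result.hsps} | set(found))
    with open(path, "w") as out:
        out.write("gene_id\tfound\tlocus\tprobability\n")
        for gid in gene_ids:
            c = found.get(gid)
            if c is None:
                out.write(f"{gid}\t0\t.\t.\n")
            else:
                m = c.model
                prob = "." if c.probability is None else f"{c.probability:.6f}"
                out.write(
                    f"{gid}\t1\t{m.contig}:{m.span[0]}-{m.span[1]}({m.strand})\t{prob}\n"
                )


def _persist(result: PipelineResult, genome, out_dir, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "hsps.tsv", "w") as fh:
        fh.write("gene_id\tisoform_id\tcontig\tstrand\tstart\tend\tpident\t"
                 "aln_len\tquery_cov\tbits\n")
        for h in result.hsps:
            fh.write(
                f"{h.gene_id}\t{h.isoform_id}\t{h.contig}\t{h.strand}\t{h.start}\t"
                f"{h.end}\t{h.pident:.2f}\t{h.aln_len}\t{h.query_cov:.4f}\t"
                f"{h.bits:.2f}\n"
            )
    formats_io.write_regions_bed(result.regions, out / "regions.bed")
    write_prediction_gff3(result.candidates, out / "candidates.gff3")
    _write_candidate_tsv(result.candidates, out / "candidates.tsv")
    write_prediction_gff3(result.report, out / "report.gff3")
    formats_io.write_fasta(
        {c.model.model_id: c.model.protein for c in result.report},
        out / "proteins.faa",
    )
    _write_summary_tsv(result, out / "summary.tsv")
    manifest = {
        "status": result.status,
        "stage_counts": result.stage_counts,
        "config": {
            "merge_gap": config.merge_gap,
            "margin": config.margin,
            "top_k": config.top_k,
            "tie_ratio": config.tie_ratio,
            "min_bits": config.min_bits,
            "min_orf_codons": config.min_orf_codons,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Filter training
# ---------------------------------------------------------------------------

def train_filter_from_candidates(
    candidates: Sequence[Candidate],
    truth,
    config: PipelineConfig | None = None,
) -> FilterModel:
    """Label candidates against truth loci, balance, train and calibrate.

    Calibration uses the pre-balancing candidate set, so the sensitivity
    floor refers to real (not oversampled) positives.
    """
    config = config or PipelineConfig()
    label_candidates(candidates, truth)
    X = np.array([c.features for c in candidates])
    y = np.array([c.label for c in candidates])
    if len(np.unique(y)) < 2:
        raise StageError("training requires both positive and negative candidates")
    Xb, yb = smote_balance(X, y, seed=config.nn.seed)
    model = train_filter(Xb, yb, config.nn)
    calibrate_threshold(model, X, y, config.calibration_sensitivity)
    model.metadata["n_candidates"] = int(len(y))
    model.metadata["n_positive"] = int(y.sum())
    return model
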