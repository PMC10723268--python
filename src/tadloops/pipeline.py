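"""End-to-end orchestration of the loop and boundary analyses.

Two composed analyses are provided: the loop analysis (derive p300-only
peaks, annotate loop anchors, census interaction categories, compute the
p300-only/H3K27me3 mark fraction, compare expression of looped genes, APA)
and the boundary analysis (boundary windows, per-boundary gene features,
category census, head-to-tail detection, oncogene scan, PT/PG/PP expression
comparison).  Both run on in-memory objects; :func:`run_pipeline` is the
file-based wrapper used by the CLI.  Stage failures raise
:class:`StageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import anchor_interactions as ai
from . import expression_stats as es
from . import headtail as ht
from . import hic_ops
from . import peak_classes as pc
from .intervals_io import (
    ChromSizes,
    ExpressionTable,
    GeneModel,
    LoopSet,
    PeakSet,
    TadSet,
    read_chrom_sizes,
    read_expression,
    read_genes,
    read_intervals,
    read_pairs,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and parameters; parameter defaults are the analysis
    windows used throughout (promoter TSS +/-1 kb, terminator TES +/-5 kb,
    boundary +/-5 kb, H3K27ac extension +/-1 kb, APA at 25 kb bins with
    window 6)."""

    genes: str | None = None
    p300: str | None = None
    h3k27ac: str | None = None
    h3k27me3: str | None = None
    loops: str | None = None
    tads: str | None = None
    expression: str | None = None
    matrix: str | None = None
    matrix_chrom: str | None = None
    chrom_sizes: str | None = None
    oncogenes: str | None = None
    promoter_flank: int = 1000
    terminator_flank: int = 5000
    boundary_flank: int = 5000
    h3k27ac_extend: int = 1000
    apa_resolution: int = 25000
    apa_window: int = 6
    merge_slack: int = 25000
    outdir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class LoopAnalysisReport:
    n_p300: int
    n_p300_only: int
    n_loops: int
    census: dict[str, int]
    mark_fraction: float
    mark_fraction_pct: str
    qualifying_loop_ids: list[str]
    expression_report: es.TestReport | None
    apa_result: hic_ops.ApaResult | None


@dataclass
class BoundaryAnalysisReport:
    n_tads: int
    census: dict[str, int]
    mark_fraction: float
    mark_fraction_pct: str
    category_counts: dict[str, int]
    headtail_pairs: list[ht.HeadTailPair]
    oncogene_hits: list[ht.HeadTailPair]
    oncogene_fraction: float | None
    expression_report: es.TestReport | None


def fig5_loop_analysis(
    loops: LoopSet,
    genes: list[GeneModel],
    p300: PeakSet,
    h3k27ac: PeakSet,
    h3k27me3: PeakSet,
    sizes: ChromSizes,
    expression: ExpressionTable | None = None,
    matrices: dict[str, hic_ops.ContactMatrix] | None = None,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
    h3k27ac_extend: int = 1000,
    apa_window: int = 6,
) -> LoopAnalysisReport:
    """Loop analysis: p300-only peaks, anchor annotation, category census,
    mark fraction, looped-gene expression comparison, APA."""
    try:
        p300_only = pc.derive_p300_only(p300, h3k27ac, sizes, h3k27ac_extend)
    except Exception as e:  # noqa: BLE001
        raise StageError("p300only", e) from e

    try:
        intra = loops.intra_chromosomal()
        annotations = []
        names = []
        for lp in intra:
            a1 = ai.annotate_anchor(
                lp.anchor1, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
            )
            a2 = ai.annotate_anchor(
                lp.anchor2, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
            )
            annotations.append((a1, a2))
            names.append(lp.name or f"loop_{len(names)}")
        census = ai.interaction_census(annotations)
        frac, pct = ai.mark_fraction(annotations)
        qualifying = [
            n for n, (a1, a2) in zip(names, annotations)
            if ai.pair_has_p300_h3k27me3(a1, a2)
        ]
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("classify-loops", e) from e

    expr_report = None
    if expression is not None:
        try:
            grouped = es.group_by_h3k27me3(
                annotations, genes, h3k27me3, expression, promoter_flank
            )
            expr_report = es.compare_groups(grouped, "h3k27me3_vs_not")
        except Exception as e:  # noqa: BLE001
            raise StageError("expr-compare", e) from e

    apa_result = None
    if matrices:
        try:
            # aggregate each chromosome's loops over its normalized matrix,
            # then combine window sums weighted by loops used
            import numpy as np

            agg = None
            used = skipped = 0
            skips: dict[str, int] = {}
            for chrom, cm in sorted(matrices.items()):
                norm = hic_ops.vc_sqrt_normalize(cm) if cm.normalized is None else cm
                try:
                    r = hic_ops.apa(norm, intra, window=apa_window)
                except Exception:
                    continue
                agg = r.aggregate * r.n_loops_used + (0 if agg is None else agg)
                used += r.n_loops_used
                for k, v in r.skip_reasons.items():
                    skips[k] = skips.get(k, 0) + v
            if agg is None or used == 0:
                raise ValueError("no loops usable for APA on any matrix")
            agg = agg / used
            skipped = sum(skips.values())
            w = apa_window
            size = 2 * w + 1
            corner = agg[size - 3 : size, 0:3].mean()
            score = float(agg[w, w] / corner) if corner > 0 else float("inf")
            apa_result = hic_ops.ApaResult(agg, used, skipped, skips, score)
        except Exception as e:  # noqa: BLE001
            raise StageError("apa", e) from e

    return LoopAnalysisReport(
        n_p300=len(p300),
        n_p300_only=len(p300_only),
        n_loops=len(intra),
        census=census,
        mark_fraction=frac,
        mark_fraction_pct=pct,
        qualifying_loop_ids=qualifying,
        expression_report=expr_report,
        apa_result=apa_result,
    )


def fig6_boundary_analysis(
    tads: TadSet,
    genes: list[GeneModel],
    p300_only: PeakSet,
    h3k27me3: PeakSet,
    sizes: ChromSizes,
    expression: ExpressionTable | None = None,
    oncogenes: set[str] | None = None,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
    boundary_flank: int = 5000,
) -> BoundaryAnalysisReport:
    """Boundary analysis: window annotation, interaction census, boundary
    gene-pair categories, head-to-tail detection, oncogene scan, per-category
    expression comparison."""
    try:
        boundary_pairs = ai.annotate_boundaries(
            tads, sizes, genes, p300_only, h3k27me3,
            boundary_flank, promoter_flank, terminator_flank,
        )
        pairs = [(bp.left_annotation, bp.right_annotation) for bp in boundary_pairs]
        census = ai.interaction_census(pairs)
        frac, pct = ai.mark_fraction(pairs)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify-boundaries", e) from e

    try:
        features = ht.boundary_gene_pairs(
            tads, genes, sizes, promoter_flank, terminator_flank, boundary_flank
        )
        cat_counts: dict[str, int] = {}
        for bf in features:
            if bf.pair_category:
                cat_counts[bf.pair_category] = cat_counts.get(bf.pair_category, 0) + 1
        detected = ht.detect_head_to_tail(
            tads, genes, sizes, promoter_flank, terminator_flank, boundary_flank
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("headtail", e) from e

    onco_hits: list[ht.HeadTailPair] = []
    onco_frac = None
    if oncogenes:
        try:
            onco_hits, onco_frac = ht.oncogene_scan(detected, oncogenes)
        except Exception as e:  # noqa: BLE001
            raise StageError("oncogene-scan", e) from e

    expr_report = None
    if expression is not None:
        try:
            present = tuple(
                c for c in ("PP", "PT", "PG", "TT", "TG", "GG") if cat_counts.get(c)
            )
            if len(present) >= 2:
                grouped = es.group_by_boundary_category(features, expression, present)
                nonempty = {k: v for k, v in grouped.values.items() if v}
                if len(nonempty) >= 2:
                    grouped = es.GroupedExpression(
                        nonempty, {k: grouped.gene_ids[k] for k in nonempty}
                    )
                    expr_report = es.compare_groups(grouped, "boundary_pair_category")
        except Exception as e:  # noqa: BLE001
            raise StageError("expr-compare", e) from e

    return BoundaryAnalysisReport(
        n_tads=len(tads),
        census=census,
        mark_fraction=frac,
        mark_fraction_pct=pct,
        category_counts=cat_counts,
        headtail_pairs=detected,
        oncogene_hits=onco_hits,
        oncogene_fraction=onco_frac,
        expression_report=expr_report,
    )


def _require(config: PipelineConfig, stage: str, *names: str) -> None:
    for n in names:
        if getattr(config, n) is None:
            raise StageError(stage, FileNotFoundError(f"config.{n} is required"))


def run_pipeline(config: PipelineConfig, analysis: str) -> dict:
    """File-based end-to-end run; writes TSV/JSON reports plus a resolved
    config snapshot into ``config.outdir`` and returns the report dict."""
    if analysis not in ("fig5_loops", "fig6_boundaries"):
        raise ValueError(f"unknown analysis {analysis!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir / "resolved_config.yaml")

    _require(config, "load", "genes", "h3k27me3", "chrom_sizes")
    genes = read_genes(config.genes)
    sizes = read_chrom_sizes(config.chrom_sizes)
    h3k27me3 = read_intervals(config.h3k27me3, _sniff(config.h3k27me3), "H3K27me3")
    expression = (
        read_expression(config.expression) if config.expression else None
    )

    if analysis == "fig5_loops":
        _require(config, "load", "p300", "h3k27ac", "loops")
        p300 = read_intervals(config.p300, _sniff(config.p300), "p300")
        h3k27ac = read_intervals(config.h3k27ac, _sniff(config.h3k27ac), "H3K27ac")
        loops = read_pairs(config.loops)
        matrices = None
        if config.matrix:
            chrom = config.matrix_chrom
            if chrom is None:
                raise StageError("load", ValueError("matrix_chrom is required"))
            n_bins = sizes[chrom] // config.apa_resolution
            matrices = {
                chrom: hic_ops.load_matrix(
                    config.matrix, config.apa_resolution, chrom, n_bins
                )
            }
        report = fig5_loop_analysis(
            loops, genes, p300, h3k27ac, h3k27me3, sizes, expression, matrices,
            config.promoter_flank, config.terminator_flank,
            config.h3k27ac_extend, config.apa_window,
        )
        out = {
            "analysis": analysis,
            "n_p300": report.n_p300,
            "n_p300_only": report.n_p300_only,
            "n_loops": report.n_loops,
            "census": report.census,
            "mark_fraction": report.mark_fraction,
            "mark_fraction_pct": report.mark_fraction_pct,
            "qualifying_loop_ids": report.qualifying_loop_ids,
        }
        if report.expression_report:
            out["expression"] = dataclasses.asdict(report.expression_report)
        if report.apa_result:
            out["apa_score"] = report.apa_result.score
            out["apa_loops_used"] = report.apa_result.n_loops_used
    else:
        _require(config, "load", "tads")
        with open(config.tads) as fh:
            from .intervals_io import GenomicInterval

            doms = []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) >= 3 and not line.startswith(("#", "track")):
                    doms.append(
                        GenomicInterval(f[0], int(f[1]), int(f[2]),
                                        name=f[3] if len(f) > 3 else None)
                    )
            tads = TadSet(doms)
        if config.p300 and config.h3k27ac:
            p300 = read_intervals(config.p300, _sniff(config.p300), "p300")
            h3k27ac = read_intervals(config.h3k27ac, _sniff(config.h3k27ac), "H3K27ac")
            p300_only = pc.derive_p300_only(p300, h3k27ac, sizes, config.h3k27ac_extend)
        else:
            p300_only = PeakSet([], mark="p300_only")
        oncogenes = None
        if config.oncogenes:
            oncogenes = {
                l.strip() for l in Path(config.oncogenes).read_text().splitlines()
                if l.strip()
            }
        report = fig6_boundary_analysis(
            tads, genes, p300_only, h3k27me3, sizes, expression, oncogenes,
            config.promoter_flank, config.terminator_flank, config.boundary_flank,
        )
        out = {
            "analysis": analysis,
            "n_tads": report.n_tads,
            "census": report.census,
            "mark_fraction": report.mark_fraction,
            "mark_fraction_pct": report.mark_fraction_pct,
            "category_counts": report.category_counts,
            "n_headtail": len(report.headtail_pairs),
            "headtail_pairs": [
                {
                    "tad": p.tad.name or f"{p.tad.chrom}:{p.tad.start}-{p.tad.end}",
                    "upstream": p.upstream_gene.gene_id,
                    "downstream": p.downstream_gene.gene_id,
                    "category": p.pair_category,
                }
                for p in report.headtail_pairs
            ],
        }
        if report.oncogene_fraction is not None:
            out["oncogene_fraction"] = report.oncogene_fraction
            out["oncogene_hits"] = [
                p.upstream_gene.gene_id for p in report.oncogene_hits
            ]
        if report.expression_report:
            out["expression"] = dataclasses.asdict(report.expression_report)

    (outdir / f"{analysis}_report.json").write_text(
        json.dumps(out, indent=1, sort_keys=True)
    )
    logger.info("%s: wrote report to %s", analysis, outdir)
    return out


def _sniff(path: str) -> str:
    """Guess a BED dialect from the filename."""
    p = str(path)
    if p.endswith((".narrowPeak", ".narrowPeak.gz")):
        return "narrowPeak"
    return "bed6" if _has_six_cols(p) else "bed3"


def _has_six_cols(path: str) -> bool:
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                return len(line.rstrip("\n").split("\t")) >= 6
    return False
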