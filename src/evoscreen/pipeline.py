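"""Workflow orchestration: screen -> candidates -> MK / site models /
running dN/dS / variant tolerance -> combined ranked report.

The report is deterministic: re-running with identical config and inputs
yields byte-identical report files (run metadata with the config echo and
seed goes to a separate metadata file; timestamps only ever appear in the
log, never in report files).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import codonseq, expression_screen, mk, sitewise, variant_effects
from .codon_models import PhyloTree, fit_nested_pair, neb_site_classes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the screen/test conventions used throughout the
    package: raw-p gate 0.001 with |z| >= 5.5 for the expression triage,
    alpha 0.05 for MK and LRT, SIFT damaging cutoff 0.05, 35% minimum
    column coverage, residue half-window 10 with pseudocount 0.5 for the
    running dN/dS.
    """

    expression_dir: Optional[str] = None
    alignment_dir: Optional[str] = None
    tree_path: Optional[str] = None
    variants_path: Optional[str] = None
    regions_path: Optional[str] = None
    mk_table_path: Optional[str] = None  # precomputed Pn/Ps/Dn/Ds per gene
    reference_taxon: str = "human"
    comparison_taxon: str = "mouse"
    p_cutoff: float = 1e-3
    z_cutoff: float = 5.5
    alpha: float = 0.05
    sift_cutoff: float = 0.05
    window: int = 10
    pseudocount: float = 0.5
    K: int = 10
    min_coverage: float = 0.35
    model_pair: tuple = ("M1a", "M2a")
    fit_site_models: bool = True
    neb_threshold: float = 0.95
    seed: int = 0
    out_dir: str = "evoscreen_out"

    def __post_init__(self):
        if not (0 < self.p_cutoff <= 1) or self.z_cutoff < 0:
            raise ValueError("screen thresholds out of range")
        if not (0 < self.alpha < 1) or not (0 < self.min_coverage <= 1):
            raise ValueError("alpha/min_coverage out of range")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "model_pair" in data:
            data["model_pair"] = tuple(data["model_pair"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class GeneReport:
    gene: str
    n_datasets_significant: int = 0
    best_p_adj: float = math.nan
    mk_p: float = math.nan
    mk_significant: bool = False
    neutrality_index: float = math.nan
    lrt_statistic: float = math.nan
    lrt_significant: bool = False
    n_positive_sites: int = 0
    fraction_damaging: float = math.nan
    n_conserved_regions: int = 0
    error: str = ""


@dataclass
class CandidateReport:
    ranked_genes: List[GeneReport] = field(default_factory=list)
    overlap: dict = field(default_factory=dict)
    failed_genes: List[str] = field(default_factory=list)
    n_candidates: int = 0


def _rank_key(r: GeneReport):
    # documented lexicographic artifact convention: MK significance first,
    # then LRT significance, then damaging-variant fraction, then name
    frac = r.fraction_damaging if math.isfinite(r.fraction_damaging) else -1.0
    return (not r.mk_significant, not r.lrt_significant, -frac, r.gene)


def run_pipeline(config: RunConfig) -> CandidateReport:
    """Run all stages in dependency order; per-gene failures are isolated."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = CandidateReport()
    gene_reports: dict = {}

    # --- expression screen ------------------------------------------------
    screens = []
    if config.expression_dir:
        for path in sorted(Path(config.expression_dir).glob("*.tsv")):
            screen = expression_screen.load_screen_table(path, dataset_id=path.stem)
            expression_screen.select_candidates(
                screen, p_cutoff=config.p_cutoff, z_cutoff=config.z_cutoff
            )
            screens.append(screen)
        report.overlap = expression_screen.cross_dataset_overlap(screens)
        for screen in screens:
            sig = screen.records[
                screen.records["probe_id"].isin(set(screen.significant_ids))
            ]
            for row in sig.itertuples(index=False):
                g = str(row.gene_symbol).upper()
                gr = gene_reports.setdefault(g, GeneReport(gene=g))
                gr.n_datasets_significant += 1
                if not (gr.best_p_adj <= row.p_adj):  # NaN-safe min
                    gr.best_p_adj = float(row.p_adj)

    # --- evolutionary stages per gene ------------------------------------
    tree = PhyloTree.from_file(config.tree_path) if config.tree_path else None
    regions_by_gene: dict = {}
    if config.regions_path:
        df = pd.read_csv(config.regions_path, sep="\t")
        for row in df.itertuples(index=False):
            regions_by_gene.setdefault(str(row.gene).upper(), []).append(
                sitewise.PeptideRegion(name=str(row.name), start=int(row.start), end=int(row.end))
            )
    variants_by_gene: dict = {}
    if config.variants_path:
        for v in variant_effects.read_variant_table(config.variants_path):
            variants_by_gene.setdefault(v.gene.upper(), []).append(v)
    mk_tables = (
        {g.upper(): t for g, t in mk.read_mk_tables(config.mk_table_path).items()}
        if config.mk_table_path
        else {}
    )

    aln_paths = {}
    if config.alignment_dir:
        for p in sorted(Path(config.alignment_dir).glob("*.fasta")):
            aln_paths[p.stem.upper()] = p
    for g in aln_paths:
        gene_reports.setdefault(g, GeneReport(gene=g))

    for gene, gr in sorted(gene_reports.items()):
        try:
            _analyze_gene(
                gene, gr, config, tree,
                aln_paths.get(gene),
                variants_by_gene.get(gene, []),
                regions_by_gene.get(gene, []),
                mk_tables.get(gene),
                out,
            )
        except Exception as exc:  # isolate the failing gene
            logger.exception("gene %s failed", gene)
            gr.error = f"{type(exc).__name__}: {exc}"
            report.failed_genes.append(gene)

    report.ranked_genes = sorted(gene_reports.values(), key=_rank_key)
    report.n_candidates = len(report.ranked_genes)
    _write_report(report, config, out)
    return report


def _analyze_gene(gene, gr, config, tree, aln_path, variants, regions, mk_table, out):
    aln = None
    ref_row = other_row = None
    if aln_path is not None:
        aln = codonseq.CodonAlignment.read_fasta(aln_path)
        aln = codonseq.filter_columns_by_coverage(aln, config.min_coverage)
        if config.reference_taxon in aln.taxa and config.comparison_taxon in aln.taxa:
            ref_row = aln.row(config.reference_taxon)
            other_row = aln.row(config.comparison_taxon)

    # variants: annotate effects against the reference CDS where available
    if variants and ref_row is not None:
        cds = "".join(c for c in ref_row if c != codonseq.GAP_CODON)
        for v in variants:
            if v.effect is None and v.cds_position <= len(cds):
                try:
                    variant_effects.annotate_variant(v, cds)
                except ValueError as exc:
                    logger.warning("gene %s variant %s: %s", gene, v.variant_id, exc)
    scored = [v for v in variants if v.sift_score is not None and v.polyphen_call is not None]
    if scored:
        summary = variant_effects.summarize_tolerance(gene, scored)
        denom = (
            summary.n_tolerated_consensus
            + summary.n_damaging_consensus
            + summary.n_discordant
        )
        if denom:
            gr.fraction_damaging = summary.n_damaging_consensus / denom

    # MK test: precomputed table wins; otherwise derive from variants + alignment
    mk_result = None
    if mk_table is not None:
        mk_result = mk.mk_test(
            (mk_table.pn, mk_table.ps), (mk_table.dn, mk_table.ds), alpha=config.alpha
        )
    elif ref_row is not None and variants:
        pn, ps = variant_effects.mk_polymorphism_counts(
            [v for v in variants if v.effect is not None]
        )
        divergence = codonseq.pairwise_counts(ref_row, other_row)
        mk_result = mk.mk_test((pn, ps), divergence, alpha=config.alpha)
    if mk_result is not None:
        gr.mk_p = mk_result.fet.p_two_sided
        gr.mk_significant = mk_result.significant
        if mk_result.neutrality_index is not None:
            gr.neutrality_index = mk_result.neutrality_index

    # site models on the full alignment
    if aln is not None and tree is not None and config.fit_site_models:
        null_id, alt_id = config.model_pair
        _null, alt, lr = fit_nested_pair(
            aln, tree, null_id, alt_id, K=config.K, alpha=config.alpha
        )
        gr.lrt_statistic = lr.statistic
        gr.lrt_significant = lr.significant
        neb = neb_site_classes(alt, positive_threshold=config.neb_threshold)
        gr.n_positive_sites = len(neb.positive_sites)

    # running dN/dS with region summary and variant overlay
    if ref_row is not None:
        per_codon = codonseq.per_codon_counts(ref_row, other_row)
        track = sitewise.running_dnds(
            per_codon, window=config.window, pseudocount=config.pseudocount
        )
        global_omega = codonseq.pairwise_counts(ref_row, other_row).omega
        summaries = sitewise.summarize_regions(track, regions, global_omega)
        gr.n_conserved_regions = sum(1 for s in summaries if s.conserved)
        overlay = sitewise.overlay_variants(
            track, regions, [v for v in variants if v.residue_position]
        )
        sitewise.track_frame(track).to_csv(
            out / f"{gene}_dnds_track.tsv", sep="\t", index=False
        )
        sitewise.overlay_frame(overlay).to_csv(
            out / f"{gene}_variant_overlay.tsv", sep="\t", index=False
        )


def _write_report(report: CandidateReport, config: RunConfig, out: Path) -> None:
    rows = []
    for rank, gr in enumerate(report.ranked_genes, 1):
        row = {"rank": rank, **asdict(gr)}
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
    payload = {
        "candidates": rows,
        "overlap": {
            g: [list(e) for e in ev] for g, ev in sorted(report.overlap.items())
        },
        "failed_genes": sorted(report.failed_genes),
        "no_candidates": len(rows) == 0,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    meta = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
    )
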