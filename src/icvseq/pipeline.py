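"""End-to-end orchestration: merge -> annotate -> clonotype -> ICV -> tree.

Every stage writes its artifact (merged FASTQ, AIRR TSV, clonotype/variant
TSVs, ICV JSON, Newick tree) into the run directory so stages can be re-run
independently, and a deterministic summary JSON records read counts through
each stage (the conservation invariant: input = merged + rejected;
merged = kept + length-filtered; kept = clonotyped + excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import clonotype as ct
from . import icv as icv_mod
from . import merge as mg
from . import phylo
from .germline import GermlineAllele, default_alleles, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sample_id: str
    repA_r1: str
    repA_r2: str
    repB_r1: str
    repB_r2: str
    germline_ref: str | None = None
    min_overlap: int = mg.DEFAULT_MIN_OVERLAP
    max_mismatch_density: float = mg.DEFAULT_MAX_MISMATCH_DENSITY
    min_length: int = mg.DEFAULT_MIN_LENGTH
    min_freq_each_replicate: float = ct.DEFAULT_MIN_FREQ_EACH_REPLICATE
    min_count_each_replicate: int = ct.DEFAULT_MIN_COUNT_EACH_REPLICATE
    dominant_threshold: float = ct.DEFAULT_DOMINANT_THRESHOLD
    top_n: int = 10
    total_tumor_cells: float | None = None

    def validate(self) -> None:
        for name in ("repA_r1", "repA_r2", "repB_r1", "repB_r2"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"replicate input {name} missing: {path}")
        if self.germline_ref is not None and not Path(self.germline_ref).exists():
            raise FileNotFoundError(f"germline reference missing: {self.germline_ref}")
        if not 0 <= self.max_mismatch_density <= 1:
            raise ValueError("max_mismatch_density outside [0,1]")
        if self.dominant_threshold < 0 or self.min_freq_each_replicate < 0:
            raise ValueError("thresholds must be non-negative")

    def load_alleles(self) -> list[GermlineAllele]:
        if self.germline_ref is None:
            return default_alleles()
        return read_fasta(self.germline_ref)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: dict
    dominant: ct.Clonotype | None = None
    variant_table: ct.VariantTable | None = None
    tree: phylo.LineageTree | None = None
    clonotypes: list[ct.Clonotype] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alleles = config.load_alleles()
    summary: dict = {"sample_id": config.sample_id, "stages": {}}

    # stage 1: merge + length filter, per replicate
    annotated: list[ann.AnnotatedRead] = []
    merge_counts = {}
    for rep, r1, r2 in (
        ("A", config.repA_r1, config.repA_r2),
        ("B", config.repB_r1, config.repB_r2),
    ):
        kept, qc = mg.merge_fastq(
            r1,
            r2,
            min_overlap=config.min_overlap,
            max_mismatch_density=config.max_mismatch_density,
            min_length=config.min_length,
        )
        mg.write_merged_fastq(kept, outdir / f"rep{rep}_merged.fastq")
        qc.to_tsv(outdir / f"rep{rep}_merge_qc.tsv")
        merge_counts[rep] = {
            "input_pairs": qc.n_input,
            "merged": qc.n_merged,
            "merge_rejected": qc.n_merge_rejected,
            "kept": qc.n_kept,
            "length_filtered": qc.n_length_filtered,
        }
        logger.info(
            "replicate %s: %d pairs -> %d merged -> %d kept",
            rep,
            qc.n_input,
            qc.n_merged,
            qc.n_kept,
        )
        # stage 2: germline annotation
        annotated.extend(ann.annotate_reads(kept, alleles, replicate=rep))
    summary["stages"]["merge"] = merge_counts
    ann.write_airr_tsv(annotated, outdir / "rearrangements.tsv")

    # stage 3: clonotyping by exact CDR3
    clonotypes, n_excluded = ct.group_by_cdr3(annotated)
    n_clonotyped = sum(c.count_total for c in clonotypes)
    summary["stages"]["annotate"] = {
        "annotated": len(annotated),
        "clonotyped": n_clonotyped,
        "excluded_no_assignment_or_cdr3": n_excluded,
    }

    if not clonotypes:
        summary["dominant"] = None
        summary["stages"]["clonotype"] = {"clonotypes": 0, "retained": 0}
        _write_summary(summary, outdir)
        logger.warning("no clonotypes after filtering: empty-result report")
        return PipelineResult(summary=summary)

    # stage 4: replicate concordance
    retained = ct.concordance_filter(
        clonotypes,
        min_freq_each_replicate=config.min_freq_each_replicate,
        min_count_each_replicate=config.min_count_each_replicate,
    )
    ct.write_clonotype_tsv(retained, outdir / "clonotypes.tsv")
    summary["stages"]["clonotype"] = {
        "clonotypes": len(clonotypes),
        "retained": len(retained),
        "retained_reads": sum(c.count_total for c in retained),
    }
    usage = ct.germline_usage_summary(retained)
    usage.to_csv(outdir / "germline_usage.tsv", sep="\t", index=False)
    summary["germline_usage"] = usage.to_dict(orient="records")

    # stage 5: dominant clone
    dominant = ct.detect_dominant(retained, threshold_pct=config.dominant_threshold)
    result = PipelineResult(summary=summary, clonotypes=retained, dominant=dominant)
    if dominant is None:
        summary["dominant"] = None
        summary["top_expansions"] = [
            {"cdr3": c.cdr3_nt, "freq_pct": round(c.freq_pct, 2)}
            for c in retained[:5]
        ]
        _write_summary(summary, outdir)
        logger.info("no dominant clonotype (threshold %.1f%%)", config.dominant_threshold)
        return result

    # stage 6: variants + ICV within the dominant clonotype
    total_a = sum(c.count_repA for c in retained)
    total_b = sum(c.count_repB for c in retained)
    raw_table = ct.enumerate_variants(dominant)
    table = ct.concordance_filter_variants(
        raw_table,
        total_a,
        total_b,
        min_freq_each_replicate=config.min_freq_each_replicate,
        min_count_each_replicate=config.min_count_each_replicate,
    )
    result.variant_table = table
    table.to_dataframe().to_csv(outdir / "variants.tsv", sep="\t", index=False)
    summary["dominant"] = {
        "cdr3": dominant.cdr3_nt,
        "v_call": dominant.v_call,
        "freq_pct": round(dominant.freq_pct, 2),
        "count_total": dominant.count_total,
        "n_variants_raw": len(raw_table.variants),
        "n_variants_retained": len(table.variants),
    }
    if table.variants:
        allele = next(a for a in alleles if a.name == dominant.v_call)
        report = icv_mod.build_icv_report(
            table,
            allele,
            table.start,
            top_n=config.top_n,
            total_tumor_cells=config.total_tumor_cells,
        )
        report.to_json(outdir / "icv_report.json")
        (outdir / "variant_alignment.txt").write_text(
            icv_mod.render_variant_alignment(table, allele, table.start, config.top_n)
            + "\n"
        )
        summary["icv"] = {
            "icv_fraction_pct": report.icv_fraction_pct,
            "dominant_variant_count": report.dominant_variant_count,
            "clonotype_total": report.clonotype_total,
            "n_variants": report.n_variants,
        }
        if report.burden_cells is not None:
            summary["icv"]["burden_cells"] = icv_mod.format_burden(report.burden_cells)

        # stage 7: NJ lineage tree over the top variants
        top = table.top_n(config.top_n)
        if len(top.variants) >= 3:
            labels = [f"v{v.rank}_{v.count_total}" for v in top.variants]
            alignment = phylo.align_variants(
                labels,
                [v.variant_seq for v in top.variants],
                [table.start] * len(top.variants),
                [dominant.v_call] * len(top.variants),
            )
            dm = phylo.pairwise_distances(alignment)
            tree = phylo.nj_tree(dm)
            (outdir / "lineage_tree.nwk").write_text(tree.to_newick() + "\n")
            result.tree = tree
            summary["tree"] = {"n_leaves": len(labels)}

    _write_summary(summary, outdir)
    return result


def _write_summary(summary: dict, outdir: Path) -> None:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


def config_defaults() -> dict:
    """Default parameter values, for --help and config templates."""
    return {
        f.name: f.default
        for f in dataclasses.fields(PipelineConfig)
        if f.default is not dataclasses.MISSING
    }
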