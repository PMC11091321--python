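"""End-to-end co-occupancy pipeline: annotation → merge → distances →
co-localization test → promoter/distal splits → histone stratification →
enhancer join → DEG joins, driven by a single config.

Outputs are deterministic given fixed inputs and config: per-stage TSV
tables, a ``summary.json`` with every headline count and fraction (keys
sorted, no timestamps), and a ``pipeline.log`` echoing every resolved
parameter.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .core import (
    Peak,
    PeakSet,
    merge_cobound,
    nearest_distance,
    read_bed,
    read_chrom_sizes,
)
from .annotation import (
    assign_feature,
    feature_distribution,
    genes_near_peaks,
    peaks_in_promoters,
    read_gene_models,
)
from .stats import colocalization_test, overlap_fraction
from .integrate import deg_join, enhancer_join, read_de_table, read_enhancers, stratify_by_mark

__all__ = ["PipelineConfig", "PipelineInputError", "run_pipeline"]


class PipelineInputError(FileNotFoundError):
    """Raised before any computation when input files are missing."""


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Defaults follow the analysis conventions the pipeline is built around:
    promoter windows 4 kb upstream / 1 kb downstream of the TSS, gene
    association within 5000 bp of a peak, enhancer interaction score
    strictly above 10, DEG FDR cutoff 0.05, and a co-localization bin width
    defaulting to the pooled mean peak length.
    """

    chrom_sizes: str
    peaks_a: str
    peaks_b: str
    genes: str
    mark_promoter: str | None = None
    mark_distal: str | None = None
    enhancers: str | None = None
    de_table: str | None = None
    name_a: str = "A"
    name_b: str = "B"
    promoter_upstream: int = 4000
    promoter_downstream: int = 1000
    max_gene_dist: int = 5000
    min_enhancer_score: float = 10.0
    fdr: float = 0.05
    bin_width: int | None = None
    outdir: str = "peakcoloc_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _require_inputs(cfg: PipelineConfig) -> None:
    required = {
        "chrom_sizes": cfg.chrom_sizes,
        "peaks_a": cfg.peaks_a,
        "peaks_b": cfg.peaks_b,
        "genes": cfg.genes,
    }
    optional = {
        "mark_promoter": cfg.mark_promoter,
        "mark_distal": cfg.mark_distal,
        "enhancers": cfg.enhancers,
        "de_table": cfg.de_table,
    }
    missing = {k: str(v) for k, v in required.items() if v is None or not Path(v).exists()}
    missing.update(
        {k: str(v) for k, v in optional.items() if v is not None and not Path(v).exists()}
    )
    if missing:
        raise PipelineInputError(
            "missing input files: "
            + ", ".join(f"{k}={v}" for k, v in sorted(missing.items()))
        )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        w.writerows(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    _require_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"{k} = {v}" for k, v in sorted(asdict(cfg).items())]

    genome = read_chrom_sizes(cfg.chrom_sizes)
    set_a = read_bed(cfg.peaks_a, genome, cfg.name_a)
    set_b = read_bed(cfg.peaks_b, genome, cfg.name_b)
    genes = read_gene_models(cfg.genes)
    summary: dict = {
        "n_peaks_a": len(set_a),
        "n_peaks_b": len(set_b),
        "n_genes": len(genes),
    }

    # 1. feature annotation of each TF peak set
    assignments = {}
    for label, ps in ((cfg.name_a, set_a), (cfg.name_b, set_b)):
        asg = assign_feature(ps, genes)
        assignments[label] = asg
        dist = feature_distribution(asg)
        _write_tsv(
            outdir / f"features_{label}.tsv",
            ["peak_id", "category", "gene_id"],
            [[a.peak_id, a.category, a.gene_id or ""] for a in asg],
        )
        summary[f"feature_pct_{label}"] = {k: round(v, 4) for k, v in dist.items()}

    # 2. merged co-bound peaks
    merged = merge_cobound(set_a, set_b)
    _write_tsv(
        outdir / "merged_peaks.tsv",
        ["chrom", "start", "end", "members_a", "members_b"],
        [
            [m.span.chrom, m.span.start, m.span.end, ",".join(m.members_a), ",".join(m.members_b)]
            for m in merged
        ],
    )
    summary["n_merged_peaks"] = len(merged)
    merged_set = PeakSet(
        "merged",
        [Peak(m.span, f"merged_{i}") for i, m in enumerate(merged)],
        genome,
    )

    # 3. distance from each B peak to the nearest A peak
    dists = nearest_distance(set_b, set_a)
    _write_tsv(
        outdir / "nearest_distance.tsv",
        ["peak_id", "distance_bp"],
        [[pid, "" if d is None else d] for pid, d in sorted(dists.items())],
    )
    frac, n_hit, n_tot = overlap_fraction(set_b, set_a)
    summary["overlap_fraction_b_on_a"] = frac
    summary["n_b_overlapping_a"] = n_hit

    # 4. binned co-localization test
    coloc = colocalization_test(set_a, set_b, genome, cfg.bin_width)
    coloc.write_json(outdir / "colocalization.json")
    summary["colocalization"] = coloc.to_dict()

    # 5. promoter / distal splits
    prom_a, prom_map_a = peaks_in_promoters(
        set_a, genes, cfg.promoter_upstream, cfg.promoter_downstream
    )
    prom_merged, _ = peaks_in_promoters(
        merged_set, genes, cfg.promoter_upstream, cfg.promoter_downstream
    )
    distal_ids_a = [
        a.peak_id for a in assignments[cfg.name_a] if a.category == "distal_intergenic"
    ]
    distal_a = set_a.subset(distal_ids_a, name=f"{cfg.name_a}_distal")
    nonprom_merged = merged_set.subset(
        [p.id for p in merged_set if p.id not in {q.id for q in prom_merged}],
        name="merged_nonpromoter",
    )
    summary["n_promoter_peaks_a"] = len(prom_a)
    summary["n_promoter_genes_a"] = len({g for gs in prom_map_a.values() for g in gs})
    summary["n_distal_peaks_a"] = len(distal_a)
    summary["n_merged_promoter"] = len(prom_merged)
    summary["n_merged_nonpromoter"] = len(nonprom_merged)

    # 6. histone-mark stratification (promoter peaks vs the promoter mark,
    #    distal peaks vs the distal mark, and the merged set vs both)
    if cfg.mark_promoter is not None:
        k4 = read_bed(cfg.mark_promoter, genome, "mark_promoter")
        s = stratify_by_mark(prom_a, k4)
        summary["promoter_peaks_a_in_mark"] = {
            "n_in": len(s.in_mark),
            "n_total": len(prom_a),
            "fraction": s.fraction_in,
        }
        sm = stratify_by_mark(prom_merged, k4)
        summary["merged_promoter_in_mark"] = {
            "n_in": len(sm.in_mark),
            "n_total": len(prom_merged),
            "fraction": sm.fraction_in,
        }
    if cfg.mark_distal is not None:
        k27 = read_bed(cfg.mark_distal, genome, "mark_distal")
        s = stratify_by_mark(distal_a, k27)
        summary["distal_peaks_a_in_mark"] = {
            "n_in": len(s.in_mark),
            "n_total": len(distal_a),
            "fraction": s.fraction_in,
        }
        sm = stratify_by_mark(merged_set, k27)
        summary["merged_in_distal_mark"] = {
            "n_in": len(sm.in_mark),
            "n_total": len(merged_set),
            "fraction": sm.fraction_in,
        }

    # 7. enhancer join on the distal peaks
    if cfg.enhancers is not None:
        enh = read_enhancers(cfg.enhancers)
        annotated, novel, reg_genes = enhancer_join(distal_a, enh, cfg.min_enhancer_score)
        summary["enhancer_join"] = {
            "n_distal": len(distal_a),
            "n_annotated": len(annotated),
            "n_novel": len(novel),
            "n_regulated_genes": len(reg_genes),
        }
        _write_tsv(
            outdir / "enhancer_regulated_genes.tsv",
            ["gene_id"],
            [[g] for g in sorted(reg_genes)],
        )

    # 8. DEG joins over genes within max_gene_dist of peaks
    if cfg.de_table is not None:
        de = read_de_table(cfg.de_table)
        gene_map_a = genes_near_peaks(set_a, genes, cfg.max_gene_dist)
        classes_a = deg_join(gene_map_a, de, cfg.fdr)
        counts = {c: 0 for c in ("up", "down", "ns", "untested")}
        for c in classes_a.values():
            counts[c] += 1
        summary["deg_a"] = counts
        gene_map_m = genes_near_peaks(merged_set, genes, cfg.max_gene_dist)
        classes_m = deg_join(gene_map_m, de, cfg.fdr)
        counts_m = {c: 0 for c in ("up", "down", "ns", "untested")}
        for c in classes_m.values():
            counts_m[c] += 1
        summary["deg_merged"] = counts_m
        _write_tsv(
            outdir / "deg_classes.tsv",
            ["gene_id", "class"],
            [[g, c] for g, c in sorted(classes_a.items())],
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log_lines.append(f"stages_completed = {len(summary)} summary entries")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
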