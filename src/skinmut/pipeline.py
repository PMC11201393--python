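"""End-to-end pipeline: triage -> expression ANOVA -> enrichment -> gene-set ANOVA.

Stage order mirrors the analysis narrative: per-patient paired subtraction,
quality filtering, target restriction, blacklist removal, cohort locus
classification, mutation-status matrix, CPM/log2 transform, gene-level
interaction ANOVA with FC >= 3 / FDR <= 0.05 differential-expression
selection, chi-square category enrichment, gene-set ANOVA, and the
mutation x arsenic-exposure stratified gene-set analysis.  Every output is
a deterministic function of the inputs and configuration; the run log
records how many calls survive each triage stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as skio
from .enrichment import chisq_2x2, enrichment_test, rank_categories
from .expression import cpm_log2, fit_all_genes, select_de_genes
from .genesets import (
    GeneSetCollection,
    fit_geneset_model,
    geneset_report,
    stratified_geneset_analysis,
)
from .triage import (
    FilterParams,
    TriageConfig,
    build_target_index,
    apply_quality_filters,
    classify_loci,
    compare_group_location,
    mutation_status_matrix,
    remove_germline_blacklist,
    restrict_to_target,
    substitution_spectrum,
    subtract_paired,
    tmb_summary,
    top_mutated_genes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and analysis knobs for a full run."""

    sample_sheet: Path
    vcf_dir: Path
    bed: Path
    blacklist: Path
    counts: Path
    gmt: Path
    out_dir: Path
    filters: FilterParams = field(default_factory=FilterParams)
    panel_size_mb: float = 1.7
    offset: float = 1.0
    fc_min: float = 3.0
    fdr_max: float = 0.05
    uacr_cut: float = 192.0
    driver_genes: tuple[str, ...] = ("PTCH1",)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_sheet", "vcf_dir", "bed", "blacklist", "counts",
                     "gmt", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate_paths(self) -> None:
        for name in ("sample_sheet", "vcf_dir", "bed", "blacklist", "counts",
                     "gmt"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filters" in raw:
            raw["filters"] = FilterParams(**raw["filters"])
        if "driver_genes" in raw:
            raw["driver_genes"] = tuple(raw["driver_genes"])
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is excluded so the same inputs and knobs hash identically
        # regardless of where the results land
        payload = {
            k: str(v) for k, v in asdict(self).items() if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the result tables under ``out_dir``."""
    config.validate_paths()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    comment = f"skinmut {__version__} config={config.config_hash()}"
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    try:
        sheet = skio.read_sample_sheet(config.sample_sheet)
        vcf_paths = {
            sid: config.vcf_dir / f"{sid}.vcf"
            for sid in list(sheet.index) + list(sheet["blood_id"])
        }
        missing = [str(p) for p in vcf_paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing VCF file(s): {missing}")
        calls = skio.read_variant_tables(vcf_paths)
        regions = skio.read_bed(config.bed)
        target_index = build_target_index(regions)
        blacklist = skio.read_blacklist(config.blacklist)
        triage_cfg = TriageConfig(
            panel_size_mb=config.panel_size_mb,
            target_regions=regions,
            germline_blacklist=blacklist,
        )

        somatic: dict[str, list] = {}
        for sid in sheet.index:
            tissue = calls[sid]
            blood = calls[sheet.loc[sid, "blood_id"]]
            log("input", f"{sid}: {len(tissue)} tissue calls, "
                f"{len(blood)} blood calls")
            step = subtract_paired(tissue, blood)
            log("subtract", f"{sid}: {len(step)} retained")
            step = apply_quality_filters(step, config.filters)
            log("filter", f"{sid}: {len(step)} retained")
            step = restrict_to_target(step, target_index)
            log("target", f"{sid}: {len(step)} retained")
            step = remove_germline_blacklist(step, triage_cfg.germline_blacklist)
            log("blacklist", f"{sid}: {len(step)} retained")
            somatic[sid] = step

        tumor_ids = [s for s in sheet.index if sheet.loc[s, "tissue"] != "healthy"]
        healthy_ids = [s for s in sheet.index if sheet.loc[s, "tissue"] == "healthy"]
        triage = classify_loci(
            {s: somatic[s] for s in tumor_ids},
            {s: somatic[s] for s in healthy_ids},
        )
        summary = triage.category_summary()
        log("classify", f"{summary['unique_loci'].sum()} unique loci: "
            + ", ".join(f"{c}={summary.loc[c, 'unique_loci']}"
                        for c in summary.index))
        skio.write_table(summary, out / "triage_summary.tsv",
                         header_comment=comment)
        loci_rows = pd.DataFrame(
            [
                {
                    "chrom": l[0], "pos": l[1], "ref": l[2], "alt": l[3],
                    "gene": triage.locus_gene[l], "category": cat,
                    "n_samples": len(triage.locus_samples[l]),
                }
                for l, cat in triage.category.items()
            ]
        ).sort_values(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)
        skio.write_table(loci_rows, out / "triage_loci.tsv",
                         header_comment=comment, index=False)

        groups = sheet["tissue"].to_dict()
        counts_per_sample = {s: len(somatic[s]) for s in sheet.index}
        tmb = tmb_summary(counts_per_sample, groups, config.panel_size_mb)
        h, p = compare_group_location(
            {
                g: [counts_per_sample[s] for s in sheet.index
                    if groups[s] == g]
                for g in sorted(set(groups.values()))
            }
        )
        tmb["kruskal_H"] = h
        tmb["kruskal_p"] = p
        skio.write_table(tmb, out / "tmb.tsv", header_comment=comment)

        per_sample_spec, spec_summary = substitution_spectrum(somatic)
        skio.write_table(spec_summary, out / "spectrum.tsv",
                         header_comment=comment)

        top = top_mutated_genes(triage, "NMSC_ONLY", 20,
                                sample_subset=tumor_ids)
        skio.write_table(
            pd.DataFrame(top, columns=["gene", "pct_samples"]),
            out / "top_mutated_genes.tsv", header_comment=comment, index=False,
        )

        panel_genes = {c.gene for cs in calls.values() for c in cs if c.gene}
        drivers = [g for g in config.driver_genes if g in panel_genes]
        if not drivers:
            raise ValueError(
                f"none of the driver genes {config.driver_genes} found in "
                "the VCF annotations"
            )
        status = mutation_status_matrix(triage, drivers,
                                        annotation_genes=panel_genes)
        skio.write_table(status, out / "mutation_status.tsv",
                         header_comment=comment)

        raw_counts = skio.read_counts(config.counts)
        expr = cpm_log2(raw_counts[list(sheet.index)], offset=config.offset)
        primary = drivers[0]
        labels = pd.Series(
            {
                s: ("healthy" if groups[s] == "healthy"
                    else f"mut{int(status.loc[s, primary])}")
                for s in sheet.index
            }
        )
        effects = fit_all_genes(expr, labels)
        skio.write_table(effects, out / "gene_effects.tsv",
                         header_comment=comment)
        de = select_de_genes(effects, config.fc_min, config.fdr_max)
        log("de", f"{len(de)} genes at |FC|>={config.fc_min}, "
            f"FDR<={config.fdr_max}")
        skio.write_table(pd.DataFrame({"gene": de}),
                         out / "de_genes.tsv", header_comment=comment,
                         index=False)

        sets = GeneSetCollection(skio.read_gmt(config.gmt), source=str(config.gmt))
        background = expr.genes
        enrich_rows = []
        for name, members in sets.restricted_to(background).sets.items():
            if de:
                enrich_rows.append(
                    enrichment_test(de, members, background, category=name)
                )
        if enrich_rows:
            ranked = rank_categories(enrich_rows)
            skio.write_table(
                pd.DataFrame([vars(r) for r in ranked]),
                out / "enrichment.tsv", header_comment=comment, index=False,
            )

        gsa = [
            fit_geneset_model(expr, members, labels, name=name)
            for name, members in sets.restricted_to(background).sets.items()
        ]
        skio.write_table(geneset_report(gsa), out / "geneset_effects.tsv",
                         header_comment=comment, index=False)

        strat = stratified_geneset_analysis(
            expr,
            sets,
            status.loc[tumor_ids, primary],
            sheet["uacr"],
            config.uacr_cut,
        )
        skio.write_table(
            geneset_report(strat), out / "stratified_geneset_effects.tsv",
            header_comment=comment, index=False,
        )
    except Exception as err:
        # remove partial outputs so a failed run leaves no half-written state
        for line in log_lines:
            logger.error("completed before failure: %s", line)
        if out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline aborted: {err}") from err

    (out / "run_log.txt").write_text(
        f"# {comment}\n" + "\n".join(log_lines) + "\n"
    )
    return out


def proportion_summary(
    counts: dict[str, tuple[int, int]],
) -> tuple[pd.DataFrame, float]:
    """Per-group event percentage plus a chi-square p for group differences.

    ``counts`` maps group -> (events, total).  Display percentages are
    rounded to one decimal; the chi-square runs on the full events /
    non-events table (no continuity correction).
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for group, (events, total) in counts.items():
        if total <= 0:
            raise ValueError(f"group {group!r} has total 0")
        if events > total:
            raise ValueError(f"group {group!r} has events > total")
        rows.append(
            {
                "group": group,
                "events": events,
                "total": total,
                "percent": round(100.0 * events / total, 1),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    if len(counts) == 2:
        (e1, t1), (e2, t2) = counts.values()
        _, p = chisq_2x2(e1, t1 - e1, e2, t2 - e2)
    else:
        from scipy import stats as sps

        obs = [[e, t - e] for e, t in counts.values()]
        _, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return table, float(p)
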