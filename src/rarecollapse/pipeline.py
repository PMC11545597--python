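"""Orchestration of the three association analyses.

``run_scan`` drives read -> QC -> tiering -> per-analysis testing ->
writing for a configured cohort:

1. primary scan: gene-level collapsing of rare inactivating variants
   (RIV), plus per-variant tests for every RIV;
2. secondary scan: gene-level collapsing of rare damaging variants (RDV);
3. tertiary scan: SKAT over the non-synonymous tier, with single-variant
   exact-resampling p-values and a Bonferroni column;
4. filter-based ranking of genes by RIV case-carrier count and the
   per-sample RIV burden summary.

Every stage's variant accounting is recorded in a run report
(JSON) together with the package version and a config hash; re-running
with identical inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import burden as bd
from . import skat as sk
from .classify import (
    ClassificationConfig,
    TierAssignment,
    classify_variant,
    cohort_af,
    qc_filter,
    select_variant_set,
)
from .io_cohort import (
    CohortGenotypes,
    SampleManifest,
    read_annotations,
    read_vcf_cohort,
    write_results,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    annotations: str
    manifest: str
    outdir: str
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    riv_scan: bool = True
    rdv_scan: bool = True
    skat_scan: bool = True
    ranking: bool = True
    burden_summary: bool = True
    exome_wide: float = bd.EXOME_WIDE_ALPHA
    suggestive: float = bd.SUGGESTIVE_ALPHA
    ranking_top_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exome_wide < self.suggestive:
            raise ValueError("exome_wide threshold must be below suggestive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cls_cfg = ClassificationConfig(**raw.pop("classification", {}))
        return cls(classification=cls_cfg, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    report: dict
    outputs: dict[str, Path]


def _classify_cohort(
    geno: CohortGenotypes, annotations, cfg: ClassificationConfig
) -> tuple[list[TierAssignment], dict]:
    """QC + tiering for every annotated (variant, gene) pair with accounting."""
    matched = [a for a in annotations if a.key in geno]
    unmatched = len(annotations) - len(matched)
    if unmatched:
        logger.warning("%d annotation rows have no genotype column", unmatched)

    qc_cache: dict = {}
    control_af_cache: dict = {}
    assignments: list[TierAssignment] = []
    n_qc_failed = n_tiered = n_untiered = 0
    filter_log: list[tuple[str, str]] = []
    for ann in matched:
        if ann.key not in qc_cache:
            qc_cache[ann.key] = qc_filter(geno, ann, cfg)
        ok, reasons = qc_cache[ann.key]
        if not ok:
            n_qc_failed += 1
            filter_log.extend((str(ann.key), r) for r in reasons)
            assignments.append(
                TierAssignment(ann.key, ann.gene, frozenset(), qc_pass=False,
                               reasons=list(reasons))
            )
            continue
        if ann.key not in control_af_cache:
            control_af_cache[ann.key] = cohort_af(geno, ann.key, "controls")
        a = classify_variant(ann, control_af_cache[ann.key], cfg)
        assignments.append(a)
        if a.tiers:
            n_tiered += 1
        else:
            n_untiered += 1

    accounting = {
        "annotation_rows": len(annotations),
        "unmatched_rows": unmatched,
        "pairs_in": len(matched),
        "qc_failed": n_qc_failed,
        "tiered": n_tiered,
        "untiered": n_untiered,
    }
    # accounting identity: every matched pair lands in exactly one bucket
    assert accounting["pairs_in"] == n_qc_failed + n_tiered + n_untiered
    return assignments, {"accounting": accounting, "filter_log": filter_log}


def run_scan(cfg: RunConfig) -> RunReport:
    """Execute the configured analyses; write result TSVs and a run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }

    def stage(name: str):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("read")
        manifest = SampleManifest.from_tsv(cfg.manifest)
        geno = read_vcf_cohort(cfg.vcf, manifest)
        annotations = read_annotations(cfg.annotations)
        if geno.n_variants == 0:
            raise PipelineError("read", "cohort VCF contains no variants")
        report["cohort"] = {
            "n_case": manifest.n_case,
            "n_control": manifest.n_control,
            "n_variants": geno.n_variants,
        }

        stage("classify")
        assignments, cls_info = _classify_cohort(geno, annotations, cfg.classification)
        report["accounting"] = cls_info["accounting"]
        if cls_info["filter_log"]:
            log_path = outdir / "filter_log.tsv"
            log_path.write_text(
                "variant\treason\n"
                + "\n".join(f"{v}\t{r}" for v, r in cls_info["filter_log"]) + "\n"
            )
            outputs["filter_log"] = log_path

        tier_sets = {
            tier: select_variant_set(assignments, tier, geno,
                                     cfg.classification.min_gene_count)
            for tier in ("RIV", "RDV", "NONSYN")
        }
        report["tier_counts"] = {
            t: {"genes": len(s), "variants": sum(len(g.variants) for g in s.values())}
            for t, s in tier_sets.items()
        }

        riv_results: list[bd.GeneAssociationResult] = []
        if cfg.riv_scan or cfg.ranking:
            stage("riv_scan")
            riv_sets = tier_sets["RIV"]
            riv_results = [bd.test_gene(g, "RIV", geno, riv_sets) for g in sorted(riv_sets)]
            if cfg.riv_scan:
                out = outdir / "riv_genes.tsv"
                write_results([r for r in riv_results if r.eligible], out)
                outputs["riv_genes"] = out
                var_results = [
                    bd.test_variant(k, geno, gene=g)
                    for g in sorted(riv_sets) for k in riv_sets[g].variants
                ]
                out = outdir / "riv_variants.tsv"
                write_results(var_results, out)
                outputs["riv_variants"] = out
                report["riv_exome_wide_genes"] = sorted(
                    r.gene for r in riv_results
                    if r.eligible and r.p_value < cfg.exome_wide
                )

        if cfg.rdv_scan:
            stage("rdv_scan")
            rdv_sets = tier_sets["RDV"]
            rdv_results = [bd.test_gene(g, "RDV", geno, rdv_sets) for g in sorted(rdv_sets)]
            out = outdir / "rdv_genes.tsv"
            write_results([r for r in rdv_results if r.eligible], out)
            outputs["rdv_genes"] = out
            report["rdv_exome_wide_genes"] = sorted(
                r.gene for r in rdv_results
                if r.eligible and r.p_value < cfg.exome_wide
            )

        if cfg.skat_scan:
            stage("skat_scan")
            null = sk.fit_null(manifest)
            nonsyn_sets = tier_sets["NONSYN"]
            skat_results = [
                sk.skat_test_gene(g, null, geno, nonsyn_sets[g])
                for g in sorted(nonsyn_sets)
            ]
            out = outdir / "skat_genes.tsv"
            _write_skat(skat_results, manifest, out)
            outputs["skat_genes"] = out
            report["skat_exome_wide_genes"] = sorted(
                r.gene for r in skat_results if r.p_value < cfg.exome_wide
            )
            # single-variant exact-resampling p-values with Bonferroni column
            sv = [
                (g, k, sk.single_variant_er_p(null, geno.column(k))[0])
                for g in sorted(nonsyn_sets) for k in nonsyn_sets[g].variants
            ]
            if sv:
                adj = sk.bonferroni([p for _, _, p in sv])
                out = outdir / "skat_variants.tsv"
                out.write_text(
                    "gene\tchrom\tpos\tref\talt\tp_value\tp_bonferroni\n"
                    + "\n".join(
                        f"{g}\t{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{p:.3e}\t{q:.3e}"
                        for (g, k, p), q in zip(sv, adj)
                    )
                    + "\n"
                )
                outputs["skat_variants"] = out
                report["skat_variants_bonferroni_significant"] = int(
                    sum(q < 0.05 for q in adj)
                )

        if cfg.ranking:
            stage("ranking")
            ranked = bd.rank_genes_filter_based(riv_results, cfg.ranking_top_n)
            out = outdir / "ranking.tsv"
            out.write_text(
                "rank\tgene\tn_case_carriers\tn_control_carriers\tp_value"
                "\todds_ratio\tp_lt_0.05\n"
                + "\n".join(
                    f"{r.rank}\t{r.result.gene}\t{r.result.table.a}\t{r.result.table.c}"
                    f"\t{r.result.p_value:.2e}\t"
                    + (f"{r.result.odds_ratio:.1f}" if r.result.odds_ratio >= 1
                       else f"{r.result.odds_ratio:.2f}")
                    + f"\t{str(r.significant_05).lower()}"
                    for r in ranked
                )
                + "\n"
            )
            outputs["ranking"] = out
            report["ranking_significant_05"] = int(sum(r.significant_05 for r in ranked))

        if cfg.burden_summary:
            stage("burden_summary")
            riv_keys = [k for s in tier_sets["RIV"].values() for k in s.variants]
            if riv_keys:
                summ = bd.per_sample_burden_summary(geno, riv_keys)
                report["riv_burden"] = {
                    "case_median": summ.case_median,
                    "case_iqr": list(summ.case_iqr),
                    "control_median": summ.control_median,
                    "control_iqr": list(summ.control_iqr),
                    "wilcoxon_p": summ.p_value,
                }

        stage("report")
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        outputs["report"] = report_path
        return RunReport(report=report, outputs=outputs)
    except PipelineError:
        _cleanup(outputs)
        raise
    except Exception as exc:
        _cleanup(outputs)
        current = report["stages"][-1] if report["stages"] else "setup"
        raise PipelineError(current, str(exc)) from exc


def _cleanup(outputs: dict[str, Path]) -> None:
    for p in outputs.values():
        p.unlink(missing_ok=True)


def _write_skat(results, manifest: SampleManifest, path: Path) -> None:
    lines = [
        "gene\tn_variants\tQ\tp_value\tmethod\tn_case_carriers\tpct_case"
        "\tn_control_carriers\tpct_control\todds_ratio\texome_wide"
    ]
    for r in results:
        t = r.table
        lines.append(
            f"{r.gene}\t{r.n_variants}\t{r.Q:.6g}\t{max(r.p_value, 1e-300):.2e}"
            f"\t{r.method}\t{t.a}\t{100 * t.a / manifest.n_case:.1f}"
            f"\t{t.c}\t{100 * t.c / manifest.n_control:.1f}"
            f"\t{r.odds_ratio:.1f}\t{str(r.exome_wide).lower()}"
        )
    path.write_text("\n".join(lines) + "\n")
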