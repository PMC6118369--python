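"""End-to-end orchestration: simulate -> preprocess -> detect -> filter ->
score -> compare -> de-novo.

The pipeline is a pure function of ``(RunConfig, SimulationConfig)``:
every random draw descends from the master seed through named
substreams, so identical configurations produce bit-identical output
bundles.  Each stage logs its input/output shapes at stage granularity.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import ComparisonSpec, ConcordanceReport, run_comparison
from .design import PM_ONLY
from .detection import DetectionCalls, detect, percent_present
from .io import ExpressionMatrix, RunConfig, write_expression_matrix, write_modules_wgmt, write_phenotype, write_probe_matrix
from .modules import GeneModule, derive_module_subset, score_modules, validate_module_subset
from .denovo import DenovoError, auc, delong_test, derive_denovo_module
from .preprocess import preprocess_dataset
from .pvac import AAB, AG, PvacError, PvacResult, run_pvac
from .simulate import (
    SimulatedExperiment,
    SimulationConfig,
    make_module_collection,
    simulate_matched_experiment,
    simulate_validation_cohort,
)

log = logging.getLogger("ffconcord")

#: the three canonical comparison schemes over the default dataset layout
DEFAULT_COMPARISONS = (
    ComparisonSpec("ref1", "ff.A", ["ffpe.A", "ff.B", "ffpe.B1", "ffpe.B2"]),
    ComparisonSpec("ref2", "ff.B", ["ffpe.B1", "ffpe.B2"]),
    ComparisonSpec("ref3", "ffpe.B1", ["ffpe.B2"]),
)


def _setup_logging(cfg: RunConfig) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(h)
    if cfg.log_file:
        log.addHandler(logging.FileHandler(cfg.log_file))


@dataclass
class PipelineResult:
    """In-memory view of a full pipeline run."""

    config: RunConfig
    sim_config: SimulationConfig
    experiment: SimulatedExperiment
    gene_exprs: dict[str, ExpressionMatrix]
    probeset_exprs: dict[str, ExpressionMatrix]
    calls: dict[str, DetectionCalls]
    percent_present: pd.DataFrame  # dataset x sample
    pvac: dict[str, dict[str, PvacResult]]  # strategy -> dataset -> result
    selected_genes: dict[str, dict[str, set[str]]]
    modules: list[GeneModule]
    kept_modules: list[GeneModule]
    reports: dict[str, ConcordanceReport]
    denovo_summary: pd.DataFrame
    denovo_modules: dict[tuple[str, str, str], GeneModule] = field(default_factory=dict)


def filter_module_collection(
    modules: list[GeneModule],
    selected_by_version: dict[tuple[str, str], set[str]],
    ref_expr: pd.DataFrame,
    rho_subset_valid: float = 0.9,
    min_size: int = 2,
    exclude_from_validation: tuple[str, ...] = ("ffpe.A",),
) -> list[GeneModule]:
    """Module-collection filtering: size rule then reference validation.

    A module is discarded entirely when any (strategy, dataset) subset
    version falls below ``min_size`` genes, or when any version's scores
    on the reference dataset correlate (Spearman) below
    ``rho_subset_valid`` with the full module's reference scores.
    Versions from datasets in ``exclude_from_validation`` (the
    near-background FFPE PM-MM dataset by default) take part in the size
    rule but not in the correlation validation.
    """
    kept: list[GeneModule] = []
    for mod in modules:
        subsets: dict[tuple[str, str], GeneModule] = {}
        ok = True
        for key, genes in selected_by_version.items():
            sub = derive_module_subset(mod, genes, min_size=min_size)
            if sub is None:
                ok = False
                break
            subsets[key] = sub
        if not ok:
            continue
        full_ref = score_modules(ref_expr, [mod], min_size=min_size)
        if mod.module_id not in full_ref.index:
            continue
        full_scores = full_ref.loc[mod.module_id]
        subset_scores = [
            score_modules(ref_expr, [sub], min_size=min_size).loc[mod.module_id]
            for (strategy, ds), sub in subsets.items()
            if ds not in exclude_from_validation
        ]
        if validate_module_subset(full_scores, subset_scores, rho_subset_valid):
            kept.append(mod)
    return kept


def run_pipeline(
    config: RunConfig,
    sim_config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run every stage on a simulated matched experiment.

    When ``write_outputs`` is true the report bundle is written under
    ``out_dir`` (default ``config.out_dir``): one directory per dataset
    with probe matrices, expression matrices, detection calls and PVAC
    selections, plus comparison tables, kept module scores and the
    de-novo ROC summary.
    """
    _setup_logging(config)
    sim_config = sim_config or SimulationConfig(seed=config.seed)
    out = Path(out_dir or config.out_dir)

    log.info("stage=simulate seed=%d n_genes=%d", sim_config.seed, sim_config.n_genes)
    exp = simulate_matched_experiment(sim_config)

    gene_exprs: dict[str, ExpressionMatrix] = {}
    probeset_exprs: dict[str, ExpressionMatrix] = {}
    log2probes: dict[str, pd.DataFrame] = {}
    calls: dict[str, DetectionCalls] = {}
    pp_rows = {}
    for ds_id, m in exp.datasets.items():
        design = exp.truth.designs[exp.truth.dataset_design[ds_id]]
        log.info("stage=preprocess dataset=%s probes=%d", ds_id, m.values.shape[0])
        lp, ps_expr, gene_expr = preprocess_dataset(m, design)
        log2probes[ds_id] = lp
        probeset_exprs[ds_id] = ps_expr
        gene_exprs[ds_id] = gene_expr
        log.info("stage=detect dataset=%s kind=%s", ds_id, design.design_kind)
        calls[ds_id] = detect(m, design, alpha=config.alpha_detection, tau=config.tau)
        pp_rows[ds_id] = percent_present(calls[ds_id], design)
    pp = pd.DataFrame(pp_rows).T

    pvac_results: dict[str, dict[str, PvacResult]] = {AAB: {}, AG: {}}
    selected_genes: dict[str, dict[str, set[str]]] = {AAB: {}, AG: {}}
    for ds_id in exp.datasets:
        design = exp.truth.designs[exp.truth.dataset_design[ds_id]]
        log.info("stage=pvac dataset=%s", ds_id)
        try:
            res = run_pvac(
                log2probes[ds_id], design, AAB, calls=calls[ds_id],
                q=config.pvac_negative_quantile,
            )
            pvac_results[AAB][ds_id] = res
            selected_genes[AAB][ds_id] = res.selected_genes(design)
        except PvacError as exc:
            log.warning("stage=pvac dataset=%s strategy=AAB failed: %s", ds_id, exc)
        if design.design_kind == PM_ONLY:
            res = run_pvac(
                log2probes[ds_id], design, AG, q=config.pvac_negative_quantile
            )
            pvac_results[AG][ds_id] = res
            selected_genes[AG][ds_id] = res.selected_genes(design)

    modules = make_module_collection(exp.truth, sim_config)
    selected_by_version = {
        (strategy, ds): genes
        for strategy, per_ds in selected_genes.items()
        for ds, genes in per_ds.items()
    }
    ref_expr = gene_exprs["ff.A"].values
    kept = filter_module_collection(
        modules,
        selected_by_version,
        ref_expr,
        rho_subset_valid=config.rho_subset_valid,
        min_size=config.min_module_size,
    )
    log.info("stage=modules total=%d kept=%d", len(modules), len(kept))

    reports: dict[str, ConcordanceReport] = {}
    for spec in DEFAULT_COMPARISONS:
        log.info("stage=compare comparison=%s ref=%s", spec.comparison_id, spec.reference_dataset)
        reports[spec.comparison_id] = run_comparison(
            spec,
            gene_exprs,
            kept,
            selected_genes_by_version=selected_genes,
            rho_reproducible=config.rho_reproducible,
            min_module_size=config.min_module_size,
        )

    log.info("stage=denovo")
    val_expr, val_pheno = simulate_validation_cohort(sim_config, exp.truth)
    denovo_rows = []
    denovo_modules: dict[tuple[str, str, str], GeneModule] = {}
    truth_modules = {
        "ER": GeneModule(
            "truth_ER",
            [(g, int(s)) for g, s in exp.truth.er_de[exp.truth.er_de != 0].items()],
            provenance="control",
        ),
        "HER2": GeneModule(
            "truth_HER2",
            [(g, int(s)) for g, s in exp.truth.her2_de[exp.truth.her2_de != 0].items()],
            provenance="control",
        ),
    }
    for ds_id, e in gene_exprs.items():
        universes: dict[str, set[str] | None] = {"none": None}
        for strategy in (AAB, AG):
            if ds_id in selected_genes[strategy]:
                universes[strategy] = selected_genes[strategy][ds_id]
        for marker in ("ER", "HER2"):
            y = (val_pheno.status(marker) == "pos").to_numpy()
            ref_scores = score_modules(val_expr.values, [truth_modules[marker]]).loc[
                truth_modules[marker].module_id
            ]
            for uname, universe in universes.items():
                try:
                    mod, table = derive_denovo_module(
                        e,
                        exp.phenotype,
                        marker,
                        fc_threshold=config.fc_threshold,
                        p_threshold=config.p_threshold,
                        gene_universe=universe,
                        module_id=f"denovo_{marker}_{ds_id}_{uname}",
                    )
                except DenovoError:
                    denovo_rows.append(
                        dict(dataset=ds_id, marker=marker, universe=uname,
                             n_genes=0, auc=np.nan, delong_p=np.nan)
                    )
                    continue
                denovo_modules[(ds_id, marker, uname)] = mod
                scores = score_modules(val_expr.values, [mod]).loc[mod.module_id]
                a = auc(scores.to_numpy(), y)
                _, _, p = delong_test(
                    scores.to_numpy(), ref_scores.to_numpy(), y
                )
                denovo_rows.append(
                    dict(dataset=ds_id, marker=marker, universe=uname,
                         n_genes=len(mod), auc=a, delong_p=p)
                )
    denovo_summary = pd.DataFrame(denovo_rows)

    result = PipelineResult(
        config=config,
        sim_config=sim_config,
        experiment=exp,
        gene_exprs=gene_exprs,
        probeset_exprs=probeset_exprs,
        calls=calls,
        percent_present=pp,
        pvac=pvac_results,
        selected_genes=selected_genes,
        modules=modules,
        kept_modules=kept,
        reports=reports,
        denovo_summary=denovo_summary,
        denovo_modules=denovo_modules,
    )
    if write_outputs:
        write_bundle(result, out)
    return result


def write_bundle(result: PipelineResult, out: Path) -> None:
    """Write the report bundle: one directory per dataset plus summaries."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    exp = result.experiment
    exp.manifest.to_csv(out / "manifest.tsv", sep="\t")
    write_phenotype(out / "phenotype.tsv", exp.phenotype)
    write_modules_wgmt(out / "modules_all.wgmt", result.modules)
    write_modules_wgmt(out / "modules_kept.wgmt", result.kept_modules)
    for ds_id, m in exp.datasets.items():
        d = out / "datasets" / ds_id
        d.mkdir(parents=True, exist_ok=True)
        write_probe_matrix(d / "probes_raw.tsv", m)
        write_expression_matrix(d / "probesets.tsv", result.probeset_exprs[ds_id])
        write_expression_matrix(d / "genes.tsv", result.gene_exprs[ds_id])
        result.calls[ds_id].calls_frame().to_csv(d / "calls.tsv", sep="\t")
        result.calls[ds_id].p_values.to_csv(d / "calls_pvalues.tsv", sep="\t")
        for strategy, per_ds in result.pvac.items():
            if ds_id in per_ds:
                sel = per_ds[ds_id].selected_probesets()
                pd.Series(sel).to_csv(
                    d / f"pvac_selected_{strategy}.tsv", sep="\t",
                    index=False, header=["probeset_id"],
                )
    result.percent_present.to_csv(out / "percent_present.tsv", sep="\t")
    for cid, report in result.reports.items():
        d = out / "comparisons" / cid
        d.mkdir(parents=True, exist_ok=True)
        report.module_rho.to_csv(d / "module_rho.tsv", sep="\t")
        report.fraction_reproducible.to_csv(d / "fraction_reproducible.tsv", sep="\t")
        for ds, s in report.gene_rho.items():
            s.to_csv(d / f"gene_rho_{ds}.tsv", sep="\t", header=["rho"])
        for ds, s in report.sample_rho.items():
            s.to_csv(d / f"sample_rho_{ds}.tsv", sep="\t", header=["rho"])
    result.denovo_summary.to_csv(out / "denovo_summary.tsv", sep="\t", index=False)
    if result.denovo_modules:
        write_modules_wgmt(out / "denovo_modules.wgmt", list(result.denovo_modules.values()))
    log.info("stage=write bundle=%s datasets=%d", out, len(exp.datasets))
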