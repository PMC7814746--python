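"""End-to-end orchestration of the stratification workflow.

Stage order mirrors the discovery analysis: ingest coverage files ->
site-inclusion filter -> global methylation comparison -> per-CpG
differential calls -> regulatory annotation and enrichment ->
extreme-phenotype selection (with normal-tissue baseline) -> clinical
scoring and survivor-group assignment -> phyloepigenetic tree and
intra-group distances -> survival/score screens and greedy panel selection
-> all-comer stratification.  Every intermediate artifact is written to the
run directory together with a JSON report of stage counts; the report is
deterministic under a fixed seed and config (wall-clock metadata lives only
in the log).  Each run gets a fresh directory so earlier outputs are never
overwritten.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, clinical, diffmeth, extremes, io, panel, phylo, simulate

logger = logging.getLogger("methylpipe")


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the published analysis values."""

    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    coverage_dir: str | None = None  # use on-disk data instead of simulating
    clinical_path: str | None = None
    min_coverage: int = 5
    min_sample_fraction: float = 0.9
    autosomes_only: bool = True
    p_cutoff: float = 0.01
    delta_cutoff: float = 0.1
    dmr_min_sites: int = 6
    dmr_max_gap: int = 5000
    low_band: tuple[float, float] = (0.0, 0.1)
    high_band: tuple[float, float] = (0.9, 1.0)
    extreme_delta: float = 0.1
    criteria: str = "strict"  # or 'relaxed'
    cluster_k: int = 3
    max_k: int = 10
    panel_mode: str = "resubstitution"  # or 'loo'
    max_panel_candidates: int = 50
    seed: int = 0
    output_dir: str = "methylpipe_runs"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["baseline_mixture"] = list(d["sim"]["baseline_mixture"])
        d["low_band"] = list(self.low_band)
        d["high_band"] = list(self.high_band)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _criteria(cfg: PipelineConfig) -> clinical.SurvivalCriteria:
    return clinical.STRICT_CRITERIA if cfg.criteria == "strict" else clinical.RELAXED_CRITERIA


def run_discovery(config: PipelineConfig, run_name: str | None = None) -> dict:
    """Execute the full stage sequence; returns the run report dict."""
    cfg = config
    cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)  # one seed drives the run
    out_root = Path(cfg.output_dir)
    if run_name is None:
        run_name = time.strftime("run-%Y%m%d-%H%M%S") + f"-{cfg.config_hash()[:8]}"
    run_dir = out_root / run_name
    run_dir.mkdir(parents=True, exist_ok=False)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "stages": {}}

    with open(run_dir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, default=str)

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        # ---- ingest
        st = stage("ingest")
        if cfg.coverage_dir:
            mm = io.read_coverage_dir(cfg.coverage_dir)
            samples = clinical.read_clinical_table(cfg.clinical_path)
            cohort = None
            normal_mm = None
        else:
            cohort = simulate.generate_cohort(cfg.sim)
            input_dir = run_dir / "inputs"
            simulate.write_cohort(cohort, input_dir)
            mm = io.read_coverage_dir(input_dir)
            samples = clinical.read_clinical_table(input_dir / "clinical.tsv")
            normal_mm = simulate.generate_normal_matrix(cohort)
        st["n_sites"] = mm.n_sites
        st["n_samples"] = mm.n_samples

        # ---- site filter
        st = stage("filter")
        mm = io.filter_sites(mm, cfg.min_coverage, cfg.min_sample_fraction,
                             cfg.autosomes_only)
        io.write_matrix(mm, run_dir / "beta.tsv", run_dir / "coverage.tsv")
        st["n_sites_retained"] = mm.n_sites

        # ---- clinical scoring / group assignment
        st = stage("clinical")
        labeled = clinical.label_cohort(samples, _criteria(cfg))
        labeled.to_csv(run_dir / "clinical_scored.tsv", sep="\t", index=False)
        groups = labeled.set_index("sample_id")["group"]
        if groups.isna().any():
            groups = labeled.set_index("sample_id")["assigned_group"]
        st["score_range"] = [int(labeled["ssign_score"].min()),
                             int(labeled["ssign_score"].max())]
        st["n_lts"] = int((groups == "LTS").sum())
        st["n_sts"] = int((groups == "STS").sum())
        plan = [
            clinical.ComparisonVariable("age_years", "continuous"),
            clinical.ComparisonVariable("sex", "binary", levels=["male", "female"]),
            clinical.ComparisonVariable("ssign_score", "categorical", levels=[0, 1, 2, 3]),
            clinical.ComparisonVariable("tumor_size_cm", "continuous"),
            clinical.ComparisonVariable("grade", "categorical", levels=[1, 2, 3, 4]),
            clinical.ComparisonVariable("necrosis", "binary", levels=[True, False],
                                        test="fisher"),
        ]
        comparison = clinical.cohort_comparison(
            labeled[groups.loc[labeled["sample_id"]].to_numpy() == "LTS"],
            labeled[groups.loc[labeled["sample_id"]].to_numpy() == "STS"],
            plan,
        )
        comparison.to_csv(run_dir / "cohort_comparison.tsv", sep="\t")

        # ---- global methylation
        st = stage("global_test")
        gres = diffmeth.global_methylation_test(mm, groups)
        st["p_value"] = gres.p_value
        st["median_lts"] = gres.median_lts
        st["median_sts"] = gres.median_sts
        st["direction"] = gres.direction

        # ---- per-CpG differential calls
        st = stage("dmcpg")
        dm, untestable = diffmeth.test_dmcpgs(mm, groups, cfg.p_cutoff, cfg.delta_cutoff)
        diffmeth.write_dm_table(dm, run_dir / "dmcpgs.tsv")
        sig = dm[dm["significant"]]
        st["n_testable"] = len(dm)
        st["n_untestable"] = len(untestable)
        st["n_significant"] = len(sig)
        st["n_hyper"] = int((sig["direction"] == "hyper").sum())
        st["n_hypo"] = int((sig["direction"] == "hypo").sum())
        regions = diffmeth.call_dm_regions(
            dm, cfg.dmr_min_sites, cfg.dmr_max_gap,
            cohort.gene_model if cohort is not None else None)
        diffmeth.write_dm_regions_bed(regions, run_dir / "dm_regions.bed",
                                      cfg.dmr_max_gap)
        st["n_regions"] = len(regions)

        # ---- regulatory annotation
        st = stage("annotation")
        if cohort is not None:
            landscape = annotate.classify_landscape(cohort.landscape)
            assignments = annotate.assign_features(mm.sites(), cohort.gene_model, landscape)
            assignments.to_csv(run_dir / "feature_assignments.tsv", sep="\t",
                               index_label="site_id")
            st["feature_counts"] = assignments["feature"].value_counts().to_dict()
            if len(sig):
                enr = annotate.feature_enrichment(sig.index, dm.index, assignments)
                enr.to_csv(run_dir / "feature_enrichment.tsv", sep="\t")
                venn = annotate.histone_overlap_venn(sig, landscape)
                st["venn"] = {"+".join(sorted(k)) or "none": v for k, v in venn.items()}
        else:
            st["skipped"] = "no landscape provided"

        # ---- extreme-phenotype selection
        st = stage("extremes")
        sel = extremes.select_extremes(mm, groups, cfg.low_band, cfg.high_band,
                                       cfg.extreme_delta)
        extremes.write_selection(sel, run_dir / "extreme_sites.tsv")
        st["n_fully_unmethylated"] = len(sel.fully_unmethylated)
        st["n_fully_methylated"] = len(sel.fully_methylated)
        if normal_mm is not None and (len(sel.fully_unmethylated) or len(sel.fully_methylated)):
            baseline = extremes.baseline_against_normal(sel, normal_mm)
            baseline.to_csv(run_dir / "extreme_baseline.tsv", sep="\t",
                            index_label="site_id")
            st["baseline_classes"] = baseline["classification"].value_counts().to_dict()

        # ---- phyloepigenetic analysis
        st = stage("tree")
        tree_sites = sig.index if len(sig) >= 2 else dm.index[: min(100, len(dm))]
        if len(tree_sites) and mm.n_samples >= 3:
            dmat = phylo.euclidean_distances(mm, tree_sites)
            phylo.write_distances(dmat, run_dir / "distances.tsv")
            newick = phylo.neighbor_joining_tree(dmat)
            (run_dir / "tree.nwk").write_text(newick + "\n")
            dists, p_intra = phylo.intra_group_distances(dmat, groups)
            st["n_sites_used"] = len(tree_sites)
            st["pair_counts"] = {g: len(v) for g, v in dists.items()}
            st["intra_group_p"] = p_intra
            st["mean_intra"] = {g: float(v.mean()) for g, v in dists.items()}
        else:
            st["skipped"] = "not enough significant sites or samples"

        # ---- survival / score screens + panel selection
        st = stage("panel")
        candidates = list(
            sig.reindex(sig["p_value"].sort_values().index)
            .head(cfg.max_panel_candidates).index
        )
        if len(candidates) >= 1:
            beta_cand = mm.beta.loc[candidates]
            meta = labeled.set_index("sample_id").loc[mm.samples]
            assoc_rows = {}
            for sid in candidates:
                assoc_rows[sid] = panel.survival_association(
                    beta_cand.loc[sid], meta["survival_years"],
                    meta["deceased_of_disease"])
            assoc = pd.DataFrame(assoc_rows).T
            assoc.to_csv(run_dir / "survival_associations.tsv", sep="\t",
                         index_label="site_id")
            st["n_survival_assoc"] = int(
                (pd.to_numeric(assoc["logrank_p"], errors="coerce") < 0.05).sum())
            score_corr = panel.correlate_with_score(
                beta_cand, meta["ssign_score"].to_numpy())
            score_corr.to_csv(run_dir / "score_correlations.tsv", sep="\t",
                              index_label="site_id")
            st["n_score_correlated"] = int(score_corr["selected"].sum())
            model = panel.stepwise_panel_selection(
                mm.beta, groups, candidates, cfg.max_k, cfg.panel_mode)
            with open(run_dir / "panel.json", "w") as fh:
                json.dump(model.to_dict(), fh, indent=2)
            st["panel_size"] = len(model.ordered_sites)
            st["final_auc"] = model.final_auc
            st["auc_trace"] = model.cumulative_auc

            # ---- all-comer stratification on the panel sites
            st = stage("stratification")
            strat = panel.stratify_all_comers(
                mm.beta.loc[model.ordered_sites], scores=meta["ssign_score"],
                k=min(cfg.cluster_k, mm.n_samples))
            strat["clusters"].to_csv(run_dir / "clusters.tsv", sep="\t",
                                     index_label="sample_id", header=True)
            st["cluster_sizes"] = strat["clusters"].value_counts().sort_index().to_dict()
            st["median_score_per_cluster"] = strat.get("median_score_per_cluster")
            st["score_p_value"] = strat.get("score_p_value")
        else:
            st["skipped"] = "no significant candidate sites"
            stage("stratification")["skipped"] = "no panel"
    except Exception as exc:
        failed_stage = list(report["stages"])[-1] if report["stages"] else "setup"
        logger.error("stage %s failed: %s", failed_stage, exc)
        report["failed_stage"] = failed_stage
        report["error"] = str(exc)
        with open(run_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        raise RuntimeError(f"pipeline failed at stage '{failed_stage}': {exc}") from exc

    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    report["run_dir"] = str(run_dir)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return list(obj)
    return str(obj)
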