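"""Synthetic RRBS cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-group tumor methylation study: per-CpG baseline
methylation drawn from a bimodal mixture (most CpGs are nearly unmethylated
or nearly fully methylated, a minority intermediate), per-sample read depth
from an overdispersed negative-binomial-like count model, methylated read
counts from a beta-binomial around the group mean, a planted differential
signal at a chosen fraction of sites (the short-term-survivor group mean
shifted by +/- ``effect_delta`` on the probability scale, clipped to [0,1]),
group-specific exponential survival times with administrative censoring,
pathologic covariates confined to the low-risk prognostic stratum
(SSIGN score 0-3), a toy gene model with histone-mark peak tracks, and an
expression table with planted methylation-expression correlations.

Default group sizes (22 long-term vs 14 short-term survivors), coverage
(mean 30x), hypermethylated fraction of planted sites (0.77) and group
median survivals (9.5 vs 2.5 years) mirror the discovery-cohort design the
pipeline was built around; site count defaults to a desk-scale 5000.

All randomness derives from one integer seed.  Each quantity is drawn from
its own named substream (``numpy`` Generator seeded with (seed, stream-id))
so adding a field never shifts other draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MethylationMatrix, chrom_sort_key, site_id

# fixed substream ids; append only, never renumber
_STREAMS = {
    "baseline": 1,
    "dm_sites": 2,
    "coverage": 3,
    "meth_counts": 4,
    "survival": 5,
    "clinical": 6,
    "genes": 7,
    "landscape": 8,
    "expression": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class SimulationConfig:
    n_lts: int = 22
    n_sts: int = 14
    n_sites: int = 5000
    frac_dm: float = 0.02
    effect_delta: float = 0.15
    hyper_fraction: float = 0.77
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0  # NB size; var = mu + mu^2/size
    baseline_mixture: tuple[float, float, float] = (0.45, 0.10, 0.45)
    methylation_precision: float = 30.0  # beta-binomial concentration
    survival_scale_lts: float = 13.7  # exponential scale (median 9.5 y)
    survival_scale_sts: float = 3.6  # exponential scale (median 2.5 y)
    censor_years: float = 25.0
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 60
    n_expr_pairs: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_lts < 2 or self.n_sts < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0 <= self.frac_dm <= 1 and 0 <= self.hyper_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if not (0 <= self.effect_delta <= 1):
            raise ValueError("effect_delta must be in [0, 1]")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        w = np.asarray(self.baseline_mixture, dtype=float)
        if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("baseline_mixture must be 3 non-negative weights summing to 1")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    methylation: MethylationMatrix
    samples: pd.DataFrame  # clinical table, one row per sample
    truth_dm_sites: pd.DataFrame  # site_id index, column signed delta
    gene_model: pd.DataFrame  # chrom, start, end, name, strand (BED-like)
    landscape: dict[str, pd.DataFrame]  # mark -> BED3 intervals
    expression: pd.DataFrame  # genes x samples
    truth_expr_pairs: pd.DataFrame  # site_id, gene, sign
    group_means: pd.DataFrame = field(default=None)  # per-site lts/sts truth


# SSIGN-consistent covariate combinations per target score; all stay in the
# 0-3 low-risk stratum under the default point table.
_SCORE_COMBOS = {
    0: [("pT1", 3.0, 2, False), ("pT1", 4.0, 1, False)],
    1: [("pT2", 3.5, 2, False), ("pT2", 4.5, 1, False)],
    2: [("pT1", 6.0, 2, False), ("pT3a", 4.0, 2, False)],
    3: [("pT1", 6.0, 3, False), ("pT3a", 4.0, 3, False)],
}
# empirical cohort-1 SSIGN distributions (scores 0/1/2/3)
_SCORE_PROBS = {"LTS": np.array([2, 2, 4, 14]) / 22, "STS": np.array([3, 4, 2, 5]) / 14}


def _draw_clinical(cfg: SimulationConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, "clinical")
    rng_surv = _rng(cfg.seed, "survival")
    rows = []
    groups = ["LTS"] * cfg.n_lts + ["STS"] * cfg.n_sts
    scales = {"LTS": cfg.survival_scale_lts, "STS": cfg.survival_scale_sts}
    for i, group in enumerate(groups):
        score = int(rng.choice(4, p=_SCORE_PROBS[group]))
        pt, size, grade, necrosis = _SCORE_COMBOS[score][int(rng.integers(len(_SCORE_COMBOS[score])))]
        death_time = rng_surv.exponential(scales[group])
        deceased = death_time < cfg.censor_years
        years = min(death_time, cfg.censor_years)
        rows.append({
            "sample_id": f"{group}_{i:03d}",
            "sex": "male" if rng.random() < 0.7 else "female",
            "age_years": float(np.round(rng.normal(68, 8), 1)),
            "pt_stage": pt,
            "pn_stage": "pN0",
            "pm_stage": "pM0",
            "tumor_size_cm": size,
            "grade": grade,
            "necrosis": necrosis,
            "survival_years": float(np.round(years, 3)),
            "deceased_of_disease": bool(deceased),
            "group": group,
        })
    return pd.DataFrame(rows)


def _draw_sites(cfg: SimulationConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, "baseline")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_idx = rng.integers(cfg.n_chroms, size=cfg.n_sites)
    pos = rng.integers(1, cfg.chrom_length, size=cfg.n_sites)
    # baseline mixture: beta shapes concentrate near 0 and 1
    comp = rng.choice(3, size=cfg.n_sites, p=np.asarray(cfg.baseline_mixture, float))
    shapes = [(2.0, 18.0), (5.0, 5.0), (18.0, 2.0)]
    a = np.array([shapes[c][0] for c in comp])
    b = np.array([shapes[c][1] for c in comp])
    pi = rng.beta(a, b)
    df = pd.DataFrame({
        "chrom": [chroms[i] for i in chrom_idx],
        "pos": pos,
        "baseline": pi,
    })
    df = df.drop_duplicates(subset=["chrom", "pos"])
    df = df.sort_values(
        ["chrom", "pos"],
        key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c,
    ).reset_index(drop=True)
    df.index = [site_id(c, p) for c, p in zip(df["chrom"], df["pos"])]
    return df


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort; bitwise deterministic in the seed."""
    cfg = config
    cfg.validate()

    sites = _draw_sites(cfg)
    n_sites = len(sites)
    pi = sites["baseline"].to_numpy()

    # plant group effects; sites are drawn preferentially where the full
    # shift fits inside [0, 1] so the planted |delta beta| stays directly
    # interpretable against the selection cutoff (clipping is the fallback
    # when a config leaves no feasible sites)
    rng_dm = _rng(cfg.seed, "dm_sites")
    n_dm = int(round(cfg.frac_dm * n_sites))
    n_hyper = int(round(n_dm * cfg.hyper_fraction))
    n_hypo = n_dm - n_hyper
    order = rng_dm.permutation(n_sites)
    hyper_pool = [i for i in order if pi[i] + cfg.effect_delta <= 1.0]
    hypo_pool = [i for i in order if pi[i] - cfg.effect_delta >= 0.0]
    hyper_idx = hyper_pool[:n_hyper]
    hypo_idx = [i for i in hypo_pool if i not in set(hyper_idx)][:n_hypo]
    spill = [i for i in order
             if i not in set(hyper_idx) and i not in set(hypo_idx)]
    hyper_idx += spill[: n_hyper - len(hyper_idx)]
    spill = [i for i in spill if i not in set(hyper_idx)]
    hypo_idx += spill[: n_hypo - len(hypo_idx)]
    dm_idx = np.array(hyper_idx + hypo_idx, dtype=int)
    signs = np.array([1.0] * len(hyper_idx) + [-1.0] * len(hypo_idx))
    mean_lts = pi.copy()
    mean_sts = pi.copy()
    if len(dm_idx):
        mean_sts[dm_idx] = np.clip(mean_sts[dm_idx] + signs * cfg.effect_delta, 0.0, 1.0)
    realized_delta = mean_sts[dm_idx] - mean_lts[dm_idx]
    # a planted site whose shift fully clips away is not a true effect
    nonzero = realized_delta != 0
    truth = pd.DataFrame(
        {"delta": realized_delta[nonzero]},
        index=sites.index[dm_idx[nonzero]],
    ).sort_index()

    clinical = _draw_clinical(cfg)
    n_samples = len(clinical)
    group_mean = np.where(
        (clinical["group"] == "STS").to_numpy()[None, :],
        mean_sts[:, None], mean_lts[:, None],
    )

    # overdispersed coverage, floor at 1 read
    rng_cov = _rng(cfg.seed, "coverage")
    r = cfg.coverage_dispersion
    p_nb = r / (r + cfg.coverage_mean)
    coverage = rng_cov.negative_binomial(r, p_nb, size=(n_sites, n_samples))
    coverage = np.maximum(coverage, 1)

    # beta-binomial methylated counts around the group mean
    rng_m = _rng(cfg.seed, "meth_counts")
    s = cfg.methylation_precision
    a = np.clip(group_mean * s, 1e-6, None)
    b = np.clip((1.0 - group_mean) * s, 1e-6, None)
    p_site = rng_m.beta(a, b)
    meth = rng_m.binomial(coverage, p_site)

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = meth / coverage
    beta_df = pd.DataFrame(beta, index=sites.index, columns=clinical["sample_id"])
    cov_df = pd.DataFrame(coverage, index=sites.index, columns=clinical["sample_id"])
    mm = MethylationMatrix(beta=beta_df, coverage=cov_df)

    gene_model = _draw_genes(cfg)
    landscape = _draw_landscape(cfg, gene_model)
    expression, truth_pairs = _draw_expression(cfg, beta_df, gene_model)

    group_means = pd.DataFrame(
        {"mean_lts": mean_lts, "mean_sts": mean_sts}, index=sites.index
    )
    return SyntheticCohort(
        config=cfg,
        methylation=mm,
        samples=clinical,
        truth_dm_sites=truth,
        gene_model=gene_model,
        landscape=landscape,
        expression=expression,
        truth_expr_pairs=truth_pairs,
        group_means=group_means,
    )


def _draw_genes(cfg: SimulationConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, "genes")
    rows = []
    for g in range(cfg.n_genes):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - 60_000))
        length = int(rng.integers(5_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"chrom": chrom, "start": start, "end": start + length,
                     "name": f"GENE{g:03d}", "strand": strand})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _draw_landscape(cfg: SimulationConfig, genes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """H3K4me3 peaks over a subset of TSSs; enhancer marks elsewhere."""
    rng = _rng(cfg.seed, "landscape")
    k4me3, k4me1, k27ac = [], [], []
    for _, g in genes.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        if rng.random() < 0.7:  # promoter peak
            k4me3.append((g["chrom"], max(0, tss - 1000), tss + 1000))
    n_enh = cfg.n_genes
    for _ in range(n_enh):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - 3_000))
        width = int(rng.integers(500, 2_500))
        k4me1.append((chrom, start, start + width))
        if rng.random() < 0.6:  # active enhancer also carries H3K27ac
            k27ac.append((chrom, start, start + width))
    cols = ["chrom", "start", "end"]
    return {
        "H3K4me3": pd.DataFrame(k4me3, columns=cols),
        "H3K4me1": pd.DataFrame(k4me1, columns=cols),
        "H3K27ac": pd.DataFrame(k27ac, columns=cols),
    }


def _draw_expression(
    cfg: SimulationConfig, beta: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = _rng(cfg.seed, "expression")
    n_samples = beta.shape[1]
    expr = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(len(genes), n_samples)),
        index=genes["name"].tolist(), columns=beta.columns,
    )
    n_pairs = min(cfg.n_expr_pairs, len(genes), beta.shape[0])
    site_pick = rng.choice(beta.shape[0], size=n_pairs, replace=False)
    gene_pick = rng.choice(len(genes), size=n_pairs, replace=False)
    signs = np.where(rng.random(n_pairs) < 0.5, 1.0, -1.0)
    pairs = []
    for si, gi, sign in zip(site_pick, gene_pick, signs):
        sid = beta.index[si]
        gname = genes["name"].iloc[gi]
        b = beta.iloc[si].to_numpy(dtype=float)
        b = np.where(np.isnan(b), np.nanmean(b), b)
        expr.loc[gname] = 8.0 + sign * 4.0 * (b - b.mean()) + rng.normal(0, 0.3, n_samples)
        pairs.append({"site_id": sid, "gene": gname, "sign": int(sign)})
    return expr, pd.DataFrame(pairs)


def generate_normal_matrix(
    cohort: SyntheticCohort, n_normals: int = 2, subsample: float = 0.8
) -> MethylationMatrix:
    """Normal-tissue companion samples for the cohort's sites.

    Betas are drawn around the per-site baseline (pre-effect) methylation
    with the cohort's coverage and precision models; each normal sample
    covers a random ``subsample`` fraction of sites, emulating the coverage
    attrition between tumor and normal sequencing runs.  Deterministic in
    the cohort's seed (dedicated substream).
    """
    cfg = cohort.config
    rng = np.random.default_rng([cfg.seed, 101])
    pi = cohort.group_means["mean_lts"].to_numpy()  # baseline = LTS mean
    n_sites = len(pi)
    r = cfg.coverage_dispersion
    p_nb = r / (r + cfg.coverage_mean)
    coverage = rng.negative_binomial(r, p_nb, size=(n_sites, n_normals))
    coverage = np.maximum(coverage, 1)
    covered = rng.random((n_sites, n_normals)) < subsample
    coverage = np.where(covered, coverage, 0)
    s = cfg.methylation_precision
    a = np.clip(pi * s, 1e-6, None)[:, None]
    b = np.clip((1.0 - pi) * s, 1e-6, None)[:, None]
    p_site = rng.beta(np.broadcast_to(a, coverage.shape),
                      np.broadcast_to(b, coverage.shape))
    meth = rng.binomial(coverage, p_site)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)
    cols = [f"NORMAL_{i:02d}" for i in range(n_normals)]
    idx = cohort.methylation.beta.index
    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=cols),
        coverage=pd.DataFrame(coverage, index=idx, columns=cols),
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort as plain-text files; returns a manifest dict.

    Emits one bismark-style coverage file per sample, one BED3 per histone
    mark, a gene-model BED6, a clinical TSV, an expression TSV, truth tables,
    and the generating config as JSON.  Round-trips through the readers in
    ``methylpipe.io`` up to count quantization.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"coverage_files": [], "bed_files": {}, "tables": {}}

    mm = cohort.methylation
    sites = mm.sites()
    for sample in mm.samples:
        cov = mm.coverage[sample].to_numpy()
        beta = mm.beta[sample].to_numpy(dtype=float)
        meth = np.where(cov > 0, np.round(np.nan_to_num(beta) * cov), 0).astype(int)
        unmeth = cov - meth
        pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), 0.0)
        out = pd.DataFrame({
            "chrom": sites["chrom"], "start": sites["pos"], "end": sites["pos"],
            "pct": np.round(pct, 6), "meth": meth, "unmeth": unmeth,
        })
        path = directory / f"{sample}.cov"
        out.to_csv(path, sep="\t", header=False, index=False)
        manifest["coverage_files"].append(str(path))

    for mark, bed in cohort.landscape.items():
        path = directory / f"{mark}.bed"
        bed.to_csv(path, sep="\t", header=False, index=False)
        manifest["bed_files"][mark] = str(path)

    genes_path = directory / "genes.bed"
    gm = cohort.gene_model.copy()
    gm["score"] = 0
    gm[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        genes_path, sep="\t", header=False, index=False)
    manifest["bed_files"]["genes"] = str(genes_path)

    for name, df, kw in [
        ("clinical", cohort.samples, {"index": False}),
        ("expression", cohort.expression, {"index_label": "gene"}),
        ("truth_dm_sites", cohort.truth_dm_sites, {"index_label": "site_id"}),
        ("truth_expr_pairs", cohort.truth_expr_pairs, {"index": False}),
    ]:
        path = directory / f"{name}.tsv"
        df.to_csv(path, sep="\t", **kw)
        manifest["tables"][name] = str(path)

    cfg_path = directory / "sim_config.json"
    with open(cfg_path, "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2, default=list)
    manifest["tables"]["config"] = str(cfg_path)

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
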