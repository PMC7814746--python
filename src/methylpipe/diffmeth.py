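"""Differential methylation between survivor groups.

Four stages: a global per-sample methylation comparison (rank-sum on
per-sample mean beta), per-CpG differential calls under the dual cutoff
(two-sided t test p < 0.01 and |delta beta| >= 0.1, where delta beta is the
short-term minus long-term group mean), cross-cohort sign concordance of
differential sites, and aggregation of runs of significant CpGs into
differentially methylated regions.

Missing values (zero-coverage cells) are excluded pairwise: a site is
testable when each group retains at least two non-missing betas.  No
multiple-testing correction enters the selection rule; a BH-FDR column is
carried alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MethylationMatrix, chrom_sort_key, split_site_id
from .stats import bh_fdr, wilcoxon_rank_sum

DM_COLUMNS = [
    "chrom", "pos", "mean_beta_lts", "mean_beta_sts", "delta_beta",
    "t_statistic", "p_value", "n_lts_used", "n_sts_used",
    "significant", "direction",
]


def _split_groups(mm: MethylationMatrix, group_labels) -> tuple[list[str], list[str]]:
    """Group labels: mapping sample -> {'LTS','STS'} (or any two labels)."""
    labels = pd.Series(group_labels)
    labels = labels.reindex(mm.samples)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without group label: {missing}")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    # LTS is the reference group when labels are the standard names
    if set(uniq) == {"LTS", "STS"}:
        ref, alt = "LTS", "STS"
    else:
        ref, alt = uniq[0], uniq[1]
    return (
        list(labels.index[labels == ref]),
        list(labels.index[labels == alt]),
    )


@dataclass
class GlobalTestResult:
    per_sample_means: pd.Series
    p_value: float
    median_lts: float
    median_sts: float
    direction: str  # 'hyper' when STS median exceeds LTS median


def global_methylation_test(mm: MethylationMatrix, group_labels) -> GlobalTestResult:
    """Compare per-sample mean beta between the two groups (rank-sum)."""
    lts, sts = _split_groups(mm, group_labels)
    if len(lts) < 2 or len(sts) < 2:
        raise ValueError("each group needs at least 2 samples")
    means = mm.beta.mean(axis=0, skipna=True)
    _, p = wilcoxon_rank_sum(means[lts], means[sts])
    med_l = float(means[lts].median())
    med_s = float(means[sts].median())
    return GlobalTestResult(
        per_sample_means=means,
        p_value=p,
        median_lts=med_l,
        median_sts=med_s,
        direction="hyper" if med_s > med_l else ("hypo" if med_s < med_l else "equal"),
    )


def test_dmcpgs(
    mm: MethylationMatrix,
    group_labels,
    p_cutoff: float = 0.01,
    delta_cutoff: float = 0.1,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-CpG two-sided t tests with the dual significance cutoff.

    Returns (records, untestable_sites).  One row per testable site with
    group means, delta beta (STS - LTS), Welch t by default (Student's with
    ``equal_var=True``), raw p, a BH-FDR column, and the significance flag
    ``p < p_cutoff and |delta| >= delta_cutoff``.  Sites with fewer than two
    non-missing betas in either group are reported in the second element.
    """
    lts, sts = _split_groups(mm, group_labels)
    a = mm.beta[lts].to_numpy(dtype=float)
    b = mm.beta[sts].to_numpy(dtype=float)
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    untestable = mm.beta.index[~testable]

    a_t = a[testable]
    b_t = b[testable]
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant sites trigger a precision warning; their p is set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(b_t, a_t, axis=1, equal_var=equal_var, nan_policy="omit")
        mean_a = np.nanmean(a_t, axis=1)
        mean_b = np.nanmean(b_t, axis=1)
    delta = mean_b - mean_a
    t_stat = np.asarray(res.statistic, dtype=float)
    p_val = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance with equal means: no evidence, p = 1
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)

    sig = (p_val < p_cutoff) & (np.abs(delta) >= delta_cutoff)
    idx = mm.beta.index[testable]
    parts = [split_site_id(s) for s in idx]
    records = pd.DataFrame({
        "chrom": [p_[0] for p_ in parts],
        "pos": [p_[1] for p_ in parts],
        "mean_beta_lts": mean_a,
        "mean_beta_sts": mean_b,
        "delta_beta": delta,
        "t_statistic": t_stat,
        "p_value": p_val,
        "q_value": bh_fdr(p_val),
        "n_lts_used": n_a[testable],
        "n_sts_used": n_b[testable],
        "significant": sig,
        "direction": np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "none")),
    }, index=idx)
    return records, untestable


def cross_cohort_concordance(
    dm_a: pd.DataFrame, dm_b: pd.DataFrame, max_distance: int = 1000
) -> tuple[pd.DataFrame, float]:
    """Match each site of cohort B to its nearest cohort-A site and compare signs.

    Matching is on the same chromosome within ``max_distance`` bp (ties to
    the smaller position); ``max_distance=0`` matches exact shared positions
    only.  Returns (pairs table, fraction of matched pairs with the same
    delta-beta sign).
    """
    if dm_a.empty or dm_b.empty:
        raise ValueError("both DM tables must be nonempty")
    pairs = []
    for chrom, grp_b in dm_b.groupby("chrom", sort=False):
        grp_a = dm_a[dm_a["chrom"] == chrom]
        if grp_a.empty:
            continue
        pos_a = grp_a["pos"].to_numpy()
        order = np.argsort(pos_a, kind="stable")
        pos_a_sorted = pos_a[order]
        for sid_b, row_b in grp_b.iterrows():
            p = row_b["pos"]
            j = np.searchsorted(pos_a_sorted, p)
            best = None
            for k in (j - 1, j):
                if 0 <= k < len(pos_a_sorted):
                    d = abs(int(pos_a_sorted[k]) - int(p))
                    # ties broken toward the smaller position (k-1 first)
                    if d <= max_distance and (best is None or d < best[0]):
                        best = (d, k)
            if best is not None:
                ia = grp_a.index[order[best[1]]]
                pairs.append({
                    "site_b": sid_b, "site_a": ia, "distance": best[0],
                    "delta_a": dm_a.loc[ia, "delta_beta"],
                    "delta_b": row_b["delta_beta"],
                })
    pairs_df = pd.DataFrame(pairs, columns=["site_b", "site_a", "distance", "delta_a", "delta_b"])
    if pairs_df.empty:
        return pairs_df, float("nan")
    consistent = np.sign(pairs_df["delta_a"]) == np.sign(pairs_df["delta_b"])
    return pairs_df, float(consistent.mean())


REGION_COLUMNS = ["chrom", "start_pos", "end_pos", "n_sites", "dominant_direction", "linked_gene"]


def call_dm_regions(
    dm: pd.DataFrame,
    min_sites: int = 6,
    max_gap: int = 5000,
    gene_model: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Chain significant CpGs into differentially methylated regions.

    Single-linkage chaining on each chromosome: consecutive significant
    sites at most ``max_gap`` bp apart join a run; runs with at least
    ``min_sites`` members are emitted.  The dominant direction is the
    majority delta-beta sign (ties called by the summed delta).  When a
    gene model is supplied, each region is linked to the gene whose span
    overlaps it most (1-based region against 0-based half-open gene spans).
    """
    sig = dm[dm["significant"]].copy()
    regions = []
    for chrom in sorted(sig["chrom"].unique(), key=chrom_sort_key):
        grp = sig[sig["chrom"] == chrom].sort_values("pos")
        pos = grp["pos"].to_numpy()
        deltas = grp["delta_beta"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n < min_sites:
                continue
            d = deltas[s:e + 1]
            n_hyper = int((d > 0).sum())
            n_hypo = int((d < 0).sum())
            if n_hyper != n_hypo:
                direction = "hyper" if n_hyper > n_hypo else "hypo"
            else:
                direction = "hyper" if d.sum() >= 0 else "hypo"
            regions.append({
                "chrom": chrom,
                "start_pos": int(pos[s]),
                "end_pos": int(pos[e]),
                "n_sites": n,
                "dominant_direction": direction,
                "linked_gene": _link_gene(chrom, int(pos[s]), int(pos[e]), gene_model),
            })
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


def _link_gene(chrom: str, start_pos: int, end_pos: int, gene_model: pd.DataFrame | None):
    if gene_model is None:
        return None
    genes = gene_model[gene_model["chrom"] == chrom]
    best_name, best_ov = None, 0
    for _, g in genes.iterrows():
        # region is 1-based inclusive, gene span 0-based half-open
        ov = min(end_pos, int(g["end"])) - max(start_pos - 1, int(g["start"]))
        if ov > best_ov:
            best_name, best_ov = g["name"], ov
    return best_name


def write_dm_table(dm: pd.DataFrame, path) -> None:
    dm.to_csv(path, sep="\t", index_label="site_id")


def write_dm_regions_bed(regions: pd.DataFrame, path, max_gap: int | None = None) -> None:
    """BED6 with the member count in the score column (0-based half-open)."""
    with open(path, "w") as fh:
        if max_gap is not None:
            fh.write(f"# max_gap={max_gap}\n")
        for _, r in regions.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start_pos'] - 1}\t{r['end_pos']}\t"
                f"{r['linked_gene'] or '.'}\t{r['n_sites']}\t"
                f"{'+' if r['dominant_direction'] == 'hyper' else '-'}\n"
            )
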