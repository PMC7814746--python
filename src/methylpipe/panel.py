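"""Integration of methylation with expression, survival, and prognostic score,
and greedy CpG-panel selection by stepwise recursive partitioning.

Per-site screens: Pearson correlation between a CpG's beta values and its
gene's expression; median-split survival association (two-sided log-rank
test plus a Cox proportional-hazards ratio for the high-methylation arm,
samples at exactly the median going to the low arm); Spearman rank
correlation against the integer prognostic score.  Raw p-value cutoffs
select sites, matching the screening design; BH-FDR columns are emitted for
reference.

Panel selection is greedy forward search: at each step every unchosen
candidate CpG is tried by fitting a small CART classifier (Gini impurity,
max depth = current panel size + 1, minimum leaf size 2) on the chosen
sites plus the candidate and scoring the resubstitution AUROC of its class
probabilities; the best candidate joins the panel (ties broken toward the
larger between-class |delta beta|, then genomic order).  Selection stops at
AUROC 1 or ``max_k``.  Resubstitution AUROC on small cohorts is optimistic;
a leave-one-out mode is available and reported alongside when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import split_site_id, chrom_sort_key


# ---------------------------------------------------------------- screens

def map_platform_overlap(
    rrbs_sites, manifest: pd.DataFrame, tolerance: int = 0
) -> pd.DataFrame:
    """Match array probes to RRBS CpG positions.

    ``manifest`` needs probe_id, chrom, pos columns (1-based).  Matching is
    exact on (chrom, pos); ``tolerance=1`` additionally accepts a +/-1 bp
    offset (strand-collapsed probes), preferring the exact hit.  Each probe
    matches at most one site.
    """
    sites = pd.Index(rrbs_sites)
    lookup = {split_site_id(s): s for s in sites}
    rows = []
    used: set = set()
    for _, probe in manifest.iterrows():
        key = (probe["chrom"], int(probe["pos"]))
        hit = None
        offsets = [0] if tolerance == 0 else [0, -1, 1]
        for off in offsets:
            cand = lookup.get((key[0], key[1] + off))
            if cand is not None and cand not in used:
                hit = (cand, off)
                break
        if hit is not None:
            used.add(hit[0])
            rows.append({"probe_id": probe["probe_id"], "site_id": hit[0],
                         "offset": hit[1]})
    return pd.DataFrame(rows, columns=["probe_id", "site_id", "offset"])


def methylation_expression_correlation(beta_row, expression_row) -> dict:
    """Pearson correlation between one CpG's betas and one gene's expression."""
    x = np.asarray(beta_row, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p_value": np.nan, "direction": "undefined",
                "n": int(ok.sum()), "note": "zero variance"}
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p),
            "direction": "positive" if r > 0 else "negative",
            "n": int(ok.sum()), "note": ""}


def survival_association(beta_row, survival_years, event_flags) -> dict:
    """Median-split survival association for one CpG.

    Dichotomizes samples at the median beta (ties to the low arm), runs a
    two-sided log-rank test between arms and fits a Cox model for the
    high-methylation arm's hazard ratio.  The favorable methylation state
    is 'hypo' when HR > 1 (hypermethylation hurts) and 'hyper' otherwise.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    x = np.asarray(beta_row, dtype=float)
    t = np.asarray(survival_years, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    ok = ~np.isnan(x)
    x, t, e = x[ok], t[ok], e[ok]
    if e.sum() == 0:
        return {"hazard_ratio": np.nan, "logrank_p": np.nan,
                "favorable_state": "undefined", "split_value": np.nan,
                "note": "all samples censored"}
    med = float(np.median(x))
    high = x > med  # ties to the low arm
    if high.sum() < 2 or (~high).sum() < 2:
        return {"hazard_ratio": np.nan, "logrank_p": np.nan,
                "favorable_state": "undefined", "split_value": med,
                "note": "fewer than 2 samples per arm"}
    lr = logrank_test(t[high], t[~high], event_observed_A=e[high],
                      event_observed_B=e[~high])
    df = pd.DataFrame({"time": t, "event": e.astype(int), "high": high.astype(int)})
    cph = CoxPHFitter(penalizer=1e-6)
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    return {
        "hazard_ratio": hr,
        "logrank_p": float(lr.p_value),
        "favorable_state": "hypo" if hr > 1 else "hyper",
        "split_value": med,
        "note": "",
    }


def correlate_with_score(
    beta_rows: pd.DataFrame, scores, p_cutoff: float = 0.01
) -> pd.DataFrame:
    """Spearman correlation of each CpG against the integer prognostic score.

    Ties are handled by midranks.  Returns all sites with rho, p, and the
    ``selected`` flag (p < p_cutoff); a constant score vector is an error.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(s) == 0:
        raise ValueError("score vector is constant")
    rows = []
    for sid, row in beta_rows.iterrows():
        x = row.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            rows.append({"rho": np.nan, "p_value": np.nan, "selected": False,
                         "note": "undefined (constant or too few values)"})
            continue
        rho, p = sps.spearmanr(x[ok], s[ok])
        rows.append({"rho": float(rho), "p_value": float(p),
                     "selected": bool(p < p_cutoff), "note": ""})
    return pd.DataFrame(rows, index=beta_rows.index)


# ---------------------------------------------------------------- AUROC

def auroc(scores, binary_labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Mann-Whitney formulation on midranks; requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)  # midranks
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------- panel

@dataclass
class PanelModel:
    ordered_sites: list[str]
    thresholds: dict[str, float]
    cumulative_auc: list[float]
    final_auc: float
    mode: str = "resubstitution"
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ordered_sites": self.ordered_sites,
            "thresholds": self.thresholds,
            "cumulative_auc": self.cumulative_auc,
            "final_auc": self.final_auc,
            "mode": self.mode,
            "skipped": self.skipped,
        }


def _fit_tree(X: np.ndarray, y: np.ndarray, depth: int):
    from sklearn.tree import DecisionTreeClassifier

    clf = DecisionTreeClassifier(
        criterion="gini", max_depth=depth, min_samples_leaf=2, random_state=0
    )
    clf.fit(X, y)
    return clf

def _panel_auc(X: np.ndarray, y: np.ndarray, depth: int, mode: str) -> float:
    if mode == "loo":
        n = len(y)
        probs = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            if len(np.unique(y[mask])) < 2:
                probs[i] = 0.5
                continue
            clf = _fit_tree(X[mask], y[mask], depth)
            probs[i] = clf.predict_proba(X[i:i + 1])[0, list(clf.classes_).index(1)]
    else:
        clf = _fit_tree(X, y, depth)
        probs = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
    return auroc(probs, y)


def _genomic_order_key(sid: str):
    chrom, pos = split_site_id(sid)
    return (chrom_sort_key(chrom), pos)


def stepwise_panel_selection(
    beta_matrix: pd.DataFrame,
    labels,
    candidate_sites,
    max_k: int = 10,
    mode: str = "resubstitution",
) -> PanelModel:
    """Greedy forward CpG-panel selection with a CART base learner.

    ``beta_matrix`` is sites x samples; ``labels`` maps samples to the
    positive (short-term survivor) class via truthy values, or to
    'STS'/'LTS' strings.  Missing betas are mean-imputed per site for the
    classifier only (the screens above never impute).  Constant candidates
    are skipped with a note.  Returns the ordered panel, per-site first
    split thresholds of the final tree, and the cumulative AUROC trace.
    """
    samples = list(beta_matrix.columns)
    lab = pd.Series(labels).reindex(samples)
    if lab.isna().any():
        raise ValueError("every sample needs a label")
    if lab.dtype == object:
        y = (lab == "STS").to_numpy()
    else:
        y = lab.astype(bool).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    candidates = [s for s in candidate_sites if s in beta_matrix.index]
    if not candidates:
        raise ValueError("no candidate sites present in the matrix")

    def site_vector(sid):
        v = beta_matrix.loc[sid].to_numpy(dtype=float)
        if np.isnan(v).any():
            v = np.where(np.isnan(v), np.nanmean(v), v)
        return v

    vectors = {s: site_vector(s) for s in candidates}
    skipped = [s for s in candidates if np.ptp(vectors[s]) == 0]
    pool = [s for s in candidates if s not in set(skipped)]
    # tie-break table: larger |delta beta| between class means, then position
    delta = {s: abs(vectors[s][y].mean() - vectors[s][~y].mean()) for s in pool}

    chosen: list[str] = []
    trace: list[float] = []
    while pool and len(chosen) < max_k:
        depth = len(chosen) + 1
        best = None
        for s in pool:
            X = np.column_stack([vectors[c] for c in chosen + [s]])
            auc = _panel_auc(X, y, depth, mode)
            key = (-auc, -delta[s], _genomic_order_key(s))
            if best is None or key < best[0]:
                best = (key, s, auc)
        _, s_best, auc_best = best
        chosen.append(s_best)
        pool.remove(s_best)
        trace.append(auc_best)
        if auc_best >= 1.0 - 1e-12:
            break

    # thresholds from the final fitted partition (first split per feature)
    X = np.column_stack([vectors[c] for c in chosen])
    clf = _fit_tree(X, y, len(chosen))
    thresholds: dict[str, float] = {}
    tree = clf.tree_
    for node in range(tree.node_count):
        f = tree.feature[node]
        if f >= 0 and chosen[f] not in thresholds:
            thresholds[chosen[f]] = float(tree.threshold[node])
    return PanelModel(
        ordered_sites=chosen,
        thresholds=thresholds,
        cumulative_auc=trace,
        final_auc=trace[-1] if trace else float("nan"),
        mode=mode,
        skipped=skipped,
    )


# ---------------------------------------------------------------- stratification

def stratify_all_comers(
    beta_matrix: pd.DataFrame,
    scores=None,
    k: int = 3,
    stage_groups=None,
) -> dict:
    """Cluster samples on panel-site methylation and compare clinical burden.

    Agglomerative clustering (Ward linkage, Euclidean) over samples, cut at
    ``k`` clusters ordered by ascending mean beta (so for k = 3 the labels
    read hypomethylated / intermediate / hypermethylated).  When ``scores``
    are given, reports per-cluster median scores and a Kruskal-Wallis p.
    When binary ``stage_groups`` are given (e.g. stage I/II vs III/IV), the
    cluster x stage contingency is tested with a Pearson chi-square.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    samples = list(beta_matrix.columns)
    n = len(samples)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = beta_matrix.to_numpy(dtype=float).T
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
    result: dict = {"samples": samples}
    if k == 1:
        raw = np.ones(n, dtype=int)
    else:
        Z = linkage(X, method="ward", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
    # order clusters by ascending mean beta: cluster 1 = most hypomethylated
    mean_beta = {c: X[raw == c].mean() for c in np.unique(raw)}
    order = sorted(mean_beta, key=mean_beta.get)
    relabel = {c: i + 1 for i, c in enumerate(order)}
    clusters = pd.Series([relabel[c] for c in raw], index=samples, name="cluster")
    result["clusters"] = clusters
    result["cluster_mean_beta"] = {relabel[c]: float(mean_beta[c]) for c in order}

    if scores is not None:
        s = scores if isinstance(scores, pd.Series) else pd.Series(list(scores), index=samples)
        s = s.reindex(samples)
        med = s.groupby(clusters).median()
        result["median_score_per_cluster"] = med.to_dict()
        groups = [s[clusters == c].dropna() for c in sorted(clusters.unique())]
        if len(groups) >= 2 and all(len(g) for g in groups):
            result["score_p_value"] = float(sps.kruskal(*groups).pvalue)
        else:
            result["score_p_value"] = float("nan")
            result["note"] = "score comparison undefined for a single cluster"
    if stage_groups is not None:
        from .stats import pearson_chi2

        g = (stage_groups if isinstance(stage_groups, pd.Series)
             else pd.Series(list(stage_groups), index=samples)).reindex(samples)
        levels = sorted(g.dropna().unique())
        table = np.array([[int(((clusters == c) & (g == lv)).sum()) for lv in levels]
                          for c in sorted(clusters.unique())])
        stat, p, _ = pearson_chi2(table)
        result["stage_table"] = table
        result["stage_p_value"] = p
    return result
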