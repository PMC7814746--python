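"""Regulatory-landscape construction and genomic-feature assignment.

Histone-mark peak sets from normal kidney define the regulatory landscape:
any region under H3K4me3 is a promoter; regions with both H3K4me1 and
H3K27ac but no H3K4me3 are active enhancers; H3K4me1 alone marks poised
enhancers.  Each CpG is then assigned exactly one of four genomic features
with precedence promoter > enhancer > body > intergenic, where "promoter"
is the union of H3K4me3 overlap and strand-aware TSS proximity
(TSS-2000 .. TSS+500 by default) and "body" is any position inside a gene
span.  Enrichment of a differential site set over a background is a
per-feature fold change with a hypergeometric test.

All intervals are 0-based half-open (BED); CpG positions are 1-based and
converted on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac")
FEATURES = ("promoter", "enhancer", "body", "intergenic")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6; returns chrom/start/end (+ name/score/strand if present)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            row = {"chrom": f[0], "start": int(f[1]), "end": int(f[2])}
            if len(f) >= 6:
                row.update({"name": f[3], "score": f[4], "strand": f[5]})
            rows.append(row)
    return pd.DataFrame(rows)


def merge_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping and bookended intervals per chromosome."""
    out = []
    for chrom, grp in bed.groupby("chrom", sort=False):
        ivs = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = None, None
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"malformed interval {chrom}:{s}-{e}")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _build_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
    return trees


@dataclass
class RegulatoryLandscape:
    """Merged per-mark peaks plus the derived mutually exclusive classes."""

    peaks: dict[str, pd.DataFrame]
    derived: pd.DataFrame = field(default=None)  # chrom, start, end, cls
    _trees: dict = field(default=None, repr=False)

    def marks_at(self, chrom: str, pos: int) -> set[str]:
        """Marks overlapping the 1-based position ``pos``."""
        p0 = pos - 1
        found = set()
        for mark in MARKS:
            tree = self._trees.get(mark, {}).get(chrom)
            if tree is not None and tree.overlaps_point(p0):
                found.add(mark)
        return found

    def classify(self, chrom: str, pos: int) -> str | None:
        """Landscape class at a 1-based position; None when unmarked."""
        marks = self.marks_at(chrom, pos)
        if "H3K4me3" in marks:
            return "promoter"
        if "H3K4me1" in marks and "H3K27ac" in marks:
            return "active_enhancer"
        if "H3K4me1" in marks:
            return "poised_enhancer"
        return None


def classify_landscape(peaks: dict[str, pd.DataFrame]) -> RegulatoryLandscape:
    """Merge each mark's peaks and derive the exclusive regulatory classes.

    The derived table partitions marked genomic space into promoter /
    active_enhancer / poised_enhancer segments by the precedence
    H3K4me3 > (H3K4me1 & H3K27ac) > H3K4me1-only.
    """
    merged = {m: merge_intervals(peaks[m]) if m in peaks and len(peaks[m]) else
              pd.DataFrame(columns=["chrom", "start", "end"]) for m in MARKS}
    trees = {m: _build_trees(merged[m]) for m in MARKS}

    # boundary sweep per chromosome to emit explicit class segments
    segments = []
    chroms = sorted({c for m in MARKS for c in merged[m]["chrom"].unique()})
    for chrom in chroms:
        bounds = sorted({
            b for m in MARKS
            for grp in [merged[m][merged[m]["chrom"] == chrom]]
            for b in list(grp["start"]) + list(grp["end"])
        })
        for s, e in zip(bounds[:-1], bounds[1:]):
            has = {m for m in MARKS
                   if chrom in trees[m] and trees[m][chrom].overlaps_point(s)}
            if "H3K4me3" in has:
                cls = "promoter"
            elif {"H3K4me1", "H3K27ac"} <= has:
                cls = "active_enhancer"
            elif "H3K4me1" in has:
                cls = "poised_enhancer"
            else:
                continue
            segments.append((chrom, s, e, cls))
    derived = pd.DataFrame(segments, columns=["chrom", "start", "end", "cls"])
    return RegulatoryLandscape(peaks=merged, derived=derived, _trees=trees)


def assign_features(
    sites: pd.DataFrame,
    gene_model: pd.DataFrame,
    landscape: RegulatoryLandscape,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.DataFrame:
    """Assign exactly one genomic feature per CpG.

    ``sites`` needs chrom and 1-based pos columns; the gene model needs
    chrom/start/end/name/strand (BED, 0-based half-open, TSS at ``start``
    for + genes and ``end - 1`` for - genes).  Feature precedence:
    promoter (TSS window or H3K4me3) > enhancer (active or poised) >
    body (inside a gene span) > intergenic.
    """
    if (gene_model["end"] <= gene_model["start"]).any():
        bad = gene_model[gene_model["end"] <= gene_model["start"]].iloc[0]
        raise ValueError(f"gene {bad['name']}: end <= start")

    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for chrom, grp in gene_model.groupby("chrom", sort=False):
        prom_iv = []
        for _, g in grp.iterrows():
            if g["strand"] == "-":
                tss = int(g["end"]) - 1
                lo, hi = tss - promoter_downstream, tss + promoter_upstream + 1
            else:
                tss = int(g["start"])
                lo, hi = tss - promoter_upstream, tss + promoter_downstream + 1
            prom_iv.append((max(lo, 0), hi))
        prom_trees[chrom] = IntervalTree.from_tuples(prom_iv)
        body_trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int)))

    rows = []
    for sid, chrom, pos in zip(sites.index, sites["chrom"], sites["pos"]):
        p0 = int(pos) - 1
        marks = landscape.marks_at(chrom, int(pos))
        cls = landscape.classify(chrom, int(pos))
        in_prom_window = chrom in prom_trees and prom_trees[chrom].overlaps_point(p0)
        if in_prom_window or cls == "promoter":
            feature = "promoter"
        elif cls in ("active_enhancer", "poised_enhancer"):
            feature = "enhancer"
        elif chrom in body_trees and body_trees[chrom].overlaps_point(p0):
            feature = "body"
        else:
            feature = "intergenic"
        rows.append({
            "chrom": chrom, "pos": int(pos), "feature": feature,
            "marks_overlapped": ",".join(sorted(marks)),
        })
    return pd.DataFrame(rows, index=sites.index)


def feature_enrichment(
    dm_sites, background_sites, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature fold change of a DM site set over its background.

    fold(f) = (fraction of DM sites in f) / (fraction of background in f);
    significance by a two-sided hypergeometric test on the DM count drawn
    from the background.  DM sites must be a subset of the background.
    """
    dm_sites = pd.Index(dm_sites)
    background_sites = pd.Index(background_sites)
    if not dm_sites.isin(background_sites).all():
        raise ValueError("dm_sites must be a subset of background_sites")
    feat_bg = assignments.loc[background_sites, "feature"]
    feat_dm = assignments.loc[dm_sites, "feature"]
    n_bg, n_dm = len(background_sites), len(dm_sites)
    rows = []
    for f in FEATURES:
        k_bg = int((feat_bg == f).sum())
        k_dm = int((feat_dm == f).sum())
        if k_bg == 0:
            rows.append({"feature": f, "n_background": 0, "n_dm": k_dm,
                         "fold_change": np.nan, "log10_fold": np.nan,
                         "p_value": np.nan, "note": "feature absent from background"})
            continue
        fold = (k_dm / n_dm) / (k_bg / n_bg) if n_dm else np.nan
        hg = sps.hypergeom(n_bg, k_bg, n_dm)
        p = min(1.0, 2.0 * min(hg.sf(k_dm - 1), hg.cdf(k_dm)))
        rows.append({
            "feature": f, "n_background": k_bg, "n_dm": k_dm,
            "fold_change": fold,
            "log10_fold": np.log10(fold) if fold and fold > 0 else -np.inf,
            "p_value": p, "note": "",
        })
    return pd.DataFrame(rows).set_index("feature")


def histone_overlap_venn(dm_sites: pd.DataFrame, landscape: RegulatoryLandscape) -> dict[frozenset, int]:
    """Partition DM sites by the exact subset of marks they overlap (8 cells)."""
    cells = {frozenset(c): 0 for c in _powerset(MARKS)}
    for chrom, pos in zip(dm_sites["chrom"], dm_sites["pos"]):
        cells[frozenset(landscape.marks_at(chrom, int(pos)))] += 1
    return cells


def _powerset(items):
    from itertools import chain, combinations
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))
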