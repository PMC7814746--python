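"""Distance-based epigenetic relationships among samples.

Samples are compared by Euclidean distance over a declared CpG set, with
pairwise-complete handling of missing betas: the summed squared difference
over the sites both samples cover is rescaled by (declared set size /
complete sites) before the square root, so sparsely covered samples are not
artificially close.  A neighbor-joining tree summarizes the distances
(negative branch lengths clamped to zero with the deficit moved to the
sibling branch), and within-group pairwise distances are compared between
groups with a rank-sum test — descriptive only, since pairwise distances
are not independent observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import MethylationMatrix
from .stats import wilcoxon_rank_sum


def euclidean_distances(mm: MethylationMatrix, site_set) -> DistanceMatrix:
    """Pairwise sample distances over ``site_set`` with missingness rescaling.

    d(i, j) = sqrt( sum_(complete sites) (b_i - b_j)^2 * S / m ) where S is
    the declared site-set size and m the number of sites complete in both
    samples.  A pair with zero complete sites is an error.
    """
    site_set = pd.Index(site_set)
    if len(site_set) == 0:
        raise ValueError("site_set is empty")
    if mm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    missing = site_set.difference(mm.beta.index)
    if len(missing):
        raise KeyError(f"site(s) not in matrix, e.g. {missing[0]}")
    B = mm.beta.loc[site_set].to_numpy(dtype=float)
    samples = mm.samples
    S = len(site_set)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(B[:, i]) & ~np.isnan(B[:, j])
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {samples[i]} and {samples[j]} share no complete site")
            ss = float(((B[both, i] - B[both, j]) ** 2).sum())
            d[i, j] = d[j, i] = np.sqrt(ss * S / m)
    return DistanceMatrix(d, ids=samples)


def neighbor_joining_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree over the distance matrix, as a newick string.

    Negative branch lengths produced by the agglomeration are set to zero
    and the deficit transferred to the adjacent branch (the standard
    correction).  Requires at least 3 labels.
    """
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    tree = nj(d)
    return str(tree).strip()


def intra_group_distances(
    d: DistanceMatrix, group_labels
) -> tuple[dict[str, np.ndarray], float]:
    """All within-group pairwise distances per group, plus a rank-sum p.

    Each group of n samples contributes n(n-1)/2 distances.  The p-value
    compares the two groups' distance lists and is descriptive (pairs are
    not independent).
    """
    labels = pd.Series(group_labels).reindex(d.ids)
    if labels.isna().any():
        raise ValueError("every sample in the distance matrix needs a group label")
    groups = sorted(labels.unique())
    out: dict[str, np.ndarray] = {}
    for g in groups:
        members = [s for s in d.ids if labels[s] == g]
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        vals = [d[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
        out[g] = np.asarray(vals)
    if len(groups) == 2:
        _, p = wilcoxon_rank_sum(out[groups[0]], out[groups[1]])
    else:
        p = float("nan")
    return out, p


def write_distances(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.data, index=d.ids, columns=d.ids).to_csv(
        path, sep="\t", index_label="sample_id")
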