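"""CpGs deviating from the methylation extremes of the long-term-survivor group.

Two threshold-defined sets: sites essentially unmethylated in LTS tumors
(group mean beta in [0, 0.1]) that gain at least ``delta`` methylation in
STS, and sites essentially fully methylated in LTS (mean beta in [0.9, 1])
that lose at least ``delta`` in STS.  Band edges are inclusive and no
significance test is applied at this stage; significance enters later via
survival association.  Against a normal-tissue baseline, gains at sites the
normal kidney also leaves unmethylated are de novo gains unique to the
short-term survivors, while losses at sites the normal kidney keeps
methylated are losses shared with (but deeper than) the tumor norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import _split_groups
from .io import MethylationMatrix


@dataclass
class ExtremeSelection:
    per_site: pd.DataFrame  # lts_mean, sts_mean, delta_beta for all sites
    fully_unmethylated: pd.Index  # LTS mean in low band, delta >= +delta
    fully_methylated: pd.Index  # LTS mean in high band, delta <= -delta
    low_band: tuple[float, float]
    high_band: tuple[float, float]
    delta: float


def select_extremes(
    mm: MethylationMatrix,
    group_labels,
    low_band: tuple[float, float] = (0.0, 0.1),
    high_band: tuple[float, float] = (0.9, 1.0),
    delta: float = 0.1,
) -> ExtremeSelection:
    """Select extreme-phenotype CpGs from LTS group means and delta beta."""
    if low_band[1] >= high_band[0]:
        raise ValueError("low and high bands overlap")
    lts, sts = _split_groups(mm, group_labels)
    lts_mean = mm.beta[lts].mean(axis=1, skipna=True)
    sts_mean = mm.beta[sts].mean(axis=1, skipna=True)
    d = sts_mean - lts_mean
    per_site = pd.DataFrame({"lts_mean": lts_mean, "sts_mean": sts_mean, "delta_beta": d})
    eps = 1e-9  # inclusive thresholds must survive float subtraction
    defined = lts_mean.notna() & sts_mean.notna()
    unmeth = (defined
              & (lts_mean >= low_band[0] - eps) & (lts_mean <= low_band[1] + eps)
              & (d >= delta - eps))
    meth = (defined
            & (lts_mean >= high_band[0] - eps) & (lts_mean <= high_band[1] + eps)
            & (d <= -delta + eps))
    return ExtremeSelection(
        per_site=per_site,
        fully_unmethylated=per_site.index[unmeth],
        fully_methylated=per_site.index[meth],
        low_band=low_band,
        high_band=high_band,
        delta=delta,
    )


def baseline_against_normal(
    selection: ExtremeSelection, normal_mm: MethylationMatrix
) -> pd.DataFrame:
    """Classify selected sites against the mean of the normal-tissue samples.

    Returns one row per selected site with columns normal_mean and
    classification in {de_novo_gain, shared_loss, other, uncovered}:
    de_novo_gain when a fully-unmethylated-set site is also at most the low
    band's upper bound in normal tissue, shared_loss when a
    fully-methylated-set site is at least the high band's lower bound in
    normal tissue, uncovered when the normal matrix lacks the site.
    """
    selected = selection.fully_unmethylated.union(selection.fully_methylated)
    if len(selected) and not selected.isin(normal_mm.beta.index).any():
        raise ValueError("normal matrix shares no site with the selection")
    normal_mean = normal_mm.beta.mean(axis=1, skipna=True)
    rows = []
    for sid in selected:
        if sid not in normal_mean.index or np.isnan(normal_mean[sid]):
            rows.append({"normal_mean": np.nan, "classification": "uncovered"})
            continue
        nm = float(normal_mean[sid])
        if sid in selection.fully_unmethylated and nm <= selection.low_band[1]:
            cls = "de_novo_gain"
        elif sid in selection.fully_methylated and nm >= selection.high_band[0]:
            cls = "shared_loss"
        else:
            cls = "other"
        rows.append({"normal_mean": nm, "classification": cls})
    return pd.DataFrame(rows, index=selected)


def write_selection(selection: ExtremeSelection, path) -> None:
    out = selection.per_site.copy()
    out["fully_unmethylated"] = out.index.isin(selection.fully_unmethylated)
    out["fully_methylated"] = out.index.isin(selection.fully_methylated)
    out.to_csv(path, sep="\t", index_label="site_id")
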