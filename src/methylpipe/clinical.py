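"""SSIGN prognostic scoring, survivor-group assignment, and cohort comparison.

The Mayo SSIGN score sums points over pathologic Stage (pT, pN, pM), tumor
SIze, nuclear Grade, and Necrosis.  The default point table used here is:

    pT1 = 0, pT2 = 1, pT3a-pT4 = 2; pNx/pN0 = 0, pN1/pN2 = 2; pM0 = 0,
    pM1 = 4; size < 5 cm = 0, >= 5 cm = 2; grade 1-2 = 0, grade 3 = 1,
    grade 4 = 3; necrosis present = 2.

Survivor groups within the low-risk stratum (scores 0-3) follow survival
inclusion criteria stratified by score.  The strict (discovery-registry)
criteria call a patient a short-term survivor (STS) when they died of
disease in < 6 years (SSIGN 0-1) or < 3.2 years (SSIGN 2-3), and a
long-term survivor (LTS) when alive > 10 years (SSIGN 0-1) or > 6.9 years
(SSIGN 2-3).  The relaxed criteria (used for array-based public cohorts)
are death < 7.5 / < 4.5 years and survival > 8.5 / > 5.5 years for the same
strata.  Patients between cutoffs, or with scores above 3, are excluded.
Patients dying of causes other than the disease are censored at death and
can qualify as LTS only if their censoring time exceeds the alive cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import fisher_exact_2x2, pearson_chi2, wilcoxon_rank_sum, yates_chi2_2x2

CLINICAL_COLUMNS = [
    "sample_id", "sex", "age_years", "pt_stage", "pn_stage", "pm_stage",
    "tumor_size_cm", "grade", "necrosis", "survival_years",
    "deceased_of_disease", "group",
]


@dataclass(frozen=True)
class SSIGNPointTable:
    pt_points: dict = field(default_factory=lambda: {
        "pT1": 0, "pT2": 1, "pT3a": 2, "pT3b": 2, "pT3c": 2, "pT4": 2})
    pn_points: dict = field(default_factory=lambda: {
        "pNx": 0, "pN0": 0, "pN1": 2, "pN2": 2})
    pm_points: dict = field(default_factory=lambda: {"pM0": 0, "pM1": 4})
    size_cutoff_cm: float = 5.0
    size_points: int = 2
    grade_points: dict = field(default_factory=lambda: {1: 0, 2: 0, 3: 1, 4: 3})
    necrosis_points: int = 2


DEFAULT_POINT_TABLE = SSIGNPointTable()


def ssign_score(record, table: SSIGNPointTable = DEFAULT_POINT_TABLE) -> int:
    """Sum SSIGN points for one sample record (mapping or Series)."""
    required = ["pt_stage", "pn_stage", "pm_stage", "tumor_size_cm", "grade", "necrosis"]
    missing = [f for f in required
               if f not in record or record[f] is None
               or (isinstance(record[f], float) and np.isnan(record[f]))]
    if missing:
        raise ValueError(f"missing pathologic field(s): {missing}")
    score = table.pt_points[record["pt_stage"]]
    score += table.pn_points[record["pn_stage"]]
    score += table.pm_points[record["pm_stage"]]
    if record["tumor_size_cm"] >= table.size_cutoff_cm:
        score += table.size_points
    score += table.grade_points[int(record["grade"])]
    if record["necrosis"]:
        score += table.necrosis_points
    return int(score)


@dataclass(frozen=True)
class SurvivalCriteria:
    """Score-stratified cutoffs; keys are the (low, high) score strata."""

    sts_death_cutoff_years: dict
    lts_alive_cutoff_years: dict

    def __post_init__(self):
        for stratum in self.sts_death_cutoff_years:
            if not self.sts_death_cutoff_years[stratum] < self.lts_alive_cutoff_years[stratum]:
                raise ValueError("STS death cutoff must be below LTS alive cutoff")


STRICT_CRITERIA = SurvivalCriteria(
    sts_death_cutoff_years={(0, 1): 6.0, (2, 3): 3.2},
    lts_alive_cutoff_years={(0, 1): 10.0, (2, 3): 6.9},
)
RELAXED_CRITERIA = SurvivalCriteria(
    sts_death_cutoff_years={(0, 1): 7.5, (2, 3): 4.5},
    lts_alive_cutoff_years={(0, 1): 8.5, (2, 3): 5.5},
)


def assign_survivor_group(
    score: int,
    survival_years: float,
    deceased_of_disease: bool,
    criteria: SurvivalCriteria = STRICT_CRITERIA,
) -> str:
    """Assign STS / LTS / excluded from score and survival."""
    stratum = next(
        (k for k in criteria.sts_death_cutoff_years if k[0] <= score <= k[1]), None)
    if stratum is None:
        return "excluded"
    if deceased_of_disease and survival_years < criteria.sts_death_cutoff_years[stratum]:
        return "STS"
    if survival_years > criteria.lts_alive_cutoff_years[stratum]:
        # alive, or censored by non-disease death after the cutoff
        return "LTS"
    return "excluded"


def label_cohort(
    records: pd.DataFrame,
    criteria: SurvivalCriteria = STRICT_CRITERIA,
    table: SSIGNPointTable = DEFAULT_POINT_TABLE,
) -> pd.DataFrame:
    """Score every record and assign survivor groups; returns a copy."""
    out = records.copy()
    out["ssign_score"] = [ssign_score(r, table) for _, r in records.iterrows()]
    out["assigned_group"] = [
        assign_survivor_group(s, y, d, criteria)
        for s, y, d in zip(out["ssign_score"], out["survival_years"],
                           out["deceased_of_disease"])
    ]
    return out


@dataclass
class ComparisonVariable:
    """One row of a cohort-comparison plan.

    kind: 'continuous' (rank-sum), 'binary' or 'categorical' (chi-square
    family).  ``levels`` declares the category levels (order and empties
    retained for the df convention); ``test`` selects 'chi2' (Pearson,
    default), 'yates', or 'fisher' (2x2 only).
    """

    name: str
    kind: str
    levels: list | None = None
    test: str = "chi2"


def cohort_comparison(
    records_a: pd.DataFrame, records_b: pd.DataFrame, plan: list[ComparisonVariable]
) -> pd.DataFrame:
    """Compare two groups variable by variable (summary-table statistics)."""
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("need at least 2 records per group")
    rows = []
    for var in plan:
        a = records_a[var.name]
        b = records_b[var.name]
        note = ""
        if var.kind == "continuous":
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                stat, p, note = 0.0, 1.0, "constant in both groups"
            else:
                stat, p = wilcoxon_rank_sum(a.dropna(), b.dropna())
            summary = f"median {a.median():g} vs {b.median():g}"
        else:
            levels = var.levels or sorted(set(a) | set(b))
            table = np.array([
                [(a == lv).sum() for lv in levels],
                [(b == lv).sum() for lv in levels],
            ])
            summary = " / ".join(f"{lv}:{ca}v{cb}" for lv, ca, cb in
                                 zip(levels, table[0], table[1]))
            if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
                stat, p, note = 0.0, 1.0, "constant in both groups"
            elif var.test == "fisher":
                if table.shape != (2, 2):
                    raise ValueError(f"{var.name}: Fisher requires a 2x2 table")
                stat, p = fisher_exact_2x2(table)
            elif var.test == "yates":
                if table.shape == (2, 2):
                    stat, p = yates_chi2_2x2(table)
                else:
                    stat, p, _ = pearson_chi2(table, df=len(levels) - 1)
                    note = "multi-level Yates request fell back to Pearson"
            else:
                stat, p, _ = pearson_chi2(table, df=len(levels) - 1)
        rows.append({"variable": var.name, "test": var.test if var.kind != "continuous"
                     else "wilcoxon", "summary": summary,
                     "statistic": stat, "p_value": p, "note": note})
    return pd.DataFrame(rows).set_index("variable")


def read_clinical_table(path) -> pd.DataFrame:
    """Read the documented clinical TSV (see CLINICAL_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise ValueError(f"clinical table missing column(s): {missing}")
    df["necrosis"] = df["necrosis"].astype(bool)
    df["deceased_of_disease"] = df["deceased_of_disease"].astype(bool)
    return df
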