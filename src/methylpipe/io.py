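"""Reading per-sample CpG calls and assembling the cohort methylation matrix.

RRBS methylation callers emit one coverage file per sample in the bismark
dialect::

    chrom <tab> start <tab> end <tab> methylation_pct <tab> count_meth <tab> count_unmeth

with 1-based inclusive coordinates and start == end for a single CpG.  This
module parses those files, joins samples into a sites x samples matrix of
beta values (methylated reads / total reads) plus the matching coverage
matrix, and applies the site-inclusion filter used throughout the analysis:
a CpG is retained when it is covered at >= ``min_coverage`` reads in at
least ``min_sample_fraction`` of samples, restricted to autosomes.

Coordinate conventions: coverage files are 1-based inclusive; BED inputs
elsewhere in the package are 0-based half-open.  Conversion happens exactly
once, at read time, and the in-memory position is always the 1-based
position of the cytosine.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("methylpipe")

_AUTOSOMES = {str(i) for i in range(1, 23)}

CALL_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth", "beta"]


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering key: chr2 < chr10 < chrX, bare names likewise."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def site_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def split_site_id(sid: str) -> tuple[str, int]:
    chrom, _, pos = sid.rpartition(":")
    return chrom, int(pos)


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.startswith("chr") else chrom
    return name in _AUTOSOMES


@dataclass
class MethylationMatrix:
    """Sites x samples beta values plus read-depth counts.

    ``beta`` and ``coverage`` share an index of ``chrom:pos`` site ids
    (ordered by natural chromosome order, then position) and identical
    sample columns.  ``beta`` is NaN exactly where ``coverage`` is zero,
    and equals count_meth / coverage everywhere else.
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.coverage.index):
            raise ValueError("beta and coverage indices differ")
        if list(self.beta.columns) != list(self.coverage.columns):
            raise ValueError("beta and coverage columns differ")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def sites(self) -> pd.DataFrame:
        """Site table with ``chrom`` and 1-based ``pos`` columns."""
        if self.n_sites == 0:
            return pd.DataFrame({"chrom": [], "pos": []})
        parts = [split_site_id(s) for s in self.beta.index]
        return pd.DataFrame(
            {"chrom": [p[0] for p in parts], "pos": [p[1] for p in parts]},
            index=self.beta.index,
        )

    def check_consistency(self) -> None:
        """Assert the beta/coverage contract (missing beta <=> zero depth)."""
        cov = self.coverage.to_numpy()
        beta = self.beta.to_numpy(dtype=float)
        if (cov < 0).any():
            raise ValueError("negative coverage")
        missing = np.isnan(beta)
        if not (missing == (cov == 0)).all():
            raise ValueError("beta missing does not coincide with zero coverage")
        with np.errstate(invalid="ignore"):
            if np.nanmax(beta, initial=0.0) > 1 + 1e-12 or np.nanmin(beta, initial=0.0) < -1e-12:
                raise ValueError("beta outside [0, 1]")


def _sorted_site_index(ids: Iterable[str]) -> list[str]:
    return sorted(ids, key=lambda s: (chrom_sort_key(split_site_id(s)[0]), split_site_id(s)[1]))


def read_coverage_file(path: str | Path) -> pd.DataFrame:
    """Parse one bismark-style coverage file into a per-sample call table.

    Returns a DataFrame with columns chrom, pos, count_meth, count_unmeth,
    beta.  The beta value is always recomputed from the counts; when the
    file's percent column disagrees with the counts by more than half a
    percentage point a warning is logged and the counts win.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start, end, pct, n_meth, n_unmeth = fields
            try:
                start_i = int(start)
                pct_f = float(pct)
                n_meth_i = int(n_meth)
                n_unmeth_i = int(n_unmeth)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
            if n_meth_i < 0 or n_unmeth_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            total = n_meth_i + n_unmeth_i
            beta = n_meth_i / total if total > 0 else np.nan
            if total > 0 and abs(pct_f - 100.0 * beta) > 0.5:
                logger.warning(
                    "%s:%d: percent column %.2f disagrees with counts (%.2f); using counts",
                    path, lineno, pct_f, 100.0 * beta,
                )
            rows.append((chrom, start_i, n_meth_i, n_unmeth_i, beta))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def merge_strand_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Optionally collapse opposite-strand CpG calls at pos and pos+1.

    A CpG dinucleotide yields a call on the plus strand at position p and on
    the minus strand at p+1; this sums the counts of each such adjacent pair
    onto the lower position.  Only immediately adjacent pairs are merged and
    merging is not chained beyond a pair.
    """
    calls = calls.sort_values(["chrom", "pos"], key=lambda c: (
        c.map(lambda v: chrom_sort_key(v)) if c.name == "chrom" else c
    )).reset_index(drop=True)
    out = []
    i = 0
    while i < len(calls):
        row = calls.iloc[i]
        if (
            i + 1 < len(calls)
            and calls.iloc[i + 1]["chrom"] == row["chrom"]
            and calls.iloc[i + 1]["pos"] == row["pos"] + 1
        ):
            nxt = calls.iloc[i + 1]
            n_meth = int(row["count_meth"] + nxt["count_meth"])
            n_unmeth = int(row["count_unmeth"] + nxt["count_unmeth"])
            total = n_meth + n_unmeth
            out.append((row["chrom"], int(row["pos"]), n_meth, n_unmeth,
                        n_meth / total if total else np.nan))
            i += 2
        else:
            out.append(tuple(row[c] for c in CALL_COLUMNS))
            i += 1
    return pd.DataFrame(out, columns=CALL_COLUMNS)


def assemble_matrix(calls_by_sample: Mapping[str, pd.DataFrame]) -> MethylationMatrix:
    """Join per-sample call tables over the union of their sites.

    Entries where a sample lacks a site get coverage 0 and missing beta.
    Duplicate (chrom, pos) within one sample is an error.
    """
    if len(calls_by_sample) == 0:
        raise ValueError("need at least one sample")
    cov_cols = {}
    meth_cols = {}
    for sample, calls in calls_by_sample.items():
        ids = [site_id(c, p) for c, p in zip(calls["chrom"], calls["pos"])]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(
                f"sample {sample}: duplicate site(s) e.g. {dup.index[0]}"
            )
        cov = calls["count_meth"].to_numpy() + calls["count_unmeth"].to_numpy()
        cov_cols[sample] = pd.Series(cov, index=ids)
        meth_cols[sample] = pd.Series(calls["count_meth"].to_numpy(), index=ids)
    coverage = pd.DataFrame(cov_cols).fillna(0).astype(int)
    meth = pd.DataFrame(meth_cols).fillna(0).astype(int)
    order = _sorted_site_index(coverage.index)
    coverage = coverage.loc[order]
    meth = meth.loc[order]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = meth / coverage.where(coverage > 0)
    mm = MethylationMatrix(beta=beta, coverage=coverage)
    _check_naming(mm)
    return mm


def _check_naming(mm: MethylationMatrix) -> str:
    """Detect 'chr'-prefixed vs bare chromosome naming; mixed is an error."""
    chroms = {split_site_id(s)[0] for s in mm.beta.index}
    prefixed = {c for c in chroms if c.startswith("chr")}
    if prefixed and prefixed != chroms:
        raise ValueError("mixed 'chr'-prefixed and bare chromosome names in one cohort")
    return "chr" if prefixed else "bare"


def filter_sites(
    mm: MethylationMatrix,
    min_coverage: int = 5,
    min_sample_fraction: float = 0.9,
    autosomes_only: bool = True,
) -> MethylationMatrix:
    """Apply the cohort site-inclusion filter.

    Retains sites covered at >= ``min_coverage`` reads in at least
    ``min_sample_fraction`` of all samples (comparison inclusive on both
    thresholds) and, when ``autosomes_only``, drops sex chromosomes and
    non-canonical contigs (autosomes are 1-22, 'chr'-prefixed or bare).
    """
    if mm.n_sites == 0:
        raise ValueError("empty matrix")
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must be in (0, 1]")
    _check_naming(mm)
    n_ok = (mm.coverage.to_numpy() >= min_coverage).sum(axis=1)
    keep = n_ok / mm.n_samples >= min_sample_fraction
    if autosomes_only:
        autos = np.array([is_autosome(split_site_id(s)[0]) for s in mm.beta.index])
        keep &= autos
    return MethylationMatrix(beta=mm.beta.loc[keep], coverage=mm.coverage.loc[keep])


def write_matrix(mm: MethylationMatrix, beta_path: str | Path, coverage_path: str | Path) -> None:
    """Write wide TSVs: site_id rows x sample columns, beta and coverage."""
    mm.beta.to_csv(beta_path, sep="\t", index_label="site_id", na_rep="NA")
    mm.coverage.to_csv(coverage_path, sep="\t", index_label="site_id")


def read_matrix(beta_path: str | Path, coverage_path: str | Path) -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col="site_id", na_values="NA")
    coverage = pd.read_csv(coverage_path, sep="\t", index_col="site_id")
    return MethylationMatrix(beta=beta, coverage=coverage)


def read_coverage_dir(directory: str | Path, pattern: str = "*.cov") -> MethylationMatrix:
    """Read every coverage file in a directory; sample name = file stem."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no coverage files matching {pattern} in {directory}")
    return assemble_matrix({f.stem: read_coverage_file(f) for f in files})
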