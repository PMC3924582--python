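"""Cohort tables of per-mouse steady-state thymocyte counts.

A cohort is a :class:`pandas.DataFrame` with columns
``mouse, n1, n2, n3, n4, n8`` (counts in cells, not millions), one row per
mouse, with ``n3 = n4 + n8`` row-wise.  The wild-type reference cohort of
eight C57BL/6 mice ships with the package (:func:`reference_cohort`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

COHORT_COLUMNS = ("mouse", "n1", "n2", "n3", "n4", "n8")
COUNT_COLUMNS = ("n1", "n2", "n3", "n4", "n8")

#: relative slack for the row-wise n3 = n4 + n8 identity (counts are printed
#: rounded to 0.01e6 cells, so the sum can be off by up to ~0.5%)
N3_SUM_RTOL = 0.005


@dataclass(frozen=True)
class CohortStats:
    """Column means and standard deviations of a cohort.

    The standard deviations are *population* SDs (``ddof=0``), matching the
    convention of the reference table's printed summary rows.
    """

    mean: pd.Series
    sd: pd.Series
    n_mice: int

    def mean_of(self, col: str) -> float:
        return float(self.mean[col])

    def sd_of(self, col: str) -> float:
        return float(self.sd[col])


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and return) a cohort table.

    Checks the schema, positivity of all counts, the per-mouse
    ``n3 = n4 + n8`` identity (to 0.5%, the table's rounding) and that at
    least two mice are present.  Errors cite offending row numbers.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(COHORT_COLUMNS)].copy()
    if len(df) < 2:
        raise ValueError(f"a cohort needs >= 2 mice, got {len(df)}")
    for col in COUNT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~(vals > 0) | ~np.isfinite(vals)].tolist()
        if bad:
            raise ValueError(f"non-positive or non-numeric {col} in row(s) {bad}")
        df[col] = vals.astype(float)
    rel = np.abs(df["n3"] - (df["n4"] + df["n8"])) / df["n3"]
    bad = df.index[rel > N3_SUM_RTOL].tolist()
    if bad:
        raise ValueError(
            f"n3 != n4 + n8 beyond {N3_SUM_RTOL:.1%} in row(s) {bad}")
    return df


def cohort_stats(df: pd.DataFrame) -> CohortStats:
    """Column means and population SDs of a validated cohort."""
    df = validate_cohort(df)
    counts = df.loc[:, list(COUNT_COLUMNS)]
    return CohortStats(mean=counts.mean(), sd=counts.std(ddof=0), n_mice=len(df))


def load_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (header ``mouse,n1,n2,n3,n4,n8``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(
            f"{path}: empty file; expected header {','.join(COHORT_COLUMNS)}") from None
    return validate_cohort(df)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, index=False)


def reference_cohort() -> pd.DataFrame:
    """The bundled wild-type cohort: eight mice, counts in cells.

    Column means reproduce the published summary (n1 mean 88.39e6 cells,
    population SD 60.11e6, ...).  Two rows are identical as printed in the
    source table; they are kept (no deduplication).
    """
    with resources.files("thymoselect.data").joinpath("table1.csv").open("rb") as fh:
        return validate_cohort(pd.read_csv(fh))
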