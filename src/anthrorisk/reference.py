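"""Age/sex reference statistics, z-scores, percentiles and correlations.

Anthropometric index values are compared across subjects after removal of the
age and sex structure of the reference population: each value is transformed
to ``z = (value - mean_cell) / sd_cell`` where the cell is the subject's sex
and age bin.  Reference tables use 5-year bins from age 18 with a terminal
open-ended bin by default; SDs follow the frequency-weighted population
convention (denominator = total weight) because the table describes a
population, not a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateReferenceError,
    DomainError,
    InsufficientDataError,
    MissingReferenceError,
    OutOfReferenceError,
    UnknownIndexError,
)

__all__ = [
    "INDEX_COLUMNS",
    "ReferenceStats",
    "default_age_bin_edges",
    "estimate_reference_stats",
    "zscore_cohort",
    "zscore_transform",
    "z_to_percentile",
    "correlation_matrix",
    "triangle_table",
]

logger = logging.getLogger(__name__)

#: Map from index name to the cohort-table column holding its values.
INDEX_COLUMNS = {
    "height": "height_cm",
    "bmi": "bmi",
    "absi": "absi",
    "hi": "hi",
    "whr": "whr",
}

DEFAULT_INDICES = ("height", "bmi", "absi", "hi")

REFERENCE_CSV_COLUMNS = ["index_name", "sex", "age_lo", "age_hi", "mean", "sd", "effective_n"]


def default_age_bin_edges(
    age_start: float = 18.0, bin_width: float = 5.0, open_from: float = 83.0
) -> np.ndarray:
    """Bin edges tiling [age_start, inf): finite bins of bin_width, then an open bin.

    The default gives [18,23), [23,28), ..., [78,83), [83, inf).
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    finite = np.arange(age_start, open_from + 0.5 * bin_width, bin_width)
    return np.append(finite, np.inf)


@dataclass
class ReferenceStats:
    """Age-bin x sex x index table of means and SDs for z-scoring.

    ``table`` has one row per (index_name, sex, age bin) cell with columns
    ``index_name, sex, age_lo, age_hi, mean, sd, effective_n``.  Cells backed
    by fewer than two records carry ``sd = NaN`` and are flagged degenerate.
    """

    table: pd.DataFrame
    age_bin_edges: np.ndarray = field(default_factory=lambda: default_age_bin_edges())

    def __post_init__(self) -> None:
        missing = sorted(set(REFERENCE_CSV_COLUMNS) - set(self.table.columns))
        if missing:
            raise DomainError(f"reference table missing columns: {missing}")
        self.age_bin_edges = np.asarray(self.age_bin_edges, dtype=float)
        if np.any(np.diff(self.age_bin_edges) <= 0):
            raise DomainError("age bin edges must be strictly increasing")

    @property
    def index_names(self) -> tuple[str, ...]:
        return tuple(self.table["index_name"].unique())

    def lookup(self, index_name: str, female: int, age_years: float, clamp_age: bool = False):
        """Return (mean, sd) of the cell covering ``age_years`` for this sex."""
        sub = self.table[
            (self.table["index_name"] == index_name) & (self.table["sex"] == int(female))
        ]
        if sub.empty:
            raise UnknownIndexError(index_name)
        age = float(age_years)
        lo, hi = sub["age_lo"].min(), sub["age_hi"].max()
        if age < lo or age >= hi:
            if not clamp_age:
                raise OutOfReferenceError(
                    f"age {age} outside reference coverage [{lo}, {hi}) for "
                    f"index={index_name}, sex={female}"
                )
            age = min(max(age, lo), np.nextafter(hi, -np.inf))
        row = sub[(sub["age_lo"] <= age) & (age < sub["age_hi"])]
        if row.empty:
            raise OutOfReferenceError(
                f"no populated reference cell for age {age}, index={index_name}, sex={female}"
            )
        mean, sd = float(row["mean"].iloc[0]), float(row["sd"].iloc[0])
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateReferenceError(
                f"degenerate reference cell (sd={sd}) for index={index_name}, "
                f"sex={female}, age={age}"
            )
        return mean, sd

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip lossless for float64 cells
        self.table[REFERENCE_CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ReferenceStats":
        table = pd.read_csv(path, float_precision="round_trip")
        edges = np.unique(
            np.concatenate([table["age_lo"].to_numpy(float), table["age_hi"].to_numpy(float)])
        )
        return cls(table=table, age_bin_edges=edges)

    def to_records(self) -> list[dict]:
        return self.table[REFERENCE_CSV_COLUMNS].to_dict("records")

    @classmethod
    def from_records(cls, records: list[dict]) -> "ReferenceStats":
        table = pd.DataFrame.from_records(records)[REFERENCE_CSV_COLUMNS]
        edges = np.unique(
            np.concatenate([table["age_lo"].to_numpy(float), table["age_hi"].to_numpy(float)])
        )
        return cls(table=table, age_bin_edges=edges)


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray, ddof_style: str):
    total = weights.sum()
    mean = float(np.average(values, weights=weights))
    ss = float(np.average((values - mean) ** 2, weights=weights))
    if ddof_style == "population":
        var = ss
    elif ddof_style == "sample":
        denom = total - 1.0
        var = ss * total / denom if denom > 0 else np.nan
    else:
        raise DomainError(f"unknown ddof_style {ddof_style!r}")
    return mean, float(np.sqrt(var)) if var == var else np.nan, float(total)


def estimate_reference_stats(
    cohort: pd.DataFrame,
    index_names=DEFAULT_INDICES,
    age_bin_width: float = 5.0,
    use_sample_weights: bool = True,
    ddof_style: str = "population",
    age_start: float = 18.0,
    age_open_from: float = 83.0,
) -> ReferenceStats:
    """Estimate per-(index, sex, age-bin) weighted means and SDs.

    The cohort must already carry the index columns (see
    :func:`anthrorisk.indices.compute_index_panel`).  Cells with fewer than two
    records get ``sd = NaN`` and are flagged degenerate at use time.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    for name in index_names:
        if name not in INDEX_COLUMNS:
            raise UnknownIndexError(name)
        if INDEX_COLUMNS[name] not in cohort.columns:
            raise UnknownIndexError(
                f"index {name!r} requires column {INDEX_COLUMNS[name]!r}; "
                "run compute_index_panel first"
            )
    edges = default_age_bin_edges(age_start, age_bin_width, age_open_from)
    ages = cohort["age_years"].to_numpy(dtype=float)
    female = cohort["female"].to_numpy(dtype=int)
    if use_sample_weights:
        weights = cohort["sample_weight"].to_numpy(dtype=float)
    else:
        weights = np.ones(len(cohort))
    bin_idx = np.digitize(ages, edges) - 1  # -1 => below age_start

    rows = []
    for name in index_names:
        values = cohort[INDEX_COLUMNS[name]].to_numpy(dtype=float)
        for sex in (0, 1):
            for b in range(len(edges) - 1):
                cell = (bin_idx == b) & (female == sex) & (weights > 0)
                n_cell = int(cell.sum())
                if n_cell == 0:
                    rows.append((name, sex, edges[b], edges[b + 1], np.nan, np.nan, 0.0))
                    continue
                mean, sd, total = _weighted_mean_sd(values[cell], weights[cell], ddof_style)
                if n_cell < 2:
                    sd = np.nan
                rows.append((name, sex, edges[b], edges[b + 1], mean, sd, total))
    table = pd.DataFrame(rows, columns=REFERENCE_CSV_COLUMNS)
    return ReferenceStats(table=table, age_bin_edges=edges)


def zscore_cohort(
    cohort: pd.DataFrame,
    stats: ReferenceStats,
    index_names=DEFAULT_INDICES,
    clamp_age: bool = False,
) -> pd.DataFrame:
    """Vectorized z-scoring of a cohort against a reference table.

    Returns a copy of the cohort with ``z_<index>`` columns appended.  Ages
    outside the reference coverage raise :class:`OutOfReferenceError` unless
    ``clamp_age`` maps them to the nearest covered bin (policy used when
    scoring an external cohort against another population's normals).
    """
    edges = stats.age_bin_edges
    ages = cohort["age_years"].to_numpy(dtype=float)
    below = ages < edges[0]
    above = ages >= edges[-1]
    if (below.any() or above.any()) and not clamp_age:
        raise OutOfReferenceError(
            f"{int(below.sum() + above.sum())} ages outside reference coverage "
            f"[{edges[0]}, {edges[-1]}); enable clamp_age to clamp"
        )
    if clamp_age and (below.any() or above.any()):
        logger.info("clamping %d out-of-range ages to reference bins", int(below.sum() + above.sum()))
        ages = np.clip(ages, edges[0], np.nextafter(edges[-1], -np.inf))
    bin_idx = np.digitize(ages, edges) - 1
    female = cohort["female"].to_numpy(dtype=int)

    out = cohort.copy()
    for name in index_names:
        if name not in INDEX_COLUMNS:
            raise UnknownIndexError(name)
        sub = stats.table[stats.table["index_name"] == name]
        if sub.empty:
            raise UnknownIndexError(f"index {name!r} not present in reference table")
        n_bins = len(edges) - 1
        means = np.full((2, n_bins), np.nan)
        sds = np.full((2, n_bins), np.nan)
        for _, row in sub.iterrows():
            b = int(np.searchsorted(edges, row["age_lo"]))
            means[int(row["sex"]), b] = row["mean"]
            sds[int(row["sex"]), b] = row["sd"]
        cell_mean = means[female, bin_idx]
        cell_sd = sds[female, bin_idx]
        used = np.isfinite(cohort[INDEX_COLUMNS[name]].to_numpy(dtype=float))
        if np.any(~np.isfinite(cell_sd) & used) or np.any(cell_sd[used] <= 0):
            bad = int(np.sum((~np.isfinite(cell_sd) | (cell_sd <= 0)) & used))
            raise DegenerateReferenceError(
                f"{bad} records fall in degenerate/empty reference cells for index {name!r}"
            )
        out[f"z_{name}"] = (cohort[INDEX_COLUMNS[name]] - cell_mean) / cell_sd
    return out


def zscore_transform(
    panel: dict, age_years: float, female: int, stats: ReferenceStats, clamp_age: bool = False
) -> dict:
    """z-score a single subject's index panel (dict index_name -> value)."""
    z = {}
    for name, value in panel.items():
        mean, sd = stats.lookup(name, female, age_years, clamp_age=clamp_age)
        z[name] = (float(value) - mean) / sd
    return z


def z_to_percentile(z, method: str = "normal", reference_z=None, reference_weights=None):
    """Map z-scores to population percentiles in (0, 100).

    ``normal`` uses 100*Phi(z); ``empirical`` uses the weighted fraction of the
    attached reference cohort's z-scores strictly below z.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DomainError("z must be finite")
    if method == "normal":
        return 100.0 * sps.norm.cdf(z)
    if method == "empirical":
        if reference_z is None:
            raise MissingReferenceError("empirical percentiles require reference_z")
        ref = np.asarray(reference_z, dtype=float)
        w = (
            np.ones_like(ref)
            if reference_weights is None
            else np.asarray(reference_weights, dtype=float)
        )
        total = w.sum()
        if total <= 0:
            raise MissingReferenceError("reference weights sum to zero")
        below = (ref[None, :] < np.atleast_1d(z)[:, None]) @ w
        pct = 100.0 * below / total
        return pct if z.ndim else float(pct[0])
    raise DomainError(f"unknown percentile method {method!r}")


def correlation_matrix(
    cohort: pd.DataFrame,
    index_names=DEFAULT_INDICES,
    on_zscores: bool = False,
    use_sample_weights: bool = True,
) -> pd.DataFrame:
    """Weighted Pearson correlation matrix of raw index values or their z-scores.

    Constant columns yield NaN rows/columns (undefined, not zero); the
    diagonal is exactly 1 for non-degenerate columns.
    """
    if len(cohort) < 3:
        raise InsufficientDataError("need >= 3 records for correlations")
    cols = []
    for name in index_names:
        col = f"z_{name}" if on_zscores else INDEX_COLUMNS.get(name, name)
        if col not in cohort.columns:
            raise UnknownIndexError(f"column {col!r} not found (index {name!r})")
        cols.append(col)
    X = cohort[cols].to_numpy(dtype=float)
    w = (
        cohort["sample_weight"].to_numpy(dtype=float)
        if use_sample_weights and "sample_weight" in cohort.columns
        else np.ones(len(cohort))
    )
    w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    degenerate = sd <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=list(index_names), columns=list(index_names))


def triangle_table(raw_corr: pd.DataFrame, z_corr: pd.DataFrame) -> pd.DataFrame:
    """Combine raw (upper-right) and z-scored (lower-left) correlations.

    Mirrors the conventional presentation: the upper triangle shows raw-value
    correlations, the lower triangle z-score correlations, diagonal 1.
    """
    if list(raw_corr.columns) != list(z_corr.columns):
        raise DomainError("raw and z-score matrices must share the same index order")
    out = raw_corr.copy()
    iu = np.tril_indices(len(out), k=-1)
    out.values[iu] = z_corr.values[iu]
    return out
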