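"""Data ingestion, preprocessing and export.

Three dataset kinds are supported:

* ``timeseries`` — one subject, rows are measurement occasions in temporal
  order, with an optional block identifier (e.g. day) delimiting valid
  consecutive pairs;
* ``panel`` — rows are subjects, columns are indicator-by-wave in the
  ``item@wave`` naming convention;
* ``moments`` — a labeled covariance CSV plus means CSV plus n, so models
  can be fit from deposited summary statistics.

Missing values are empty cells (or a caller-chosen sentinel) and are kept
as an explicit mask — never imputed at read time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import DataError, MomentData

__all__ = [
    "Dataset",
    "read_timeseries",
    "read_panel",
    "read_moments",
    "build_augmented",
    "timeseries_moments",
    "panel_moments",
    "detrend",
]


@dataclass
class Dataset:
    """Validated data table with kind-specific metadata."""

    kind: str  # 'timeseries' | 'panel' | 'moments'
    frame: pd.DataFrame = None
    variables: list = None
    block: np.ndarray = None  # per-row block identifier (timeseries)
    occasion: np.ndarray = None  # numeric occasion index (timeseries)
    n_waves: int = None  # panel
    means: np.ndarray = None  # moments
    cov: np.ndarray = None
    n: int = None

    def __post_init__(self):
        if self.kind == "timeseries":
            if self.block is None:
                self.block = np.zeros(len(self.frame), dtype=int)
            self.block = np.asarray(self.block)
            if self.occasion is None:
                self.occasion = np.arange(len(self.frame), dtype=float)
            self.occasion = np.asarray(self.occasion, dtype=float)
            for b in np.unique(self.block):
                occ = self.occasion[self.block == b]
                if np.any(np.diff(occ) <= 0):
                    raise DataError(
                        f"occasions must be strictly increasing within block {b!r}"
                    )
        if self.kind == "panel" and self.n_waves is not None and self.n_waves < 3:
            raise DataError("panel data require at least three waves")

    @property
    def n_rows(self) -> int:
        return len(self.frame) if self.frame is not None else self.n


def _read_csv(path, na) -> pd.DataFrame:
    # inspect the raw header: pandas silently renames duplicate labels
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    seen, dup = set(), []
    for label in header:
        if label in seen:
            dup.append(label)
        seen.add(label)
    if dup:
        raise DataError(f"duplicate column labels: {dup}")
    return pd.read_csv(path, na_values=[na] if na else None)


def read_timeseries(
    path, block_column: str = None, occasion_column: str = None, na: str = None
) -> Dataset:
    """Read single-subject time-series data from a wide CSV."""
    df = _read_csv(path, na)
    block = None
    occasion = None
    if block_column is not None:
        if block_column not in df.columns:
            raise DataError(f"block column {block_column!r} not in file")
        block = df[block_column].to_numpy()
        df = df.drop(columns=[block_column])
    if occasion_column is not None:
        if occasion_column not in df.columns:
            raise DataError(f"occasion column {occasion_column!r} not in file")
        occasion = df[occasion_column].to_numpy(dtype=float)
        df = df.drop(columns=[occasion_column])
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise DataError(f"non-numeric cell in time-series data: {exc}") from None
    return Dataset(
        kind="timeseries",
        frame=df.reset_index(drop=True),
        variables=list(df.columns),
        block=block,
        occasion=occasion,
    )


def read_panel(path, subject_column: str = None, na: str = None) -> Dataset:
    """Read wide panel data; columns named ``item@wave`` (e.g. ``SE1@1``)."""
    df = _read_csv(path, na)
    if subject_column is not None:
        df = df.drop(columns=[subject_column])
    waves, items = [], []
    for col in df.columns:
        if "@" not in col:
            raise DataError(
                f"panel column {col!r} does not follow the item@wave convention"
            )
        item, wave = col.rsplit("@", 1)
        items.append(item)
        waves.append(wave)
    wave_order = list(dict.fromkeys(waves))
    variables = list(dict.fromkeys(items))
    # canonical ordering: wave-major, items in first-seen order, waves renamed 1..n_t
    cols = []
    for w in wave_order:
        for v in variables:
            src = f"{v}@{w}"
            if src in df.columns:
                cols.append(src)
    df = df[cols].astype(float)
    rename = {
        f"{v}@{w}": f"{v}@{i + 1}"
        for i, w in enumerate(wave_order)
        for v in variables
        if f"{v}@{w}" in df.columns
    }
    df = df.rename(columns=rename)
    return Dataset(
        kind="panel",
        frame=df.reset_index(drop=True),
        variables=variables,
        n_waves=len(wave_order),
    )


def read_moments(cov_path, means_path, n: int) -> Dataset:
    """Read a labeled covariance matrix and mean vector (summary input)."""
    cov = pd.read_csv(cov_path, index_col=0)
    means = pd.read_csv(means_path, index_col=0).iloc[:, 0]
    if list(cov.index) != list(cov.columns):
        raise DataError("covariance row and column labels differ")
    if list(means.index) != list(cov.columns):
        raise DataError("means labels do not match covariance labels")
    c = cov.to_numpy(dtype=float)
    if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise DataError("covariance matrix is not symmetric")
    return Dataset(
        kind="moments",
        variables=list(cov.columns),
        means=means.to_numpy(dtype=float),
        cov=c,
        n=int(n),
    )


def build_augmented(dataset: Dataset) -> pd.DataFrame:
    """Pair consecutive occasions into (previous, current) rows.

    Every occasion yields one row; the first occasion of each block has
    missing previous-occasion values, so pairs never straddle block
    boundaries (e.g. overnight gaps).  Row count equals occasion count.
    """
    if dataset.kind != "timeseries":
        raise DataError("augmentation applies to time-series data")
    values = dataset.frame.to_numpy(dtype=float)
    n, p = values.shape
    prev = np.full((n, p), np.nan)
    blocks = dataset.block
    for i in range(1, n):
        if blocks[i] == blocks[i - 1]:
            prev[i] = values[i - 1]
    cols = [f"{v}@prev" for v in dataset.variables] + list(dataset.variables)
    return pd.DataFrame(np.hstack([prev, values]), columns=cols)


def timeseries_moments(dataset: Dataset, method: str = "fiml") -> MomentData:
    """Augmented-layout moments for ts fitting.

    ``fiml`` keeps the block-initial rows (missing lead values) as their
    own missingness pattern; ``ml`` keeps complete pairs only.
    """
    aug = build_augmented(dataset)
    if method == "ml":
        aug = aug.dropna()
    return MomentData.from_dataframe(aug)


def panel_moments(dataset: Dataset, method: str = "ml") -> MomentData:
    """Stacked per-subject moments for panel fitting."""
    if dataset.kind == "moments":
        return MomentData.from_moments(
            dataset.means, dataset.cov, dataset.n, dataset.variables
        )
    frame = dataset.frame
    if method == "ml":
        frame = frame.dropna()
    return MomentData.from_dataframe(frame)


def detrend(dataset: Dataset, alpha: float = 0.05):
    """Replace linearly trending variables by their detrending residuals.

    Each variable is regressed on the occasion index; when the slope is
    significant at ``alpha`` the scores are replaced by the regression
    residuals, otherwise left unchanged.  Returns ``(dataset, report)``
    where the report lists per-variable slope, p-value and whether the
    variable was detrended.
    """
    if dataset.kind != "timeseries":
        raise DataError("detrending applies to time-series data")
    t = dataset.occasion
    frame = dataset.frame.copy()
    report = []
    for v in dataset.variables:
        y = frame[v].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3 or np.nanstd(y) == 0:
            report.append({"variable": v, "slope": np.nan, "p": np.nan, "detrended": False})
            continue
        res = stats.linregress(t[ok], y[ok])
        hit = bool(res.pvalue < alpha)
        if hit:
            y = y - (res.intercept + res.slope * t)
            frame[v] = y
        report.append(
            {"variable": v, "slope": res.slope, "p": res.pvalue, "detrended": hit}
        )
    new = Dataset(
        kind="timeseries",
        frame=frame,
        variables=list(dataset.variables),
        block=dataset.block.copy(),
        occasion=dataset.occasion.copy(),
    )
    return new, pd.DataFrame(report)
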