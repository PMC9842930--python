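"""Functional connectivity construction from parcellated BOLD time series.

Individual FC matrices are Pearson correlations between regional time
series with negative edges zeroed and a unit diagonal — the nonnegative
symmetric matrix every nested-spectral-partition computation consumes.
A group "stable" network is built by temporally concatenating the
(per-subject z-scored) series of all subjects in a group, which averages
out the sampling noise of short single-subject scans and serves as the
calibration target downstream.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_fc",
    "build_stable_fc",
    "connectivity_density",
    "read_timeseries",
    "write_fc",
    "read_fc",
    "load_atlas",
    "bundled_atlas",
]

_MIN_TIMEPOINTS = 3


class DegenerateTimeSeriesError(ValueError):
    """A region's time series is constant (zero variance)."""


def _as_frame(ts) -> pd.DataFrame:
    if isinstance(ts, pd.DataFrame):
        return ts
    arr = np.asarray(ts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("time series must be a 2-D (time x regions) array")
    return pd.DataFrame(arr, columns=[str(j) for j in range(arr.shape[1])])


def _check_timeseries(df: pd.DataFrame) -> None:
    if df.shape[0] < _MIN_TIMEPOINTS:
        raise ValueError(
            f"need at least {_MIN_TIMEPOINTS} time points, got {df.shape[0]}"
        )
    if df.isna().any().any():
        raise ValueError("time series contains missing values")
    if df.columns.duplicated().any():
        raise ValueError("region ids must be unique")
    sd = df.std(axis=0, ddof=0)
    dead = sd.index[sd.values == 0.0]
    if len(dead):
        raise DegenerateTimeSeriesError(
            f"zero-variance time series for region(s): {list(map(str, dead))}"
        )


def compute_fc(ts) -> pd.DataFrame:
    """Pearson FC matrix of a T x N time-series table.

    Negative correlations are set to zero and the diagonal is fixed at
    one, then the matrix is symmetrized exactly. Accepts a DataFrame
    (columns = region ids) or a plain 2-D array.

    Raises
    ------
    DegenerateTimeSeriesError
        If any region has a constant time series.
    """
    df = _as_frame(ts)
    _check_timeseries(df)
    c = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    c = np.clip(c, 0.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=df.columns, columns=df.columns)


def build_stable_fc(cohort_ts: Sequence) -> pd.DataFrame:
    """Group stable FC from temporally concatenated subject series.

    Each subject's series is z-scored per region over its own scan
    length before concatenation so that no subject's variance scale
    dominates the group network; the concatenated (sum-T) x N matrix is
    then passed through :func:`compute_fc`.
    """
    if len(cohort_ts) == 0:
        raise ValueError("need at least one subject")
    frames = [_as_frame(ts) for ts in cohort_ts]
    cols = frames[0].columns
    for k, f in enumerate(frames):
        if not f.columns.equals(cols):
            raise ValueError(f"subject {k} has mismatched region ids")
        _check_timeseries(f)
    zscored = [
        (f - f.mean(axis=0)) / f.std(axis=0, ddof=0) for f in frames
    ]
    return compute_fc(pd.concat(zscored, axis=0, ignore_index=True))


def connectivity_density(fc, threshold: float) -> float:
    """Fraction of upper-triangle edges strictly above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    c = np.asarray(fc, dtype=float)
    iu = np.triu_indices_from(c, k=1)
    return float(np.mean(c[iu] > threshold))


# ---------------------------------------------------------------------------
# I/O: TSV time series, FC matrices and the region -> system atlas table
# ---------------------------------------------------------------------------

def read_timeseries(path) -> pd.DataFrame:
    """Read a T x N TSV/CSV time-series table (header row = region ids)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return df.astype(float)


def write_fc(fc: pd.DataFrame, path) -> None:
    fc.to_csv(path, sep="\t", index_label="region_id")


def read_fc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_atlas(path) -> pd.Series:
    """Load a two-column (region_id, system_name) TSV as a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("atlas table must have exactly two columns")
    df.columns = ["region_id", "system_name"]
    if df["region_id"].duplicated().any():
        raise ValueError("atlas maps some region more than once")
    return df.set_index("region_id")["system_name"]


def bundled_atlas() -> pd.Series:
    """Bundled synthetic Schaefer-100-style -> Yeo-7 mapping table.

    A stand-in lookup table with Schaefer-convention region names and
    plausible per-system parcel counts; it is synthetic, not the
    published atlas, and exists so the pipeline runs without downloads.
    """
    ref = resources.files("nspnet.data") / "schaefer100_yeo7_synthetic.tsv"
    with resources.as_file(ref) as p:
        return load_atlas(Path(p))
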