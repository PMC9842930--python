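"""Scan-length calibration of individual NSP components.

Short scans bias single-subject networks toward stronger segregation.
The remedy is a per-group rescaling: within each group the subject
values of a component (H_Se or H_In) are multiplied by the ratio of the
group's stable-network value to the group mean of the raw values, so
that the calibrated group mean equals the stable-network target exactly
while every subject's rank (and any within-group correlation with
external variables) is untouched. Regional components are rescaled by
the same subject-level factor, preserving each region's relative
contribution. H_B is recomputed from the calibrated H_In and H_Se.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["calibrate_global", "calibrate_regional", "calibrate_group"]


def calibrate_global(values, target: float) -> np.ndarray:
    """Rescale subject values so their group mean equals ``target``.

    ``calibrated_n = raw_n * target / mean(raw)``; idempotent when the
    mean already equals the target.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("group mean of raw values must be positive")
    if not np.isfinite(target) or target < 0:
        raise ValueError("calibration target must be finite and >= 0")
    return v * (target / mean)


def calibrate_regional(
    regional_raw, subject_calibrated_global, group_mean_raw_global: float
) -> np.ndarray:
    """Rescale a subjects x regions table of one regional component.

    ``H^j(cal) = H^j(raw) / mean-of-raw-global * subject-calibrated-global``
    — a per-subject positive factor, so within-subject regional ratios
    are preserved. The denominator is the group mean of the raw *global*
    component (the regional formula's group average is read as the
    global one; see the methods note for the alternative reading).
    """
    if group_mean_raw_global <= 0:
        raise ValueError("group mean of raw global values must be positive")
    x = np.asarray(regional_raw, dtype=float)
    g = np.asarray(subject_calibrated_global, dtype=float)
    if x.ndim != 2 or x.shape[0] != g.shape[0]:
        raise ValueError("regional table and global vector are misaligned")
    return x * (g / group_mean_raw_global)[:, None]


def calibrate_group(
    global_df: pd.DataFrame,
    regional: dict[str, pd.DataFrame],
    h_in_stable: float,
    h_se_stable: float,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Calibrate one group's H_In and H_Se (global + regional); rebuild H_B.

    Parameters
    ----------
    global_df
        Subjects x {HIn, HSe, ...} raw global components.
    regional
        Mapping measure name -> subjects x regions raw regional table
        (at least "HIn" and "HSe").
    h_in_stable, h_se_stable
        The group's stable-network components (calibration targets).
    """
    out = global_df.copy()
    raw_mean = {"HIn": global_df["HIn"].mean(), "HSe": global_df["HSe"].mean()}
    out["HIn"] = calibrate_global(global_df["HIn"].to_numpy(), h_in_stable)
    out["HSe"] = calibrate_global(global_df["HSe"].to_numpy(), h_se_stable)
    out["HB"] = out["HIn"] - out["HSe"]
    out["absHB"] = out["HB"].abs()

    reg_out: dict[str, pd.DataFrame] = {}
    for name in ("HIn", "HSe"):
        tab = regional[name]
        cal = calibrate_regional(
            tab.to_numpy(), out[name].to_numpy(), raw_mean[name]
        )
        reg_out[name] = pd.DataFrame(cal, index=tab.index, columns=tab.columns)
    reg_out["HB"] = reg_out["HIn"] - reg_out["HSe"]
    reg_out["absHB"] = reg_out["HB"].abs()
    return out, reg_out
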