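"""Small, exactly specified in-vivo and plate-assay computations.

Caliper tumor volumes and growth curves for xenograft experiments, percent
survival for fly drug-feeding assays, and the two-step fluorescence
normalization (signal over Hoechst nuclear stain, then fold over the
control-well mean) used for autophagy and caspase plate assays.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "tumor_volume",
    "growth_curve",
    "survival_percent",
    "normalize_assay",
]


def tumor_volume(length, width):
    """Caliper tumor volume in mm^3: ((length + width) / 2) * length * width.

    The formula is symmetric in its arguments; if width exceeds length the
    two are swapped with a warning (the value is unaffected, but the swap
    is recorded for provenance).  Accepts scalars or arrays.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("tumor dimensions must be positive")
    if np.any(width > length):
        warnings.warn("width > length; swapping (volume unchanged)", stacklevel=2)
        length, width = np.maximum(length, width), np.minimum(length, width)
    vol = (length + width) / 2.0 * length * width
    return float(vol) if vol.ndim == 0 else vol


def growth_curve(
    measurements: pd.DataFrame,
    vehicle_arm: str = "vehicle",
    arm_col: str = "arm",
    day_col: str = "day",
    length_col: str = "length",
    width_col: str = "width",
) -> pd.DataFrame:
    """Arm-wise tumor growth summary with percent-of-control.

    For each (arm, day): mean volume, SD and animal count; plus
    ``percent_of_control`` = 100 * mean(arm) / mean(vehicle) for that day.
    Days missing from the vehicle arm yield a missing percent.  Formal
    group comparisons are left to standard ANOVA routines.
    """
    df = measurements.copy()
    df["volume"] = tumor_volume(df[length_col].to_numpy(), df[width_col].to_numpy())
    agg = (
        df.groupby([arm_col, day_col])["volume"]
        .agg(mean_volume="mean", sd_volume="std", n="count")
        .reset_index()
    )
    vehicle = agg[agg[arm_col] == vehicle_arm].set_index(day_col)["mean_volume"]
    agg["percent_of_control"] = 100.0 * agg["mean_volume"] / agg[day_col].map(vehicle)
    return agg


def survival_percent(alive, initial):
    """Percent of flies still alive at each time point: 100 * alive / initial.

    ``alive`` may be a sequence (a time series of counts); ``initial`` a
    scalar starting count or a matching sequence (e.g. per-vial).
    """
    alive = np.asarray(alive, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if np.any(initial <= 0):
        raise ValueError("initial count must be positive")
    if np.any(alive > initial):
        raise ValueError("alive count exceeds initial count")
    if np.any(alive < 0):
        raise ValueError("negative alive count")
    pct = 100.0 * alive / initial
    return float(pct) if pct.ndim == 0 else pct


def normalize_assay(
    readings: pd.DataFrame,
    signal_col: str = "signal",
    hoechst_col: str = "hoechst",
    group_col: str = "group",
    control_label: str = "control",
) -> pd.DataFrame:
    """Two-step fluorescence normalization for autophagy/caspase plate assays.

    Step 1 divides each well's assay fluorescence by its Hoechst
    fluorescence, correcting for cell density.  Step 2 divides by the mean
    step-1 value of the control wells, giving fold-over-control.  Wells
    with non-positive Hoechst are excluded with a warning; the whole
    normalization is invariant to rescaling either channel by a common
    positive factor.
    """
    df = readings.copy()
    bad = df[hoechst_col] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} well(s) with non-positive Hoechst", stacklevel=2)
        df = df[~bad]
    df["normalized_signal"] = df[signal_col] / df[hoechst_col]
    ctrl = df.loc[df[group_col] == control_label, "normalized_signal"]
    if ctrl.empty:
        raise ValueError("no control wells")
    df["fold_over_control"] = df["normalized_signal"] / ctrl.mean()
    return df
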