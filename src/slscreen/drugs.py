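"""Drug dose-response normalization and combination-interaction analysis.

Viability readouts (e.g. CellTiter-Glo luminescence) are normalized to the
no-drug control of the same cell line to give fold changes.  For two-drug
combinations the coefficient of drug interaction,

    CDI = AB / (A x B),

compares the combination fold change AB to the Bliss-independence
expectation A x B from the single agents; CDI < 1 indicates synergy
(< 0.7 strong synergy, < 0.95 the practical synergy call), values near 1
additivity, and CDI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CdiResult",
    "fold_change",
    "compute_cdi",
    "classify_cdi",
    "cdi_from_replicates",
    "dose_selectivity",
]

CdiClass = Literal["strong_synergy", "synergy", "additive", "antagonism"]


@dataclass(frozen=True)
class CdiResult:
    """Coefficient of drug interaction for one drug pair in one cell line."""

    a: float            # fold change, drug 1 alone
    b: float            # fold change, drug 2 alone
    ab: float           # fold change, combination
    cdi: float
    label: CdiClass
    ci_low: float = np.nan   # bootstrap CI over replicates, when available
    ci_high: float = np.nan


def fold_change(
    table: pd.DataFrame,
    readout_col: str = "readout",
    dose_cols: Sequence[str] = ("dose1", "dose2"),
    group_cols: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Normalize readouts to the mean no-drug control of each group.

    Control wells are rows where every dose column is zero.  Each readout
    is divided by the mean control readout of its ``group_cols`` group
    (default: per cell line), preserving replicate structure; the pooled
    control group therefore has mean fold change exactly 1.
    """
    df = table.copy()
    dose_cols = [c for c in dose_cols if c in df.columns]
    if not dose_cols:
        raise ValueError("no dose columns found")
    gc = list(group_cols)
    is_control = (df[dose_cols] == 0).all(axis=1)
    df["is_control"] = is_control

    ctrl_mean = df[is_control].groupby(gc)[readout_col].mean()
    all_groups = set(df.groupby(gc).groups)
    missing = all_groups - set(ctrl_mean.index)
    if missing:
        raise ValueError(f"missing zero-dose control group for: {sorted(missing)}")
    bad = ctrl_mean[(~np.isfinite(ctrl_mean)) | (ctrl_mean == 0)]
    if not bad.empty:
        raise ValueError(f"degenerate control mean for: {list(bad.index)}")
    key = pd.MultiIndex.from_frame(df[gc]) if len(gc) > 1 else pd.Index(df[gc[0]])
    df["fold_change"] = df[readout_col].to_numpy() / ctrl_mean.reindex(key).to_numpy()
    return df


def classify_cdi(
    cdi: float,
    synergy_cut: float = 0.95,
    strong_cut: float = 0.7,
    additive_band: tuple[float, float] = (0.95, 1.05),
) -> CdiClass:
    """Map a CDI value onto interaction classes.

    strong synergy below ``strong_cut``; synergy up to ``synergy_cut``;
    additive within ``additive_band``; antagonism above it.  The bands
    partition (0, inf) totally and deterministically.
    """
    if cdi <= 0:
        raise ValueError("CDI must be positive")
    if cdi < strong_cut:
        return "strong_synergy"
    if cdi < synergy_cut:
        return "synergy"
    if cdi <= additive_band[1]:
        return "additive"
    return "antagonism"


def compute_cdi(
    a: float,
    b: float,
    ab: float,
    synergy_cut: float = 0.95,
    strong_cut: float = 0.7,
    additive_band: tuple[float, float] = (0.95, 1.05),
) -> CdiResult:
    """CDI = AB / (A x B) from single-agent and combination fold changes."""
    if a <= 0 or b <= 0 or ab <= 0:
        raise ValueError("fold changes must be positive")
    cdi = ab / (a * b)
    return CdiResult(
        a=float(a), b=float(b), ab=float(ab), cdi=float(cdi),
        label=classify_cdi(cdi, synergy_cut, strong_cut, additive_band),
    )


def cdi_from_replicates(
    a_reps: Sequence[float],
    b_reps: Sequence[float],
    ab_reps: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> CdiResult:
    """CDI from replicate fold changes, with a bootstrap confidence interval.

    A, B and AB are the means of their replicate fold changes (no
    per-replicate CDI is formed); uncertainty comes from a nonparametric
    bootstrap over replicates.
    """
    a_reps, b_reps, ab_reps = (np.asarray(x, float) for x in (a_reps, b_reps, ab_reps))
    base = compute_cdi(a_reps.mean(), b_reps.mean(), ab_reps.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        a = rng.choice(a_reps, a_reps.size).mean()
        b = rng.choice(b_reps, b_reps.size).mean()
        ab = rng.choice(ab_reps, ab_reps.size).mean()
        boots[i] = ab / (a * b)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return CdiResult(
        a=base.a, b=base.b, ab=base.ab, cdi=base.cdi, label=base.label,
        ci_low=float(lo), ci_high=float(hi),
    )


def dose_selectivity(
    table: pd.DataFrame,
    genotypes: tuple[str, str] = ("WT", "KO"),
    dose_col: str = "dose1",
    value_col: str = "fold_change",
    anova: bool = False,
) -> pd.DataFrame:
    """Per-dose genotype-selective killing: mean fold change WT minus KO.

    Requires matched dose grids in both genotypes; mismatches raise with
    the offending doses listed.  Returns per-dose means, SDs, replicate
    counts and the delta.  With ``anova=True`` a standard two-way ANOVA
    (genotype x dose, with interaction) is attached as ``result.attrs["anova"]``.
    """
    wt, ko = genotypes
    df = table[table["genotype"].isin(genotypes)]
    doses = {g: set(df.loc[df["genotype"] == g, dose_col].unique()) for g in genotypes}
    if doses[wt] != doses[ko]:
        only_wt = sorted(doses[wt] - doses[ko])
        only_ko = sorted(doses[ko] - doses[wt])
        raise ValueError(f"unmatched dose grids: only in {wt}: {only_wt}; only in {ko}: {only_ko}")
    agg = (
        df.groupby(["genotype", dose_col])[value_col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .pivot(index=dose_col, columns="genotype")
    )
    out = pd.DataFrame(
        {
            "dose": agg.index,
            f"mean_{wt}": agg[("mean", wt)].to_numpy(),
            f"mean_{ko}": agg[("mean", ko)].to_numpy(),
            f"sd_{wt}": agg[("sd", wt)].to_numpy(),
            f"sd_{ko}": agg[("sd", ko)].to_numpy(),
            f"n_{wt}": agg[("n", wt)].to_numpy(),
            f"n_{ko}": agg[("n", ko)].to_numpy(),
        }
    ).reset_index(drop=True)
    out["delta"] = out[f"mean_{wt}"] - out[f"mean_{ko}"]
    if anova:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols(
            f"{value_col} ~ C(genotype) * C({dose_col})",
            data=df.rename(columns={value_col: value_col, dose_col: dose_col}),
        ).fit()
        out.attrs["anova"] = sm.stats.anova_lm(model, typ=2)
    return out
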