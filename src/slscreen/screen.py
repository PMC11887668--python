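"""Plate-based RNAi screen analysis.

Implements the primary analysis chain for a two-genotype synthetic-lethal
viability screen: ingestion of long-format plate readouts, removal of
multiplicative row/column plate artifacts by alternating median division,
per-replicate Z-scoring against the library-well distribution, differential
hit calling between a knockout and a wild-type genotype, edge-position
artifact flagging, and replicate-correlation quality control.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with
one row per well, wrapped in :class:`ScreenDataset` together with the plate
geometry.
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateGeometry",
    "ScreenDataset",
    "ConvergenceInfo",
    "PositionEffectReport",
    "CorrelationSummary",
    "ROLES",
    "read_screen_table",
    "normalize_plate",
    "normalize_dataset",
    "compute_zscores",
    "call_hits",
    "flag_position_effects",
    "position_effect_report",
    "replicate_correlation",
]

#: Recognised well roles.  ``library`` wells carry screening reagents and
#: define all normalization/Z statistics; controls are transformed alongside
#: but never enter a median or a mean/SD fit.
ROLES = frozenset({"library", "negative_control", "positive_control", "empty"})

WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


@dataclass(frozen=True)
class PlateGeometry:
    """Rectangular plate layout, rows lettered from ``A``, columns 1-based."""

    n_rows: int = 16
    n_cols: int = 24

    @property
    def row_labels(self) -> list[str]:
        return list(string.ascii_uppercase[: self.n_rows])

    def parse_well(self, well: str) -> tuple[int, int]:
        """Convert an ``A01``-style label to 1-based (row, col) indices."""
        m = WELL_RE.match(str(well).strip())
        if not m:
            raise ValueError(f"malformed well coordinate: {well!r}")
        row = ord(m.group(1).upper()) - ord("A") + 1
        col = int(m.group(2))
        if not 1 <= row <= self.n_rows:
            raise ValueError(f"row out of range for {well!r} on {self.n_rows}x{self.n_cols} plate")
        if not 1 <= col <= self.n_cols:
            raise ValueError(f"column out of range for {well!r} on {self.n_rows}x{self.n_cols} plate")
        return row, col


#: Columns every well table must carry.
WELL_COLUMNS = ["plate", "row", "col", "reagent", "role", "genotype", "replicate", "readout"]


@dataclass
class ScreenDataset:
    """A plate-structured screen: one tidy row per well.

    ``wells`` columns: plate, row (1-based int), col (1-based int), reagent,
    role, genotype, replicate (int), readout; after normalization an
    additional ``value`` column holds the unitless normalized readout.
    """

    wells: pd.DataFrame
    geometry: PlateGeometry = field(default_factory=PlateGeometry)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"well table missing columns: {missing}")
        bad_roles = set(self.wells["role"].unique()) - ROLES
        if bad_roles:
            raise ValueError(f"unknown well role(s): {sorted(bad_roles)}")
        key = ["genotype", "replicate", "plate", "row", "col"]
        if self.wells.duplicated(key).any():
            dup = self.wells[self.wells.duplicated(key, keep=False)].iloc[0]
            raise ValueError(
                f"duplicate well: plate {dup['plate']} row {dup['row']} col {dup['col']}"
            )
        readout = self.wells["readout"]
        if not np.issubdtype(readout.dtype, np.number):
            raise ValueError("readout column must be numeric")
        if (readout.dropna() < 0).any():
            raise ValueError("negative readout encountered")

    @property
    def value_column(self) -> str:
        return "value" if "value" in self.wells.columns else "readout"

    def replicate_keys(self) -> list[tuple[str, int]]:
        """Sorted (genotype, replicate) pairs present in the dataset."""
        return sorted(
            self.wells[["genotype", "replicate"]].drop_duplicates().itertuples(index=False)
        )


def read_screen_table(path, geometry: PlateGeometry | None = None, sep: str | None = None) -> ScreenDataset:
    """Read a long-format screen table (TSV or CSV) into a :class:`ScreenDataset`.

    Expected columns: ``plate``, ``well`` (``A01`` dialect) *or* ``row``/``col``,
    ``reagent``, ``role``, ``genotype``, ``replicate``, ``readout``.
    """
    geometry = geometry or PlateGeometry()
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("plate", "reagent", "role", "genotype", "replicate", "readout"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    if "well" in df.columns:
        parsed = [geometry.parse_well(w) for w in df["well"]]
        df["row"] = [r for r, _ in parsed]
        df["col"] = [c for _, c in parsed]
    elif {"row", "col"} <= set(df.columns):
        if df["row"].dtype == object:  # letter rows
            df["row"] = [ord(str(r).strip().upper()) - ord("A") + 1 for r in df["row"]]
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        if (df["row"] < 1).any() or (df["row"] > geometry.n_rows).any():
            raise ValueError("row out of range")
        if (df["col"] < 1).any() or (df["col"] > geometry.n_cols).any():
            raise ValueError("column out of range")
    else:
        raise ValueError("need a 'well' column or 'row'/'col' columns")
    df["readout"] = pd.to_numeric(df["readout"], errors="raise")
    df["replicate"] = df["replicate"].astype(int)
    return ScreenDataset(df[WELL_COLUMNS].copy(), geometry)


@dataclass(frozen=True)
class ConvergenceInfo:
    """Outcome of the alternating median normalization of one plate."""

    iterations: int
    residual: float
    converged: bool


def _masked_median(values: np.ndarray, mask: np.ndarray, axis: int) -> np.ndarray:
    """Median over library wells along ``axis``; NaN where < 2 wells."""
    lib = np.where(mask, values, np.nan)
    counts = np.sum(mask & np.isfinite(values), axis=axis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(lib, axis=axis)
    med = np.where(counts >= 2, med, np.nan)
    return med


def normalize_plate(
    plate_values: np.ndarray,
    library_mask: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 25,
) -> tuple[np.ndarray, ConvergenceInfo]:
    """Remove row/column biases by alternating median division in ratio space.

    Each pass divides every well by the median of the library wells in its
    row, then by the median of the library wells in its column, iterating
    until all row and column medians of the library wells lie within
    ``tol`` of 1.  Control and empty wells (``library_mask`` False) are
    excluded from the medians but divided by the same factors.  A purely
    multiplicative plate ``g * r_i * c_j`` is mapped exactly to all-ones.

    Rows or columns with fewer than two usable library wells are skipped
    (factor 1) with a warning; a zero median raises ``ValueError``.
    """
    values = np.asarray(plate_values, dtype=float).copy()
    if values.ndim != 2:
        raise ValueError("plate must be a 2-D matrix")
    mask = np.ones_like(values, dtype=bool) if library_mask is None else np.asarray(library_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("library_mask shape mismatch")

    def residual() -> float:
        rm = _masked_median(values, mask, axis=1)
        cm = _masked_median(values, mask, axis=0)
        meds = np.concatenate([rm, cm])
        meds = meds[np.isfinite(meds)]
        if meds.size == 0:
            return 0.0
        return float(np.max(np.abs(meds - 1.0)))

    # lines with a single usable library well are suspicious and skipped with
    # a warning; lines with none at all (e.g. all-control columns) are
    # structural and skip silently
    n_single = 0
    for axis in (1, 0):
        counts = np.sum(mask & np.isfinite(values), axis=axis)
        n_single += int((counts == 1).sum())
    if n_single:
        warnings.warn(
            f"{n_single} row(s)/column(s) with <2 library wells skipped", stacklevel=2
        )

    # converge a notch below tol so that a re-run moves no value by more
    # than tol (each pass divides by medians within the residual of 1)
    inner_tol = tol / 4
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for axis, shape in ((1, (-1, 1)), (0, (1, -1))):
            med = _masked_median(values, mask, axis=axis)
            if np.any(med == 0):
                raise ValueError("degenerate plate: zero row/column median")
            med = np.where(np.isfinite(med), med, 1.0)
            values = values / med.reshape(shape)
        res = residual()
        if res <= inner_tol:
            return values, ConvergenceInfo(iterations, res, True)
    return values, ConvergenceInfo(iterations, residual(), False)


def normalize_dataset(
    dataset: ScreenDataset, tol: float = 1e-6, max_iter: int = 25
) -> ScreenDataset:
    """Normalize every plate of every replicate screen.

    Returns a new dataset whose ``value`` column holds row/column-median
    normalized readouts; per-plate convergence diagnostics are attached as
    ``dataset.convergence_info`` keyed by (genotype, replicate, plate).
    """
    geo = dataset.geometry
    df = dataset.wells.copy()
    df["value"] = np.nan
    info: dict[tuple, ConvergenceInfo] = {}
    for (genotype, replicate, plate), idx in df.groupby(
        ["genotype", "replicate", "plate"], sort=False
    ).groups.items():
        sub = df.loc[idx]
        mat = np.full((geo.n_rows, geo.n_cols), np.nan)
        mask = np.zeros((geo.n_rows, geo.n_cols), dtype=bool)
        r = sub["row"].to_numpy() - 1
        c = sub["col"].to_numpy() - 1
        mat[r, c] = sub["readout"].to_numpy()
        mask[r, c] = sub["role"].to_numpy() == "library"
        norm, conv = normalize_plate(mat, mask, tol=tol, max_iter=max_iter)
        df.loc[idx, "value"] = norm[r, c]
        info[(genotype, replicate, plate)] = conv
    out = ScreenDataset(df, geo)
    out.convergence_info = info  # type: ignore[attr-defined]
    return out


def compute_zscores(
    dataset: ScreenDataset, robust: bool = False
) -> pd.DataFrame:
    """Per-replicate Z-scores for every reagent.

    The standardizing mean and sample (n-1) SD are fit on the library wells
    of each replicate screen only; control reagents receive Z-scores from
    the library fit but never influence it.  With ``robust=True`` the fit
    uses median and scaled MAD instead.

    Returns a wide table indexed by reagent with MultiIndex columns
    ``(genotype, replicate)``; a ``role`` column records each reagent's role.
    """
    df = dataset.wells
    value_col = dataset.value_column
    records = []
    for (genotype, replicate), sub in df.groupby(["genotype", "replicate"], sort=True):
        scored = sub[sub["role"] != "empty"]
        lib = scored.loc[scored["role"] == "library", value_col].dropna()
        if robust:
            center = float(lib.median())
            scale = float(stats.median_abs_deviation(lib, scale="normal"))
        else:
            center = float(lib.mean())
            scale = float(lib.std(ddof=1))
        if not np.isfinite(scale) or scale == 0:
            raise ValueError(
                f"degenerate replicate ({genotype}, {replicate}): zero spread in library wells"
            )
        z = (scored[value_col] - center) / scale
        rec = pd.DataFrame(
            {
                "reagent": scored["reagent"],
                "role": scored["role"],
                "genotype": genotype,
                "replicate": replicate,
                "z": z,
            }
        )
        records.append(rec)
    long = pd.concat(records, ignore_index=True)
    # a control reagent occupies many wells: average its Z per replicate
    long = long.groupby(["reagent", "role", "genotype", "replicate"], as_index=False)["z"].mean()
    wide = long.pivot_table(index=["reagent", "role"], columns=["genotype", "replicate"], values="z")
    wide = wide.reset_index(level="role")
    return wide


def call_hits(
    zscores: pd.DataFrame,
    threshold: float = -1.5,
    min_fraction: float = 2 / 3,
    rule: Literal["replicate_fraction", "median_z"] = "replicate_fraction",
    ko: str = "KO",
    wt: str = "WT",
) -> pd.DataFrame:
    """Call differential (synthetic-lethal) hits between two genotypes.

    ``replicate_fraction`` (the default): a reagent is a hit when the
    fraction of KO replicates with Z strictly below ``threshold`` is at
    least ``min_fraction`` *and* the fraction of WT replicates with
    Z >= ``threshold`` is at least ``min_fraction``.  ``median_z``: hit when
    median KO Z < ``threshold`` and median WT Z >= ``threshold``.

    Reagents with fewer than two non-missing Z values in either genotype
    are reported with ``callable = False`` and are never hits.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if rule not in ("replicate_fraction", "median_z"):
        raise ValueError(f"unknown rule: {rule}")
    cols = zscores.columns
    genotypes = {g for g in cols.get_level_values(0) if g != "role"}
    for g in (ko, wt):
        if g not in genotypes:
            raise ValueError(f"genotype {g!r} missing from Z table")

    zko = zscores[ko]
    zwt = zscores[wt]
    n_ko = zko.notna().sum(axis=1)
    n_wt = zwt.notna().sum(axis=1)
    callable_ = (n_ko >= 2) & (n_wt >= 2)

    ko_pass = zko.lt(threshold)
    wt_pass = zwt.ge(threshold)
    ko_frac = ko_pass.sum(axis=1) / n_ko.replace(0, np.nan)
    wt_frac = wt_pass.sum(axis=1) / n_wt.replace(0, np.nan)

    if rule == "replicate_fraction":
        is_hit = (ko_frac >= min_fraction) & (wt_frac >= min_fraction)
    else:
        is_hit = zko.median(axis=1).lt(threshold) & zwt.median(axis=1).ge(threshold)
    is_hit &= callable_

    if "role" in zscores.columns:
        role = zscores["role"]
        if isinstance(role, pd.DataFrame):  # MultiIndex column ('role', '')
            role = role.iloc[:, 0]
    else:
        role = pd.Series("library", index=zscores.index)
    out = pd.DataFrame(
        {
            "role": role,
            "is_hit": is_hit.fillna(False),
            "callable": callable_,
            "ko_pass_fraction": ko_frac,
            "wt_pass_fraction": wt_frac,
            "ko_median_z": zko.median(axis=1),
            "wt_median_z": zwt.median(axis=1),
        },
        index=zscores.index,
    )
    for r in zko.columns:
        out[f"ko_rep{r}_pass"] = ko_pass[r]
    for r in zwt.columns:
        out[f"wt_rep{r}_pass"] = wt_pass[r]
    out.attrs.update({"threshold": threshold, "min_fraction": min_fraction, "rule": rule})
    return out


def screen_pipeline(
    dataset: ScreenDataset,
    threshold: float = -1.5,
    min_fraction: float = 2 / 3,
    rule: Literal["replicate_fraction", "median_z"] = "replicate_fraction",
    ko: str = "KO",
    wt: str = "WT",
) -> tuple[ScreenDataset, pd.DataFrame, pd.DataFrame]:
    """Run normalize -> Z-score -> hit calling and return all three stages."""
    normalized = normalize_dataset(dataset)
    zscores = compute_zscores(normalized)
    hits = call_hits(zscores, threshold=threshold, min_fraction=min_fraction, rule=rule, ko=ko, wt=wt)
    return normalized, zscores, hits


@dataclass(frozen=True)
class PositionEffectReport:
    """Edge-vs-interior diagnostic for one assay plate (report only)."""

    plate_id: str
    edge_vs_interior_effect: float
    log2_effect: float
    test_p: float
    flagged: bool
    n_edge: int
    n_interior: int


def flag_position_effects(
    plate_values: np.ndarray,
    library_mask: np.ndarray | None = None,
    alpha: float = 0.01,
    min_effect: float = 0.5,
    plate_id: str = "",
) -> PositionEffectReport:
    """Test one plate for an edge position effect.

    Compares the outermost ring of library wells against the interior with
    a two-sided Wilcoxon rank-sum (Mann-Whitney U) test; the plate is
    flagged when ``p < alpha`` and the |log2 ratio of medians| exceeds
    ``min_effect``.  Purely diagnostic: the data are never mutated, and
    exclusion of a flagged plate is a user decision.
    """
    values = np.asarray(plate_values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if library_mask is None else np.asarray(library_mask, bool)
    nr, nc = values.shape
    ring = np.zeros_like(mask)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    edge = values[ring & mask & np.isfinite(values)]
    interior = values[~ring & mask & np.isfinite(values)]
    if len(edge) < 10 or len(interior) < 10:
        warnings.warn(f"plate {plate_id or '?'}: too few wells for position-effect test", stacklevel=2)
        return PositionEffectReport(plate_id, np.nan, np.nan, np.nan, False, len(edge), len(interior))
    effect = float(np.median(edge) / np.median(interior))
    log2_effect = float(np.log2(effect))
    p = float(stats.mannwhitneyu(edge, interior, alternative="two-sided").pvalue)
    flagged = (p < alpha) and (abs(log2_effect) > min_effect)
    return PositionEffectReport(plate_id, effect, log2_effect, p, flagged, len(edge), len(interior))


def position_effect_report(
    dataset: ScreenDataset, alpha: float = 0.01, min_effect: float = 0.5
) -> pd.DataFrame:
    """Run :func:`flag_position_effects` on every plate of every replicate."""
    geo = dataset.geometry
    rows = []
    for (genotype, replicate, plate), sub in dataset.wells.groupby(
        ["genotype", "replicate", "plate"], sort=True
    ):
        mat = np.full((geo.n_rows, geo.n_cols), np.nan)
        mask = np.zeros((geo.n_rows, geo.n_cols), dtype=bool)
        r = sub["row"].to_numpy() - 1
        c = sub["col"].to_numpy() - 1
        mat[r, c] = sub["readout"].to_numpy()
        mask[r, c] = sub["role"].to_numpy() == "library"
        rep = flag_position_effects(mat, mask, alpha=alpha, min_effect=min_effect, plate_id=str(plate))
        rows.append(
            {
                "genotype": genotype,
                "replicate": replicate,
                "plate": plate,
                "effect": rep.edge_vs_interior_effect,
                "log2_effect": rep.log2_effect,
                "test_p": rep.test_p,
                "flagged": rep.flagged,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationSummary:
    """Pairwise replicate Pearson correlations within each genotype."""

    pairs: pd.DataFrame  # genotype, rep_a, rep_b, r, n
    min: float
    max: float
    mean: float


def replicate_correlation(
    dataset: ScreenDataset, subset: Literal["library", "control"] = "library"
) -> CorrelationSummary:
    """Pearson correlation between replicate screens, a screen-quality metric.

    Library wells are paired by reagent; control wells by plate/well
    position.  Requires at least two replicates per genotype and three
    shared points per pair.
    """
    df = dataset.wells
    value_col = dataset.value_column
    if subset == "library":
        sel = df[df["role"] == "library"]
        key = ["plate", "reagent"]
    elif subset == "control":
        sel = df[df["role"].isin(["negative_control", "positive_control"])]
        key = ["plate", "row", "col"]
    else:
        raise ValueError(f"unknown subset: {subset}")
    rows = []
    for genotype, sub in sel.groupby("genotype", sort=True):
        wide = sub.pivot_table(index=key, columns="replicate", values=value_col)
        reps = list(wide.columns)
        if len(reps) < 2:
            raise ValueError(f"genotype {genotype!r}: need >= 2 replicates")
        for a, b in combinations(reps, 2):
            paired = wide[[a, b]].dropna()
            if len(paired) < 3:
                raise ValueError(f"genotype {genotype!r} replicates {a},{b}: < 3 shared points")
            r = float(stats.pearsonr(paired[a], paired[b]).statistic)
            rows.append({"genotype": genotype, "rep_a": a, "rep_b": b, "r": r, "n": len(paired)})
    pairs = pd.DataFrame(rows)
    return CorrelationSummary(
        pairs, float(pairs["r"].min()), float(pairs["r"].max()), float(pairs["r"].mean())
    )
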