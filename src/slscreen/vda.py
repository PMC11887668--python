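"""Variable Dose Analysis (VDA) viability scoring from per-cell fluorescence.

In a VDA assay each cell in a transfected population receives a different
dose of shRNA, reported by a co-transfected fluorescent marker (GFP).  If
the knockdown is lethal, high-dose (bright) cells are selectively depleted,
so the distribution of reporter intensity among surviving cells shifts
down.  Viability is quantified as the area under the inverted cumulative
distribution (the survival function) of log-intensity among gated
reporter-positive cells, linearly rescaled so that a neutral shRNA control
scores 1 and a lethal control scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "CellPopulation",
    "VdaCurve",
    "VdaScore",
    "gate_positive",
    "dynamic_range",
    "inverted_cdf_auc",
    "normalize_vda",
    "selectivity",
    "best_shrna",
]


@dataclass
class CellPopulation:
    """Per-cell fluorescence events for one sample."""

    events: np.ndarray
    label: Literal["test", "negative_control", "positive_control", "untransfected"] = "test"
    genotype: str = "WT"
    reagent_id: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float).ravel()
        if not np.all(np.isfinite(self.events)):
            raise ValueError("non-finite fluorescence intensity")
        if np.any(self.events < 0):
            raise ValueError("negative fluorescence intensity")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class VdaCurve:
    """Survival function of log10 intensity on an even grid over [lo, hi]."""

    grid: np.ndarray        # log10-intensity grid, length = grid_points
    survival: np.ndarray    # fraction of events strictly above each grid point
    lo: float
    hi: float
    auc: float              # trapezoidal area, normalized to axis length 1


@dataclass(frozen=True)
class VdaScore:
    """Normalized VDA viability for one sample (1 = neutral, 0 = lethal)."""

    auc: float
    viability: float
    genotype: str = ""
    reagent_id: str = ""
    in_range: bool = True   # False when viability falls outside [0, 1]


def gate_positive(
    population: CellPopulation | np.ndarray,
    untransfected_reference: CellPopulation | np.ndarray | None = None,
    quantile: float = 0.99,
    threshold: float | None = None,
    min_reference_events: int = 200,
) -> tuple[np.ndarray, float]:
    """Gate reporter-positive cells against an untransfected reference.

    The gate is the reference population's ``quantile`` (default 99th
    percentile); events strictly above it count as transfected.  Returns
    the gated intensities and the transfection efficiency (gated fraction
    of the test population).  An absolute ``threshold`` may replace the
    reference.
    """
    events = population.events if isinstance(population, CellPopulation) else np.asarray(population, float)
    if threshold is None:
        if untransfected_reference is None:
            raise ValueError("need an untransfected reference or an absolute threshold")
        ref = (
            untransfected_reference.events
            if isinstance(untransfected_reference, CellPopulation)
            else np.asarray(untransfected_reference, float)
        )
        if len(ref) < min_reference_events:
            raise ValueError(f"reference has {len(ref)} events; need >= {min_reference_events}")
        threshold = float(np.quantile(ref, quantile))
    gated = events[events > threshold]
    if gated.size == 0:
        raise ValueError("no positive events above the gate")
    return gated, gated.size / events.size


def dynamic_range(populations: Iterable[np.ndarray | CellPopulation]) -> tuple[float, float]:
    """Pooled log10 intensity range of the given (typically control) samples.

    Fixing [lo, hi] per experiment from pooled controls makes AUC values
    comparable across samples of a batch.
    """
    pooled = np.concatenate(
        [p.events if isinstance(p, CellPopulation) else np.asarray(p, float) for p in populations]
    )
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise ValueError("no positive intensities to define a dynamic range")
    logs = np.log10(pooled)
    lo, hi = float(logs.min()), float(logs.max())
    if hi <= lo:
        raise ValueError("degenerate dynamic range")
    return lo, hi


def inverted_cdf_auc(
    population: CellPopulation | np.ndarray,
    lo: float,
    hi: float,
    grid_points: int = 256,
) -> VdaCurve:
    """Survival curve of log10 intensity and its normalized area.

    Intensities are log10-transformed (values <= 0 clamp to ``lo``); the
    survival function — the fraction of events strictly above x — is
    evaluated on an even ``grid_points`` grid spanning [lo, hi] and
    integrated by the trapezoidal rule, normalized so a curve pinned at 1
    across the whole axis has area 1.
    """
    if hi <= lo:
        raise ValueError("degenerate dynamic range")
    events = population.events if isinstance(population, CellPopulation) else np.asarray(population, float)
    if events.size == 0:
        raise ValueError("no gated events")
    logs = np.where(events > 0, np.log10(np.maximum(events, np.finfo(float).tiny)), lo)
    grid = np.linspace(lo, hi, grid_points)
    # survival(x) = P(intensity > x); searchsorted on the sorted sample
    srt = np.sort(logs)
    survival = 1.0 - np.searchsorted(srt, grid, side="right") / logs.size
    auc = float(np.trapezoid(survival, grid) / (hi - lo))
    return VdaCurve(grid=grid, survival=survival, lo=lo, hi=hi, auc=auc)


def normalize_vda(
    auc_test: float,
    auc_neg: float,
    auc_pos: float,
    genotype: str = "",
    reagent_id: str = "",
) -> VdaScore:
    """Rescale a raw AUC between the control anchors.

    viability = (auc_test - auc_pos) / (auc_neg - auc_pos); the negative
    (neutral) control maps to exactly 1 and the positive (lethal) control
    to exactly 0.  Values outside [0, 1] are possible for extreme samples
    and are flagged rather than clipped.
    """
    if auc_neg == auc_pos:
        raise ValueError("controls not separated: auc_neg == auc_pos")
    viability = (auc_test - auc_pos) / (auc_neg - auc_pos)
    return VdaScore(
        auc=float(auc_test),
        viability=float(viability),
        genotype=genotype,
        reagent_id=reagent_id,
        in_range=0.0 <= viability <= 1.0,
    )


@dataclass(frozen=True)
class Selectivity:
    """Genotype-selective viability reduction for one reagent."""

    delta: float
    selective: bool


def selectivity(viab_ko: float, viab_wt: float, min_delta: float = 0.10) -> Selectivity:
    """Score genotype selectivity of a knockdown.

    delta = viability(WT) - viability(KO); the reagent is selective when
    the KO reduction strictly exceeds ``min_delta`` (default: the >10%
    reduction rule).
    """
    delta = viab_wt - viab_ko
    return Selectivity(delta=float(delta), selective=bool(delta > min_delta))


def best_shrna(
    deltas: Mapping[str, float],
    viab_ko: Mapping[str, float] | None = None,
) -> tuple[str, float]:
    """Pick the most selective shRNA for a gene.

    Maximal delta wins; ties break toward the lower KO viability (the more
    lethal reagent), then the lexically smaller identifier.
    """
    if not deltas:
        raise ValueError("no shRNA scores supplied")
    viab_ko = viab_ko or {}

    def sort_key(item):
        sh, delta = item
        return (-delta, viab_ko.get(sh, np.inf), sh)

    sh, delta = min(deltas.items(), key=sort_key)
    return sh, float(delta)
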