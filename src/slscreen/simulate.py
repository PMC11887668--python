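"""Synthetic data with the statistical structure the analysis stages assume.

Three generators, all seed-deterministic and all returning ground truth
alongside the data, so every pipeline stage can be exercised and its
operating characteristics (sensitivity, false-positive rate, rank
recovery, CDI calibration) measured without any external data.

* :func:`simulate_screen` — a two-genotype, multi-plate, replicated
  viability screen with multiplicative row/column plate biases, optional
  edge-well artifacts on a subset of plates, lognormal measurement noise,
  and planted genotype-selective (synthetic-lethal) and broadly lethal
  gene effects.
* :func:`simulate_vda_population` — per-cell reporter-fluorescence events
  in which each cell's shRNA dose is random and lethal knockdowns deplete
  high-dose (bright) cells.
* :func:`simulate_combo` — Hill-curve single-agent responses combined
  under Bliss independence scaled by a known synergy factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .screen import PlateGeometry, ScreenDataset
from .vda import CellPopulation

__all__ = [
    "ScreenSimConfig",
    "VdaSimConfig",
    "HillCurve",
    "ComboSimConfig",
    "simulate_screen",
    "simulate_vda_population",
    "simulate_combo",
]


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for a simulated two-genotype screen.

    Defaults mirror a genome-scale triplicate screen: ~10,000 library
    reagents on 384-well plates (controls in the two rightmost columns),
    1% planted synthetic-lethal genes that drop KO viability to 40% of
    baseline, 2% broadly lethal genes at 30% in both genotypes,
    +/-0.3 log2 multiplicative row/column biases, a x0.5 edge artifact on
    5% of assay plates, and 12% lognormal measurement noise.
    """

    n_genes: int = 10_000
    replicates: int = 3
    planted_sl_fraction: float = 0.01
    sl_effect: float = 0.4            # KO viability multiplier for planted genes
    wt_lethal_fraction: float = 0.02
    wt_lethal_effect: float = 0.3     # viability multiplier in both genotypes
    row_col_bias_log2: float = 0.3    # biases ~ 2**U(-b, b)
    edge_effect_fraction: float = 0.05
    edge_effect_magnitude: float = 0.5
    noise_cv: float = 0.12
    baseline: float = 1.0e4           # arbitrary luminescence units
    pos_control_effect: float = 0.15
    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    n_control_cols: int = 2           # rightmost columns reserved for controls
    genotypes: tuple[str, str] = ("WT", "KO")

    def __post_init__(self) -> None:
        for name in ("planted_sl_fraction", "wt_lethal_fraction", "edge_effect_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("sl_effect", "wt_lethal_effect", "edge_effect_magnitude", "pos_control_effect"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.geometry.n_cols - self.n_control_cols < 1:
            raise ValueError("geometry too small for the control layout")


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_screen(config: ScreenSimConfig, seed: int) -> tuple[ScreenDataset, pd.DataFrame]:
    """Generate a plate-structured screen plus its ground-truth gene labels.

    Per-well readout = baseline x gene effect (genotype-dependent) x row
    bias x column bias x edge factor x lognormal noise.  The reagent map
    (gene -> plate/well) is identical across replicates and genotypes, as
    in a real arrayed library; plate biases and edge artifacts are drawn
    independently for every physical assay plate.

    Returns the dataset and a truth table with one row per gene and its
    class: ``neutral``, ``synthetic_lethal`` or ``broadly_lethal``.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    geo = cfg.geometry
    n_lib_cols = geo.n_cols - cfg.n_control_cols
    wells_per_plate = geo.n_rows * n_lib_cols
    n_plates = math.ceil(cfg.n_genes / wells_per_plate)

    genes = np.array([f"gene_{i + 1:05d}" for i in range(cfg.n_genes)])
    classes = np.full(cfg.n_genes, "neutral", dtype=object)
    n_sl = int(round(cfg.planted_sl_fraction * cfg.n_genes))
    n_wl = int(round(cfg.wt_lethal_fraction * cfg.n_genes))
    special = rng.choice(cfg.n_genes, size=n_sl + n_wl, replace=False)
    classes[special[:n_sl]] = "synthetic_lethal"
    classes[special[n_sl:]] = "broadly_lethal"

    # genotype-specific viability multiplier per gene
    effect = {g: np.ones(cfg.n_genes) for g in cfg.genotypes}
    wt, ko = cfg.genotypes
    effect[ko][classes == "synthetic_lethal"] = cfg.sl_effect
    for g in cfg.genotypes:
        effect[g][classes == "broadly_lethal"] = cfg.wt_lethal_effect

    # static library layout: plate-major, row-major within plate; slots past
    # the last gene are empty wells (media only)
    slots = n_plates * wells_per_plate
    slot_idx = np.arange(slots)
    gene_plate = slot_idx // wells_per_plate
    within = slot_idx % wells_per_plate
    gene_row = within // n_lib_cols + 1
    gene_col = within % n_lib_cols + 1
    slot_valid = slot_idx < cfg.n_genes
    slot_reagent = np.where(slot_valid, np.resize(genes, slots), "")
    slot_role = np.where(slot_valid, "library", "empty")
    empty_background = 0.02  # residual luminescence of a cell-free well

    sigma = _lognormal_sigma(cfg.noise_cv)
    half = geo.n_rows * cfg.n_control_cols // 2
    ctrl_roles = np.array(
        ["negative_control"] * half + ["positive_control"] * (geo.n_rows * cfg.n_control_cols - half)
    )
    ctrl_effect = {
        "negative_control": 1.0,
        "positive_control": cfg.pos_control_effect,
    }
    ctrl_cols = np.repeat(np.arange(n_lib_cols + 1, geo.n_cols + 1), geo.n_rows)
    ctrl_rows = np.tile(np.arange(1, geo.n_rows + 1), cfg.n_control_cols)

    frames = []
    for genotype in cfg.genotypes:
        for rep in range(1, cfg.replicates + 1):
            for p in range(n_plates):
                on_plate = gene_plate == p
                valid = slot_valid[on_plate]
                rows = np.concatenate([gene_row[on_plate], ctrl_rows])
                cols = np.concatenate([gene_col[on_plate], ctrl_cols])
                reagents = np.concatenate([slot_reagent[on_plate], ctrl_roles])
                roles = np.concatenate([slot_role[on_plate], ctrl_roles])
                slot_eff = np.where(
                    valid,
                    effect[genotype][np.minimum(slot_idx[on_plate], cfg.n_genes - 1)],
                    empty_background,
                )
                eff = np.concatenate(
                    [slot_eff, np.array([ctrl_effect[r] for r in ctrl_roles])]
                )
                row_bias = 2.0 ** rng.uniform(-cfg.row_col_bias_log2, cfg.row_col_bias_log2, geo.n_rows)
                col_bias = 2.0 ** rng.uniform(-cfg.row_col_bias_log2, cfg.row_col_bias_log2, geo.n_cols)
                edge = np.ones((geo.n_rows, geo.n_cols))
                if rng.random() < cfg.edge_effect_fraction:
                    edge[0, :] = edge[-1, :] = cfg.edge_effect_magnitude
                    edge[:, 0] = edge[:, -1] = cfg.edge_effect_magnitude
                noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, rows.size))
                readout = (
                    cfg.baseline
                    * eff
                    * row_bias[rows - 1]
                    * col_bias[cols - 1]
                    * edge[rows - 1, cols - 1]
                    * noise
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": f"P{p + 1:03d}",
                            "row": rows,
                            "col": cols,
                            "reagent": reagents,
                            "role": roles,
                            "genotype": genotype,
                            "replicate": rep,
                            "readout": readout,
                        }
                    )
                )
    wells = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({"gene": genes, "class": classes})
    truth["is_synthetic_lethal"] = truth["class"] == "synthetic_lethal"
    return ScreenDataset(wells, geo), truth


# ---------------------------------------------------------------------------
# VDA simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VdaSimConfig:
    """Study conditions for a simulated VDA flow-cytometry sample.

    Each seeded cell is transfected with probability ``transfection_rate``;
    a transfected cell receives a lognormal shRNA dose whose co-expressed
    reporter adds dose-proportional fluorescence on top of lognormal
    autofluorescence.  A lethal knockdown removes cells with probability
    1 - exp(-slope x dose / median dose) before measurement, depleting the
    bright tail.  The negative-control class is wired to slope 0 and the
    positive-control class to ``pos_control_slope``.
    """

    n_events: int = 5000
    transfection_rate: float = 0.6
    dose_log10_mean: float = 2.5
    dose_log10_sd: float = 0.5
    background_log10_mean: float = 1.0
    background_log10_sd: float = 0.15
    pos_control_slope: float = 6.0
    class_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"negative_control": 0.0, "positive_control": 6.0}
    )

    def __post_init__(self) -> None:
        if not 0 < self.transfection_rate <= 1:
            raise ValueError("transfection_rate must be in (0, 1]")
        if any(s < 0 for s in self.class_slopes.values()):
            raise ValueError("lethality slopes must be >= 0")


def simulate_vda_population(
    config: VdaSimConfig,
    lethality_slope: float,
    seed: int,
    label: str = "test",
    genotype: str = "WT",
) -> CellPopulation:
    """Simulate the surviving-cell fluorescence events of one VDA sample."""
    if lethality_slope < 0:
        raise ValueError("lethality_slope must be >= 0")
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_events
    transfected = rng.random(n) < cfg.transfection_rate
    dose = np.zeros(n)
    dose[transfected] = 10.0 ** rng.normal(
        cfg.dose_log10_mean, cfg.dose_log10_sd, int(transfected.sum())
    )
    background = 10.0 ** rng.normal(cfg.background_log10_mean, cfg.background_log10_sd, n)
    intensity = background + dose  # reporter is dose-proportional
    dose_ref = 10.0 ** cfg.dose_log10_mean
    p_death = 1.0 - np.exp(-lethality_slope * dose / dose_ref)
    alive = rng.random(n) >= p_death
    return CellPopulation(events=intensity[alive], label=label, genotype=genotype)


def simulate_vda_experiment(
    config: VdaSimConfig, seed: int, genotype: str = "WT"
) -> dict[str, CellPopulation]:
    """Untransfected reference plus negative and positive control samples."""
    cfg = config
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    untransfected = CellPopulation(
        events=10.0 ** np.random.default_rng(int(sub[0])).normal(
            cfg.background_log10_mean, cfg.background_log10_sd, cfg.n_events
        ),
        label="untransfected",
        genotype=genotype,
    )
    neg = simulate_vda_population(
        cfg, cfg.class_slopes.get("negative_control", 0.0), int(sub[1]),
        label="negative_control", genotype=genotype,
    )
    pos = simulate_vda_population(
        cfg, cfg.class_slopes.get("positive_control", cfg.pos_control_slope), int(sub[2]),
        label="positive_control", genotype=genotype,
    )
    return {"untransfected": untransfected, "negative_control": neg, "positive_control": pos}


# ---------------------------------------------------------------------------
# drug combination simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillCurve:
    """Four-parameter Hill (log-logistic) dose-response in fold-change units."""

    top: float = 1.0
    bottom: float = 0.2
    ic50: float = 1.0
    slope: float = 1.5

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    def response(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            frac = (dose / self.ic50) ** self.slope
        return self.bottom + (self.top - self.bottom) / (1.0 + frac)


@dataclass(frozen=True)
class ComboSimConfig:
    """Study conditions for a simulated two-drug combination experiment.

    Single-agent fold changes follow each drug's Hill curve; the
    combination response is the Bliss-independent product scaled by
    ``1 / synergy_factor`` (factor 1 = Bliss independence, > 1 = synergy,
    < 1 = antagonism), with lognormal replicate noise.
    """

    drug_a: HillCurve = field(default_factory=HillCurve)
    drug_b: HillCurve = field(default_factory=lambda: HillCurve(ic50=2.0, slope=1.0))
    synergy_factor: float = 1.0
    replicates: int = 4
    noise_cv: float = 0.05
    baseline: float = 1.0e4
    cell_line: str = "simulated"
    genotype: str = "KO"

    def __post_init__(self) -> None:
        if self.synergy_factor <= 0:
            raise ValueError("synergy_factor must be positive")


def simulate_combo(
    config: ComboSimConfig,
    seed: int,
    dose_a: float | None = None,
    dose_b: float | None = None,
) -> pd.DataFrame:
    """Simulate a no-drug / A / B / A+B viability experiment.

    Doses default to each drug's IC50.  Returns a long-format table
    (cell_line, genotype, drug1, dose1, drug2, dose2, replicate, readout)
    ready for :func:`slscreen.drugs.fold_change`.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    dose_a = cfg.drug_a.ic50 if dose_a is None else dose_a
    dose_b = cfg.drug_b.ic50 if dose_b is None else dose_b
    fa = float(cfg.drug_a.response(dose_a))
    fb = float(cfg.drug_b.response(dose_b))
    conditions = [
        ("none", 0.0, "none", 0.0, 1.0),
        ("A", dose_a, "none", 0.0, fa),
        ("none", 0.0, "B", dose_b, fb),
        ("A", dose_a, "B", dose_b, fa * fb / cfg.synergy_factor),
    ]
    sigma = _lognormal_sigma(cfg.noise_cv)
    rows = []
    for drug1, d1, drug2, d2, mean_fc in conditions:
        noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, cfg.replicates))
        for rep, nz in enumerate(noise, start=1):
            rows.append(
                {
                    "cell_line": cfg.cell_line,
                    "genotype": cfg.genotype,
                    "drug1": drug1,
                    "dose1": d1,
                    "drug2": drug2,
                    "dose2": d2,
                    "replicate": rep,
                    "readout": cfg.baseline * mean_fc * nz,
                }
            )
    return pd.DataFrame(rows)
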