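# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the toolkit, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Screen normalization

Raw per-well luminescence from a plate-based viability screen carries
multiplicative artifacts: dispenser and incubation gradients that act on
whole rows and columns, and evaporation effects at the plate edge. We model
the readout of well (i, j) as

    y_ij = v_ij · r_i · c_j · ε_ij,

with v the biological viability, r and c row/column factors and ε lognormal
noise, and remove r and c by alternating median division: divide every well
in a row by the median of that row's *library* wells, then every well in a
column by its column median, and repeat until all row and column medians of
library wells are within `tol = 1e-6` of 1 (default cap 25 passes;
convergence is reported per plate, and internally the loop targets `tol/4`
so that re-running the normalization on its own output moves no value by
more than `tol`). A single pass removes an exact rank-1 bias; iteration
makes the row/column-median invariant exact for general plates. Median (not
mean) division keeps the estimate robust to the planted lethal tail.
Decisions:

* **Controls and empty wells are excluded from every median** but divided
  by the same factors, so a plate's control columns cannot drag the library
  distribution. Rows or columns containing no library wells (the control
  columns) are skipped silently; ones with a single usable library well are
  skipped with a warning.
* A row/column median of zero is a degenerate plate and raises rather than
  silently producing infinities.
* Alternating median polish converges linearly and can exceed 25 passes on
  small noisy plates; the default cap mirrors common screening practice and
  leaves residuals orders of magnitude below anything that affects hit
  calling, while `max_iter` can be raised where exact idempotence matters.

## Z-scores and the differential hit rule

Per replicate screen (one genotype, one replicate, all plates pooled),
normalized library values are standardized by their mean and sample (n−1)
SD. Controls receive Z-scores from the library fit but are excluded from
it, so strong positive controls cannot inflate the SD and mask hits.
Whether the original analysis used population or sample SD is not
determinable; sample SD is the conventional choice and the difference is
O(1/n) at screen scale. A median/MAD variant (`robust=True`) is available
for heavy-tailed screens but off by default.

A reagent is called a synthetic-lethal hit when

* `Z < −1.5` in at least 2/3 of KO replicates, **and**
* `Z ≥ −1.5` in at least 2/3 of wild-type replicates.

"Below" is strict and "above" inclusive, so a Z of exactly −1.5 counts as a
WT pass and a KO fail. The same 2/3 fraction applies to both clauses. An
alternative rule (`rule="median_z"`) calls a hit when the median KO Z is
below −1.5 and the median WT Z is not; the two formulations come from the
same study design and coincide for triplicates without missing data, but
the replicate-fraction version is the default because it degrades more
gracefully with missing replicates. Reagents with fewer than two usable Z
values in either genotype are reported as un-callable, never as hits.

Note a subtlety: lowering the threshold tightens the KO clause but
*relaxes* the WT clause, so hit calls are not globally monotone in the
threshold — a gene lethal in both genotypes can enter the hit list at a
more negative threshold. Raising `min_fraction` is monotone (never adds a
hit). The tests assert exactly these properties.

## Position-effect QC

Edge wells are compared to interior library wells with a two-sided
Mann-Whitney U test; a plate is flagged when p < 0.01 **and** the |log2
ratio of medians| exceeds 0.5. The double criterion keeps the flag rate at
the nominal level on null plates while catching a ×0.5 edge artifact with
near-certainty (both calibrations are tested by simulation). Flagging never
mutates or removes data: excluding a flagged plate is an explicit user
decision, which makes an otherwise manual curation step reproducible.

## Network corroboration, orthologs, grouping

False positives from reagent off-target effects rarely have physically
interacting partners in the hit list, so hits are retained only if they
share an edge with at least one *other* hit. The criterion is evaluated
against the original hit list in a single pass — by symmetry, the partner
that corroborates a hit is always retained too, so iteration cannot change
the answer. Retention is monotone in the edge set. Ortholog filtering keeps
genes with at least one mapping at or above a configurable confidence; one
screened gene may expand to several human genes. Functional grouping is the
connected components of the hit-induced subgraph — deterministic and
dependency-free, with functional labels left to manual annotation. Network
and ortholog resources are user-supplied edge lists and tables, so results
depend on the database release used; no live queries are made.

## VDA scoring

The assay premise: transfection dose varies per cell and a co-transfected
fluorescent reporter measures it, so a lethal knockdown selectively
depletes bright cells. Choices, in assay order:

* **Gating.** Reporter-positive cells are those above the 99th percentile
  of an untransfected reference (≥ 200 events required); an absolute
  threshold can replace the reference. The gated fraction doubles as the
  transfection efficiency.
* **Transform and grid.** Intensities are log10-transformed (flow data are
  scale-heavy); the survival function `S(x) = P(intensity > x)` is
  evaluated on a 256-point even grid spanning a dynamic range [lo, hi]
  fixed per batch from the pooled controls, so AUCs are comparable across
  samples. Non-positive intensities clamp to `lo`.
* **Integration.** Trapezoidal rule, normalized to axis length 1, so the
  AUC lies in [0, 1]; doubling the grid changes the AUC by less than one
  part in the grid size.
* **Normalization.** `viability = (AUC − AUC_pos)/(AUC_neg − AUC_pos)`,
  anchoring the neutral control at exactly 1 and the lethal control at
  exactly 0. Values outside [0, 1] are possible for extreme samples and are
  flagged (`in_range=False`), not clipped.
* **Selectivity.** `delta = viability(WT) − viability(KO)`; selective means
  strictly greater than 0.10. Per gene, the representative shRNA is the one
  with maximal delta, ties broken toward lower KO viability, then lexical
  id.

Scoring uses gated events only; passing the full population through the
same functions is possible by gating with `threshold=0`.

## Dose response and CDI

Fold change divides each readout by the mean zero-dose control of its cell
line, so the pooled control group has mean 1 by construction. CDI is
computed from replicate means (A, B, AB), never per replicate, with
uncertainty from a seeded nonparametric bootstrap over replicates (default
1000 resamples). Classification bands: strong synergy below 0.7, synergy
below 0.95, additive in [0.95, 1.05], antagonism above 1.05. The additive
band is a deliberate widening of the measure-zero point "CDI = 1" so that
the additive class has nonzero measure; antagonism therefore begins
strictly above 1.05. Per-dose genotype selectivity reports mean fold-change
differences with dispersions; formal inference is delegated to standard
two-way ANOVA (statsmodels), not re-derived.

## Phenotype assays

Tumor volume is `((length + width)/2) · length · width` (mm³), symmetric in
its arguments; caliper length/width order is not trusted, and a width
larger than its length is swapped with a warning. Growth curves aggregate
per arm and day with means ± SD (matching how such data are plotted) and
report percent-of-control against the vehicle arm, undefined where the
vehicle day is missing. Fly survival is `100 · alive/initial` per time
point, computed per replicate vial and averaged (vial-level averaging
preserves the between-vial dispersion). Autophagy/caspase readouts divide
signal by Hoechst per well (cell-density correction) and then by the mean
of control wells; the result is invariant to rescaling either channel.

## Synthetic data: what it emulates, and what it does not

`simulate_screen` draws per-well readouts as
`baseline · gene_effect(genotype) · row_bias · col_bias · edge_factor ·
lognormal(cv)`. Defaults define the reference study conditions: 10,000
library genes in triplicate in two genotypes on 16×24 plates (columns 23-24
reserved for negative/positive controls, mirroring common 384-well
practice); 1% of genes planted as KO-selective lethals at 0.4 of baseline;
2% broadly lethal at 0.3 in both genotypes; row/column biases 2^U(−0.3,
0.3); a ×0.5 edge artifact on a random 5% of assay plates; 12% lognormal
CV. Noise distributions are choices, not measurements — lognormal noise
and log-uniform biases were picked for positivity and multiplicative plate
physics. The generator returns ground-truth labels, enabling the measured
operating characteristics: at these conditions the pipeline recovers
planted hits with sensitivity ≥ 0.90 at a false-positive rate ≤ 0.01, and
null screens (no planted KO-selective effect) stay below a 1% hit rate.

`simulate_vda_population` gives each of 5000 seeded cells a transfection
event (rate 0.6, typical for the assay), a lognormal dose (log10 mean 2.5,
SD 0.5), reporter intensity = autofluorescence + dose, and a death
probability `1 − exp(−slope · dose/dose_ref)`; survivors are measured.
Slope 0 is wired to the neutral control and slope 6 to the lethal control
(at slope 6 a median-dose cell survives with probability `e^-6`, placing the
lethal control near the bottom of the dynamic range). Planted slopes are
recovered in rank by the measured deltas (Spearman ρ ≥ 0.9).

`simulate_combo` composes four-parameter Hill single-agent responses
(defaults: top 1, bottom 0.2, IC50-anchored doses) under Bliss independence
scaled by `1/s`; the expected CDI is analytically `1/s` in the noise-free
limit, which the tests verify at s ∈ {0.8, 1, 2}.

Passing these tests shows the chain is correct under its own generative
assumptions. Real screens add features the generators omit: spatially
correlated (non-separable) plate artifacts, reagent-specific efficacy and
off-target structure, batch drift between replicates, flow-cytometer
compensation and debris, and non-Hill drug responses. Results on real data
therefore still require the QC outputs (replicate correlations,
position-effect reports, convergence info) to be inspected.

## Problem sizes and determinism

Every generator takes an explicit integer seed and is byte-reproducible.
The test suite exercises the screen chain at genome scale (10,000 genes;
20 seeds for sensitivity/FPR, 10 for the null) and smaller two-plate
screens elsewhere; VDA calibrations use 4000-5000 events and 20 seeds;
CDI calibrations 20 seeds of 6 replicates. `scripts/acceptance.py` uses
the same sizes, deriving all streams from its `--seed`.

## Known limitations

* The normalization assumes multiplicative separable row/column biases;
  non-separable spatial artifacts (bowl shapes, corner gradients) are only
  flagged, not corrected, and no B-score/loess alternative is provided.
* Hit calling treats replicates as exchangeable; no plate-level random
  effects.
* The ortholog step trusts the supplied mapping table; "clear ortholog" is
  operationalized as a confidence threshold.
* FCS parsing is out of scope: VDA expects per-event intensity tables
  already extracted from the cytometer.
* No IC50/4PL curve fitting and no Loewe or Chou-Talalay indices; CDI is
  the only combination statistic.
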