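# Methods

This note records the models implemented in `calpain_ppi`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish.

## Solvent-accessible surface area and interface calling

SASA is computed by Shrake–Rupley quadrature. For atom *i* with van der
Waals radius *rᵢ* and probe radius *p*, `n_points` quasi-uniform test points
are placed on the expanded sphere of radius *rᵢ + p*; a point is accessible
iff it lies outside every other atom's expanded sphere, and the atom's area
is the accessible fraction times `4π(rᵢ+p)²`. Candidate occluders are
limited by a KD-tree to atoms within `rᵢ + rⱼ + 2p`, the exact geometric
bound for sphere–sphere overlap.

Choices and rationale:

* **Point set** — a spherical Fibonacci (golden-spiral) lattice. It is
  deterministic (no RNG anywhere in the SASA path, so areas are bitwise
  reproducible), nearly uniform, and its quadrature error decays roughly as
  1/n. Default `n_points = 960`: on the toy complexes, doubling to 1920
  moves per-residue areas by well under 2%, and 960 points keep a
  ~200-atom interface calculation interactive. A minimum of 32 points is
  enforced; below that the quadrature noise is comparable to the burial
  signal the method exists to measure.
* **Probe radius** — 1.4 Å, the conventional water probe.
* **Radii** — a single explicit element table (C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20 Å; anything else 1.80 Å with a warning), overridable per
  call. Publishing the table is what makes ΔSASA values reproducible;
  the exact values matter far less than their disclosure, since interface
  calling depends on a free/bound *difference* at identical radii.
* **PDB dialect** — fixed columns, first MODEL only, altloc blank/'A',
  HETATM/waters/hydrogens excluded by default. These are the conventions
  under which deposited crystal structures are directly usable for SASA
  without hydrogen placement or symmetry handling (both out of scope).

Interface classification follows the burial definition
`ΔSASA = SASA_free − SASA_bound` computed **per residue** (atom areas are
retained in `SasaResult` for inspection; the aggregation level is a design
choice — per-residue is what a mutagenesis campaign consumes). The free
state is the subunit at its bound coordinates with the partner deleted: a
rigid-body assumption appropriate for a single crystal structure, not a
relaxed unbound model. "Nonzero ΔSASA" is operationalised as
`ΔSASA > 0.1 Å²` because finite quadrature never yields exact zeros; the
threshold is configurable and the default sits two orders of magnitude
below a meaningful burial (tens of Å²).

## Consensus ranking of interface mutations

Each alanine substitution carries per-predictor values for ΔΔG_binding
(complex formation) and ΔΔG_folding (monomer stability), in kcal/mol with
positive = destabilising. The pipeline averages each quantity over the
predictors that scored the mutation, then:

1. **Stability filter**: retain iff averaged |ΔΔG_folding| ≤ 0.5 kcal/mol
   (strictly greater excludes). The folding average is `|mean(values)|` by
   default; `mean(|values|)` is available via `folding_mode` — the two
   differ when predictors disagree on sign, and the default follows the
   "absolute value of the average change" convention.
2. **Per-predictor ranks** over the retained set only (filtering precedes
   ranking), descending in ΔΔG_binding, fractional ranks for ties
   (`scipy.stats.rankdata`, mean method).
3. **Consensus**: ascending mean rank; ties broken by larger averaged
   ΔΔG_binding, then by (subunit, position) so output is deterministic.

Missing predictors are tolerated down to `min_predictors = 4` of 6 per
table (webserver outages are routine); a predictor ranks only the mutations
it scored, and the mean rank is over available predictors. Rank averaging is
invariant under any monotone per-predictor transformation, which is exactly
why it is preferred over averaging raw ΔΔG: the six predictors are on
different effective scales.

A 20-row reference table for the calpain-2 heterodimer (final ranks plus
the two averaged energies) ships with the package
(`consensus.load_table1_fixture`); it contains averages only, so the
rank-aggregation code path is validated against an independent brute-force
implementation on randomized tables instead.

## Binding models and curve fitting

All concentrations are nM internally; log transforms are base 10.

* **Hyperbolic occupancy** `L/(K_D+L)` assumes free ≈ total ligand.
* **Quadratic (ligand-depletion) model**: the exact mass balance for totals
  a₀, b₀ gives `[AB] = ((a₀+b₀+K_D) − √((a₀+b₀+K_D)² − 4a₀b₀))/2`,
  implemented in the cancellation-free form `2a₀b₀/(s+√(s²−4a₀b₀))`.
* **Competitive ternary model**: with A shared between reporter B and
  competitor I, free [A] solves a strictly increasing scalar equation on
  [0, a₀] (Brent's method, rtol 1e-14); `[AB] = [A]b₀/(K_AB+[A])`.

The fitting engine is a four-parameter logistic on log₁₀ x,
`y = bottom + (top−bottom)/(1+10^((log₁₀m − log₁₀x)·h))`, least squares via
`scipy.optimize.curve_fit`, initialised from the response range and the
half-range crossing. Results are normalised to `top ≥ bottom` with the sign
of *h* encoding direction. A response whose range is below 3× the replicate
noise raises a "no dose dependence" error rather than returning a
meaningless midpoint. Standard errors come from the asymptotic covariance
of log₁₀m; the 95% CI is formed on the log scale and back-transformed,
which is why it is asymmetric around the estimate (consistent with how the
reported homodimer CI, 606.2–665.1 nM around 634.7 nM, is shaped).

**K_D estimation** offers two modes. `inflection` is the assay convention:
4PL with Hill slope fixed to 1 (the first-order binding assumption) on mean
RLU vs total titrant; its midpoint is reported as K_D. Because it treats
total titrant as free, it overestimates K_D whenever the fixed component
concentration is comparable to K_D — at 100 nM fixed and K_D ≈ 509 nM the
noiseless bias is about +10%, and it grows with the fixed concentration.
`quadratic` fits `RLU = background + gain·[AB](titrant; b₀, K_D)` and is
exact on depletion-generated data; it needs the fixed concentration as
input. Both are exposed so the convention and the correction can be
compared on the same dataset. EC50/IC50 fits leave the Hill slope free
(calcium activation involves multiple EF-hand sites and is not expected to
be first order); direction mismatches are auto-corrected with a warning.
Background luminescence is a free fit parameter, never pre-subtracted; the
LgBiT-alone control enters only the fold-change statistic.

Other statistics: Z-factor `1 − 3(s₊+s₋)/|m₊−m₋|` with sample SDs (≥3
replicates per arm); fold change as mean(sample)/mean(control); the
calcium-independence check is an OLS slope with a Wald F-test of slope = 0
(`statsmodels`), the F statistic being the squared t of the slope.

## Synthetic data

The generator emulates the study conditions, not arbitrary data:

* **Titrations**: mean signal `background + gain·[AB]` with the quadratic
  model, fixed component 100 nM (the saturation-assay setting), 12
  log-spaced titrant points spanning roughly 1 nM–100 µM (extended to 1 mM
  for the weak Mg²⁺ heterodimer), 3 replicates.
* **Dose–response / inhibition**: 4PL means, Hill 1.5 for calcium
  activation (mild cooperativity across multiple EF hands), 1.0 for
  competitive inhibition; 10–11 points per curve.
* **Noise**: multiplicative Gaussian with CV 5%, truncated at zero —
  luminescence scatter grows with signal. Replicate *j* draws from the
  substream seeded `(master_seed, j)`, so extending the replicate count
  never reshuffles existing replicates.
* **Defaults chosen once**: gain 1000 RLU/nM and background 500 RLU give a
  ~200-fold dynamic range, typical of purified-protein NanoBiT assays; 3
  replicates and CV 5% reflect a well-behaved plate assay.
* **Toy complexes**: two identical chains (straight rods or gentle
  helices) of uniform carbon-like atoms, chain B offset so the closest
  surface separation equals `inter_chain_gap`. Gap 0 produces van der
  Waals contact along the whole length; 50 Å isolates the chains.

A registry (`synth.reference_constants`) holds the experimentally reported
constants used as simulation ground truth: heterodimer K_D 185.4 nM
(CAPN1, Ca²⁺), 508.6 nM (CAPN2, Ca²⁺), 361.8 and 1651 nM (Mg²⁺), homodimer
K_D 634.7 nM, calcium EC50 59.9 µM (calpain-1) and 940.8 µM (calpain-2),
competitor IC50 463.3 nM, and the reported Z-factor 0.75.

### What passing tests show — and do not

Recovery tests demonstrate that the estimators are unbiased and precise
*under the generator's own assumptions* (the fitted model family matches
the generating family; noise is independent, multiplicative, mid-sized).
They do not validate behaviour against instrument drift, substrate decay
over a read, pipetting covariance between replicates, plate edge effects,
or model misspecification (e.g. genuine cooperativity in a curve fitted
with Hill 1) — none of which the generator emulates. Likewise the toy
complexes validate the SASA quadrature and the burial logic, not the
biological interface of a real heterodimer: atoms are uniform spheres, and
there is no side-chain packing or shape complementarity.

## Numerical details

* SASA quadrature is deterministic; the independent checks in the test
  suite use a separately implemented 16384-point Monte-Carlo oracle with
  all-pairs occlusion, agreement within 1% of total area on random
  clusters.
* `occupancy_quadratic` uses the rationalised root to avoid cancellation
  and clips to `[0, min(a₀,b₀)]` against rounding at the stoichiometric
  limit.
* Curve fits run with xtol/ftol 1e-12 and report `converged = False`
  (flagged, not silent) if the solver gives up; flat input is rejected
  before fitting.
* Ties everywhere resolve deterministically (documented tie-break chains);
  no code path seeds from the clock — stochastic CLI subcommands require
  an explicit `--seed`.

## Problem sizes

Default test and acceptance workloads are sized for an interactive
workflow: toy complexes of 12–24 atoms per chain, 200 simulated datasets
per recovery study (about a dozen fits per second), SASA oracle
comparisons on 20-atom clusters. Scaling the same code to a full
heterodimer structure (~6500 heavy atoms) raises the SASA cost roughly
linearly in atom count times neighbours and stays well within a desktop
budget at 960 points.

## Known limitations

* The free state is the bound geometry minus the partner; no relaxation,
  so ΔSASA slightly overstates burial relative to a re-folded monomer.
* Per-residue ΔSASA classification cannot distinguish a residue buried by
  many small contacts from one with a single deep contact.
* Predicted ΔΔG_binding values are consumed as given; the known systematic
  underestimation of such predictors (roughly two-fold against experiment)
  is deliberately not corrected.
* The asymptotic CI on log₁₀ midpoint undercovers at very low information
  (few points spanning the transition); profile likelihood would be the
  upgrade path.
* The 4PL inflection K_D is a biased estimator under ligand depletion by
  construction; it is kept because it is the community convention the
  biosensor results are quoted in, and the quadratic mode quantifies the
  bias.
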