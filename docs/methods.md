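# Methods

This note documents the models implemented in `greenscape`, their
assumptions, the parameters that matter, and the design choices made where
the published methodology left the design open.

## Data model

Landscapes are 2-D integer rasters over a configurable class scheme; the
default is the seven-class Globeland30 coding (cultivated 10, forest 20,
grassland 30, wetland 50, water 60, artificial 80, bare 90), with the
first five flagged as green space. Cells are squares (default 100 m,
0.01 km²); row 0 is the northernmost row. Nodata cells are excluded from
every count, sample, metric and allocation. All stages require identical
shape and cell size and fail fast otherwise; reprojection and resampling
are out of scope — inputs are assumed pre-aligned.

Raster I/O supports single-band TIFF (cell size and nodata carried in the
image-description tag) and the ESRI ASCII grid text format. Min–max
normalization maps each driver layer to [0, 1]; a constant layer maps to
all zeros, since it carries no information and the formula is otherwise
undefined.

## Change dynamics

The transition matrix cross-tabulates two dates over their jointly valid
cells, so row sums equal initial class areas and total area is conserved.
The comprehensive dynamic degree uses the **off-diagonal (transferred)
area only** in its numerator: unchanged area is not "change", and this
reading makes the index 0 exactly when the two maps agree and invariant
under uniform rescaling of all areas. The interval length T is a real
number of years.

## Suitability network

The per-class occurrence probability is modeled by a feed-forward network
with **one hidden layer of 12 logistic units** and one output per class —
the published description of "12 hidden layers" is read as 12 hidden
neurons in a single hidden layer, which is what the one-hidden-layer
formula for the output probabilities describes. The "sampling parameter
20" is read as a 2% (20‰) uniform sampling rate, the convention of the
software family this model descends from; both readings are config
defaults (`ANNConfig`) that users can override. Training uses
stochastic-gradient (Adam) optimization, 200 epochs, learning rate 0.01,
deterministic given the seed; the network itself is scikit-learn's
`MLPClassifier`, since an ordinary MLP fit is a standard step rather than
a contribution of this package.

Raw outputs are clipped at 1e-9 and divided by their per-cell sum, so the
normalization constraint Σ_k p(p,k) = 1 holds by construction, and it is
asserted (not assumed) after every prediction. Classes absent from the
training sample trigger a warning and fall back to their full-grid prior
frequency. Whether the published RMSE of 0.21 was train or test error is
unstated in the source methodology; the package's `suitability_rmse`
pools squared error over all (valid cell, class) pairs against the
one-hot truth, which gives 0 for a perfect cube and
√((k−1)/k)/√k ≈ 0.350 for the uniform cube at k = 7.

## Markov demand, scenarios, and CA allocation

Demand at the horizon is `current_areas · P^steps`, with P the
row-normalized empirical transition matrix (rows with zero initial area
default to identity), converted to whole cells by largest-remainder
rounding so the cell total is preserved exactly.

Scenario policies are multiplicative factors on selected transition
probabilities. The source text mixes "reducing … to X%" and "increasing
… by X%" phrasings; both are implemented as multiplicative factors (0.5,
0.3, 1.2 for ecological protection; 1.5, 1.5, 1.3 for economic
development) — an interpretation, documented here and encoded in the
shipped `ScenarioConfig` presets. The adjusted row's mass change is
absorbed by the diagonal stay probability and the row renormalized,
preserving row-stochasticity while honoring the stated directional
intent; an adjustment that would drive the stay probability negative is
an error naming the row.

Allocation combines, per cell and candidate class k,

    TP_k = suitability_k × Ω_k × inertia_k,

with Ω_k the fraction of class-k cells in the moving window (center
excluded) times a per-class expansion weight in [0, 1], and hard zeroes
where the conversion-cost matrix forbids the change or the restriction
mask applies. Each iteration draws a candidate class per cell by roulette
over TP (at an exact cumulative-sum boundary the tie resolves to the
next class in ascending scheme order), then commits drawn changes in
seeded random order, accepting a change only while the donor class is
above and the receiver class below its target — so every committed change
strictly shrinks the total demand gap and the cell total is conserved by
construction. Inertia starts at 1 and is multiplied each iteration by
(target/allocated) clipped to [0.5, 2], monotone pressure toward demand.
The window (3×3), convergence tolerance (0.1% of valid cells) and
iteration cap (300) are defaults the source methodology does not pin
down ("tested numerous times"); all are exposed in the API. Infeasible
demand (not enough convertible donor cells for some class) raises before
iterating; hitting the iteration cap yields a warning and the best-effort
map with diagnostics.

Map agreement uses overall accuracy and Cohen's kappa with chance
agreement from the marginal products; when both maps are single-class
(chance agreement 1) kappa is defined as 1 for identical maps, else 0.

## Landscape metrics

Patches are connected components of equal-valued cells, 8-connectivity by
default (the conventional default; 4 is exposed — which rule the source
analysis used is unstated). Patch perimeter counts cell edges against a
different class, nodata, or the landscape boundary. ED counts **interior
inter-class edges only** (no boundary, no nodata edges), the no-border
convention; this matters on small grids. AI uses single-count rook
like-adjacencies g_ii against the maximum attainable for the class's cell
count a: with n = ⌊√a⌋ and m = a − n², max g = 2n(n−1) plus 0, 2m−1 or
2m−2 for m = 0, m ≤ n, m > n. CONTAG uses the adjacency-entropy formula
over double-count rook adjacencies; SHDI/SHEI use natural logs over
classes present; DIVISION is 1 − Σ(patch area/total area)². Degenerate
single-class landscapes take the limits SHEI = 0 and CONTAG = 100.

Where the published index table is typographically corrupted (the AI and
CONTAG rows as printed are not well-formed formulas), the standard
FRAGSTATS definitions are implemented and each is unit-tested against
hand-enumerable toys — the only reading consistent with the analysis
having been run in Fragstats. One such hand enumeration worth recording:
a two-class checkerboard has **CONTAG = 50%**, not 0 — all adjacencies
are unlike, so only 2 of the 4 (class, neighbor-class) states carry mass
(0.5 each), giving entropy ln 2 against the 2·ln 2 maximum; CONTAG = 0
would require all four states equally likely, i.e. random mixing.

## Structure optimization

The LP maximizes α·Ed(x) + β·Ep(x) (α = 0.60, β = 0.40 in the preset)
over seven class areas under per-class box bounds and one total-area
equality. For this structure the exact optimum is greedy: start at the
lower bounds and hand the slack to variables in descending weighted
coefficient α·d_i + β·p_i (ties broken by ascending index), each up to
its cap. The greedy path in exact arithmetic is the primary solver; a
floating-point simplex (scipy HiGHS) is a cross-check only. In the
shipped preset all weighted coefficients are distinct, so the optimal
vertex is unique.

Units: the benefit coefficients are printed as "CNY 1 million/km²", but
applied to areas in km² that scale is inconsistent with the published
benefit magnitudes. Reported benefits divide the raw Σ coeff·area by 100
(`report_divisor`, configurable), the single rescaling that reproduces
the published ecological benefit at the optimum to 0.0003%. The LP itself
uses the raw coefficients — any common rescaling leaves the argmax
unchanged, and a differential rescaling would contradict the published
optimum. The published economic benefit at the optimum is **not**
reproducible from the printed coefficients under any single rescaling we
could identify (raw/100 gives 602,823.30 vs the printed 241,129.06); the
package reports what the stated objective computes and makes no claim to
match that printed value.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) spatially autocorrelated categorical maps by
rank-thresholding a Gaussian field smoothed with a separable kernel at
width `correlation_length`, so class proportions are exact to one cell
and monotonically controlled; (ii) drivers equal to a per-class mean plus
smoothed noise scaled by 1/SNR (SNR=∞ deterministic in class, SNR=0
uninformative); (iii) a second date drawn cellwise from a known
transition matrix with optional adjacency bias; (iv) contiguous
restricted-area blobs at an exact coverage fraction. A single seed feeds
a dedicated RNG per operation, so stages are independently reproducible.

Defaults describe a slowly changing, cultivated-land-dominated temperate
landscape: proportions (0.49, 0.36, 0.08, 0.02, 0.02, 0.025, 0.005),
correlation length 8 cells, 6 drivers at SNR 5, and (in the examples) a
~6%-off-diagonal decadal transition matrix with adjacency bias 1 and a 5%
restricted fraction. These emulate the statistical structure the pipeline
assumes — not real geography: there are no road networks, elevation
gradients, or anisotropic growth corridors, and driver–class association
is stationary. Passing tests therefore demonstrate that the mechanisms
(accounting identities, normalization, demand convergence, legality,
metric formulas) are correct, not that any particular real region's maps
or accuracy scores would be reproduced.

## Problem sizes and numerical choices

Tests and examples run on 64×64 to 300×300 grids — large enough for
frequency-based checks (±0.02 tolerances follow from binomial error at
these cell counts) while keeping the full suite fast on one CPU. Exact
rank-based thresholding avoids quantile ties; largest-remainder rounding
preserves totals; roulette boundaries break ties by ascending class
order; all stochastic components take explicit integer seeds. The CA's
accept-if-it-helps commit rule makes demand convergence monotone, at the
cost of slightly damping churn relative to a free resampling CA — a
deliberate choice favoring a guaranteed demand match, which is what the
downstream metric comparison needs.

## Known limitations

* Suitability uses one global network; no per-period retraining or
  spatially varying coefficients.
* The CA has no patch-generation mechanism; new patches of a class can
  only grow from existing cells of that class (a class demanded to grow
  from zero presence is infeasible by design).
* CONTAG/AI assume rook adjacency and the no-border edge convention;
  other conventions will differ on small or heavily masked grids.
* The LP optimizes quantity structure only; it does not feed back into
  the spatial allocation.
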