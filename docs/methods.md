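# Methods

This note documents the models, the tunable parameters, the synthetic
data the tests run on, and the numerical and design choices — in the
spirit of a package methods appendix. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Ancestral range reconstruction

**Assumption.** Early divergence is geographic: an ancestor's continuous
range is subdivided by environmental change, and divergence proceeds in
the isolates without gene flow. Under habitat niche conservatism the
ancestor's environmental tolerance at a node is approximated by the
*pooled* tolerances of its close descendants, so a niche model fitted on
the union of descendant occurrences can be projected onto
paleo-environmental layers around the node's age.

**Niche model.** A presence/background SDM equivalent to lasso-penalized
MaxEnt: features are built from standardized variables (classes
configurable among linear, quadratic, pairwise product, and
forward/reverse hinge ramps at training-quantile knots; default
linear+quadratic+hinge with 4 knots per variable), and weights minimize
the logistic negative log-likelihood plus λ‖β‖₁ with the intercept
unpenalized. Defaults: λ (`beta`) = 1, background = 10 000 cells (capped
at availability), logistic output. The cloglog transform is deliberately
not offered: one output transform with a clear [0, 1] contract, recorded
in every report. Duplicate presences in one grid cell are collapsed —
minimal spatial thinning against pseudo-replication on coarse grids.

*Solver.* Proximal gradient (FISTA) with function-value adaptive restart,
step 1/L with L = ‖X‖₂²/4; convergence when the minimal-norm subgradient
drops below 1e-6, capped at 10 000 iterations (a warning reports the
final norm otherwise). On a fixed synthetic set the solution is checked
in the tests against an independent penalized-logistic solver
(scikit-learn SAGA) on the identical design matrix; the reference solver
is never used as the implementation.

*Evaluation.* Rank-based (Mann–Whitney) AUC with ties counted ½. The
binarization threshold rule is configurable — max sensitivity+specificity
(midpoint of the optimal interval in the separable case), minimum
presence score, or a presence percentile — because published per-node
thresholds generally do not identify the rule that produced them.

**Windows and projection.** A node's window contains the slices with age
in [age_lo − Δ, age_hi + Δ]; Δ defaults to 0.1 My so that slices just
outside a dated credible interval are inspected too. The model is trained
on the present-day (youngest) slice only and transferred to paleo slices;
training directly on paleo layers is not offered, since descendant
occurrences only evidence the present environment. Slice spacing is
whatever the supplied series provides; the synthetic series defaults to
0.01 My steps.

**Occupancy.** Suitability ≥ τ defines the potential range; occupancy
separates "suitable" from "actually inhabited". The oldest window slice
is seeded from pooled occurrence cells (if none falls inside the range,
the largest component is seeded, with a warning). A later component is
occupied iff any of its cells is within the dispersal radius (Chebyshev
distance, default 1 cell per slice step) of an occupied cell of the
previous slice. The radius and the adjacency rule (default rook) are the
minimal explicit operationalizations of "narrow corridor" and
"connectivity", both configurable.

**Event grammar and verdicts.** Transitions between consecutive slices
emit:

* SPLIT — an occupied component maps to ≥ 2 occupied components;
* MERGE — ≥ 2 occupied components map to one;
* CORRIDOR_OPEN — an occupied and a suitable-but-*unoccupied* component
  become connected (one merged component, or contact within the dispersal
  radius);
* CORRIDOR_CLOSE — a tracked corridor's two sides lose contact while both
  remain occupied;
* EXTINCTION — an occupied component has no occupied successor.

A divergence is **vicariance** when a SPLIT's isolates remain occupied
through the window end, **founder** when a CORRIDOR_OPEN is followed by a
CORRIDOR_CLOSE whose newly colonized isolate persists — occupied and
disconnected — for all remaining slices, **ambiguous** when both patterns
occur (no tie-break; mirroring that both modes can be equally supported),
and **none** otherwise. One disambiguation is essential: when a component
*assembled by a tracked corridor opening* fragments again along the same
seam, that transition is reported as the corridor closing, not as a
vicariant split — otherwise every founder history would also contain a
split and could never be classified. This grammar is the package's
explicit formalization of what is usually judged by inspecting range
maps; it is deterministic (labels in scanline order, events in fixed
traversal order), so identical inputs give byte-identical event lists.

## Fossil calibration from ghost lineages

With Td the true node age and FAD the first appearance of the descending
lineage, the ghost lineage is g = Td − FAD and the relative ghost time is
r = g/FAD. The model assumes r is identically distributed across nodes
whose record is reasonably complete — FAD > Td/2, i.e. r < 1; nodes
failing the condition are excluded from the fit and reported.

**Fitting.** Default lognormal by moment matching (σ² = ln(1 + v/m²),
μ = ln m − σ²/2 from the sample mean m and variance v); maximum
likelihood is available as an option. At least 3 retained values are
required; an all-zero sample (every fossil binding) is flagged degenerate
and refuses to produce priors.

**Priors.** For a node with first appearance FAD and stratigraphic-zone
base FAD_min, the prior on Td has the shape of FAD·(1+r) with support
offset to FAD_min: the excess Td − FAD_min = (FAD − FAD_min) + FAD·r is
moment-matched to a lognormal. The stratigraphic gap therefore fattens
the lower tail without moving the hard floor, which is the only hard
constraint. The soft maximum is the prior's quantile q (default 0.95,
configurable); it is strictly increasing in both FAD and q, and the
density is identically zero below FAD_min.

**Scale handling — an identifiability caveat.** The chain needs node
heights on the time axis. Three modes are offered:

* `chronogram` (default): heights are already in My (e.g. from a
  preliminary relaxed-clock analysis); the minimal consistent scale
  s_min = maxᵢ FADᵢ/hᵢ is computed only as a stratigraphic-consistency
  check (s_min ≤ 1 must hold, otherwise a fossil is older than its node).
* `min`: heights are scaled by s_min. This is the bracketing lower edge:
  it forces the tightest calibration's ghost time to zero and therefore
  *systematically underestimates* every r by the smallest relative gap in
  the sample. Useful as a bound, not as an estimate.
* `corrected`: s_min inflated by the expected minimum gap of n draws,
  solved by indirect inference on the first two moments. This de-biases
  on average but remains high-variance: the absolute scale is only weakly
  identified from the FADs alone (the shifted-lognormal family is nearly
  scale-shift degenerate), so a dated chronogram should be preferred
  whenever one exists.

**Polymorphism correction.** Gene divergence predates population
divergence, so gene-tree (concatenation) node ages y exceed species
divergence times. OLS of y on relative species divergence x gives
y = a + b·x; the intercept a (My) is the mean allele-minus-species
interval and y − a are the corrected ages. Requires ≥ 3 pairs and
non-constant x.

## Synthetic data

The generators are pure functions of (parameters, seed) and expose their
ground truth.

* **Landscapes** are built on a 40×40 geographic grid (0.5° cells) with
  10 slices and 3 variables by default — large enough for
  multi-component geometry, small enough for seconds-scale tests. The
  first variable drives the niche (suitability = σ(12·(v₁ − 0.5)), so the
  true range at τ = 0.5 is exactly v₁ > 0.5); the others are smooth
  nuisance fields of Gaussian bumps with gentle temporal drift. Scripted
  events modify the driver: a *barrier* zeroes a band from its start
  slice onward; a *corridor pulse* saturates a band during its window.
  Contradictory (overlapping barrier+corridor) scripts are rejected.
* **Scripted scenarios**: the vicariance script cuts one broad occupied
  blob with a persistent 3-cell barrier (wider than the default dispersal
  radius) at a seeded slice; the founder script briefly connects an
  occupied and an empty blob for exactly one slice. Event positions and
  geometry are jittered by seed.
* **Occurrences** are presence-only draws with cell probability
  proportional to true suitability (no detection or absence model),
  matching the presence/background design of the SDM.
* **Trees** follow a pure-birth Yule process (forward simulation; the
  clock stops one exponential waiting time after the n-th lineage arises,
  so a 2-tip tree's root age is Exp(2λ)).
* **Fossils**: per selected node, r is drawn from a lognormal (defaults
  meanlog = −1.0, sdlog = 0.3, i.e. mean r ≈ 0.39 with CV ≈ 0.31 and
  negligible mass above 1, so the FAD > Td/2 filter rarely binds) and
  FAD = Td/(1+r); FAD_min defaults to 90% of FAD (relative gap mode, so a
  gap can never swallow a shallow node's FAD).

**What passing tests do and do not show.** The landscapes have sharp,
scripted connectivity changes and no spatial autocorrelation structure
beyond Gaussian bumps; occurrences carry no sampling bias; the niche is
exactly logistic in the layers. Passing therefore demonstrates the
machinery — labeling, propagation, event parsing, solver correctness,
prior construction — under controlled truth, not that real paleo-layers,
biased occurrence records, or non-conserved niches would yield correct
histories. In particular, the niche model can latch onto nuisance
variables that geographically separate occupied from unoccupied habitat
(as real SDMs do), which is why the pipeline's verdicts on fitted models
are validated on scripted landscapes via their ground-truth masks.

## Numerical choices and degenerate inputs

* Ultrametricity tolerance 1e-6 on root-to-tip spans; violations name the
  worst tip pair. Tip ages are clamped to exactly 0.
* Raster cell centers at (xll + (j+½)·cs, yll + (i_s+½)·cs); points map
  to the cell containing them (nearest center; boundary ties resolve by
  floor). Points outside the extent are flagged and counted, never
  silently dropped. Grid round-trips use `%.17g`, which is value-exact
  for doubles.
* Component labels are assigned in first-encounter scanline order
  (explicit remap after `scipy.ndimage.label`), making all downstream
  event lists order-deterministic.
* Threshold rule `max_sens_plus_spec` evaluates Youden's J at every
  observed score with the ≥ τ decision rule and returns the midpoint of
  the optimal interval.
* Per-node background sampling derives its stream from
  (seed, crc32(node id)), so batch results are independent of node
  iteration order.
* Reports are written with fixed float formatting (`%.10g`) to make
  byte-identical determinism checkable.

## Known limitations

* Occupancy is binary per component; no abundance, no within-component
  structure, no least-cost-path corridor modelling.
* Component identity across slices is cell-overlap extended by the
  dispersal radius; strongly drifting ranges could alias identities on
  coarse slice spacing.
* The founder verdict requires the corridor to close within the analysis
  window; a corridor still open at the window's young edge yields
  `none`/`ambiguous` rather than a premature call.
* Geographic lat/lon only; no projections, no GeoTIFF/NetCDF.
* The calibration module constructs priors for transcription into dating
  software; it does not run any Bayesian dating itself.
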