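# paleorange

Ancestral geographic range reconstruction for dated phylogenies, built on
environmental niche models projected onto paleo-climate time slices — with
automated classification of each divergence as **vicariance** or
**founder-event speciation**, and a companion module that turns fossil
first appearance data into **soft-maximum calibration priors** via a
ghost-lineage time model.

It is written for phylogeographers and systematists who want to go beyond
area-coding methods (DEC/DIVA and relatives): instead of pre-defined
discrete areas, the ancestral range at an internal node is estimated from
the *environment itself*, assuming habitat niche conservatism across the
node's closest descendants.

## The method

For every internal node of a dated ultrametric tree:

1. **Pool descendant occurrences.** The ancestor's niche is approximated
   by the union of the occurrence records of all tips descending from the
   node (deduplicated per grid cell).
2. **Fit a presence/background niche model.** A maximum-entropy-style SDM:
   environmental variables are expanded into linear, quadratic, product
   and hinge features and the weights β maximize the L1-penalized logistic
   presence/background log-likelihood

       max_β  Σᵢ [ yᵢ log σ(fᵢᵀβ) + (1−yᵢ) log(1−σ(fᵢᵀβ)) ] − λ‖β‖₁,

   the standard correspondence between lasso-regularized MaxEnt and
   penalized logistic regression on the expanded feature space. Output is
   the logistic transform, reported with the rank-based AUC and a
   binarization threshold τ (max sensitivity+specificity, minimum
   presence, or a presence percentile).
3. **Project through time.** The model is transferred to every
   paleo-environmental slice within the node's age window
   [age_lo − Δ, age_hi + Δ] and binarized at τ.
4. **Propagate occupancy and classify.** Connected range components
   (rook/queen adjacency) are tracked through slices: a component is
   occupied iff it lies within the dispersal radius (Chebyshev, in cells)
   of an occupied component one slice earlier. Transitions are parsed into
   SPLIT / MERGE / CORRIDOR_OPEN / CORRIDOR_CLOSE / EXTINCTION events, and
   the node is classified:
   * **vicariance** — an occupied range splits and both isolates stay
     occupied through the window;
   * **founder event** — a transient corridor lets the lineage colonize a
     suitable-but-empty component which then persists in isolation;
   * **ambiguous** / **none** otherwise.

Separately, the **calibration** module models ghost lineages: with Td the
true divergence time and FAD the fossil first appearance, the relative
ghost time r = (Td − FAD)/FAD is assumed identically distributed across
nodes whose fossil record covers more than half the lineage duration
(FAD > Td/2). The r distribution (lognormal, moment-fitted) fitted from
available calibrations yields, per node, an offset-lognormal prior on Td
that is zero below the hard minimum FAD_min and whose q-quantile is the
soft maximum. An OLS regression of gene-tree node ages on relative species
divergence times supplies the ancestral-polymorphism correction (the
intercept is the mean allele-minus-species divergence interval).

## Worked example

`examples/project_ancestral_range.py` builds a complete synthetic
workspace (dated 5-species Yule tree, a 10-slice environmental series with
a scripted one-slice corridor, occurrences sampled from the known niche)
and runs the full chain for the root node. It prints:

```
node n0 (age 0.60 My):
  model AUC = 0.922, threshold = 0.213 (118 presences vs 600 background)
  window slices: [0.8, 0.6, 0.4] My
  verdict: vicariance (event between 0.4 and 0.4 My)
    MERGE at 0.6 My  {'merged': 1, 'sources': [1, 2]}
    SPLIT at 0.4 My  {'parent': 1, 'children': [1, 2]}
```

Reading: the projected ancestral range consisted of two occupied blocks
that fused at 0.6 My and re-fragmented at 0.4 My with both sides still
occupied — the classical vicariance pattern, dated to the transition
slice. `examples/detect_speciation_events.py` shows the founder-event
counterpart (a corridor opening into *unoccupied* habitat and closing one
slice later), and `examples/fossil_calibration_priors.py` prints a
calibration table:

```
20 fossil calibrations; 0 excluded (FAD < Td/2)
fitted relative ghost time: mean 0.382, variance 0.0321 (generating mean 0.385)

node      FAD   hard_min  soft_max(q=0.95)
n0      1.076    0.968     1.846
n1      1.487    1.338     2.551
```

## Command line

The same pipeline is scriptable from a shell:

```bash
paleorange fixture --out ws --seed 5          # emit a demo workspace
paleorange all --config ws/config.txt --out results
paleorange node --config ws/config.txt --node-id n0 --out node0
paleorange calibrate --config ws/config.txt --out calib
```

`all` writes one scenario row per internal node dated inside the
configured interval (default Pliocene–Pleistocene, 0.01–5.33 My), plus
per-node suitability/range grids (ESRI ASCII), an events CSV and a
manifest carrying the config hash. Identical config and seed give
byte-identical outputs.

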