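# Methods

This note records the models implemented in `foldpath`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions adopted where the design was
genuinely open.

## Domain model

A **Conformation** is one 3D structural state of a (possibly partial)
protein chain: residues identified by author residue number (1-based,
strictly increasing; insertion codes are rejected), each with a Cα
coordinate and optionally further atoms. An entry carries a *deposited*
sequence range and the *modeled* sub-range that actually has
coordinates; the modeled range must lie within the deposited one. A
**Pathway** is a time-ordered list of intermediates, each holding one or
more conformations. Nesting of deposited ranges (start fixed, end
non-decreasing) and native-last ordering are validated through
`Pathway.validate_cotranslational()` rather than enforced at
construction: real catalogued data include a study whose native
structure is the *shorter* deposited construct, so a hard native-last
invariant would reject legitimate data.

PDB I/O is Cα-centric and delegated to biotite. The default chain is
the first in the file, overridable; this is also how attached entities
deposited in other chains (a ribosome, a fusion partner) are excluded
from nascent-chain analyses. Altloc resolution keeps the highest
occupancy. Residues without a Cα are dropped with a logged warning.
Multi-model writes require identical residue sets across models because
PDB MODEL blocks share one atom table.

## TM-score

For mapped residue pairs (always mapped by author residue number — no
sequence-order-independent alignment), the score is
`(1/L_norm) · Σ 1/(1 + (d_i/d0)²)` maximised over rigid superpositions,
with `d0 = 1.24·(L_norm − 15)^⅓ − 1.8` Å floored at 0.5 Å so short
fragments (L ≤ 21) remain scorable.

* **Normalization.** The default `common` normalizes by the number of
  mapped residues, the appropriate convention when comparing nascent
  chains of unequal coverage; `target` (asymmetric, conventional) and
  `shorter` are provided. For a model covering a subset of the target,
  `target` never exceeds `common`.
* **Search.** Kabsch superposition on the full mapped set and on
  contiguous seed fragments of lengths n, n/2, n/4 at every offset;
  each seed is refined by re-superposing on the residues with
  `d_i < max(d0, 4.5 Å)` until the included set is stable (at most 20
  iterations). Both the raw and the refined transform of every seed are
  scored, so the reported score never falls below the plain global
  Kabsch score. Reflections are always excluded (chirality is
  physical); collinear point sets are treated as degenerate.
* **Interpretation bands** at 0.17 / 0.3 / 0.5 partition (0, 1];
  boundary values belong to the lower band because the upper categories
  are defined by *exceeding* the threshold.

The superposition itself uses scipy's proper-rotation Kabsch solver;
`rmsd` in a TM result is computed over all mapped pairs under the
best-scoring transform, so `rmsd² = mean(d_i²)` holds for the reported
distances.

## Proxy intermediates

Prefix lengths are k, 2k, … with the final entry the full chain length
(no short remainder-only intermediate). k defaults to 5 residues,
roughly one secondary-structure element per step. Prefixes are taken
over modeled residues in order, not author-number arithmetic, so
natives with unmodeled gaps still yield well-formed proxies.
`match_proxy` pairs an experimental conformation with the proxy of
closest residue count (ties to the longer proxy) because experimental
modeled ranges rarely align to multiples of k. Proxies share
coordinates with the native by construction — comparing proxies of one
native always yields TM = 1 over shared residues, which is the designed
differential against genuinely dynamic pathways.

## Protein structure networks and graphlets

Default contact rule: Cα–Cα ≤ 6.0 Å with sequence separation ≥ 1 — a
common PSN convention, configurable (`any_atom` mode with a 4.0 Å
cutoff uses minimum inter-atom distance and requires full-atom
records). Dynamic PSNs are one snapshot per pathway intermediate;
nesting of node and edge sets is *validated* and reported, never
forced, since only proxy-derived pathways guarantee it.

Graphlet features count the 9 connected induced subgraph classes on
2–4 nodes exactly (edge; 2-path; triangle; 3-path; 3-star; 4-cycle;
tailed triangle; diamond; 4-clique), via single-visit enumeration of
connected subsets classified by degree sequence. Limiting to 4 nodes
keeps exhaustive-oracle verification tractable; orbit decompositions
and 5-node graphlets are deliberately out of scope. The dynamic feature
vector — per-bin graphlet frequencies over `n_bins` (default 10) time
bins resampled by nearest snapshot position, plus a 9-long
first-arrival histogram ((1-based snapshot of first appearance)/T, 1.0
if never) — is this package's explicit per-snapshot stand-in for full
dynamic-graphlet machinery, and is documented as such.

## Classification

L2-regularized logistic regression (C = 1.0, one-vs-rest beyond two
classes) on features standardized with statistics fit on training folds
only, under stratified 5-fold cross-validation shuffled by the seed.
`compare_feature_modes` uses identical fold splits for the static and
dynamic representations so the comparison is paired, and reports a
sign test across folds (ties dropped). Reports are fully deterministic
given the seed.

## Kinetics statistics

**Contact order** uses Cα ≤ 6.0 Å with |i−j| ≥ 2 (backbone neighbors
excluded); relative contact order divides by the residue count. Zero
contacts yield explicit undefined markers rather than numbers — an
ideal extended strand at 3.5 Å/residue rise has no qualifying contacts
under the default cutoff.

**Two-state fraction.** Native contacts are computed once from the
native structure. For each secondary-structure-element pair with at
least one native inter-SSE contact, the formation time in a pathway is
the first snapshot at which ≥ 50% of that pair's native contacts are
present (the snapshot count if never — "never formed" is deliberately
late rather than missing, so it widens the spread). "Around the same
time" is operationalized as a spread (max − min formation time) of at
most `window` snapshots, default 1. Both the 50% formation fraction and
the window are explicit knobs because the underlying criterion is only
ever described qualitatively. SSE annotations are inputs; no secondary
structure assignment algorithm is bundled. Pairs without native
contacts are excluded with a warning, and a single qualifying pair
makes every pathway trivially two-state (warned as degenerate).

## Synthetic generators

The generators emulate, with ideal Cα-trace geometry (no side chains —
all downstream scoring is Cα-based):

* multi-conformation intermediates (independent self-avoiding coils of
  one sequence range),
* nascent chains of growing length whose earlier subsequence changes
  over time (hinge-perturbed proxy prefixes),
* native structures from which prefix substructures are extracted,
* two structural classes distinguishable by contact topology
  (helix-rich vs strand-like) or *only* by folding order (identical
  final structure, N-terminal-first vs C-terminal-first growth).

Geometry: helix rise 1.50 Å/residue, 100°/residue twist, 2.30 Å radius
(consecutive Cα distance 3.83 Å); strand rise 3.50 Å/residue with a
zigzag half-amplitude of 0.739 Å chosen so the consecutive Cα distance
is exactly 3.80 Å; coils are self-avoiding walks with 3.8 Å steps and a
3.2 Å avoidance radius. All conformers keep consecutive Cα distances in
[3.7, 3.9] Å and no Cα pair below 2 Å.

Hinge perturbations (rotation of the chain tail about the local chain
axis through the hinge Cα) were chosen over isotropic noise for
"conformational change over time" fixtures because they preserve local
geometry while changing the global fold — matching the observed
fold-level change between nascent-chain time points. The simulated
co-translational pathway applies hinges at every half-segment
(`max(2, k//2)` residues) with per-boundary random signs and magnitude
`hinge_per_step · (T − 1 − t)`, decreasing to zero so the final
intermediate is exactly the native; hinges at half-segment rather than
segment spacing ensure even the first-segment subsequence changes
between time points. With zero per-step angle the simulation is
bit-identical to proxy extraction — the two modules' shared reduction.

The classification dataset uses per-item coordinate jitter of
σ = 0.3 Å, chain length 48, and balanced classes. In `order_only` mode
both classes share the final native (a helical half joined to an
extended half), so static final-snapshot features are class-identical
in distribution and static classification sits at chance, while the
opposite growth directions give early snapshots with distinct graphlet
content — the package's core differential: dynamics adds signal that
statics cannot see.

What the generators do **not** emulate: real side-chain packing,
ribosome interactions, energetics, or physically realistic folding
kinetics (no molecular dynamics or Monte-Carlo energy model). Passing
tests therefore demonstrate correctness of the *measurements and
statistics* on well-controlled geometry, not predictive power on
experimental structures.

## Problem sizes and numerical conventions

The shipped tests and the acceptance script run on chains of 10–70
residues, classification datasets of 10 seeds × 30 pathways, 100-graph
graphlet-oracle batches (n ≤ 12), and 10,000-placement Monte-Carlo
superposition oracles on 12-residue chains — sizes chosen so every
exhaustive oracle remains exact and the whole suite completes in about
a minute on one core. Seeds are mandatory arguments throughout; there
is no global random state. Ties: similarity-band boundaries go to the
lower band; proxy-length ties to the longer proxy; sign-test ties are
dropped.

## Known limitations

* The packaged catalogue manifest is a synthetic reconstruction of the
  published table (its docstring details which fields are placeholders);
  analyses over real deposited entries require user-supplied PDB files.
* TM-scores between partial chains depend on the normalization
  convention; published comparisons do not always state theirs, so both
  are exposed.
* The graphlet feature set (2–4 nodes, no orbits) is smaller than full
  dynamic-graphlet schemes; absolute misclassification rates are not
  comparable to results obtained with richer features or at database
  scale.
* Structure prediction is never run here; predicted conformations are
  inputs, matched by (protein, intermediate, conformation) key with
  rank-1 selection by default.
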