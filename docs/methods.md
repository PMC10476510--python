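# Methods

## The model

`decranges` implements the dispersal–extinction–cladogenesis (DEC) model
of geographic range evolution on a rooted, time-calibrated, binary
phylogeny. The character state is a *range*: the set of discrete areas a
lineage occupies, out of `n` areas with at most `max_size` occupied at
once (default 2), plus the null range ∅ representing global extinction of
the lineage. With 13 areas and `max_size = 2` the state space has
1 + 13 + 78 = 92 states; ∅ always takes index 0 and states are ordered by
size, then lexicographically, so matrix layouts are reproducible
byte-for-byte.

### Anagenesis

Along a branch the range evolves by a continuous-time Markov chain with
instantaneous rate matrix `Q`:

- expansion `R → R ∪ {a}` at rate `d · Σ_{b∈R} m[b,a]`, where `d` is the
  base dispersal rate (events per area pair per My) and `m` is the
  dispersal-multiplier matrix (the summation over occupied source areas
  follows the convention of the established DEC implementations);
- contraction `R → R \ {a}` at rate `e` per occupied area (events per
  area per My); a single-area range contracts to ∅, which is absorbing.

Both rates are shared across areas, so every model has exactly two free
parameters and AIC = 4 − 2·logL throughout.

Finite-time transition probabilities are `P(t) = expm(Q t)`. (Some
presentations print this with a negative exponent while also writing
negative diagonals into `Q`; that combination diverges, so the standard
forward form is used.) The public `transition_probabilities` uses dense
scaling-and-squaring `expm`; the likelihood engine instead
eigendecomposes each epoch's `Q` once per parameter value and applies
`P(t)·v` as two matrix–vector products, falling back to `expm` whenever
the eigenvector matrix is ill-conditioned (condition number above 1e8).
At the state-space sizes involved (≤ ~120) no sparse machinery is
needed.

### Constraints

Dispersal-multiplier matrices encode geological hypotheses: pairwise
land connections and multiway blocks carry weight 1, distance classes
may carry intermediate weights (0.1 for near islands in the
island-distance scenario), and all remaining pairs carry a small floor,
0.001 by default, rather than exact zero so that constrained models
remain fittable. Epoch stratification is a separate, *hard* mechanism:
within an epoch, expansions into an area outside the "available" mask
get rate exactly 0. Ranges already containing an unavailable area stay
in the state space and can only contract — lineages stranded by an area
becoming unavailable can go locally extinct — which keeps a single state
indexing across epochs. One multiplier matrix is shared by all epochs.

### Cladogenesis

At a node the ancestral range is partitioned between the daughters under
the classic DEC convention: a single-area ancestor is copied to both
daughters; a wider ancestor either splits into two disjoint non-empty
parts (vicariance) or passes the full range to one daughter and a single
member area to the other (subset sympatry). All ordered daughter pairs
are equiprobable — a two-area ancestor has six events of probability
1/6. Founder-event ("jump") dispersal at nodes is deliberately not
implemented: with single-area endemic tips, +J fits are known to
degenerate to zero anagenetic rates, apportioning all change to jumps,
which is a pathology rather than an estimate.

### Likelihood, fitting, comparison

The likelihood integrates over all internal-node ranges and cladogenetic
events by pruning, with per-node rescaling in log space. Branches
crossing epoch boundaries are split at the boundary ages and the
per-segment transition matrices are chained oldest → youngest. At the
root the conditional-likelihood vector is summed over non-null ranges
(unweighted — the classic DEC convention); a uniform-prior average is
available via `root="uniform"`. The likelihood does not condition on
survival; see *Limitations*.

`fit_dec` maximises over `(log d, log e)` with L-BFGS-B inside the box
[1e−9, 10] from four fixed log-spaced starting points
(d, e ∈ {10⁻³, 10⁻¹}), ftol 1e−10 — deterministic given the inputs.
`compare_models` ranks by AIC with ties broken by model name;
`selection_frequency` splits exact ties equally across winners.

Node ages are measured backward from the deepest tip. Trees whose tip
depths differ by more than 10⁻³ of the root height trigger a warning
(published trees carry rounding), not an error.

## The hypothesis library

Thirteen built-in models cover the competing assembly scenarios for New
Guinea and its satellite islands over the 13 georegions (5 mainland
terranes V, C, F, A, E; 7 islands Y, G, W, M, S, R, B; Southeast Asia
N). Hypotheses are declared on the 11-region display layout (the two
sampled D'Entrecasteaux islands collapsed into "D", Southeast Asia
omitted) and expanded to the working 13: Normanby and Fergusson each
inherit D's connections and are joined to each other with 1; Southeast
Asia attaches at the floor everywhere. Both expansion rules are
overridable through `HypothesisSpec`.

Interpretive choices, flagged as such and config-overridable:

- *Slow and Steady* (b) is read as prolonged piecewise accretion joining
  every mainland terrane pair (current connectivity a plus V–E, C–E,
  C–A). The published current-connectivity matrix already joins E to F
  and A, so b must add the remaining terrane pairs to differ from a.
- *Owen Stanleys* (g) follows its published matrix exactly: a's mainland
  block plus one multiway block joining the EPCT and every offshore
  island. The other island-history variants (e, f, h, i, j, k, l) layer
  their island structure on b's mainland.
- Time strata are printed nowhere, so the shipped defaults are: *Mobile
  Belt* (c) — the Accreted Terranes become available at 11 Ma, when
  docking (15–11 Ma) completes; *Recent Emergence* (d) — before 5 Ma only
  the Fold Belt (the emergent central mountains) and the offshore
  islands are available.

## The synthetic-data generator

The generator emulates the study conditions: pure-birth (Yule) trees
rescaled to a 20 My root depth (the clade's age), 218 tips, a
single-area root on the EPCT, and rates of the magnitude estimated on
the real data (d = 0.0094, e = 0.021 events/My, recorded in
`decranges.study`). Anagenetic events are drawn by competing
exponentials from the epoch-appropriate rates, with epoch changes
handled at boundary ages; cladogenetic events are drawn uniformly from
the DEC event set. A pure-birth tree keeps the simulation ultrametric
and simple; a fixed-tree mode accepts any user tree. Lineages that reach
∅ stay extinct; because DEC is fitted to observed extant clades, such
tips are pruned before fitting in the recovery experiments. One seeded
generator drives each experiment, with per-replicate substreams derived
deterministically via `SeedSequence`.

What the generator does *not* emulate: diversification–extinction of
lineages independent of range (trees are pure-birth), range-dependent
speciation, sampling gaps, and phylogenetic error. Passing recovery
tests therefore validate the estimator against its own generating
process at realistic scale, not robustness to misspecified trees or
sampling.

## Numerical choices

- Pruning vectors are rescaled by their maximum at every node; the
  likelihood accumulates the log-scale exactly.
- Eigendecomposition propagators are validated per epoch by the
  condition number of the eigenvector matrix; small negative round-off
  in propagated vectors and in `expm` output is clipped at zero.
- Epoch files and stratifications must tile root-to-present contiguously
  and end at 0 Ma with every area available in the youngest epoch.
- Transition-count bins are half-open `[older, younger)`: a boundary age
  joins the bin it opens (age 15 falls in 15–10 Ma), the oldest bin is
  closed at the root age (with a 1e−9 relative tolerance for float
  fuzz), and the youngest bin is closed at the present. Ages outside all
  bins go to an overflow list with a warning.
- Majority-rule areas are the argmax of the equally-apportioned per-area
  vector; exact ties resolve to the lowest area index with a warning.
- A shift on the edge above a tip is assigned to the parent node's bin;
  shifts are counted on *all* edges, including edges into tips.

## Validation

The pruning likelihood is checked against an independent oracle that
explicitly enumerates every internal-node range assignment (with the
per-node cladogenetic weight obtained by direct event enumeration and
dense `expm` branch matrices) on all trees up to 5 tips and 3 areas,
agreeing to better than 1e−8 relative error, stratified models included.
Marginal ancestral reconstructions are checked the same way against the
enumerated posterior. Recovery experiments at the study scale (20
replicates, 218 tips) recover the dispersal rate with a median relative
error of about 13%, and AIC prefers the generating constraint scenario
over the naive alternative in 100% of replicates.

## Limitations

- **The extinction rate is weakly identified.** In study-scale
  simulations the ML extinction rate collapses to the lower bound in
  nearly every replicate even though the data were generated with
  e = 0.021. Two structural reasons: the likelihood is not conditioned
  on survival while extinct lineages are (necessarily) absent from the
  fitted tree, biasing ê downward; and DEC cladogenesis resets ranges to
  single areas at almost every node of a densely sampled tree, so
  single-area endemism carries no extinction signal. Near-zero DEC
  extinction estimates are a long-recognised behaviour of the model;
  extinction rates reported by DEC fits should not be interpreted as
  demographic extinction rates.
- Dispersal multipliers are relative weights, not probabilities; only
  ratios of weights matter given `d`.
- The ultrametricity check warns rather than fails, so ages on strongly
  non-ultrametric trees are only as meaningful as the input.
- Ancestral reconstructions are marginal per node (a joint max-product
  mode exists for sensitivity checks); majority-rule assignment discards
  uncertainty that the per-area probability tables retain.
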