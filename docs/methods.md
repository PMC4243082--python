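# Methods

## The modelling framework

`logicfate` implements generalised (multi-valued) logical models in the
Thomas tradition. A model is a finite set of components, each holding an
integer activity level in `[0, max_level]`, and a set of rules. A rule
`(component, target_level, condition)` states that while `condition` holds
over the regulators' levels, the component is driven toward
`target_level`. The **image function** `K(x)` maps a state `x` (one level
per component) to the vector of target levels: for each component the
target of its unique satisfied rule, `0` when no rule is satisfied (level-0
rules are never written explicitly), and the current level for input
components, which are constant carriers of extrinsic conditions.

Rules of one component must be **mutually exclusive**: at most one
condition may hold for any combination of its regulators' levels. This is
validated exhaustively over each component's regulator subspace (these
subspaces are small — at most a few hundred assignments in the bundled
model). An overlap is reported as a model bug; there is no silent priority
or tie-break.

**Atom semantics.** Conditions are AND/OR/NOT trees over interval atoms
`lo <= x[regulator] <= hi`. In rule text, the bare form `X = n` follows
the threshold convention of the field's modelling tools and reads *level n
or above* (`[n, max]`); explicit ranges `X = a-b` read `[a, b]`. Where a
rule needs an exact sub-maximal level it says so explicitly
(`X = 1 AND NOT (X = 2)`), the same style multi-valued rules are written
in the literature. The exact-equality reading was rejected because it
provably breaks the bundled model's no-damage behaviour: with
`CDC25A = 1` read as "exactly 1", full CDC25A activity (level 2) would no
longer sustain CDK4/6–CyclinD, creating a spurious arrested fixed point in
the absence of damage.

**Dynamics.** Updates are unit-step: an enabled component (image differs
from level) moves one level toward its image, never jumps. The
asynchronous scheme yields one successor per enabled component
(non-determinism is an explicit successor set, never a hidden scheduler);
the synchronous scheme moves all enabled components at once. Stable states
— fixed points of `K` — are identical under both schemes; trajectories are
not. Attractors are terminal strongly connected components of the state
transition graph: singleton fixed points (`stable_state`) or cyclic sets
(`complex`).

**Perturbations.** A loss-of-function clamps a component into `[0, 0]`, a
gain-of-function into a positive level or interval; the image is clipped
into the clamp window. Clamping an input is equivalent to fixing its
level. Clamps compose commutatively, so double mutants are order
independent.

## Stable-state enumeration

Stable states are found by feedback-vertex-set (FVS) decomposition: with
inputs fixed, the dependency graph of the remaining components is made
acyclic by greedily removing a small feedback set (self-loop nodes first,
then the highest in×out degree node of each non-trivial strongly connected
component); the feedback components' levels are enumerated exhaustively
(within clamp windows), the acyclic remainder is propagated in topological
order, and assignments whose feedback images are inconsistent are
discarded. Every candidate is re-checked against the full image function
before being reported. For the bundled model the feedback set has two
members (one in the p53–Mdm2 module, one in the E2F/RB1/cyclin cycle), so
enumeration is instantaneous.

The greedy feedback set is not guaranteed minimum — only correct; the
enumeration cost is exponential only in the feedback set size.
`brute_force_stable_states` scans the full restricted subspace (refusing,
never truncating, above a configurable cap, default 10^7) and is the
independent oracle the decomposition is tested against, on the bundled
model's cyclic core and on hundreds of seeded random models.

Full-state-space attractor search (`attractors`) is intended for small
models (default cap 10^6 visited states); for larger models a set of
initial states restricts the search to their reachable subgraph.

## The G1/S checkpoint model

21 components: inputs SSB and DSB (0 none / 1 reparable / 2 irreparable);
the sensors ATM (activated by DSB) and ATR (by SSB), each 3-levelled; the
checkpoint kinases CHEK1/CHEK2; the stress kinase p38MAPK (4 levels,
integrating ATM and ATR); the CDKN2A products p14ARF and p16INK4a; the
p53–Mdm2–p21 module (p53 3-levelled, level 2 being the apoptotic
threshold); CDC25A (3 levels, fully inactivated only by the joint action of
CHEK1, CHEK2 and p38MAPK); the E2F/RB1/cyclin cell-cycle core; and four
Boolean fate read-outs. `proliferation` is CDK2–CyclinE activity,
`cycle_arrest` its absence; `apoptosis` requires p53 at level 2;
`senescence` requires p21 together with p16INK4a, with CDC25A absent — or,
when CDC25A is partially active, p16INK4a at its maximal level — and p53
below its apoptotic level.

Two encoding decisions deserve note:

* **p14ARF threshold.** The package encodes p14ARF as activated by
  p38MAPK at level 3 (or by E2F). The printed source rule uses level 2,
  under which irreparable DSB alone (DSB=2, SSB<2) sequesters Mdm2, drives
  p53 to level 2 and converts the senescent outcomes into apoptosis,
  contradicting the model's own reported fate map. The level-3 threshold
  uniquely restores that map and mirrors the p16INK4a rule
  (`2: p38MAPK = 3`). The printed rule is retained behind
  `build_g1s_model(variant="printed-p14ARF")` and a regression test
  documents exactly how it fails.
* **Canonical names.** `cycle_arrest`, `CDK46CycD`, `CDK2CycE`,
  `p16INK4a` — each appears under one spelling everywhere (source
  material varies).

One known discrepancy is quarantined rather than encoded: the claim that
CHEK2 loss of function still yields senescence when SSB = 2 is not
reproducible under any reading we attempted — senescence needs either full
CDC25A inactivation (which needs CHEK2) or maximal p16INK4a (which needs
maximal p38MAPK, which forces apoptotic p53). The screen reports cycle
arrest or apoptosis for those columns, and no test asserts the
irreproducible sentence.

## Circuit functionality

Circuits are simple cycles of the signed regulatory graph. Edge signs are
computed by exhaustive monotonicity of the image function (varying the
source over its range in every context of the co-regulators): `+` if the
target's image can only increase, `-` only decrease, `dual` if both (the
bundled model has none). Circuit sign is the parity of `-` edges.

Functionality is approximated by *threshold-consistent edge decisiveness*.
For edge `u -> v` and thresholds `(θ_u, θ_v)`, a co-regulator context is
decisive when moving `u` from `θ_u - 1` to `θ_u` flips
`image(v) >= θ_v`. A circuit is **functional** when one threshold per
member can be chosen so that every edge has a non-empty decisive context
at its endpoints' thresholds; it is **sustainable** under given inputs
when some stable state realises every edge's context simultaneously. This
is a simplified stand-in for the full algebraic functionality-context
computation of the circuit-analysis literature; it is exact enough to
reproduce all three structural claims about the bundled model:

* the sole positive circuit (CDK2CycE, RB1, E2F) is functional but not
  sustainable in the wild type — every no-damage stable state has
  CDK4/6–CyclinD active, bypassing the circuit;
* under a p16INK4a gain of function (clamp `[1,2]`), the bypass is silenced
  and the context is sustainable exactly at (SSB, DSB) = (0, 0), where the
  model is indeed bistable;
* the negative loop (p53, Mdm2) is not functional: Mdm2 only selects
  between p53 levels 1 and 2, while p53 acts on Mdm2 at threshold 1, so no
  consistent threshold assignment exists and the loop cannot generate
  sustained oscillations. A plain "the edge changes the image somewhere"
  reading would miss this.

The approximation requires each edge's context family to be non-empty but
checks joint realisability only at stable states (the sustainability
step); it does not construct the full state-space region symbolically.

## Monte-Carlo reachability

Attractor reach probabilities are estimated with an unbiased asynchronous
random walk: initial states uniform over the clamp-respecting space with
inputs fixed; at each step a uniform choice among enabled unit
transitions; absorption at a stable state, or `unresolved` after
`max_steps`. Defaults: `n_runs = 10^4`, `max_steps = 10^4`, one seeded
generator per estimate (same seed, same estimate). Unresolved runs above
1% raise a visible warning and are reported, never dropped; frequencies
plus the unresolved fraction sum to one. Binomial 95% intervals use the
normal approximation.

The estimator is checked against `exact_absorption_probabilities`, which
solves the absorption linear system `(I - Q) B = R` of the same
uniform-choice chain on the full transition graph of small models
(agreement within three standard errors is a test). For the bundled model
under a p16INK4a gain of function at no damage, 10^4 runs give
P(cycle-arrest attractor) ≈ 0.91 (seed dependent within the binomial
interval), comfortably above the 0.9 reference bound.

## Synthetic models

`random_model` draws, for each non-input component, an explicit image
table over its (at most 3) regulators and reads the rules off the table —
one rule per positive target level, as a disjunction of exact regulator
assignments. Exclusivity therefore holds by construction, keeping the
validator's exclusivity check meaningful when run on hand-written models.
The generator is seeded and deterministic. These models exercise the
engine (stable-state decomposition vs brute force, scheme independence,
sign computation, circuit enumeration) but emulate no biological topology:
no degree structure, no signed-motif statistics, no input/output layering
beyond the requested input count. Passing the property suite shows the
*engine* is correct on arbitrary small models; it says nothing about the
biological adequacy of any particular encoding, which is why the bundled
model carries its own fate-map, screen and circuit tests.

## Problem sizes and numerical choices

The packaged analyses are exact and small: stable-state enumeration per
input condition touches at most a few dozen candidate assignments;
the mutant screen (33 perturbation configurations × 9 conditions) runs in
well under a second; property suites use models of 3–8 components where
brute force covers ≤ ~3000 states. The Monte-Carlo default of 10^4 runs
matches the published sampling size; unit tests use smaller run counts
with correspondingly generous bounds, while the acceptance-level checks
use the full 10^4. Ties never arise in deterministic outputs: states sort
by component-level tuples in canonical component order, circuits by their
lexicographically smallest rotation.

## Known limitations

* Attractor search is explicit, not symbolic; complex-attractor detection
  on the full 21-component model is out of reach by design (the bundled
  model's analyses need only fixed points, whose completeness does not
  depend on state-space search; absence of complex attractors is supported
  by every Monte-Carlo run resolving, not proven).
* The functionality analysis is the documented approximation above, not
  the full algebraic context computation.
* The sampling scheme is the plain uniform random walk; no
  variance-reduction or importance scheme is attempted.
* GINML/SBML-qual import/export is not implemented; the JSON dialect
  described in `logicfate.io` is the only model format.
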