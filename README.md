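# logicfate

Multi-valued logical modelling of cell-fate decision at the G1/S DNA-damage
checkpoint — a generic Thomas-formalism engine plus a fully encoded,
extensively tested checkpoint model.

## The problem

When a cell senses DNA damage — single-strand breaks (SSB) or double-strand
breaks (DSB) — signalling through ATM/ATR, the checkpoint kinases, p38MAPK
and the p53 and p16INK4a axes decides between four fates at the G1/S
checkpoint: keep **proliferating**, **arrest** transiently for repair,
enter **senescence** (permanent arrest), or trigger **apoptosis**. The
package is for systems biologists who want to analyse this decision (or any
other small regulatory network) qualitatively, without kinetic parameters.

## The model

Each component `i` holds a discrete level `x_i ∈ {0, …, max_i}`. Logical
rules define the image function `K(x)`: the vector of levels the rules
drive the system toward at state `x`. Dynamics are unit-step and (by
default) asynchronous — one enabled component moves one level toward its
image per transition. Fixed points of `K` are the stable states; terminal
strongly connected components of the transition graph are the attractors.
Perturbations clamp components (loss of function `[0,0]`, gain of function
a positive level or window). Circuits of the signed interaction graph are
screened for functionality (can the circuit actually produce
multistability or oscillations, and is its context sustainable at a stable
state?), and basins of attraction are estimated by a seeded uniform
asynchronous random walk, cross-checked against exact absorption
probabilities on small models.

The bundled G1/S model has 21 components: graded inputs SSB and DSB
(0 none / 1 reparable / 2 irreparable), 15 internal regulators (p53 and
CDC25A 3-levelled, p38MAPK 4-levelled) and 4 Boolean fate read-outs. See
`docs/methods.md` for the full formalism, encoding decisions and known
limitations.

## Worked example

```python
from logicfate import (build_g1s_model, stable_states, fate_of,
                       apply_perturbation, gain_of_function,
                       estimate_probabilities, McConfig)

model = build_g1s_model()
assert model.validate() == []

# wild type: every damage combination has exactly one stable state
for ssb in range(3):
    for dsb in range(3):
        (state,) = stable_states(model, {"SSB": ssb, "DSB": dsb})
        print((ssb, dsb), sorted(fate_of(model, state)))
```

```
(0, 0) ['proliferation']
(0, 1) ['cycle_arrest']
(0, 2) ['cycle_arrest', 'senescence']
(1, 0) ['cycle_arrest']
(1, 1) ['cycle_arrest']
(1, 2) ['cycle_arrest', 'senescence']
(2, 0) ['cycle_arrest']
(2, 1) ['cycle_arrest']
(2, 2) ['apoptosis', 'cycle_arrest']
```

No damage → proliferation; irreparable DSB with sub-maximal SSB →
senescence (with arrest); both inputs irreparable → apoptosis; everything
else → transient arrest. Note irreparable SSB alone does *not* induce
senescence.

Holding p16INK4a positive (gain of function in `[1,2]`) without damage
makes the model bistable, and the random walk says arrest dominates:

```python
mutant = apply_perturbation(model, gain_of_function("p16INK4a", 1, 2))
est = estimate_probabilities(mutant, {"SSB": 0, "DSB": 0},
                             McConfig(n_runs=10_000, seed=1))
for attractor, p, ci in zip(est.attractors, est.probabilities, est.intervals):
    print(sorted(fate_of(mutant, attractor)), p, ci)
```

```
['cycle_arrest'] 0.9072 (0.9015, 0.9129)
['proliferation'] 0.0928 (0.0871, 0.0985)
```

So a cell with constitutively positive p16INK4a arrests from ~91% of random
initial configurations even with pristine DNA — the proliferative state
survives only for trajectories that engage the CDK2CycE/RB1/E2F positive
circuit before p16INK4a shuts the CDK4/6 bypass.

The same analyses are available from the shell:

```sh
logicfate stable-states --format csv          # 9-row fate table
logicfate screen --perturb p53=0              # mutant vs wild type
logicfate circuits                            # 4 circuits, 1 positive
logicfate reach --perturb p16INK4a=1:2 --inputs SSB=0,DSB=0 \
    --runs 10000 --seed 1
```

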