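# flutor

Identification and enumeration of **relative flux trade-offs** in
constraint-based metabolic models.

## The problem

A genome-scale metabolic model constrains the fluxes `v` of its `n`
reactions by steady state, `N v = 0` (with `N` the `m x n` stoichiometric
matrix), and by bounds `lb <= v <= ub`. Within that space, growth (the flux
`v_bio` of a biomass reaction, or any other reaction of interest `r_j`) can
often be realized by many alternative flux distributions. A *relative flux
trade-off* is a relation

    v_j = sum_{i != j} alpha_i * v_i,     alpha_i >= 0,

with at least two irreversible, variable reactions carrying positive
coefficients, that holds on **every** steady-state flux distribution. At
fixed `v_j` the participating fluxes can only be traded against one
another; away from the optimum, raising any flux with `alpha_i > 0` can
raise `v_j` itself — which makes the support reactions natural
overexpression candidates for strain design.

Such relations are exactly the vectors `alpha = k N` in the row space of
`N` (for a metabolite weight vector `k`) with the sign pattern above:
simple examples are the mass-balance row of a branch-point metabolite (a
*directionally coupled equation*) and sums of rows that cancel shared
reactions (*merged* directionally coupled equations).

## The method

The pipeline has three steps:

1. **Preprocess** — maximize `v_j` by flux balance analysis (FBA), impose a
   growth bound `v_j >= f * v_j_opt` (f = 0.90 / 0.95 / 0.99), classify all
   reactions by flux variability analysis (FVA) as blocked / fixed /
   variable, remove blocked reactions and dead-end metabolites, and split
   effectively reversible reactions into forward and reverse parts.
2. **Couple** — run flux coupling analysis; *fully coupled* sets (fluxes in
   a fixed ratio) are merged into single reactions, which shrinks the MILP
   and removes ratio-degenerate duplicates.
3. **Enumerate** — solve a mixed-integer linear program over `k`:
   minimize `||k N||_1` subject to `alpha = k N`, `alpha_j = -1`,
   `alpha_i >= 0`, binary support indicators with `eps z_i <= alpha_i <=
   M z_i`, at least two support members, and a steady-state witness flux
   block. Each found support `Z` is excluded, together with its supersets,
   by an integer cut `sum_{i in Z} z_i <= |Z| - 1`; iterating to
   infeasibility yields exactly the inclusion-minimal supports. Merged
   trade-offs are finally expanded back through the coupling classes.

Downstream analyses classify subsystems (always / sometimes / never in
trade-off) and proteins (all / none / some catalysed reactions in
trade-off), run a 2x3 Fisher exact test (Freeman–Halton) for association
with enzyme promiscuity, compare trade-off supports with the reactions
partially/directionally coupled to the target, and screen supports that
stay FVA-variable at a higher growth bound as overexpression targets.

## Worked example: the Calvin–Benson toy network

The built-in five-metabolite cycle (GAP, Ru5P, RuBP, DPGA, PGA; seven
irreversible reactions, upper bounds 600, 1000, 1000, 1000, 600, 200,
166.7 mmol/gDW/h) is the package's running example:

```python
>>> import flutor as ft
>>> model = ft.build_calvin_benson_fixture()
>>> comp = ft.compact_model(model, ft.fva(model))
>>> ft.full_coupling_sets(comp)
[('r1', 'r2', 'r3'), ('r4', 'r5'), ('r6',), ('r7',)]
>>> run = ft.run_flutor(model, growth_fraction=0.9, target="r4")
>>> run.optimum, run.enumeration.milp_solves
(600.0, 3)
>>> for t in run.enumeration.expanded:
...     print(sorted(t.support), {r: round(a, 4) for r, a in sorted(t.alpha.items())})
['r1', 'r7'] {'r1': 1.6667, 'r4': -1.0, 'r7': 1.0}
['r2', 'r7'] {'r2': 1.6667, 'r4': -1.0, 'r7': 1.0}
['r3', 'r7'] {'r3': 1.6667, 'r4': -1.0, 'r7': 1.0}
['r6', 'r7'] {'r4': -1.0, 'r6': 5.0, 'r7': 6.0}
```

Reading the output: r1–r3 (regeneration + carboxylation, class "rA") and
r4–r5 (reduction, class "rB") are fully coupled and merge to two reactions.
With rB as the reaction of interest, two merged trade-offs are found in
three MILP solves (the third proves completeness):
`v_B = 5/3 v_A + v_7` — the GAP balance, expanding over the class of rA to
the family {r1,r7}, {r2,r7}, {r3,r7} — and `v_B = 5 v_6 + 6 v_7`, which
eliminates the internal fluxes entirely. Running the other internal class
rA as target adds {r4,r6}, {r5,r6} and {r6,r7}: six distinct trade-offs in
the cycle from three distinct merged MILP solutions. The interpretation is
immediate: at a fixed reduction-phase flux, carbon export through PGA (r6)
and GAP (r7) can only be traded against the internal cycle fluxes, and
raising either export while growth is suboptimal raises the attainable
cycle flux.

The same API drives the command line:

```sh
flutor fixture toys/
flutor enumerate --model toys/calvin_benson.json --growth-fraction 0.9 --outdir out/
flutor report --model toys/calvin_benson.json --outdir out/
```

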