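# Methods

## Model and feasible space

A metabolic network is the stoichiometric matrix `N` (`m` metabolites by
`n` reactions) with flux bounds in mmol/gDW/h. The analysed space is
`F = {v : N v = 0, lb <= v <= ub}`; after the growth bound is applied the
target reaction `r_j` additionally satisfies `v_j >= f * v_j_opt`, where
`v_j_opt` is the FBA maximum and `f` in (0, 1] is the growth fraction
(0.90, 0.95, 0.99 in the standard sweeps). Exchange reactions follow the
arrow-to-nothing convention: single-sided stoichiometric columns, no
external metabolite rows. Reversibility is identified with a negative
lower bound, so the flag and the bounds cannot disagree.

## Relative trade-offs as row-space vectors

A relative trade-off w.r.t. `r_j` is a vector `alpha` with
`alpha = k N` for some metabolite weight vector `k`, `alpha_j < 0`,
`alpha_i >= 0` for `i != j`, and at least two irreversible *variable*
reactions in the support. Because `alpha` lies in the row space of `N`,
`alpha . v = 0` for every steady state, i.e.
`v_j = sum alpha_i v_i` (after scaling `alpha_j` to -1) on all of `F`.
Strict inequality `alpha_j < 0` is not expressible in an LP; by scale
invariance of `k N = alpha` the normalization `alpha_j = -1` is lossless,
removes the degeneracy, and makes coefficients comparable across
trade-offs. The support constraint is implemented as "at least two
eligible non-target members"; with the target itself this gives total
support of at least three.

Two further eligibility rules, both consequences of the definition:

* Coefficients on FVA-**fixed** reactions are forced to zero — a nonzero
  coefficient on a constant flux would make the relation affine
  (`v_j = c + sum alpha_i v_i`), not a trade-off between variable fluxes.
* Only irreversible (post-splitting) reactions can carry support, mirroring
  the restriction of directionally coupled equations to irreversible
  reactions carrying non-zero flux.

## Pipeline

1. **FBA / growth bound / FVA.** 2n LPs give per-reaction flux ranges over
   the growth-bounded `F`. Statuses: *blocked* (|range| within `tol`),
   *fixed* (width within `variability_tol`), else *variable*. Tolerances
   `tol = variability_tol = 1e-6` sit three orders of magnitude above
   HiGHS solver noise; the LP feasibility tolerance is the solver default
   (~1e-9).
2. **Compaction.** Blocked reactions are removed; dead-end metabolites
   (producible-only or consumable-only, judged by the observed flux
   directions) are removed together with their reactions, iterated to a
   fixed point because one removal can orphan further metabolites.
   Effectively reversible reactions (FVA range crossing zero) are split
   into `_fwd`/`_rev` parts whose bounds partition the original range; a
   reaction observed to run only backwards is flipped in place. The result
   has zero lower bounds everywhere; the growth bound is carried by the
   pipeline and reapplied to the target wherever a later stage needs it
   (merged-model FVA, the MILP witness block).
3. **Coupling and merging.** Coupling is decided by zero-forcing LPs on the
   compacted model: `r_i` is directionally coupled to `r_j` when
   `max v_i s.t. v_j = 0` vanishes (within 1e-6 relative to the bound
   scale); partial coupling is both directions; full coupling additionally
   requires the ratio `v_i / v_j` to be constant, probed at two
   normalization points of `v_j` to guard against boundary artifacts.
   Pairwise tests are pruned by connected components of the
   reaction–metabolite graph and by transitivity of established classes.
   Each full-coupling class collapses to its first member: the merged
   column is the ratio-weighted sum of member columns, bounds are the
   scaled intersection, and the mapping `v_member = scale * v_merged` is
   retained for expansion. Coupling queries are run on the zero-lower-bound
   model: with a growth bound in place every reaction would be trivially
   "coupled" to the target (its flux can never vanish), which would void
   the comparison analyses.
4. **MILP.** Variables `k` (free), `alpha` (with `alpha = k N` as equality
   rows), binaries `z` over eligible reactions, and a witness flux `v`
   (`N v = 0`, bounds, growth bound on the target). Constraints
   `eps z_i <= alpha_i <= M z_i` link support membership to the binaries;
   `sum z_i >= 2`. Because all non-target coefficients are sign-constrained,
   `||k N||_1` is simply `1 + sum alpha_i` and the objective is linear
   without an absolute-value split. Defaults `eps = 1e-4`, `M = 1e4`
   (coefficients are normalized by `alpha_j = -1`, so both are far from the
   solver's feasibility and integrality tolerances); the support-reporting
   threshold is `coeff_eps = 1e-6`. After each solve the coefficients are
   re-polished by an LP restricted to the found support, so reported
   coefficients are independent of MILP vagaries and runs are
   deterministic (single-threaded HiGHS).
5. **Integer cuts and enumeration.** Each found support `Z` adds
   `sum_{i in Z} z_i <= |Z| - 1`, which forbids `Z` *and its supersets*.
   The enumeration therefore terminates with exactly the inclusion-minimal
   feasible supports, in increasing L1 order, and the terminating
   infeasible MILP is counted in `milp_solves` (`milp_solves =
   |tradeoffs| + 1` on complete runs). The design was genuinely open:
   a plain no-good cut (forbidding only the exact set) would additionally
   enumerate conic combinations of already-found trade-offs — on the
   Calvin–Benson toy a third, redundant support {rA, r6, r7} padded at the
   `eps` floor — inflating both the solve count and the trade-off list
   with non-minimal relations. Minimal-support semantics also make the
   enumeration directly comparable to the exhaustive oracle
   (`brute_force_tradeoffs`), which solves per-support feasibility LPs on
   an independent code path.
6. **Expansion.** A merged support member is replaced, one at a time, by
   each member of its coupling class with the coefficient divided by the
   class scale (`alpha_member = alpha_merged / c` when
   `v_member = c v_merged`); results are de-duplicated by (target,
   support). The target keeps its class representative: the corresponding
   relations for other members of the target's class are implied by the
   full coupling itself, and fanning the target out would multiply-count
   what is a single constraint.

## Downstream analyses

* **Subsystem classes.** Across all trade-offs of a sweep: *always* — some
  reaction of the subsystem is in every support; *sometimes* — in at least
  one but not all; *never* — in none. Unlabelled reactions fall into an
  "unannotated" bucket.
* **Proteins.** A protein is a gene symbol occurring in any GPR rule
  (the models' rules are gene-level); classes all_in / none_in / mixed by
  the trade-off membership of the reactions whose rules mention it.
  Malformed rules (unbalanced parentheses) drop the reaction from the
  protein map with a warning.
* **Fisher 2x3.** Rows: protein catalyses only trade-off reactions / only
  non-trade-off reactions / both; columns: one vs several catalysed
  reactions. The null distribution fixes both margins; the probability of
  a table is the product of per-row binomials over the left-column
  hypergeometric normalizer, computed in log space (lgamma). The p-value
  sums all tables with probability not exceeding the observed one
  (two-sided Freeman–Halton; the single-table probability alone is not a
  test, so the tail construction is this package's documented choice), with
  a 1e-9 log-tolerance for ties.
* **Coupling comparison.** Per condition, the overlap between trade-off
  reactions and the set partially or directionally coupled to the target.
  Containment of supports in the coupled set is a theorem (non-zero flux
  through a support reaction forces non-zero target flux); the package
  asserts it on every run and reports violations as diagnostics for
  tolerance problems.
* **Overexpression targets.** Support reactions that remain FVA-variable
  when the growth bound is raised to a higher fraction (default 0.99): for
  those, increasing the flux need not be compensated elsewhere and can
  push the target flux toward its optimum.

## Built-in networks and the generator

* **Calvin–Benson toy** (5 metabolites, 7 irreversible reactions; upper
  bounds 600, 1000, 1000, 1000, 600, 200, 166.7 mmol/gDW/h). The figure it
  is drawn from prints the bounds and the coupling structure but not the
  stoichiometric coefficients; the fixture uses the canonical cycle ratios
  (5 triose phosphates regenerate 3 pentose phosphates, hence 5/3 on r1;
  carboxylation yields 2 PGA per RuBP on r3, the carbon gain that lets
  both exports run). These are the unique ratios consistent with textbook
  stoichiometry; any admissible alternative must preserve the coupling
  partition and the trade-off family, which a build-time self-check
  asserts so a transcription error fails immediately. Note one deliberate
  reading: the exports r6/r7 are "uncoupled" in the *full-coupling* sense
  (they join no merged class and are mutually uncoupled); under the strict
  directional definition an export of an internally produced metabolite is
  necessarily coupled to its producers, and the package reports exactly
  that.
* **Branch-point (DCE) network.** One metabolite, one producer, `c >= 2`
  consumers with given molarities: the minimal network whose single
  mass-balance row is itself the unique minimal trade-off.
* **Random planted networks.** Deterministic composition (NumPy
  `default_rng(seed)`) of chain motifs (each one planted full-coupling
  class), branch motifs (each one planted minimal trade-off), plus filler
  source→sink pairs (extra size-2 classes) and orphan sinks (planted
  blocked reactions). Integer stoichiometries in 1–3 and bounds in 2–20
  keep the LPs well-scaled. The generator records the ground truth it
  plants, and by construction the motifs are metabolite-disjoint, so the
  planted answers are provably the complete answers — which is what makes
  them usable as oracles. What the generator does *not* emulate: dense
  cross-pathway sharing of cofactors, reversible cycles, and the
  degeneracy of genome-scale models; passing these tests certifies the
  algorithms, not performance or conditioning at genome scale.

## Numerical choices and degenerate inputs

LPs and MILPs run on HiGHS via SciPy, single-threaded, which makes every
run bit-reproducible for a fixed input. FVA ranges are clamped so
`min <= max` before classification. Merged classes can produce all-zero
columns (a merged source→sink pair converts nothing to nothing); such
reactions can never carry support since `alpha_i = k . 0 = 0`. Models with
only one non-target eligible reaction short-circuit to "no trade-off"
without a solve being wasted. Row-space verification uses least squares
with residual tolerance 1e-8 and never trusts a stored `k`.

## Problem sizes in the shipped tests

The default suite and the acceptance script run entirely on the toy
networks and on 20–50 seeded planted networks of at most ~12 reactions
after merging, where the exhaustive oracle is exact; genome-scale runs are
provided as a separate script requiring the published model files. The
per-support feasibility enumeration in the oracle is guarded at 200,000
candidate supports.

## Known limitations

* Only minimal-support relative trade-offs are enumerated; non-minimal
  sign-feasible row-space vectors (conic combinations) are derivable but
  not listed.
* No loopless-FVA variant, no parsimonious FBA, no absolute
  (environment-invariant) trade-off mode, no gap-filling or thermodynamic
  constraints.
* Positive lower bounds other than the growth bound (e.g. ATP maintenance)
  are dropped to zero during compaction; their effect on FVA
  classification is retained but the compacted feasible set is then a
  relaxation.
* Protein identity is the gene symbol; isoenzyme/complex semantics of GPR
  rules (AND vs OR) are not distinguished in the protein classes.
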