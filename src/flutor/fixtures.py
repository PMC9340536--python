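"""Built-in toy networks and the seeded random-network generator.

The Calvin-Benson toy is the worked example used throughout the package
documentation; the single-branch-point network is the minimal directionally
coupled equation (DCE); :func:`generate_random_model` composes chain and
branch motifs with ground-truth bookkeeping so that coupling analysis and
trade-off enumeration can be tested against planted answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MetabolicModel

__all__ = [
    "build_calvin_benson_fixture",
    "build_branch_fixture",
    "generate_random_model",
    "PlantedModel",
]

# Coupling classes asserted by the fixture self-check (see module docs):
# {r1,r2,r3} (merged "rA"), {r4,r5} (merged "rB"), with the two exchange
# reactions r6 and r7 in singleton classes.
CALVIN_COUPLING_SETS = (
    frozenset({"r1", "r2", "r3"}),
    frozenset({"r4", "r5"}),
    frozenset({"r6"}),
    frozenset({"r7"}),
)

_calvin_checked = False


def build_calvin_benson_fixture(self_check: bool = True) -> MetabolicModel:
    """Five-metabolite Calvin-Benson cycle with seven irreversible reactions.

    Metabolites: GAP, Ru5P, RuBP, DPGA, PGA.  Reactions (all lower bounds 0;
    upper bounds 600, 1000, 1000, 1000, 600, 200, 166.7 mmol/gDW/h)::

        r1: 5/3 GAP -> Ru5P      (regeneration phase, lumped)
        r2: Ru5P -> RuBP         (phosphoribulokinase)
        r3: RuBP -> 2 PGA        (RuBisCO carboxylation; CO2 not modelled)
        r4: PGA -> DPGA          (phosphoglycerate kinase)
        r5: DPGA -> GAP          (GAP dehydrogenase)
        r6: PGA ->               (export)
        r7: GAP ->               (export)

    The 5/3 regeneration and 2:1 carboxylation ratios are the canonical
    Calvin-cycle stoichiometry (5 triose phosphates regenerate 3 pentose
    phosphates; one carboxylation yields two phosphoglycerates).  The first
    call runs a self-check asserting the full-coupling partition
    {r1,r2,r3}, {r4,r5}, {r6}, {r7}, so a transcription error fails fast.
    """
    mets = ("GAP", "Ru5P", "RuBP", "DPGA", "PGA")
    rxns = ("r1", "r2", "r3", "r4", "r5", "r6", "r7")
    S = np.zeros((5, 7))
    i = {m: k for k, m in enumerate(mets)}
    S[i["GAP"], 0] = -5.0 / 3.0
    S[i["Ru5P"], 0] = 1.0
    S[i["Ru5P"], 1] = -1.0
    S[i["RuBP"], 1] = 1.0
    S[i["RuBP"], 2] = -1.0
    S[i["PGA"], 2] = 2.0
    S[i["PGA"], 3] = -1.0
    S[i["DPGA"], 3] = 1.0
    S[i["DPGA"], 4] = -1.0
    S[i["GAP"], 4] = 1.0
    S[i["PGA"], 5] = -1.0
    S[i["GAP"], 6] = -1.0
    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        lower_bounds=np.zeros(7),
        upper_bounds=np.array([600.0, 1000.0, 1000.0, 1000.0, 600.0, 200.0, 166.7]),
        subsystems=(
            "Regeneration",
            "Regeneration",
            "Carboxylation",
            "Reduction",
            "Reduction",
            "Export",
            "Export",
        ),
        gpr=("TKL1", "PRK1", "RBCL and RBCS", "PGK1", "GAPA or GAPB", "", ""),
        target_reaction="r4",
        name="calvin_benson",
    )
    global _calvin_checked
    if self_check and not _calvin_checked:
        _calvin_self_check(model)
        _calvin_checked = True
    return model


def _calvin_self_check(model: MetabolicModel) -> None:
    # deferred imports: the fixture sits below preprocess/coupling in the stack
    from .coupling import full_coupling_sets
    from .preprocess import compact_model, fva

    compacted = compact_model(model, fva(model))
    sets = {frozenset(s) for s in full_coupling_sets(compacted)}
    expected = set(CALVIN_COUPLING_SETS)
    if sets != expected:
        raise AssertionError(
            "Calvin-Benson fixture transcription error: full-coupling partition "
            f"is {sorted(map(sorted, sets))}, expected {sorted(map(sorted, expected))}"
        )


def build_branch_fixture(
    molarities: Sequence[float],
    n_consumers: int | None = None,
    consumer_upper_bounds: Sequence[float] | None = None,
    producer_upper_bound: float = 1000.0,
) -> MetabolicModel:
    """One branch-point metabolite m1: r1 produces it, r2..r(n+1) consume it.

    Consumer i withdraws ``molarities[i]`` units of m1 per unit flux, so every
    steady state satisfies v1 = sum_i molarity_i * v_(i+1): the canonical
    directionally coupled equation.  All reactions are irreversible with
    finite upper bounds (consumers default to 10 mmol/gDW/h).
    """
    molarities = [float(a) for a in molarities]
    if n_consumers is None:
        n_consumers = len(molarities)
    if n_consumers < 2:
        raise ValueError("a branch point needs at least two consumers")
    if len(molarities) != n_consumers:
        raise ValueError(
            f"got {len(molarities)} molarities for {n_consumers} consumers"
        )
    if any(a <= 0 for a in molarities):
        raise ValueError("all molarities must be positive")
    if consumer_upper_bounds is None:
        consumer_upper_bounds = [10.0] * n_consumers
    if len(consumer_upper_bounds) != n_consumers:
        raise ValueError("one upper bound per consumer is required")
    n = n_consumers + 1
    S = np.zeros((1, n))
    S[0, 0] = 1.0
    for k, a in enumerate(molarities):
        S[0, k + 1] = -a
    return MetabolicModel(
        metabolite_ids=("m1",),
        reaction_ids=tuple(f"r{k + 1}" for k in range(n)),
        S=S,
        lower_bounds=np.zeros(n),
        upper_bounds=np.array([producer_upper_bound, *consumer_upper_bounds]),
        target_reaction="r1",
        name="branch_point",
    )


@dataclass(frozen=True)
class PlantedModel:
    """A random model together with the ground truth planted into it."""

    model: MetabolicModel
    coupling_sets: tuple[frozenset[str], ...]  # full-coupling classes (unblocked)
    tradeoffs: tuple[tuple[str, frozenset[str]], ...]  # (target, minimal support)
    blocked_reactions: frozenset[str]


def generate_random_model(
    n_metabolites: int,
    n_reactions: int,
    planted_coupling_sets: Sequence[int] = (),
    planted_branches: Sequence[int] = (),
    seed: int = 0,
) -> PlantedModel:
    """Deterministically compose chain and branch motifs into a random model.

    ``planted_coupling_sets`` lists chain lengths (each chain is one
    fully coupled class of that size); ``planted_branches`` lists consumer
    counts (each branch contributes one planted minimal trade-off: the
    producer expressed as the positive sum of its consumers).  Leftover
    metabolite/reaction budget is filled with source->sink pairs (extra
    size-2 coupling classes) and orphan sinks (blocked reactions), whose
    bookkeeping is also recorded.
    """
    rng = np.random.default_rng(seed)
    mets: list[str] = []
    cols: list[dict[int, float]] = []
    rids: list[str] = []
    ubs: list[float] = []
    coupling_sets: list[frozenset[str]] = []
    tradeoffs: list[tuple[str, frozenset[str]]] = []
    blocked: set[str] = set()

    def add_met(mid: str) -> int:
        mets.append(mid)
        return len(mets) - 1

    def add_rxn(rid: str, stoich: dict[int, float], ub: float) -> None:
        rids.append(rid)
        cols.append(stoich)
        ubs.append(float(ub))

    for c, length in enumerate(planted_coupling_sets):
        if length < 2:
            raise ValueError("planted chains must have length >= 2")
        members = []
        prev = None
        for k in range(length):
            rid = f"c{c}_r{k + 1}"
            members.append(rid)
            stoich: dict[int, float] = {}
            if prev is not None:
                stoich[prev] = -float(rng.integers(1, 4))
            if k < length - 1:
                cur = add_met(f"c{c}_m{k + 1}")
                stoich[cur] = float(rng.integers(1, 4))
                prev = cur
            add_rxn(rid, stoich, float(rng.integers(5, 21)))
        coupling_sets.append(frozenset(members))

    for b, n_cons in enumerate(planted_branches):
        if n_cons < 2:
            raise ValueError("planted branches need at least two consumers")
        node = add_met(f"b{b}_m")
        producer = f"b{b}_r0"
        add_rxn(producer, {node: 1.0}, 200.0)
        consumers = []
        for k in range(n_cons):
            rid = f"b{b}_r{k + 1}"
            consumers.append(rid)
            add_rxn(rid, {node: -float(rng.integers(1, 4))}, float(rng.integers(2, 11)))
        coupling_sets.append(frozenset({producer}))
        coupling_sets.extend(frozenset({c_}) for c_ in consumers)
        tradeoffs.append((producer, frozenset(consumers)))

    extra_m = n_metabolites - len(mets)
    extra_r = n_reactions - len(rids)
    if extra_m < 0 or extra_r < 0:
        raise ValueError(
            "requested counts are below what the planted motifs require "
            f"(need >= {len(mets)} metabolites, >= {len(rids)} reactions)"
        )
    # each filler consumes one metabolite and one (orphan sink, blocked) or
    # two (source->sink pair, live) reactions
    if not (extra_m <= extra_r <= 2 * extra_m):
        raise ValueError(
            "infeasible filler budget: need extra reactions between "
            f"{extra_m} and {2 * extra_m}, got {extra_r}"
        )
    n_pairs = extra_r - extra_m
    for e in range(extra_m):
        node = add_met(f"x{e}_m")
        if e < n_pairs:
            src, snk = f"x{e}_src", f"x{e}_snk"
            coef = float(rng.integers(1, 4))
            add_rxn(src, {node: coef}, float(rng.integers(5, 21)))
            add_rxn(snk, {node: -float(rng.integers(1, 4))}, float(rng.integers(5, 21)))
            coupling_sets.append(frozenset({src, snk}))
        else:
            rid = f"x{e}_dead"
            add_rxn(rid, {node: -1.0}, float(rng.integers(5, 21)))
            blocked.add(rid)

    S = np.zeros((len(mets), len(rids)))
    for j, stoich in enumerate(cols):
        for i_, coef in stoich.items():
            S[i_, j] = coef
    target = tradeoffs[0][0] if tradeoffs else (rids[0] if rids else None)
    model = MetabolicModel(
        metabolite_ids=tuple(mets),
        reaction_ids=tuple(rids),
        S=S,
        lower_bounds=np.zeros(len(rids)),
        upper_bounds=np.array(ubs),
        target_reaction=target,
        name=f"planted_seed{seed}",
    )
    return PlantedModel(
        model=model,
        coupling_sets=tuple(coupling_sets),
        tradeoffs=tuple(tradeoffs),
        blocked_reactions=frozenset(blocked),
    )
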