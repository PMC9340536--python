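"""Downstream reporting: condition sweeps, enrichment, coupling comparison.

The sweep runs the full trade-off pipeline under a list of media conditions
(exchange bounds + growth fraction).  Subsystems are classified as always /
sometimes / never in trade-off across every identified trade-off of the
sweep; proteins (gene symbols from GPR rules) by whether the reactions they
catalyze are all / none / partly in trade-off; a 2x3 Fisher exact test
(Freeman-Halton) quantifies whether trade-offs are underpinned by
promiscuous proteins.  Trade-off supports are compared against the set of
reactions partially or directionally coupled to the target, and support
reactions that stay FVA-variable at a higher growth bound are reported as
overexpression targets: if the target flux is below its optimum, raising
any support flux with a positive coefficient can raise the target flux.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coupling import CoupledSets, coupled_to_reaction
from .model import InfeasibleModelError, MediaCondition, MetabolicModel
from .preprocess import apply_growth_bound, fva, original_reaction_id
from .tradeoffs import FlutorConfig, FlutorRun, run_flutor

__all__ = [
    "ContingencyTable2x3",
    "ConditionResult",
    "ConditionSweepResult",
    "run_condition_sweep",
    "classify_subsystems",
    "classify_proteins",
    "fisher_exact_2x3",
    "protein_promiscuity_table",
    "compare_with_coupling",
    "CouplingComparison",
    "identify_overexpression_targets",
    "subsystem_edges",
]


# -- condition sweeps ---------------------------------------------------------


@dataclass(frozen=True)
class ConditionResult:
    condition: MediaCondition
    status: str  # "ok" | "failed"
    reason: str = ""
    run: FlutorRun | None = None

    @property
    def tradeoff_reactions(self) -> frozenset[str]:
        return self.run.tradeoff_reactions if self.run is not None else frozenset()


@dataclass(frozen=True)
class ConditionSweepResult:
    model: MetabolicModel
    conditions: tuple[ConditionResult, ...]

    def result(self, name: str) -> ConditionResult:
        for c in self.conditions:
            if c.condition.name == name:
                return c
        raise KeyError(f"no condition named {name!r}")

    @property
    def all_tradeoffs(self) -> list:
        """Expanded trade-offs across all successful conditions."""
        out = []
        for c in self.conditions:
            if c.run is not None:
                out.extend(c.run.enumeration.expanded)
        return out

    @property
    def tradeoff_reactions(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.conditions:
            out |= c.tradeoff_reactions
        return frozenset(out)


def run_condition_sweep(
    model: MetabolicModel,
    conditions: Sequence[MediaCondition],
    cfg: FlutorConfig | None = None,
) -> ConditionSweepResult:
    """Run the full pipeline independently under each media condition.

    Infeasible conditions are recorded as failed (with the reason) and the
    sweep continues; results are keyed by condition name and invariant to
    condition order.
    """
    results = []
    for cond in conditions:
        try:
            conditioned = cond.apply(model)
            run = run_flutor(conditioned, growth_fraction=cond.growth_fraction, cfg=cfg)
        except (InfeasibleModelError, ValueError, KeyError) as exc:
            results.append(
                ConditionResult(condition=cond, status="failed", reason=str(exc))
            )
            continue
        results.append(ConditionResult(condition=cond, status="ok", run=run))
    return ConditionSweepResult(model=model, conditions=tuple(results))


# -- subsystem / protein classification ---------------------------------------


def _support_sets(sweep_or_tradeoffs) -> list[frozenset[str]]:
    if isinstance(sweep_or_tradeoffs, ConditionSweepResult):
        tradeoffs = sweep_or_tradeoffs.all_tradeoffs
    else:
        tradeoffs = list(sweep_or_tradeoffs)
    return [
        frozenset(original_reaction_id(r) for r in t.support) for t in tradeoffs
    ]


def classify_subsystems(
    model: MetabolicModel, sweep: "ConditionSweepResult | Iterable"
) -> dict[str, str]:
    """Classify each subsystem as always / sometimes / never in trade-off.

    A subsystem is *always in trade-off* when at least one of its reactions
    participates in every identified trade-off of the sweep; *sometimes*
    when some reaction participates in at least one but not all; *never*
    otherwise.  Unlabelled reactions are grouped under "unannotated".
    """
    supports = _support_sets(sweep)
    n_total = len(supports)
    in_all: set[str] = set.intersection(*map(set, supports)) if supports else set()
    in_any: set[str] = set().union(*supports) if supports else set()
    out: dict[str, str] = {}
    for j, rid in enumerate(model.reaction_ids):
        sub = model.subsystems[j] or "unannotated"
        cur = out.get(sub, "never")
        if rid in in_all and n_total > 0:
            out[sub] = "always"
        elif rid in in_any and cur != "always":
            out[sub] = "sometimes"
        else:
            out.setdefault(sub, "never")
    return out


def _parse_gpr(rule: str) -> set[str]:
    if rule.count("(") != rule.count(")"):
        raise ValueError(f"unbalanced parentheses in GPR rule {rule!r}")
    tokens = rule.replace("(", " ").replace(")", " ").split()
    return {t for t in tokens if t.lower() not in ("and", "or")}


def classify_proteins(
    model: MetabolicModel, tradeoff_reactions: Iterable[str]
) -> dict[str, str]:
    """Classify each protein (gene symbol in GPR rules) by trade-off involvement.

    ``all_in``: every reaction catalysed by the protein is in a trade-off;
    ``none_in``: none is; ``mixed``: some are.  Reactions with malformed GPR
    rules are skipped with a warning.
    """
    tset = set(tradeoff_reactions)
    catalyses: dict[str, list[str]] = {}
    for j, rid in enumerate(model.reaction_ids):
        rule = model.gpr[j]
        if not rule:
            continue
        try:
            genes = _parse_gpr(rule)
        except ValueError as exc:
            warnings.warn(f"skipping reaction {rid!r}: {exc}")
            continue
        for g in genes:
            catalyses.setdefault(g, []).append(rid)
    out = {}
    for gene, rxns in catalyses.items():
        hits = sum(r in tset for r in rxns)
        if hits == 0:
            out[gene] = "none_in"
        elif hits == len(rxns):
            out[gene] = "all_in"
        else:
            out[gene] = "mixed"
    return out


# -- Fisher 2x3 exact test ----------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x3:
    """Three rows (all / none / some reactions in trade-off) by two columns
    (protein catalyses one reaction / several reactions); cells a..f as
    (a,b), (c,d), (e,f)."""

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.cells):
            raise ValueError("contingency counts must be non-negative")

    @property
    def cells(self) -> tuple[int, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    @property
    def n(self) -> int:
        return sum(self.cells)


def _log_table_probability(a: int, c: int, e: int, row_sums, col1: int, n: int) -> float:
    # printed hypergeometric term: C(a+b,a) C(c+d,c) C(e+f,e) / C(n, a+c+e)
    r1, r2, r3 = row_sums

    def lchoose(nn: int, kk: int) -> float:
        return (
            math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)
        )

    return (
        lchoose(r1, a) + lchoose(r2, c) + lchoose(r3, e) - lchoose(n, col1)
    )


def fisher_exact_2x3(table: ContingencyTable2x3, tie_tol: float = 1e-9) -> float:
    """Exact 2x3 test (Freeman-Halton extension of Fisher's exact test).

    Enumerates every table with the observed margins and sums, in log
    space, the probabilities of all tables whose probability does not
    exceed the observed one.
    """
    if table.n == 0:
        raise ValueError("cannot test an all-zero contingency table")
    r1, r2, r3 = table.a + table.b, table.c + table.d, table.e + table.f
    col1 = table.a + table.c + table.e
    n = table.n
    log_obs = _log_table_probability(table.a, table.c, table.e, (r1, r2, r3), col1, n)
    total = 0.0
    for a in range(0, min(r1, col1) + 1):
        for c in range(0, min(r2, col1 - a) + 1):
            e = col1 - a - c
            if e < 0 or e > r3:
                continue
            lp = _log_table_probability(a, c, e, (r1, r2, r3), col1, n)
            if lp <= log_obs + tie_tol:
                total += math.exp(lp)
    return min(total, 1.0)


def protein_promiscuity_table(
    model: MetabolicModel, tradeoff_reactions: Iterable[str]
) -> ContingencyTable2x3:
    """Build the 2x3 table: protein promiscuity versus trade-off involvement.

    Columns split proteins catalysing exactly one reaction from those
    catalysing several; rows are the all / none / some trade-off classes.
    """
    tset = set(tradeoff_reactions)
    catalyses: dict[str, list[str]] = {}
    for j, rid in enumerate(model.reaction_ids):
        if not model.gpr[j]:
            continue
        try:
            genes = _parse_gpr(model.gpr[j])
        except ValueError:
            continue
        for g in genes:
            catalyses.setdefault(g, []).append(rid)
    counts = {("all", 1): 0, ("all", 2): 0, ("none", 1): 0, ("none", 2): 0,
              ("some", 1): 0, ("some", 2): 0}
    for gene, rxns in catalyses.items():
        promiscuity = 1 if len(rxns) == 1 else 2
        hits = sum(r in tset for r in rxns)
        row = "all" if hits == len(rxns) else ("none" if hits == 0 else "some")
        counts[(row, promiscuity)] += 1
    return ContingencyTable2x3(
        a=counts[("all", 1)], b=counts[("all", 2)],
        c=counts[("none", 1)], d=counts[("none", 2)],
        e=counts[("some", 1)], f=counts[("some", 2)],
    )


# -- comparison with flux coupling --------------------------------------------


@dataclass(frozen=True)
class CouplingComparison:
    condition: str
    coupled: frozenset[str]  # partially or directionally coupled to target
    tradeoff: frozenset[str]  # reactions in any trade-off support
    frac_coupled_in_tradeoff: float  # |coupled & tradeoff| / |coupled|
    frac_tradeoff_coupled: float  # |coupled & tradeoff| / |tradeoff|
    uncoupled_tradeoff_reactions: frozenset[str]  # diagnostic; empty in theory


def compare_with_coupling(sweep: ConditionSweepResult) -> list[CouplingComparison]:
    """Per condition, overlap between trade-off supports and coupled reactions.

    Every reaction in a relative trade-off w.r.t. the target is partially
    or directionally coupled to it, so ``uncoupled_tradeoff_reactions``
    should be empty up to tolerance; the converse containment does not hold,
    which is what the two fractions quantify.
    """
    out = []
    for c in sweep.conditions:
        if c.run is None:
            continue
        run = c.run
        merged = run.reduced.model
        sets = coupled_to_reaction(merged, merged.target_reaction)
        coupled: set[str] = set()
        for rep in sets.union:
            coupled.update(
                original_reaction_id(rid) for rid, _ in run.reduced.mapping[rep]
            )
        tset = set(c.tradeoff_reactions)
        inter = coupled & tset
        out.append(
            CouplingComparison(
                condition=c.condition.name,
                coupled=frozenset(coupled),
                tradeoff=frozenset(tset),
                frac_coupled_in_tradeoff=len(inter) / len(coupled) if coupled else 0.0,
                frac_tradeoff_coupled=len(inter) / len(tset) if tset else 0.0,
                uncoupled_tradeoff_reactions=frozenset(tset - coupled),
            )
        )
    return out


# -- overexpression targets ---------------------------------------------------


def identify_overexpression_targets(
    model: MetabolicModel,
    sweep: ConditionSweepResult,
    higher_fraction: float = 0.99,
) -> frozenset[str]:
    """Support reactions that remain FVA-variable at a raised growth bound.

    When the target flux sits below its optimum, increasing any support flux
    with a positive coefficient can raise it; the candidates that are still
    variable close to the optimum (default 99%) are the actionable
    overexpression targets.
    """
    candidates = sweep.tradeoff_reactions
    if not candidates:
        return frozenset()
    out: set[str] = set()
    for c in sweep.conditions:
        if c.run is None:
            continue
        conditioned = c.condition.apply(model)
        bounded = apply_growth_bound(conditioned, higher_fraction)
        cls = fva(bounded)
        for rid in c.tradeoff_reactions:
            if rid in cls.reaction_ids and cls.status_of(rid) == "variable":
                out.add(rid)
    return frozenset(out)


# -- report exports -----------------------------------------------------------


def sweep_report(model: MetabolicModel, sweep: ConditionSweepResult) -> pd.DataFrame:
    """Per condition and reaction: trade-off membership and subsystem class."""
    sub_class = classify_subsystems(model, sweep)
    rows = []
    for c in sweep.conditions:
        if c.run is None:
            continue
        supports = [
            frozenset(original_reaction_id(r) for r in t.support)
            for t in c.run.enumeration.expanded
        ]
        for j, rid in enumerate(model.reaction_ids):
            n_t = sum(rid in s for s in supports)
            sub = model.subsystems[j] or "unannotated"
            rows.append(
                {
                    "condition": c.condition.name,
                    "reaction_id": rid,
                    "in_tradeoff": n_t > 0,
                    "n_tradeoffs": n_t,
                    "subsystem": sub,
                    "subsystem_class": sub_class[sub],
                }
            )
    return pd.DataFrame(rows)


def protein_report(model: MetabolicModel, sweep: ConditionSweepResult) -> pd.DataFrame:
    classes = classify_proteins(model, sweep.tradeoff_reactions)
    counts: dict[str, int] = {}
    for j, rid in enumerate(model.reaction_ids):
        if not model.gpr[j]:
            continue
        try:
            for g in _parse_gpr(model.gpr[j]):
                counts[g] = counts.get(g, 0) + 1
        except ValueError:
            continue
    return pd.DataFrame(
        [
            {"protein": g, "class": cls, "n_reactions": counts.get(g, 0)}
            for g, cls in sorted(classes.items())
        ]
    )


def comparison_report(sweep: ConditionSweepResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": cmp.condition,
                "n_coupled": len(cmp.coupled),
                "n_tradeoff": len(cmp.tradeoff),
                "frac_coupled_in_tradeoff": cmp.frac_coupled_in_tradeoff,
                "frac_tradeoff_coupled": cmp.frac_tradeoff_coupled,
                "n_uncoupled_tradeoff": len(cmp.uncoupled_tradeoff_reactions),
            }
            for cmp in compare_with_coupling(sweep)
        ]
    )


def subsystem_edges(model: MetabolicModel, sweep: ConditionSweepResult) -> pd.DataFrame:
    """Edge list: pairs of subsystems sharing a pair of reactions in a trade-off."""
    weights: dict[tuple[str, str], int] = {}
    for t in sweep.all_tradeoffs:
        rids = sorted(original_reaction_id(r) for r in t.support)
        for r1, r2 in itertools.combinations(rids, 2):
            s1 = model.subsystems[model.reaction_index(r1)] or "unannotated"
            s2 = model.subsystems[model.reaction_index(r2)] or "unannotated"
            if s1 == s2:
                continue
            key = tuple(sorted((s1, s2)))
            weights[key] = weights.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"subsystem_i": k[0], "subsystem_j": k[1], "n_shared_tradeoff_pairs": w}
            for k, w in sorted(weights.items())
        ]
    )
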