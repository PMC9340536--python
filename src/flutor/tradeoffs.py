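"""Step 3: the relative-trade-off MILP, its enumeration, and verification.

A relative flux trade-off with respect to a target reaction r_j is a vector
alpha in the row space of the stoichiometric matrix (alpha = kN for some
metabolite weight vector k) with alpha_j = -1, alpha_i >= 0 elsewhere and at
least two irreversible variable reactions in its support; then
v_j = sum_i alpha_i v_i holds on every steady-state flux distribution.
Support minimization is NP-hard, so the MILP minimizes the L1 norm of kN
(linear here because all non-target coefficients are sign-constrained),
with binary indicators z_i and big-M linking to control the support.
Enumeration proceeds by integer cuts sum_{i in Z} z_i <= |Z| - 1 for every
found support Z, which excludes Z and its supersets: the enumerated supports
are exactly the inclusion-minimal ones, matching the brute-force oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .coupling import ReducedModel, merge_fully_coupled
from .model import MetabolicModel, SolverError
from .preprocess import (
    ReactionClassification,
    apply_growth_bound,
    compact_model,
    fba_optimum,
    fva,
)

__all__ = [
    "FlutorConfig",
    "TradeOff",
    "EnumerationResult",
    "find_relative_tradeoff",
    "enumerate_relative_tradeoffs",
    "expand_tradeoffs",
    "verify_tradeoff",
    "VerificationReport",
    "brute_force_tradeoffs",
    "run_flutor",
    "FlutorRun",
]


@dataclass(frozen=True)
class FlutorConfig:
    """Tunable parameters of the trade-off MILP.

    ``eps`` is the smallest admissible support coefficient after the target
    is normalized to -1; ``big_m`` bounds coefficients from above; both are
    chosen so that eps clears the solver's feasibility/integrality
    tolerances by orders of magnitude.  ``coeff_eps`` is the reporting
    threshold for support membership.
    """

    eps: float = 1e-4
    big_m: float = 1e4
    coeff_eps: float = 1e-6
    min_support: int = 2  # non-target members; with the target, supp(alpha) >= 3
    max_tradeoffs: int | None = None


@dataclass(frozen=True)
class TradeOff:
    """One relative trade-off: v_target = sum_i alpha_i v_i over all steady states."""

    target: str
    alpha: Mapping[str, float]  # nonzero coefficients; alpha[target] == -1
    support: frozenset[str]  # non-target reactions with alpha above threshold
    k: Mapping[str, float] | None = None  # metabolite weights with kN = alpha

    def coefficient(self, reaction_id: str) -> float:
        return float(self.alpha.get(reaction_id, 0.0))

    def key(self) -> tuple[str, frozenset[str]]:
        return (self.target, self.support)


@dataclass(frozen=True)
class EnumerationResult:
    tradeoffs: tuple[TradeOff, ...]  # in the merged space, discovery order
    milp_solves: int  # includes the terminating infeasible MILP when complete
    expanded: tuple[TradeOff, ...]  # original-reaction space, de-duplicated
    status: str  # "complete" | "hit_limit"


def _alpha_vector(model: MetabolicModel, tradeoff: TradeOff) -> np.ndarray:
    v = np.zeros(model.n_reactions)
    for rid, a in tradeoff.alpha.items():
        v[model.reaction_index(rid)] = a
    return v


def _require_merged_input(model: MetabolicModel) -> None:
    if np.any(model.lower_bounds != 0):
        raise ValueError(
            "the trade-off MILP expects a compacted, merged model "
            "(irreversible reactions with zero lower bounds)"
        )


def find_relative_tradeoff(
    model: MetabolicModel,
    target: str | None = None,
    excluded_supports: Sequence[Iterable[str]] = (),
    cfg: FlutorConfig | None = None,
    eligible: Iterable[str] | None = None,
    growth_lb: float | None = None,
) -> TradeOff | None:
    """Solve one trade-off MILP; return the L1-minimal trade-off or None.

    ``eligible`` restricts support membership (by default every non-target
    reaction; the pipeline passes the FVA-variable reactions, since a
    coefficient on a constant flux would make the relation affine rather
    than a trade-off).  ``excluded_supports`` receive integer cuts that
    forbid each set and its supersets.  ``growth_lb`` is the lower bound on
    the target's witness flux.
    """
    cfg = cfg or FlutorConfig()
    _require_merged_input(model)
    if target is None:
        target = model.target_reaction
    if target is None:
        raise ValueError("no target reaction given")
    j = model.reaction_index(target)
    n, m = model.n_reactions, model.n_metabolites
    if eligible is None:
        elig_idx = [i for i in range(n) if i != j]
    else:
        elig_idx = sorted(model.reaction_index(r) for r in eligible)
        if j in elig_idx:
            raise ValueError("the target reaction cannot be support-eligible")
    ne = len(elig_idx)
    if ne < cfg.min_support:
        return None
    pos_of = {i: p for p, i in enumerate(elig_idx)}

    # variable layout: [k (m) | alpha (n) | z (ne) | v (n)]
    off_a, off_z, off_v = m, m + n, m + n + ne
    n_var = m + 2 * n + ne

    lb = np.full(n_var, -np.inf)
    ub = np.full(n_var, np.inf)
    lb[off_a : off_a + n] = 0.0
    ub[off_a : off_a + n] = 0.0
    for i in elig_idx:
        ub[off_a + i] = cfg.big_m
    lb[off_a + j] = ub[off_a + j] = -1.0
    lb[off_z : off_z + ne] = 0.0
    ub[off_z : off_z + ne] = 1.0
    lb[off_v : off_v + n] = 0.0
    ub[off_v : off_v + n] = model.upper_bounds
    if growth_lb is not None:
        lb[off_v + j] = growth_lb

    integrality = np.zeros(n_var)
    integrality[off_z : off_z + ne] = 1

    rows, cols, vals, con_lb, con_ub = [], [], [], [], []
    r = 0

    def add_entry(row: int, col: int, val: float) -> None:
        rows.append(row)
        cols.append(col)
        vals.append(val)

    # alpha = kN  (alpha_i - N[:, i] . k = 0)
    for i in range(n):
        add_entry(r, off_a + i, 1.0)
        for imet in np.flatnonzero(model.S[:, i]):
            add_entry(r, int(imet), -float(model.S[imet, i]))
        con_lb.append(0.0)
        con_ub.append(0.0)
        r += 1
    # witness flux block: Nv = 0
    for imet in range(m):
        nz = np.flatnonzero(model.S[imet, :])
        if nz.size == 0:
            continue
        for i in nz:
            add_entry(r, off_v + int(i), float(model.S[imet, i]))
        con_lb.append(0.0)
        con_ub.append(0.0)
        r += 1
    # support linking: eps z_i <= alpha_i <= M z_i
    for i in elig_idx:
        add_entry(r, off_a + i, 1.0)
        add_entry(r, off_z + pos_of[i], -cfg.big_m)
        con_lb.append(-np.inf)
        con_ub.append(0.0)
        r += 1
        add_entry(r, off_a + i, 1.0)
        add_entry(r, off_z + pos_of[i], -cfg.eps)
        con_lb.append(0.0)
        con_ub.append(np.inf)
        r += 1
    # at least min_support non-target members
    for i in elig_idx:
        add_entry(r, off_z + pos_of[i], 1.0)
    con_lb.append(float(cfg.min_support))
    con_ub.append(np.inf)
    r += 1
    # integer cuts: forbid each excluded support and its supersets
    for excl in excluded_supports:
        members = [model.reaction_index(rid) for rid in excl]
        for i in members:
            if i not in pos_of:
                raise ValueError(
                    f"excluded support member {model.reaction_ids[i]!r} is not eligible"
                )
            add_entry(r, off_z + pos_of[i], 1.0)
        con_lb.append(-np.inf)
        con_ub.append(float(len(members) - 1))
        r += 1

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    c = np.zeros(n_var)
    for i in elig_idx:
        c[off_a + i] = 1.0  # L1 of kN: non-target coefficients are >= 0

    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.array(con_lb), np.array(con_ub)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status == 2:  # proven infeasible: no further trade-off exists
        return None
    if res.status != 0:
        raise SolverError(f"trade-off MILP failed (status {res.status}): {res.message}")
    z = res.x[off_z : off_z + ne]
    support_idx = [i for i in elig_idx if z[pos_of[i]] > 0.5]
    # polish: re-solve the LP restricted to the found support for clean
    # coefficients that do not depend on MILP vagaries
    alpha, k = _support_lp(model, j, support_idx, cfg)
    if alpha is None:  # numerically marginal MILP answer; fall back to raw values
        alpha = res.x[off_a : off_a + n]
        k = res.x[:m]
    support = frozenset(
        model.reaction_ids[i] for i in support_idx if alpha[i] > cfg.coeff_eps
    )
    alpha_map = {
        model.reaction_ids[i]: float(alpha[i])
        for i in range(n)
        if abs(alpha[i]) > cfg.coeff_eps
    }
    alpha_map[target] = -1.0
    return TradeOff(
        target=target,
        alpha=alpha_map,
        support=support,
        k={model.metabolite_ids[t]: float(k[t]) for t in range(m)},
    )


def _support_lp(
    model: MetabolicModel, j: int, support_idx: Sequence[int], cfg: FlutorConfig
):
    """Min-L1 coefficients for a fixed support (LP in k only); None if infeasible."""
    m, n = model.n_metabolites, model.n_reactions
    sup = set(support_idx)
    A_ub_rows, b_ub = [], []
    A_eq_rows, b_eq = [], []
    A_eq_rows.append(model.S[:, j])
    b_eq.append(-1.0)
    for i in range(n):
        if i == j or i in sup:
            continue
        A_eq_rows.append(model.S[:, i])
        b_eq.append(0.0)
    for i in support_idx:
        A_ub_rows.append(-model.S[:, i])  # alpha_i >= eps
        b_ub.append(-cfg.eps)
        A_ub_rows.append(model.S[:, i])  # alpha_i <= big_m
        b_ub.append(cfg.big_m)
    c = np.zeros(m)
    for i in support_idx:
        c = c + model.S[:, i]
    res = linprog(
        c,
        A_ub=np.array(A_ub_rows),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq_rows),
        b_eq=np.array(b_eq),
        bounds=[(None, None)] * m,
        method="highs",
    )
    if not res.success:
        return None, None
    k = res.x
    alpha = k @ model.S
    return alpha, k


def enumerate_relative_tradeoffs(
    model: MetabolicModel | ReducedModel,
    target: str | None = None,
    cfg: FlutorConfig | None = None,
    eligible: Iterable[str] | None = None,
    growth_lb: float | None = None,
) -> EnumerationResult:
    """Enumerate all minimal-support relative trade-offs via integer cuts.

    Accepts either a plain compacted model (identity expansion) or a
    :class:`~flutor.coupling.ReducedModel`, in which case the merged
    trade-offs are expanded back to original-reaction space.
    """
    cfg = cfg or FlutorConfig()
    if isinstance(model, ReducedModel):
        reduced = model
        merged = reduced.model
    else:
        merged = model
        reduced = None
    found: list[TradeOff] = []
    cuts: list[frozenset[str]] = []
    solves = 0
    status = "complete"
    while True:
        if cfg.max_tradeoffs is not None and len(found) >= cfg.max_tradeoffs:
            status = "hit_limit"
            break
        t = find_relative_tradeoff(
            merged,
            target=target,
            excluded_supports=cuts,
            cfg=cfg,
            eligible=eligible,
            growth_lb=growth_lb,
        )
        solves += 1
        if t is None:
            break
        found.append(t)
        cuts.append(t.support)
    mapping = reduced.mapping if reduced is not None else None
    expanded = expand_tradeoffs(found, mapping, model=None)
    return EnumerationResult(
        tradeoffs=tuple(found),
        milp_solves=solves,
        expanded=tuple(expanded),
        status=status,
    )


def expand_tradeoffs(
    tradeoffs: Iterable[TradeOff] | EnumerationResult,
    mapping: Mapping[str, tuple[tuple[str, float], ...]] | None,
    model: MetabolicModel | None = None,
) -> list[TradeOff]:
    """Expand merged trade-offs to original-reaction space.

    Each merged support member is replaced, one at a time, by every member
    of its full-coupling class, with the coefficient rescaled by the class
    ratio (if v_member = c * v_merged then alpha_member = alpha_merged / c).
    The target keeps its class representative: the relations for the other
    class members are implied by the full coupling itself.  Output is
    de-duplicated by (target, support).  When ``model`` (the pre-merge,
    compacted model) is given, a metabolite weight vector k is recomputed
    for every expanded trade-off by least squares.
    """
    if isinstance(tradeoffs, EnumerationResult):
        tradeoffs = tradeoffs.tradeoffs
    out: list[TradeOff] = []
    seen: set[tuple[str, frozenset[str]]] = set()

    def emit(target: str, alpha: dict[str, float]) -> None:
        support = frozenset(r for r, a in alpha.items() if r != target and a > 0)
        key = (target, support)
        if key in seen:
            return
        seen.add(key)
        k = None
        if model is not None:
            vec = np.zeros(model.n_reactions)
            for rid, a in alpha.items():
                vec[model.reaction_index(rid)] = a
            sol, *_ = np.linalg.lstsq(model.S.T, vec, rcond=None)
            k = {mid: float(sol[t]) for t, mid in enumerate(model.metabolite_ids)}
        out.append(TradeOff(target=target, alpha=alpha, support=support, k=k))

    for t in tradeoffs:
        if mapping is None:
            emit(t.target, dict(t.alpha))
            continue
        base = dict(t.alpha)
        emit(t.target, base)
        for member in t.support:
            cls = mapping.get(member, ((member, 1.0),))
            for rid, scale in cls:
                if rid == member:
                    continue
                alt = dict(base)
                coef = alt.pop(member)
                alt[rid] = coef / scale
                emit(t.target, alt)
    return out


@dataclass(frozen=True)
class VerificationReport:
    ok: bool
    failures: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.ok


def verify_tradeoff(
    model: MetabolicModel,
    tradeoff: TradeOff,
    eligible: Iterable[str] | None = None,
    rowspace_tol: float = 1e-8,
    cfg: FlutorConfig | None = None,
) -> VerificationReport:
    """Check row-space membership, sign pattern and support of a trade-off.

    Row-space membership is established independently of any stored k by a
    least-squares solve of kN = alpha; its residual must stay below
    ``rowspace_tol``, which also certifies alpha . v = 0 on the null space.
    """
    cfg = cfg or FlutorConfig()
    failures = []
    try:
        alpha = _alpha_vector(model, tradeoff)
        j = model.reaction_index(tradeoff.target)
    except KeyError as exc:
        return VerificationReport(False, (str(exc),))
    if alpha[j] != -1.0:
        failures.append(f"target coefficient is {alpha[j]}, expected exactly -1")
    others = np.delete(alpha, j)
    if np.any(others < -cfg.coeff_eps):
        failures.append("negative coefficient on a non-target reaction")
    support = {
        model.reaction_ids[i]
        for i in range(model.n_reactions)
        if i != j and alpha[i] > cfg.coeff_eps
    }
    if support != set(tradeoff.support):
        failures.append("declared support does not match the coefficients")
    if len(support) < cfg.min_support:
        failures.append(
            f"support has {len(support)} members, needs >= {cfg.min_support}"
        )
    if np.any(model.lower_bounds[[model.reaction_index(r) for r in support]] < 0):
        failures.append("support contains a reversible reaction")
    if eligible is not None:
        extra = support - set(eligible)
        if extra:
            failures.append(f"support members not eligible (fixed/blocked): {sorted(extra)}")
    k, *_ = np.linalg.lstsq(model.S.T, alpha, rcond=None)
    residual = float(np.linalg.norm(model.S.T @ k - alpha))
    if residual > rowspace_tol:
        failures.append(
            f"alpha is not in the row space of N (residual {residual:.2e})"
        )
    return VerificationReport(not failures, tuple(failures))


def brute_force_tradeoffs(
    model: MetabolicModel,
    target: str | None = None,
    max_support: int | None = None,
    cfg: FlutorConfig | None = None,
    eligible: Iterable[str] | None = None,
    combination_guard: int = 200_000,
) -> list[TradeOff]:
    """Oracle: exhaustively enumerate minimal feasible supports (no MILP).

    For every candidate support up to ``max_support``, solve a feasibility
    LP in k with the trade-off sign/normalization constraints; supports with
    a feasible proper subset are skipped, so the result is exactly the set
    of inclusion-minimal supports.  Independent of the MILP code path.
    """
    cfg = cfg or FlutorConfig()
    _require_merged_input(model)
    if target is None:
        target = model.target_reaction
    j = model.reaction_index(target)
    if eligible is None:
        elig = [i for i in range(model.n_reactions) if i != j]
    else:
        elig = sorted(model.reaction_index(r) for r in eligible)
    if max_support is None:
        max_support = len(elig)
    max_support = min(max_support, len(elig))
    total = sum(math.comb(len(elig), s) for s in range(cfg.min_support, max_support + 1))
    if total > combination_guard:
        raise ValueError(
            f"{total} candidate supports exceed the combinatorial guard "
            f"({combination_guard}); reduce max_support"
        )
    found: list[TradeOff] = []
    found_sets: list[set[int]] = []
    for size in range(cfg.min_support, max_support + 1):
        for combo in itertools.combinations(elig, size):
            sset = set(combo)
            if any(f <= sset for f in found_sets):
                continue
            alpha, k = _feasible_support(model, j, combo, elig, cfg)
            if alpha is None:
                continue
            found_sets.append(sset)
            alpha_map = {
                model.reaction_ids[i]: float(alpha[i])
                for i in range(model.n_reactions)
                if abs(alpha[i]) > cfg.coeff_eps
            }
            alpha_map[target] = -1.0
            found.append(
                TradeOff(
                    target=target,
                    alpha=alpha_map,
                    support=frozenset(model.reaction_ids[i] for i in combo),
                    k={
                        mid: float(k[t])
                        for t, mid in enumerate(model.metabolite_ids)
                    },
                )
            )
    return found


def _feasible_support(model, j, combo, elig, cfg):
    """Feasibility LP for one candidate support (brute-force path)."""
    m = model.n_metabolites
    A_eq = [model.S[:, j]]
    b_eq = [-1.0]
    for i in range(model.n_reactions):
        if i == j or i in combo:
            continue
        A_eq.append(model.S[:, i])
        b_eq.append(0.0)
    A_ub, b_ub = [], []
    for i in combo:
        A_ub.append(-model.S[:, i])
        b_ub.append(-cfg.eps)
        A_ub.append(model.S[:, i])
        b_ub.append(cfg.big_m)
    c = np.sum([model.S[:, i] for i in combo], axis=0)
    res = linprog(
        c,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq),
        b_eq=np.array(b_eq),
        bounds=[(None, None)] * m,
        method="highs",
    )
    if not res.success:
        return None, None
    return res.x @ model.S, res.x


# -- end-to-end pipeline ------------------------------------------------------


@dataclass(frozen=True)
class FlutorRun:
    """Everything produced by one full run on one model/condition."""

    model: MetabolicModel  # as analysed (media applied)
    optimum: float  # FBA optimum of the target
    growth_lb: float  # fraction * optimum
    classification: ReactionClassification  # on the growth-bounded model
    compacted: MetabolicModel
    reduced: ReducedModel
    merged_classification: ReactionClassification  # growth bound reapplied
    eligible: frozenset[str]  # support-eligible merged reactions
    enumeration: EnumerationResult

    @property
    def tradeoff_reactions(self) -> frozenset[str]:
        """Original-space reactions appearing in any expanded trade-off support."""
        from .preprocess import original_reaction_id

        out: set[str] = set()
        for t in self.enumeration.expanded:
            out.update(original_reaction_id(r) for r in t.support)
        return frozenset(out)


def run_flutor(
    model: MetabolicModel,
    growth_fraction: float = 0.90,
    cfg: FlutorConfig | None = None,
    target: str | None = None,
) -> FlutorRun:
    """Full chain: FBA -> growth bound -> FVA -> compact -> merge -> enumerate.

    The growth bound (``growth_fraction`` times the FBA optimum of the
    target) shapes the FVA classification and the support eligibility; the
    coupling analysis itself runs on the compacted network with zero lower
    bounds, where the coupling definitions are stated.
    """
    cfg = cfg or FlutorConfig()
    if target is not None:
        model = model.with_target(target)
    if model.target_reaction is None:
        raise ValueError("model has no target reaction and none was given")
    optimum = fba_optimum(model)
    growth_lb = growth_fraction * optimum
    bounded = model.with_bounds(lower={model.target_reaction: growth_lb})
    classification = fva(bounded)
    compacted = compact_model(bounded, classification)
    if compacted.target_reaction is None:
        raise ValueError("target reaction was removed during compaction (blocked)")
    reduced = merge_fully_coupled(compacted)
    merged = reduced.model
    rep = merged.target_reaction
    scale_t = dict(reduced.mapping[rep])[compacted.target_reaction]
    merged_growth_lb = growth_lb / scale_t
    merged_bounded = merged.with_bounds(lower={rep: merged_growth_lb})
    merged_classification = fva(merged_bounded)
    eligible = frozenset(merged_classification.variable - {rep})
    enumeration = enumerate_relative_tradeoffs(
        ReducedModel(model=merged, mapping=reduced.mapping),
        target=rep,
        cfg=cfg,
        eligible=eligible,
        growth_lb=merged_growth_lb,
    )
    # expanded trade-offs recomputed with k against the compacted model
    expanded = expand_tradeoffs(enumeration.tradeoffs, reduced.mapping, model=compacted)
    enumeration = EnumerationResult(
        tradeoffs=enumeration.tradeoffs,
        milp_solves=enumeration.milp_solves,
        expanded=tuple(expanded),
        status=enumeration.status,
    )
    return FlutorRun(
        model=model,
        optimum=optimum,
        growth_lb=growth_lb,
        classification=classification,
        compacted=compacted,
        reduced=reduced,
        merged_classification=merged_classification,
        eligible=eligible,
        enumeration=enumeration,
    )
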