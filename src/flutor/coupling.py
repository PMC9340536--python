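"""Step 2: flux coupling analysis, full-coupling classes and merging.

Coupling is decided over the compacted (all-irreversible, zero lower bound)
model by a zero-forcing LP scheme: reaction i is directionally coupled to j
when max v_i subject to v_j = 0 vanishes; when both directions force, a full
coupling is recognized by ratio constancy of v_i at two normalizations of
v_j.  Fully coupled classes are collapsed to single representative columns,
with a ratio-preserving mapping back to the member reactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, SolverError

__all__ = [
    "CouplingRelation",
    "ReducedModel",
    "CoupledSets",
    "coupling_type",
    "full_coupling_sets",
    "merge_fully_coupled",
    "coupled_to_reaction",
    "ZERO_FORCE_TOL",
    "RATIO_TOL",
]

ZERO_FORCE_TOL = 1e-6  # "forced to zero", relative to the bound scale
RATIO_TOL = 1e-6


@dataclass(frozen=True)
class CouplingRelation:
    """Classified coupling between an ordered pair of reactions.

    ``kind`` is one of ``fully``, ``partially``, ``directional_i_to_j``,
    ``directional_j_to_i`` or ``uncoupled``; ``ratio`` (v_i / v_j) is present
    exactly when the pair is fully coupled.
    """

    ri: str
    rj: str
    kind: str
    ratio: float | None = None

    def __post_init__(self) -> None:
        if (self.kind == "fully") != (self.ratio is not None):
            raise ValueError("ratio must be present iff the pair is fully coupled")
        if self.ratio is not None and self.ratio == 0:
            raise ValueError("a full-coupling ratio cannot be zero")


@dataclass(frozen=True)
class ReducedModel:
    """Merged model plus mapping: merged id -> [(original id, scale)].

    ``scale`` relates the original flux to the merged flux:
    v_original = scale * v_merged.
    """

    model: MetabolicModel
    mapping: Mapping[str, tuple[tuple[str, float], ...]]

    def class_of(self, merged_id: str) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.mapping[merged_id])

    def expand_flux(self, merged_flux: Mapping[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for mid, w in merged_flux.items():
            for rid, scale in self.mapping[mid]:
                out[rid] = scale * w
        return out


def _require_compacted(model: MetabolicModel) -> None:
    if np.any(model.lower_bounds != 0):
        raise ValueError(
            "coupling analysis requires a compacted model "
            "(all reactions irreversible with zero lower bounds)"
        )


def _max_flux_given_zero(model: MetabolicModel, i: int, j: int) -> float:
    """max v_i over F with v_j fixed to 0."""
    c = np.zeros(model.n_reactions)
    c[i] = -1.0
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    bounds[j] = (0.0, 0.0)
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise SolverError(f"zero-forcing LP failed: {res.message}")
    return float(-res.fun)


def _flux_range_given(model: MetabolicModel, i: int, j: int, vj: float):
    """(min, max) of v_i over F with v_j fixed to vj."""
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    bounds[j] = (vj, vj)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(model.n_reactions)
        c[i] = sign
        res = linprog(
            c,
            A_eq=model.S,
            b_eq=np.zeros(model.n_metabolites),
            bounds=bounds,
            method="highs",
        )
        if not res.success:
            raise SolverError(f"ratio LP failed: {res.message}")
        out.append(sign * res.fun)
    return out[0], out[1]


def _fva_max(model: MetabolicModel, j: int) -> float:
    c = np.zeros(model.n_reactions)
    c[j] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lower_bounds, model.upper_bounds)),
        method="highs",
    )
    if not res.success:
        raise SolverError(f"FVA LP failed: {res.message}")
    return float(-res.fun)


def _zero_scale(model: MetabolicModel) -> float:
    finite = model.upper_bounds[np.isfinite(model.upper_bounds)]
    return float(finite.max()) if finite.size else 1.0


def coupling_type(
    model: MetabolicModel, ri: str, rj: str, tol: float = ZERO_FORCE_TOL
) -> CouplingRelation:
    """Classify the coupling between two unblocked reactions of a compacted model."""
    _require_compacted(model)
    i, j = model.reaction_index(ri), model.reaction_index(rj)
    scale = _zero_scale(model)
    vmax_i = _fva_max(model, i)
    vmax_j = _fva_max(model, j)
    if vmax_i <= tol * scale or vmax_j <= tol * scale:
        raise ValueError(
            f"blocked reaction in coupling query ({ri!r}, {rj!r}); compact the model first"
        )
    i_forces_j = _max_flux_given_zero(model, i, j) <= tol * scale  # vi!=0 => vj!=0
    j_forces_i = _max_flux_given_zero(model, j, i) <= tol * scale
    if i_forces_j and j_forces_i:
        # ratio constancy probed at two normalization points of v_j
        if not np.isfinite(vmax_j):
            points = [0.5, 1.0]
        else:
            points = sorted({vmax_j / 2.0, min(1.0, vmax_j)})
        ratios = []
        for p in points:
            lo, hi = _flux_range_given(model, i, j, p)
            ratios.extend((lo / p, hi / p))
        if max(ratios) - min(ratios) <= RATIO_TOL * max(1.0, abs(ratios[0])):
            return CouplingRelation(ri, rj, "fully", float(np.mean(ratios)))
        return CouplingRelation(ri, rj, "partially")
    if i_forces_j:
        return CouplingRelation(ri, rj, "directional_i_to_j")
    if j_forces_i:
        return CouplingRelation(ri, rj, "directional_j_to_i")
    return CouplingRelation(ri, rj, "uncoupled")


def _connected_components(model: MetabolicModel) -> list[set[int]]:
    """Reaction components of the bipartite reaction-metabolite graph (pruning only)."""
    parent = list(range(model.n_reactions))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(model.n_metabolites):
        touching = np.flatnonzero(model.S[i, :])
        for j in touching[1:]:
            union(int(touching[0]), int(j))
    comps: dict[int, set[int]] = {}
    for j in range(model.n_reactions):
        comps.setdefault(find(j), set()).add(j)
    return list(comps.values())


def full_coupling_sets(
    model: MetabolicModel, tol: float = ZERO_FORCE_TOL
) -> list[tuple[str, ...]]:
    """Partition of the reactions into full-coupling classes (model order).

    Pairwise LP tests are pruned by connected-component screening and by
    transitivity of full coupling (members of an established class are not
    re-tested).
    """
    _require_compacted(model)
    n = model.n_reactions
    cls = list(range(n))  # class label per reaction

    def label(a: int) -> int:
        while cls[a] != a:
            cls[a] = cls[cls[a]]
            a = cls[a]
        return a

    for comp in _connected_components(model):
        members = sorted(comp)
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1 :]:
                if label(a) == label(b):
                    continue
                rel = coupling_type(
                    model, model.reaction_ids[a], model.reaction_ids[b], tol=tol
                )
                if rel.kind == "fully":
                    cls[label(b)] = label(a)
    groups: dict[int, list[int]] = {}
    for j in range(n):
        groups.setdefault(label(j), []).append(j)
    ordered = sorted(groups.values(), key=lambda g: g[0])
    return [tuple(model.reaction_ids[j] for j in g) for g in ordered]


def _pair_ratio(model: MetabolicModel, ri: str, rj: str) -> float:
    rel = coupling_type(model, ri, rj)
    if rel.kind != "fully":
        raise ValueError(f"{ri!r} and {rj!r} are not fully coupled")
    return float(rel.ratio)


def merge_fully_coupled(
    model: MetabolicModel,
    sets: Iterable[tuple[str, ...]] | None = None,
    tol: float = ZERO_FORCE_TOL,
) -> ReducedModel:
    """Collapse each full-coupling class into its first member (the representative).

    The merged column is the ratio-weighted sum of the member columns, merged
    bounds are the scaled intersection of the member bounds, and the mapping
    records v_member = scale * v_representative for every member.  If the
    target reaction belongs to a merged class, the class representative
    becomes the new target.
    """
    _require_compacted(model)
    if sets is None:
        sets = full_coupling_sets(model, tol=tol)
    merged_ids: list[str] = []
    cols: list[np.ndarray] = []
    ubs: list[float] = []
    subsystems: list[str | None] = []
    gprs: list[str] = []
    mapping: dict[str, tuple[tuple[str, float], ...]] = {}
    target = model.target_reaction
    new_target = None
    for group in sets:
        rep = group[0]
        scales = [(rep, 1.0)]
        for member in group[1:]:
            scales.append((member, _pair_ratio(model, member, rep)))
        col = np.zeros(model.n_metabolites)
        ub = np.inf
        for rid, scale in scales:
            j = model.reaction_index(rid)
            col += scale * model.S[:, j]
            if scale > 0 and np.isfinite(model.upper_bounds[j]):
                ub = min(ub, model.upper_bounds[j] / scale)
        merged_ids.append(rep)
        cols.append(col)
        ubs.append(ub)
        j_rep = model.reaction_index(rep)
        subsystems.append(model.subsystems[j_rep])
        gprs.append(model.gpr[j_rep])
        mapping[rep] = tuple(scales)
        if target in {rid for rid, _ in scales}:
            new_target = rep
    S = np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0))
    merged = MetabolicModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=tuple(merged_ids),
        S=S,
        lower_bounds=np.zeros(len(merged_ids)),
        upper_bounds=np.array(ubs),
        subsystems=tuple(subsystems),
        gpr=tuple(gprs),
        target_reaction=new_target,
        name=(model.name + "_merged") if model.name else "merged",
    )
    return ReducedModel(model=merged, mapping=mapping)


@dataclass(frozen=True)
class CoupledSets:
    """Reactions coupled to a query reaction rj (disjoint sets)."""

    partially_coupled: frozenset[str]
    directionally_coupled: frozenset[str]  # one-way (ri -> rj) only

    @property
    def union(self) -> frozenset[str]:
        return self.partially_coupled | self.directionally_coupled


def coupled_to_reaction(
    model: MetabolicModel, rj: str, tol: float = ZERO_FORCE_TOL
) -> CoupledSets:
    """All reactions ri with v_i != 0 => v_j != 0, split by whether the converse holds."""
    _require_compacted(model)
    j = model.reaction_index(rj)
    scale = _zero_scale(model)
    partial: set[str] = set()
    directional: set[str] = set()
    for i, ri in enumerate(model.reaction_ids):
        if i == j:
            continue
        if _max_flux_given_zero(model, i, j) <= tol * scale:
            if _max_flux_given_zero(model, j, i) <= tol * scale:
                partial.add(ri)
            else:
                directional.add(ri)
    return CoupledSets(
        partially_coupled=frozenset(partial),
        directionally_coupled=frozenset(directional),
    )
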