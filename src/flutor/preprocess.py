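"""Step 1 of the pipeline: FBA optimum, growth bound, FVA, compaction.

The feasible set is F = {v : Nv = 0, lb <= v <= ub}; after a growth bound is
applied, the target reaction's lower bound is a fraction of its FBA optimum.
FVA classifies each reaction as blocked, fixed or variable over F, and
:func:`compact_model` removes blocked reactions and dead-end metabolites and
splits every effectively reversible reaction into a forward and a reverse
irreversible part, yielding a model with zero lower bounds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import (
    InfeasibleModelError,
    MetabolicModel,
    SolverError,
    UnboundedObjectiveError,
)

__all__ = [
    "ReactionClassification",
    "fba_optimum",
    "apply_growth_bound",
    "fva",
    "compact_model",
    "BLOCKED_TOL",
    "VARIABILITY_TOL",
]

# Paper gives no tolerances; these sit well above HiGHS solver noise.
BLOCKED_TOL = 1e-6
VARIABILITY_TOL = 1e-6


def _solve_lp(model: MetabolicModel, c: np.ndarray) -> "linprog.OptimizeResult":
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lower_bounds, model.upper_bounds)),
        method="highs",
    )
    return res


def fba_optimum(model: MetabolicModel, objective: str | None = None) -> float:
    """Maximum of the objective flux over F (flux balance analysis).

    Raises :class:`InfeasibleModelError` when F is empty and
    :class:`UnboundedObjectiveError` when the objective is unbounded above.
    """
    if objective is None:
        objective = model.target_reaction
    if objective is None:
        raise ValueError("no objective reaction given and no target set")
    j = model.reaction_index(objective)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0
    res = _solve_lp(model, c)
    if res.status == 2:
        raise InfeasibleModelError("steady-state LP is infeasible under the bounds")
    if res.status == 3:
        raise UnboundedObjectiveError(f"objective flux {objective!r} is unbounded")
    if not res.success:
        raise SolverError(f"LP solver failure: {res.message}")
    return float(-res.fun)


def apply_growth_bound(model: MetabolicModel, fraction: float) -> MetabolicModel:
    """Copy of the model with lb(target) = fraction * FBA optimum of the target."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"growth fraction must be in (0, 1], got {fraction}")
    if model.target_reaction is None:
        raise ValueError("model has no target reaction")
    opt = fba_optimum(model, model.target_reaction)
    return model.with_bounds(lower={model.target_reaction: fraction * opt})


@dataclass(frozen=True)
class ReactionClassification:
    """Per-reaction FVA ranges and statuses over the constrained space F."""

    reaction_ids: tuple[str, ...]
    fva_min: np.ndarray
    fva_max: np.ndarray
    status: tuple[str, ...]  # blocked | fixed | variable
    effectively_reversible: np.ndarray  # bool per reaction

    def status_of(self, reaction_id: str) -> str:
        return self.status[self.reaction_ids.index(reaction_id)]

    def range_of(self, reaction_id: str) -> tuple[float, float]:
        j = self.reaction_ids.index(reaction_id)
        return float(self.fva_min[j]), float(self.fva_max[j])

    @property
    def blocked(self) -> frozenset[str]:
        return frozenset(
            r for r, s in zip(self.reaction_ids, self.status) if s == "blocked"
        )

    @property
    def fixed(self) -> frozenset[str]:
        return frozenset(
            r for r, s in zip(self.reaction_ids, self.status) if s == "fixed"
        )

    @property
    def variable(self) -> frozenset[str]:
        return frozenset(
            r for r, s in zip(self.reaction_ids, self.status) if s == "variable"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "fva_min": self.fva_min,
                "fva_max": self.fva_max,
                "status": self.status,
                "effectively_reversible": self.effectively_reversible,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fva(
    model: MetabolicModel,
    tol: float = BLOCKED_TOL,
    variability_tol: float = VARIABILITY_TOL,
) -> ReactionClassification:
    """Flux variability analysis: min and max of every flux over F (2n LPs)."""
    n = model.n_reactions
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve_lp(model, c)
        if lo.status == 2:
            raise InfeasibleModelError("FVA: model infeasible under current bounds")
        if not lo.success:
            raise SolverError(f"FVA LP failure on {model.reaction_ids[j]}: {lo.message}")
        c[j] = -1.0
        hi = _solve_lp(model, c)
        if not hi.success:
            raise SolverError(f"FVA LP failure on {model.reaction_ids[j]}: {hi.message}")
        vmin[j], vmax[j] = lo.fun, -hi.fun
    # clamp solver noise so that vmin <= vmax exactly
    vmin, vmax = np.minimum(vmin, vmax), np.maximum(vmin, vmax)
    status = []
    for j in range(n):
        if abs(vmin[j]) <= tol and abs(vmax[j]) <= tol:
            status.append("blocked")
        elif vmax[j] - vmin[j] <= variability_tol:
            status.append("fixed")
        else:
            status.append("variable")
    eff_rev = (vmin < -tol) & (vmax > tol)
    return ReactionClassification(
        reaction_ids=model.reaction_ids,
        fva_min=vmin,
        fva_max=vmax,
        status=tuple(status),
        effectively_reversible=eff_rev,
    )


def compact_model(
    model: MetabolicModel,
    classification: ReactionClassification,
    tol: float = BLOCKED_TOL,
) -> MetabolicModel:
    """Remove blocked reactions and dead-end metabolites; split reversibles.

    Every effectively reversible reaction ``r`` is replaced by ``r_fwd``
    (original column, bounds [0, ub]) and ``r_rev`` (negated column, bounds
    [0, -lb]); a reaction observed to run only backwards is flipped in place
    (suffix ``_rev``).  Dead-end removal iterates to a fixed point, since
    deleting a reaction can orphan further metabolites.  The result has zero
    lower bounds on all reactions; any growth bound on the target is carried
    by the caller and reapplied where needed.
    """
    if classification.reaction_ids != model.reaction_ids:
        raise ValueError("classification does not match this model's reactions")
    keep = [
        j
        for j, rid in enumerate(model.reaction_ids)
        if classification.status[j] != "blocked"
    ]
    # iterated dead-end pruning on the surviving submatrix; direction of a
    # surviving reaction follows the sign of its observed flux range
    keep_set = set(keep)
    changed = True
    while changed:
        changed = False
        live_mets = []
        for i in range(model.n_metabolites):
            produced = consumed = False
            for j in keep_set:
                coef = model.S[i, j]
                if coef == 0:
                    continue
                fwd_ok = classification.fva_max[j] > tol
                rev_ok = classification.fva_min[j] < -tol
                if (coef > 0 and fwd_ok) or (coef < 0 and rev_ok):
                    produced = True
                if (coef < 0 and fwd_ok) or (coef > 0 and rev_ok):
                    consumed = True
            live_mets.append(produced and consumed)
        for j in list(keep_set):
            col = model.S[:, j]
            for i in np.flatnonzero(col):
                if not live_mets[i]:
                    keep_set.discard(j)
                    changed = True
                    break
    keep = [j for j in keep if j in keep_set]
    met_keep = [
        i for i in range(model.n_metabolites) if np.any(model.S[i, keep] != 0)
    ]

    new_ids: list[str] = []
    new_cols: list[np.ndarray] = []
    new_ub: list[float] = []
    new_sub: list[str | None] = []
    new_gpr: list[str] = []
    for j in keep:
        rid = model.reaction_ids[j]
        col = model.S[met_keep, j]
        fmax = classification.fva_max[j]
        fmin = classification.fva_min[j]
        if classification.effectively_reversible[j]:
            new_ids.append(f"{rid}_fwd")
            new_cols.append(col.copy())
            new_ub.append(float(model.upper_bounds[j]))
            new_sub.append(model.subsystems[j])
            new_gpr.append(model.gpr[j])
            new_ids.append(f"{rid}_rev")
            new_cols.append(-col)
            new_ub.append(float(-model.lower_bounds[j]))
            new_sub.append(model.subsystems[j])
            new_gpr.append(model.gpr[j])
        elif fmax <= tol and fmin < -tol:
            new_ids.append(f"{rid}_rev")
            new_cols.append(-col)
            new_ub.append(float(-model.lower_bounds[j]))
            new_sub.append(model.subsystems[j])
            new_gpr.append(model.gpr[j])
        else:
            new_ids.append(rid)
            new_cols.append(col.copy())
            new_ub.append(float(model.upper_bounds[j]))
            new_sub.append(model.subsystems[j])
            new_gpr.append(model.gpr[j])

    target = model.target_reaction
    if target is not None and target not in new_ids:
        if f"{target}_fwd" in new_ids:
            target = f"{target}_fwd"
        else:
            target = None
    S = np.column_stack(new_cols) if new_cols else np.zeros((len(met_keep), 0))
    return MetabolicModel(
        metabolite_ids=tuple(model.metabolite_ids[i] for i in met_keep),
        reaction_ids=tuple(new_ids),
        S=S,
        lower_bounds=np.zeros(len(new_ids)),
        upper_bounds=np.array(new_ub),
        subsystems=tuple(new_sub),
        gpr=tuple(new_gpr),
        target_reaction=target,
        name=model.name + "_compacted" if model.name else "compacted",
    )


def original_reaction_id(compacted_id: str) -> str:
    """Map a compacted reaction id back to its source id (_fwd/_rev stripped)."""
    for suffix in ("_fwd", "_rev"):
        if compacted_id.endswith(suffix):
            return compacted_id[: -len(suffix)]
    return compacted_id
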