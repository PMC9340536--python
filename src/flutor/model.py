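"""Core metabolic-model container and readers/writers.

A :class:`MetabolicModel` is a thin, explicit wrapper around the stoichiometric
matrix ``N`` (m metabolites x n reactions) together with per-reaction flux
bounds (mmol/gDW/h), optional subsystem annotations and gene-protein-reaction
(GPR) rules, and the identifier of the target reaction (typically biomass)
with respect to which relative flux trade-offs are sought.

Two on-disk formats are supported: the widely used cobra JSON schema (so
public models load unmodified) and SBML Level 3 with the FBC package, read
and written through cobrapy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "InfeasibleModelError",
    "UnboundedObjectiveError",
    "SolverError",
    "MetabolicModel",
    "MediaCondition",
    "validate_model",
    "load_model",
    "save_model_json",
    "to_cobra",
    "from_cobra",
    "write_sbml",
]


class FormatError(ValueError):
    """A model file does not conform to the named standard."""


class InfeasibleModelError(RuntimeError):
    """The steady-state LP has no feasible solution under the current bounds."""


class UnboundedObjectiveError(RuntimeError):
    """The requested objective flux is unbounded above."""


class SolverError(RuntimeError):
    """The LP/MILP solver failed for a reason other than proven infeasibility."""


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric model with bounds and annotations.

    ``reversible`` is not stored: a reaction is reversible iff its lower
    bound is negative, which keeps the flag and the bounds consistent by
    construction.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray  # m x n, stoichiometric coefficients
    lower_bounds: np.ndarray  # per reaction, mmol/gDW/h
    upper_bounds: np.ndarray
    subsystems: tuple[str | None, ...] = ()
    gpr: tuple[str, ...] = ()
    target_reaction: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "lower_bounds", np.asarray(self.lower_bounds, dtype=float))
        object.__setattr__(self, "upper_bounds", np.asarray(self.upper_bounds, dtype=float))
        if not self.subsystems:
            object.__setattr__(self, "subsystems", (None,) * len(self.reaction_ids))
        else:
            object.__setattr__(self, "subsystems", tuple(self.subsystems))
        if not self.gpr:
            object.__setattr__(self, "gpr", ("",) * len(self.reaction_ids))
        else:
            object.__setattr__(self, "gpr", tuple(self.gpr))

    # -- basic introspection -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Boolean flag per reaction; true iff the lower bound is negative."""
        return self.lower_bounds < 0

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id: {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id: {metabolite_id!r}") from None

    def subsystem_of(self, reaction_id: str) -> str | None:
        return self.subsystems[self.reaction_index(reaction_id)]

    def gpr_of(self, reaction_id: str) -> str:
        return self.gpr[self.reaction_index(reaction_id)]

    def exchange_reactions(self) -> list[str]:
        """Reactions whose stoichiometric column is single-sided.

        Exchanges follow the arrow-to-nothing convention: no external
        metabolite row, so an export column has only negative entries and an
        import column only positive ones.
        """
        out = []
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            nz = col[col != 0]
            if nz.size and (np.all(nz < 0) or np.all(nz > 0)):
                out.append(rid)
        return out

    def with_bounds(
        self,
        lower: Mapping[str, float] | None = None,
        upper: Mapping[str, float] | None = None,
    ) -> "MetabolicModel":
        """Return a copy with the given per-reaction bounds replaced."""
        lb = self.lower_bounds.copy()
        ub = self.upper_bounds.copy()
        for rid, val in (lower or {}).items():
            lb[self.reaction_index(rid)] = val
        for rid, val in (upper or {}).items():
            ub[self.reaction_index(rid)] = val
        return replace(self, lower_bounds=lb, upper_bounds=ub)

    def with_target(self, reaction_id: str) -> "MetabolicModel":
        self.reaction_index(reaction_id)  # validate
        return replace(self, target_reaction=reaction_id)


@dataclass(frozen=True)
class MediaCondition:
    """A named environment: exchange-reaction bounds plus a growth fraction.

    ``growth_fraction`` is the lower bound on the target flux expressed as a
    fraction of its FBA optimum (the study conditions use 0.90, 0.95, 0.99,
    but any value in (0, 1] is accepted).
    """

    name: str
    exchange_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    growth_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.growth_fraction <= 1.0):
            raise ValueError(
                f"growth_fraction must be in (0, 1], got {self.growth_fraction}"
            )

    def validate_against(self, model: MetabolicModel) -> None:
        for rid in self.exchange_bounds:
            model.reaction_index(rid)

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        self.validate_against(model)
        lower = {rid: lb for rid, (lb, _) in self.exchange_bounds.items()}
        upper = {rid: ub for rid, (_, ub) in self.exchange_bounds.items()}
        return model.with_bounds(lower=lower, upper=upper)


# -- validation ---------------------------------------------------------------


def validate_model(model: MetabolicModel) -> list[str]:
    """Return human-readable findings for violated invariants (empty if valid)."""
    findings: list[str] = []
    m, n = model.S.shape if model.S.ndim == 2 else (0, 0)
    if model.S.ndim != 2 or m != model.n_metabolites or n != model.n_reactions:
        findings.append(
            f"dimension mismatch: S is {model.S.shape}, expected "
            f"({model.n_metabolites}, {model.n_reactions})"
        )
        return findings  # index-based checks below would be unreliable
    seen: set[str] = set()
    for rid in model.reaction_ids:
        if rid in seen:
            findings.append(f"duplicate reaction id: {rid!r}")
        seen.add(rid)
    seen = set()
    for mid in model.metabolite_ids:
        if mid in seen:
            findings.append(f"duplicate metabolite id: {mid!r}")
        seen.add(mid)
    for j, rid in enumerate(model.reaction_ids):
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        if not (math.isfinite(lb) or lb == -math.inf) or math.isnan(ub):
            findings.append(f"non-numeric bounds on reaction {rid!r}")
        elif lb > ub:
            findings.append(f"lower bound exceeds upper bound on reaction {rid!r}")
        if not np.any(model.S[:, j]):
            findings.append(f"empty stoichiometric column (reaction {rid!r})")
    for i, mid in enumerate(model.metabolite_ids):
        if not np.any(model.S[i, :]):
            findings.append(f"dead row: metabolite {mid!r} participates in no reaction")
    if model.target_reaction is None:
        findings.append("no target reaction set")
    elif model.target_reaction not in model.reaction_ids:
        findings.append(f"target reaction {model.target_reaction!r} not in the model")
    return findings


# -- JSON (cobra schema) ------------------------------------------------------


def _model_to_json_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        mets = {
            model.metabolite_ids[i]: float(col[i])
            for i in np.flatnonzero(col)
        }
        reactions.append(
            {
                "id": rid,
                "metabolites": mets,
                "lower_bound": float(model.lower_bounds[j]),
                "upper_bound": float(model.upper_bounds[j]),
                "gene_reaction_rule": model.gpr[j],
                "subsystem": model.subsystems[j] or "",
                "objective_coefficient": 1.0 if rid == model.target_reaction else 0.0,
            }
        )
    genes = sorted(
        {g for rule in model.gpr for g in _gpr_genes(rule)}
    )
    return {
        "id": model.name or "flutor_model",
        "metabolites": [
            {"id": mid, "name": mid, "compartment": ""} for mid in model.metabolite_ids
        ],
        "reactions": reactions,
        "genes": [{"id": g, "name": g} for g in genes],
        "version": "1",
    }


def _gpr_genes(rule: str) -> list[str]:
    tokens = rule.replace("(", " ").replace(")", " ").split()
    return [t for t in tokens if t.lower() not in ("and", "or")]


def save_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Write the model in the cobra JSON dialect (canonical: sorted keys)."""
    payload = _model_to_json_dict(model)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _model_from_json_dict(data: dict, path: str = "<json>") -> MetabolicModel:
    try:
        met_entries = data["metabolites"]
        rxn_entries = data["reactions"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing top-level element {exc}") from None
    metabolite_ids = []
    for entry in met_entries:
        if "id" not in entry:
            raise FormatError(f"{path}: metabolite entry without an 'id'")
        metabolite_ids.append(str(entry["id"]))
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    n = len(rxn_entries)
    S = np.zeros((len(metabolite_ids), n))
    lb = np.empty(n)
    ub = np.empty(n)
    reaction_ids, subsystems, gpr = [], [], []
    target = None
    for j, entry in enumerate(rxn_entries):
        if "id" not in entry:
            raise FormatError(f"{path}: reaction entry without an 'id'")
        rid = str(entry["id"])
        reaction_ids.append(rid)
        if "lower_bound" not in entry or "upper_bound" not in entry:
            raise FormatError(f"{path}: reaction {rid!r} has no explicit bounds")
        lb[j] = float(entry["lower_bound"])
        ub[j] = float(entry["upper_bound"])
        for mid, coef in entry.get("metabolites", {}).items():
            if mid not in met_index:
                raise FormatError(
                    f"{path}: reaction {rid!r} references unknown metabolite {mid!r}"
                )
            S[met_index[mid], j] = float(coef)
        subsystems.append(entry.get("subsystem") or None)
        gpr.append(entry.get("gene_reaction_rule", "") or "")
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            target = rid
    return MetabolicModel(
        metabolite_ids=tuple(metabolite_ids),
        reaction_ids=tuple(reaction_ids),
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        subsystems=tuple(subsystems),
        gpr=tuple(gpr),
        target_reaction=target,
        name=str(data.get("id", "")),
    )


# -- cobrapy bridge (SBML L3+FBC) --------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML export and test oracles)."""
    import cobra

    cm = cobra.Model(model.name or "flutor_model")
    mets = {
        mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids
    }
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        col = model.S[:, j]
        rxn.add_metabolites(
            {mets[model.metabolite_ids[i]]: float(col[i]) for i in np.flatnonzero(col)}
        )
        if model.gpr[j]:
            rxn.gene_reaction_rule = model.gpr[j]
        if model.subsystems[j]:
            rxn.subsystem = model.subsystems[j]
        reactions.append(rxn)
    cm.add_reactions(reactions)
    if model.target_reaction is not None:
        cm.objective = model.target_reaction
    return cm


def from_cobra(cm, target_override: str | None = None) -> MetabolicModel:
    """Convert a cobrapy Model, preserving stoichiometry, bounds, GPR, subsystems."""
    metabolite_ids = tuple(m.id for m in cm.metabolites)
    reaction_ids = tuple(r.id for r in cm.reactions)
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    subsystems = []
    gpr = []
    for j, rxn in enumerate(cm.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        subsystems.append(rxn.subsystem or None)
        gpr.append(rxn.gene_reaction_rule or "")
    target = target_override
    if target is None:
        # the FBC objective becomes the target reaction
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if coeffs:
            target = max(coeffs, key=lambda r: abs(coeffs[r])).id
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        subsystems=tuple(subsystems),
        gpr=tuple(gpr),
        target_reaction=target,
        name=cm.id or "",
    )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def load_model(
    path: str | Path,
    format: str | None = None,
    target_override: str | None = None,
) -> MetabolicModel:
    """Load a model from disk.

    Parameters
    ----------
    path:
        Model file. Must exist.
    format:
        ``"json"`` (cobra dialect) or ``"sbml"``; inferred from the file
        extension when omitted.
    target_override:
        Reaction id to use as the target instead of the declared objective.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"model file not found: {p}")
    if format is None:
        format = "sbml" if p.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            data = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{p}: not valid JSON ({exc})") from None
        model = _model_from_json_dict(data, path=str(p))
        if target_override is not None:
            model = model.with_target(target_override)
    elif format == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(p))
        except Exception as exc:  # libsbml raises many concrete types
            raise FormatError(f"{p}: SBML parse failure ({exc})") from None
        model = from_cobra(cm, target_override=target_override)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'json')")
    findings = [
        f
        for f in validate_model(model)
        if "target" not in f  # a target may legitimately be set later
    ]
    if any("duplicate" in f or "dimension" in f or "bound" in f for f in findings):
        raise FormatError(f"{p}: " + "; ".join(findings))
    return model
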