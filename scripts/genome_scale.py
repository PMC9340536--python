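#!/usr/bin/env python
"""Genome-scale integration runs (optional; requires user-supplied models).

These analyses are hours of compute and need the published genome-scale
model files, which are not distributed with the package:

  * iJO1366 (E. coli, 1805 metabolites / 2583 reactions, SBML or JSON)
  * yeastGEM v8.3.3 (S. cerevisiae, 2691 / 3963)
  * AraCore (A. thaliana, 407 / 549)

Usage:
    python scripts/genome_scale.py MODEL_FILE --target BIOMASS_ID \\
        [--fractions 0.90 0.95 0.99] [--conditions conditions.json] \\
        [--out results/genome_scale.json]

For each growth fraction (and optionally each media condition) the script
runs the full pipeline and reports: number of blocked reactions, number of
reactions in any relative trade-off, the set present in every trade-off,
and the always/sometimes/never subsystem classes — the quantities to hold
against the published genome-scale observations (e.g. sixteen E. coli
reactions in all trade-offs, all from cofactor biosynthesis; 42 invariant
A. thaliana reactions; three subsystems always in trade-off).

Media bounds for specific carbon/nitrogen sources must be supplied via a
conditions JSON file (same schema as the `flutor sweep` subcommand); they
are not hard-coded here.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import flutor as ft
from flutor.analysis import classify_subsystems, run_condition_sweep
from flutor.model import MediaCondition


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("model", type=Path)
    ap.add_argument("--target", default=None, help="biomass reaction id override")
    ap.add_argument("--fractions", type=float, nargs="+", default=[0.90, 0.95, 0.99])
    ap.add_argument("--conditions", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/genome_scale.json"))
    ap.add_argument("--max-tradeoffs", type=int, default=500)
    args = ap.parse_args()

    model = ft.load_model(args.model, target_override=args.target)
    if args.conditions:
        raw = json.loads(args.conditions.read_text())
    else:
        raw = [{"name": "default"}]
    conditions = [
        MediaCondition(
            name=f"{entry['name']}_f{frac}",
            exchange_bounds={
                rid: (float(lo), float(hi))
                for rid, (lo, hi) in entry.get("exchange_bounds", {}).items()
            },
            growth_fraction=frac,
        )
        for entry in raw
        for frac in args.fractions
    ]
    cfg = ft.FlutorConfig(max_tradeoffs=args.max_tradeoffs)
    sweep = run_condition_sweep(model, conditions, cfg=cfg)

    supports = [
        frozenset(t.support) for t in sweep.all_tradeoffs
    ]
    in_all = set.intersection(*map(set, supports)) if supports else set()
    classes = classify_subsystems(model, sweep)
    payload = {
        "model": model.name,
        "n_reactions": model.n_reactions,
        "n_metabolites": model.n_metabolites,
        "conditions": {
            c.condition.name: {
                "status": c.status,
                "reason": c.reason,
                "n_blocked": (
                    len(c.run.classification.blocked) if c.run else None
                ),
                "n_tradeoff_reactions": len(c.tradeoff_reactions),
            }
            for c in sweep.conditions
        },
        "n_reactions_in_any_tradeoff": len(sweep.tradeoff_reactions),
        "reactions_in_all_tradeoffs": sorted(in_all),
        "subsystems_always_in_tradeoff": sorted(
            s for s, cls in classes.items() if cls == "always"
        ),
        "subsystems_sometimes_in_tradeoff": sorted(
            s for s, cls in classes.items() if cls == "sometimes"
        ),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    print(json.dumps(payload, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
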