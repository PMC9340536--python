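import subprocess
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flutor as ft
from flutor.analysis import (
    ContingencyTable2x3,
    _log_table_probability,
    classify_proteins,
    classify_subsystems,
    compare_with_coupling,
    comparison_report,
    fisher_exact_2x3,
    identify_overexpression_targets,
    protein_promiscuity_table,
    subsystem_edges,
    sweep_report,
)
from flutor.model import MediaCondition
from flutor.tradeoffs import TradeOff


@pytest.fixture(scope="module")
def calvin_sweep(calvin):
    conditions = [MediaCondition(name=f"f{f}", growth_fraction=f) for f in (0.90, 0.95)]
    return ft.run_condition_sweep(calvin, conditions)


def fisher_oracle(t: ContingencyTable2x3) -> float:
    """Independent full-enumeration oracle in exact rational arithmetic."""
    r1, r2, r3 = t.a + t.b, t.c + t.d, t.e + t.f
    col1, n = t.a + t.c + t.e, t.n

    def prob(a, c, e):
        return Fraction(comb(r1, a) * comb(r2, c) * comb(r3, e), comb(n, col1))

    obs = prob(t.a, t.c, t.e)
    total = Fraction(0)
    for a in range(min(r1, col1) + 1):
        for c in range(min(r2, col1 - a) + 1):
            e = col1 - a - c
            if 0 <= e <= r3:
                p = prob(a, c, e)
                if p <= obs:
                    total += p
    return float(total)


class TestFisher:
    def test_single_admissible_table_gives_p_one(self):
        # row sums (2,0,0) and left-column sum 2 admit exactly one table
        assert fisher_exact_2x3(ContingencyTable2x3(2, 0, 0, 0, 0, 0)) == pytest.approx(1.0)

    def test_worked_example_against_exact_oracle(self):
        t = ContingencyTable2x3(3, 1, 1, 2, 0, 3)
        assert fisher_oracle(t) == pytest.approx(0.22857142857142856, abs=1e-12)
        assert fisher_exact_2x3(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            cells = rng.integers(0, 12, size=6)
            if cells.sum() == 0:
                continue
            t = ContingencyTable2x3(*map(int, cells))
            assert fisher_exact_2x3(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=6, max_size=6))
    def test_probabilities_sum_to_one_over_margins(self, cells):
        if sum(cells) == 0:
            return
        t = ContingencyTable2x3(*cells)
        r = (t.a + t.b, t.c + t.d, t.e + t.f)
        col1 = t.a + t.c + t.e
        total = 0.0
        for a in range(min(r[0], col1) + 1):
            for c in range(min(r[1], col1 - a) + 1):
                e = col1 - a - c
                if 0 <= e <= r[2]:
                    total += np.exp(_log_table_probability(a, c, e, r, col1, t.n))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x3(ContingencyTable2x3(0, 0, 0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x3(-1, 0, 0, 0, 0, 0)

    def test_agrees_with_r_fisher_test(self):
        """Cross-check the test construction against R's fisher.test."""
        tables = [(3, 1, 1, 2, 0, 3), (5, 2, 1, 4, 2, 2), (1, 0, 2, 3, 4, 1)]
        cells = ";".join(",".join(map(str, t)) for t in tables)
        script = (
            f'for (s in strsplit("{cells}", ";")[[1]]) '
            "{ x <- as.numeric(strsplit(s, \",\")[[1]]); "
            "cat(sprintf('%.12f\\n', fisher.test(matrix(x, nrow=3, byrow=TRUE))$p.value)) }"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_values = [float(x) for x in out.stdout.split()]
        for cells_t, r_p in zip(tables, r_values):
            assert fisher_exact_2x3(ContingencyTable2x3(*cells_t)) == pytest.approx(
                r_p, abs=1e-7
            )


class TestSubsystemClassification:
    def test_calvin_sweep_classes(self, calvin, calvin_sweep):
        classes = classify_subsystems(calvin, calvin_sweep)
        # r7 (Export) is in every trade-off support; regeneration and
        # carboxylation reactions appear in some; reduction never (r4 is the
        # target, r5 its merged partner)
        assert classes["Export"] == "always"
        assert classes["Regeneration"] == "sometimes"
        assert classes["Carboxylation"] == "sometimes"
        assert classes["Reduction"] == "never"

    def test_classes_partition_all_subsystems(self, calvin, calvin_sweep):
        classes = classify_subsystems(calvin, calvin_sweep)
        assert set(classes) == {"Export", "Regeneration", "Carboxylation", "Reduction"}
        assert set(classes.values()) <= {"always", "sometimes", "never"}

    def test_synthetic_tradeoffs_by_definition(self, calvin):
        tradeoffs = [
            TradeOff(target="r4", alpha={"r4": -1.0, "r1": 1.0, "r6": 1.0},
                     support=frozenset({"r1", "r6"})),
            TradeOff(target="r4", alpha={"r4": -1.0, "r1": 1.0, "r7": 1.0},
                     support=frozenset({"r1", "r7"})),
            TradeOff(target="r4", alpha={"r4": -1.0, "r1": 1.0, "r3": 1.0},
                     support=frozenset({"r1", "r3"})),
        ]
        classes = classify_subsystems(calvin, tradeoffs)
        assert classes["Regeneration"] == "always"  # r1 is in all three
        assert classes["Export"] == "sometimes"  # r6, r7 in one each
        assert classes["Reduction"] == "never"

    def test_unannotated_bucket(self, calvin_sweep):
        import dataclasses

        calvin = ft.build_calvin_benson_fixture()
        stripped = dataclasses.replace(calvin, subsystems=(None,) * 7)
        classes = classify_subsystems(stripped, calvin_sweep)
        assert set(classes) == {"unannotated"}


class TestProteinClassification:
    def test_calvin_protein_classes(self, calvin, calvin_sweep):
        classes = classify_proteins(calvin, calvin_sweep.tradeoff_reactions)
        # r1/r2/r3 genes catalyse only trade-off reactions; r4/r5 genes none
        assert classes["TKL1"] == "all_in"
        assert classes["RBCL"] == "all_in"
        assert classes["PGK1"] == "none_in"
        assert classes["GAPA"] == "none_in"

    def test_mixed_protein(self):
        model = ft.MetabolicModel(
            metabolite_ids=("A",),
            reaction_ids=("r1", "r2"),
            S=np.array([[1.0, -1.0]]),
            lower_bounds=np.zeros(2),
            upper_bounds=np.ones(2),
            gpr=("G1", "G1 or G2"),
            target_reaction="r2",
        )
        classes = classify_proteins(model, {"r1"})
        assert classes == {"G1": "mixed", "G2": "none_in"}

    def test_empty_gprs_give_empty_map(self, branch):
        assert classify_proteins(branch, {"r2"}) == {}

    def test_malformed_gpr_warns_and_skips(self):
        model = ft.MetabolicModel(
            metabolite_ids=("A",),
            reaction_ids=("r1", "r2"),
            S=np.array([[1.0, -1.0]]),
            lower_bounds=np.zeros(2),
            upper_bounds=np.ones(2),
            gpr=("(G1", "G2"),
            target_reaction="r2",
        )
        with pytest.warns(UserWarning, match="r1"):
            classes = classify_proteins(model, set())
        assert classes == {"G2": "none_in"}

    def test_promiscuity_table_counts(self, calvin, calvin_sweep):
        table = protein_promiscuity_table(calvin, calvin_sweep.tradeoff_reactions)
        # 4 single-reaction proteins all in trade-off (TKL1, PRK1, RBCL, RBCS),
        # 3 single-reaction proteins never in trade-off (PGK1, GAPA, GAPB)
        assert (table.a, table.b) == (4, 0)
        assert (table.c, table.d) == (3, 0)
        assert (table.e, table.f) == (0, 0)


class TestCouplingComparison:
    def test_branch_supports_are_coupled(self, branch):
        sweep = ft.run_condition_sweep(
            branch, [MediaCondition(name="base", growth_fraction=0.9)]
        )
        (cmp,) = compare_with_coupling(sweep)
        assert cmp.tradeoff <= cmp.coupled
        assert cmp.frac_tradeoff_coupled == pytest.approx(1.0)
        assert cmp.uncoupled_tradeoff_reactions == frozenset()

    def test_no_tradeoffs_gives_zero_ratios(self):
        from conftest import simple_chain

        sweep = ft.run_condition_sweep(
            simple_chain(10.0), [MediaCondition(name="base", growth_fraction=0.9)]
        )
        (cmp,) = compare_with_coupling(sweep)
        assert cmp.frac_tradeoff_coupled == 0.0
        assert cmp.tradeoff == frozenset()

    def test_report_frame_columns(self, calvin_sweep):
        df = comparison_report(calvin_sweep)
        assert list(df.columns) == [
            "condition", "n_coupled", "n_tradeoff",
            "frac_coupled_in_tradeoff", "frac_tradeoff_coupled",
            "n_uncoupled_tradeoff",
        ]
        assert (df["n_uncoupled_tradeoff"] == 0).all()


class TestOverexpressionTargets:
    def test_branch_consumers_stay_variable_at_higher_bound(self, branch):
        sweep = ft.run_condition_sweep(
            branch, [MediaCondition(name="base", growth_fraction=0.9)]
        )
        targets = identify_overexpression_targets(branch, sweep, higher_fraction=0.99)
        assert targets == {"r2", "r3", "r4"}

    def test_reactions_fixed_at_optimum_excluded(self):
        model = ft.build_branch_fixture([1.0, 1.0], consumer_upper_bounds=[5.0, 5.0])
        sweep = ft.run_condition_sweep(
            model, [MediaCondition(name="base", growth_fraction=0.9)]
        )
        assert sweep.tradeoff_reactions == {"r2", "r3"}
        # at the optimum both consumers are pinned at their bounds
        assert identify_overexpression_targets(model, sweep, higher_fraction=1.0) == frozenset()

    def test_empty_sweep_empty_targets(self):
        from conftest import simple_chain

        model = simple_chain(10.0)
        sweep = ft.run_condition_sweep(
            model, [MediaCondition(name="base", growth_fraction=0.9)]
        )
        assert identify_overexpression_targets(model, sweep) == frozenset()


class TestSweep:
    def test_inactive_exchange_bound_does_not_change_tradeoffs(self, calvin):
        base = MediaCondition(name="base", growth_fraction=0.9)
        loose = MediaCondition(
            name="loose", exchange_bounds={"r6": (0.0, 200.0)}, growth_fraction=0.9
        )
        sweep = ft.run_condition_sweep(calvin, [base, loose])
        s1 = {t.support for t in sweep.result("base").run.enumeration.expanded}
        s2 = {t.support for t in sweep.result("loose").run.enumeration.expanded}
        assert s1 == s2

    def test_infeasible_condition_recorded_not_raised(self, calvin):
        # demanding more GAP export than the network can sustain
        bad = MediaCondition(
            name="forced", exchange_bounds={"r7": (150.0, 166.7)}, growth_fraction=0.9
        )
        ok = MediaCondition(name="ok", growth_fraction=0.9)
        sweep = ft.run_condition_sweep(calvin, [bad, ok])
        assert sweep.result("forced").status == "failed"
        assert sweep.result("forced").reason
        assert sweep.result("ok").status == "ok"

    def test_condition_order_invariance(self, calvin):
        c1 = MediaCondition(name="a", growth_fraction=0.9)
        c2 = MediaCondition(name="b", growth_fraction=0.95)
        fwd = ft.run_condition_sweep(calvin, [c1, c2])
        rev = ft.run_condition_sweep(calvin, [c2, c1])
        for name in ("a", "b"):
            sf = {t.support for t in fwd.result(name).run.enumeration.expanded}
            sr = {t.support for t in rev.result(name).run.enumeration.expanded}
            assert sf == sr

    def test_unknown_exchange_id_fails_condition(self, calvin):
        bad = MediaCondition(
            name="typo", exchange_bounds={"r99": (0.0, 1.0)}, growth_fraction=0.9
        )
        sweep = ft.run_condition_sweep(calvin, [bad])
        assert sweep.result("typo").status == "failed"

    def test_growth_fraction_validation(self):
        with pytest.raises(ValueError):
            MediaCondition(name="x", growth_fraction=0.0)

    def test_sweep_report_shape(self, calvin, calvin_sweep):
        df = sweep_report(calvin, calvin_sweep)
        assert set(df["condition"]) == {"f0.9", "f0.95"}
        r7 = df[(df["condition"] == "f0.9") & (df["reaction_id"] == "r7")].iloc[0]
        assert bool(r7["in_tradeoff"]) and r7["n_tradeoffs"] == 4
        assert r7["subsystem_class"] == "always"

    def test_subsystem_edge_list(self, calvin, calvin_sweep):
        df = subsystem_edges(calvin, calvin_sweep)
        pairs = set(zip(df["subsystem_i"], df["subsystem_j"]))
        assert ("Export", "Regeneration") in pairs
        assert ("Carboxylation", "Export") in pairs
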