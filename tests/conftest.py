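import numpy as np
import pytest

import flutor as ft


@pytest.fixture(scope="session")
def calvin():
    return ft.build_calvin_benson_fixture()


@pytest.fixture(scope="session")
def calvin_run(calvin):
    """Pipeline run with the reduction-phase class (representative r4) as target."""
    return ft.run_flutor(calvin, growth_fraction=0.9, target="r4")


@pytest.fixture(scope="session")
def calvin_run_regen(calvin):
    """Pipeline run with the regeneration-phase class (representative r1) as target."""
    return ft.run_flutor(calvin, growth_fraction=0.9, target="r1")


@pytest.fixture(scope="session")
def branch():
    return ft.build_branch_fixture(
        [2.0, 3.0, 1.0], consumer_upper_bounds=[2.0, 3.0, 10.0]
    )


@pytest.fixture(scope="session")
def branch_run(branch):
    return ft.run_flutor(branch, growth_fraction=0.9)


def planted_instance(seed: int) -> ft.PlantedModel:
    """Deterministic recipe for one seeded random planted network (<= 12 reactions)."""
    rng = np.random.default_rng(seed + 1000)
    n_chain = int(rng.integers(0, 3))
    chains = [int(rng.integers(2, 4)) for _ in range(n_chain)]
    branches = [int(rng.integers(2, 4)) for _ in range(int(rng.integers(1, 3)))]
    need_m = sum(c - 1 for c in chains) + len(branches)
    need_r = sum(chains) + sum(b + 1 for b in branches)
    extra_m = int(rng.integers(0, 3))
    extra_r = extra_m + int(rng.integers(0, extra_m + 1))
    return ft.generate_random_model(
        need_m + extra_m, need_r + extra_r, chains, branches, seed=seed
    )


def simple_chain(ub: float = 10.0) -> ft.MetabolicModel:
    """import -> A -> export, all irreversible with the same upper bound."""
    S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    return ft.MetabolicModel(
        metabolite_ids=("A", "B"),
        reaction_ids=("r_in", "r_mid", "r_out"),
        S=S,
        lower_bounds=np.zeros(3),
        upper_bounds=np.full(3, ub),
        target_reaction="r_out",
        name="chain",
    )
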