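import numpy as np
import pytest

import alans


@pytest.fixture(scope="session")
def atlas():
    return alans.load_packaged_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny planted cohort: 3 modules over 12 regions, 8 participants."""
    pair_ids = tuple(f"r{i:02d}" for i in range(12)) + ("n1", "n2", "n3")
    planted = {p: ("Left" if i % 3 == 0 else "Right") for i, p in enumerate(pair_ids[:12])}
    module_spec = {
        "A": pair_ids[0:4],
        "B": pair_ids[4:8],
        "C": pair_ids[8:12],
    }
    return alans.CohortConfig(
        n_participants=8,
        n_pairs=15,
        pair_ids=pair_ids,
        planted_pairs=planted,
        module_spec=module_spec,
        between_module_r={("A", "B"): 0.1, ("A", "C"): -0.1},
        hub_spec={"r00": ("B",)},
        n_timepoints=120,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def demo_stack_and_truth():
    """One full-scale demo cohort realization, shared across tests."""
    cfg = alans.demo_config(rng_seed=42)
    truth = alans.planted_truth(cfg)
    panel = alans.simulate_rest_timeseries(cfg)
    stack = alans.stack_from_timeseries(
        panel.data, panel.region_ids, panel.participant_ids
    )
    return cfg, truth, stack
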