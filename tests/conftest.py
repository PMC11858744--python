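import numpy as np
import pytest

import viscoweber as vw


@pytest.fixture(scope="session")
def transparent_stimuli():
    return vw.builtin_stimuli("transparent")


@pytest.fixture(scope="session")
def opaque_stimuli():
    return vw.builtin_stimuli("opaque")


@pytest.fixture(scope="session")
def transparent_groups(transparent_stimuli):
    return vw.build_group_designs(transparent_stimuli)


@pytest.fixture(scope="session")
def mixed_groups(opaque_stimuli, transparent_stimuli):
    """Opaque references, transparent tests (the bias-task layout)."""
    return vw.build_group_designs(opaque_stimuli, test_stimuli=transparent_stimuli)


@pytest.fixture(scope="session")
def group_c(transparent_groups):
    return next(g for g in transparent_groups if g.label == "C")


@pytest.fixture(scope="session")
def task1a_design(transparent_groups):
    return vw.enumerate_unique_pairs(
        transparent_groups, include_equal_pair=True,
        dedup_policy="within_appearance", task_id="task1a",
    )


@pytest.fixture(scope="session")
def small_trials():
    """A small but structurally complete simulated task-1a dataset."""
    config = vw.scenario("task1a", n_subjects=12, seed=11)
    return vw.simulate_experiment(config)


def make_counts_table(group, w_true, p_true=None, n=None, rng=None):
    """Binomial counts drawn from the model on a group's design (or the
    noiseless expected counts when rng is None)."""
    p_true = p_true if p_true is not None else group.reference.viscosity
    targets = sorted(
        list(group.tests) + ([group.reference] if group.include_equal_pair else []),
        key=lambda s: s.viscosity,
    )
    counts = []
    for t in targets:
        prob = vw.predict(t.viscosity, vw.PsychometricParams(w_true, p_true))
        if rng is None:
            counts.append((t.viscosity, int(round(prob * n)), n))
        else:
            counts.append((t.viscosity, int(rng.binomial(n, prob)), n))
    return vw.ResponseTable.from_counts(group.label, group.reference.viscosity, counts)
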