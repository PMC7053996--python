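"""Shared synthetic datasets (session-scoped: simulated once per run)."""

from __future__ import annotations

import pytest

from spinedyn import generate_dataset, preset
from spinedyn import dynamics as dyn
from spinedyn import quantify as q


@pytest.fixture(scope="session")
def l23_baseline_ds():
    cfg = preset("L23_baseline", seed=11, n_neurons=8,
                 dendrites_per_neuron=4, spines_per_dendrite_mean=18)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def l5_baseline_ds():
    cfg = preset("L5_baseline", seed=12, n_neurons=8,
                 dendrites_per_neuron=4, spines_per_dendrite_mean=18)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def l23_vd_ds():
    cfg = preset("L23_VD", seed=13, n_neurons=12, dendrites_per_neuron=2,
                 spines_per_dendrite_mean=15)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def l5_vd_ds():
    cfg = preset("L5_VD", seed=14, n_neurons=12, dendrites_per_neuron=2,
                 spines_per_dendrite_mean=15)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def l23_sham_ds():
    cfg = preset("L23_sham", seed=15, n_neurons=8, dendrites_per_neuron=3,
                 spines_per_dendrite_mean=15)
    return generate_dataset(cfg)


def derived(ds):
    """Ratio table, fates and persistent-spine ids for a dataset."""
    ratios = q.ratio_table(ds.spines)
    fates = dyn.classify_fates(ds.spines, ds.schedule)
    pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
    return ratios, fates, pers


@pytest.fixture(scope="session")
def l23_baseline_derived(l23_baseline_ds):
    return derived(l23_baseline_ds)


@pytest.fixture(scope="session")
def l5_baseline_derived(l5_baseline_ds):
    return derived(l5_baseline_ds)


@pytest.fixture(scope="session")
def l23_vd_derived(l23_vd_ds):
    return derived(l23_vd_ds)


@pytest.fixture(scope="session")
def l5_vd_derived(l5_vd_ds):
    return derived(l5_vd_ds)
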