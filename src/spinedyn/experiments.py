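"""Canned in-silico experiments over the synthetic presets.

Each function simulates an experimental arm at a stated sample size,
runs the corresponding analysis end to end (raw ROI table -> ratio
normalization -> fate / summary -> statistic) and returns the headline
quantity.  They are the programmatic equivalents of the figure-level
analyses and are used by the reproduction script and the test suite.
"""

from __future__ import annotations

import numpy as np

from . import deprivation as depr
from . import dynamics as dyn
from . import quantify as q
from .stats import route_test
from .synthgen import generate_dataset, preset

__all__ = [
    "persistence_experiment",
    "basal_apical_experiment",
    "decrease_fraction_experiment",
]


def persistence_experiment(preset_name: str, seed: int,
                           n_neurons: int = 10,
                           dendrites_per_neuron: int = 5,
                           spines_per_dendrite_mean: float = 20.0,
                           ) -> tuple[float, int]:
    """Percent of first-session spines persisting through all sessions.

    Defaults put ~1000 spines on the first session.  Returns
    ``(percent, n_first_session_spines)``.
    """
    cfg = preset(
        preset_name, seed=seed, n_neurons=n_neurons,
        dendrites_per_neuron=dendrites_per_neuron,
        spines_per_dendrite_mean=spines_per_dendrite_mean,
    )
    ds = generate_dataset(cfg)
    fates = dyn.classify_fates(ds.spines, ds.schedule)
    n_day1 = int((fates["first_detected"] == ds.schedule.sessions[0]).sum())
    return dyn.persistence_fraction(fates, ds.schedule), n_day1


def basal_apical_experiment(seed: int, n_neurons: int = 16,
                            spines_per_dendrite_mean: float = 12.0,
                            ) -> tuple[float, float, int]:
    """Per-neuron basal/apical sGluA1-change ratio at deprivation day 7.

    Each neuron contributes one apical and one basal dendrite; spines are
    baseline-normalized, summarized per dendrite by geometric mean over
    persistent spines, pooled per compartment, and the basal/apical
    ratio tested against 1 (one-sample, normality-routed).  Returns
    ``(mean_ratio, p_value, n_neurons_included)``.
    """
    cfg = preset(
        "L23_VD", seed=seed, n_neurons=n_neurons, dendrites_per_neuron=2,
        spines_per_dendrite_mean=spines_per_dendrite_mean,
    )
    ds = generate_dataset(cfg)
    sched = ds.schedule
    ratios = q.ratio_table(ds.spines)
    fates = dyn.classify_fates(ds.spines, sched)
    pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
    norm = q.normalize_traces(ratios, "to_baseline_mean", sched)
    norm = norm.loc[norm["spine_id"].isin(pers)]
    summaries = q.dendrite_summary(norm, "sglua1")
    ratio_df = depr.basal_apical_ratio(summaries, ds.dendrites, "VD7")
    if len(ratio_df) < 3:
        raise ValueError("too few neurons with both compartments at VD7")
    res = route_test(ratio_df["ratio"].to_numpy(), "one_sample_vs_1")
    return float(ratio_df["ratio"].mean()), res.p_value, len(ratio_df)


def decrease_fraction_experiment(seed: int, n_neurons: int = 50,
                                 threshold: float = 0.18,
                                 ) -> tuple[float, int]:
    """Fraction of apical dendrites classified "decrease" at VD1 (L23_VD).

    Returns ``(fraction, n_dendrites)``.
    """
    cfg = preset(
        "L23_VD", seed=seed, n_neurons=n_neurons, dendrites_per_neuron=2,
    )
    ds = generate_dataset(cfg)
    sched = ds.schedule
    ratios = q.ratio_table(ds.spines)
    fates = dyn.classify_fates(ds.spines, sched)
    pers = set(fates.loc[fates["fate"] == "persistent", "spine_id"])
    norm = q.normalize_traces(ratios, "to_baseline_mean", sched)
    norm = norm.loc[norm["spine_id"].isin(pers)]
    summaries = q.dendrite_summary(norm, "sglua1")
    comp = ds.dendrites.set_index("dendrite_id")["compartment"]
    apical = summaries.loc[summaries["dendrite_id"].map(comp) == "apical"]
    vd1 = apical.loc[apical["session"] == "VD1"].set_index(
        "dendrite_id")["value"]
    cls = depr.classify_response(vd1, threshold)
    summary = depr.classification_summary(cls)
    return summary["percent_decrease"] / 100.0, summary["n_total"]
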