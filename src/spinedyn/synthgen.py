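"""Generative model for longitudinal two-channel spine-imaging datasets.

The generator emulates the statistical structure of in vivo SEP-GluA1 /
dsRed2 spine imaging experiments: spines on dendritic segments are tracked
over daily sessions; each spine has a lognormal surface-GluA1 (sGluA1)
set-point and a size set-point coupled to it; persistent spines fluctuate
multiplicatively day to day around their set-point with a layer-specific
coefficient of variation; transient spines sit at lower levels and ramp up
after formation / down before elimination; a per-session multiplicative
imaging gain (laser power, window quality) multiplies every ROI of a
session in both channels and is cancelled downstream by shaft-dsRed
normalization; visual-deprivation presets multiply post-deprivation latent
sGluA1 by a per-session effect that differs between a "decrease" and a
"no-decrease" subpopulation, between apical and basal compartments, and
along relative spine depth.

Latent ground truth (set-points, fates, subpopulation labels) is carried
alongside the simulated raw ROI intensities strictly for testing; analysis
modules consume only the observable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .schedules import Schedule, get_schedule

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "preset",
    "generate_dataset",
    "PRESET_NAMES",
]

Compartment = Literal["apical", "basal"]
Subpop = Literal["decrease", "no_decrease"]

# z-depth ranges below the pia (µm) from which dendrite segments are drawn
_DEPTH_RANGE = {"apical": (30.0, 120.0), "basal": (150.0, 300.0)}


class SyntheticConfig(BaseModel):
    """Full parameterization of the generative model.

    ``effect_timecourse`` maps subpopulation -> compartment -> one
    multiplicative sGluA1 effect per session (1.0 = no effect).  Baseline
    sessions must be 1.0; the depth modulation
    ``effect * (1 + depth_gradient * relative_depth)`` is applied on
    post-deprivation sessions only.
    """

    model_config = dict(frozen=True)

    preset_name: str = "custom"
    n_neurons: int = Field(6, ge=1)
    dendrites_per_neuron: int = Field(4, ge=1)
    spines_per_dendrite_mean: float = Field(15.0, gt=0)
    spines_per_dendrite_dispersion: float = Field(0.0, ge=0)
    schedule: str = "baseline10"
    layer: Literal["L23", "L5"] = "L23"
    region: Literal["V1", "nonV1"] = "V1"
    genotype: Literal["WT", "Grip1KO"] = "WT"
    condition: Literal["sham", "VD"] = "sham"
    compartments: tuple[Compartment, ...] = ("apical",)

    survival_per_session: float = Field(0.958, gt=0, le=1)
    formation_rate: float = Field(0.15, ge=0)

    baseline_log_mean: float = -0.2
    baseline_log_sd: float = Field(0.45, gt=0)
    size_coupling_rho: float = Field(0.7, ge=-1, le=1)
    fluctuation_cv: float = Field(0.25, gt=0)
    fluctuation_cv_post: float | None = Field(None, gt=0)
    transient_level: float = Field(0.55, gt=0)
    baseline_distance_coupling: float = 0.3

    shaft_intensity: float = Field(300.0, gt=0)
    session_gain_sd: float = Field(0.1, ge=0)
    background_level: float = Field(50.0, gt=0)
    noise_sd: float = Field(2.0, ge=0)

    decrease_fraction: float = Field(0.5, ge=0, le=1)
    subpop_unit: Literal["dendrite", "cell"] = "dendrite"
    effect_timecourse: dict[str, dict[str, tuple[float, ...]]] | None = None
    depth_gradient: float = 0.0
    seed: int = 0

    @field_validator("effect_timecourse")
    @classmethod
    def _positive_effects(cls, v):
        if v is not None:
            for sub in v.values():
                for tc in sub.values():
                    if any(e <= 0 for e in tc):
                        raise ValueError("effect_timecourse entries must be > 0")
        return v

    @model_validator(mode="after")
    def _check_consistency(self):
        sched = get_schedule(self.schedule)
        if self.effect_timecourse is not None:
            n_base = len(sched.baseline)
            for sub, by_comp in self.effect_timecourse.items():
                for comp, tc in by_comp.items():
                    if len(tc) != sched.n_sessions:
                        raise ValueError(
                            f"effect_timecourse[{sub}][{comp}] has {len(tc)} "
                            f"entries; schedule {self.schedule!r} has "
                            f"{sched.n_sessions} sessions"
                        )
                    if any(e != 1.0 for e in tc[:n_base]):
                        raise ValueError("baseline-session effects must be 1.0")
        if self.condition == "sham":
            for sub in (self.effect_timecourse or {}).values():
                for tc in sub.values():
                    if any(e != 1.0 for e in tc):
                        raise ValueError(
                            "sham condition requires an all-ones effect_timecourse"
                        )
        return self

    def schedule_obj(self) -> Schedule:
        return get_schedule(self.schedule)

    def effect(self, subpop: str, compartment: str) -> np.ndarray:
        sched = self.schedule_obj()
        if self.effect_timecourse is None:
            return np.ones(sched.n_sessions)
        by_comp = self.effect_timecourse.get(subpop)
        if by_comp is None or compartment not in by_comp:
            return np.ones(sched.n_sessions)
        return np.asarray(by_comp[compartment], dtype=float)


def _flat(n: int) -> tuple[float, ...]:
    return tuple([1.0] * n)


def _tc(apical=None, basal=None, *, decrease=None, no_decrease=None):
    """Build an effect_timecourse dict; shared profile per compartment or
    per-subpopulation profiles."""
    out: dict[str, dict[str, tuple[float, ...]]] = {}
    for sub in ("decrease", "no_decrease"):
        by_comp = {}
        sub_profiles = {"decrease": decrease, "no_decrease": no_decrease}[sub]
        if sub_profiles is not None:
            by_comp.update({c: tuple(v) for c, v in sub_profiles.items()})
        if apical is not None and "apical" not in by_comp:
            by_comp["apical"] = tuple(apical)
        if basal is not None and "basal" not in by_comp:
            by_comp["basal"] = tuple(basal)
        out[sub] = by_comp
    return out


_BASE = dict(n_neurons=6, dendrites_per_neuron=4, spines_per_dendrite_mean=15.0)

# Deprivation-schedule effect profiles (BL1 BL2 BL3 VD1 VD2 VD3 VD7).
# L2/3 apical: "decrease" dendrites dip at VD1 and recover to baseline by
# VD7; "no-decrease" dendrites are flat at VD1 and potentiate by VD7.
_L23_APICAL_DEC = (1, 1, 1, 0.65, 0.85, 1.00, 1.00)
_L23_APICAL_NODEC = (1, 1, 1, 1.00, 1.05, 1.10, 1.30)
# L2/3 basal: potentiated from VD1 onwards, larger than apical.
_L23_BASAL = (1, 1, 1, 1.15, 1.25, 1.35, 1.50)
# non-V1: systematic decrease, never above 1.
_NONV1 = (1, 1, 1, 0.95, 0.90, 0.88, 0.85)
# L5 apical (cell-level subpopulations): dip-and-recover vs slight,
# non-significant creep; no net late increase.
_L5_DEC = (1, 1, 1, 0.80, 0.85, 0.95, 1.00)
_L5_NODEC = (1, 1, 1, 1.00, 1.02, 1.05, 1.08)
# GRIP1 KO: initial dip that recovers by VD7, no potentiation.
_GRIP1KO = (1, 1, 1, 0.85, 0.85, 0.88, 1.00)

_PRESETS: dict[str, dict] = {
    # survival 0.958/session -> 0.958^9 ~ 0.68 of day-1 spines persist
    "L23_baseline": dict(
        _BASE, schedule="baseline10", layer="L23", condition="sham",
        survival_per_session=0.958, fluctuation_cv=0.25,
    ),
    "L23_sham": dict(
        _BASE, schedule="deprivation", layer="L23", condition="sham",
        survival_per_session=0.958, fluctuation_cv=0.25,
    ),
    "L23_VD": dict(
        _BASE, schedule="deprivation", layer="L23", condition="VD",
        compartments=("apical", "basal"),
        survival_per_session=0.958, fluctuation_cv=0.25,
        fluctuation_cv_post=0.18, decrease_fraction=0.51,
        depth_gradient=0.3,
        effect_timecourse=_tc(
            basal=_L23_BASAL,
            decrease={"apical": _L23_APICAL_DEC},
            no_decrease={"apical": _L23_APICAL_NODEC},
        ),
    ),
    "L23_VD_basal": dict(
        _BASE, schedule="deprivation", layer="L23", condition="VD",
        compartments=("basal",),
        survival_per_session=0.958, fluctuation_cv=0.25,
        fluctuation_cv_post=0.18, decrease_fraction=0.51,
        depth_gradient=0.3,
        effect_timecourse=_tc(basal=_L23_BASAL),
    ),
    "nonV1_VD": dict(
        _BASE, schedule="deprivation", layer="L23", region="nonV1",
        condition="VD", survival_per_session=0.958, fluctuation_cv=0.25,
        effect_timecourse=_tc(apical=_NONV1),
    ),
    # survival 0.955/session -> 0.955^9 ~ 0.66
    "L5_baseline": dict(
        _BASE, schedule="baseline10", layer="L5", condition="sham",
        survival_per_session=0.955, fluctuation_cv=0.15,
    ),
    "L5_VD": dict(
        _BASE, schedule="deprivation", layer="L5", condition="VD",
        survival_per_session=0.955, fluctuation_cv=0.15,
        fluctuation_cv_post=0.21, decrease_fraction=0.5,
        subpop_unit="cell",
        effect_timecourse=_tc(
            decrease={"apical": _L5_DEC}, no_decrease={"apical": _L5_NODEC},
        ),
    ),
    "GRIP1KO_VD": dict(
        _BASE, schedule="deprivation", layer="L23", genotype="Grip1KO",
        condition="VD", survival_per_session=0.958, fluctuation_cv=0.25,
        effect_timecourse=_tc(apical=_GRIP1KO),
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, **overrides) -> SyntheticConfig:
    """Return the named experimental-arm configuration.

    Parameters may be overridden by keyword (e.g. ``seed``, ``n_neurons``).
    """
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(_PRESETS[name], preset_name=name)
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class SyntheticDataset:
    """Simulated dataset: observable tables plus latent ground truth.

    ``spines`` is the long-format observable table (one row per spine x
    session); ``dendrites`` the segment metadata.  ``truth`` holds latent
    fields (set-points, per-session true values, fates, subpopulation
    labels) used only by tests — analysis modules must never read it.
    """

    config: SyntheticConfig
    schedule: Schedule
    spines: pd.DataFrame
    dendrites: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def observable(self) -> "SyntheticDataset":
        """Copy with all latent ground-truth fields removed (firewall)."""
        return SyntheticDataset(
            config=self.config,
            schedule=self.schedule,
            spines=self.spines.copy(),
            dendrites=self.dendrites.copy(),
            truth={},
        )


def _spine_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        n = rng.poisson(mean)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        n = rng.negative_binomial(r, p)
    return max(2, int(n))


def _sigma_for_cv(cv: float) -> float:
    # lognormal(sigma) has CV = sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate a full dataset; deterministic in ``(config, config.seed)``."""
    sched = config.schedule_obj()
    n_s = sched.n_sessions
    rng = np.random.default_rng(config.seed)

    # one imaging gain per session, shared by every ROI and both channels
    gains = np.exp(rng.normal(0.0, config.session_gain_sd, size=n_s))

    n_base = len(sched.baseline)
    is_post = np.array([s not in sched.baseline for s in sched.sessions])
    sig_base = _sigma_for_cv(config.fluctuation_cv)
    sig_post = _sigma_for_cv(config.fluctuation_cv_post or config.fluctuation_cv)
    sigma_t = np.where(is_post, sig_post, sig_base)

    spine_rows: list[pd.DataFrame] = []
    dend_rows: list[dict] = []
    truth_spine: list[pd.DataFrame] = []
    truth_traj: list[pd.DataFrame] = []

    for ni in range(config.n_neurons):
        neuron_id = f"n{ni:02d}"
        cell_subpop: Subpop = (
            "decrease" if rng.random() < config.decrease_fraction else "no_decrease"
        )
        for di in range(config.dendrites_per_neuron):
            dendrite_id = f"{neuron_id}_d{di:02d}"
            compartment = config.compartments[di % len(config.compartments)]
            if config.subpop_unit == "cell":
                subpop = cell_subpop
            else:
                subpop = (
                    "decrease"
                    if rng.random() < config.decrease_fraction
                    else "no_decrease"
                )

            # --- segment geometry ----------------------------------------
            zlo, zhi = _DEPTH_RANGE[compartment]
            z_prox = rng.uniform(zlo, zhi)
            length = rng.uniform(30.0, 60.0)
            slope = rng.uniform(-0.8, 0.8)  # dz per µm of arc
            z_dist = float(np.clip(z_prox + slope * length, 5.0, 400.0))
            x0, y0 = rng.uniform(0, 100, size=2)
            dend_rows.append(dict(
                dendrite_id=dendrite_id, neuron_id=neuron_id,
                compartment=compartment, layer=config.layer,
                region=config.region, genotype=config.genotype,
                condition=config.condition,
                prox_x_um=x0, prox_y_um=y0, prox_z_um=z_prox,
                dist_x_um=x0 + length, dist_y_um=y0, dist_z_um=z_dist,
            ))

            # --- spine census: presence over sessions --------------------
            n0 = _spine_count(
                rng, config.spines_per_dendrite_mean,
                config.spines_per_dendrite_dispersion,
            )
            presence = [np.zeros(n_s, dtype=bool) for _ in range(n0)]
            for pr in presence:
                pr[0] = True
                alive = True
                for t in range(1, n_s):
                    alive = alive and (rng.random() < config.survival_per_session)
                    pr[t] = alive
            for t in range(1, n_s):
                for _ in range(rng.poisson(config.formation_rate)):
                    pr = np.zeros(n_s, dtype=bool)
                    pr[t] = True
                    alive = True
                    for u in range(t + 1, n_s):
                        alive = alive and (rng.random() < config.survival_per_session)
                        pr[u] = alive
                    presence.append(pr)
            n_spines = len(presence)
            presence_m = np.array(presence)

            # --- spine geometry ------------------------------------------
            arc = np.sort(rng.uniform(0.0, length, size=n_spines))
            z = z_prox + (z_dist - z_prox) * arc / length
            zr = z.max() - z.min()
            rel_depth = (z - z.min()) / zr if zr > 0 else np.zeros(n_spines)
            rel_dist = (
                (arc - arc.min()) / (arc.max() - arc.min())
                if arc.max() > arc.min() else np.zeros(n_spines)
            )

            # --- latent set-points ---------------------------------------
            rho = config.size_coupling_rho
            e1 = rng.normal(size=n_spines)
            e2 = rho * e1 + np.sqrt(max(0.0, 1 - rho * rho)) * rng.normal(size=n_spines)
            log_g = config.baseline_log_mean + config.baseline_log_sd * e1
            log_r = config.baseline_log_mean + config.baseline_log_sd * e2
            log_g = log_g + config.baseline_distance_coupling * (rel_dist - 0.5)
            first = presence_m.argmax(axis=1)
            last = n_s - 1 - presence_m[:, ::-1].argmax(axis=1)
            persistent = presence_m.all(axis=1)
            set_g = np.exp(log_g) * np.where(persistent, 1.0, config.transient_level)
            set_r = np.exp(log_r) * np.where(persistent, 1.0, config.transient_level)

            # --- daily multiplicative fluctuations (coupled channels) ----
            f1 = rng.normal(size=(n_spines, n_s))
            f2 = rho * f1 + np.sqrt(max(0.0, 1 - rho * rho)) * rng.normal(
                size=(n_spines, n_s))
            fluct_g = np.exp(sigma_t * f1 - 0.5 * sigma_t**2)
            fluct_r = np.exp(sigma_t * f2 - 0.5 * sigma_t**2)

            # --- transient ramps: x0.5 at the event session, x0.75 next to it
            ramp = np.ones((n_spines, n_s))
            for i in range(n_spines):
                if first[i] > 0:  # newly formed
                    ramp[i, first[i]] *= 0.5
                    if first[i] + 1 <= last[i]:
                        ramp[i, first[i] + 1] *= 0.75
                if last[i] < n_s - 1:  # eliminated later
                    ramp[i, last[i]] *= 0.5
                    if last[i] - 1 >= first[i]:
                        ramp[i, last[i] - 1] *= 0.75

            # --- deprivation effect --------------------------------------
            eff = config.effect(subpop, compartment)  # (n_s,)
            depth_mod = np.where(
                is_post[None, :],
                1.0 + config.depth_gradient * rel_depth[:, None],
                1.0,
            )
            eff_g = np.where(is_post[None, :], eff[None, :] * depth_mod, 1.0)
            # spine size follows the same trend with about half the
            # log-magnitude of the sGluA1 change
            eff_r = np.sqrt(eff_g)

            true_g = set_g[:, None] * fluct_g * ramp * eff_g
            true_r = set_r[:, None] * fluct_r * ramp * eff_r

            # --- raw two-channel ROI intensities -------------------------
            shaft = config.shaft_intensity * np.exp(rng.normal(0.0, 0.1))
            bg = config.background_level
            noise = rng.normal(0.0, config.noise_sd, size=(6, n_spines, n_s))
            g_row = gains[None, :]  # broadcast over spines

            def roi(signal, k):
                return g_row * (signal + bg) + noise[k]

            raw = {
                "green_spine": roi(true_g * shaft, 0),
                "red_spine": roi(true_r * shaft, 1),
                "red_shaft": roi(np.full_like(true_g, shaft), 2),
                "bg_green_spine": roi(0.0 * true_g, 3),
                "bg_red_spine": roi(0.0 * true_g, 4),
                "bg_red_shaft": roi(0.0 * true_g, 5),
            }
            absent = ~presence_m
            for arr in raw.values():
                arr[absent] = np.nan

            fate = np.where(
                persistent, "persistent",
                np.where(
                    (first > 0) & (last < n_s - 1), "formed_and_eliminated",
                    np.where(first > 0, "formed", "eliminated"),
                ),
            )
            spine_ids = np.array(
                [f"{dendrite_id}_s{i:03d}" for i in range(n_spines)])

            truth_spine.append(pd.DataFrame(dict(
                spine_id=spine_ids, dendrite_id=dendrite_id,
                neuron_id=neuron_id, fate=fate, subpop=subpop,
                set_point_sglua1=set_g, set_point_size=set_r,
                rel_depth=rel_depth, rel_dist=rel_dist,
            )))
            flat = dict(
                spine_id=np.repeat(spine_ids, n_s),
                dendrite_id=dendrite_id, neuron_id=neuron_id,
                session=np.tile(np.array(sched.sessions), n_spines),
                present=presence_m.ravel(),
                x_um=np.repeat(x0 + arc, n_s), y_um=y0,
                z_um=np.repeat(z, n_s),
                dist_branch_um=np.repeat(arc, n_s),
            )
            flat.update({k: v.ravel() for k, v in raw.items()})
            spine_rows.append(pd.DataFrame(flat))
            pm = presence_m.ravel()
            truth_traj.append(pd.DataFrame(dict(
                spine_id=np.repeat(spine_ids, n_s)[pm],
                session=np.tile(np.array(sched.sessions), n_spines)[pm],
                true_sglua1=true_g.ravel()[pm],
                true_size=true_r.ravel()[pm],
            )))

    spines = pd.concat(spine_rows, ignore_index=True)
    dendrites = pd.DataFrame(dend_rows)
    truth = {
        "spines": pd.concat(truth_spine, ignore_index=True),
        "trajectories": pd.concat(truth_traj, ignore_index=True),
        "session_gains": pd.DataFrame(
            {"session": list(sched.sessions), "gain": gains}
        ),
    }
    return SyntheticDataset(
        config=config, schedule=sched, spines=spines,
        dendrites=dendrites, truth=truth,
    )
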