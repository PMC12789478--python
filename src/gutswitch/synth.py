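"""Synthetic data generation.

Emulates the bioreactor measurement layer on simulated trajectories: batch
monoculture growth curves sampled on the experimental cadence (every
4 h for the first 48 h, every 12 h afterwards), chemostat time series
with feed/pH perturbation protocols, multiplicative lognormal noise on
cell counts (flow cytometry) and additive truncated-Gaussian noise on
metabolites (HPLC) and pH.  Also ships the minimal bistable fixture: a
one-species, two-phenotype, one-substrate chemostat community
hand-constructed to have exactly two attractors.

What these generators do NOT emulate: instrument drift, replicate
batch effects, detection limits, or the residual species of the real
bioreactor runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ObservationDataset
from .community import (CommunityModel, Environment, Gate, Metabolite, PHModel,
                        Subpopulation, TransitionRule, build_default_community)
from .dynamics import MixEvent, PerturbationSchedule, Segment, simulate

__all__ = [
    "NoiseModel",
    "wc_medium",
    "observe",
    "subset_model",
    "batch_fixture",
    "chemostat_fixture",
    "protocol_library",
    "minimal_bistable_fixture",
    "minimal_bistable_pulse_schedule",
    "BATCH_SAMPLE_TIMES",
]

#: sampling cadence of the batch experiments: every 4 h to 48 h, then
#: every 12 h to 120 h
BATCH_SAMPLE_TIMES = np.array(sorted(set(np.arange(0, 49, 4)) |
                                     set(np.arange(48, 121, 12))), dtype=float)

CHEMOSTAT_DILUTION = 0.04  # 1/h, the feed rate of the minibioreactor runs
BATCH_PHASE_H = 4.0        # batch mode before continuous feeding starts


@dataclass
class NoiseModel:
    """Measurement noise: multiplicative lognormal on cells, additive
    truncated Gaussian on metabolites and pH."""

    cell_noise_cv: float = 0.05
    met_noise_sd: float = 0.1   # mM
    ph_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.cell_noise_cv, self.met_noise_sd, self.ph_noise_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")


def wc_medium():
    """Default WC-medium composition used as feed and initial state.

    Trehalose (0.71 mM) and feed pH (6.4) are measured values; the
    sugar/pyruvate/glutamate concentrations are declared, unmeasured
    placeholders.  Fermentation acids start at zero (fresh medium).
    """
    model = build_default_community()
    feed = {m.name: m.feed_conc for m in model.metabolites}
    return feed, model.environment.feed_ph


def observe(trajectory, noise: NoiseModel, sample_times, replicate="r1",
            species_context=None) -> ObservationDataset:
    """Sample a trajectory into a tidy noisy observation table.

    Cell observations are per-species live totals; zero noise returns
    the trajectory values exactly; identical seeds give identical
    datasets.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    t = trajectory.times
    if sample_times.min() < t.min() - 1e-9 or sample_times.max() > t.max() + 1e-9:
        raise ValueError("sample time outside simulated span")
    idx = [int(np.argmin(np.abs(t - st))) for st in sample_times]
    if np.max(np.abs(t[idx] - sample_times)) > 1e-6:
        raise ValueError("sample times must lie on the simulated grid")
    rng = np.random.default_rng(noise.seed)
    model = trajectory.model
    rows = []
    totals = trajectory.species_totals(live_only=True)
    sigma = np.sqrt(np.log1p(noise.cell_noise_cv ** 2))
    for sp in model.species:
        vals = totals[sp][idx]
        if noise.cell_noise_cv > 0:
            # lognormal with unit mean and the requested CV
            vals = vals * rng.lognormal(-0.5 * sigma ** 2, sigma, size=len(vals))
        for st, v in zip(sample_times, vals):
            rows.append((st, replicate, sp, float(v), "cells/uL"))
    for name in model.met_names:
        vals = trajectory.variable(name)[idx]
        if noise.met_noise_sd > 0:
            vals = np.maximum(vals + rng.normal(0, noise.met_noise_sd, len(vals)), 0.0)
        for st, v in zip(sample_times, vals):
            rows.append((st, replicate, name, float(v), "mM"))
    ph = trajectory.ph_series()[idx]
    if noise.ph_noise_sd > 0:
        ph = np.maximum(ph + rng.normal(0, noise.ph_noise_sd, len(ph)), 0.0)
    for st, v in zip(sample_times, ph):
        rows.append((st, replicate, "pH", float(v), "pH"))
    records = pd.DataFrame(rows, columns=ObservationDataset.REQUIRED)
    return ObservationDataset(
        records=records,
        species_context=list(species_context or model.species),
        provenance=dict(kind="synthetic", seed=noise.seed,
                        true_params_hash=model.model_hash()))


def subset_model(model: CommunityModel, species_subset) -> CommunityModel:
    """Restrict a community model to a subset of its species."""
    keep = set(species_subset)
    subs = [s for s in model.subpopulations if s.species in keep]
    ids = {s.id for s in subs}
    trans = [t for t in model.transitions if t.source in ids and t.target in ids]
    return CommunityModel(model.metabolites, subs, trans,
                          model.ph_model, model.environment)


def batch_fixture(species_subset, seed=1, cell_noise_cv=0.05,
                  met_noise_sd=0.1, ph_noise_sd=0.02, n_replicates=3,
                  base_model: CommunityModel = None):
    """Noisy batch (D=0) monoculture/co-culture dataset plus its truth.

    120 h simulation of the default (placeholder-calibrated) model for
    the given species, sampled on the experimental cadence, with
    independent noise per replicate.
    """
    if not species_subset:
        raise ValueError("species_subset must be nonempty")
    model = subset_model(base_model or build_default_community(), species_subset)
    model.environment.dilution = 0.0
    times = np.linspace(0.0, 120.0, 481)
    traj = simulate(model, model.default_init(), times=times)
    frames = []
    for r in range(n_replicates):
        noise = NoiseModel(cell_noise_cv=cell_noise_cv, met_noise_sd=met_noise_sd,
                           ph_noise_sd=ph_noise_sd, seed=seed * 1000 + r)
        ds = observe(traj, noise, BATCH_SAMPLE_TIMES, replicate=f"r{r + 1}",
                     species_context=species_subset)
        frames.append(ds.records)
    records = pd.concat(frames, ignore_index=True)
    dataset = ObservationDataset(records=records,
                                 species_context=list(species_subset),
                                 provenance=dict(kind="synthetic", seed=seed,
                                                 true_params_hash=model.model_hash()))
    return dataset, model


# ---------------------------------------------------------------------------
# chemostat protocols
# ---------------------------------------------------------------------------

def protocol_library(t_end=200.0) -> dict:
    """Named perturbation schedules mirroring the bioreactor protocols.

    All templates start with a 4 h batch phase, then continuous feed at
    0.04 1/h, and restore the baseline environment in their final
    segment:

    - ``control``: no perturbation.
    - ``feed_stop``: feed stopped for 12 h (t=108-120), then an
      instantaneous 50% fresh-medium addition, then baseline feed.
    - ``ph_then_feed``: acidified feed (pH 3.7) for 24 h (t=88-112),
      later a feed stop for 12 h (t=150-162) with the 50% medium
      addition, then baseline feed.
    """
    D = CHEMOSTAT_DILUTION
    base = dict(dilution=D)
    lib = {}
    lib["control"] = PerturbationSchedule(segments=[
        Segment(0.0, BATCH_PHASE_H, dilution=0.0),
        Segment(BATCH_PHASE_H, t_end, **base),
    ])
    # perturbation templates need room after their last perturbation to
    # restore the baseline; they are omitted for shorter horizons
    if t_end > 120.0:
        lib["feed_stop"] = PerturbationSchedule(segments=[
            Segment(0.0, BATCH_PHASE_H, dilution=0.0),
            Segment(BATCH_PHASE_H, 108.0, **base),
            Segment(108.0, 120.0, dilution=0.0),
            Segment(120.0, t_end, **base),
        ], events=[MixEvent(time=120.0, fraction=0.5)])
    if t_end > 162.0:
        lib["ph_then_feed"] = PerturbationSchedule(segments=[
            Segment(0.0, BATCH_PHASE_H, dilution=0.0),
            Segment(BATCH_PHASE_H, 88.0, **base),
            Segment(88.0, 112.0, dilution=D, feed_ph=3.7),
            Segment(112.0, 150.0, **base),
            Segment(150.0, 162.0, dilution=0.0),
            Segment(162.0, t_end, **base),
        ], events=[MixEvent(time=162.0, fraction=0.5)])
    return lib


def chemostat_fixture(protocol_name, seed=1, t_end=200.0,
                      noise: NoiseModel = None, sample_every=4.0):
    """Noisy chemostat time series under a named perturbation protocol.

    Returns ``(ObservationDataset, PerturbationSchedule)``.  The feed's
    acidified pH enters through the emergent-pH base (feed pH override),
    and the 50% fresh-medium addition after a feed stop is modeled as an
    instantaneous state mix.
    """
    lib = protocol_library(t_end=t_end)
    if protocol_name not in lib:
        raise KeyError(f"unknown protocol {protocol_name!r}; have {sorted(lib)}")
    schedule = lib[protocol_name]
    model = build_default_community()
    times = np.arange(0.0, t_end + 1e-9, 0.5)
    traj = simulate(model, model.default_init(), schedule=schedule, times=times)
    if noise is None:
        noise = NoiseModel(seed=seed)
    else:
        noise = NoiseModel(noise.cell_noise_cv, noise.met_noise_sd,
                           noise.ph_noise_sd, seed=seed)
    sample_times = np.arange(0.0, t_end + 1e-9, sample_every)
    dataset = observe(traj, noise, sample_times, replicate="r1")
    dataset.provenance["protocol"] = protocol_name
    return dataset, schedule


# ---------------------------------------------------------------------------
# minimal bistable fixture
# ---------------------------------------------------------------------------

def minimal_bistable_fixture(k_switch=0.1, dilution=0.05) -> CommunityModel:
    """One species, two phenotypes, one substrate; exactly two attractors.

    A 'thrifty' phenotype grows slowly with poor substrate affinity; a
    'greedy' phenotype grows fast with high affinity but is
    growth-repressed at high substrate (it only pays off once the
    substrate is already scarce).  Switching toward greedy turns on
    when the substrate falls below 0.5 mM, and back-switching returns
    cells at high substrate.  At D=0.05 1/h the chemostat then admits
    two self-consistent states: thrifty-dominated with ~2 mM residual
    substrate, and greedy-dominated with ~6 uM residual substrate.  A
    transient feed stop from the thrifty state starves the culture,
    converts it to greedy, and the system does not return when the
    feed is restored; with ``k_switch=0`` the pulse is fully
    reversible.
    """
    mets = [Metabolite("substrate", feed_conc=10.0, init_conc=10.0)]
    subs = [
        Subpopulation(id="thrifty", species="sp", mu_max=0.1,
                      uptake={"substrate": (2.0e-4, 2.0)},
                      ph_opt=0.0, ph_steep=1.0),
        Subpopulation(id="greedy", species="sp", mu_max=0.5,
                      uptake={"substrate": (2.0e-3, 0.05)},
                      inhibition={"substrate": (0.5, 4.0)},
                      ph_opt=0.0, ph_steep=1.0),
    ]
    trans = [
        TransitionRule(source="thrifty", target="greedy", signal="substrate",
                       k_switch=k_switch, theta=0.5, n_hill=4.0,
                       direction="repressing"),
        TransitionRule(source="greedy", target="thrifty", signal="substrate",
                       k_switch=k_switch, theta=0.5, n_hill=4.0,
                       direction="activating"),
    ]
    ph_model = PHModel(mode="fixed", fixed_value=6.4, base_ph=6.4, acid_coeffs={})
    env = Environment(dilution=dilution, feed={"substrate": 10.0}, feed_ph=6.4)
    return CommunityModel(mets, subs, trans, ph_model, env)


def minimal_bistable_pulse_schedule(pulse_h=24.0, settle_h=300.0,
                                    dilution=0.05) -> PerturbationSchedule:
    """Feed-stop pulse protocol for the minimal bistable fixture: run at
    baseline, stop the feed for ``pulse_h`` hours, restore baseline."""
    return PerturbationSchedule(segments=[
        Segment(0.0, settle_h, dilution=dilution),
        Segment(settle_h, settle_h + pulse_h, dilution=0.0),
        Segment(settle_h + pulse_h, settle_h + pulse_h + settle_h,
                dilution=dilution),
    ])
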