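"""Stability-landscape analyses of the community model.

Maps steady states over (pH, dilution-rate) grids, classifies which
species are present at each grid point, runs history-dependence
(hysteresis) protocols, and locates tipping points by bisection on a
control parameter.  Grid sweeps fix the pH at the axis value (pH is
the controlled variable there); dilution-protocol runs typically let
the pH emerge from the accumulated organic acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .community import CommunityModel, CommunityState
from .dynamics import (PerturbationSchedule, Segment, compile_model,
                       find_steady_state, resolve_env, simulate)

__all__ = [
    "LandscapeGrid",
    "PhaseMap",
    "sweep",
    "normalize_grid",
    "phase_map",
    "hysteresis_run",
    "find_tipping_point",
    "presence_classifier",
]

#: default species-presence threshold, cells/uL (absolute units)
PRESENCE_THRESHOLD = 1.0


@dataclass
class LandscapeGrid:
    """Steady-state concentrations over a (pH, dilution) grid.

    ``values`` has shape (n_variables, n_ph, n_d); variables are the
    model's metabolites followed by its subpopulations.
    """

    ph_values: np.ndarray
    d_values: np.ndarray
    values: np.ndarray
    converged: np.ndarray
    variables: list
    model: CommunityModel = None
    normalized: bool = False

    def variable_slice(self, name):
        return self.values[self.variables.index(name)]

    def to_frame(self):
        import pandas as pd
        rows = []
        for k, var in enumerate(self.variables):
            for i, ph in enumerate(self.ph_values):
                for j, d in enumerate(self.d_values):
                    rows.append((var, ph, d, self.values[k, i, j],
                                 bool(self.converged[i, j])))
        return pd.DataFrame(rows, columns=["variable", "ph", "dilution_h-1",
                                           "value", "converged"])


@dataclass
class PhaseMap:
    """Categorical species-presence labels over the (pH, dilution) grid."""

    ph_values: np.ndarray
    d_values: np.ndarray
    labels: np.ndarray          # object array of label strings
    presence_threshold: float

    def to_frame(self):
        import pandas as pd
        rows = [(ph, d, self.labels[i, j])
                for i, ph in enumerate(self.ph_values)
                for j, d in enumerate(self.d_values)]
        return pd.DataFrame(rows, columns=["ph", "dilution_h-1", "label"])


def sweep(model: CommunityModel, ph_values, d_values,
          init: CommunityState = None, tol=1e-6, t_max=4000.0) -> LandscapeGrid:
    """Independent steady-state solve at each (pH, D) grid point.

    Every point starts from the same initial state (default: fresh
    medium, 300 cells/uL per species) with the pH fixed at the axis
    value.  Convergence failures are recorded in the mask, not raised.
    """
    ph_values = np.asarray(ph_values, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    if ph_values.size == 0 or d_values.size == 0:
        raise ValueError("empty grid")
    if init is None:
        init = model.default_init()
    variables = list(model.met_names) + list(model.sub_ids)
    values = np.zeros((len(variables), len(ph_values), len(d_values)))
    converged = np.zeros((len(ph_values), len(d_values)), dtype=bool)
    for i, ph in enumerate(ph_values):
        for j, d in enumerate(d_values):
            env = Segment(0.0, t_max, dilution=float(d),
                          ph_mode="fixed", ph_fixed=float(ph))
            try:
                state, ok = find_steady_state(model, init, env=env,
                                              tol=tol, t_max=t_max)
            except RuntimeError:
                ok, state = False, None
            if state is not None:
                values[:, i, j] = state.to_vector(model)
            converged[i, j] = ok
    return LandscapeGrid(ph_values, d_values, values, converged,
                         variables, model=model)


def normalize_grid(grid: LandscapeGrid) -> LandscapeGrid:
    """Divide each variable's slice by its own maximum (all-zero slices
    are left unchanged).  Raises on double normalization."""
    if grid.normalized:
        raise ValueError("grid is already normalized")
    values = grid.values.copy()
    for k in range(values.shape[0]):
        m = values[k].max()
        if m > 0:
            values[k] /= m
    return LandscapeGrid(grid.ph_values, grid.d_values, values,
                         grid.converged.copy(), list(grid.variables),
                         model=grid.model, normalized=True)


def phase_map(grid: LandscapeGrid,
              presence_threshold: float = PRESENCE_THRESHOLD) -> PhaseMap:
    """Label each grid point by the set of species whose summed live
    pools exceed the threshold ('none' if empty)."""
    if grid.normalized:
        raise ValueError("phase_map needs absolute (unnormalized) units")
    model = grid.model
    labels = np.empty((len(grid.ph_values), len(grid.d_values)), dtype=object)
    for i in range(len(grid.ph_values)):
        for j in range(len(grid.d_values)):
            present = []
            for sp in model.species:
                total = sum(grid.values[grid.variables.index(s.id), i, j]
                            for s in model.subs_of(sp, live_only=True))
                if total > presence_threshold:
                    present.append(sp)
            labels[i, j] = "+".join(present) if present else "none"
    return PhaseMap(grid.ph_values, grid.d_values, labels, presence_threshold)


def hysteresis_run(model: CommunityModel, init: CommunityState,
                   forward_schedule: PerturbationSchedule,
                   comparison_tol: float = 0.05,
                   presence_threshold: float = PRESENCE_THRESHOLD,
                   settle_tol=1e-6, t_max=4000.0):
    """Test whether a perturbation leaves a lasting mark on the state.

    The schedule's last segment must restore the first segment's
    environment.  The system is settled under the baseline environment,
    then driven through the full schedule and settled again under the
    restored environment; the two settled states are compared by
    relative L-infinity distance over live cell pools above the
    presence threshold.

    Returns ``(state_before, state_after, same)``.
    """
    segs = sorted(forward_schedule.segments, key=lambda s: s.t_start)
    if len(segs) < 1:
        raise ValueError("schedule needs at least a baseline segment")
    first, last = segs[0], segs[-1]
    for attr in ("dilution", "feed", "feed_ph", "ph_mode", "ph_fixed"):
        if getattr(first, attr) != getattr(last, attr):
            raise ValueError("schedule does not restore the baseline environment")
    # settle under the baseline
    base_env = Segment(0.0, t_max, dilution=first.dilution, feed=first.feed,
                       feed_ph=first.feed_ph, ph_mode=first.ph_mode,
                       ph_fixed=first.ph_fixed)
    state_before, ok0 = find_steady_state(model, init, env=base_env,
                                          tol=settle_tol, t_max=t_max)
    # run the perturbation protocol from the settled state
    t0, t1 = segs[0].t_start, segs[-1].t_end
    traj = simulate(model, state_before, schedule=forward_schedule,
                    times=np.linspace(t0, t1, 201))
    # settle again under the restored environment
    state_after, ok1 = find_steady_state(model, traj.final_state, env=base_env,
                                         tol=settle_tol, t_max=t_max)
    same = states_close(state_before, state_after, model,
                        rel_tol=comparison_tol, floor=presence_threshold)
    return state_before, state_after, same


def states_close(a: CommunityState, b: CommunityState, model,
                 rel_tol=0.05, floor=PRESENCE_THRESHOLD):
    """Relative L-infinity comparison over live cell pools above floor."""
    worst = 0.0
    for sub in model.subpopulations:
        if sub.state_class != "active":
            continue
        va, vb = a.cells[sub.id], b.cells[sub.id]
        if max(va, vb) < floor:
            continue
        worst = max(worst, abs(va - vb) / max(va, vb))
    return worst < rel_tol


def basin_map(model: CommunityModel, pool_a: str, pool_b: str,
              grid_a, grid_b, mets: dict = None, settle_tol=1e-6,
              t_max=2000.0, match_rtol=0.05):
    """Brute-force basin-of-attraction map over a 2-D grid of initial
    cell-pool values.

    Each grid point ``(a, b)`` starts the model at ``pool_a = a``,
    ``pool_b = b`` (metabolites at ``mets`` or the model's initial
    medium) and is settled to steady state; settled states are grouped
    into attractors by relative L-infinity proximity (``match_rtol``).

    Returns ``(labels, attractors)``: an integer array of shape
    ``(len(grid_a), len(grid_b))`` and the list of distinct attractor
    states (-1 marks non-converged points).
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if mets is None:
        mets = {m.name: m.init_conc for m in model.metabolites}
    labels = np.full((len(grid_a), len(grid_b)), -1, dtype=int)
    attractors = []
    base_cells = {s.id: 0.0 for s in model.subpopulations}
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            cells = dict(base_cells)
            cells[pool_a] = float(a)
            cells[pool_b] = float(b)
            init = CommunityState(cells=cells, mets=dict(mets))
            state, ok = find_steady_state(model, init, tol=settle_tol,
                                          t_max=t_max)
            if not ok:
                continue
            vec = state.to_vector(model)
            for k, att in enumerate(attractors):
                ref = att.to_vector(model)
                denom = np.maximum(np.maximum(np.abs(vec), np.abs(ref)), 1.0)
                if np.max(np.abs(vec - ref) / denom) < match_rtol:
                    labels[i, j] = k
                    break
            else:
                attractors.append(state)
                labels[i, j] = len(attractors) - 1
    return labels, attractors


def presence_classifier(model: CommunityModel, species=None,
                        threshold: float = PRESENCE_THRESHOLD) -> Callable:
    """Classifier mapping a state to its species-presence label.

    With ``species`` given, returns that species' presence as a bool;
    otherwise the full presence tuple.
    """
    def classify(state: CommunityState):
        totals = state.species_totals(model, live_only=True)
        if species is not None:
            return totals[species] > threshold
        return tuple(sp for sp in model.species if totals[sp] > threshold)

    return classify


def find_tipping_point(model: CommunityModel, param: str, lo: float, hi: float,
                       classifier: Callable = None, tol: float = 5e-4,
                       init: CommunityState = None, settle_tol=1e-6,
                       t_max=4000.0):
    """Bisection on ``param`` ('dilution' or 'ph') for the critical value
    where the steady-state classification changes.

    Each evaluation settles the system from the same fresh initial
    state (default 300 cells/uL per species).  Returns the bracket
    midpoint once the bracket width is <= ``tol``, or None when both
    endpoints classify identically.  Raises on a non-converged steady
    state inside the bracket.
    """
    if param not in ("dilution", "ph"):
        raise ValueError("param must be 'dilution' or 'ph'")
    if not lo < hi:
        raise ValueError("need lo < hi")
    if classifier is None:
        classifier = presence_classifier(model)
    if init is None:
        init = model.default_init()

    def label_at(value):
        if param == "dilution":
            env = Segment(0.0, t_max, dilution=float(value))
        else:
            env = Segment(0.0, t_max, ph_mode="fixed", ph_fixed=float(value))
        state, ok = find_steady_state(model, init, env=env,
                                      tol=settle_tol, t_max=t_max)
        if not ok:
            raise RuntimeError(f"steady state did not converge at {param}={value}")
        return classifier(state)

    lab_lo, lab_hi = label_at(lo), label_at(hi)
    if lab_lo == lab_hi:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if label_at(mid) == lab_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
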