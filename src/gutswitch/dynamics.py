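"""Integration of the community ODEs.

The state vector is ``y = [metabolites (mM), subpopulations (cells/uL)]``
in the model's fixed ordering.  For each subpopulation i::

    dX_i/dt = mu_i(mets, pH) X_i - D X_i + sum(in-switching)
              - sum(out-switching) - death_i X_i

with ``mu_i = mu_max * ph_factor * prod(Monod over limiting substrates)
* prod(repressing-Hill growth inhibitions)``; death routes cells into
the species' inactive pool.  For each metabolite m::

    dm/dt = D (feed_m - m) - sum(uptake) + sum(production)

with uptake ``V_max * monod(m) * X`` and production proportional to the
producer's primary-substrate uptake flux (substrate-centric
stoichiometry).  pH is either fixed or an emergent linear function of
accumulated organic acids.

Integration uses a stiff-capable adaptive solver (LSODA, rtol 1e-6,
atol 1e-9); small negative excursions are clipped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .community import CommunityModel, CommunityState

__all__ = [
    "EnvParams",
    "Segment",
    "MixEvent",
    "PerturbationSchedule",
    "Trajectory",
    "compile_model",
    "rhs",
    "simulate",
    "simulate_euler",
    "find_steady_state",
]

_CONC_FLOOR = 1e-3  # scale floor for relative-derivative convergence metric


# ---------------------------------------------------------------------------
# environment & schedule
# ---------------------------------------------------------------------------

@dataclass
class EnvParams:
    """Fully resolved environment for one integration segment."""

    dilution: float
    feed: np.ndarray          # aligned with model metabolite order
    feed_ph: float
    ph_mode: str              # "emergent" | "fixed"
    ph_fixed: float


@dataclass
class Segment:
    """Piecewise-constant environment override on [t_start, t_end)."""

    t_start: float
    t_end: float
    dilution: Optional[float] = None
    feed: Optional[dict] = None        # partial metabolite->mM override
    feed_ph: Optional[float] = None
    ph_mode: Optional[str] = None
    ph_fixed: Optional[float] = None

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("segment must have t_start < t_end")


@dataclass
class MixEvent:
    """Instantaneous replacement of a fraction of the culture volume by
    fresh feed medium (metabolites move toward feed, cells are diluted)."""

    time: float
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("mix fraction must be in [0, 1]")


@dataclass
class PerturbationSchedule:
    """Contiguous, non-overlapping environment segments plus optional
    instantaneous medium-mix events."""

    segments: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def validate(self, t0, t1):
        segs = sorted(self.segments, key=lambda s: s.t_start)
        if not segs:
            return
        if segs[0].t_start > t0 or segs[-1].t_end < t1:
            raise ValueError(f"schedule does not cover [{t0}, {t1}]")
        for a, b in zip(segs, segs[1:]):
            if a.t_end > b.t_start + 1e-12:
                raise ValueError("overlapping schedule segments")
            if b.t_start - a.t_end > 1e-9:
                raise ValueError("gap in schedule segments")

    def segment_at(self, t):
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        if self.segments and abs(t - self.segments[-1].t_end) < 1e-9:
            return self.segments[-1]
        return None


def resolve_env(model: CommunityModel, segment: Optional[Segment]) -> EnvParams:
    env = model.environment
    phm = model.ph_model
    feed = model.feed_vector()
    dilution, feed_ph = env.dilution, env.feed_ph
    ph_mode, ph_fixed = phm.mode, phm.fixed_value
    if segment is not None:
        if segment.dilution is not None:
            dilution = segment.dilution
        if segment.feed is not None:
            for met, conc in segment.feed.items():
                feed[model.met_index[met]] = conc
        if segment.feed_ph is not None:
            feed_ph = segment.feed_ph
        if segment.ph_mode is not None:
            ph_mode = segment.ph_mode
        if segment.ph_fixed is not None:
            ph_fixed = segment.ph_fixed
    return EnvParams(dilution, feed, feed_ph, ph_mode, ph_fixed)


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

class _CompiledTransition:
    __slots__ = ("src", "tgt", "k", "sig_idx", "is_ph", "theta", "n", "sign",
                 "g_idx", "g_is_ph", "g_theta", "g_n", "g_sign")

    def __init__(self, model, rule):
        self.src = model.sub_index[rule.source]
        self.tgt = model.sub_index[rule.target]
        self.k = rule.k_switch
        self.is_ph, self.sig_idx = _signal_idx(model, rule.signal)
        self.theta, self.n = rule.theta, rule.n_hill
        self.sign = 1 if rule.direction == "activating" else -1
        if rule.gate is not None:
            g = rule.gate
            self.g_is_ph, self.g_idx = _signal_idx(model, g.signal)
            self.g_theta, self.g_n = g.theta, g.n_hill
            self.g_sign = 1 if g.direction == "activating" else -1
        else:
            self.g_idx = None


def _signal_idx(model, signal):
    names = [signal] if isinstance(signal, str) else list(signal)
    if names == ["pH"]:
        return True, None
    return False, np.array([model.met_index[n] for n in names], dtype=int)


def _hill_fast(s, theta, n, sign):
    r = (s / theta) ** n
    return r / (1.0 + r) if sign > 0 else 1.0 / (1.0 + r)


class CompiledModel:
    """Array form of a :class:`CommunityModel` for fast RHS evaluation."""

    def __init__(self, model: CommunityModel):
        self.model = model
        self.n_met, self.n_sub = model.n_met, model.n_sub
        up_sub, up_met, up_vmax, up_km, up_prim = [], [], [], [], []
        prod_sub, prod_met, prod_yield = [], [], []
        lim_sub, lim_met, lim_km = [], [], []
        inh_sub, inh_met, inh_theta, inh_n = [], [], [], []
        for i, sub in enumerate(model.subpopulations):
            for met, (vmax, km) in sub.uptake.items():
                up_sub.append(i)
                up_met.append(model.met_index[met])
                up_vmax.append(vmax)
                up_km.append(km)
                up_prim.append(met == sub.primary)
            for met, y in sub.yields.items():
                prod_sub.append(i)
                prod_met.append(model.met_index[met])
                prod_yield.append(y)
            for met in (sub.limiting or []):
                lim_sub.append(i)
                lim_met.append(model.met_index[met])
                lim_km.append(sub.uptake[met][1])
            for met, (theta, n) in sub.inhibition.items():
                inh_sub.append(i)
                inh_met.append(model.met_index[met])
                inh_theta.append(theta)
                inh_n.append(n)
        self.up_sub = np.array(up_sub, dtype=int)
        self.up_met = np.array(up_met, dtype=int)
        self.up_vmax = np.array(up_vmax)
        self.up_km = np.array(up_km)
        self.up_prim = np.array(up_prim, dtype=bool)
        self.prod_sub = np.array(prod_sub, dtype=int)
        self.prod_met = np.array(prod_met, dtype=int)
        self.prod_yield = np.array(prod_yield)
        self.lim_sub = np.array(lim_sub, dtype=int)
        self.lim_met = np.array(lim_met, dtype=int)
        self.lim_km = np.array(lim_km)
        self.inh_sub = np.array(inh_sub, dtype=int)
        self.inh_met = np.array(inh_met, dtype=int)
        self.inh_theta = np.array(inh_theta)
        self.inh_n = np.array(inh_n)
        self.mu_max = np.array([s.mu_max for s in model.subpopulations])
        self.ph_opt = np.array([s.ph_opt for s in model.subpopulations])
        self.ph_steep = np.array([s.ph_steep for s in model.subpopulations])
        self.death_rate = np.array([s.death_rate for s in model.subpopulations])
        self.death_tgt = np.array(
            [model.sub_index.get(model.inactive_pool(s.species), -1)
             for s in model.subpopulations], dtype=int)
        self.transitions = [_CompiledTransition(model, r) for r in model.transitions]
        self.acid_coeffs = np.zeros(self.n_met)
        for met, c in model.ph_model.acid_coeffs.items():
            self.acid_coeffs[model.met_index[met]] = c
        self.base_ph = model.ph_model.base_ph
        self.ph_floor = model.ph_model.ph_floor

    def ph_of(self, mets, envp: EnvParams):
        if envp.ph_mode == "fixed":
            return envp.ph_fixed
        return float(np.clip(self.base_ph - self.acid_coeffs @ mets,
                             self.ph_floor, self.base_ph))

    def rhs(self, t, y, envp: EnvParams):
        mets = np.maximum(y[: self.n_met], 0.0)
        cells = np.maximum(y[self.n_met:], 0.0)
        ph = self.ph_of(mets, envp)
        d_met = envp.dilution * (envp.feed - mets)
        # uptake
        prim_flux = np.zeros(self.n_sub)
        if self.up_sub.size:
            s = mets[self.up_met]
            flux = self.up_vmax * (s / (s + self.up_km)) * cells[self.up_sub]
            np.subtract.at(d_met, self.up_met, flux)
            prim_flux[self.up_sub[self.up_prim]] = flux[self.up_prim]
        # production proportional to primary uptake flux
        if self.prod_sub.size:
            np.add.at(d_met, self.prod_met, self.prod_yield * prim_flux[self.prod_sub])
        # growth
        fac = np.ones(self.n_sub)
        if self.lim_sub.size:
            s = mets[self.lim_met]
            np.multiply.at(fac, self.lim_sub, s / (s + self.lim_km))
        if self.inh_sub.size:
            r = (mets[self.inh_met] / self.inh_theta) ** self.inh_n
            np.multiply.at(fac, self.inh_sub, 1.0 / (1.0 + r))
        z = np.clip(self.ph_steep * (ph - self.ph_opt), -500.0, 500.0)
        mu = self.mu_max * fac / (1.0 + np.exp(-z))
        d_cell = (mu - envp.dilution) * cells
        # explicit death rates route into the inactive pool
        if np.any(self.death_rate > 0):
            dflux = self.death_rate * cells
            d_cell -= dflux
            for i in np.nonzero(self.death_rate > 0)[0]:
                if self.death_tgt[i] >= 0:
                    d_cell[self.death_tgt[i]] += dflux[i]
        # Hill-gated transitions
        for tr in self.transitions:
            sig = ph if tr.is_ph else float(mets[tr.sig_idx].sum())
            h = _hill_fast(sig, tr.theta, tr.n, tr.sign)
            if tr.g_idx is not None or getattr(tr, "g_theta", None) is not None:
                if tr.g_idx is None and tr.g_is_ph:
                    gsig = ph
                elif tr.g_idx is not None:
                    gsig = float(mets[tr.g_idx].sum())
                else:  # pragma: no cover
                    gsig = ph
                h *= _hill_fast(gsig, tr.g_theta, tr.g_n, tr.g_sign)
            f = tr.k * h * cells[tr.src]
            d_cell[tr.src] -= f
            d_cell[tr.tgt] += f
        return np.concatenate([d_met, d_cell])


def compile_model(model: CommunityModel) -> CompiledModel:
    return CompiledModel(model)


def rhs(state: CommunityState, env=None, model: CommunityModel = None,
        compiled: CompiledModel = None):
    """Derivative of a :class:`CommunityState` (public convenience wrapper)."""
    if compiled is None:
        compiled = CompiledModel(model)
    model = compiled.model
    envp = resolve_env(model, None) if not isinstance(env, EnvParams) else env
    if env is not None and not isinstance(env, EnvParams):
        # an Environment object: resolve against the model's pH model
        feed = np.zeros(model.n_met)
        for met, conc in env.feed.items():
            feed[model.met_index[met]] = conc
        envp = EnvParams(env.dilution, feed, env.feed_ph,
                         model.ph_model.mode, model.ph_model.fixed_value)
    y = state.to_vector(model)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite state")
    return compiled.rhs(0.0, y, envp)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

class Trajectory:
    """Time course of the community state on a fixed time grid."""

    def __init__(self, times, ys, model, schedule=None):
        self.times = np.asarray(times, dtype=float)
        self.ys = np.asarray(ys, dtype=float)
        self.model = model
        self.schedule = schedule
        if len(self.times) != len(self.ys):
            raise ValueError("times/states length mismatch")

    def state_at(self, i) -> CommunityState:
        envp = resolve_env(self.model,
                           self.schedule.segment_at(self.times[i]) if self.schedule else None)
        cm = CompiledModel(self.model)
        ph = cm.ph_of(np.maximum(self.ys[i][: self.model.n_met], 0.0), envp)
        return CommunityState.from_vector(self.ys[i], self.model, ph=ph)

    @property
    def final_state(self) -> CommunityState:
        return self.state_at(len(self.times) - 1)

    def variable(self, name):
        """Series of one metabolite (mM) or subpopulation (cells/uL)."""
        if name in self.model.met_index:
            return self.ys[:, self.model.met_index[name]]
        return self.ys[:, self.model.n_met + self.model.sub_index[name]]

    def ph_series(self):
        cm = CompiledModel(self.model)
        out = np.empty(len(self.times))
        for i, t in enumerate(self.times):
            envp = resolve_env(self.model,
                               self.schedule.segment_at(t) if self.schedule else None)
            out[i] = cm.ph_of(np.maximum(self.ys[i][: self.model.n_met], 0.0), envp)
        return out

    def species_totals(self, live_only=True):
        out = {}
        for sp in self.model.species:
            idx = [self.model.n_met + self.model.sub_index[s.id]
                   for s in self.model.subs_of(sp, live_only=live_only)]
            out[sp] = self.ys[:, idx].sum(axis=1)
        return out

    def to_frame(self):
        import pandas as pd
        rows = []
        ph = self.ph_series()
        for j, name in enumerate(self.model.met_names):
            for i, t in enumerate(self.times):
                rows.append((t, name, self.ys[i, j], "mM"))
        for j, sid in enumerate(self.model.sub_ids):
            for i, t in enumerate(self.times):
                rows.append((t, sid, self.ys[i, self.model.n_met + j], "cells/uL"))
        for i, t in enumerate(self.times):
            rows.append((t, "pH", ph[i], "pH"))
        return pd.DataFrame(rows, columns=["time_h", "variable", "value", "unit"])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _clip_neg(y, atol):
    worst = float(np.min(y, initial=0.0))
    if worst < -10.0 * atol:
        warnings.warn(f"negative excursion {worst:.3e} clipped to 0", RuntimeWarning)
    np.clip(y, 0.0, None, out=y)
    return y


def simulate(model: CommunityModel, init: CommunityState = None,
             schedule: PerturbationSchedule = None, times=None,
             solver_opts=None) -> Trajectory:
    """Integrate the community model over ``times`` (hours).

    The environment is switched at schedule breakpoints (integration
    restarts at each); mix events instantaneously replace a fraction of
    the culture volume by fresh feed.
    """
    if times is None:
        times = np.linspace(0.0, 120.0, 241)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if init is None:
        init = model.default_init()
    opts = dict(method="LSODA", rtol=1e-6, atol=1e-9)
    if solver_opts:
        opts.update(solver_opts)
    atol = opts["atol"]
    cm = CompiledModel(model)
    t0, t1 = float(times[0]), float(times[-1])
    if schedule is not None:
        schedule.validate(t0, t1)
    # breakpoints: segment edges and event times inside (t0, t1)
    breaks = {t0, t1}
    if schedule is not None:
        for seg in schedule.segments:
            breaks.update([seg.t_start, seg.t_end])
        for ev in schedule.events:
            breaks.add(ev.time)
    breaks = sorted(b for b in breaks if t0 <= b <= t1)
    events = sorted((ev for ev in (schedule.events if schedule else [])
                     if t0 < ev.time <= t1), key=lambda e: e.time)
    ev_by_time = {ev.time: ev for ev in events}

    y = init.to_vector(model)
    out_t, out_y = [t0], [y.copy()]
    for a, b in zip(breaks, breaks[1:]):
        seg = schedule.segment_at(a) if schedule is not None else None
        envp = resolve_env(model, seg)
        t_eval = times[(times > a) & (times < b)]
        t_eval = np.concatenate([[a], t_eval, [b]])
        sol = solve_ivp(cm.rhs, (a, b), y, t_eval=t_eval, args=(envp,), **opts)
        if not sol.success:
            raise RuntimeError(
                f"solver failure at t={sol.t[-1]:.3f} h (state={sol.y[:, -1]}): {sol.message}")
        for ti, yi in zip(sol.t[1:], sol.y.T[1:]):
            yi = _clip_neg(yi.copy(), atol)
            if np.any(np.isin(ti, times)) and ti != b:
                out_t.append(float(ti))
                out_y.append(yi)
        y = _clip_neg(sol.y[:, -1].copy(), atol)
        if b in ev_by_time:
            f = ev_by_time[b].fraction
            envp_next = resolve_env(model, schedule.segment_at(b) if schedule else None)
            y[: model.n_met] = (1 - f) * y[: model.n_met] + f * envp_next.feed
            y[model.n_met:] = (1 - f) * y[model.n_met:]
        if np.any(np.isin(b, times)) and b != t0:
            out_t.append(float(b))
            out_y.append(y.copy())
    # collate exactly onto the requested grid
    out_t = np.asarray(out_t)
    out_y = np.asarray(out_y)
    keep = []
    for t in times:
        idx = np.nonzero(np.isclose(out_t, t, rtol=0.0, atol=1e-9))[0]
        keep.append(idx[-1])
    return Trajectory(times, out_y[keep], model, schedule)


def simulate_euler(model: CommunityModel, init: CommunityState, t_end,
                   dt=1e-3, env_segment: Segment = None, record_every=100):
    """Fixed-step forward-Euler integrator (independent oracle).

    Deliberately naive: no adaptivity, clipping to zero after each
    step.  Used to cross-check the adaptive integration.
    """
    cm = CompiledModel(model)
    envp = resolve_env(model, env_segment)
    y = init.to_vector(model)
    n = int(round(t_end / dt))
    times, ys = [0.0], [y.copy()]
    for i in range(1, n + 1):
        y = y + dt * cm.rhs(i * dt, y, envp)
        np.clip(y, 0.0, None, out=y)
        if i % record_every == 0 or i == n:
            times.append(i * dt)
            ys.append(y.copy())
    return Trajectory(np.asarray(times), np.asarray(ys), model)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def find_steady_state(model: CommunityModel, init: CommunityState = None,
                      env: Segment = None, tol=1e-6, t_max=4000.0,
                      chunk=250.0, polish=False, solver_opts=None):
    """Integrate until the relative derivative norm drops below ``tol``.

    Returns ``(CommunityState, converged)``.  The convergence metric is
    ``max_i |dy_i/dt| / max(|y_i|, 1e-3)`` (units 1/h), so washed-out
    pools do not block convergence.  ``env`` optionally overrides the
    model's baseline environment.  With ``polish=True`` the settled
    state is refined by root finding on the RHS.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if init is None:
        init = model.default_init()
    cm = CompiledModel(model)
    envp = resolve_env(model, env)
    opts = dict(method="LSODA", rtol=1e-6, atol=1e-9)
    if solver_opts:
        opts.update(solver_opts)
    y = init.to_vector(model)
    t, converged = 0.0, False
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(cm.rhs, (t, t_next), y, args=(envp,), **opts)
        if not sol.success:
            raise RuntimeError(f"solver failure at t={sol.t[-1]:.3f} h: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t = t_next
        dy = cm.rhs(t, y, envp)
        metric = float(np.max(np.abs(dy) / np.maximum(np.abs(y), _CONC_FLOOR)))
        if metric < tol:
            converged = True
            break
    if polish and converged:
        res = root(lambda v: cm.rhs(0.0, v, envp), y, method="hybr")
        if res.success and np.all(res.x > -1e-9):
            y = np.clip(res.x, 0.0, None)
    ph = cm.ph_of(np.maximum(y[: model.n_met], 0.0), envp)
    return CommunityState.from_vector(y, model, ph=ph), converged
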