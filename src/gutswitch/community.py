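"""Declarative definition of the kinetic community model.

A :class:`CommunityModel` bundles metabolites, subpopulations (the
metabolic modes of each species, plus one inactive pool per species),
Hill-gated transition rules between subpopulations, a pH model and the
chemostat environment.  The packaged default is a three-species human
gut community -- Blautia hydrogenotrophica (Bh), Bacteroides
thetaiotaomicron (Bt) and Roseburia intestinalis (Ri) -- wired from
monoculture life-history observations: Bh consumes trehalose first and
switches to a glucose-consuming phenotype only when trehalose is
depleted; Bt acidifies the medium and inactivates under nutrient
scarcity in acid; Ri dies rapidly without glucose and shifts to a slow
acetate/lactate-consuming, butyrate-producing mode.

State ordering is fixed: metabolites in the canonical order below, then
subpopulations grouped by species (Bh, Bt, Ri).  All cell pools are in
cells/uL, metabolites in mM, time in hours.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

__all__ = [
    "Metabolite",
    "Subpopulation",
    "Gate",
    "TransitionRule",
    "PHModel",
    "Environment",
    "CommunityModel",
    "CommunityState",
    "build_default_community",
    "METABOLITE_ORDER",
    "SPECIES_ORDER",
]

#: canonical metabolite ordering of the default community
METABOLITE_ORDER = [
    "trehalose", "glucose", "mannose", "pyruvate", "glutamate",
    "acetate", "lactate", "butyrate", "succinate", "formate",
]

SPECIES_ORDER = ["bh", "bt", "ri"]


@dataclass
class Metabolite:
    name: str
    feed_conc: float = 0.0
    init_conc: float = 0.0
    is_organic_acid: bool = False

    def __post_init__(self):
        if self.feed_conc < 0 or self.init_conc < 0:
            raise ValueError(f"negative concentration for metabolite {self.name!r}")


@dataclass
class Subpopulation:
    """One metabolic mode of a species.

    ``uptake`` maps metabolite -> (V_max [mM/(cells/uL)/h], K_M [mM]).
    ``yields`` maps metabolite -> mM produced per mM of the primary
    substrate consumed (substrate-centric stoichiometry).
    ``limiting`` lists the substrates whose Monod factors multiply into
    the growth rate; defaults to the primary substrate alone.
    ``inhibition`` maps metabolite -> (theta, n): repressing Hill
    factors multiplying growth (used e.g. for trehalose repression of
    the glucose-consuming phenotype).
    """

    id: str
    species: str
    state_class: str = "active"
    mu_max: float = 0.0
    uptake: dict = field(default_factory=dict)
    primary: Optional[str] = None
    limiting: Optional[list] = None
    yields: dict = field(default_factory=dict)
    inhibition: dict = field(default_factory=dict)
    ph_opt: float = 4.0
    ph_steep: float = 2.0
    death_rate: float = 0.0

    def __post_init__(self):
        if self.mu_max < 0:
            raise ValueError(f"negative mu_max for {self.id!r}")
        if self.death_rate < 0:
            raise ValueError(f"negative death_rate for {self.id!r}")
        if self.state_class not in ("active", "inactive"):
            raise ValueError(f"bad state_class {self.state_class!r}")
        for met, (vmax, km) in self.uptake.items():
            if vmax <= 0 or km <= 0:
                raise ValueError(f"V_max and K_M must be positive for {self.id}:{met}")
        if self.state_class == "inactive" and (self.mu_max != 0 or self.uptake):
            raise ValueError(f"inactive pool {self.id!r} must have mu_max=0, no uptake")
        if self.primary is None and self.uptake:
            self.primary = next(iter(self.uptake))
        if self.limiting is None:
            self.limiting = [self.primary] if self.primary else []


@dataclass
class Gate:
    """Optional second Hill condition multiplying a transition flux."""

    signal: str | Sequence[str]
    theta: float
    n_hill: float = 2.0
    direction: str = "activating"


@dataclass
class TransitionRule:
    """Hill-gated flux ``k_switch * H(signal) [* H_gate] * [source]``.

    ``signal`` is a metabolite id, a list of metabolite ids (summed
    concentrations), or the string ``"pH"``.
    """

    source: str
    target: str
    signal: str | Sequence[str]
    k_switch: float
    theta: float
    n_hill: float = 2.0
    direction: str = "activating"
    gate: Optional[Gate] = None

    def __post_init__(self):
        if self.k_switch < 0:
            raise ValueError("k_switch must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if self.direction not in ("activating", "repressing"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class PHModel:
    mode: str = "emergent"   # or "fixed"
    fixed_value: float = 6.4
    base_ph: float = 6.4
    acid_coeffs: dict = field(default_factory=dict)  # metabolite -> pH drop per mM
    ph_floor: float = 3.5

    def __post_init__(self):
        if self.mode not in ("emergent", "fixed"):
            raise ValueError(f"bad pH mode {self.mode!r}")


@dataclass
class Environment:
    dilution: float = 0.0            # D, 1/h
    feed: dict = field(default_factory=dict)  # metabolite -> mM in inflow
    feed_ph: float = 6.4

    def __post_init__(self):
        if self.dilution < 0:
            raise ValueError("dilution must be >= 0")


class CommunityModel:
    """Fully resolved community model with a fixed state ordering."""

    def __init__(self, metabolites, subpopulations, transitions, ph_model, environment):
        self.metabolites = list(metabolites)
        self.subpopulations = list(subpopulations)
        self.transitions = list(transitions)
        self.ph_model = ph_model
        self.environment = environment
        self.met_names = [m.name for m in self.metabolites]
        self.sub_ids = [s.id for s in self.subpopulations]
        self.met_index = {n: i for i, n in enumerate(self.met_names)}
        self.sub_index = {s: i for i, s in enumerate(self.sub_ids)}
        self.species = []
        for s in self.subpopulations:
            if s.species not in self.species:
                self.species.append(s.species)
        self.validate()

    # -- resolution & validation ------------------------------------
    def validate(self):
        if len(set(self.met_names)) != len(self.met_names):
            raise ValueError("duplicate metabolite names")
        if len(set(self.sub_ids)) != len(self.sub_ids):
            raise ValueError("duplicate subpopulation ids")
        for sub in self.subpopulations:
            for met in list(sub.uptake) + list(sub.yields) + list(sub.inhibition):
                if met not in self.met_index:
                    raise ValueError(f"unresolved metabolite {met!r} in {sub.id!r}")
            if sub.primary is not None and sub.primary not in sub.uptake:
                raise ValueError(f"primary substrate {sub.primary!r} of {sub.id!r} not in uptake")
        for rule in self.transitions:
            for sid in (rule.source, rule.target):
                if sid not in self.sub_index:
                    raise ValueError(f"unresolved subpopulation {sid!r} in transition")
            self._check_signal(rule.signal)
            if rule.gate is not None:
                self._check_signal(rule.gate.signal)
        for met in self.environment.feed:
            if met not in self.met_index:
                raise ValueError(f"unresolved feed metabolite {met!r}")
        for met in self.ph_model.acid_coeffs:
            if met not in self.met_index:
                raise ValueError(f"unresolved acid metabolite {met!r}")

    def _check_signal(self, signal):
        names = [signal] if isinstance(signal, str) else list(signal)
        for n in names:
            if n != "pH" and n not in self.met_index:
                raise ValueError(f"unresolved signal metabolite {n!r}")

    # -- helpers -----------------------------------------------------
    @property
    def n_met(self):
        return len(self.metabolites)

    @property
    def n_sub(self):
        return len(self.subpopulations)

    def subs_of(self, species, live_only=False):
        return [s for s in self.subpopulations
                if s.species == species and (not live_only or s.state_class == "active")]

    def inactive_pool(self, species):
        for s in self.subpopulations:
            if s.species == species and s.state_class == "inactive":
                return s.id
        return None

    def copy(self):
        return copy.deepcopy(self)

    def feed_vector(self):
        import numpy as np
        v = np.zeros(self.n_met)
        for met, conc in self.environment.feed.items():
            v[self.met_index[met]] = conc
        return v

    def default_init(self, cells_per_species=300.0):
        """Default initial state: WC-medium metabolites, all cells of a
        species in its first declared (live) mode."""
        mets = {m.name: m.init_conc for m in self.metabolites}
        cells = {s.id: 0.0 for s in self.subpopulations}
        for sp in self.species:
            live = self.subs_of(sp, live_only=True)
            if live:
                cells[live[0].id] = cells_per_species
        return CommunityState(cells=cells, mets=mets)

    # -- serialization ----------------------------------------------
    def to_config(self):
        def _sig(s):
            return s if isinstance(s, str) else list(s)

        cfg = {
            "metabolites": [asdict(m) for m in self.metabolites],
            "subpopulations": [
                {**asdict(s),
                 "uptake": {k: list(v) for k, v in s.uptake.items()},
                 "inhibition": {k: list(v) for k, v in s.inhibition.items()}}
                for s in self.subpopulations
            ],
            "transitions": [
                {**{k: v for k, v in asdict(t).items() if k != "gate"},
                 "signal": _sig(t.signal),
                 "gate": None if t.gate is None else {**asdict(t.gate), "signal": _sig(t.gate.signal)}}
                for t in self.transitions
            ],
            "ph_model": asdict(self.ph_model),
            "environment": asdict(self.environment),
        }
        return cfg

    @classmethod
    def from_config(cls, cfg):
        mets = [Metabolite(**m) for m in cfg["metabolites"]]
        subs = []
        for s in cfg["subpopulations"]:
            s = dict(s)
            s["uptake"] = {k: tuple(v) for k, v in s.get("uptake", {}).items()}
            s["inhibition"] = {k: tuple(v) for k, v in s.get("inhibition", {}).items()}
            subs.append(Subpopulation(**s))
        trans = []
        for t in cfg["transitions"]:
            t = dict(t)
            gate = t.pop("gate", None)
            if gate is not None:
                gate = Gate(**gate)
            trans.append(TransitionRule(gate=gate, **t))
        return cls(mets, subs, trans, PHModel(**cfg["ph_model"]), Environment(**cfg["environment"]))

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_config(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        try:
            with open(source) as fh:
                cfg = yaml.safe_load(fh)
        except (OSError, TypeError):
            cfg = yaml.safe_load(source)
        return cls.from_config(cfg)

    def model_hash(self):
        blob = json.dumps(self.to_config(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CommunityState:
    """Concentration snapshot: cell pools (cells/uL), metabolites (mM)."""

    cells: dict
    mets: dict
    ph: Optional[float] = None

    def __post_init__(self):
        if any(v < 0 for v in self.cells.values()) or any(v < 0 for v in self.mets.values()):
            raise ValueError("negative concentration in state")

    def to_vector(self, model):
        import numpy as np
        y = np.zeros(model.n_met + model.n_sub)
        for met, v in self.mets.items():
            y[model.met_index[met]] = v
        for sub, v in self.cells.items():
            y[model.n_met + model.sub_index[sub]] = v
        return y

    @classmethod
    def from_vector(cls, y, model, ph=None):
        import numpy as np
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        mets = {n: float(y[i]) for n, i in model.met_index.items()}
        cells = {s: float(y[model.n_met + i]) for s, i in model.sub_index.items()}
        return cls(cells=cells, mets=mets, ph=ph)

    def species_totals(self, model, live_only=True):
        out = {}
        for sp in model.species:
            out[sp] = sum(self.cells[s.id] for s in model.subs_of(sp, live_only=live_only))
        return out


# ---------------------------------------------------------------------------
# packaged default community (placeholder-calibrated)
# ---------------------------------------------------------------------------

#: calibrated trehalose-repression threshold (mM) of the Bh
#: trehalose->glucose phenotype switch; sets the dilution rate at which
#: the community tips between the Bh-dominated and Ri-permissive states.
TREHALOSE_REPRESSION_THETA = 0.0307
TREHALOSE_REPRESSION_N = 6.0


def default_config():
    """Config dict of the packaged default community.

    Mechanistic wiring (who consumes/produces what, which transitions
    exist and what triggers them) follows the monoculture life-history
    observations; rate constants are placeholder-calibrated: chosen so
    the model reproduces the observed qualitative regimes and the
    reported location of the dilution tipping point, not fitted to the
    original measurements.  WC-medium glucose/pyruvate/mannose/glutamate
    concentrations are unmeasured placeholders (only trehalose, 0.71 mM,
    is a measured value).
    """
    mets = [
        dict(name="trehalose", feed_conc=0.71, init_conc=0.71, is_organic_acid=False),
        dict(name="glucose", feed_conc=5.5, init_conc=5.5, is_organic_acid=False),
        dict(name="mannose", feed_conc=0.25, init_conc=0.25, is_organic_acid=False),
        dict(name="pyruvate", feed_conc=5.0, init_conc=5.0, is_organic_acid=False),
        dict(name="glutamate", feed_conc=2.0, init_conc=2.0, is_organic_acid=False),
        dict(name="acetate", feed_conc=0.0, init_conc=0.0, is_organic_acid=True),
        dict(name="lactate", feed_conc=0.0, init_conc=0.0, is_organic_acid=True),
        dict(name="butyrate", feed_conc=0.0, init_conc=0.0, is_organic_acid=True),
        dict(name="succinate", feed_conc=0.0, init_conc=0.0, is_organic_acid=True),
        dict(name="formate", feed_conc=0.0, init_conc=0.0, is_organic_acid=True),
    ]
    th, nh = TREHALOSE_REPRESSION_THETA, TREHALOSE_REPRESSION_N
    subs = [
        # Blautia hydrogenotrophica: trehalose mode first, glucose mode
        # unlocked (and kept viable) only at low trehalose.
        dict(id="bh_trehalose", species="bh", mu_max=0.15,
             uptake={"trehalose": [2.0e-5, 0.1]},
             yields={"acetate": 1.5, "lactate": 0.3, "formate": 0.8},
             ph_opt=4.0, ph_steep=2.0),
        dict(id="bh_glucose", species="bh", mu_max=0.45,
             uptake={"glucose": [2.0e-5, 0.02], "pyruvate": [1.0e-5, 0.5],
                     "glutamate": [5.0e-6, 1.0]},
             primary="glucose",
             yields={"acetate": 1.5, "lactate": 0.3, "formate": 0.8},
             inhibition={"trehalose": [th, nh]},
             ph_opt=4.2, ph_steep=2.5),
        dict(id="bh_inactive", species="bh", state_class="inactive"),
        # Bacteroides thetaiotaomicron: fast acidifying glucose mode,
        # minor mannose mode, inactivation in acid + scarcity.
        dict(id="bt_glucose", species="bt", mu_max=0.5,
             uptake={"glucose": [2.5e-5, 0.6], "pyruvate": [1.2e-5, 0.5]},
             primary="glucose",
             yields={"acetate": 1.8, "lactate": 0.6, "succinate": 1.2},
             ph_opt=5.5, ph_steep=6.0),
        dict(id="bt_mannose", species="bt", mu_max=0.25,
             uptake={"mannose": [2.0e-5, 0.05], "pyruvate": [1.0e-5, 0.5]},
             primary="mannose",
             yields={"acetate": 1.8, "lactate": 0.6, "succinate": 1.2},
             ph_opt=5.0, ph_steep=6.0),
        dict(id="bt_inactive", species="bt", state_class="inactive"),
        # Roseburia intestinalis: fast glucose mode dying without
        # glucose, slow lactate/acetate mode producing butyrate.
        dict(id="ri_fast", species="ri", mu_max=0.35,
             uptake={"glucose": [2.0e-5, 0.15], "pyruvate": [1.0e-5, 0.5]},
             primary="glucose",
             yields={"acetate": 0.8, "lactate": 0.4, "butyrate": 1.0},
             ph_opt=4.9, ph_steep=4.0),
        dict(id="ri_slow", species="ri", mu_max=0.02,
             uptake={"lactate": [6.0e-6, 1.0], "acetate": [6.0e-6, 1.0]},
             primary="lactate",
             yields={"butyrate": 0.8},
             ph_opt=4.7, ph_steep=4.0),
        dict(id="ri_inactive", species="ri", state_class="inactive"),
    ]
    trans = [
        # Bh phenotype switch: unlocked when trehalose is scarce;
        # trehalose accumulation sends glucose-mode cells back.
        dict(source="bh_trehalose", target="bh_glucose", signal="trehalose",
             k_switch=0.05, theta=th, n_hill=nh, direction="repressing"),
        dict(source="bh_glucose", target="bh_trehalose", signal="trehalose",
             k_switch=0.2, theta=0.1, n_hill=4.0, direction="activating"),
        # Bt: mannose mode engages when glucose runs out; inactivation
        # requires BOTH nutrient scarcity and acidity.
        dict(source="bt_glucose", target="bt_mannose", signal="glucose",
             k_switch=0.1, theta=0.05, n_hill=4.0, direction="repressing"),
        dict(source="bt_glucose", target="bt_inactive",
             signal=["glucose", "pyruvate", "mannose"],
             k_switch=0.4, theta=0.5, n_hill=4.0, direction="repressing",
             gate=dict(signal="pH", theta=5.3, n_hill=8.0, direction="repressing")),
        dict(source="bt_mannose", target="bt_inactive",
             signal=["glucose", "pyruvate", "mannose"],
             k_switch=0.4, theta=0.5, n_hill=4.0, direction="repressing",
             gate=dict(signal="pH", theta=5.3, n_hill=8.0, direction="repressing")),
        # Ri: slow-growth shift in response to lactate+acetate; rapid
        # death in the absence of glucose.
        dict(source="ri_fast", target="ri_slow", signal=["lactate", "acetate"],
             k_switch=0.15, theta=14.0, n_hill=6.0, direction="activating"),
        dict(source="ri_fast", target="ri_inactive", signal="glucose",
             k_switch=0.25, theta=0.03, n_hill=4.0, direction="repressing"),
    ]
    ph_model = dict(mode="emergent", fixed_value=6.4, base_ph=6.4, ph_floor=3.5,
                    acid_coeffs={"acetate": 0.08, "lactate": 0.09, "butyrate": 0.075,
                                 "succinate": 0.1, "formate": 0.06})
    env = dict(dilution=0.0,
               feed={m["name"]: m["feed_conc"] for m in mets},
               feed_ph=6.4)
    return dict(metabolites=mets, subpopulations=subs, transitions=trans,
                ph_model=ph_model, environment=env)


def build_default_community(config=None):
    """Build the packaged three-species community model.

    With no ``config``, the packaged placeholder-calibrated defaults are
    used: 10 metabolites, 6 active metabolic modes plus one inactive
    pool per species (9 cell pools).  ``config`` may be a config dict, a
    YAML string or a path to a YAML file.
    """
    if config is None:
        return CommunityModel.from_config(default_config())
    if isinstance(config, dict):
        return CommunityModel.from_config(config)
    return CommunityModel.from_yaml(config)
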