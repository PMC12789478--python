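"""Phenotype-block generalized Lotka-Volterra formalism.

Species are defined by gLV growth rates and a phenotype-level
interaction matrix; a switching species carries two phenotypes linked
by Hill transition functions of a static environmental factor E.  When
the alternative phenotype interacts strongly (mean interaction
magnitude shifted above the community average), sweeping E across the
Hill threshold tips the community between alternative states; across an
ensemble of random communities with random E this produces two
composition clusters and a bimodal abundance distribution of the
switching species ("tipping element").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import kurtosis, skew

from .kinetics import hill

__all__ = [
    "ToyTransition",
    "ToyModel",
    "ToyEnsemble",
    "make_random_toy",
    "toy_rhs",
    "simulate_toy",
    "ensemble",
    "bimodality_coefficient",
    "enterotype_projection",
    "BIMODALITY_CUTOFF",
]

#: bimodality call threshold: (skew^2+1)/kurtosis of a uniform is 5/9
BIMODALITY_CUTOFF = 5.0 / 9.0

EXTINCTION_THRESHOLD = 1e-6


@dataclass
class ToyTransition:
    source: int          # phenotype index
    target: int
    k_switch: float
    theta: float
    n_hill: float = 4.0
    direction: str = "activating"


@dataclass
class ToyModel:
    """Phenotype-level gLV community with environment-driven switching."""

    n_species: int
    growth: np.ndarray               # per-phenotype intrinsic rates
    interactions: np.ndarray         # per-phenotype matrix A (A[p,q]: effect of q on p)
    phenotype_blocks: dict           # species index -> list of phenotype indices
    transitions: list = field(default_factory=list)
    E: float = 0.5

    def __post_init__(self):
        A = np.asarray(self.interactions, dtype=float)
        if np.any(np.diag(A) >= 0):
            raise ValueError("self-interactions must be negative")
        owner = {}
        for sp, phs in self.phenotype_blocks.items():
            for p in phs:
                if p in owner:
                    raise ValueError(f"phenotype {p} assigned to two species")
                owner[p] = sp
        if sorted(owner) != list(range(len(self.growth))):
            raise ValueError("every phenotype must belong to exactly one species")
        for tr in self.transitions:
            if owner[tr.source] != owner[tr.target]:
                raise ValueError("transitions must connect phenotypes of one species")

    @property
    def n_phenotypes(self):
        return len(self.growth)

    def species_totals(self, x):
        x = np.asarray(x, dtype=float)
        return np.array([x[self.phenotype_blocks[s]].sum()
                         for s in range(self.n_species)])


@dataclass
class ToyEnsemble:
    """Steady-state species-total abundances of many random communities."""

    abundances: np.ndarray      # community x species
    E_values: np.ndarray
    switcher_id: int
    regime: str
    convergence_fraction: float = 1.0


def make_random_toy(n_species=50, switcher_config=None, dist_config=None,
                    seed=0) -> ToyModel:
    """Random phenotype-block gLV community.

    Off-diagonal interactions are N(mean, sd) (default N(-0.1, 0.05)),
    diagonal -1.  One switching species (index 0) carries a second
    phenotype that competes more efficiently: its outgoing interactions
    are drawn with mean and sd magnitudes multiplied by ``strength``
    (default 3) and the competition it receives is damped by
    ``received_scale`` (default 0.2).  ``strength=1`` with
    ``received_scale=1`` gives the matched null regime.  Transitions
    toward the second phenotype activate with E.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    sw = dict(species=0, strength=3.0, received_scale=0.2, k_switch=1.0,
              theta=0.5, n_hill=8.0)
    sw.update(switcher_config or {})
    dist = dict(mean=-0.1, sd=0.05, growth_lo=0.9, growth_hi=1.1)
    dist.update(dist_config or {})
    if dist["sd"] < 0 or dist["growth_lo"] > dist["growth_hi"]:
        raise ValueError("invalid distribution parameters")
    rng = np.random.default_rng(seed)
    n_ph = n_species + 1
    strong = n_species  # extra phenotype index
    switcher = sw["species"]
    A = rng.normal(dist["mean"], dist["sd"], size=(n_ph, n_ph))
    # strong phenotype: hits others harder, is hit softer
    A[:, strong] = rng.normal(dist["mean"] * sw["strength"],
                              dist["sd"] * sw["strength"], size=n_ph)
    A[strong, :] = A[strong, :] * sw["received_scale"]
    np.fill_diagonal(A, -1.0)
    # phenotypes of one species share a niche: full competition block
    A[switcher, strong] = A[strong, switcher] = -1.0
    growth = rng.uniform(dist["growth_lo"], dist["growth_hi"], size=n_ph)
    blocks = {s: [s] for s in range(n_species)}
    blocks[switcher] = [switcher, strong]
    trans = [
        ToyTransition(switcher, strong, sw["k_switch"], sw["theta"],
                      sw["n_hill"], "activating"),
        ToyTransition(strong, switcher, sw["k_switch"], sw["theta"],
                      sw["n_hill"], "repressing"),
    ]
    return ToyModel(n_species=n_species, growth=growth, interactions=A,
                    phenotype_blocks=blocks, transitions=trans)


def toy_rhs(x, E, model: ToyModel):
    """dx_p/dt = x_p (r_p + sum_q A_pq x_q) + switching fluxes."""
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite abundances")
    xx = np.maximum(x, 0.0)
    dx = xx * (model.growth + model.interactions @ xx)
    for tr in model.transitions:
        f = tr.k_switch * hill(E, tr.theta, tr.n_hill, tr.direction) * xx[tr.source]
        dx[tr.source] -= f
        dx[tr.target] += f
    return dx


def simulate_toy(model: ToyModel, init=None, t_end=600.0, opts=None):
    """Integrate to steady state; returns (species_totals, converged).

    Phenotype abundances below the extinction threshold are set to
    zero.  A phenotype counts as settled if its derivative is
    relatively small, or if it is effectively extinct (< 1e-3) and
    still decaying -- near-threshold extinctions approach zero
    exponentially and would otherwise stall the convergence call.
    Unbounded growth is reported as a RuntimeError rather than
    silently truncated.
    """
    if init is None:
        init = np.full(model.n_phenotypes, 0.05)
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("init must be nonnegative")
    options = dict(method="LSODA", rtol=1e-7, atol=1e-10)
    options.update(opts or {})

    def f(t, y):
        return toy_rhs(y, model.E, model)

    sol = solve_ivp(f, (0.0, t_end), init, **options)
    if not sol.success or np.any(np.abs(sol.y[:, -1]) > 1e8):
        raise RuntimeError(f"divergent or failed toy integration: {sol.message}")
    x = np.clip(sol.y[:, -1], 0.0, None)
    x[x < EXTINCTION_THRESHOLD] = 0.0
    dx = toy_rhs(x, model.E, model)
    small = np.abs(dx) / np.maximum(x, 1e-3) < 1e-4
    dying = (x < 1e-3) & (dx <= 0.0)
    converged = bool(np.all(small | dying))
    return model.species_totals(x), converged


def ensemble(n_communities=200, n_species=50, regime="strong", seed=1,
             e_range=(0.0, 1.0), t_end=1000.0) -> ToyEnsemble:
    """Random-community ensemble with per-community random E.

    Each community draws independent interactions and an independent
    environmental factor from the shared regime; rows of the abundance
    matrix come from converged runs only.  Aborts if fewer than half
    converge.
    """
    if n_communities < 2:
        raise ValueError("need at least 2 communities")
    if regime not in ("strong", "null"):
        raise ValueError("regime must be 'strong' or 'null'")
    switcher_cfg = (dict(strength=3.0, received_scale=0.2) if regime == "strong"
                    else dict(strength=1.0, received_scale=1.0))
    rng = np.random.default_rng(seed)
    rows, es = [], []
    n_failed = 0
    for i in range(n_communities):
        model = make_random_toy(n_species, switcher_config=switcher_cfg,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
        model.E = float(rng.uniform(*e_range))
        try:
            totals, ok = simulate_toy(model, t_end=t_end)
        except RuntimeError:
            ok = False
        if ok:
            rows.append(totals)
            es.append(model.E)
        else:
            n_failed += 1
    frac = 1.0 - n_failed / n_communities
    if frac < 0.5:
        raise RuntimeError(
            f"only {frac:.0%} of communities converged (regime={regime}, seed={seed})")
    return ToyEnsemble(abundances=np.array(rows), E_values=np.array(es),
                       switcher_id=0, regime=regime, convergence_fraction=frac)


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient (skewness^2 + 1) / kurtosis with
    population moments and non-excess kurtosis.

    Benchmarks: normal 1/3, uniform 5/9, symmetric two-point mixture 1.
    Values above 5/9 are called bimodal.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 finite values")
    if np.var(v) == 0:
        raise ValueError("zero variance")
    g1 = skew(v, bias=True)
    g2 = kurtosis(v, fisher=False, bias=True)
    return float((g1 ** 2 + 1.0) / g2)


def enterotype_projection(ens: ToyEnsemble, n_clusters=2, random_state=0):
    """PCA of relative abundances plus a 2-cluster k-means partition.

    Returns ``(coords, labels, silhouette, explained_variance)`` with
    coords the first two principal-component scores.  The silhouette
    (Euclidean, on PC1-2) makes "two distinct clusters" an assertable
    number instead of a visual impression.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = np.asarray(ens.abundances, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 communities")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("community with zero total abundance")
    rel = X / totals[:, None]
    centered = rel - rel.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate ensemble: all compositions identical")
    pca = PCA(n_components=2, random_state=random_state)
    coords = pca.fit_transform(rel)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=random_state)
    labels = km.fit_predict(coords)
    sil = float(silhouette_score(coords, labels, metric="euclidean"))
    return coords, labels, sil, pca.explained_variance_ratio_
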