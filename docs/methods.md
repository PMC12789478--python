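# Methods

This note documents the models implemented in `gutswitch`, their
assumptions, the packaged parameter values and how they were chosen,
the synthetic-data generators, and the numerical choices that matter
for reproducing the results.

## 1. The kinetic community model

### State and units

The state vector is `[metabolites, subpopulations]` in a fixed order:
metabolites trehalose, glucose, mannose, pyruvate, glutamate, acetate,
lactate, butyrate, succinate, formate (mM), then cell pools grouped by
species — Bh (trehalose mode, glucose mode, inactive), Bt (glucose
mode, mannose mode, inactive), Ri (fast, slow, inactive) — in cells/µL.
Time is in hours. Inactive pools have zero growth and no uptake; they
are carried (and washed out) by dilution only, mirroring dead cells
that remain countable by flow cytometry.

### Rate laws

- **Uptake** of metabolite *m* by pool *i*: `V_max · m/(m+K_M) · X_i`
  (Monod). Each mode has a *primary* substrate (its namesake).
- **Growth**: `mu_max · ph_factor · monod(primary) · inhibitions`.
  Only the primary substrate is growth-limiting by default
  (configurable per pool via `limiting`); auxiliary substrates
  (pyruvate, glutamate) are consumed opportunistically without gating
  growth. Taking the product over *all* consumed substrates would halt
  growth whenever an auxiliary substrate ran out, which contradicts the
  observed sequential-substrate growth curves.
- **Production**: product *p* is formed at `y_{i,p} ·
  (primary uptake flux of i)` — substrate-centric stoichiometry, so
  product steady states in a chemostat scale with the amount of
  substrate actually converted.
- **pH permissivity**: a logistic factor `1/(1+exp(-steep·(pH-opt)))`,
  equal to ½ at the pool's `ph_opt`. Acid-sensitive pools (Bt modes)
  have a high optimum and steep slope; acid-tolerant pools (Bh
  trehalose mode, Ri) a low optimum.
- **Transitions**: flux `k_switch · H(signal) [· H_gate] · X_source`,
  with `H` an activating or repressing Hill function of a metabolite
  concentration (or a sum of several) or of pH. Death and inactivation
  are transitions into the species' inactive pool, so species totals
  are conserved by switching (only dilution removes cells).
- **Emergent pH**: `pH = clip(base_pH − Σ c_m·[m], floor, base_pH)`
  over the organic acids (acetate, lactate, butyrate, succinate,
  formate), the simplest monotone map from acid accumulation to
  acidification. The coefficients are calibration targets; the floor is
  3.5, the base 6.4 (fresh WC medium).

### Default wiring (life histories)

- **Bh** consumes trehalose first; the trehalose→glucose transition is
  *repressed* by trehalose, and the glucose mode's growth carries the
  same repressing-Hill inhibition (θ = 0.0307 mM, n = 6). Both are
  needed: with transition gating alone, glucose-mode cells seeded
  during the inoculation transient take over at any dilution rate and
  the tipping point disappears. A reverse (trehalose-activated)
  transition returns glucose-mode cells when trehalose accumulates.
- **Bt** races through glucose with a high maximal rate but a high K_M
  (0.6 mM): it dominates batch conversion at high substrate but loses
  the glucose-scarce chemostat competition. Both Bt modes convert to
  the inactive pool under the joint condition *nutrient scarcity AND
  acidity* (repressing Hill on glucose+pyruvate+mannose, gated by a
  repressing Hill on pH below ~5.3).
- **Ri** dies rapidly without glucose (repressing-Hill-gated transition
  to its inactive pool, θ = 0.03 mM) and shifts to the slow mode when
  lactate+acetate accumulate past ~14 mM — batch-fermentation levels,
  not chemostat levels. The slow mode consumes lactate (primary) and
  acetate and produces butyrate; its `mu_max` (0.02 h⁻¹) is below any
  chemostat dilution rate of interest, so it persists only in batch.

### Parameter provenance

The packaged parameters are **placeholder-calibrated**: the wiring
(who eats/produces what, what triggers each switch) follows the
monoculture life-history observations, and the rate constants were
hand-calibrated, once, so the model reproduces the reported qualitative
regimes — sequential trehalose→glucose growth in Bh monoculture, Bt's
boom/crash with acidification, Ri's peak and slow decline, a
Bh-dominated state below and an Ri-dominated state above a critical
dilution rate near 0.040 h⁻¹, and landscape maxima of butyrate and
succinate at zero dilution. They are not fits to the original
measurements; re-calibration against real data is what the
`calibration` module is for. WC-medium glucose (5.5 mM), pyruvate
(5 mM), mannose (0.25 mM) and glutamate (2 mM) are placeholders (only
trehalose, 0.71 mM, and the feed pH, 6.4, are measured values), flagged
as such in the config.

The tipping calibration deserves one note: the critical dilution rate
is controlled by where the chemostat's residual trehalose
`s* ≈ K_M·D/(µ_eff−D)` crosses the repression threshold θ. θ was set by
a secant step on this relation and a numerical refinement of the full
model, landing the Ri-presence boundary at D ≈ 0.0395 h⁻¹.

## 2. Landscape analyses

Sweeps fix pH at the axis value (pH is the controlled variable there)
and solve an independent steady state per grid point from the same
fresh inoculum (300 cells/µL per species, all in each species' first
mode). Dilution-protocol analyses (tipping, hysteresis on the default
community) use emergent pH. Species presence uses summed *live* pools
against an absolute threshold of 1 cell/µL; sensitivity is mild because
steady pools are either far below (washout decays exponentially) or far
above (10²–10⁵ cells/µL) the threshold.

Tipping points are located operationally — bisection on the parameter
with a fresh inoculum per evaluation and a categorical classifier —
not by continuation; that matches how the landscape is actually probed
by simulation and by experiments. Near the boundary, convergence slows
(critical slowing down), so tipping runs use a longer `t_max` (8000 h).

Hysteresis runs settle the system under the baseline, drive it through
a schedule whose last segment restores the baseline, settle again, and
compare live pools above the presence threshold by relative L∞ with
tolerance 0.05.

## 3. The minimal bistable fixture

One species, one substrate (feed 10 mM, D = 0.05 h⁻¹), two phenotypes:

| phenotype | mu_max | K_M | V_max | growth inhibition |
|---|---|---|---|---|
| thrifty | 0.1 h⁻¹ | 2.0 mM | 2·10⁻⁴ | none |
| greedy | 0.5 h⁻¹ | 0.05 mM | 2·10⁻³ | repressing Hill on substrate (θ=0.5 mM, n=4) |

Switching thrifty→greedy is substrate-repressed and greedy→thrifty
substrate-activated (both k = 0.1 h⁻¹, θ = 0.5 mM, n = 4). The two
self-consistent states are: thrifty-dominated with ~2 mM residual
substrate (greedy cannot invade — its growth is substrate-inhibited)
and greedy-dominated with ~6 µM residual (thrifty cannot sustain and
drains into greedy). A 24 h feed stop from the thrifty state depletes
the substrate, converts the population, and the restored feed then
holds the greedy state. With `k_switch = 0` the fixture is a
single-phenotype chemostat and the pulse is fully reversible. A 50×50
brute-force basin map over initial (thrifty, greedy) densities in
[1, 5000] cells/µL finds exactly these two attractors.

## 4. Calibration

The loss is a range-scaled weighted SSE: per variable, residuals are
divided by that variable's observed range, making cell counts
(10⁵ cells/µL) and metabolites (mM) commensurate; pH is up-weighted ×2
because it gates both growth and inactivation. Fitting uses Powell's
derivative-free method on log₁₀-transformed parameters with box bounds
— deterministic, no gradients through the ODE solver. Identifiability
is screened by perturbing each parameter ±50% around the truth: if the
loss changes by less than 1% (relative to the residual scale), the
parameter is flagged non-identifiable and excluded from recovery
summaries. With the packaged batch design this flags the primary-
substrate K_M (0.1–0.15 mM against 5.5 mM starting glucose — the data
contain almost no information about it), while `mu_max`, `V_max` and
the main product yield are recovered within a few percent at 5%
measurement noise.

## 5. The phenotype-block gLV formalism

Phenotype-level gLV: `dx_p/dt = x_p(r_p + Σ_q A_pq x_q) + switching`,
where the switcher species' two phenotypes are joined by Hill
transitions in a static environmental factor E (per-community draw,
uniform on [0,1], threshold 0.5, n = 8, k = 1). Off-diagonal
interactions are N(−0.1, 0.05), diagonal −1; phenotypes of one species
compete fully (−1). Growth rates are U(0.9, 1.1).

The *strong* phenotype is an efficient competitor in both directions:
its outgoing interactions are drawn with mean and sd magnitudes ×3,
and the competition it receives is damped ×0.2. An outgoing shift
alone (the first design tried) is statistically invisible at 50
species — the community-level suppression `ΔA·x` is small against
r ≈ 1 — and the strong/null regimes were indistinguishable. With the
two-sided design the ensemble separates cleanly: communities with
E above threshold collapse into a switcher-dominated composition,
giving two PCA clusters (silhouette ≈ 0.6 vs ≈ 0.33 for the matched
null) and a bimodal switcher abundance (Sarle's coefficient ≈ 0.7 vs
≈ 0.4, cutoff 5/9). All knobs are exposed via `switcher_config` /
`dist_config`.

Sarle's bimodality coefficient uses population moments with non-excess
kurtosis: normal → 1/3, uniform → 5/9, symmetric two-point → 1. The
enterotype projection closes each community to relative abundances
(compositional convention), takes the first two principal components,
partitions with k-means (k = 2, fixed seed) and reports the Euclidean
silhouette on PC1–2.

Steady states of the toy model are accepted when every phenotype either
has a small relative derivative or is effectively extinct (< 10⁻³) and
decaying — near-threshold extinctions decay exponentially and would
otherwise stall the call. Non-converged communities (~25%: slow
extinctions and oscillatory pockets) are dropped and the converged
fraction reported; an ensemble aborts below 50%.

## 6. Time-series state analysis

Variables are min–max scaled to [0,1] per column (constant columns map
to 0), then the Bray–Curtis dissimilarity is computed between each
sample and the sample two *sampling steps* ahead; maximal runs below
the threshold are steady windows. The default threshold is 0.05; it is
an exposed choice, and with 5% multiplicative cell noise the
noise floor of the lag-2 dissimilarity sits near 0.03–0.06, so noisy
series fragment their windows at 0.05 while noise-free series call
settling within ~2 samples of an independent L∞ criterion. Replicates
are analyzed independently. PCA is computed on the scaled, centered
matrix via SVD; components beyond the data's rank are zero and produce
a warning, not an error.

## 7. Synthetic data

The generators emulate the measurement layer of the bioreactor system:
batch monocultures sampled every 4 h for 48 h then every 12 h to 120 h,
3 replicates; chemostats starting with a 4 h batch phase then
D = 0.04 h⁻¹, with protocol templates `control`, `feed_stop` (feed off
108–120 h, then an instantaneous replacement of 50% of the volume by
fresh medium, modeled as a state mix) and `ph_then_feed` (feed pH 3.7
during 88–112 h, feed stop 150–162 h plus the mix). Noise defaults:
multiplicative lognormal with 5% CV on cell counts (unit mean),
additive Gaussian truncated at zero with sd 0.1 mM on metabolites and
0.02 on pH. Every dataset embeds its generating seed and the truth
model's hash.

Not emulated: instrument drift, replicate batch effects, detection
limits, plate-position effects, or additional community members.
Passing tests therefore demonstrate correctness of the procedures under
the stated error model, not robustness to real-world measurement
pathologies.

## 8. Numerics

LSODA with rtol 10⁻⁶, atol 10⁻⁹ throughout; integration restarts at
every schedule breakpoint and event. Negative excursions are clipped to
zero after each segment (warning above 10·atol). Steady states
integrate in 250 h chunks until `max_i |dy_i|/max(|y_i|, 10⁻³)` falls
below 10⁻⁶ h⁻¹ (the floor keeps washed-out pools from blocking the
call); optional polishing by `scipy.optimize.root` gives exact fixed
points (used where a result is compared to an analytic value). The
fixed-step Euler oracle (dt = 10⁻³ h) is deliberately naive and agrees
with the adaptive path to < 10⁻³ relative over 48 h of the default
model.

Problem sizes in the tests and the acceptance script are the package's
defaults for routine runs: landscape grids of 7×9 to 16×21 (the
argmax-at-D=0 property is resolution-independent; a 31×41 display grid
is available via `analysis/03_stability_landscape.py --full`),
ensembles of 200 communities, recovery over 5 seeds, and a 50×50 basin
map.

## 9. Known limitations

- The default parameters are a calibrated *demonstration* set, not a
  fit to measurements; quantitative predictions (e.g. absolute
  metabolite levels) should not be read off them.
- Mannose kinetics are structural placeholders (small feed, one
  consumer mode); the underlying biology is unresolved.
- The emergent-pH map is linear in acid concentrations with uniform
  buffering; real medium buffering is nonlinear.
- Hysteresis of the full default community exists in a narrow window
  around the tipping point; the packaged demonstration of
  history-dependence uses the minimal fixture, where the basin
  structure is fully characterized.
- The toy ensemble treats E as static per community; the dynamic-
  mediator variant (E consumed/produced by species) is not implemented.
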