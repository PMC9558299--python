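# Methods

## Model

The holobiont is a coral host and $k \ge 1$ algal symbiont populations,
each an exponentially growing biomass pool driven by specific rates
(per C-mol per day).  All biological conversions are synthesizing units
(SUs): saturating kinetic operators on one or two substrate arrival rates.
The model's assumptions, in brief:

* **Sharing the surplus.**  Host and symbionts act selfishly: each uses all
  the carbon/nitrogen it can for its own growth and passes only the surplus
  to the partner.  The host cannot favour one symbiont over another; shared
  nitrogen and CCM-delivered CO₂ are divided among symbionts in proportion
  to biomass, so every symbiont sees the same per-C-mol share.
* **CCM feedback.**  Excess host carbon powers a carbon-concentrating
  mechanism delivering CO₂ to photosynthesis ($k_{CO_2} = 10$ mol CO₂ per
  mol fixed C).  This positive loop creates bistability: a healthy,
  nitrogen-limited branch with strong photosynthesis, and a bleached,
  carbon-limited branch where the loop is collapsed.
* **Light as the stressor.**  Absorbed light not used by photochemistry and
  not dissipated by quenching (capacity $k_{NPQ} = 112$) raises relative ROS
  production $c_{ROS}$, which divides photosynthesis and multiplies symbiont
  turnover by $1 + b\,(c_{ROS}-1)$ with $b = 5$.  ROS are local: each
  symbiont species suffers only its own.  Temperature and other stressors
  are not modelled; stress enters only through the light axis.
* **Exponential growth.**  There is no density dependence beyond
  self-shading of light (amplification $A = 1.26 + 1.39\,e^{-6.48\,\Sigma
  S_i/H}$), so in a constant environment one symbiont always excludes the
  other eventually; coexistence in the model is only ever transient.

The symbiont phenotypes differ in three parameters: the sensitive symbiont
has $j_{CPm} = 2.8$, $j_{SGm} = 0.25$ d⁻¹, $k_{ROS} = 80$; the tolerant one
$j_{CPm} = 1.0$, $j_{SGm} = 0.15$ d⁻¹, $k_{ROS} = 250$ (all other
parameters shared).  Reference parameter values ship as JSON documents in
`coralsym/data/` and load as dataclass defaults.  One printed source gives
the tolerant maximum growth rate as 0.1 d⁻¹ in prose where the parameter
table (twice-stated) has 0.15; the package defaults to 0.15 and exposes the
value as an ordinary parameter.

## Numerics

**Lagged-flux Euler integration.**  The SU network is cyclic in two places:
shared carbon → host growth → shared nitrogen → symbiont growth → shared
carbon, and photosynthesis → excess light → ROS → photosynthesis.  Each
Euler step (default `dt = 0.1` d) first advances the biomasses with the
current fluxes, then re-evaluates all fluxes in dependency order using the
previous step's `rho_C`, `j_SG` and `c_ROS` where a cycle would occur.
This treats the fluxes as lagged fast variables; a `fixed_point` mode
iterates the flux map to self-consistency at every step for steady-state
checks.  Outcome classifications are verified to be stable under halving
`dt` on an environment panel.

**Clamps.**  `j_eC` and `j_eL` are clamped at zero: the CCM and quenching
cannot run in reverse, and negative values can only arise as lag/rounding
artifacts (with the lagged scheme the SU output bound in fact keeps both
nonnegative up to float rounding).  Clamp events are counted and
inspectable via `deb_core.clamp_counts()`.  Symbiont biomass that would
overshoot below zero in a step is floored at 0.

**Initializations.**  `init_healthy` sets the fluxes to the fixed point of
the flux map at the initial state under the run's own environment, reached
from an optimistic (saturated-rate) starting guess; plain iteration is
tried first and a damped (half-mixing) fallback breaks the two-cycles that
strong ROS feedback can cause.  Convergence tolerance is a maximum relative
change of 1e-9 across all fluxes.  `init_bleached` anchors the fast
variables at zero host biomass formation and zero photosynthesis and
derives every other flux from those anchors in dependency order — a
slow–fast construction that places a low-symbiont state in the bleached
basin.

**No-symbiont convention.**  When total symbiont biomass is zero the
per-C-mol shares of host nitrogen and CCM carbon are defined as zero (no
recipients); the host then behaves as a plain heterotroph.  Per-C-mol
symbiont rates remain defined (they multiply zero biomass in the state
equations).

**Renormalized survey engine.**  Every flux depends on the biomasses only
through the ratios $S_i/H$, and the Euler update commutes exactly with a
common rescaling of $(H, S)$.  The vectorized survey engine therefore
renormalizes the host to 1 after each step, which leaves growth rates,
shares and all outcome labels unchanged while preventing overflow in
decade-long runs of exponentially growing pools.  Scalar `run()` keeps
absolute biomasses.  Parity between the two paths, and between the
two-symbiont code restricted to one species and an independently coded
one-symbiont stepper, is tested.

## Experiments

All three experiments use a 100-day vitality check: the host is dead if its
specific growth rate $j_{HG} - j_{HT}$ is not positive at day 100.
Vitality is the only "functional symbiosis" criterion applied; the signed
host carbon/nitrogen limitation index (positive = nitrogen-limited, the
healthy signature) is available as an optional diagnostic column so that a
stricter carbon-limitation screen can be applied downstream.

* **Competition**: healthy start, 1 C-mol host, 0.5 C-mol of each
  symbiont; classify the numerically dominant symbiont after 10 years.
* **Exclusion**: healthy start with 0.99 C-mol of the inferior competitor
  and 0.01 C-mol of the winner; record the first time the winner holds 99%
  of the symbiont biomass.  Runs are censored at 25 years — a cap chosen so
  that "slower than 20 years" cases are identifiable rather than truncated
  at the 10-year survey horizon.  Hosts that die from the 99:1 start are
  excluded from timing statistics.
* **Recovery**: bleached start with 1e-4 C-mol of symbiont.  Stage 1 uses
  the sensitive symbiont alone; if the host is not growing by day 100,
  stage 2 restarts with 5e-5 C-mol of each symbiont, and survivors are
  classified by the dominant symbiont at day 1000.

Environments are sampled uniformly over light 5–60 mol photons m⁻² d⁻¹,
DIN 1e-8–1e-5 mol L⁻¹ and prey 0–4e-7 C-mol L⁻¹ — normal through stressful
reef conditions.  The samplers and experiments are deterministic given the
seed and environment list.

**Problem sizes.**  The test suite and `scripts/acceptance.py` use
desk-scale designs chosen once: 500 sampled environments per survey (the
LDA trace shares are stable to ~1 percentage point across seeds at this
size), a 6×6×6 grid for the exclusion minima (grid minima bound
dense-sample minima from above), and a 20-environment panel for the
dt-halving check.

**Dominance-switch summaries.**  Two summaries of where dominance flips
along light are provided.  `dominance_switch_light` scans a transect at
fixed mid-range DIN ($10^{-6.5}$ mol L⁻¹, the geometric midpoint of a
three-decade range) and prey (2e-7 C-mol L⁻¹); the switch location rises
with nitrogen (≈32 at the transect DIN, ≈41 at 1e-6 mol L⁻¹).
`marginal_switch_light` bins a sampled survey by light and reports where
the tolerant-won fraction of surviving outcomes crosses one half — the
histogram view, which lands at 40 under the standard sampling ranges and is
the figure-level summary used by the acceptance script.

## LDA

`discriminant.fit_lda` summarizes a survey by solving the generalized
eigenproblem of between- versus within-class scatter with
class-proportional priors (scikit-learn's eigen solver; eigenvectors are
within-scatter-orthonormal, the classical scaling convention).  Variables
are used untransformed — no standardization, no log axis.  Axis signs are
not identifiable and tests compare axes up to sign.  Variables that are
constant overall are dropped with zero loadings; a variable constant within
every class but varying between classes is reported as a degeneracy.

## What the generator does and does not emulate

The environment sampler reproduces the study design (uniform independent
draws of constant light, DIN and prey).  Real reefs have diel and seasonal
light cycles, correlated nutrient/food fluctuations and temperature
stress, none of which are modelled; a passing survey therefore shows that
the *mechanism* (ROS-mediated trade-off plus surplus sharing) produces the
reported competitive geography under constant forcing, not that the
quantitative thresholds transfer to field conditions.  Within-host symbiont
interactions beyond shared light, nitrogen and CO₂ pools (e.g. direct
interference) are out of scope, as are host control of symbiont ratios and
dissolved-organic-carbon subsidies.

## Known limitations

* Outcomes very close to the dominance switch take decades to resolve;
  with the 25-year cap these appear as `censored` rather than as an exact
  exclusion time.
* The flux fixed point used by `init_healthy` is not guaranteed unique; the
  optimistic start deliberately selects the healthy branch where one
  exists.  The original simulation package's unpublished default flux
  initialization may differ in detail; agreement is established at the
  level of reported outcomes, not flux-by-flux.
* With the fixed 99:1 exclusion design the winner can never already be at
  threshold at t = 0, so a zero exclusion time is unreachable by
  construction.
* Explicit Euler is first-order; `dt` well below 0.1 d sharpens exclusion
  times by a few tenths of a day but does not change labels on the tested
  panels.
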