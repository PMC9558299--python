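"""The three simulation studies and the environment sampler.

* **Competition** — from a healthy 0.5/0.5 C-mol start, which symbiont is
  numerically dominant after 10 simulated years (or ``no_survival`` if host
  growth is not positive at day 100)?
* **Exclusion rate** — from a 99:1 start favouring the *inferior* competitor,
  how long until the winner reaches 99% of the symbiont population?
* **Bleaching recovery** — from a bleached start (1e-4 C-mol of symbiont),
  can the host return to positive growth within 100 days with the first
  (sensitive) symbiont alone; if not, does adding the second (tolerant)
  symbiont rescue it, and who dominates 1000 days in?

Surveys over many environments run through a vectorized engine that steps
all environments simultaneously with numpy broadcasting.  Because every flux
is a specific rate depending only on the biomass *ratios* S_i/H, the engine
renormalizes the host biomass to 1 after each Euler step (an exact symmetry
of the update) so decade-long simulations cannot overflow; growth rates,
dominance and share trajectories are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deb_core import (
    Environment,
    FluxState,
    HolobiontState,
    ParameterError,
    ParameterSet,
    compute_fluxes,
    fixed_point_fluxes,
)
from .simulator import init_bleached

__all__ = [
    "EnvRanges",
    "ExperimentConfig",
    "TieError",
    "NO_SURVIVAL",
    "CENSORED",
    "sample_environments",
    "grid_environments",
    "stack_environments",
    "competition_outcome",
    "time_to_exclusion",
    "recovery_outcome",
    "run_survey",
    "competition_labels",
    "recovery_labels",
    "light_transect",
    "dominance_switch_light",
    "marginal_switch_light",
]

log = logging.getLogger(__name__)

NO_SURVIVAL = "no_survival"
CENSORED = "censored"
EXCLUDED = "excluded"
NO_RECOVERY = "no_recovery"


class TieError(RuntimeError):
    """Symbionts exactly equally abundant at the classification time."""


@dataclass(frozen=True)
class EnvRanges:
    """Sampling ranges for the environmental variables.

    Defaults span normal to stressful reef conditions: light 5–60
    mol photons m^-2 d^-1, dissolved inorganic nitrogen 1e-8–1e-5 mol L^-1,
    prey 0–4e-7 C-mol L^-1.
    """

    light: tuple = (5.0, 60.0)
    din: tuple = (1e-8, 1e-5)
    prey: tuple = (0.0, 4e-7)

    def __post_init__(self):
        for name in ("light", "din", "prey"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"range for {name} must have lo <= hi")


@dataclass(frozen=True)
class ExperimentConfig:
    """Horizons and thresholds shared by the three experiments (days)."""

    vitality_check_day: float = 100.0
    dominance_horizon: float = 3650.0      # 10 years
    exclusion_threshold: float = 0.99
    exclusion_cap: float = 9125.0          # 25 years: censoring horizon
    recovery_horizon: float = 1000.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("vitality_check_day", "dominance_horizon",
                     "exclusion_cap", "recovery_horizon", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.5 < self.exclusion_threshold < 1:
            raise ParameterError("exclusion_threshold must be in (0.5, 1)")


def competition_labels(params: ParameterSet) -> tuple:
    return params.labels + (NO_SURVIVAL,)


def recovery_labels(params: ParameterSet) -> tuple:
    first, second = params.labels[0], params.labels[1]
    return (
        f"recovers_with_{first}",
        f"recovers_with_{second}",
        f"recovers_with_{first}_in_presence_of_{second}",
        NO_RECOVERY,
    )


# ---------------------------------------------------------------------------
# Environment sampling
# ---------------------------------------------------------------------------

def sample_environments(n: int, ranges: EnvRanges = EnvRanges(),
                        seed: int = 0) -> list:
    """``n`` independent uniform draws of (light, DIN, prey); reproducible."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    L = rng.uniform(*ranges.light, size=n)
    N = rng.uniform(*ranges.din, size=n)
    X = rng.uniform(*ranges.prey, size=n)
    return [Environment(light=float(l), din=float(d), prey=float(p))
            for l, d, p in zip(L, N, X)]


def grid_environments(n_light: int = 6, n_din: int = 6, n_prey: int = 6,
                      ranges: EnvRanges = EnvRanges()) -> list:
    """A regular (light x DIN x prey) grid over the sampling ranges."""
    out = []
    for L in np.linspace(*ranges.light, n_light):
        for N in np.linspace(*ranges.din, n_din):
            for X in np.linspace(*ranges.prey, n_prey):
                out.append(Environment(light=float(L), din=float(N), prey=float(X)))
    return out


def stack_environments(envs) -> Environment:
    """Stack scalar environments into one array-valued Environment."""
    return Environment(
        light=np.array([e.light for e in envs], dtype=float),
        din=np.array([e.din for e in envs], dtype=float),
        prey=np.array([e.prey for e in envs], dtype=float),
    )


# ---------------------------------------------------------------------------
# Vectorized stepping engine
# ---------------------------------------------------------------------------

class _Batch:
    """Holobiont ensemble advanced in lockstep over an environment batch.

    Host biomass is renormalized to 1 after every step; all classification
    quantities (growth-rate signs, symbiont shares) are ratio-based and
    therefore unaffected.
    """

    def __init__(self, state: HolobiontState, flux: FluxState,
                 env: Environment, params: ParameterSet, dt: float):
        n = np.asarray(env.light).shape[0]
        k = params.n_symbionts
        H = np.broadcast_to(np.asarray(state.host_biomass, dtype=float), (n,)).copy()
        S = np.broadcast_to(np.asarray(state.symbiont_biomass, dtype=float), (n, k)).copy()
        self.env = env
        self.params = params
        self.dt = dt
        self.step_count = 0
        self.S = S / H[:, None]
        self.H = np.ones(n)
        self.flux = _broadcast_flux(flux, n, k)
        self.active = np.ones(n, dtype=bool)

    @property
    def time(self) -> float:
        return self.step_count * self.dt

    @property
    def shares(self) -> np.ndarray:
        """Per-symbiont share of total symbiont biomass (0 where none left)."""
        tot = self.S.sum(axis=1)
        safe = np.where(tot > 0, tot, 1.0)
        return np.where(tot[:, None] > 0, self.S / safe[:, None], 0.0)

    @property
    def host_growth(self) -> np.ndarray:
        return np.asarray(self.flux.j_HG) - np.asarray(self.flux.j_HT)

    def freeze(self, mask: np.ndarray) -> None:
        """Stop advancing the masked runs (their state is held)."""
        self.active &= ~mask

    def step(self, n_steps: int = 1) -> None:
        for _ in range(n_steps):
            f = self.flux
            gH = 1.0 + (np.asarray(f.j_HG) - np.asarray(f.j_HT)) * self.dt
            gS = 1.0 + (np.asarray(f.j_SG) - np.asarray(f.j_ST)) * self.dt
            H_new = self.H * gH
            S_new = np.maximum(self.S * gS, 0.0)
            # renormalize: fluxes depend only on S/H, so divide out H.
            S_new = S_new / H_new[:, None]
            H_new = np.ones_like(H_new)
            self.H = np.where(self.active, H_new, self.H)
            self.S = np.where(self.active[:, None], S_new, self.S)
            new_flux = compute_fluxes(
                HolobiontState(self.H, self.S), self.env, self.params, self.flux
            )
            self.flux = _merge_flux(new_flux, self.flux, self.active)
            self.step_count += 1


def _broadcast_flux(flux: FluxState, n: int, k: int) -> FluxState:
    out = {}
    for name, v in flux.as_dict().items():
        v = np.asarray(v, dtype=float)
        if name in FluxState.host_fields:
            out[name] = np.broadcast_to(v, (n,)).copy()
        else:
            out[name] = np.broadcast_to(v, (n, k)).copy()
    return FluxState(**out)


def _merge_flux(new: FluxState, old: FluxState, active: np.ndarray) -> FluxState:
    out = {}
    for name, v in new.as_dict().items():
        o = np.asarray(getattr(old, name))
        v = np.asarray(v)
        mask = active if v.ndim == 1 else active[:, None]
        out[name] = np.where(mask, v, o)
    return FluxState(**out)


def _steps(days: float, dt: float) -> int:
    return int(round(days / dt))


def _init_healthy_batch(params: ParameterSet, env: Environment,
                        symbiont0) -> _Batch:
    n = np.asarray(env.light).shape[0]
    s0 = np.broadcast_to(np.asarray(symbiont0, dtype=float),
                         (n, params.n_symbionts)).copy()
    state = HolobiontState(np.ones(n), s0)
    flux = fixed_point_fluxes(state, env, params)
    return state, flux


def _run_vitality(batch: _Batch, check_day: float) -> np.ndarray:
    """Advance to the vitality check; return alive mask and freeze the dead."""
    batch.step(_steps(check_day, batch.dt) - batch.step_count)
    alive = batch.host_growth > 0
    batch.freeze(~alive)
    return alive


# ---------------------------------------------------------------------------
# Experiment outcomes (batch cores + scalar wrappers)
# ---------------------------------------------------------------------------

def _competition_batch(env: Environment, params: ParameterSet,
                       cfg: ExperimentConfig):
    state, flux = _init_healthy_batch(params, env, np.full(params.n_symbionts, 0.5))
    batch = _Batch(state, flux, env, params, cfg.dt)
    alive = _run_vitality(batch, cfg.vitality_check_day)
    batch.step(_steps(cfg.dominance_horizon, cfg.dt) - batch.step_count)
    S = batch.S
    outcomes = np.empty(S.shape[0], dtype=object)
    outcomes[~alive] = NO_SURVIVAL
    dominant = np.argmax(S, axis=1)
    ties = alive & (S[:, 0] == S[:, 1]) if params.n_symbionts == 2 else np.zeros(len(alive), bool)
    if np.any(ties):
        raise TieError("symbionts exactly equally abundant at the horizon")
    labels = np.array(params.labels, dtype=object)
    outcomes[alive] = labels[dominant[alive]]
    detail = np.where(alive, batch.shares[:, 0], np.nan)
    return outcomes, detail, batch


def competition_outcome(env: Environment, params: ParameterSet,
                        cfg: ExperimentConfig = ExperimentConfig()) -> str:
    """Winner of within-host competition from a healthy 0.5/0.5 start.

    Returns the dominant symbiont's label after the 10-year horizon, or
    ``"no_survival"`` if host growth is not positive at the day-100 check.
    """
    if params.n_symbionts != 2:
        raise ParameterError("competition requires exactly two symbionts")
    outcomes, _, _ = _competition_batch(_as_batch_env(env), params, cfg)
    return str(outcomes[0])


def _exclusion_batch(env: Environment, params: ParameterSet,
                     winner_idx: np.ndarray, cfg: ExperimentConfig):
    """99:1 start favouring the loser; time for the winner to reach 99%."""
    n = np.asarray(env.light).shape[0]
    s0 = np.full((n, 2), 0.99)
    s0[np.arange(n), winner_idx] = 0.01
    state, flux = _init_healthy_batch(params, env, s0)
    batch = _Batch(state, flux, env, params, cfg.dt)

    crossing = np.full(n, np.nan)
    idx = np.arange(n)
    win_share = batch.shares[idx, winner_idx]
    crossing[win_share >= cfg.exclusion_threshold] = 0.0

    check = _steps(cfg.vitality_check_day, cfg.dt)
    total = _steps(cfg.exclusion_cap, cfg.dt)
    alive = np.ones(n, dtype=bool)
    for i in range(1, total + 1):
        batch.step()
        if i == check:
            alive = batch.host_growth > 0
            batch.freeze(~alive)
        share = batch.shares[idx, winner_idx]
        hit = np.isnan(crossing) & (share >= cfg.exclusion_threshold) & batch.active
        crossing[hit] = i * cfg.dt
        batch.freeze(hit)
        if not batch.active.any() and i >= check:
            break
    outcomes = np.empty(n, dtype=object)
    outcomes[:] = EXCLUDED
    outcomes[np.isnan(crossing)] = CENSORED
    outcomes[~alive] = NO_SURVIVAL
    crossing[~alive] = np.nan
    return outcomes, crossing


def time_to_exclusion(env: Environment, params: ParameterSet, winner: str,
                      cfg: ExperimentConfig = ExperimentConfig()):
    """Days until ``winner`` reaches the exclusion threshold from a 1% start.

    Returns ``(outcome, time_d)`` where outcome is ``"excluded"`` (time in
    days), ``"censored"`` (cap reached; time is NaN) or ``"no_survival"``
    (host growth not positive at day 100; these runs are excluded from
    exclusion-time statistics).
    """
    if winner not in params.labels:
        raise ParameterError(f"unknown winner label {winner!r}")
    widx = np.array([params.labels.index(winner)])
    outcomes, times = _exclusion_batch(_as_batch_env(env), params, widx, cfg)
    return str(outcomes[0]), float(times[0])


def _recovery_batch(env: Environment, params: ParameterSet,
                    cfg: ExperimentConfig):
    n = np.asarray(env.light).shape[0]
    first, second = params.labels

    # Stage 1: bleached start with the first (sensitive) symbiont alone.
    p1 = params.subset([first])
    state1, flux1 = init_bleached(p1, env, host0=np.ones(n),
                                  total_symbiont0=1e-4, split=np.array([1.0]))
    b1 = _Batch(state1, flux1, env, p1, cfg.dt)
    alive1 = _run_vitality(b1, cfg.vitality_check_day)

    # Stage 2: both symbionts, half the biomass each (same total).
    state2, flux2 = init_bleached(params, env, host0=np.ones(n),
                                  total_symbiont0=1e-4,
                                  split=np.full(2, 0.5))
    b2 = _Batch(state2, flux2, env, params, cfg.dt)
    alive2 = _run_vitality(b2, cfg.vitality_check_day)
    b2.step(_steps(cfg.recovery_horizon, cfg.dt) - b2.step_count)

    S = b2.S
    ties = (~alive1) & alive2 & (S[:, 0] == S[:, 1])
    if np.any(ties):
        raise TieError("symbionts exactly equally abundant at the recovery horizon")

    outcomes = np.empty(n, dtype=object)
    outcomes[:] = NO_RECOVERY
    second_dominant = S[:, 1] > S[:, 0]
    outcomes[(~alive1) & alive2 & second_dominant] = f"recovers_with_{second}"
    outcomes[(~alive1) & alive2 & ~second_dominant] = (
        f"recovers_with_{first}_in_presence_of_{second}"
    )
    outcomes[alive1] = f"recovers_with_{first}"

    detail = np.full(n, np.nan)
    detail[alive1] = 1.0
    two = (~alive1) & alive2
    detail[two] = b2.shares[two, 0]
    return outcomes, detail, b2


def recovery_outcome(env: Environment, params: ParameterSet,
                     cfg: ExperimentConfig = ExperimentConfig()) -> str:
    """Four-way post-bleaching classification for one environment.

    Stage 1 starts bleached with the first symbiont alone (1e-4 C-mol); if
    host growth is positive at day 100 the outcome is recovery with that
    symbiont.  Otherwise stage 2 starts bleached with both symbionts (5e-5
    C-mol each): death at day 100 means no recovery, survival is labelled by
    the numerically dominant symbiont at the 1000-day horizon.
    """
    if params.n_symbionts != 2:
        raise ParameterError("recovery requires exactly two symbionts")
    outcomes, _, _ = _recovery_batch(_as_batch_env(env), params, cfg)
    return str(outcomes[0])


def _as_batch_env(env: Environment) -> Environment:
    if np.asarray(env.light).ndim == 0:
        return stack_environments([env])
    return env


def _host_limitation(batch: _Batch) -> np.ndarray:
    """Signed host C/N limitation index at the final state (positive:
    nitrogen-limited, the healthy signature; negative: carbon-limited)."""
    hp = batch.params.host
    f = batch.flux
    carbon = hp.y_C * ((np.asarray(f.rho_C) * batch.S).sum(axis=1) / batch.H
                       + np.asarray(f.j_X))
    nitrogen = (np.asarray(f.j_N) + hp.n_NX * np.asarray(f.j_X)
                + np.asarray(f.r_NH)) / hp.n_NH
    out = np.full(batch.H.shape, np.nan)
    ok = (carbon > 0) & (nitrogen > 0)
    if np.any(ok):
        out[ok] = np.log(np.minimum(carbon[ok], hp.j_HGm)
                         / np.minimum(nitrogen[ok], hp.j_HGm))
    return out


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def run_survey(envs, experiment: str, params: ParameterSet,
               cfg: ExperimentConfig = ExperimentConfig(),
               diagnostics: bool = False) -> pd.DataFrame:
    """Run one experiment over an environment list; one row per environment.

    Columns: ``light, din, prey, outcome, detail``.  ``detail`` is the final
    share of the first symbiont (competition/recovery) or the exclusion time
    in days.  For ``experiment="exclusion"`` the winner in each environment
    is determined by a competition run first, as in the original study design;
    environments without a surviving two-symbiont start are ``no_survival``.
    With ``diagnostics=True`` a ``host_cn_limitation`` column is appended
    (positive: nitrogen-limited host; negative: carbon-limited).
    """
    if experiment not in ("competition", "exclusion", "recovery"):
        raise ParameterError(f"unknown experiment {experiment!r}")
    cols = {
        "light": np.array([e.light for e in envs], dtype=float),
        "din": np.array([e.din for e in envs], dtype=float),
        "prey": np.array([e.prey for e in envs], dtype=float),
    }
    if len(envs) == 0:
        frame = pd.DataFrame({**cols, "outcome": np.array([], dtype=object),
                              "detail": np.array([], dtype=float)})
        return frame
    env = stack_environments(envs)
    log.info("survey %s: %d environments", experiment, len(envs))
    if experiment == "competition":
        outcomes, detail, batch = _competition_batch(env, params, cfg)
    elif experiment == "recovery":
        outcomes, detail, batch = _recovery_batch(env, params, cfg)
    else:
        comp, _, _ = _competition_batch(env, params, cfg)
        labels = np.array(params.labels, dtype=object)
        survived = comp != NO_SURVIVAL
        winner_idx = np.where(comp == labels[0], 0, 1)
        outcomes = np.empty(len(envs), dtype=object)
        detail = np.full(len(envs), np.nan)
        winner = np.where(survived, labels[winner_idx], None)
        batch = None
        if np.any(survived):
            sub_env = Environment(light=np.asarray(env.light)[survived],
                                  din=np.asarray(env.din)[survived],
                                  prey=np.asarray(env.prey)[survived])
            out_s, t_s = _exclusion_batch(sub_env, params,
                                          winner_idx[survived], cfg)
            outcomes[survived] = out_s
            detail[survived] = t_s
        outcomes[~survived] = NO_SURVIVAL
    frame = pd.DataFrame({**cols, "outcome": outcomes, "detail": detail})
    if diagnostics and experiment == "exclusion":
        frame["winner"] = winner
    if diagnostics and batch is not None:
        frame["host_cn_limitation"] = _host_limitation(batch)
    log.info("survey %s done: %s", experiment,
             dict(pd.Series(outcomes).value_counts()))
    return frame


# ---------------------------------------------------------------------------
# Transect helpers
# ---------------------------------------------------------------------------

MID_DIN = 10 ** -6.5   # geometric mid of the DIN range (log-spanning variable)
MID_PREY = 2e-7        # linear mid of the prey range


def light_transect(n: int = 23, lo: float = 5.0, hi: float = 60.0,
                   din: float = MID_DIN, prey: float = MID_PREY) -> list:
    """Environments along a light gradient at fixed mid-range DIN and prey."""
    return [Environment(light=float(L), din=din, prey=prey)
            for L in np.linspace(lo, hi, n)]


def marginal_switch_light(frame: pd.DataFrame, winner_label: str = "tolerant",
                          bin_width: float = 5.0, lo: float = 5.0,
                          hi: float = 60.0) -> float:
    """Light at which competitive dominance flips in a sampled survey.

    Mirrors the stacked-histogram view of a competition survey: among
    environments where either symbiont wins, the fraction won by
    ``winner_label`` (the high-light competitor) is computed per light bin,
    and the switch is the bin edge where that fraction crosses one half.
    """
    two_way = frame[frame.outcome != NO_SURVIVAL]
    if two_way.outcome.nunique() < 2:
        raise RuntimeError("survey has no dominance switch")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(two_way.light, edges) - 1, 0, len(edges) - 2)
    frac = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum():
            frac[b] = np.mean(two_way.outcome[sel].to_numpy() == winner_label)
    below = np.where(frac < 0.5)[0]
    above = np.where(frac > 0.5)[0]
    if len(below) == 0 or len(above) == 0 or above.min() < below.max():
        raise RuntimeError("no clean dominance flip along light")
    return float(edges[above.min()])


def dominance_switch_light(params: ParameterSet,
                           cfg: ExperimentConfig = ExperimentConfig(),
                           n: int = 23, lo: float = 5.0, hi: float = 60.0,
                           din: float = MID_DIN, prey: float = MID_PREY) -> float:
    """Light level where competitive dominance flips along the transect.

    Returns the midpoint between the last light at which the first symbiont
    wins and the first light at which the second wins (surviving points only).
    """
    envs = light_transect(n, lo, hi, din, prey)
    frame = run_survey(envs, "competition", params, cfg)
    first, second = params.labels
    win1 = frame.loc[frame.outcome == first, "light"]
    win2 = frame.loc[frame.outcome == second, "light"]
    if win1.empty or win2.empty:
        raise RuntimeError("no dominance switch on this transect")
    return float((win1.max() + win2.min()) / 2.0)
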