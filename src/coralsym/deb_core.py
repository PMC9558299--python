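"""Core flux equations of the coral–symbiont Dynamic Energy Budget model.

The holobiont is modelled as a coral host exchanging metabolites with one or
more algal symbiont populations.  Each biological conversion (feeding, biomass
synthesis, photosynthesis, quenching) is a *synthesizing unit* (SU): a
saturating kinetic operator that turns one or two substrate arrival rates into
a product-formation rate.  The host and symbionts "share the surplus": the
host passes on nitrogen it cannot use for growth, the symbionts pass on fixed
carbon they cannot use, and surplus host carbon powers a carbon-concentrating
mechanism (CCM) that feeds CO2 back to symbiont photosynthesis — the positive
feedback responsible for bistability (healthy vs bleached states).

All rate functions are *specific* rates (per C-mol of host or symbiont
biomass, per day) and accept scalars or numpy arrays; host-level quantities
broadcast against per-symbiont quantities whose trailing axis indexes the
symbiont species.  This lets one code path serve single simulations and
vectorized environment surveys.

The flux network is cyclic (shared carbon -> host growth -> shared nitrogen ->
symbiont growth -> shared carbon; and photosynthesis -> excess light -> ROS ->
photosynthesis).  :func:`compute_fluxes` breaks the cycles by taking the
previous step's fluxes ("lagged" values) where a current value would be
circular; :func:`fixed_point_fluxes` iterates this map at a frozen state to a
self-consistent flux set.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "DomainError",
    "FixedPointError",
    "Environment",
    "HostParams",
    "SymbiontParams",
    "ParameterSet",
    "HolobiontState",
    "FluxState",
    "su_single",
    "su_parallel",
    "light_amplification",
    "limitation_index",
    "compute_fluxes",
    "fixed_point_fluxes",
    "optimistic_fluxes",
    "default_params",
    "clamp_counts",
    "reset_clamp_counts",
]


class ParameterError(ValueError):
    """A parameter is outside its admissible range."""


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class FixedPointError(RuntimeError):
    """Flux fixed-point iteration failed to converge."""


# Counters for the rare clamps applied to transiently negative fluxes
# (lag artifacts only; the CCM and NPQ cannot run in reverse).
_CLAMPS = {"j_eC": 0, "j_eL": 0}


def clamp_counts() -> dict:
    """Return a copy of the clamp-event counters."""
    return dict(_CLAMPS)


def reset_clamp_counts() -> None:
    for k in _CLAMPS:
        _CLAMPS[k] = 0


# ---------------------------------------------------------------------------
# Synthesizing-unit primitives
# ---------------------------------------------------------------------------

def su_single(max_rate, input_flux):
    """Single-substrate synthesizing unit ``(m^-1 + x^-1)^-1``.

    Parameters
    ----------
    max_rate : float or ndarray
        Maximum product-formation rate ``m`` (> 0).
    input_flux : float or ndarray
        Substrate arrival rate ``x`` (>= 0).

    Returns
    -------
    Product-formation rate; ``0`` in the continuous limit ``x -> 0`` and
    never exceeding ``min(m, x)``.
    """
    m = np.asarray(max_rate, dtype=float)
    x = np.asarray(input_flux, dtype=float)
    if np.any(m <= 0):
        raise ParameterError("su_single: max_rate must be strictly positive")
    if np.any(x < 0):
        raise DomainError("su_single: input_flux must be nonnegative")
    # (1/m + 1/x)^-1 == m*x/(m+x), with the removable singularity at x=0.
    out = m * x / (m + x)
    if out.ndim == 0:
        return float(out)
    return out


def su_parallel(max_rate, input_a, input_b):
    """Parallel complementary SU for two jointly required substrates.

    Evaluates ``(m^-1 + x^-1 + y^-1 - (x+y)^-1)^-1``: both substrates are
    needed, arrivals are not stored, and the rate saturates at ``m``.  The
    result is 0 whenever either substrate is absent and reduces to
    :func:`su_single` in ``x`` as ``y -> inf``.
    """
    m = np.asarray(max_rate, dtype=float)
    x = np.asarray(input_a, dtype=float)
    y = np.asarray(input_b, dtype=float)
    if np.any(m <= 0):
        raise ParameterError("su_parallel: max_rate must be strictly positive")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("su_parallel: substrate fluxes must be nonnegative")
    x, y, m = np.broadcast_arrays(x, y, m)
    ok = (x > 0) & (y > 0)
    xs = np.where(ok, x, 1.0)
    ys = np.where(ok, y, 1.0)
    denom = 1.0 / m + 1.0 / xs + 1.0 / ys - 1.0 / (xs + ys)
    out = np.where(ok, 1.0 / denom, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def light_amplification(total_symbiont, host):
    """Skeleton light amplification ``A = 1.26 + 1.39 exp(-6.48 * S/H)``.

    The coral skeleton scatters downwelling light (amplification up to 2.65
    for a bare skeleton) while symbiont cells self-shade, so A decays toward
    1.26 as the symbiont-to-host biomass ratio ``S/H`` grows.
    """
    s = np.asarray(total_symbiont, dtype=float)
    h = np.asarray(host, dtype=float)
    if np.any(h <= 0):
        raise DomainError("light_amplification: host biomass must be positive")
    if np.any(s < 0):
        raise DomainError("light_amplification: symbiont biomass must be >= 0")
    out = 1.26 + 1.39 * np.exp(-6.48 * s / h)
    if out.ndim == 0:
        return float(out)
    return out


def limitation_index(input_a, input_b, max_rate):
    """Which substrate limits a two-substrate SU: ``log(min(a,m)/min(b,m))``.

    Positive values mean substrate *b* (the second input) is limiting,
    negative values mean substrate *a* is; 0 means the substrates are equally
    limiting or the SU runs at its maximum rate.  For the host growth SU with
    carbon first and nitrogen second, healthy (nitrogen-limited) holobionts
    give positive values and bleached (carbon-limited) ones negative values.
    """
    a = np.asarray(input_a, dtype=float)
    b = np.asarray(input_b, dtype=float)
    m = np.asarray(max_rate, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0) or np.any(m <= 0):
        raise DomainError("limitation_index: all arguments must be positive")
    out = np.log(np.minimum(a, m) / np.minimum(b, m))
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class Environment:
    """Environmental forcing: light, dissolved inorganic nitrogen, prey.

    Attributes
    ----------
    light : float or ndarray
        Downwelling irradiance L, mol photons m^-2 d^-1.
    din : float or ndarray
        Dissolved inorganic nitrogen N, mol L^-1.
    prey : float or ndarray
        Prey carbon concentration X, C-mol L^-1.
    """

    light: object
    din: object
    prey: object
    light_max: float = 100.0

    def __post_init__(self):
        L = np.asarray(self.light, dtype=float)
        N = np.asarray(self.din, dtype=float)
        X = np.asarray(self.prey, dtype=float)
        if np.any(L < 0) or np.any(N < 0) or np.any(X < 0):
            raise ParameterError("Environment fields must be nonnegative")
        if np.any(L > self.light_max):
            raise ParameterError(
                f"light exceeds validity range [0, {self.light_max}]"
            )


@dataclass(frozen=True)
class HostParams:
    """Coral-host parameters (defaults: the model's reference coral).

    Units: rates are specific rates, d^-1 or mol (C-mol host)^-1 d^-1;
    half-saturation constants share the units of the matching environmental
    variable.
    """

    n_NH: float = 0.18     # N:C molar ratio of host biomass
    n_NX: float = 0.2      # N:C molar ratio of prey
    j_HT0: float = 0.03    # host biomass turnover (maintenance) rate, d^-1
    sigma_NH: float = 0.9  # fraction of turnover N recycled
    sigma_CH: float = 0.1  # fraction of metabolic CO2 recycled to photosynthesis
    j_Xm: float = 0.13     # max prey assimilation rate
    K_X: float = 1e-6      # prey half-saturation, C-mol L^-1
    j_Nm: float = 0.035    # max DIN uptake rate
    K_N: float = 1.5e-6    # DIN half-saturation, mol L^-1
    k_CO2: float = 10.0    # CCM efficacy, mol CO2 per mol fixed C
    j_HGm: float = 1.0     # max specific host growth rate, d^-1
    y_C: float = 0.8       # yield of biomass from carbon (shared with symbionts)

    def __post_init__(self):
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"host parameter {f.name} must be > 0")
        _require(0 <= self.sigma_NH <= 1, "sigma_NH must be in [0, 1]")
        _require(0 <= self.sigma_CH <= 1, "sigma_CH must be in [0, 1]")
        _require(0 < self.y_C <= 1, "y_C must be in (0, 1]")


@dataclass(frozen=True)
class SymbiontParams:
    """Parameters of one symbiont species.

    The stress-sensitive and stress-tolerant phenotypes differ in three
    parameters: ``k_ROS`` (unquenched light that doubles ROS production;
    80 vs 250), ``j_CPm`` (max photosynthesis; 2.8 vs 1.0) and ``j_SGm``
    (max growth; 0.25 vs 0.15).  Defaults are the sensitive symbiont.
    """

    label: str = "sensitive"
    n_NS: float = 0.13     # N:C molar ratio of symbiont biomass
    j_ST0: float = 0.03    # baseline biomass turnover, d^-1
    sigma_NS: float = 0.9  # fraction of baseline-turnover N recycled
    sigma_CS: float = 0.9  # fraction of metabolic CO2 recycled
    y_CL: float = 0.1      # quantum yield, mol C per mol photons
    a_star: float = 1.34   # light-absorbing cross-section, m^2 (C-mol)^-1
    k_NPQ: float = 112.0   # nonphotochemical-quenching capacity
    k_ROS: float = 80.0    # excess photons doubling ROS production
    j_CPm: float = 2.8     # max specific photosynthesis rate
    j_SGm: float = 0.25    # max specific growth rate, d^-1
    b: float = 5.0         # bleaching-response scaling

    def __post_init__(self):
        for f in fields(self):
            if f.name == "label":
                continue
            _require(getattr(self, f.name) > 0, f"symbiont parameter {f.name} must be > 0")
        _require(0 <= self.sigma_NS <= 1, "sigma_NS must be in [0, 1]")
        _require(0 <= self.sigma_CS <= 1, "sigma_CS must be in [0, 1]")

    @classmethod
    def sensitive(cls) -> "SymbiontParams":
        return cls(label="sensitive")

    @classmethod
    def tolerant(cls) -> "SymbiontParams":
        return cls(label="tolerant", k_ROS=250.0, j_CPm=1.0, j_SGm=0.15)


class _SymArrays:
    """Per-symbiont parameters stacked into length-k vectors for broadcasting."""

    _FIELDS = ("n_NS", "j_ST0", "sigma_NS", "sigma_CS", "y_CL",
               "a_star", "k_NPQ", "k_ROS", "j_CPm", "j_SGm", "b")

    def __init__(self, symbionts: Sequence[SymbiontParams]):
        for name in self._FIELDS:
            setattr(self, name, np.array([getattr(s, name) for s in symbionts]))


@dataclass(frozen=True)
class ParameterSet:
    """Host parameters plus an ordered list of symbiont parameterizations."""

    host: HostParams
    symbionts: tuple

    def __post_init__(self):
        _require(len(self.symbionts) >= 1, "at least one symbiont is required")
        labels = [s.label for s in self.symbionts]
        _require(len(set(labels)) == len(labels), "symbiont labels must be unique")

    @property
    def n_symbionts(self) -> int:
        return len(self.symbionts)

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.symbionts)

    @property
    def sym(self) -> _SymArrays:
        return _SymArrays(self.symbionts)

    def subset(self, labels: Sequence[str]) -> "ParameterSet":
        """A ParameterSet keeping only the named symbionts (order preserved)."""
        keep = tuple(s for s in self.symbionts if s.label in set(labels))
        if len(keep) != len(labels):
            raise ParameterError(f"unknown symbiont label(s) in {labels}")
        return ParameterSet(host=self.host, symbionts=keep)


def default_params() -> ParameterSet:
    """The reference two-symbiont parameter set (sensitive first, tolerant second)."""
    return ParameterSet(
        host=HostParams(),
        symbionts=(SymbiontParams.sensitive(), SymbiontParams.tolerant()),
    )


@dataclass
class HolobiontState:
    """Slow variables: host biomass H and per-symbiont biomasses S_i (C-mol).

    ``symbiont_biomass`` has the symbiont species on its trailing axis, in
    the order of the matching ``ParameterSet.symbionts``.
    """

    host_biomass: object
    symbiont_biomass: object

    def __post_init__(self):
        self.host_biomass = np.asarray(self.host_biomass, dtype=float)
        self.symbiont_biomass = np.asarray(self.symbiont_biomass, dtype=float)
        if np.any(self.host_biomass <= 0):
            raise ParameterError("host biomass must be strictly positive")
        if np.any(self.symbiont_biomass < 0):
            raise ParameterError("symbiont biomasses must be nonnegative")

    @property
    def total_symbiont(self):
        return self.symbiont_biomass.sum(axis=-1)

    def copy(self) -> "HolobiontState":
        return HolobiontState(self.host_biomass.copy(), self.symbiont_biomass.copy())


_HOST_FLUXES = ("j_X", "j_N", "j_HG", "j_HT", "r_NH", "rho_N",
                "j_eC", "j_CO2", "r_CH", "amplification")
_SYM_FLUXES = ("j_L", "r_CS", "j_CP", "j_eL", "j_NPQ",
               "c_ROS", "r_NS", "j_SG", "rho_C", "j_ST")


@dataclass
class FluxState:
    """Fast variables: every specific rate of the model at one instant.

    Host-level fields broadcast like the host biomass; per-symbiont fields
    carry the symbiont species on the trailing axis.  In the lagged-update
    scheme a FluxState doubles as the "previous step" input that breaks the
    algebraic loops of the SU network.
    """

    j_X: object
    j_N: object
    j_HG: object
    j_HT: object
    r_NH: object
    rho_N: object
    j_eC: object
    j_CO2: object
    r_CH: object
    amplification: object
    j_L: object
    r_CS: object
    j_CP: object
    j_eL: object
    j_NPQ: object
    c_ROS: object
    r_NS: object
    j_SG: object
    rho_C: object
    j_ST: object

    host_fields = _HOST_FLUXES
    symbiont_fields = _SYM_FLUXES

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def copy(self) -> "FluxState":
        return FluxState(**{k: np.array(v, dtype=float)
                            for k, v in self.as_dict().items()})

    def max_relative_difference(self, other: "FluxState") -> float:
        """max over fields of |a-b| / max(|a|, |b|, 1e-12)."""
        worst = 0.0
        for name, a in self.as_dict().items():
            b = getattr(other, name)
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-12)
            worst = max(worst, float(np.max(np.abs(a - b) / denom)))
        return worst


# ---------------------------------------------------------------------------
# Flux evaluation
# ---------------------------------------------------------------------------

def _pos(x):
    """Positive part (x)_+."""
    return np.maximum(x, 0.0)


def compute_fluxes(state: HolobiontState, env: Environment,
                   params: ParameterSet, lagged: FluxState) -> FluxState:
    """Evaluate every model flux at ``state`` under ``env``.

    The evaluation follows the dependency order of the flux network, using
    ``lagged`` (the previous step's fluxes) exactly where the network is
    cyclic: the symbionts' shared carbon ``rho_C`` and growth ``j_SG`` feed
    host-side fluxes, and the ROS factor ``c_ROS`` divides photosynthesis.
    Everything else is computed from current values.

    With no symbionts present (sum S_i = 0) the per-C-mol shares of host
    nitrogen and CCM carbon are defined as 0 — there is nobody to receive
    them — and the host side reduces to a plain heterotroph.
    """
    hp = params.host
    sp = params.sym

    H = np.asarray(state.host_biomass, dtype=float)
    S = np.asarray(state.symbiont_biomass, dtype=float)
    if S.shape[-1] != params.n_symbionts:
        raise ParameterError("state has wrong number of symbiont species")
    for name in ("rho_C", "j_SG"):
        if np.any(np.asarray(getattr(lagged, name)) < 0):
            raise DomainError(f"lagged flux {name} must be nonnegative")
    if np.any(np.asarray(lagged.c_ROS) < 1):
        raise DomainError("lagged c_ROS must be >= 1")

    L = np.asarray(env.light, dtype=float)
    N = np.asarray(env.din, dtype=float)
    X = np.asarray(env.prey, dtype=float)

    one = np.ones(np.broadcast_shapes(H.shape, L.shape))

    # Host assimilation (Michaelis-Menten in prey and DIN).
    j_X = hp.j_Xm * X / (X + hp.K_X) * one
    j_N = hp.j_Nm * N / (N + hp.K_N) * one

    # Light: skeleton amplification and per-symbiont absorption.
    Ssum = S.sum(axis=-1)
    A = np.asarray(light_amplification(Ssum, H)) * one
    j_L = (A * L)[..., None] * sp.a_star

    # Host maintenance and recycled nitrogen.
    j_HT = hp.j_HT0 * one
    r_NH = hp.sigma_NH * hp.n_NH * j_HT

    # Host growth SU: carbon from symbiont surplus (lagged) + prey; nitrogen
    # from DIN, prey and recycled turnover.
    rho_C_total = (np.asarray(lagged.rho_C) * S).sum(axis=-1) / H
    carbon_in = hp.y_C * (rho_C_total + j_X)
    nitrogen_in = (j_N + hp.n_NX * j_X + r_NH) / hp.n_NH
    j_HG = np.asarray(su_parallel(hp.j_HGm, carbon_in, nitrogen_in)) * one

    # Surpluses rejected by the host growth SU.
    rho_N = _pos(j_N + hp.n_NX * j_X + r_NH - hp.n_NH * j_HG)
    j_eC_raw = j_X + rho_C_total - j_HG / hp.y_C
    if np.any(j_eC_raw < 0):
        _CLAMPS["j_eC"] += int(np.count_nonzero(j_eC_raw < 0))
    j_eC = _pos(j_eC_raw)

    # CCM-delivered CO2 and recycled host CO2.
    j_CO2 = hp.k_CO2 * j_eC
    r_CH = hp.sigma_CH * (j_HT + (1.0 - hp.y_C) * j_HG / hp.y_C)

    # Host-level pools divided per C-mol of symbiont biomass.
    share = np.where(Ssum > 0, H / np.where(Ssum > 0, Ssum, 1.0), 0.0)

    # Symbiont CO2 recycling (lagged growth feeds metabolic CO2).
    r_CS = sp.sigma_CS * (sp.j_ST0 + (1.0 - hp.y_C) * np.asarray(lagged.j_SG) / hp.y_C)

    # Photosynthesis SU (light x CO2), throttled by lagged ROS.
    co2_in = (j_CO2 + r_CH)[..., None] * share[..., None] + r_CS
    j_CP = np.asarray(su_parallel(sp.j_CPm, sp.y_CL * j_L, co2_in)) / np.asarray(lagged.c_ROS)

    # Excess light, quenching, ROS.
    j_eL_raw = j_L - j_CP / sp.y_CL
    if np.any(j_eL_raw < 0):
        _CLAMPS["j_eL"] += int(np.count_nonzero(j_eL_raw < 0))
    j_eL = _pos(j_eL_raw)
    j_NPQ = np.asarray(su_single(sp.k_NPQ, j_eL))
    c_ROS = 1.0 + _pos(j_eL - j_NPQ) / sp.k_ROS

    # Symbiont nitrogen recycling and growth SU (photosynthate x nitrogen).
    r_NS = sp.sigma_NS * sp.n_NS * sp.j_ST0 * np.ones_like(j_L)
    n_in_S = (rho_N[..., None] * share[..., None] + r_NS) / sp.n_NS
    j_SG = np.asarray(su_parallel(sp.j_SGm, hp.y_C * j_CP, n_in_S))

    # Carbon surplus shared with the host; ROS-scaled turnover.
    rho_C = _pos(j_CP - j_SG / hp.y_C)
    j_ST = sp.j_ST0 * (1.0 + sp.b * (c_ROS - 1.0))

    return FluxState(
        j_X=j_X, j_N=j_N, j_HG=j_HG, j_HT=j_HT, r_NH=r_NH * one, rho_N=rho_N,
        j_eC=j_eC, j_CO2=j_CO2, r_CH=r_CH, amplification=A,
        j_L=j_L, r_CS=r_CS * np.ones_like(j_L), j_CP=j_CP, j_eL=j_eL,
        j_NPQ=j_NPQ, c_ROS=c_ROS, r_NS=r_NS, j_SG=j_SG, rho_C=rho_C, j_ST=j_ST,
    )


def optimistic_fluxes(state: HolobiontState, env: Environment,
                      params: ParameterSet) -> FluxState:
    """A generous starting flux guess in the healthy basin.

    Seeds the lagged quantities at their saturated values (photosynthesis and
    growth at their maxima, no ROS), then evaluates one pass of
    :func:`compute_fluxes` so all remaining fields are consistent with the
    state.  Iterating from here converges to the healthy flux branch wherever
    one exists.
    """
    sp = params.sym
    shape_host = np.broadcast_shapes(np.shape(state.host_biomass), np.shape(env.light))
    ones_h = np.ones(shape_host)
    ones_s = np.ones(shape_host + (params.n_symbionts,))
    seed = FluxState(
        j_X=0 * ones_h, j_N=0 * ones_h, j_HG=params.host.j_HGm * ones_h,
        j_HT=params.host.j_HT0 * ones_h, r_NH=0 * ones_h, rho_N=0 * ones_h,
        j_eC=0 * ones_h, j_CO2=0 * ones_h, r_CH=0 * ones_h,
        amplification=np.full(shape_host, 2.65),
        j_L=0 * ones_s, r_CS=0 * ones_s, j_CP=sp.j_CPm * ones_s,
        j_eL=0 * ones_s, j_NPQ=0 * ones_s, c_ROS=ones_s.copy(),
        r_NS=0 * ones_s,
        j_SG=sp.j_SGm * ones_s,
        rho_C=_pos(sp.j_CPm - sp.j_SGm / params.host.y_C) * ones_s,
        j_ST=sp.j_ST0 * ones_s,
    )
    return compute_fluxes(state, env, params, seed)


def fixed_point_fluxes(state: HolobiontState, env: Environment,
                       params: ParameterSet, start: FluxState | None = None,
                       tol: float = 1e-9, max_iter: int = 100,
                       damped_iter: int = 400) -> FluxState:
    """Iterate :func:`compute_fluxes` at a frozen state to a fixed point.

    Plain iteration of the lagged map is tried first (``max_iter`` passes);
    if it cycles rather than contracts — which can happen under strong
    light/ROS feedback — a damped iteration (averaging old and new fluxes)
    is used as a fallback for up to ``damped_iter`` further passes.

    Raises
    ------
    FixedPointError
        If the maximum relative change across all fluxes stays above ``tol``.
    """
    flux = start if start is not None else optimistic_fluxes(state, env, params)
    for _ in range(max_iter):
        new = compute_fluxes(state, env, params, flux)
        if new.max_relative_difference(flux) < tol:
            return new
        flux = new
    # Damped fallback: mix old and new to break two-cycles.
    for _ in range(damped_iter):
        new = compute_fluxes(state, env, params, flux)
        if new.max_relative_difference(flux) < tol:
            return new
        mixed = {}
        for name, v in new.as_dict().items():
            mixed[name] = 0.5 * (np.asarray(v, dtype=float)
                                 + np.asarray(getattr(flux, name), dtype=float))
        # c_ROS must remain >= 1 and the mix of two values >= 1 is >= 1.
        flux = FluxState(**mixed)
    new = compute_fluxes(state, env, params, flux)
    if new.max_relative_difference(flux) < tol:
        return new
    raise FixedPointError(
        f"flux fixed point did not converge below {tol} "
        f"(residual {new.max_relative_difference(flux):.3e})"
    )
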