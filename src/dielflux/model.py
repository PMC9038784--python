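"""Three-pool model of diel metabolite transfer from a diatom to a bacterium.

State variables (arbitrary concentration units):

* ``P`` — phytoplankton endometabolite pool,
* ``E`` — dissolved exometabolite pool in the medium,
* ``B`` — bacterial endometabolite pool,

coupled by five fluxes::

    dP/dt = N - T - R        dE/dt = R - U        dB/dt = U - C

``N`` is light-driven biosynthesis, ``T`` allocation of endometabolites to
biomass/energy (first-order in P), ``R`` extracellular release, ``U``
Michaelis-Menten bacterial uptake, and ``C`` first-order bacterial
catabolism.  The base model releases by passive diffusion only,
``R = r_diff (P - E)``.  Three optional active mechanisms extend it:

* ``o`` — fixation-irradiance oscillation: after the irradiance peak,
  production declines faster than irradiance, ``N *= exp(-o_decay (clock -
  peak_time))``.
* ``h`` — homeostasis: release gains a production-coupled overflow term,
  ``R += h_coef · N``.
* ``b`` — bacterial response: production is multiplied by ``b_factor`` once
  bacteria are present.

Integration is explicit forward Euler at 0.1-h steps over a 10-day protocol:
6 days of axenic growth (``B = U = 0``) followed by instantaneous
inoculation and 4 days of co-culture.  Pools driven below zero by a step are
clamped to zero and the event is logged.  A vectorised integrator evaluates
many parameter sets simultaneously for grid-search fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign
from .light import IrradianceProfile, clock_hour, irradiance

__all__ = [
    "ModelParameters",
    "SimConfig",
    "Trajectory",
    "Variant",
    "canonical_variant",
    "production",
    "release",
    "uptake",
    "step",
    "simulate",
    "simulate_batch",
    "sample_trajectory",
]

#: Canonical ordering of the eight mechanism variants.
VARIANTS = ("base", "o", "h", "b", "oh", "ob", "hb", "ohb")

Variant = str


def canonical_variant(variant: str | set | frozenset) -> str:
    """Normalise a variant id to one of {base,o,h,b,oh,ob,hb,ohb}."""
    if isinstance(variant, str):
        terms = set() if variant in ("", "base") else set(variant)
    else:
        terms = set(variant)
    if not terms <= {"o", "h", "b"}:
        raise ValueError(f"unknown active terms in variant {variant!r}")
    return "".join(t for t in "ohb" if t in terms) or "base"


def active_terms(variant: str) -> frozenset:
    return frozenset() if variant == "base" else frozenset(variant)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the base model and the three active terms.

    The six base fields parameterise N, T, R, U (two) and C; the last three
    belong to the optional mechanisms and are ignored by variants that do
    not include them.
    """

    n_scale: float = 0.02    # production per unit irradiance per hour
    t_frac: float = 0.05     # allocation fraction, per hour
    r_diff: float = 0.05     # diffusive release rate, per hour
    u_vmax: float = 1.0      # maximal uptake, units per hour
    u_km: float = 1.0        # uptake half-saturation, E units
    c_frac: float = 0.1      # catabolism fraction, per hour
    o_decay: float = 0.0     # post-peak fixation attenuation, per hour
    h_coef: float = 0.0      # production-coupled release coefficient
    b_factor: float = 1.0    # multiplicative production response to bacteria

    def __post_init__(self) -> None:
        for name in ("n_scale", "t_frac", "r_diff", "u_vmax", "c_frac", "o_decay", "h_coef"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.u_km <= 0:
            raise ValueError(f"u_km must be > 0, got {self.u_km}")
        if self.b_factor <= 0:
            raise ValueError(f"b_factor must be > 0, got {self.b_factor}")

    BASE_FIELDS = ("n_scale", "t_frac", "r_diff", "u_vmax", "u_km", "c_frac")
    ACTIVE_FIELDS = {"o": "o_decay", "h": "h_coef", "b": "b_factor"}


@dataclass(frozen=True)
class SimConfig:
    """Integration protocol: 10 simulated days, first 6 axenic, final 2
    compared to the experimental window."""

    dt: float = 0.1             # hours
    duration_days: float = 10.0
    axenic_days: float = 6.0
    comparison_days: float = 2.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.axenic_days < self.duration_days:
            raise ValueError("axenic_days must be < duration_days")
        steps = self.duration_days * 24.0 / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"duration x 24 / dt = {steps} is not an integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 24.0 / self.dt))

    @property
    def inoculation_time(self) -> float:
        return self.axenic_days * 24.0


@dataclass
class Trajectory:
    """Stored model run: pools and fluxes on the integration grid.

    Arrays all have length ``n_steps + 1``; entry ``i`` holds the state at
    time ``time[i]`` and the fluxes evaluated from that state.
    ``clamp_events`` lists ``(step_index, pool_name)`` for every clamping of
    a pool at zero.
    """

    time: np.ndarray
    P: np.ndarray
    E: np.ndarray
    B: np.ndarray
    N: np.ndarray
    T: np.ndarray
    R: np.ndarray
    U: np.ndarray
    C: np.ndarray
    clamp_events: list = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return len(self.time) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.time,
                "P": self.P,
                "E": self.E,
                "B": self.B,
                "N": self.N,
                "T": self.T,
                "R": self.R,
                "U": self.U,
                "C": self.C,
            }
        )


# ---------------------------------------------------------------------------
# Process rates.  Each accepts scalars or numpy arrays for the parameter
# values so the grid-search integrator can evaluate many parameter sets in
# one pass; time is always scalar.


def production(t, params, variant: str = "base", post_inoculation: bool = False,
               profile: IrradianceProfile = IrradianceProfile()):
    """Biosynthesis rate N at elapsed time ``t``.

    Base: ``n_scale × irradiance``.  With ``o``, production after the
    irradiance peak is attenuated exponentially in hours past the peak; with
    ``b`` and bacteria present, production is multiplied by ``b_factor``.
    """
    terms = active_terms(canonical_variant(variant))
    N = _get(params, "n_scale") * irradiance(t, profile)
    if "o" in terms:
        past_peak = clock_hour(t) - profile.peak_time
        if past_peak > 0:
            N = N * np.exp(-_get(params, "o_decay") * past_peak)
    if "b" in terms and post_inoculation:
        N = N * _get(params, "b_factor")
    return N


def release(P, E, N, params, variant: str = "base"):
    """Extracellular release rate R.

    Diffusive gradient term, plus the homeostatic overflow ``h_coef · N``
    when ``h`` is active.  May be negative when E > P (back-diffusion); the
    stepper enforces pool non-negativity.
    """
    terms = active_terms(canonical_variant(variant))
    R = _get(params, "r_diff") * (P - E)
    if "h" in terms:
        R = R + _get(params, "h_coef") * N
    return R


def uptake(E, params, post_inoculation: bool = True):
    """Michaelis-Menten bacterial uptake U; zero during the axenic phase."""
    if not post_inoculation:
        return np.zeros_like(np.asarray(E, dtype=float)) if np.ndim(E) else 0.0
    return _get(params, "u_vmax") * E / (_get(params, "u_km") + E)


def _get(params, name):
    """Field accessor working for ModelParameters and dicts of arrays."""
    if isinstance(params, dict):
        return params[name]
    return getattr(params, name)


def step(state, t, params, variant: str = "base", dt: float = 0.1,
         post_inoculation: bool = True,
         profile: IrradianceProfile = IrradianceProfile()):
    """One forward-Euler step from ``state = (P, E, B)`` at time ``t``.

    Returns ``((P', E', B'), fluxes, clamped)`` where ``fluxes`` is a dict
    of N, T, R, U, C evaluated at ``t`` and ``clamped`` lists the pools that
    were clamped at zero.
    """
    P, E, B = state
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(E)) and np.all(np.isfinite(B))):
        raise FloatingPointError(f"non-finite state at t={t}: {state}")
    N = production(t, params, variant, post_inoculation, profile)
    T = _get(params, "t_frac") * P
    R = release(P, E, N, params, variant)
    U = uptake(E, params, post_inoculation)
    C = _get(params, "c_frac") * B
    P2 = P + (N - T - R) * dt
    E2 = E + (R - U) * dt
    B2 = B + (U - C) * dt
    clamped = [name for name, v in (("P", P2), ("E", E2), ("B", B2)) if np.any(v < 0)]
    P2, E2, B2 = np.maximum(P2, 0.0), np.maximum(E2, 0.0), np.maximum(B2, 0.0)
    fluxes = {"N": N, "T": T, "R": R, "U": U, "C": C}
    return (P2, E2, B2), fluxes, clamped


def simulate(params: ModelParameters, variant: str = "base",
             config: SimConfig = SimConfig(),
             profile: IrradianceProfile = IrradianceProfile()) -> Trajectory:
    """Integrate the model over the full protocol and record everything.

    Starts from ``P = E = B = 0``; uptake and the bacterial pool are forced
    to zero until inoculation at the end of the axenic phase.
    """
    variant = canonical_variant(variant)
    n = config.n_steps
    time = np.arange(n + 1) * config.dt
    out = {k: np.empty(n + 1) for k in "PEBNTRUC"}
    clamp_events: list[tuple[int, str]] = []
    t_inoc = config.inoculation_time
    state = (0.0, 0.0, 0.0)
    for i in range(n + 1):
        t = time[i]
        post = t >= t_inoc
        out["P"][i], out["E"][i], out["B"][i] = state
        if i == n:
            # final state: record fluxes without stepping
            _, fluxes, _ = step(state, t, params, variant, config.dt, post, profile)
            for k in "NTRUC":
                out[k][i] = fluxes[k]
            break
        state, fluxes, clamped = step(state, t, params, variant, config.dt, post, profile)
        for k in "NTRUC":
            out[k][i] = fluxes[k]
        for name in clamped:
            clamp_events.append((i, name))
    return Trajectory(time=time, P=out["P"], E=out["E"], B=out["B"],
                      N=out["N"], T=out["T"], R=out["R"], U=out["U"],
                      C=out["C"], clamp_events=clamp_events)


def simulate_batch(param_arrays: dict, variant: str,
                   sample_times: np.ndarray,
                   config: SimConfig = SimConfig(),
                   profile: IrradianceProfile = IrradianceProfile()):
    """Integrate ``m`` parameter sets at once; return sampled P and U.

    ``param_arrays`` maps each ModelParameters field name to an array of
    shape ``(m,)``.  Only the values of P and U at ``sample_times`` (hours)
    are stored.  Returns ``(P_s, U_s, clamp_counts)`` with shapes
    ``(m, len(sample_times))`` and ``(m,)``.

    The update arithmetic is identical to :func:`step`, so a batch of size
    one reproduces :func:`simulate` bitwise on the same grid.
    """
    variant = canonical_variant(variant)
    m = len(np.asarray(param_arrays["n_scale"]))
    n = config.n_steps
    dt = config.dt
    t_inoc = config.inoculation_time
    sample_idx = np.asarray(
        [int(round(ts / dt)) for ts in np.asarray(sample_times, dtype=float)]
    )
    if np.any(sample_idx < 0) or np.any(sample_idx > n):
        raise ValueError("sample time outside the simulated trajectory")
    want = {int(ix): k for k, ix in enumerate(sample_idx)}

    P = np.zeros(m)
    E = np.zeros(m)
    B = np.zeros(m)
    P_s = np.empty((m, len(sample_idx)))
    U_s = np.empty((m, len(sample_idx)))
    clamp_counts = np.zeros(m, dtype=int)

    pa = {k: np.asarray(v, dtype=float) for k, v in param_arrays.items()}
    t_frac = pa["t_frac"]
    c_frac = pa["c_frac"]
    time = np.arange(n + 1) * dt
    for i in range(n + 1):
        t = time[i]
        post = t >= t_inoc
        if i in want:
            P_s[:, want[i]] = P
            U_s[:, want[i]] = uptake(E, pa, post)
        if i == n:
            break
        N = production(t, pa, variant, post, profile)
        T = t_frac * P
        R = release(P, E, N, pa, variant)
        U = uptake(E, pa, post)
        C = c_frac * B
        P = P + (N - T - R) * dt
        E = E + (R - U) * dt
        B = B + (U - C) * dt
        neg = (P < 0) | (E < 0) | (B < 0)
        if neg.any():
            clamp_counts += neg
            P = np.maximum(P, 0.0)
            E = np.maximum(E, 0.0)
            B = np.maximum(B, 0.0)
    return P_s, U_s, clamp_counts


def sample_trajectory(traj: Trajectory, design: ExperimentDesign,
                      config: SimConfig = SimConfig()):
    """P and U at the design timepoints mapped onto the final comparison days.

    The experimental window is aligned so that its last sample coincides
    with the end of the run; at the default dt the sample times land exactly
    on grid points (nearest-grid-point lookup otherwise).
    """
    if design.window > config.comparison_days * 24.0 + 1e-9:
        raise ValueError(
            f"design window {design.window} h exceeds comparison period "
            f"{config.comparison_days * 24.0} h"
        )
    t0 = config.duration_days * 24.0 - design.window
    times = t0 + design.times
    dt = config.dt
    idx = np.round(times / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= len(traj.time)):
        raise ValueError("sample timepoint outside the stored trajectory")
    return traj.P[idx], traj.U[idx]


def comparison_sample_times(design: ExperimentDesign,
                            config: SimConfig = SimConfig()) -> np.ndarray:
    """Absolute simulation times (hours) of the design samples."""
    t0 = config.duration_days * 24.0 - design.window
    return t0 + design.times
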