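"""Stochastic motor-clutch simulator of adhesion growth under integrin delivery.

The model couples a myosin-motor ensemble pulling actin rearward to a set of
explicit substrate binding sites ("clutches"). Integrins engage free sites at a
rate proportional to the current implicit integrin density ``d_int``; engaged
clutches are loaded through a clutch/substrate series spring by retrograde actin
flow and detach with a force-dependent (catch-slip) off-rate. Talin in each
engaged clutch unfolds under force (Bell kinetics); every unfolding event is
read as an adhesion-reinforcement event and raises the integrin density by
``d_add``, up to a hard cap of ``cap_factor`` times the initial density.
Because only growth is modeled, the normalized density trace starts at 1, is
nondecreasing, and never exceeds the cap.

Tuning ``d_add`` emulates changed availability of newly delivered integrins:
a larger increment per unfolding event predicts faster adhesion growth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "ClutchParams",
    "ClutchState",
    "GrowthTrace",
    "TraceSummary",
    "bond_off_rate",
    "talin_rates",
    "step_ensemble",
    "apply_reinforcement",
    "simulate_adhesion_growth",
    "simulate_many",
    "summarize_traces",
]


@dataclass(frozen=True)
class ClutchParams:
    """Parameterization of the clutch ensemble.

    Forces are in pN, lengths in nm, rates in 1/s, densities in integrins/um^2.
    Defaults are documented placeholders drawn from the published motor-clutch
    model family; they are configuration, not physics hard-coded anywhere else.
    """

    n_motors: int = 50
    stall_force: float = 2.0  # pN per motor
    unloaded_speed_v: float = 110.0  # nm/s
    clutch_stiffness: float = 1.0  # pN/nm
    substrate_stiffness: float = 10.0  # pN/nm (stiff glass-like substrate)
    n_sites: int = 30
    site_area: float = 1.0  # um^2 represented by the ensemble
    k_on: float = 0.1  # 1/(s * (integrins/um^2)) per free site
    koff_catch_rate: float = 0.5  # 1/s, catch branch prefactor
    koff_slip_rate: float = 0.05  # 1/s, slip branch prefactor
    koff_catch_force: float = 10.0  # pN, catch decay scale
    koff_slip_force: float = 15.0  # pN, slip growth scale
    kunfold_0: float = 0.004  # 1/s, talin unfolding at zero force
    kunfold_force: float = 20.0  # pN, Bell scale for unfolding
    kfold_0: float = 0.1  # 1/s, constant refolding
    d_int0: float = 1.0  # integrins/um^2 initial density
    d_add: float = 0.01  # density increment per reinforcement event
    cap_factor: float = 3.0  # density cap as multiple of d_int0
    dt: float = 0.02  # s
    t_end: float = 1800.0  # s
    output_interval: float = 1.0  # s between recorded trace points
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "n_motors stall_force unloaded_speed_v clutch_stiffness "
            "substrate_stiffness k_on koff_catch_rate koff_slip_rate "
            "koff_catch_force koff_slip_force kunfold_0 kunfold_force kfold_0 "
            "d_int0 d_add"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cap_factor < 1:
            raise ValueError("cap_factor must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.output_interval <= 0:
            raise ValueError("output_interval must be > 0")
        fastest = max(
            self.koff_catch_rate + self.koff_slip_rate,
            self.kunfold_0,
            self.kfold_0,
            self.k_on * self.d_int0,
        )
        if self.dt * fastest >= 0.1:
            warnings.warn(
                f"dt*max zero-force rate = {self.dt * fastest:.3g} >= 0.1; "
                "consider a smaller dt for accurate kinetics",
                stacklevel=2,
            )

    @property
    def k_series(self) -> float:
        """Effective stiffness of the clutch + substrate series spring (pN/nm)."""
        kc, ks = self.clutch_stiffness, self.substrate_stiffness
        if kc <= 0 or ks <= 0:
            return 0.0
        return 1.0 / (1.0 / kc + 1.0 / ks)

    @property
    def d_cap(self) -> float:
        return self.cap_factor * self.d_int0

    def with_(self, **kwargs) -> "ClutchParams":
        return replace(self, **kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClutchParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ClutchState:
    """Instantaneous state of the clutch ensemble."""

    time: float
    bound: np.ndarray  # (n_sites,) bool
    extension: np.ndarray  # (n_sites,) nm, extension of the series spring
    talin_unfolded: np.ndarray  # (n_sites,) bool
    d_int_current: float
    retrograde_speed: float
    cumulative_unfolding_events: int = 0

    @classmethod
    def initial(cls, params: ClutchParams) -> "ClutchState":
        n = params.n_sites
        return cls(
            time=0.0,
            bound=np.zeros(n, dtype=np.bool_),
            extension=np.zeros(n, dtype=np.float64),
            talin_unfolded=np.zeros(n, dtype=np.bool_),
            d_int_current=params.d_int0,
            retrograde_speed=params.unloaded_speed_v,
        )

    def forces(self, params: ClutchParams) -> np.ndarray:
        """Per-clutch force (pN); zero for unbound sites."""
        return params.k_series * self.extension * self.bound


@dataclass
class GrowthTrace:
    """Normalized integrin-density time course from one simulation."""

    times: np.ndarray  # s
    normalized_density: np.ndarray  # d_int_current / d_int0
    unfolding_event_times: np.ndarray  # s
    seed: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized_density = np.asarray(self.normalized_density, dtype=float)
        self.unfolding_event_times = np.asarray(self.unfolding_event_times, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "seed": self.seed,
                "normalized_density": self.normalized_density,
            }
        )


def bond_off_rate(force: float, params: ClutchParams) -> float:
    """Catch-slip integrin-substrate off-rate at the given force (1/s).

    Sum of a force-weakened (catch) and a force-strengthened (slip)
    exponential; the minimum lies at a finite positive force whenever both
    branches are active.
    """
    force = float(force)
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    catch = params.koff_catch_rate * math.exp(-force / params.koff_catch_force)
    slip = params.koff_slip_rate * math.exp(force / params.koff_slip_force)
    return catch + slip


def talin_rates(force: float, params: ClutchParams) -> tuple[float, float]:
    """(k_unfold, k_fold) at the given force.

    Unfolding follows Bell kinetics, k_unfold0 * exp(F / F_unfold); refolding
    is force-independent at its zero-force rate.
    """
    force = float(force)
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    k_unfold = params.kunfold_0 * math.exp(force / params.kunfold_force)
    return k_unfold, params.kfold_0


def apply_reinforcement(state: ClutchState, params: ClutchParams) -> ClutchState:
    """Apply one reinforcement event: raise d_int by d_add up to the cap.

    The density never decreases; at the cap the state is returned unchanged
    apart from the event count.
    """
    new_d = min(state.d_int_current + params.d_add, params.d_cap)
    state.d_int_current = new_d
    return state


# Stepping kernel shared by step_ensemble and simulate_adhesion_growth.
# u is a (4, n_sites) block of uniforms: row 0 binding, 1 unbinding,
# 2 unfolding, 3 refolding. Operates in place on bound/ext/unfolded.
@njit(cache=True)
def _step_kernel(
    bound,
    ext,
    unfolded,
    d_int,
    u,
    n_motors,
    stall_force,
    v0,
    k_eff,
    k_on,
    koff_c,
    f_c,
    koff_s,
    f_s,
    ku0,
    fu,
    kf0,
    d_add,
    d_cap,
    dt,
):
    n = bound.size
    f_tot = 0.0
    for i in range(n):
        if bound[i]:
            f_tot += k_eff * ext[i]
    f_stall = n_motors * stall_force
    if f_stall > 0.0:
        v = v0 * max(0.0, 1.0 - f_tot / f_stall)
    else:
        v = 0.0  # no motors, no pulling
    dx = v * dt

    # binding may saturate (p -> 1 in the fast-binding limit); the resolution
    # guard applies to the force-dependent and recovery transitions
    p_on = 1.0 - math.exp(-k_on * d_int * dt)
    if kf0 * dt > 1.0:
        raise ValueError("refolding rate * dt > 1; use a smaller dt")
    p_fold = 1.0 - math.exp(-kf0 * dt)

    n_unfold = 0
    for i in range(n):
        if bound[i]:
            ext[i] += dx
            f = k_eff * ext[i]
            koff = koff_c * math.exp(-f / f_c) + koff_s * math.exp(f / f_s)
            if koff * dt > 1.0:
                raise ValueError("unbinding rate * dt > 1; use a smaller dt")
            if u[1, i] < 1.0 - math.exp(-koff * dt):
                bound[i] = False
                ext[i] = 0.0
                unfolded[i] = False
            elif not unfolded[i]:
                ku = ku0 * math.exp(f / fu)
                if ku * dt > 1.0:
                    raise ValueError("unfolding rate * dt > 1; use a smaller dt")
                if u[2, i] < 1.0 - math.exp(-ku * dt):
                    unfolded[i] = True
                    n_unfold += 1
            else:
                if u[3, i] < p_fold:
                    unfolded[i] = False
        else:
            if u[0, i] < p_on:
                bound[i] = True
                ext[i] = 0.0
                unfolded[i] = False
    if n_unfold > 0:
        d_int = min(d_int + n_unfold * d_add, d_cap)
    return d_int, n_unfold, v


def _kernel_args(params: ClutchParams) -> tuple:
    return (
        float(params.n_motors),
        params.stall_force,
        params.unloaded_speed_v,
        params.k_series,
        params.k_on,
        params.koff_catch_rate,
        params.koff_catch_force,
        params.koff_slip_rate,
        params.koff_slip_force,
        params.kunfold_0,
        params.kunfold_force,
        params.kfold_0,
        params.d_add,
        params.d_cap,
        params.dt,
    )


def step_ensemble(
    state: ClutchState, params: ClutchParams, rng: np.random.Generator
) -> ClutchState:
    """Advance the ensemble by one fixed timestep dt.

    Update order: motor force-velocity sets the retrograde speed from the
    current total clutch load; bound extensions advance by v*dt; free sites
    bind with probability 1-exp(-k_on*d_int*dt); bound clutches unbind with
    probability 1-exp(-k_off(F)*dt) (resetting extension and talin state);
    surviving folded talins unfold, unfolded ones refold; every unfolding
    event adds d_add to the density, capped at cap_factor*d_int0.
    """
    bound = state.bound.copy()
    ext = state.extension.copy()
    unfolded = state.talin_unfolded.copy()
    u = rng.random((4, params.n_sites))
    d_int, n_unfold, v = _step_kernel(
        bound, ext, unfolded, state.d_int_current, u, *_kernel_args(params)
    )
    return ClutchState(
        time=state.time + params.dt,
        bound=bound,
        extension=ext,
        talin_unfolded=unfolded,
        d_int_current=d_int,
        retrograde_speed=v,
        cumulative_unfolding_events=state.cumulative_unfolding_events + n_unfold,
    )


def simulate_adhesion_growth(params: ClutchParams, seed: int | None = None) -> GrowthTrace:
    """Run the ensemble from t=0 to t_end and record the normalized density.

    The trace is recorded every ``output_interval`` seconds of simulated time
    (including t=0 and t_end) and is fully reproducible given the seed.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n_steps = int(round(params.t_end / params.dt))
    record_every = max(1, int(round(params.output_interval / params.dt)))

    bound = np.zeros(params.n_sites, dtype=np.bool_)
    ext = np.zeros(params.n_sites, dtype=np.float64)
    unfolded = np.zeros(params.n_sites, dtype=np.bool_)
    d_int = params.d_int0
    args = _kernel_args(params)

    times = [0.0]
    density = [1.0]
    event_times: list[float] = []
    for step in range(1, n_steps + 1):
        u = rng.random((4, params.n_sites))
        d_int, n_unfold, _v = _step_kernel(bound, ext, unfolded, d_int, u, *args)
        t = step * params.dt
        if n_unfold:
            event_times.extend([t] * n_unfold)
        if step % record_every == 0 or step == n_steps:
            times.append(t)
            density.append(d_int / params.d_int0)
    return GrowthTrace(
        times=np.array(times),
        normalized_density=np.array(density),
        unfolding_event_times=np.array(event_times),
        seed=seed,
    )


def simulate_many(params: ClutchParams, n_seeds: int, base_seed: int | None = None) -> list[GrowthTrace]:
    """Simulate n_seeds independent traces; child seeds are base_seed + i."""
    if base_seed is None:
        base_seed = params.seed
    return [simulate_adhesion_growth(params, seed=base_seed + i) for i in range(n_seeds)]


@dataclass
class TraceSummary:
    """Pointwise summary of a set of traces sharing one output time grid."""

    table: pd.DataFrame  # columns time_s, mean, sd
    time_to_threshold: pd.Series | None = None  # indexed by seed; NaN = never
    threshold: float | None = None


def summarize_traces(traces, threshold: float | None = None) -> TraceSummary:
    """Pointwise mean/SD over traces, plus per-trace first-crossing times.

    All traces must share the output time grid. ``time_to_threshold`` is the
    first recorded time at which the normalized density reaches the threshold,
    or NaN if it never does.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise ValueError("traces do not share a common output time grid")
    stack = np.vstack([tr.normalized_density for tr in traces])
    table = pd.DataFrame(
        {"time_s": grid, "mean": stack.mean(axis=0), "sd": stack.std(axis=0, ddof=0)}
    )
    tth = None
    if threshold is not None:
        vals = {}
        for tr in traces:
            hit = np.nonzero(tr.normalized_density >= threshold)[0]
            vals[tr.seed] = grid[hit[0]] if hit.size else np.nan
        tth = pd.Series(vals, name="time_to_threshold_s")
    return TraceSummary(table=table, time_to_threshold=tth, threshold=threshold)
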