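"""Reduced Wong-Wang excitatory/inhibitory mean-field network dynamics.

Each region hosts one excitatory (NMDA) and one inhibitory (GABA) population
described by synaptic gating variables S_E, S_I in [0, 1].  Excitatory
populations are coupled across regions through the structural connectome C_ij,
scaled by the global coupling G; within a region the inhibitory population
projects back onto the excitatory one with weight J_i.  Feedback inhibition
control (FIC) tunes J_i so every excitatory population fires at ~3 Hz on
average, the intrinsic rate of an isolated population.

Currents are in nA, rates in Hz, gating dimensionless.  Integration is
Euler-Maruyama in millisecond time units with additive noise on both gating
equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .connectome import StructuralConnectome

__all__ = [
    "RwwParameters",
    "SimulationConfig",
    "NeuralTrajectory",
    "FicResult",
    "transfer_rate",
    "drift",
    "integrate",
    "mean_firing_rates",
    "tune_fic",
    "tune_fic_feasible",
    "FicNonConvergenceError",
    "NumericalDivergenceError",
]


class FicNonConvergenceError(RuntimeError):
    """Inhibition tuning failed to bring all regions to the target rate."""


class NumericalDivergenceError(RuntimeError):
    """The integrator produced a non-finite state."""


@dataclass
class RwwParameters:
    """Constants of the reduced Wong-Wang E/I model (Deco-2014 defaults).

    None of these are fitted to data here except ``G`` (by the coupling sweep)
    and ``J`` (by feedback inhibition control); the rest are the standard
    published constants of the model family.
    """

    a_E: float = 310.0      # excitatory gain, 1/(nC)
    b_E: float = 125.0      # excitatory threshold, Hz
    d_E: float = 0.16       # excitatory saturation, s
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0    # NMDA gating time constant, ms
    tau_I: float = 10.0     # GABA gating time constant, ms
    gamma_kin: float = 0.641 / 1000.0  # kinetic rate per ms
    J_NMDA: float = 0.15    # excitatory synaptic coupling, nA
    w_plus: float = 1.4     # local recurrent excitation
    W_E: float = 1.0
    W_I: float = 0.7
    I_0: float = 0.382      # external input, nA
    sigma: float = 0.01     # noise amplitude, nA
    G: float = 0.0          # global coupling (dimensionless)
    J: np.ndarray | None = None  # per-region inhibitory weight, nA

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if self.J is not None:
            self.J = np.asarray(self.J, dtype=float)
            if np.any(self.J <= 0):
                raise ValueError("all J_i must be positive")

    def with_(self, **kw) -> "RwwParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings; ``dt`` in ms, durations in seconds."""

    dt: float = 0.1
    duration: float = 390.0
    burn_in: float = 2.0
    seed: int = 0
    record_rates: bool = True
    record_dt: float = 1.0  # sampling interval of recorded state, ms

    def __post_init__(self):
        if self.dt > 1.0 or self.dt <= 0:
            raise ValueError("dt must be in (0, 1] ms")
        if not self.duration > self.burn_in >= 0:
            raise ValueError("need duration > burn_in >= 0")


@dataclass(frozen=True)
class NeuralTrajectory:
    """Recorded gating variables and excitatory rates, post burn-in."""

    s_exc: np.ndarray       # n x steps, in [0,1]
    s_inh: np.ndarray
    r_exc: np.ndarray | None  # Hz; None unless record_rates
    time: np.ndarray        # seconds, aligned with columns
    mean_rates: np.ndarray  # exact per-region time-average of r_E, every step


@dataclass(frozen=True)
class FicResult:
    j: np.ndarray
    rates: np.ndarray
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# transfer function


def transfer_rate(current, a: float, b: float, d: float):
    """Population firing rate phi(I) = x / (1 - exp(-d x)), x = a I - b.

    Continuous at x = 0 with value 1/d.  Defined for all finite currents;
    tends to 0+ as x -> -inf and to x as x -> +inf.
    """
    arr = np.asarray(current, dtype=float)
    x = a * np.atleast_1d(arr) - b
    u = d * x
    out = np.empty_like(x)
    near_zero = np.abs(u) < 1e-9
    deep_neg = u < -30.0  # 1 - exp(-u) ~ -exp(-u); avoids overflow
    generic = ~(near_zero | deep_neg)
    out[near_zero] = 1.0 / d
    out[deep_neg] = -x[deep_neg] * np.exp(u[deep_neg])
    out[generic] = x[generic] / (1.0 - np.exp(-u[generic]))
    if arr.ndim == 0:
        return float(out[0])
    return out.reshape(arr.shape)


@njit(cache=True)
def _phi(x, d):
    u = d * x
    if abs(u) < 1e-9:
        return 1.0 / d
    if u < -30.0:
        return -x * np.exp(u)  # underflows to 0 for very negative x
    return x / (1.0 - np.exp(-u))


def drift(s_exc, s_inh, sc: StructuralConnectome | np.ndarray, params: RwwParameters):
    """Deterministic part of (dS_E/dt, dS_I/dt), in 1/ms.

    I_E,i = W_E I_0 + w+ J_NMDA S_E,i + G J_NMDA sum_j C_ij S_E,j - J_i S_I,i
    I_I,i = W_I I_0 + J_NMDA S_E,i - S_I,i
    dS_E  = -S_E/tau_E + (1 - S_E) gamma r_E(I_E)
    dS_I  = -S_I/tau_I + r_I(I_I) / 1000
    """
    C = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc)
    s_exc = np.asarray(s_exc, dtype=float)
    s_inh = np.asarray(s_inh, dtype=float)
    p = params
    J = p.J if p.J is not None else np.ones(C.shape[0])
    i_exc = p.W_E * p.I_0 + p.w_plus * p.J_NMDA * s_exc + p.G * p.J_NMDA * (C @ s_exc) - J * s_inh
    i_inh = p.W_I * p.I_0 + p.J_NMDA * s_exc - s_inh
    r_exc = transfer_rate(i_exc, p.a_E, p.b_E, p.d_E)
    r_inh = transfer_rate(i_inh, p.a_I, p.b_I, p.d_I)
    ds_exc = -s_exc / p.tau_E + (1.0 - s_exc) * p.gamma_kin * r_exc
    ds_inh = -s_inh / p.tau_I + r_inh / 1000.0
    if not (np.all(np.isfinite(ds_exc)) and np.all(np.isfinite(ds_inh))):
        bad = int(np.flatnonzero(~(np.isfinite(ds_exc) & np.isfinite(ds_inh)))[0])
        raise NumericalDivergenceError(f"non-finite drift at region {bad}")
    return ds_exc, ds_inh


# ---------------------------------------------------------------------------
# Euler-Maruyama kernel (compiled once, shared by integrate and tune_fic)


@njit(cache=True)
def _em_kernel(C, G, J, dt, n_steps, burn_steps, stride, sigma, seed,
               a_E, b_E, d_E, a_I, b_I, d_I, tau_E, tau_I, gamma,
               J_NMDA, w_plus, W_E, W_I, I_0, record):
    np.random.seed(seed)
    n = C.shape[0]
    s_e = np.full(n, 0.1)
    s_i = np.full(n, 0.1)
    n_rec = (n_steps - burn_steps) // stride if record else 0
    rec_se = np.empty((n, n_rec))
    rec_si = np.empty((n, n_rec))
    rec_re = np.empty((n, n_rec))
    mean_r = np.zeros(n)
    sq = np.sqrt(dt)
    k = 0
    for step in range(n_steps):
        # coupling term
        net = C @ s_e
        for i in range(n):
            i_e = W_E * I_0 + w_plus * J_NMDA * s_e[i] + G * J_NMDA * net[i] - J[i] * s_i[i]
            i_i = W_I * I_0 + J_NMDA * s_e[i] - s_i[i]
            r_e = _phi(a_E * i_e - b_E, d_E)
            r_i = _phi(a_I * i_i - b_I, d_I)
            if step >= burn_steps:
                mean_r[i] += r_e
                if record and (step - burn_steps) % stride == 0 and k < n_rec:
                    rec_se[i, k] = s_e[i]
                    rec_si[i, k] = s_i[i]
                    rec_re[i, k] = r_e
            ds_e = (-s_e[i] / tau_E + (1.0 - s_e[i]) * gamma * r_e) * dt
            ds_i = (-s_i[i] / tau_I + r_i / 1000.0) * dt
            if sigma > 0.0:
                ds_e += sigma * sq * np.random.standard_normal()
                ds_i += sigma * sq * np.random.standard_normal()
            s_e[i] = min(max(s_e[i] + ds_e, 0.0), 1.0)
            s_i[i] = min(max(s_i[i] + ds_i, 0.0), 1.0)
        if record and step >= burn_steps and (step - burn_steps) % stride == 0:
            k += 1
    denom = max(n_steps - burn_steps, 1)
    for i in range(n):
        mean_r[i] /= denom
    return rec_se, rec_si, rec_re, mean_r


def integrate(sc: StructuralConnectome, params: RwwParameters,
              config: SimulationConfig) -> NeuralTrajectory:
    """Simulate the coupled network, returning the post-burn-in trajectory.

    Euler-Maruyama with step ``config.dt`` ms and additive noise
    sigma*sqrt(dt)*N(0,1) on both gating equations; gating clamped to [0,1].
    Bit-reproducible under ``config.seed``.
    """
    C = np.ascontiguousarray(sc.weights)
    n = C.shape[0]
    J = params.J if params.J is not None else np.ones(n)
    if len(J) != n:
        raise ValueError("params.J length must match the connectome")
    dt = config.dt
    n_steps = int(round(config.duration * 1000.0 / dt))
    burn_steps = int(round(config.burn_in * 1000.0 / dt))
    stride = max(int(round(config.record_dt / dt)), 1)
    p = params
    rec_se, rec_si, rec_re, mean_r = _em_kernel(
        C, p.G, np.ascontiguousarray(J, dtype=float), dt, n_steps, burn_steps,
        stride, p.sigma, int(config.seed) & 0x7FFFFFFF,
        p.a_E, p.b_E, p.d_E, p.a_I, p.b_I, p.d_I, p.tau_E, p.tau_I,
        p.gamma_kin, p.J_NMDA, p.w_plus, p.W_E, p.W_I, p.I_0, True,
    )
    if not np.all(np.isfinite(mean_r)):
        bad = int(np.flatnonzero(~np.isfinite(mean_r))[0])
        raise NumericalDivergenceError(f"non-finite state for region {bad}")
    t0 = config.burn_in
    time = t0 + np.arange(rec_se.shape[1]) * (stride * dt) / 1000.0
    return NeuralTrajectory(
        s_exc=rec_se,
        s_inh=rec_si,
        r_exc=rec_re if config.record_rates else None,
        time=time,
        mean_rates=mean_r,
    )


def _window_mean_rates(C, params: RwwParameters, J, dt, window_s, burn_s, seed):
    """Exact per-region mean excitatory rate over a (burn_s, burn_s+window_s) run."""
    p = params
    n_steps = int(round((window_s + burn_s) * 1000.0 / dt))
    burn_steps = int(round(burn_s * 1000.0 / dt))
    _, _, _, mean_r = _em_kernel(
        np.ascontiguousarray(C), p.G, np.ascontiguousarray(J, dtype=float),
        dt, n_steps, burn_steps, n_steps + 1, p.sigma, int(seed) & 0x7FFFFFFF,
        p.a_E, p.b_E, p.d_E, p.a_I, p.b_I, p.d_I, p.tau_E, p.tau_I,
        p.gamma_kin, p.J_NMDA, p.w_plus, p.W_E, p.W_I, p.I_0, False,
    )
    return mean_r


def mean_firing_rates(traj: NeuralTrajectory) -> np.ndarray:
    """Time-averaged excitatory firing rate per region (Hz), post burn-in."""
    if traj.r_exc is None:
        raise ValueError("trajectory was recorded without rates")
    if traj.r_exc.shape[1] == 0:
        raise ValueError("empty averaging window")
    return traj.r_exc.mean(axis=1)


def tune_fic(sc: StructuralConnectome, params: RwwParameters,
             config: SimulationConfig | None = None,
             target_rate: float = 3.0, tol: float = 0.25,
             max_iter: int = 50, eta: float = 0.005,
             window: float = 30.0, j_min: float = 0.1,
             raise_on_failure: bool = True) -> FicResult:
    """Feedback inhibition control: tune J_i until each excitatory population
    fires at ``target_rate`` (~3 Hz) on average.

    Proportional controller with per-region adaptive gain:
    J_i <- max(j_min, J_i + m_i * eta * (mean rate - target)), evaluated on a
    ``window``-second simulation after ``config.burn_in`` s of burn-in, with
    the same frozen noise realization every iteration so the loop is
    deterministic under ``config.seed``.  The multiplier m_i starts at 1,
    grows by 1.3x while the rate error keeps its sign (the plain proportional
    step stalls near the fixed point, where the rate becomes insensitive to
    J), and halves on a sign flip; individual steps are capped at 1 nA.
    Warm-starts from ``params.J`` when provided.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    config = config or SimulationConfig()
    C = sc.weights
    n = C.shape[0]
    if params.J is None and params.G > 0.5:
        # continuation: a cold start directly at moderate coupling can land in
        # the collectively unstable basin; walk G up in 0.25 steps instead,
        # warm-starting each stage from the previous one (loose tolerance at
        # intermediate couplings, full settings at the target G)
        stages = np.arange(0.5, params.G, 0.25)
        j_warm = None
        for g_stage in stages:
            res = tune_fic(sc, params.with_(G=float(g_stage), J=j_warm), config,
                           target_rate=target_rate, tol=max(tol, 0.5),
                           max_iter=max_iter, eta=eta, window=window,
                           j_min=j_min, raise_on_failure=False)
            j_warm = res.j
        params = params.with_(J=j_warm)
    J = np.ones(n) if params.J is None else np.array(params.J, dtype=float)
    gain = np.ones(n)
    prev_sign = np.zeros(n)
    rates = _window_mean_rates(C, params, J, config.dt, window,
                               config.burn_in, config.seed)
    err = rates - target_rate
    loss = float(np.sqrt(np.mean(err**2)))
    best_loss = loss
    stall = 0
    for it in range(1, max_iter + 1):
        if np.all(np.abs(err) <= tol):
            return FicResult(j=J, rates=rates, n_iter=it, converged=True)
        sign = np.sign(err)
        gain = np.where(sign == prev_sign, np.minimum(gain * 1.3, 30.0),
                        np.maximum(gain * 0.5, 1.0))
        prev_sign = sign
        step = np.clip(gain * eta * err, -0.2, 0.2)
        # backtracking: shrink the global step while the frozen-window RMS
        # rate error worsens (guards against collective over-shoot near the
        # critical coupling, where all regions move together)
        scale = 1.0
        for bt in range(5):
            j_new = np.maximum(j_min, J + scale * step)
            r_new = _window_mean_rates(C, params, j_new, config.dt, window,
                                       config.burn_in, config.seed)
            e_new = r_new - target_rate
            l_new = float(np.sqrt(np.mean(e_new**2)))
            if l_new <= loss or bt == 4:
                J, rates, err, loss = j_new, r_new, e_new, l_new
                break
            scale *= 0.25
            gain = np.maximum(gain * 0.7, 1.0)
        # stall detection: in the supercritical regime no J meets the clamp
        # on a finite window; give up early instead of burning iterations
        if loss < best_loss * 0.98:
            best_loss = loss
            stall = 0
        else:
            stall += 1
            if stall >= 8:
                break
    if np.all(np.abs(err) <= tol):
        return FicResult(j=J, rates=rates, n_iter=max_iter, converged=True)
    bad = np.flatnonzero(np.abs(err) > tol)
    if raise_on_failure:
        raise FicNonConvergenceError(
            f"FIC did not converge (max |rate error| "
            f"{float(np.abs(err).max()):.2f} Hz > tol {tol} Hz); "
            f"offending regions: {bad.tolist()}"
        )
    return FicResult(j=J, rates=rates, n_iter=max_iter, converged=False)


def tune_fic_feasible(sc: StructuralConnectome, g_target: float,
                      params: RwwParameters | None = None,
                      config: SimulationConfig | None = None,
                      g_start: float = 0.5, step: float = 0.15,
                      **fic_kwargs) -> tuple[float, FicResult]:
    """Tune inhibition at the largest simulable coupling not exceeding
    ``g_target``.

    The rate clamp is only well-posed below a connectome-dependent critical
    coupling; past it, window-averaged rates fluctuate more than any
    tolerance.  This helper walks G up from ``g_start`` in increments of
    ``step``, warm-starting J at each stage, and returns the last coupling at
    which tuning converged (with its FicResult).  Raises if even the first
    stage fails.
    """
    params = params or RwwParameters()
    config = config or SimulationConfig()
    gs = np.arange(min(g_start, g_target), g_target - 1e-9, step)
    gs = np.append(gs, g_target)
    best: tuple[float, FicResult] | None = None
    j_warm = params.J
    for g in gs:
        try:
            fic = tune_fic(sc, params.with_(G=float(g), J=j_warm), config,
                           **fic_kwargs)
        except FicNonConvergenceError:
            break
        best = (float(g), fic)
        j_warm = fic.j
    if best is None:
        raise FicNonConvergenceError(
            f"no simulable coupling at or below {g_target} (start {g_start})"
        )
    return best
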