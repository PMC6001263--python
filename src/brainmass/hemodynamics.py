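"""Balloon-Windkessel hemodynamic forward model.

Converts a neural drive (the excitatory synaptic gating S_E by convention)
into a BOLD signal through the vasodilatory-signal / inflow / volume /
deoxyhemoglobin cascade, then samples the continuous BOLD at the scanner
repetition time TR.  Constants follow the standard Friston parameterization;
integration is deterministic RK4 at the neural recording step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectome import BoldRun

__all__ = ["BalloonParameters", "bold_forward", "sample_at_tr"]


@dataclass(frozen=True)
class BalloonParameters:
    kappa: float = 0.65     # vasodilatory signal decay, 1/s
    gamma_f: float = 0.41   # flow-dependent elimination, 1/s
    tau_h: float = 0.98     # hemodynamic transit time, s
    alpha: float = 0.32     # Grubb vessel stiffness exponent
    rho: float = 0.34       # resting oxygen extraction fraction
    V0: float = 0.02        # resting venous blood volume fraction
    k1: float = 7.0 * 0.34
    k2: float = 2.0
    k3: float = 2.0 * 0.34 - 0.2

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.rho < 1):
            raise ValueError("rho must be in (0, 1)")
        for name in ("kappa", "gamma_f", "tau_h", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@njit(cache=True)
def _balloon_rhs(z, s, f, v, q, kappa, gamma_f, tau, ialpha, rho):
    ds = z - kappa * s - gamma_f * (f - 1.0)
    df = s
    fv = v ** ialpha  # outflow
    dv = (f - fv) / tau
    ef = 1.0 - (1.0 - rho) ** (1.0 / f)  # oxygen extraction E(f, rho)
    dq = (f * ef / rho - fv * q / v) / tau
    return ds, df, dv, dq


@njit(cache=True)
def _balloon_kernel(drive, dt, kappa, gamma_f, tau, alpha, rho, V0, k1, k2, k3):
    n, steps = drive.shape
    bold = np.empty((n, steps))
    ialpha = 1.0 / alpha
    for i in range(n):
        # start at the steady state of the initial drive so the shared onset
        # transient does not contaminate BOLD correlations; zero drive keeps
        # the exact resting fixed point (s=0, f=v=q=1)
        z0 = drive[i, 0]
        s = 0.0
        if z0 == 0.0:
            f = 1.0
            v = 1.0
            q = 1.0
        else:
            f = 1.0 + z0 / gamma_f
            if f < 1e-6:
                f = 1e-6
            v = f ** alpha
            q = v * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho
        for t in range(steps):
            z0 = drive[i, t]
            z1 = drive[i, t + 1] if t + 1 < steps else z0
            zm = 0.5 * (z0 + z1)
            ds1, df1, dv1, dq1 = _balloon_rhs(z0, s, f, v, q, kappa, gamma_f, tau, ialpha, rho)
            ds2, df2, dv2, dq2 = _balloon_rhs(
                zm, s + 0.5 * dt * ds1, f + 0.5 * dt * df1,
                v + 0.5 * dt * dv1, q + 0.5 * dt * dq1,
                kappa, gamma_f, tau, ialpha, rho)
            ds3, df3, dv3, dq3 = _balloon_rhs(
                zm, s + 0.5 * dt * ds2, f + 0.5 * dt * df2,
                v + 0.5 * dt * dv2, q + 0.5 * dt * dq2,
                kappa, gamma_f, tau, ialpha, rho)
            ds4, df4, dv4, dq4 = _balloon_rhs(
                z1, s + dt * ds3, f + dt * df3, v + dt * dv3, q + dt * dq3,
                kappa, gamma_f, tau, ialpha, rho)
            s += dt * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4) / 6.0
            f += dt * (df1 + 2.0 * df2 + 2.0 * df3 + df4) / 6.0
            v += dt * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4) / 6.0
            q += dt * (dq1 + 2.0 * dq2 + 2.0 * dq3 + dq4) / 6.0
            if f < 1e-6:
                f = 1e-6
            if v < 1e-6:
                v = 1e-6
            if q < 1e-6:
                q = 1e-6
            bold[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return bold


def bold_forward(neural_drive: np.ndarray, dt: float,
                 params: BalloonParameters | None = None) -> np.ndarray:
    """Integrate the Balloon-Windkessel ODEs driven by ``neural_drive``.

    Parameters
    ----------
    neural_drive
        n_regions x steps array of neural activity (typically S_E).
    dt
        Sampling step of the drive in seconds (<= 0.01 s).
    params
        Hemodynamic constants; defaults to the standard parameterization.

    Returns the BOLD signal at the same sampling as the drive.  States are
    initialized at the steady state of the initial drive value, so a constant
    drive produces a flat (offset) BOLD rather than a shared onset transient
    that would spuriously correlate all regions.  The resting state (zero
    drive, f = v = q = 1) is an exact fixed point, so zero drive yields
    identically zero BOLD.
    """
    drive = np.ascontiguousarray(neural_drive, dtype=float)
    if drive.ndim != 2:
        raise ValueError("neural_drive must be n_regions x steps")
    if not np.all(np.isfinite(drive)):
        raise ValueError("neural_drive must be finite")
    if dt <= 0 or dt > 0.010 + 1e-12:
        raise ValueError("dt must be in (0, 0.01] s")
    p = params or BalloonParameters()
    bold = _balloon_kernel(drive, float(dt), p.kappa, p.gamma_f, p.tau_h,
                           p.alpha, p.rho, p.V0, p.k1, p.k2, p.k3)
    if not np.all(np.isfinite(bold)):
        raise FloatingPointError("Balloon-Windkessel integration diverged")
    return bold


def sample_at_tr(bold: np.ndarray, dt: float, tr: float,
                 duration: float | None = None) -> BoldRun:
    """Sample the dense BOLD signal every ``tr`` seconds.

    Returns floor(duration / tr) samples taken at t = tr, 2 tr, ....  Column i
    of ``bold`` is the end of integration step i, i.e. time (i+1)*dt, so
    sample k maps to column floor(k*tr/dt) - 1.
    """
    bold = np.asarray(bold, dtype=float)
    steps = bold.shape[1]
    if duration is None:
        duration = steps * dt
    if tr < dt:
        raise ValueError("tr must be >= dt")
    n_samples = int(np.floor(duration / tr + 1e-9))
    if n_samples < 1:
        raise ValueError("duration shorter than one TR")
    idx = np.floor(np.arange(1, n_samples + 1) * tr / dt + 1e-9).astype(int) - 1
    idx = np.clip(idx, 0, steps - 1)
    return BoldRun(series=bold[:, idx], tr=tr, source="simulated")
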