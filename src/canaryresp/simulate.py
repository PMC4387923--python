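"""Fixed-step integration of the four-population circuit.

A classical 4th-order Runge–Kutta scheme with a fixed step is used: the
drives are discontinuous square pulses, so an adaptive stepper buys little,
while a fixed grid makes runs bit-reproducible and drive sampling
unambiguous.  Drive values are sampled at the RK sub-stage times; the final
sub-stage of each step uses the drive's left-sided limit, so that a pulse
edge landing exactly on a step boundary never leaks into the preceding step
and the scheme keeps its full order on edge-aligned grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .drives import DriveSet
from .model import ModelParams, NetworkState, SIGMOID_CLAMP

__all__ = ["Trajectory", "IntegrationError", "integrate", "resting_state"]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite; carries the failure time."""

    def __init__(self, time: float):
        super().__init__(f"non-finite state encountered at t = {time:g} ms")
        self.time = time


@dataclass
class Trajectory:
    """Result of one integration: uniform time grid, states and drive values.

    ``states`` has one row per time point with columns
    (e_er, i_er, e_ra, i_ra); ``drive_trace`` holds (F, Fd, Fd2).
    """

    times: np.ndarray
    states: np.ndarray
    drive_trace: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if self.states.shape != (n, 4) or self.drive_trace.shape != (n, 3):
            raise ValueError("Trajectory: inconsistent array lengths")

    @property
    def dt(self) -> float:
        return float(self.meta.get("dt", self.times[1] - self.times[0]))

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def e_er(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def i_er(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def e_ra(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def i_ra(self) -> np.ndarray:
        return self.states[:, 3]

    def final_state(self) -> NetworkState:
        return NetworkState.from_array(self.states[-1])


def integrate(
    params: ModelParams,
    drives: DriveSet,
    t0: float,
    t_end: float,
    dt: float = 0.05,
    initial: Optional[NetworkState] = None,
) -> Trajectory:
    """Integrate the circuit from ``t0`` to ``t_end`` with step ``dt`` (ms).

    ``initial`` defaults to the resting state of the circuit (see
    :func:`resting_state`).  The run is fully deterministic: identical
    arguments produce bit-identical trajectories.

    Raises
    ------
    IntegrationError
        If the state stops being finite (reports the time of failure).
    """
    if not (t_end > t0):
        raise ValueError("integrate: t_end must exceed t0")
    if not (0 < dt <= 1.0):
        raise ValueError("integrate: dt must lie in (0, 1] ms")
    if initial is None:
        initial = resting_state(params, dt=dt)

    n_steps = int(round((t_end - t0) / dt))
    n_steps = max(n_steps, 1)
    times = t0 + dt * np.arange(n_steps + 1)

    er, ra, rates = params.er, params.ra, params.rates
    be, bi = er.bias_e, er.bias_i
    aF, aer_ra, air_ra = er.alpha_eer_F, er.alpha_eer_ra, er.alpha_ier_ra
    wee, wei, wie, wii = er.w_ee, er.w_ei, er.w_ie, er.w_ii
    rhoE, aeFd, aeFd2, aera, bera = ra.rho_e, ra.a_e_Fd, ra.a_e_Fd2, ra.a_e_ra, ra.b_e_ra
    rhoI, aiFd, aiFd2, aira, bira = ra.rho_i, ra.a_i_Fd, ra.a_i_Fd2, ra.a_i_ra, ra.b_i_ra
    re, rr = rates.r_er, rates.r_ra
    clamp = SIGMOID_CLAMP
    exp = math.exp
    right = drives.values_at
    left = drives.values_left

    def s(a: float) -> float:
        if a < -clamp:
            a = -clamp
        elif a > clamp:
            a = clamp
        return 1.0 / (1.0 + exp(-a))

    def f(dr, x0, x1, x2, x3):
        F, Fd, Fd2 = dr
        return (
            re * (-x0 + s(be + aer_ra * x2 + aF * F + wee * x0 + wei * x1)),
            re * (-x1 + s(bi + air_ra * x2 + wie * x0 + wii * x1)),
            rr * (-x2 + s(rhoE + aeFd * Fd + aeFd2 * Fd2 + aera * x2 + bera * x3)),
            rr * (-x3 + s(rhoI + aiFd * Fd + aiFd2 * Fd2 + aira * x2 + bira * x3)),
        )

    states = np.empty((n_steps + 1, 4))
    drive_trace = np.empty((n_steps + 1, 3))
    x0, x1, x2, x3 = initial.e_er, initial.i_er, initial.e_ra, initial.i_ra
    states[0] = (x0, x1, x2, x3)
    drive_trace[0] = right(times[0])

    h = dt
    h2 = 0.5 * dt
    h6 = dt / 6.0
    for i in range(n_steps):
        t = times[i]
        t_next = times[i + 1]
        dr1 = right(t)
        dr2 = right(t + h2)
        dr4 = left(t_next)
        k1 = f(dr1, x0, x1, x2, x3)
        k2 = f(dr2, x0 + h2 * k1[0], x1 + h2 * k1[1], x2 + h2 * k1[2], x3 + h2 * k1[3])
        k3 = f(dr2, x0 + h2 * k2[0], x1 + h2 * k2[1], x2 + h2 * k2[2], x3 + h2 * k2[3])
        k4 = f(dr4, x0 + h * k3[0], x1 + h * k3[1], x2 + h * k3[2], x3 + h * k3[3])
        x0 += h6 * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
        x1 += h6 * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
        x2 += h6 * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
        x3 += h6 * (k1[3] + 2.0 * (k2[3] + k3[3]) + k4[3])
        if not (math.isfinite(x0) and math.isfinite(x1) and math.isfinite(x2) and math.isfinite(x3)):
            raise IntegrationError(t_next)
        states[i + 1] = (x0, x1, x2, x3)
        drive_trace[i + 1] = right(t_next)

    meta = {
        "t0": float(t0),
        "t_end": float(t_end),
        "dt": float(dt),
        "params": params.to_dict(),
        "drives": drives.to_meta(),
        "deterministic": True,
    }
    return Trajectory(times=times, states=states, drive_trace=drive_trace, meta=meta)


def resting_state(
    params: ModelParams, duration: float = 500.0, dt: float = 0.05
) -> NetworkState:
    """Resting equilibrium reached from the origin with all drives off.

    The circuit is relaxed for ``duration`` ms from (0, 0, 0, 0) under zero
    drive; 500 ms is an order of magnitude longer than the slowest time
    constant, so the returned state sits on the "off" fixed point to well
    below plotting precision.
    """
    traj = integrate(
        params,
        DriveSet(),
        t0=0.0,
        t_end=duration,
        dt=dt,
        initial=NetworkState(0.0, 0.0, 0.0, 0.0),
    )
    return traj.final_state()
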