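"""Additive rate model of the canary respiratory motor circuit.

The model tracks the mean activity of four neural populations: an
excitatory/inhibitory pair in a brainstem expiratory-related area (ER,
plausibly RAm), whose excitatory activity ``e_er`` stands in for air-sac
pressure, and an excitatory/inhibitory pair in the telencephalic nucleus RA
(robust nucleus of the arcopallium).  Each population obeys the additive
(Wilson–Cowan-type) equation

    dx/dt = r * (-x + S(bias + sum of weighted inputs)),

with the logistic sigmoid ``S``.  The ER pair is driven directly by a
square-pulse command ``F`` from a brainstem initiating area and indirectly by
RA output; the RA pair is driven by delayed copies of that command
(``F_delayed``, ``F_delayed2``) that stand for HVC bursts relayed through the
thalamus.  The internal ER couplings are fixed; the remaining gains select
which of the four canonical canary pressure patterns (P0, P1, P2, pulsatile)
the circuit produces.

Activities are dimensionless in [0, 1]; time is in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "NetworkState",
    "ERCoupling",
    "RACoupling",
    "RateConstants",
    "ModelParams",
    "sigmoid",
    "rhs",
    "find_equilibria",
]

#: sigmoid arguments are clamped to +/- this value before exponentiation;
#: far beyond anything the model reaches (|arg| < ~400 even at full drive)
SIGMOID_CLAMP = 700.0


def sigmoid(x):
    """Logistic nonlinearity ``S(x) = 1 / (1 + exp(-x))``.

    Accepts scalars or arrays.  Strictly increasing, with values in (0, 1).
    Arguments are clamped to ``+/-SIGMOID_CLAMP`` so that extreme inputs
    saturate instead of overflowing.

    Raises
    ------
    ValueError
        If any input element is NaN or infinite.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid: input must be finite")
    out = 1.0 / (1.0 + np.exp(-np.clip(arr, -SIGMOID_CLAMP, SIGMOID_CLAMP)))
    if arr.ndim == 0:
        return float(out)
    return out


def _sigmoid_scalar(a: float) -> float:
    # fast path used by the integrator's inner loop
    if a < -SIGMOID_CLAMP:
        a = -SIGMOID_CLAMP
    elif a > SIGMOID_CLAMP:
        a = SIGMOID_CLAMP
    return 1.0 / (1.0 + math.exp(-a))


@dataclass(frozen=True)
class NetworkState:
    """Activities of the four populations (dimensionless, each in [0, 1])."""

    e_er: float  # ER excitatory (proxy for air-sac pressure)
    i_er: float  # ER inhibitory
    e_ra: float  # RA excitatory (output sent back to ER)
    i_ra: float  # RA inhibitory

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"NetworkState.{f.name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.e_er, self.i_er, self.e_ra, self.i_ra], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "NetworkState":
        e, i, er, ir = (float(v) for v in x)
        return cls(e, i, er, ir)


@dataclass(frozen=True)
class ERCoupling:
    """Couplings of the expiratory-related (ER) excitatory/inhibitory pair.

    The three free gains (``alpha_eer_F``, ``alpha_eer_ra``, ``alpha_ier_ra``)
    are the per-pattern parameters; the biases and internal weights are the
    fixed circuit constants of the published model.
    """

    alpha_eer_F: float  # gain of the initiating-area pulse F on e_er
    alpha_eer_ra: float  # gain of RA excitatory output on e_er
    alpha_ier_ra: float  # gain of RA excitatory output on i_er
    bias_e: float = -7.5
    bias_i: float = -11.5
    w_ee: float = 10.0  # e_er self-excitation
    w_ei: float = -10.0  # i_er -> e_er
    w_ie: float = 10.0  # e_er -> i_er
    w_ii: float = 2.0  # i_er self term


@dataclass(frozen=True)
class RACoupling:
    """Couplings of the RA excitatory/inhibitory pair.

    Both sigmoid arguments are affine in (e_ra, i_ra, F_delayed, F_delayed2).
    Note the asymmetry of the published circuit: in the i_ra equation the
    ``a_i_ra`` gain multiplies *e_ra* (excitatory drive onto the inhibitory
    population), while ``b_i_ra`` multiplies i_ra itself.
    """

    rho_e: float  # bias of e_ra
    a_e_Fd: float  # gain of F_delayed on e_ra
    a_e_Fd2: float  # gain of F_delayed2 on e_ra
    a_e_ra: float  # e_ra self-excitation
    b_e_ra: float  # i_ra -> e_ra
    rho_i: float  # bias of i_ra
    a_i_Fd: float  # gain of F_delayed on i_ra
    a_i_Fd2: float  # gain of F_delayed2 on i_ra
    a_i_ra: float  # e_ra -> i_ra
    b_i_ra: float  # i_ra self term


@dataclass(frozen=True)
class RateConstants:
    """Inverse time constants (per ms) shared within each area.

    Defaults correspond to a fast expiratory area (tau_ER = 1000/149.5 ~
    6.7 ms) and a slower RA (tau_RA = 20 ms).  This separation is what lets
    the pressure proxy e_er track the 20 ms command pulse (the brief leading
    peak of P0), dip visibly during the 22 ms telencephalic delay of P2, and
    ride the slowly decaying RA output as the long second lobe, while RA
    shows its characteristic sharp rise and ~tens-of-ms exponential decay
    after an HVC burst.  Any other pair of positive rates can be supplied,
    e.g. ``RateConstants(1/49.5, 1/20)`` for a uniformly slow variant; fixed
    points of the dynamics do not depend on the rates, only transients do.
    """

    r_er: float = 0.1495
    r_ra: float = 1.0 / 20.0

    def __post_init__(self) -> None:
        if not (self.r_er > 0 and self.r_ra > 0):
            raise ValueError("rate constants must be strictly positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: ER couplings, RA couplings and rate constants."""

    er: ERCoupling
    ra: RACoupling
    rates: RateConstants = field(default_factory=RateConstants)

    def to_dict(self) -> dict:
        return {
            "er": {f.name: getattr(self.er, f.name) for f in fields(ERCoupling)},
            "ra": {f.name: getattr(self.ra, f.name) for f in fields(RACoupling)},
            "rates": {f.name: getattr(self.rates, f.name) for f in fields(RateConstants)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {"er", "ra", "rates"}
        if unknown:
            raise ValueError(f"ModelParams: unknown keys {sorted(unknown)}")
        for section, typ in (("er", ERCoupling), ("ra", RACoupling), ("rates", RateConstants)):
            if section in d:
                bad = set(d[section]) - {f.name for f in fields(typ)}
                if bad:
                    raise ValueError(f"ModelParams.{section}: unknown keys {sorted(bad)}")
        return cls(
            er=ERCoupling(**d["er"]),
            ra=RACoupling(**d["ra"]),
            rates=RateConstants(**d.get("rates", {})),
        )


def _sigmoid_args(x: np.ndarray, drives: Sequence[float], p: ModelParams) -> np.ndarray:
    """The four affine sigmoid arguments at state ``x`` and drive values."""
    e, i, er, ir = x
    F, Fd, Fd2 = drives
    c_er, c_ra = p.er, p.ra
    return np.array(
        [
            c_er.bias_e + c_er.alpha_eer_ra * er + c_er.alpha_eer_F * F
            + c_er.w_ee * e + c_er.w_ei * i,
            c_er.bias_i + c_er.alpha_ier_ra * er + c_er.w_ie * e + c_er.w_ii * i,
            c_ra.rho_e + c_ra.a_e_Fd * Fd + c_ra.a_e_Fd2 * Fd2
            + c_ra.a_e_ra * er + c_ra.b_e_ra * ir,
            c_ra.rho_i + c_ra.a_i_Fd * Fd + c_ra.a_i_Fd2 * Fd2
            + c_ra.a_i_ra * er + c_ra.b_i_ra * ir,
        ]
    )


def rhs(state, t: float, params: ModelParams, drives) -> np.ndarray:
    """Time derivative of the four activities at time ``t``.

    Parameters
    ----------
    state : NetworkState or length-4 sequence
        Current activities (e_er, i_er, e_ra, i_ra).
    t : float
        Time in ms (the system is non-autonomous through the drives).
    params : ModelParams
    drives : DriveSet
        Square-pulse drive signals, evaluated at ``t``.

    Returns
    -------
    numpy.ndarray, shape (4,)
        (d e_er/dt, d i_er/dt, d e_ra/dt, d i_ra/dt).
    """
    if not math.isfinite(t):
        raise ValueError("rhs: time must be finite")
    x = state.as_array() if isinstance(state, NetworkState) else np.asarray(state, float)
    if x.shape != (4,) or not np.all(np.isfinite(x)):
        raise ValueError("rhs: state must be 4 finite values")
    args = _sigmoid_args(x, drives.values_at(t), params)
    rates = np.array(
        [params.rates.r_er, params.rates.r_er, params.rates.r_ra, params.rates.r_ra]
    )
    return rates * (-x + sigmoid(args))


def find_equilibria(
    params: ModelParams,
    constant_drives: Sequence[float] = (0.0, 0.0, 0.0),
    n_starts: int = 81,
    residual_tol: float = 1e-10,
    merge_tol: float = 1e-6,
) -> list[NetworkState]:
    """Locate fixed points of the network under constant drive values.

    Roots of ``-x + S(args(x))`` are sought from a regular grid of starting
    points in [0, 1]^4 (the grid has ``ceil(n_starts**(1/4))`` levels per
    axis) using scipy's damped hybrid (Powell) root refinement.  Rate
    constants scale the vector field but not its zeros, so equilibria do not
    depend on them.

    Returns the distinct converged roots (residual norm below
    ``residual_tol``, duplicates within ``merge_tol`` merged), sorted by
    ascending ``e_er``.  An empty list means no start converged.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    drives = tuple(float(v) for v in constant_drives)

    def g(x: np.ndarray) -> np.ndarray:
        return -x + sigmoid(np.clip(_sigmoid_args(x, drives, params), -SIGMOID_CLAMP, SIGMOID_CLAMP))

    m = max(2, math.ceil(n_starts ** 0.25))
    levels = np.linspace(0.0, 1.0, m)
    roots: list[np.ndarray] = []
    for start in np.stack(np.meshgrid(*[levels] * 4, indexing="ij"), axis=-1).reshape(-1, 4):
        sol = optimize.root(g, start, method="hybr", tol=1e-13)
        x = sol.x
        if not np.all(np.isfinite(x)) or np.linalg.norm(g(x)) >= residual_tol:
            continue
        if any(np.linalg.norm(x - r) < merge_tol for r in roots):
            continue
        roots.append(x)
    roots.sort(key=lambda r: r[0])
    return [NetworkState.from_array(r) for r in roots]
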