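"""Published parameter presets and experiment runners.

Each canonical canary pressure pattern (P0, pulsatile, P2, P1) corresponds
to one setting of the free gains of the circuit: the three ER gains
(alpha_eer_F, alpha_eer_ra, alpha_ier_ra) and the two RA quintuples
(rho, a_Fd, a_Fd2, a_ra, b_ra) for the excitatory and inhibitory RA
populations.  The values stored here are the printed ones, verbatim.

``run_cooling_experiment`` reruns the P0 preset with HVC-derived pulses
stretched and delayed, the model's account of mild HVC hypothermia: the
circuit parameters and the initiating-area pulse are identical between the
normal and cooled runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

from .drives import DriveSet, apply_cooling, build_drives
from .model import ERCoupling, ModelParams, NetworkState, RACoupling, RateConstants
from .simulate import Trajectory, integrate, resting_state

__all__ = [
    "PatternPreset",
    "SimSettings",
    "get_preset",
    "list_presets",
    "run_pattern",
    "run_cooling_experiment",
    "COOLING_STRETCH_MS",
    "COOLING_DELAY_MS",
]

#: published cooling perturbation: HVC bursts 15 ms longer, starting 5 ms later
COOLING_STRETCH_MS = 15.0
COOLING_DELAY_MS = 5.0


@dataclass(frozen=True)
class SimSettings:
    """Integration window and step for one preset run."""

    t0: float = 0.0
    t_end: float = 600.0
    dt: float = 0.05
    initial: str = "rest"  # "rest" (relaxed equilibrium) or "origin"


@dataclass(frozen=True)
class PatternPreset:
    """Named bundle: parameters + drive schedule + integration settings."""

    name: str
    params: ModelParams
    schedule: dict = field(default_factory=dict)
    sim: SimSettings = field(default_factory=SimSettings)

    def drives(self) -> DriveSet:
        return build_drives(self.name, **self.schedule)


# (alpha_eer_F, alpha_eer_ra, alpha_ier_ra) | RA_e and RA_i quintuples
# (rho, a_Fd, a_Fd2, a_ra, b_ra), exactly as printed.
_PARAM_TABLE = {
    "P0": ((1.0, 10.0, 0.0), (-3.0, 5.0, 0.0, 6.0, -3.0), (-6.0, 0.05, 0.0, 6.0, 6.0)),
    "pulsatile": (
        (0.25, 10.0, 6.0),
        (-5.25, 15.0, 0.0, 10.0, -10.0),
        (-12.0, 0.0, 25.0, 10.0, 2.0),
    ),
    "P2": ((1.0, 10.0, 0.0), (-7.0, 2.0, 0.0, 3.5, -5.0), (-4.5, 0.05, 0.0, 16.0, 6.0)),
    "P1": (
        (0.25, 4.65, 4.5),
        (-5.25, 35.0, 0.0, 10.0, -10.0),
        (-12.0, 0.0, 25.0, 10.0, 2.0),
    ),
}

#: slower patterns (oscillating segments) get a longer default horizon
_HORIZON = {"P0": 600.0, "P2": 600.0, "pulsatile": 800.0, "P1": 800.0}


def _params_from_table(name: str) -> ModelParams:
    er3, rae, rai = _PARAM_TABLE[name]
    return ModelParams(
        er=ERCoupling(alpha_eer_F=er3[0], alpha_eer_ra=er3[1], alpha_ier_ra=er3[2]),
        ra=RACoupling(
            rho_e=rae[0], a_e_Fd=rae[1], a_e_Fd2=rae[2], a_e_ra=rae[3], b_e_ra=rae[4],
            rho_i=rai[0], a_i_Fd=rai[1], a_i_Fd2=rai[2], a_i_ra=rai[3], b_i_ra=rai[4],
        ),
        rates=RateConstants(),
    )


def list_presets() -> tuple[str, ...]:
    return tuple(_PARAM_TABLE)


def get_preset(name: str) -> PatternPreset:
    """Return the published preset for one of P0, pulsatile, P2, P1."""
    if name not in _PARAM_TABLE:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PARAM_TABLE)}")
    return PatternPreset(
        name=name,
        params=_params_from_table(name),
        schedule={},
        sim=SimSettings(t_end=_HORIZON[name]),
    )


def _resolve_initial(preset: PatternPreset) -> NetworkState:
    if preset.sim.initial == "origin":
        return NetworkState(0.0, 0.0, 0.0, 0.0)
    if preset.sim.initial == "rest":
        return resting_state(preset.params, dt=preset.sim.dt)
    raise ValueError(f"unknown initial-condition policy {preset.sim.initial!r}")


def run_pattern(
    preset: PatternPreset | str,
    *,
    params: Optional[ModelParams] = None,
    schedule: Optional[dict] = None,
    sim: Optional[dict] = None,
    drives: Optional[DriveSet] = None,
    initial: Optional[NetworkState] = None,
) -> Trajectory:
    """Simulate one pattern preset, with optional overrides.

    ``schedule`` entries are passed to :func:`~canaryresp.drives.build_drives`
    (or pass a fully explicit ``drives``); ``sim`` entries override fields of
    :class:`SimSettings`.  Returns the trajectory tagged with the preset name.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if params is not None:
        preset = replace(preset, params=params)
    if schedule is not None:
        preset = replace(preset, schedule={**preset.schedule, **schedule})
    if sim is not None:
        preset = replace(preset, sim=replace(preset.sim, **sim))

    drv = drives if drives is not None else preset.drives()
    init = initial if initial is not None else _resolve_initial(preset)
    traj = integrate(
        preset.params, drv, preset.sim.t0, preset.sim.t_end, preset.sim.dt, init
    )
    traj.meta["preset"] = preset.name
    return traj


def run_cooling_experiment(
    stretch: float = COOLING_STRETCH_MS,
    extra_delay: float = COOLING_DELAY_MS,
    mode: str = "both",
    preset: PatternPreset | str = "P0",
    sim: Optional[dict] = None,
) -> tuple[Trajectory, Trajectory]:
    """Run a pattern at normal and cooled HVC temperature.

    Returns ``(normal, cooled)`` trajectories.  Both runs share the circuit
    parameters, the initiating-area pulse and the initial condition; cooling
    only stretches (and, for ``mode="both"``, delays) the HVC-derived pulses
    Fd and Fd2.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if sim is not None:
        preset = replace(preset, sim=replace(preset.sim, **sim))
    drv = preset.drives()
    cooled_drv = apply_cooling(drv, stretch=stretch, extra_delay=extra_delay, mode=mode)
    init = _resolve_initial(preset)
    normal = run_pattern(preset, drives=drv, initial=init)
    cooled = run_pattern(preset, drives=cooled_drv, initial=init)
    cooled.meta["cooling"] = {"stretch": stretch, "extra_delay": extra_delay, "mode": mode}
    return normal, cooled
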