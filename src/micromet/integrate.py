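"""Scenario definitions and the delay-ODE integrator front end.

Three canonical scenarios describe the interaction of an initiating
micrometastasis (30 cells, M0 = 0.00081 n.u.) with the immune system:

1. non-immunogenic growth (no T-cell activation, ``k_apc = 0``), read out
   at day 30;
2. inherent antitumor response (``k_apc = 0.04``), read out at day 1500;
3. immunotherapy-supported response (``k_apc = 0.04`` plus the pulsed
   vaccine input), read out at day 1500.

Integration uses the method of steps on a fixed-step classical RK4 scheme
(default 0.05 d), with the delayed T value read from the stored trajectory
by linear interpolation and a constant pre-history ``T(t) = T0`` for t < 0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .model import ModelParameters, Regimen, SystemState, VaccineSchedule

__all__ = [
    "Scenario",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "run_scenario",
    "DEFAULT_STEP",
]

DEFAULT_STEP = 0.05

#: One tumor cell in normalized units (M0 = 0.00081 n.u. represents a
#: 30-cell initiating cluster). A deterministic ODE would let vanishingly
#: small populations (far below a single cell) regrow after therapy ends;
#: populations pushed below one cell are instead treated as eradicated.
EXTINCTION_THRESHOLD = 2.7e-5

_SCENARIO_DEFAULTS = {
    1: dict(k_apc=0.0, vaccine=False, horizon=30.0, evaluation_time=30.0),
    2: dict(k_apc=0.04, vaccine=False, horizon=1500.0, evaluation_time=1500.0),
    3: dict(k_apc=0.04, vaccine=True, horizon=1500.0, evaluation_time=1500.0),
}


class IntegrationError(RuntimeError):
    """Raised when a trajectory diverges; carries the offending time."""

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class Scenario:
    """A simulation setting: initial state, activation override, vaccine
    flag, horizon and read-out time (all times in days).

    ``id`` 1-3 are the canonical scenarios (build them with
    :meth:`from_id`); ``id = 0`` marks an ad-hoc scenario.
    """

    id: int = 0
    T0: float = 0.0
    M0: float = 0.00081
    k_apc: float | None = None
    vaccine: bool = False
    horizon: float = 1500.0
    evaluation_time: float = 1500.0

    def __post_init__(self):
        if self.T0 < 0 or self.M0 < 0:
            raise ValueError("initial populations must be >= 0")
        if self.horizon < self.evaluation_time:
            raise ValueError("horizon must cover evaluation_time")

    @classmethod
    def from_id(cls, scenario_id: int, **overrides) -> "Scenario":
        if scenario_id not in _SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario id {scenario_id!r}; expected 1, 2 or 3")
        kwargs = dict(_SCENARIO_DEFAULTS[scenario_id])
        kwargs.update(overrides)
        return cls(id=scenario_id, **kwargs)


@dataclass
class Trajectory:
    """Time course of (T, M) on a uniform grid starting at t = 0."""

    times: np.ndarray
    T: np.ndarray
    M: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if not (len(self.times) == len(self.T) == len(self.M)):
            raise ValueError("times, T and M must have equal length")
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name, arr in (("T", self.T), ("M", self.M)):
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} values must be finite and >= 0")

    def at(self, t: float) -> SystemState:
        return SystemState(float(np.interp(t, self.times, self.T)),
                           float(np.interp(t, self.times, self.M)))

    def M_at(self, t: float) -> float:
        return self.at(t).M

    @property
    def endpoint(self) -> SystemState:
        return SystemState(float(self.T[-1]), float(self.M[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "T": self.T, "M": self.M})

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {k: v for k, v in self.metadata.items()}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=str))

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(frame["time"].to_numpy(), frame["T"].to_numpy(),
                   frame["M"].to_numpy(), metadata)


def _params_hash(params: ModelParameters) -> str:
    payload = repr(tuple(params.to_array()))
    return hashlib.md5(payload.encode()).hexdigest()[:12]


def integrate(
    params: ModelParameters,
    scenario: Scenario,
    regimen: Regimen | None = None,
    schedule: VaccineSchedule = VaccineSchedule(),
    step: float = DEFAULT_STEP,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> Trajectory:
    """Integrate the delayed system for one scenario and return the
    trajectory on the uniform output grid.

    The vaccine input is active only when both the scenario and the regimen
    include it. A melanoma population falling below ``extinction_threshold``
    (default: one cell) is absorbed at zero; pass 0 to disable. Raises
    :class:`IntegrationError` (naming the time) if any population exceeds
    the divergence guard or becomes non-finite.
    """
    if regimen is None:
        regimen = Regimen(vaccine=scenario.vaccine)
    if step <= 0:
        raise ValueError("step must be positive")
    if step > params.t_dtc / 10.0:
        raise ValueError(f"step {step} too large; require step <= t_dtc/10 = {params.t_dtc / 10}")
    n_steps = int(round(scenario.horizon / step))
    if abs(n_steps * step - scenario.horizon) > 1e-9:
        raise ValueError("horizon must be an integer number of steps")
    k_eval = scenario.evaluation_time / step
    if abs(k_eval - round(k_eval)) > 1e-9:
        raise ValueError("evaluation_time must fall on the output grid")

    if scenario.k_apc is not None:
        params = params.replace(k_apc=scenario.k_apc)

    vac_on = bool(scenario.vaccine and regimen.vaccine)
    T_hist, u_hist, status, fail = _kernel.rk4_dde(
        params.to_array(), float(scenario.T0), float(scenario.M0),
        n_steps, float(step),
        vac_on, schedule.end_time, schedule.cycle_length,
        schedule.pulse_length, schedule.amplitude,
        bool(regimen.il2), bool(regimen.ifna),
        regimen.il2_factor, regimen.ifna_factor, regimen.therapy_window,
        np.log(extinction_threshold) if extinction_threshold > 0 else -np.inf,
    )
    if status != _kernel.STATUS_OK:
        t_fail = fail * step
        raise IntegrationError(
            f"integration diverged at t = {t_fail:g} d (scenario {scenario.id})", t_fail)

    times = np.arange(n_steps + 1) * step
    if scenario.M0 == 0.0:
        M = np.zeros(n_steps + 1)
    else:
        M = np.exp(u_hist)
        M[u_hist <= _kernel.U_FLOOR] = 0.0
    return Trajectory(times, T_hist, M, metadata={
        "scenario": scenario.id,
        "params_hash": _params_hash(params),
        "step": step,
        "vaccine": vac_on,
        "il2": regimen.il2,
        "ifna": regimen.ifna,
    })


def run_scenario(
    params: ModelParameters,
    scenario_id: int,
    step: float = DEFAULT_STEP,
    schedule: VaccineSchedule = VaccineSchedule(),
) -> Trajectory:
    """Run one of the three canonical scenarios with its standard initial
    condition and read-out horizon."""
    scenario = Scenario.from_id(scenario_id)
    regimen = Regimen(vaccine=scenario.vaccine)
    return integrate(params, scenario, regimen, schedule, step)
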