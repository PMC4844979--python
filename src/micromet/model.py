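"""Core kinetic model of the tumor--immune interaction in melanoma micrometastasis.

The model couples two populations in normalized units (n.u.): cytotoxic
T cells ``T`` and melanoma cells ``M`` in a pre-angiogenic micrometastasis.
The governing system is a pair of nonlinear ODEs with a single discrete time
delay in the T-cell depletion term:

.. math::

    dT/dt = (k_{apc} + k_{gir} V_c(t))
            \\frac{(k_{atg} M)^{g_1}}{k_{tapc}^{g_1} + (k_{atg} M)^{g_1}}
          + k_{atc} T \\frac{(k_{atg} M)^{g_2}}{k_{tatc}^{g_2} + (k_{atg} M)^{g_2}}
          - k_{dtc}\\left(T^3 + \\rho_{mem} T(t - t_{dtc})\\right)

    dM/dt = k_{pmc} M (1 - M/M_T)
          - \\frac{k_{iap} k_{atg}}{1 + k_{iev}} T M
          - k_{ink} M \\frac{k_{nkc}^{g_{nk}}}{k_{nkc}^{g_{nk}} + k_{atg}^{g_{nk}}}

Term by term: APC-mediated activation of naive T cells (inherent ``k_apc``
plus the pulsed vaccine input amplified by ``k_gir``), saturating in the
amount of presented antigen ``k_atg * M``; antigen-driven self-expansion of
activated T cells; biphasic depletion (fast third-order decay plus a small
delayed contribution standing in for long-lived memory cells); logistic
self-limited tumor growth; T-cell-mediated killing proportional to antigen
presentation and attenuated by immune evasion ``k_iev``; and NK-cell killing
that switches on when surface antigen presentation (HLA, lumped into
``k_atg``) is low, modelled by a decreasing Hill function.

The displayed algebraic forms are a reconstruction assembled from the
qualitative description of each rate process; every stated dependency
(saturating activation, evasion-attenuated killing, NK activity decreasing
in antigen presentation, biphasic depletion) is reproduced and the forms
are validated dynamically elsewhere in the package (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import yaml

__all__ = [
    "PARAM_ORDER",
    "SCREENED_PARAMS",
    "ModelParameters",
    "VaccineSchedule",
    "Regimen",
    "SystemState",
    "nominal_values",
    "vaccine_input",
    "effective_parameters",
    "model_rhs",
]

#: Canonical field order used by the integration kernel and array round-trips.
PARAM_ORDER = (
    "k_pmc", "M_T", "k_iap", "k_ink", "k_atg", "k_iev", "k_nkc", "g_nk",
    "k_apc", "k_gir", "k_atc", "k_tapc", "g_1", "k_tatc", "g_2",
    "k_dtc", "rho_mem", "t_dtc",
)

#: The five parameters perturbed in the virtual-patient screen.
SCREENED_PARAMS = ("k_pmc", "k_atg", "k_iap", "k_iev", "k_gir")

#: Ratio tying NK-mediated killing to T-cell cytotoxic efficiency.
K_INK_RATIO = 0.02

_NOMINAL: dict[str, float] | None = None


def nominal_values() -> dict[str, float]:
    """Nominal parameter values loaded from the packaged config file."""
    global _NOMINAL
    if _NOMINAL is None:
        text = resources.files("micromet.data").joinpath("nominal_params.yaml").read_text()
        _NOMINAL = {k: float(v) for k, v in yaml.safe_load(text).items()}
    return dict(_NOMINAL)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and exponents of the tumor--immune system.

    All rates are per day, populations in normalized units. Fields left as
    ``None`` are filled from the nominal configuration; ``k_ink`` defaults to
    ``0.02 * k_iap`` unless set explicitly.
    """

    k_pmc: float = None
    M_T: float = None
    k_iap: float = None
    k_ink: float = None
    k_atg: float = None
    k_iev: float = None
    k_nkc: float = None
    g_nk: float = None
    k_apc: float = None
    k_gir: float = None
    k_atc: float = None
    k_tapc: float = None
    g_1: float = None
    k_tatc: float = None
    g_2: float = None
    k_dtc: float = None
    rho_mem: float = None
    t_dtc: float = None

    def __post_init__(self):
        nominal = nominal_values()
        for name in PARAM_ORDER:
            if getattr(self, name) is None:
                if name == "k_ink":
                    object.__setattr__(self, name, K_INK_RATIO * self.k_iap)
                else:
                    object.__setattr__(self, name, nominal[name])
            else:
                object.__setattr__(self, name, float(getattr(self, name)))
        self._validate()

    def _validate(self):
        for name in PARAM_ORDER:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name}={v!r} must be finite and >= 0")
        if self.M_T <= 0:
            raise ValueError("M_T must be positive")
        for name in ("g_1", "g_2", "g_nk"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill exponent {name} must be >= 1")
        if self.t_dtc <= 0:
            raise ValueError("t_dtc must be positive")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_ORDER}

    def to_array(self):
        import numpy as np

        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ModelParameters":
        return cls(**dict(zip(PARAM_ORDER, map(float, values))))


@dataclass(frozen=True)
class VaccineSchedule:
    """Pulsed vaccine input: ``n_cycles`` cycles of ``cycle_length`` days,
    each starting with a ``pulse_length``-day pulse of the given amplitude."""

    n_cycles: int = 6
    cycle_length: float = 180.0
    pulse_length: float = 5.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if not 0 < self.pulse_length < self.cycle_length:
            raise ValueError("require 0 < pulse_length < cycle_length")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def end_time(self) -> float:
        return self.n_cycles * self.cycle_length


@dataclass(frozen=True)
class Regimen:
    """Therapy composition: the vaccine plus optional cytokine co-adjuvants.

    IL-2 boosts T-cell cytotoxicity and self-expansion (``k_iap``, ``k_atc``);
    IFN-alpha upregulates HLA, i.e. antigen presentation (``k_atg``). The
    co-adjuvant factors apply only during the first ``therapy_window`` days.
    """

    vaccine: bool = True
    il2: bool = False
    ifna: bool = False
    il2_factor: float = 10.0
    ifna_factor: float = 15.0
    therapy_window: float = 30.0

    def __post_init__(self):
        if self.il2_factor < 1 or self.ifna_factor < 1:
            raise ValueError("co-adjuvant factors must be >= 1")
        if self.therapy_window < 0:
            raise ValueError("therapy_window must be >= 0")

    @classmethod
    def none(cls) -> "Regimen":
        return cls(vaccine=False)

    @classmethod
    def vaccine_only(cls) -> "Regimen":
        return cls(vaccine=True)


class SystemState(NamedTuple):
    """Instantaneous state: T cells and melanoma cells, both in n.u."""

    T: float
    M: float


def vaccine_input(t: float, schedule: VaccineSchedule = VaccineSchedule()) -> float:
    """Vaccine activation level at time ``t`` (days).

    Returns the pulse amplitude while ``t mod cycle_length`` lies strictly
    inside ``(0, pulse_length)`` and ``t`` is within the scheduled cycles,
    otherwise 0.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if t >= schedule.end_time:
        return 0.0
    phase = t % schedule.cycle_length
    return schedule.amplitude if 0.0 < phase < schedule.pulse_length else 0.0


def effective_parameters(params: ModelParameters, regimen: Regimen, t: float) -> ModelParameters:
    """Parameters as modified by active co-adjuvants at time ``t``.

    Inside the therapy window IL-2 multiplies ``k_iap`` and ``k_atc`` by
    ``il2_factor`` and IFN-alpha multiplies ``k_atg`` by ``ifna_factor``;
    outside the window the input is returned unchanged. The input object is
    never mutated.
    """
    if not (regimen.il2 or regimen.ifna) or not (0 <= t < regimen.therapy_window):
        return params
    changes: dict[str, float] = {}
    if regimen.il2:
        changes["k_iap"] = params.k_iap * regimen.il2_factor
        changes["k_atc"] = params.k_atc * regimen.il2_factor
    if regimen.ifna:
        changes["k_atg"] = params.k_atg * regimen.ifna_factor
    return params.replace(**changes)


def model_rhs(
    t: float,
    state: SystemState,
    delayed_T: float,
    params: ModelParameters,
    schedule: VaccineSchedule = VaccineSchedule(),
    regimen: Regimen = Regimen.none(),
) -> tuple[float, float]:
    """Right-hand side (dT/dt, dM/dt) of the delayed system at time ``t``.

    ``delayed_T`` is the T-cell population at ``t - t_dtc``. Co-adjuvant
    modifications are applied through :func:`effective_parameters`; the
    vaccine input is evaluated only when the regimen includes it.
    """
    T, M = state
    if not (math.isfinite(T) and math.isfinite(M) and math.isfinite(delayed_T)):
        raise ValueError("state and delayed_T must be finite")
    if T < 0 or M < 0 or delayed_T < 0:
        raise ValueError("state and delayed_T must be >= 0")

    p = effective_parameters(params, regimen, t)
    vc = vaccine_input(t, schedule) if regimen.vaccine else 0.0

    am = p.k_atg * M
    if am > 0:
        act = (p.k_apc + p.k_gir * vc) * am ** p.g_1 / (p.k_tapc ** p.g_1 + am ** p.g_1)
        expand = p.k_atc * T * am ** p.g_2 / (p.k_tatc ** p.g_2 + am ** p.g_2)
    else:
        act = 0.0
        expand = 0.0
    dT = act + expand - p.k_dtc * (T ** 3 + p.rho_mem * delayed_T)

    growth = p.k_pmc * M * (1.0 - M / p.M_T)
    t_kill = (p.k_iap * p.k_atg / (1.0 + p.k_iev)) * T * M
    nk_kill = p.k_ink * M * p.k_nkc ** p.g_nk / (p.k_nkc ** p.g_nk + p.k_atg ** p.g_nk)
    dM = growth - t_kill - nk_kill
    return dT, dM
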