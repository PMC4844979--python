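"""Mathematical persistence analysis of the tumor-free state.

While the T-cell population sits at a transiently stable level ``T_s``, the
melanoma equation linearized at M -> 0 gives a per-capita balance between
growth and immune elimination. The immune-efficiency function

    F_imef(T_s) = k_iap * k_atg / (1 + k_iev) * T_s
                + k_ink * k_nkc^g_nk / (k_nkc^g_nk + k_atg^g_nk)

is the per-capita loss rate of M near extinction (T-cell killing plus NK
killing). The micrometastasis persists — the tumor-free state is unstable
and a non-zero steady state exists — exactly when the tumor growth rate
exceeds it, ``k_pmc > F_imef``. Because the T-killing part grows linearly
in antigen presentation while the NK part falls with it, the total
elimination pressure can have an interior minimum in ``k_atg``: tumors with
an intermediate level of antigen presentation minimize the combined T/NK
attack, the resistance mechanism highlighted by the screen's
vaccine-resistant signatures.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .model import ModelParameters, Regimen, SystemState, VaccineSchedule, model_rhs

__all__ = [
    "f_imef",
    "persists",
    "zero_tumor_growth_rate",
    "total_killing_rate",
    "frozen_T_growth_rate",
    "f_imef_grid",
    "KILLING_CURVE_CALIBRATION",
]

#: Documented calibration setting for the total-killing-rate curve: strong
#: immune evasion makes the T-cell and NK contributions comparable, so the
#: combined per-capita killing over k_atg in [0.01, 100] dips at an
#: intermediate antigen presentation level (T = M = 1 n.u.).
KILLING_CURVE_CALIBRATION = dict(k_iap=1.0, k_iev=100.0, k_ink=0.02, k_nkc=1.0, g_nk=6.0)


def _nk_hill(params: ModelParameters, k_atg: float | np.ndarray):
    return params.k_nkc ** params.g_nk / (params.k_nkc ** params.g_nk + k_atg ** params.g_nk)


def f_imef(params: ModelParameters, T_s: float) -> float:
    """Immune-elimination efficiency (1/day) at steady T-cell level ``T_s``:
    the per-capita loss rate of M at M -> 0."""
    if T_s < 0:
        raise ValueError("T_s must be >= 0")
    t_kill = params.k_iap * params.k_atg / (1.0 + params.k_iev) * T_s
    nk_kill = params.k_ink * _nk_hill(params, params.k_atg)
    return t_kill + nk_kill


def persists(params: ModelParameters, T_s: float) -> tuple[bool, float]:
    """Whether the micrometastasis resists an immune response held at
    ``T_s``, with the margin ``k_pmc - F_imef`` (1/day)."""
    margin = params.k_pmc - f_imef(params, T_s)
    return margin > 0, margin


def zero_tumor_growth_rate(params: ModelParameters, T_s: float) -> float:
    """Linearized growth rate of M at the tumor-free state (1/day);
    positive iff M = 0 is unstable iff the tumor persists."""
    return params.k_pmc - f_imef(params, T_s)


def total_killing_rate(
    k_atg_value: float,
    params: ModelParameters,
    T: float = 1.0,
    M: float = 1.0,
) -> float:
    """Combined per-capita melanoma killing rate (1/day) by T cells and NK
    cells at the given antigen presentation level.

    Per unit of M both contributions are independent of M; ``M`` is kept in
    the signature for symmetry with the trajectory read-outs.
    """
    if k_atg_value <= 0:
        raise ValueError("k_atg_value must be positive")
    t_kill = params.k_iap * k_atg_value / (1.0 + params.k_iev) * T
    nk_kill = params.k_ink * _nk_hill(params, k_atg_value)
    return t_kill + nk_kill


def frozen_T_growth_rate(
    params: ModelParameters,
    T_s: float,
    M0: float = 1e-4,
    horizon: float = 0.5,
    step: float = 0.005,
) -> float:
    """Per-capita growth rate of M from a short simulation with the T-cell
    population clamped at ``T_s``.

    Integrates the melanoma equation alone (classical RK4 on ln M, T frozen,
    no vaccine input) from ``M0`` and returns (ln M(h) - ln M0) / h — the
    dynamical counterpart of :func:`zero_tumor_growth_rate` used to validate
    the persistence inequality against the full right-hand side.
    """
    if M0 <= 0:
        raise ValueError("M0 must be positive")
    regimen = Regimen.none()
    schedule = VaccineSchedule()

    def du(t: float, u: float) -> float:
        M = math.exp(u)
        _, dM = model_rhs(t, SystemState(T_s, M), T_s, params, schedule, regimen)
        return dM / M

    u = math.log(M0)
    n = int(round(horizon / step))
    for i in range(n):
        t = i * step
        k1 = du(t, u)
        k2 = du(t + step / 2, u + step / 2 * k1)
        k3 = du(t + step / 2, u + step / 2 * k2)
        k4 = du(t + step, u + step * k3)
        u += step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return (u - math.log(M0)) / horizon


def f_imef_grid(
    params: ModelParameters,
    T_s_values,
    k_atg_values,
) -> pd.DataFrame:
    """F_imef evaluated on a (T_s, k_atg) grid, long format (columns
    ``T_s``, ``k_atg``, ``F_imef``) ready for surface plotting or TSV
    export. All other parameters, including k_iev, stay at their configured
    values."""
    records = []
    for ts in T_s_values:
        for ka in k_atg_values:
            records.append((ts, ka, f_imef(params.replace(k_atg=ka), ts)))
    return pd.DataFrame(records, columns=["T_s", "k_atg", "F_imef"])
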