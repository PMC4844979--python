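"""Co-adjuvant therapy simulation on the vaccine-resistant cohort.

The therapeutic vaccine is combined with low-dose cytokine co-adjuvants:
IL-2 (boosts T-cell cytotoxicity k_iap and self-expansion k_atc by a factor
of 10) and IFN-alpha (upregulates HLA, i.e. antigen presentation k_atg, by
a factor of 15). Therapy acts during the first 30 days; simulations start
from the standard initiating micrometastasis (T0 = 0, M0 = 0.00081,
k_apc = 0.04) and run to day 100, where depletion is scored against the
0.05-n.u. control threshold.
"""

from __future__ import annotations

import pandas as pd

from .integrate import DEFAULT_STEP, Scenario, Trajectory, integrate
from .model import ModelParameters, Regimen, VaccineSchedule
from .screen import CONTROL_THRESHOLD, params_from_row

__all__ = ["REGIMENS", "simulate_regimen", "depletion_fraction", "compare_regimens"]

#: The four regimens of the co-adjuvant comparison.
REGIMENS: dict[str, Regimen] = {
    "vaccine_only": Regimen(vaccine=True),
    "il2": Regimen(vaccine=True, il2=True),
    "ifna": Regimen(vaccine=True, ifna=True),
    "both": Regimen(vaccine=True, il2=True, ifna=True),
}

THERAPY_HORIZON = 100.0


def simulate_regimen(
    params: ModelParameters,
    regimen: Regimen,
    horizon: float = THERAPY_HORIZON,
    step: float = DEFAULT_STEP,
    schedule: VaccineSchedule = VaccineSchedule(),
) -> Trajectory:
    """Trajectory under one regimen from the standard initial condition
    (first vaccine cycle of the standard schedule; co-adjuvant factors
    active inside the regimen's therapy window)."""
    scenario = Scenario(id=0, T0=0.0, M0=0.00081, k_apc=0.04,
                        vaccine=regimen.vaccine, horizon=horizon,
                        evaluation_time=horizon)
    return integrate(params, scenario, regimen, schedule, step)


def depletion_fraction(
    cohort: pd.DataFrame,
    regimen: Regimen,
    threshold: float = CONTROL_THRESHOLD,
    at_day: float = THERAPY_HORIZON,
    step: float = DEFAULT_STEP,
) -> float:
    """Fraction of cohort rows whose melanoma population is below
    ``threshold`` at ``at_day`` under the regimen.

    ``cohort`` is a frame of screened-parameter rows (e.g. the
    vaccine-resistant block of a :class:`~micromet.screen.ScreenResult`).
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    depleted = 0
    for _, row in cohort.iterrows():
        traj = simulate_regimen(params_from_row(row), regimen,
                                horizon=at_day, step=step)
        if traj.M[-1] < threshold:
            depleted += 1
    return depleted / len(cohort)


def compare_regimens(
    cohort: pd.DataFrame,
    regimens: dict[str, Regimen] = REGIMENS,
    threshold: float = CONTROL_THRESHOLD,
    at_day: float = THERAPY_HORIZON,
    step: float = DEFAULT_STEP,
) -> dict[str, float]:
    """Depletion fraction per regimen on the same cohort."""
    return {name: depletion_fraction(cohort, regimen, threshold, at_day, step)
            for name, regimen in regimens.items()}
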