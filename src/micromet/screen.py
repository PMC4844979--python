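"""Virtual-patient cohort screen.

Five biologically interpretable parameters — tumor proliferation
(``k_pmc``), antigen presentation (``k_atg``), T-cell cytotoxic efficiency
(``k_iap``), immune evasion (``k_iev``) and the vaccine-induced systemic
response (``k_gir``) — are perturbed by Latin hypercube sampling in log10
space (``k_pmc`` in [1, 5], the others in [0.02, 50]). Each sampled
parameter set is simulated under the three canonical scenarios and
classified:

* ``non_tumor``      — M(30) <= 0.9 under non-immunogenic growth;
* ``immune_sensitive`` — tumor grows in scenario 1 but M(1500) < 0.05
  under the inherent response;
* ``vaccine_sensitive`` — resistant to the inherent response but
  M(1500) < 0.05 under vaccination;
* ``vaccine_resistant`` — resistant to both.

Ties at the thresholds go to the less-sensitive label (strict
inequalities). ``k_ink`` tracks the sampled ``k_iap`` through the fixed
ratio 0.02.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .integrate import DEFAULT_STEP, IntegrationError, run_scenario
from .model import SCREENED_PARAMS, ModelParameters

__all__ = [
    "INTERVALS",
    "PHENOTYPE_LABELS",
    "TUMOR_THRESHOLD",
    "CONTROL_THRESHOLD",
    "ParameterMatrix",
    "ScreenResult",
    "lhs_sample",
    "classify",
    "run_screen",
    "params_from_row",
]

#: Sampling intervals (linear scale); sampling is log10-uniform within each.
INTERVALS: dict[str, tuple[float, float]] = {
    "k_pmc": (1.0, 5.0),
    "k_atg": (0.02, 50.0),
    "k_iap": (0.02, 50.0),
    "k_iev": (0.02, 50.0),
    "k_gir": (0.02, 50.0),
}

PHENOTYPE_LABELS = (
    "non_tumor", "immune_sensitive", "vaccine_sensitive",
    "vaccine_resistant", "unclassified",
)

#: scenario-1 tumor-growth criterion: M(30) must exceed this (n.u.).
TUMOR_THRESHOLD = 0.9
#: depleted/controlled criterion at day 1500 (n.u.).
CONTROL_THRESHOLD = 0.05


@dataclass
class ParameterMatrix:
    """An LHS design over the five screened parameters (linear scale)."""

    values: pd.DataFrame
    seed: int
    intervals: dict[str, tuple[float, float]]

    def __post_init__(self):
        if list(self.values.columns) != list(SCREENED_PARAMS):
            raise ValueError(f"columns must be {SCREENED_PARAMS}")

    def __len__(self) -> int:
        return len(self.values)


def lhs_sample(n: int, seed: int) -> ParameterMatrix:
    """Latin hypercube design of ``n`` parameter sets, log10-uniform per
    interval, with exactly one sample per equal-width log10 stratum per
    column. Reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(SCREENED_PARAMS), seed=seed)
    unit = sampler.random(n)
    cols = {}
    for j, name in enumerate(SCREENED_PARAMS):
        lo, hi = INTERVALS[name]
        cols[name] = 10.0 ** (math.log10(lo) + unit[:, j] * (math.log10(hi) - math.log10(lo)))
    frame = pd.DataFrame(cols, columns=list(SCREENED_PARAMS))
    return ParameterMatrix(frame, seed=seed, intervals=dict(INTERVALS))


def params_from_row(row) -> ModelParameters:
    """Full parameter object for one screen row; unscreened parameters stay
    nominal and ``k_ink`` follows the sampled ``k_iap``."""
    return ModelParameters(**{name: float(row[name]) for name in SCREENED_PARAMS})


def classify(m1: float, m2: float, m3: float) -> str:
    """Phenotype label from the three scenario endpoints.

    ``m2``/``m3`` may be NaN when the corresponding scenario was skipped
    because an earlier criterion already decided the label.
    """
    for value in (m1, m2, m3):
        if value is not None and not math.isnan(value) and value < 0:
            raise ValueError("endpoints must be >= 0")
    if not m1 > TUMOR_THRESHOLD:
        return "non_tumor"
    if m2 < CONTROL_THRESHOLD:
        return "immune_sensitive"
    if m3 < CONTROL_THRESHOLD:
        return "vaccine_sensitive"
    return "vaccine_resistant"


@dataclass
class ScreenResult:
    """Sampled parameters, scenario endpoints and phenotype labels.

    ``table`` columns: the five parameters, ``M1`` (day-30 endpoint of
    scenario 1), ``M2``/``M3`` (day-1500 endpoints; NaN when skipped),
    ``label`` and ``diverged``. Diverged rows are labelled ``unclassified``
    and must be excluded from signature mining.
    """

    table: pd.DataFrame
    seed: int
    step: float
    intervals: dict[str, tuple[float, float]]

    def __len__(self) -> int:
        return len(self.table)

    def group_counts(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        return {label: int(counts.get(label, 0)) for label in PHENOTYPE_LABELS}

    def group(self, label: str) -> pd.DataFrame:
        if label not in PHENOTYPE_LABELS:
            raise ValueError(f"unknown label {label!r}")
        mask = (self.table["label"] == label) & ~self.table["diverged"]
        return self.table.loc[mask]

    def parameters(self, label: str) -> pd.DataFrame:
        """Screened-parameter block for one phenotype group (diverged rows
        excluded)."""
        return self.group(label)[list(SCREENED_PARAMS)]

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=True, index_label="row")
        sidecar = {
            "seed": self.seed,
            "step": self.step,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "n": len(self.table),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "ScreenResult":
        path = Path(path)
        table = pd.read_csv(path, sep="\t", index_col="row", float_precision="round_trip")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        intervals = {k: tuple(v) for k, v in meta.get("intervals", INTERVALS).items()}
        return cls(table, seed=meta.get("seed", -1), step=meta.get("step", DEFAULT_STEP),
                   intervals=intervals)


def run_screen(
    n: int = 10_000,
    seed: int = 0,
    step: float = DEFAULT_STEP,
    design: ParameterMatrix | None = None,
    progress: bool = False,
) -> ScreenResult:
    """Simulate and classify a virtual cohort.

    One LHS design is reused across the three scenarios. Scenarios 2 and 3
    are run only when an earlier endpoint has not already fixed the label
    (pure optimization: the skipped endpoints cannot change the outcome).
    Rows whose integration diverges are flagged, not dropped.
    """
    design = lhs_sample(n, seed) if design is None else design
    rows = design.values
    iterator = rows.iterrows()
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, total=len(rows), desc="screen")

    records = []
    for idx, row in iterator:
        params = params_from_row(row)
        m1 = m2 = m3 = float("nan")
        diverged = False
        try:
            m1 = run_scenario(params, 1, step=step).M[-1]
            if m1 > TUMOR_THRESHOLD:
                m2 = run_scenario(params, 2, step=step).M[-1]
                if not m2 < CONTROL_THRESHOLD:
                    m3 = run_scenario(params, 3, step=step).M[-1]
        except IntegrationError:
            diverged = True
        label = "unclassified" if diverged else classify(m1, m2, m3)
        records.append({**{k: row[k] for k in SCREENED_PARAMS},
                        "M1": m1, "M2": m2, "M3": m3,
                        "label": label, "diverged": diverged})

    table = pd.DataFrame.from_records(records, index=rows.index)
    return ScreenResult(table, seed=design.seed, step=step, intervals=design.intervals)
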