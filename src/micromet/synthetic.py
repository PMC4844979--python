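"""Synthetic patient-expression cohorts.

The clinical input of the comparison pipeline is a pretreatment expression
matrix of 84 immune-related genes over melanoma patients with and without
clinical benefit from immunotherapy. That dataset is not redistributable,
so this module generates matrices with the same structure: genes split
across the five functional categories, two patient groups whose
category-level mean expression encodes the qualitative clinical contrast —
benefit patients high in antigen presentation and general immune response,
non-benefit patients intermediate in antigen presentation and low in
immune-mediated apoptosis — plus independent Gaussian noise per gene and
sample on the (log-like) relative-expression scale.

Everything downstream (metagene aggregation, patient clustering, profile
comparison) treats these files exactly like real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metagenes import ALL_CATEGORIES

__all__ = [
    "DEFAULT_GENES_PER_CATEGORY",
    "DEFAULT_CATEGORY_MEANS",
    "SyntheticCohort",
    "generate_expression",
]

#: Split of the 84-gene signature across the five categories. The original
#: per-category counts are not published; this fixed split is a synthetic
#: stand-in.
DEFAULT_GENES_PER_CATEGORY = (20, 20, 20, 14, 10)

#: Group-level mean relative expression per category, order as
#: ALL_CATEGORIES. Benefit: high antigen presentation and general immune
#: response; non-benefit: intermediate antigen presentation, low
#: immune-mediated apoptosis, elevated evasion.
DEFAULT_CATEGORY_MEANS = {
    "benefit": (6.0, 4.0, 1.5, 6.0, 2.0),
    "nonbenefit": (2.5, 1.2, 3.0, 1.5, 2.0),
}

DEFAULT_NOISE_SD = 1.0


@dataclass
class SyntheticCohort:
    """Expression matrix (samples x genes), gene annotation table and true
    group labels of one simulated cohort."""

    expression: pd.DataFrame
    annotation: pd.DataFrame
    labels: pd.Series

    def write_tsv(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": directory / "expression.tsv",
            "annotation": directory / "annotation.tsv",
            "labels": directory / "labels.tsv",
        }
        self.expression.to_csv(paths["expression"], sep="\t", index_label="sample")
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.labels.rename("group").to_csv(paths["labels"], sep="\t", index_label="sample")
        return paths


def generate_expression(
    n_benefit: int = 14,
    n_nonbenefit: int = 22,
    genes_per_category: tuple[int, ...] = DEFAULT_GENES_PER_CATEGORY,
    category_means: dict[str, tuple[float, ...]] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate an expression cohort with category-structured group means.

    Gene ``g`` in category ``c`` for a sample of group ``j`` is drawn as
    ``category_means[j][c] + N(0, noise_sd)``, independently per gene and
    sample. Reproducible for a fixed seed.
    """
    if n_benefit < 1 or n_nonbenefit < 1:
        raise ValueError("both groups need at least one sample")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(genes_per_category) != len(ALL_CATEGORIES):
        raise ValueError(f"genes_per_category must have {len(ALL_CATEGORIES)} entries")
    if any(c < 1 for c in genes_per_category[:4]):
        raise ValueError("productive categories 1-4 need at least one gene each")
    if genes_per_category[-1] < 0:
        raise ValueError("gene counts must be >= 0")
    category_means = dict(DEFAULT_CATEGORY_MEANS if category_means is None else category_means)
    for group in ("benefit", "nonbenefit"):
        if len(category_means[group]) != len(ALL_CATEGORIES):
            raise ValueError(f"category_means[{group!r}] must have {len(ALL_CATEGORIES)} entries")

    gene_ids: list[str] = []
    categories: list[str] = []
    for cat, count in zip(ALL_CATEGORIES, genes_per_category):
        prefix = "".join(word[0].upper() for word in cat.split("_"))
        for k in range(count):
            gene_ids.append(f"{prefix}{k + 1:03d}")
            categories.append(cat)
    annotation = pd.DataFrame({"gene_id": gene_ids, "category": categories})

    samples = [f"Bn{j + 1:02d}" for j in range(n_benefit)] + \
              [f"Nbn{j + 1:02d}" for j in range(n_nonbenefit)]
    groups = ["benefit"] * n_benefit + ["nonbenefit"] * n_nonbenefit
    labels = pd.Series(groups, index=samples, name="group")

    cat_index = {cat: i for i, cat in enumerate(ALL_CATEGORIES)}
    gene_means = {
        group: np.array([category_means[group][cat_index[c]] for c in categories])
        for group in ("benefit", "nonbenefit")
    }
    rng = np.random.default_rng(seed)
    rows = [gene_means[group] + rng.normal(0.0, noise_sd, size=len(gene_ids))
            for group in groups]
    expression = pd.DataFrame(np.vstack(rows), index=samples, columns=gene_ids)
    return SyntheticCohort(expression, annotation, labels)
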