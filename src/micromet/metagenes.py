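"""Metagene aggregation and comparison of patient data with model signatures.

Genes of a pretreatment expression signature are annotated into five
functional categories; the first four map onto model parameters:

1. antigen presentation machinery      -> k_atg
2. immune-mediated tumor apoptosis /
   cytotoxic T-cell killing            -> k_iap
3. tumor immune evasion mechanisms     -> k_iev
4. general immune response             -> k_gir
5. none/unknown                        -> (ignored)

A metagene is the arithmetic average of the member genes' expression per
sample. Patients are clustered (complete linkage, Euclidean distance) and
the two subtrees of the root define the margin clusters, labelled clinical
benefit (Bn) / no clinical benefit (Nbn). Cluster-mean metagene profiles
and in-silico signature means, both log10-normalized to [-1, 1], are then
compared by Euclidean distance and co-clustered for a joint heat map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .signatures import log_normalize, _olo_linkage

__all__ = [
    "CATEGORIES",
    "ALL_CATEGORIES",
    "CATEGORY_TO_PARAM",
    "PatientClusters",
    "ComparisonResult",
    "aggregate_metagenes",
    "cluster_patients",
    "patient_profiles",
    "compare_signatures",
]

#: The four productive categories, in the fixed profile order.
CATEGORIES = ("antigen_presentation", "immune_apoptosis", "immune_evasion", "general_immune")
ALL_CATEGORIES = CATEGORIES + ("none_unknown",)
CATEGORY_TO_PARAM = {
    "antigen_presentation": "k_atg",
    "immune_apoptosis": "k_iap",
    "immune_evasion": "k_iev",
    "general_immune": "k_gir",
}


def _annotation_map(annotation) -> pd.Series:
    if isinstance(annotation, pd.DataFrame):
        if not {"gene_id", "category"} <= set(annotation.columns):
            raise ValueError("annotation table needs columns gene_id and category")
        mapping = annotation.set_index("gene_id")["category"]
    else:
        mapping = pd.Series(annotation)
    unknown = set(mapping.unique()) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    return mapping


def aggregate_metagenes(expression: pd.DataFrame, annotation) -> pd.DataFrame:
    """Per-sample metagene profile: arithmetic mean of member-gene
    expression for each of the four productive categories.

    ``expression`` is samples x genes; every gene column must be annotated
    and each productive category must contain at least one gene.
    Category-5 genes are ignored.
    """
    mapping = _annotation_map(annotation)
    missing = [g for g in expression.columns if g not in mapping.index]
    if missing:
        raise ValueError(f"unannotated genes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    out = {}
    for category in CATEGORIES:
        genes = [g for g in expression.columns if mapping[g] == category]
        if not genes:
            raise ValueError(f"category {category!r} has no genes in the matrix")
        out[category] = expression[genes].mean(axis=1)
    return pd.DataFrame(out, columns=list(CATEGORIES))


@dataclass
class PatientClusters:
    """Margin clusters of the patient dendrogram with raw metagene means."""

    benefit: list
    nonbenefit: list
    linkage: np.ndarray
    metagenes: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.benefit or not self.nonbenefit:
            raise ValueError("both clusters must be non-empty")
        if set(self.benefit) & set(self.nonbenefit):
            raise ValueError("clusters must be disjoint")


def cluster_patients(
    expression: pd.DataFrame,
    annotation=None,
    labels: pd.Series | dict | None = None,
) -> PatientClusters:
    """Complete-linkage Euclidean clustering of patient samples; the two
    subtrees of the dendrogram root are the margin clusters.

    Benefit/non-benefit naming uses sample ``labels`` (values ``benefit`` /
    ``nonbenefit``) by majority vote when given; otherwise the cluster with
    the higher mean general-immune metagene is called Bn (immunotherapy
    response tracks immunocompetence), which requires ``annotation``.
    """
    if len(expression) < 4:
        raise ValueError("need at least 4 samples to cluster")
    link = hierarchy.linkage(expression.to_numpy(dtype=float), method="complete",
                             metric="euclidean")
    assignment = hierarchy.fcluster(link, 2, criterion="maxclust")
    side_a = list(expression.index[assignment == 1])
    side_b = list(expression.index[assignment == 2])

    metagenes = aggregate_metagenes(expression, annotation) if annotation is not None else None
    if labels is not None:
        labels = pd.Series(labels)
        benefit_votes_a = (labels.loc[side_a] == "benefit").mean()
        benefit_votes_b = (labels.loc[side_b] == "benefit").mean()
        benefit, nonbenefit = ((side_a, side_b) if benefit_votes_a >= benefit_votes_b
                               else (side_b, side_a))
    elif metagenes is not None:
        gi = metagenes["general_immune"]
        benefit, nonbenefit = ((side_a, side_b)
                               if gi.loc[side_a].mean() >= gi.loc[side_b].mean()
                               else (side_b, side_a))
    else:
        raise ValueError("provide labels or an annotation to name the clusters")
    return PatientClusters(benefit, nonbenefit, link, metagenes)


def patient_profiles(
    expression: pd.DataFrame,
    annotation,
    clusters: PatientClusters | None = None,
    labels=None,
) -> tuple[pd.Series, pd.Series]:
    """Normalized cluster-mean metagene profiles (X_Bn, X_Nbn).

    Per-sample metagenes are log10-normalized to [-1, 1] per category over
    all samples, then averaged within each margin cluster.
    """
    if clusters is None:
        clusters = cluster_patients(expression, annotation=annotation, labels=labels)
    metagenes = aggregate_metagenes(expression, annotation)
    normalized = log_normalize(metagenes)
    x_bn = normalized.loc[clusters.benefit].mean(axis=0)
    x_nbn = normalized.loc[clusters.nonbenefit].mean(axis=0)
    return x_bn, x_nbn


@dataclass
class ComparisonResult:
    """Distances of in-silico signature means to the patient profiles, plus
    the joint clustering used for the side-by-side heat map."""

    distances: pd.DataFrame
    merged: pd.DataFrame
    linkage: np.ndarray
    order: np.ndarray

    def nearest(self, cluster) -> str:
        row = self.distances.loc[cluster]
        return "nonbenefit" if row["D_Nbn"] <= row["D_Bn"] else "benefit"


def compare_signatures(
    insilico: pd.DataFrame,
    x_bn: pd.Series,
    x_nbn: pd.Series,
) -> ComparisonResult:
    """Euclidean distances D_Bn = ||X - X_Bn|| and D_Nbn = ||X - X_Nbn|| for
    every in-silico cluster mean X, and a joint average-linkage clustering
    (optimal leaf ordering) of all profiles.

    All inputs must be log10-normalized to [-1, 1] on the shared four
    dimensions; in-silico columns may be named by parameter or by category
    (matched positionally in the fixed category order).
    """
    insilico = pd.DataFrame(insilico)
    if insilico.shape[1] != 4 or len(x_bn) != 4 or len(x_nbn) != 4:
        raise ValueError("profiles must have exactly the 4 mapped dimensions")
    x_bn = pd.Series(np.asarray(x_bn, dtype=float), index=list(CATEGORIES), name="Bn")
    x_nbn = pd.Series(np.asarray(x_nbn, dtype=float), index=list(CATEGORIES), name="Nbn")
    block = insilico.to_numpy(dtype=float)

    d_bn = np.linalg.norm(block - x_bn.to_numpy(), axis=1)
    d_nbn = np.linalg.norm(block - x_nbn.to_numpy(), axis=1)
    distances = pd.DataFrame({"D_Bn": d_bn, "D_Nbn": d_nbn}, index=insilico.index)
    distances["nearest"] = np.where(d_nbn <= d_bn, "nonbenefit", "benefit")

    merged = pd.DataFrame(
        np.vstack([block, x_nbn.to_numpy(), x_bn.to_numpy()]),
        index=list(insilico.index) + ["Nbn", "Bn"],
        columns=list(CATEGORIES),
    )
    link, order = _olo_linkage(merged.to_numpy())
    return ComparisonResult(distances, merged, link, order)
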