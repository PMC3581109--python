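"""Disease-by-age matrix construction and hierarchical clustering.

For every ontology disease mapped in the evidence store, the number of
instances per integer age (0..120) is counted.  Instances with inferred age
ranges are excluded — an inferred [0, 30] interval says nothing about where
in that interval the phenomenon concentrates.  An instance whose range spans
several years increments every covered integer age (fractional bounds are
rounded outward).  To correct for uneven literature coverage, each
disease-age count is divided by the number of instances associated with that
disease.

Diseases are then clustered agglomeratively with distance
``1 - Pearson correlation`` between normalized age profiles (average linkage
by default).  Zero-variance profiles are excluded (the correlation is
undefined), as are diseases below a minimum instance count.  The dendrogram
can be cut into k clusters or exported as a rooted Newick tree with branch
lengths, and per-cluster mean age profiles with their peak age summarize
what the literature says about each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .age_extraction import MAX_AGE_YEARS, expand_to_integer_ages
from .evidence_store import EvidenceStore

__all__ = [
    "DiseaseAgeMatrix",
    "ClusterResult",
    "build_matrix",
    "normalize_matrix",
    "cluster_diseases",
    "cluster_age_profile",
]

AGES = np.arange(0, int(MAX_AGE_YEARS) + 1)


@dataclass
class DiseaseAgeMatrix:
    """Counts of evidence instances per (disease, integer age).

    ``counts``: DataFrame indexed by disease term id, columns 0..120.
    ``instance_totals``: per-disease number of distinct instances.
    ``normalized``: counts divided row-wise by instance totals (None until
    :func:`normalize_matrix` is applied).  Note a row of ``normalized`` sums
    to more than 1 when instances span multiple ages — each instance
    contributes one unit per covered age.
    """

    counts: pd.DataFrame
    instance_totals: pd.Series
    normalized: pd.DataFrame | None = None


def build_matrix(
    store: EvidenceStore,
    *,
    include_redundant: bool = False,
) -> DiseaseAgeMatrix:
    """Count instances per disease and integer age, excluding inferred ranges."""
    usable = [i for i in store if not i.age_range.inferred]
    rows: dict[str, np.ndarray] = {}
    totals: dict[str, int] = {}
    for inst in usable:
        for disease in sorted(inst.ontology_terms(include_redundant=include_redundant)):
            if disease not in rows:
                rows[disease] = np.zeros(len(AGES), dtype=np.int64)
                totals[disease] = 0
            totals[disease] += 1
            for age in expand_to_integer_ages(inst.age_range):
                rows[disease][age] += 1
    if not rows:
        raise ValueError(
            "no usable instances: store is empty or contains only "
            "inferred-range instances"
        )
    diseases = sorted(rows)
    counts = pd.DataFrame(
        np.vstack([rows[d] for d in diseases]), index=diseases, columns=AGES
    )
    return DiseaseAgeMatrix(
        counts=counts,
        instance_totals=pd.Series({d: totals[d] for d in diseases}, name="instances"),
    )


def normalize_matrix(m: DiseaseAgeMatrix, *, row_sum: bool = False) -> DiseaseAgeMatrix:
    """Divide each disease's counts by its instance total (literature-coverage
    correction).  ``row_sum=True`` divides by the row sum of cells instead."""
    keep = m.instance_totals[m.instance_totals > 0].index
    counts = m.counts.loc[keep]
    denom = counts.sum(axis=1) if row_sum else m.instance_totals.loc[keep]
    m.counts = counts
    m.instance_totals = m.instance_totals.loc[keep]
    m.normalized = counts.div(denom, axis=0)
    return m


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    distances: np.ndarray  # condensed, 1 - Pearson r
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters (labels 1..k)."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))

    def to_newick(self) -> str:
        """Rooted Newick with ultrametric branch lengths (node height = dist/2)."""
        tree = hierarchy.to_tree(self.linkage)

        def height(node) -> float:
            return node.dist / 2.0

        def label(name: str) -> str:
            # quote labels containing Newick metacharacters (e.g. DOID:0100)
            if any(c in name for c in ":;,()[]' \t"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def emit(node) -> str:
            if node.is_leaf():
                return label(self.labels[node.id])
            h = height(node)
            parts = []
            for child in (node.left, node.right):
                child_h = height(child) if not child.is_leaf() else 0.0
                parts.append(f"{emit(child)}:{max(h - child_h, 0.0):.6g}")
            return "(" + ",".join(parts) + ")"

        return emit(tree) + ";"


def cluster_diseases(
    m: DiseaseAgeMatrix,
    min_instances: int = 5,
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of normalized disease age profiles.

    Distance is ``1 - Pearson correlation``; rows with fewer than
    ``min_instances`` instances or zero variance are excluded.  Raises
    ValueError when fewer than two usable rows remain.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    if m.normalized is None:
        normalize_matrix(m)
    keep = m.instance_totals[m.instance_totals >= min_instances].index
    X = m.normalized.loc[keep]
    variances = X.var(axis=1, ddof=0)
    X = X.loc[variances[variances > 0].index]
    if len(X) < 2:
        raise ValueError(
            f"need at least 2 usable disease rows, found {len(X)} "
            f"(min_instances={min_instances}, zero-variance rows excluded)"
        )
    d = pdist(X.to_numpy(dtype=float), metric="correlation")
    d = np.clip(d, 0.0, 2.0)  # guard tiny negative rounding
    Z = hierarchy.linkage(d, method=method)
    return ClusterResult(labels=list(X.index), linkage=Z, distances=d, method=method)


def cluster_age_profile(
    cluster: set[str] | list[str],
    m: DiseaseAgeMatrix,
) -> tuple[np.ndarray, int]:
    """Mean instance count per age over the cluster's diseases, and peak age.

    The peak is the argmax of the profile; ties resolve to the earliest age.
    """
    diseases = sorted(set(cluster))
    if not diseases:
        raise ValueError("cluster is empty")
    missing = [d for d in diseases if d not in m.counts.index]
    if missing:
        raise KeyError(f"diseases not in matrix: {missing}")
    profile = m.counts.loc[diseases].mean(axis=0).to_numpy(dtype=float)
    peak = int(np.argmax(profile))
    return profile, peak


def distance_matrix(result: ClusterResult) -> np.ndarray:
    """Square symmetric distance matrix corresponding to ``result.distances``."""
    return squareform(result.distances)
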