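"""Colocalization-conditioned marker discovery and reference subclustering.

Finds candidate chemotactic factors: genes separating the epithelial
spots colocalized with a given immune cluster from the epithelial spots
colocalized with any other immune cluster (or with fibroblasts, the
gate's control). A companion routine reclusters selected reference
clusters at higher resolution and profiles a gene across the resulting
subclusters — the evidence pattern used to pin a signaling
subpopulation (e.g. stress-response PT cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exact_tests import fisher_exact_greater, rank_sum_test
from .secondary import DEFAULT_CONTROL
from .signatures import ClusteringParams, cluster_cells, find_markers

MIN_GROUP_SIZE = 3


@dataclass
class ColocDEResult:
    epithelial: str
    immune: str
    n_coloc: int
    n_other: int
    table: pd.DataFrame | None
    insufficient: bool = False
    reason: str = ""

    def volcano_export(self) -> pd.DataFrame:
        if self.table is None:
            return pd.DataFrame(columns=["gene", "log_fold_change", "neg_log10_p"])
        out = self.table[["gene", "log_fold_change", "p_value"]].copy()
        out["neg_log10_p"] = -np.log10(np.maximum(out.pop("p_value"), 1e-300))
        return out


def coloc_de(
    spots_normalized: ad.AnnData,
    dominant: pd.DataFrame,
    secondary: pd.DataFrame,
    epithelial: str,
    immune_cluster: str,
    immune: Iterable[str],
    control: str = DEFAULT_CONTROL,
    include_control: bool = True,
    min_group: int = MIN_GROUP_SIZE,
) -> ColocDEResult:
    """Wilcoxon DE between E spots colocalized with I and E spots
    colocalized with any other immune cluster (plus fibroblast-gated
    spots when ``include_control``)."""
    immune = set(immune)
    if immune_cluster not in immune:
        raise ValueError(f"{immune_cluster!r} is not among the immune clusters")
    dom = dominant.set_index("barcode")["dominant"]
    sec = secondary.set_index("barcode")["coloc_identity"]
    common = dom.index.intersection(sec.index).intersection(spots_normalized.obs_names)
    dom, sec = dom.loc[common], sec.loc[common]

    comparators = (immune - {immune_cluster}) | ({control} if include_control else set())
    g1 = common[(dom == epithelial) & (sec == immune_cluster)]
    g2 = common[(dom == epithelial) & sec.isin(comparators)]
    if len(g1) < min_group or len(g2) < min_group:
        return ColocDEResult(
            epithelial,
            immune_cluster,
            len(g1),
            len(g2),
            None,
            insufficient=True,
            reason=f"group sizes {len(g1)} vs {len(g2)} below {min_group}",
        )
    sub = spots_normalized[list(g1) + list(g2)]
    labels = pd.Series(
        ["coloc"] * len(g1) + ["other"] * len(g2), index=list(g1) + list(g2)
    )
    table = find_markers(sub, labels, "coloc", reference_group="other")
    return ColocDEResult(epithelial, immune_cluster, len(g1), len(g2), table)


def expression_gate_test(
    spots_normalized: ad.AnnData,
    gene: str,
    group1: Sequence[str],
    group2: Sequence[str],
) -> dict:
    """Compare a gene's expression distribution between two spot groups.

    The gene is binarized as detected (count > 0) vs not and tested with
    a one-sided Fisher exact test for higher detection in group 1; a
    Wilcoxon rank-sum on the continuous values is reported alongside
    (the binarization convention is a choice, so both views are emitted).
    """
    if gene not in set(spots_normalized.var_names):
        raise ValueError(f"gene {gene!r} absent from the matrix")
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    j = list(spots_normalized.var_names).index(gene)
    X = spots_normalized.X
    col = X[:, j].toarray().ravel() if sp.issparse(X) else np.asarray(X)[:, j]
    vals = pd.Series(col, index=spots_normalized.obs_names)
    x1, x2 = vals.loc[group1].to_numpy(), vals.loc[group2].to_numpy()
    det1, det2 = int((x1 > 0).sum()), int((x2 > 0).sum())
    a, b = det1, len(group1) - det1
    c, d = det2, len(group2) - det2
    degenerate = det1 + det2 == 0
    fisher_p = 1.0 if degenerate else fisher_exact_greater(a, b, c, d)
    _, wilcoxon_p = rank_sum_test(x1, x2)
    return {
        "gene": gene,
        "fisher_p": fisher_p,
        "wilcoxon_p": wilcoxon_p,
        "detected_frac_1": det1 / len(group1),
        "detected_frac_2": det2 / len(group2),
        "table": (a, b, c, d),
        "degenerate": degenerate,
    }


def subcluster_and_profile(
    reference_normalized: ad.AnnData,
    labels: pd.Series,
    target_clusters: Sequence[str],
    gene: str,
    params: ClusteringParams = ClusteringParams(),
    resolution: float | None = None,
) -> pd.DataFrame:
    """Recluster the target clusters at increased resolution and profile
    a gene per subcluster.

    Returns one row per subcluster: cell count, origin-cluster
    composition, fraction of cells with nonzero expression of ``gene``,
    and its mean normalized expression.
    """
    labels = labels.reindex(reference_normalized.obs_names)
    keep = labels.isin(list(target_clusters))
    if not keep.any():
        raise ValueError(f"no cells in target clusters {list(target_clusters)}")
    sub = reference_normalized[keep.to_numpy()].copy()
    res = resolution if resolution is not None else params.recluster_resolution
    sub_labels = cluster_cells(sub, params, resolution=res)

    if gene not in set(sub.var_names):
        raise ValueError(f"gene {gene!r} absent from the matrix")
    j = list(sub.var_names).index(gene)
    X = sub.X
    col = X[:, j].toarray().ravel() if sp.issparse(X) else np.asarray(X)[:, j]
    origin = labels[keep]

    rows = []
    for sc_label in sorted(sub_labels.unique(), key=lambda s: (len(s), s)):
        mask = (sub_labels == sc_label).to_numpy()
        comp = origin[mask].value_counts(normalize=True).to_dict()
        rows.append(
            {
                "subcluster": sc_label,
                "n_cells": int(mask.sum()),
                "origin_composition": ";".join(f"{k}:{v:.3f}" for k, v in sorted(comp.items())),
                "frac_expressing": float((col[mask] > 0).mean()),
                "mean_expression": float(col[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
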