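"""Per-spot deconvolution against the cluster signature matrix.

Each spot's expression is modelled as a non-negative mixture of cluster
profiles; weights are estimated by non-negative least squares (NNLS) on
the shared marker genes and renormalized to sum to one. The regression
is solved on the linear CP10K scale (the scale on which mixtures are
additive); inputs are the log-normalized matrices used everywhere else
and are converted internally, keeping spots and signatures on one scale.

Spots with no counts on the shared genes, or whose fit is residual-
dominated, are flagged unassigned and carry all-zero scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from .io import RegionMask

UNASSIGNED = "unassigned"
MAX_REL_RESIDUAL = 0.99
MIN_DISPLAY_FRACTION = 0.10


@dataclass
class ScoreMatrix:
    """Spot x cluster non-negative scores; assigned rows sum to 1."""

    scores: pd.DataFrame
    assigned: pd.Series
    residual: pd.Series

    @property
    def clusters(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.scores.index)


def deconvolve(
    spots_normalized: ad.AnnData,
    signature: pd.DataFrame,
    max_rel_residual: float = MAX_REL_RESIDUAL,
) -> ScoreMatrix:
    """NNLS proportions of each signature cluster per spot.

    ``spots_normalized`` is the log1p(CP10K) spot matrix; ``signature``
    is clusters x genes on the same scale.
    """
    shared = [g for g in signature.columns if g in set(spots_normalized.var_names)]
    if not shared:
        raise ValueError("signature and spots share no genes")
    if signature.duplicated().any():
        warnings.warn("signature contains identical cluster rows; weights are not unique")

    # regression operates on the linear CP10K scale where mixing is additive
    S = np.expm1(signature[shared].to_numpy(dtype=float))  # clusters x genes
    col = {g: i for i, g in enumerate(spots_normalized.var_names)}
    idx = [col[g] for g in shared]
    X = spots_normalized.X[:, idx]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    Y = np.expm1(X)

    clusters = sorted(signature.index.astype(str))
    order = [list(signature.index.astype(str)).index(c) for c in clusters]
    S = S[order]

    n_spots = Y.shape[0]
    W = np.zeros((n_spots, len(clusters)))
    assigned = np.zeros(n_spots, dtype=bool)
    residual = np.full(n_spots, np.nan)
    A = S.T  # genes x clusters
    for i in range(n_spots):
        y = Y[i]
        norm_y = np.linalg.norm(y)
        if norm_y == 0:
            continue
        w, rnorm = nnls(A, y)
        rel = rnorm / norm_y
        residual[i] = rel
        total = w.sum()
        if rel > max_rel_residual or total == 0:
            continue
        W[i] = w / total
        assigned[i] = True

    barcodes = list(spots_normalized.obs_names)
    return ScoreMatrix(
        scores=pd.DataFrame(W, index=barcodes, columns=clusters),
        assigned=pd.Series(assigned, index=barcodes, name="assigned"),
        residual=pd.Series(residual, index=barcodes, name="rel_residual"),
    )


def dominant_labels(scores: ScoreMatrix) -> pd.DataFrame:
    """Highest-scoring cluster per assigned spot.

    Ties resolve to the alphabetically first cluster; unassigned spots
    are labeled 'unassigned' with score 0.
    """
    cols = sorted(scores.scores.columns)
    mat = scores.scores[cols].to_numpy()
    best = np.argmax(mat, axis=1)  # first (alphabetical) argmax on ties
    labels = np.array(cols, dtype=object)[best]
    best_scores = mat[np.arange(len(mat)), best]
    labels = np.where(scores.assigned.to_numpy(), labels, UNASSIGNED)
    best_scores = np.where(scores.assigned.to_numpy(), best_scores, 0.0)
    return pd.DataFrame(
        {"barcode": scores.barcodes, "dominant": labels, "dominant_score": best_scores}
    )


def signature_fraction_by_region(
    scores: ScoreMatrix, region_a: RegionMask, region_b: RegionMask
) -> pd.DataFrame:
    """Per-cluster signature fraction split between two regions.

    For each cluster, scores are summed per region, divided by the
    region's spot count (removing region-size effects), and the two
    normalized sums are expressed as fractions summing to 1.
    """
    set_a = [b for b in region_a.member_spots if b in scores.scores.index]
    set_b = [b for b in region_b.member_spots if b in scores.scores.index]
    if set(set_a) & set(set_b):
        raise ValueError("regions overlap; they must partition the analyzed spots")
    rows = []
    for cl in scores.clusters:
        norm = {}
        for name, members in (("a", set_a), ("b", set_b)):
            norm[name] = (
                scores.scores.loc[members, cl].sum() / len(members) if members else np.nan
            )
        total = norm["a"] + norm["b"]
        frac_a = norm["a"] / total if total and np.isfinite(total) and total > 0 else np.nan
        rows.append(
            {
                "cluster": cl,
                "norm_sum_a": norm["a"],
                "norm_sum_b": norm["b"],
                "fraction_a": frac_a,
                "fraction_b": 1.0 - frac_a if np.isfinite(frac_a) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def spot_composition_report(
    scores: ScoreMatrix, min_display: float = MIN_DISPLAY_FRACTION
) -> pd.DataFrame:
    """Clusters contributing at least ``min_display`` of each spot's
    signature (pie-chart style report); long format barcode/cluster/score."""
    rows = []
    for barcode, row in scores.scores.iterrows():
        if not scores.assigned[barcode]:
            continue
        for cl, val in row.items():
            if val >= min_display and val > 0:
                rows.append({"barcode": barcode, "cluster": cl, "score": val})
    return pd.DataFrame(rows, columns=["barcode", "cluster", "score"])
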