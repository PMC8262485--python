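"""Replicate-level drivers for the synthetic colocalization study.

One replicate = simulate a reference and spatial sample at a seed, build
the signature, deconvolve, label, and measure every planted quantity:
the colocalization odds ratio of the planted pair, the rank of the
planted chemotactic gene in colocalization-conditioned DE, deconvolution
proportion error, the low-region total-count ratio, and injury-gene
ranks in the region comparison. These drivers are shared by the
analysis scripts, the acceptance checks, and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import coloc_table, permute_secondary
from .coloc_markers import coloc_de, subcluster_and_profile
from .deconvolution import ScoreMatrix, deconvolve, dominant_labels
from .io import region_membership
from .regions import region_de
from .secondary import secondary_label
from .signatures import build_signature_matrix, normalize, qc_filter_cells
from .simulate import (
    DEFAULT_PRESERVED_REGION,
    MITO_GENES,
    GroundTruth,
    SimulationConfig,
    simulate_reference,
    simulate_spots,
)


@dataclass
class ReplicateResult:
    """Everything a downstream check needs from one simulated replicate."""

    config: SimulationConfig
    truth: GroundTruth
    ref_adata: object
    ref_labels: pd.Series
    signature: pd.DataFrame
    spot_counts: object
    spot_table: object
    spot_adata: object
    scores: ScoreMatrix
    dominant: pd.DataFrame
    secondary: pd.DataFrame
    immune: list[str]
    epithelial: list[str]
    coloc: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def run_replicate(config: SimulationConfig) -> ReplicateResult:
    """Simulate and run the full spot-labeling pipeline at one seed."""
    ref_counts, annotation, truth = simulate_reference(config)
    mito = [g for g in MITO_GENES if g in ref_counts.gene_ids]
    kept, _ledger = qc_filter_cells(
        ref_counts, mito, samples=annotation.table.set_index("obs_id")["sample"]
    )
    ref_adata = normalize(kept)
    ref_labels = annotation.labels().reindex(ref_adata.obs_names)
    signature, _ = build_signature_matrix(ref_adata, ref_labels)

    spot_counts, spot_table, spot_truth = simulate_spots(config, reference_truth=truth)
    spot_adata = normalize(spot_counts)
    scores = deconvolve(spot_adata, signature)
    dominant = dominant_labels(scores)
    immune = annotation.clusters_of_class("immune")
    epithelial = annotation.clusters_of_class("epithelial")
    suppressed = annotation.clusters_of_class("epithelial", "endothelial")
    secondary = secondary_label(scores, suppressed, immune)
    coloc = coloc_table(dominant, secondary, sample_id=f"seed{config.seed}",
                        epithelial=epithelial, immune=immune)

    merged_truth = GroundTruth(
        cells=truth.cells,
        gene_params=truth.gene_params,
        spot_proportions=spot_truth.spot_proportions,
        spot_region=spot_truth.spot_region,
        coloc_spots=spot_truth.coloc_spots,
        epithelial_dominant_spots=spot_truth.epithelial_dominant_spots,
        low_region_spots=spot_truth.low_region_spots,
        planted=spot_truth.planted,
    )
    return ReplicateResult(
        config=config,
        truth=merged_truth,
        ref_adata=ref_adata,
        ref_labels=ref_labels,
        signature=signature,
        spot_counts=spot_counts,
        spot_table=spot_table,
        spot_adata=spot_adata,
        scores=scores,
        dominant=dominant,
        secondary=secondary,
        immune=immune,
        epithelial=epithelial,
        coloc=coloc,
    )


def planted_pair_record(rep: ReplicateResult) -> pd.Series | None:
    """The colocalization record of the planted (epithelial, immune) pair."""
    c = rep.config.coloc
    hit = rep.coloc[(rep.coloc["epithelial"] == c.epithelial) & (rep.coloc["immune"] == c.immune)]
    return hit.iloc[0] if len(hit) else None


def proportion_mae(rep: ReplicateResult) -> float:
    """Mean absolute error of estimated vs true spot proportions."""
    truth = rep.truth.spot_proportions
    est = rep.scores.scores.loc[truth.index, truth.columns]
    return float(np.abs(est.to_numpy() - truth.to_numpy()).mean())


def chemokine_rank(rep: ReplicateResult, permuted_rng: np.random.Generator | None = None):
    """0-based rank of the planted chemotactic gene in coloc-conditioned DE.

    With ``permuted_rng`` the secondary labels are permuted across spots
    first (null construction). Returns (rank or None, n Bonferroni hits,
    DE result).
    """
    sec = rep.secondary if permuted_rng is None else permute_secondary(rep.secondary, permuted_rng)
    result = coloc_de(
        rep.spot_adata,
        rep.dominant,
        sec,
        epithelial=rep.config.coloc.epithelial,
        immune_cluster=rep.config.coloc.immune,
        immune=rep.immune,
    )
    if result.table is None:
        return None, 0, result
    genes = result.table["gene"].tolist()
    gene = rep.config.chemokine.gene
    rank = genes.index(gene) if gene in genes else None
    n_bonf = int((result.table["p_adj"] < 0.05).sum())
    return rank, n_bonf, result


def subpopulation_ratio(rep: ReplicateResult) -> float:
    """Best subcluster expressing-fraction ratio for the planted gene.

    Reclusters the planted cluster at increased resolution and returns
    max over subclusters of (expressing fraction) / (expressing fraction
    of all remaining cells).
    """
    sub = rep.config.subpop
    prof = subcluster_and_profile(rep.ref_adata, rep.ref_labels, [sub.cluster], gene=sub.gene)
    best = 0.0
    for _, row in prof.iterrows():
        rest = prof[prof["subcluster"] != row["subcluster"]]
        n_rest = rest["n_cells"].sum()
        rate_rest = (rest["n_cells"] * rest["frac_expressing"]).sum() / n_rest if n_rest else 0.0
        ratio = row["frac_expressing"] / rate_rest if rate_rest > 0 else np.inf
        best = max(best, float(ratio))
    return best


def low_region_count_ratio(rep: ReplicateResult) -> float:
    """Median total counts inside the low region over the rest of the tissue."""
    totals = rep.spot_counts.total_counts()
    low = rep.truth.low_region_spots
    return float(np.median(totals.loc[low]) / np.median(totals.drop(low)))


def injury_gene_ranks(rep: ReplicateResult) -> list[int]:
    """0-based ranks of the planted injury genes in low-vs-preserved DE."""
    cfg = rep.config
    low_spec = next(r for r in cfg.regions if r.region_id == cfg.low_region.region)
    low = region_membership(rep.spot_table, low_spec.circle, region_id=low_spec.region_id)
    preserved = region_membership(rep.spot_table, DEFAULT_PRESERVED_REGION, region_id="preserved")
    table = region_de(rep.spot_adata, low, preserved)
    genes = table["gene"].tolist()
    return [genes.index(g) for g in cfg.low_region.injury_genes if g in genes]


def permutation_pair_pvalues(
    rep: ReplicateResult, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """One-sided Fisher p-values of every tested pair under label permutation.

    Secondary labels are shuffled across spots; each permutation retests
    every (epithelial, immune) pair that meets the table guards.
    """
    dom = rep.dominant.set_index("barcode")["dominant"]
    sec = rep.secondary.set_index("barcode")["label"].reindex(dom.index)
    labels = sec.to_numpy().copy()
    is_e = {e: (dom == e).to_numpy() for e in rep.epithelial}
    from .exact_tests import fisher_exact_greater

    pvals = []
    n = len(labels)
    for _ in range(n_permutations):
        rng.shuffle(labels)
        for e, e_mask in is_e.items():
            n_e = int(e_mask.sum())
            for i in rep.immune:
                i_mask = labels == i
                a = int(np.sum(e_mask & i_mask))
                b = n_e - a
                c = int(i_mask.sum()) - a
                d = n - a - b - c
                if a + b < 5 or a + c < 1:
                    continue
                pvals.append(fisher_exact_greater(a, b, c, d))
    return np.asarray(pvals)
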