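"""Reference processing: QC, normalization, clustering, markers, signatures.

The single-cell reference is QC-filtered (mitochondrial fraction,
unique-gene floor, per-sample percentile band), normalized to
log1p(counts-per-10k), optionally clustered (PCA -> kNN graph -> Leiden
community detection), and summarized as a cluster x marker-gene
signature matrix that serves as the deconvolution design downstream.

Marker discovery is a per-gene two-sided Wilcoxon rank-sum test (midrank
ties; exact enumeration for small groups) with a pseudo-counted natural-log
fold change on the CP10K scale, Bonferroni- and BH-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exact_tests import EXACT_RANKSUM_MAX_N, rank_sum_matrix, rank_sum_test
from .io import GeneMatrix

LOGFC_PSEUDOCOUNT = 1e-9  # on the CP10K scale
CP10K_TARGET = 1e4


class QCError(RuntimeError):
    """All cells removed by quality control."""


class ClusteringError(RuntimeError):
    """Degenerate input for community detection."""


@dataclass(frozen=True)
class QCThresholds:
    max_mito_fraction: float = 0.50
    min_unique_genes: int = 200
    lower_pct: float = 0.10
    upper_pct: float = 0.05  # top tail

    def __post_init__(self) -> None:
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.lower_pct + self.upper_pct >= 1:
            raise ValueError("percentile bands overlap")


@dataclass(frozen=True)
class ClusteringParams:
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 0.65
    recluster_resolution: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.recluster_resolution <= 0:
            raise ValueError("resolution must be positive")


def qc_filter_cells(
    counts: GeneMatrix,
    mito_gene_ids: list[str],
    thresholds: QCThresholds = QCThresholds(),
    samples: pd.Series | None = None,
) -> tuple[GeneMatrix, pd.DataFrame]:
    """Remove low-quality cells; return the kept matrix and a removal ledger.

    Rules, applied in order with each cell charged to its first failure:
    (1) mitochondrial count fraction strictly above ``max_mito_fraction``;
    (2) unique (detected) gene count strictly below ``min_unique_genes``;
    (3) unique-gene count strictly below the ``lower_pct`` quantile or
    strictly above the ``1 - upper_pct`` quantile of the distribution of
    cells that survived rules 1-2, computed per sample.
    """
    unknown = set(mito_gene_ids) - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"mito genes absent from the matrix: {sorted(unknown)}")
    mat = counts.values.tocsc()
    totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    gene_idx = {g: i for i, g in enumerate(counts.gene_ids)}
    mito_rows = [gene_idx[g] for g in mito_gene_ids]
    mito_counts = (
        np.asarray(mat[mito_rows, :].sum(axis=0)).ravel().astype(float)
        if mito_rows
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    unique_genes = np.asarray((mat > 0).sum(axis=0)).ravel()

    obs = np.array(counts.obs_ids)
    fail_mito = mito_frac > thresholds.max_mito_fraction
    fail_min = (~fail_mito) & (unique_genes < thresholds.min_unique_genes)
    survivors = ~(fail_mito | fail_min)

    if samples is None:
        sample_of = pd.Series("all", index=obs)
    else:
        sample_of = samples.reindex(obs)
    fail_pct = np.zeros(len(obs), dtype=bool)
    for s in sample_of.unique():
        in_s = (sample_of == s).to_numpy()
        pool = unique_genes[in_s & survivors]
        if pool.size == 0:
            continue
        lo = np.quantile(pool, thresholds.lower_pct)
        hi = np.quantile(pool, 1.0 - thresholds.upper_pct)
        fail_pct |= in_s & survivors & ((unique_genes < lo) | (unique_genes > hi))

    ledger_rows = []
    for i in np.flatnonzero(fail_mito):
        ledger_rows.append((obs[i], "mito", mito_frac[i]))
    for i in np.flatnonzero(fail_min):
        ledger_rows.append((obs[i], "min_genes", float(unique_genes[i])))
    for i in np.flatnonzero(fail_pct):
        ledger_rows.append((obs[i], "percentile", float(unique_genes[i])))
    ledger = pd.DataFrame(ledger_rows, columns=["obs_id", "rule", "value"])

    keep = ~(fail_mito | fail_min | fail_pct)
    if not keep.any():
        raise QCError("quality control removed every cell")
    kept = counts.subset_obs(list(obs[keep]))
    return kept, ledger


def normalize(counts: GeneMatrix) -> ad.AnnData:
    """log1p(CP10K) normalization; all-zero observations are dropped.

    Returns an observations x genes AnnData with normalized X, raw
    counts in ``layers['counts']`` and dropped barcodes in
    ``uns['dropped_obs']``.
    """
    totals = counts.total_counts()
    nonzero = totals[totals > 0].index.tolist()
    dropped = totals[totals == 0].index.tolist()
    gm = counts.subset_obs(nonzero) if dropped else counts
    adata = gm.to_adata()
    adata.layers["counts"] = adata.X.copy()
    X = adata.X.tocsr().astype(np.float64)
    scale = CP10K_TARGET / np.asarray(X.sum(axis=1)).ravel()
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    adata.X = X
    adata.obs["total_counts"] = gm.total_counts().to_numpy()
    adata.uns["dropped_obs"] = dropped
    return adata


def cluster_cells(adata: ad.AnnData, params: ClusteringParams = ClusteringParams(), resolution: float | None = None) -> pd.Series:
    """PCA -> kNN graph -> Leiden communities at resolution gamma.

    Deterministic for a fixed seed. Labels are strings '0', '1', ...
    """
    import scanpy as sc

    n_obs, n_genes = adata.shape
    if n_obs < params.k_neighbors + 1:
        raise ClusteringError(
            f"need at least k_neighbors+1={params.k_neighbors + 1} observations, got {n_obs}"
        )
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    if np.allclose(X, X[0]):
        raise ClusteringError("matrix has no variation to cluster")
    work = ad.AnnData(X=X.copy(), obs=adata.obs.copy())
    if n_genes > 100:
        # feature selection keeps real programs above the n << p noise
        # floor; variance of the log-normalized values favours genes with
        # genuine between-cell structure (markers, bimodal programs)
        top = np.argsort(X.var(axis=0))[::-1][: min(500, n_genes)]
        work = work[:, np.sort(top)].copy()
    sc.pp.scale(work, max_value=10)  # unit variance so low-abundance programs register
    n_comps = int(min(params.n_pcs, n_obs - 1, n_genes - 1))
    sc.pp.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=params.seed)
    sc.pp.neighbors(work, n_neighbors=min(params.k_neighbors, n_obs - 1), random_state=params.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=float(resolution if resolution is not None else params.resolution),
            random_state=params.seed,
            flavor="leidenalg",
            directed=False,
        )
    return pd.Series(work.obs["leiden"].astype(str).to_numpy(), index=adata.obs_names, name="cluster")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def find_markers(
    adata: ad.AnnData,
    labels: pd.Series,
    group: str,
    reference_group: str = "rest",
    pseudocount: float = LOGFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test of ``group`` vs the reference.

    Columns: gene, cluster, stat (rank sum W of the group), p_value,
    p_adj (Bonferroni), p_adj_bh, log_fold_change (natural log of
    pseudo-counted CP10K mean ratio), pct_in, pct_out. Sorted by p_value,
    then |logFC| descending, then gene id.
    """
    labels = labels.reindex(adata.obs_names)
    mask1 = (labels == group).to_numpy()
    if reference_group == "rest":
        mask2 = ~mask1
    else:
        mask2 = (labels == reference_group).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 == 0:
        raise ValueError(f"group {group!r} is empty")
    if n2 == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")

    sub = _dense(adata.X[mask1 | mask2])
    m1 = mask1[mask1 | mask2]
    X1, X2 = sub[m1], sub[~m1]

    if n1 <= EXACT_RANKSUM_MAX_N and n2 <= EXACT_RANKSUM_MAX_N:
        stats = np.empty(sub.shape[1])
        pvals = np.empty(sub.shape[1])
        for j in range(sub.shape[1]):
            stats[j], pvals[j] = rank_sum_test(X1[:, j], X2[:, j])
    else:
        stats, pvals = rank_sum_matrix(sub, m1)

    cp1 = np.expm1(X1).mean(axis=0)
    cp2 = np.expm1(X2).mean(axis=0)
    logfc = np.log((cp1 + pseudocount) / (cp2 + pseudocount))
    pct_in = (X1 > 0).mean(axis=0)
    pct_out = (X2 > 0).mean(axis=0)

    n_genes = sub.shape[1]
    from statsmodels.stats.multitest import multipletests

    p_bh = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "cluster": group,
            "stat": stats,
            "p_value": pvals,
            "p_adj": np.minimum(pvals * n_genes, 1.0),
            "p_adj_bh": p_bh,
            "log_fold_change": logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
        }
    )
    out["_abs_lfc"] = out["log_fold_change"].abs()
    out = out.sort_values(
        ["p_value", "_abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return out.reset_index(drop=True)


def build_signature_matrix(
    adata: ad.AnnData,
    labels: pd.Series,
    top_n_markers: int = 60,
    marker_tables: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x marker-gene signature matrix.

    The gene set is the union over clusters of their top ``top_n_markers``
    positive markers (by adjusted p, then |logFC|). Entries are
    log1p(mean CP10K) of the cluster, so the linear-scale cluster profile
    is recovered exactly by expm1. Returns (signature, marker table).
    """
    if top_n_markers < 1:
        raise ValueError("top_n_markers must be >= 1")
    labels = labels.reindex(adata.obs_names)
    clusters = sorted(labels.dropna().unique())
    tables = []
    selected: dict[str, list[str]] = {}
    for cl in clusters:
        table = (
            marker_tables[cl]
            if marker_tables is not None and cl in marker_tables
            else find_markers(adata, labels, cl)
        )
        positive = table[table["log_fold_change"] > 0]
        if positive.empty:
            warnings.warn(f"cluster {cl!r} has no positive markers; using top logFC genes")
            positive = table.sort_values("log_fold_change", ascending=False)
        selected[cl] = positive["gene"].head(top_n_markers).tolist()
        tables.append(table.assign(selected=table["gene"].isin(selected[cl])))
    genes = sorted(set(g for gs in selected.values() for g in gs))

    X = _dense(adata.X)
    col = {g: i for i, g in enumerate(adata.var_names)}
    gene_idx = [col[g] for g in genes]
    rows = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        mean_cp10k = np.expm1(X[np.ix_(mask, gene_idx)]).mean(axis=0)
        rows.append(np.log1p(mean_cp10k))
    signature = pd.DataFrame(rows, index=clusters, columns=genes)
    if (signature.sum(axis=1) == 0).any():
        warnings.warn("signature has an all-zero cluster row")
    return signature, pd.concat(tables, ignore_index=True)
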