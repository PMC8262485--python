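"""Synthetic single-cell reference and Visium-like spatial sample.

The generator emulates a murine acute-kidney-injury experiment: a
single-cell reference with epithelial, immune, fibroblast and
endothelial clusters, and a hexagonal-grid spatial sample whose 55 μm
spots are mixtures of cluster expression profiles ("a spot overlies
multiple cells"). Planted ground truth drives every downstream test:

* cluster-specific negative-binomial expression with marker genes;
* an immune-epithelial colocalization pattern confined to an
  "outer stripe" circle: a fraction ``f`` of the epithelial-dominant
  spots there receive extra weight ``w`` of one immune cluster
  (neutrophils infiltrating PT S3 territory);
* a chemotactic factor (``Mdk``, diffusely expressed) upregulated only
  in those colocalized epithelial spots;
* a reference-side stress subpopulation (20% of PT-S3 cells with high
  ``Atf3`` and co-regulated immediate-early genes);
* a low-total-expression region with upregulated injury markers
  (``Havcr1``, ``Lcn2``);
* QC contaminants: a small fraction of high-mitochondrial and
  low-library cells.

Counts are gamma-Poisson (negative binomial); mixing happens at the
mean level (mix cluster means, then sample once), which keeps every
spot's expected profile analytically known for oracle tests. A
deterministic mode emits rounded means without sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CellAnnotation,
    Circle,
    GeneMatrix,
    RegionMask,
    SpotTable,
    hex_grid,
    region_membership,
    write_counts,
    write_spot_table,
)


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    cls: str  # epithelial | endothelial | immune | fibroblast | other
    n_cells: int = 150


@dataclass(frozen=True)
class RegionSpec:
    region_id: str
    circle: Circle
    alpha: dict[str, float]  # Dirichlet concentration per cluster


@dataclass(frozen=True)
class PlantedColoc:
    epithelial: str = "PT-S3"
    immune: str = "Neutrophil"
    region: str = "outer_stripe"
    fraction: float = 0.2  # of epithelial-dominant spots in the region
    weight: float = 0.2  # immune weight added, then renormalized


@dataclass(frozen=True)
class PlantedChemokine:
    gene: str = "Mdk"
    fold: float = 4.0  # applied in colocalized epithelial spots


@dataclass(frozen=True)
class PlantedSubpopulation:
    """A high-expression subpopulation inside one reference cluster."""

    cluster: str = "PT-S3"
    fraction: float = 0.2
    gene: str = "Atf3"
    fold: float = 6.0
    co_genes: tuple[str, ...] = (
        "Jun", "Junb", "Fos", "Egr1", "Hspa1a", "Klf6", "Dusp1", "Zfp36",
    )
    co_fold: float = 10.0  # immediate-early genes swing harder than the probe gene


@dataclass(frozen=True)
class PlantedLowRegion:
    region: str = "cortex_low"
    scale: float = 0.5  # library-size multiplier inside the region
    injury_genes: tuple[str, ...] = ("Havcr1", "Lcn2")
    injury_fold: float = 4.0


MARKER_BASELINE = 0.4

MITO_GENES = ("mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3", "mt-Cytb", "mt-Atp6")

_DEFAULT_CLUSTERS = (
    # proximal tubule dominates murine kidney references
    ClusterSpec("PT-S1S2", "epithelial", 300),
    ClusterSpec("PT-S3", "epithelial", 420),
    ClusterSpec("TAL", "epithelial"),
    ClusterSpec("DCT-CD", "epithelial"),
    ClusterSpec("Endothelial", "endothelial"),
    ClusterSpec("Fibroblast", "fibroblast"),
    ClusterSpec("Neutrophil", "immune"),
    ClusterSpec("Macrophage", "immune"),
    ClusterSpec("NK", "immune"),
)

# Dirichlet concentrations: epithelium dominates everywhere, immune
# signal is a trace component outside the planted infiltration.
_REST_ALPHA = {
    "PT-S1S2": 2.0,
    "PT-S3": 1.0,
    "TAL": 1.5,
    "DCT-CD": 1.0,
    "Endothelial": 0.5,
    "Fibroblast": 1.2,
    "Neutrophil": 0.002,
    "Macrophage": 0.002,
    "NK": 0.002,
}

_OUTER_STRIPE_ALPHA = {
    "PT-S1S2": 0.5,
    "PT-S3": 8.0,
    "TAL": 0.5,
    "DCT-CD": 0.3,
    "Endothelial": 0.3,
    "Fibroblast": 1.2,
    "Neutrophil": 0.002,
    "Macrophage": 0.002,
    "NK": 0.002,
}

_DEFAULT_REGIONS = (
    RegionSpec("outer_stripe", Circle(850.0, 800.0, 800.0), _OUTER_STRIPE_ALPHA),
    RegionSpec("cortex_low", Circle(2500.0, 800.0, 800.0), _REST_ALPHA),
)

# a size-matched comparator for the low-expression region, outside every
# planted region; used by the region-analysis stage, not the generator
DEFAULT_PRESERVED_REGION = Circle(1675.0, 2300.0, 800.0)

# absolute relative-expression weights for the named genes (the generic
# baseline is lognormal(0,1), mean ~1.65): Mdk is a diffusely, highly
# expressed growth factor; Atf3 is near-silent outside the stress
# subpopulation; its co-regulated immediate-early genes are moderate
_FIXED_BASELINES = {
    "Mdk": 25.0,
    "Atf3": 0.04,
    "Havcr1": 3.0,
    "Lcn2": 3.0,
    **{g: 6.0 for g in (
        "Jun", "Junb", "Fos", "Egr1", "Hspa1a", "Klf6", "Dusp1", "Zfp36",
    )},
    **{g: 14.0 for g in MITO_GENES},
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    clusters: tuple[ClusterSpec, ...] = _DEFAULT_CLUSTERS
    markers_per_cluster: int = 60
    marker_fold: float = 8.0
    nb_size_cells: float = 10.0
    nb_size_spots: float = 50.0
    cell_library_mean: float = 5000.0
    cell_library_sigma: float = 0.35
    spot_library_mean: float = 20000.0
    spot_library_sigma: float = 0.25
    grid_rows: int = 34
    grid_cols: int = 34
    spacing_um: float = 100.0
    regions: tuple[RegionSpec, ...] = _DEFAULT_REGIONS
    rest_alpha: dict[str, float] = field(default_factory=lambda: dict(_REST_ALPHA))
    coloc: PlantedColoc = PlantedColoc()
    chemokine: PlantedChemokine = PlantedChemokine()
    subpop: PlantedSubpopulation = PlantedSubpopulation()
    low_region: PlantedLowRegion = PlantedLowRegion()
    high_mito_fraction: float = 0.06
    low_quality_fraction: float = 0.04
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clusters) < 2:
            raise ConfigError("at least 2 clusters are required")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ConfigError("cluster names must be unique")
        if not (0.0 <= self.coloc.fraction <= 1.0):
            raise ConfigError("coloc fraction must lie in [0, 1]")
        if not (0.0 < self.coloc.weight <= 1.0):
            raise ConfigError("coloc weight must lie in (0, 1]")
        if not (0.0 < self.low_region.scale <= 1.0):
            raise ConfigError("low-region scale must lie in (0, 1]")
        for fold in (self.marker_fold, self.chemokine.fold, self.subpop.fold, self.low_region.injury_fold):
            if fold < 1.0:
                raise ConfigError("fold changes must be >= 1")
        if self.coloc.epithelial not in names or self.coloc.immune not in names:
            raise ConfigError("planted coloc clusters must exist")

    def cluster_names(self) -> list[str]:
        return [c.name for c in self.clusters]

    def classes(self) -> dict[str, str]:
        return {c.name: c.cls for c in self.clusters}

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def null(self) -> "SimulationConfig":
        """The matched null condition: no planted colocalization, unit
        chemotactic fold, and no background immune infiltration, so the
        spot groups compared downstream are drawn from identical
        distributions."""
        eps = 1e-6
        regions = tuple(
            dataclasses.replace(
                r,
                alpha={
                    k: (eps if self.classes().get(k) == "immune" else v)
                    for k, v in r.alpha.items()
                },
            )
            for r in self.regions
        )
        rest = {
            k: (eps if self.classes().get(k) == "immune" else v)
            for k, v in self.rest_alpha.items()
        }
        return self.replace(
            coloc=dataclasses.replace(self.coloc, fraction=0.0),
            chemokine=dataclasses.replace(self.chemokine, fold=1.0),
            regions=regions,
            rest_alpha=rest,
        )


@dataclass
class GeneParams:
    """Deterministic per-gene structure shared by cells and spots."""

    gene_ids: list[str]
    baseline: np.ndarray  # relative expression weight per gene
    markers: dict[str, list[str]]  # cluster -> marker gene ids
    profiles: np.ndarray  # clusters x genes, rows sum to 1 (base profile)
    effective_profiles: np.ndarray  # includes the subpopulation mixture
    cluster_names: list[str]

    def profile_df(self, effective: bool = True) -> pd.DataFrame:
        mat = self.effective_profiles if effective else self.profiles
        return pd.DataFrame(mat, index=self.cluster_names, columns=self.gene_ids)


@dataclass
class GroundTruth:
    cells: pd.DataFrame | None = None  # obs_id, cluster, sample, subpop, high_mito, low_quality
    gene_params: GeneParams | None = None
    spot_proportions: pd.DataFrame | None = None  # spots x clusters, rows sum to 1
    spot_region: pd.Series | None = None
    coloc_spots: list[str] = field(default_factory=list)
    epithelial_dominant_spots: list[str] = field(default_factory=list)
    low_region_spots: list[str] = field(default_factory=list)
    planted: dict = field(default_factory=dict)


def _named_gene_ids(config: SimulationConfig) -> list[str]:
    named = (
        [config.chemokine.gene, config.subpop.gene]
        + list(config.subpop.co_genes)
        + list(config.low_region.injury_genes)
        + list(MITO_GENES)
    )
    named = list(dict.fromkeys(named))  # keep order, drop duplicates
    n_generic = config.n_genes - len(named)
    if n_generic < config.markers_per_cluster * len(config.clusters):
        raise ConfigError("n_genes too small for the requested marker structure")
    generic = [f"g{i + 1:04d}" for i in range(n_generic)]
    return generic + named


def gene_params(config: SimulationConfig) -> GeneParams:
    """Baseline weights, marker assignment and cluster profiles.

    Fully determined by the config seed; shared between
    :func:`simulate_reference` and :func:`simulate_spots` so the spot
    mixture uses exactly the profiles the reference cells are drawn from.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 0])
    gene_ids = _named_gene_ids(config)
    n_genes = len(gene_ids)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    for g, w in _FIXED_BASELINES.items():
        if g in gene_ids:
            baseline[gene_ids.index(g)] = w

    names = config.cluster_names()
    generic_pool = [i for i, g in enumerate(gene_ids) if g.startswith("g")]
    chosen = rng.choice(
        generic_pool, size=config.markers_per_cluster * len(names), replace=False
    )
    # cell-type-defining markers are specific: moderate expression inside
    # the cluster, near-silent elsewhere (fixed low shared baseline)
    baseline[chosen] = MARKER_BASELINE
    markers = {
        name: sorted(gene_ids[i] for i in chosen[k * config.markers_per_cluster : (k + 1) * config.markers_per_cluster])
        for k, name in enumerate(names)
    }

    profiles = np.tile(baseline, (len(names), 1))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for k, name in enumerate(names):
        for g in markers[name]:
            profiles[k, gene_index[g]] *= config.marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    effective = profiles.copy()
    sub = config.subpop
    if sub.cluster in names and sub.fraction > 0:
        k = names.index(sub.cluster)
        sub_profile = profiles[k].copy()
        sub_profile[gene_index[sub.gene]] *= sub.fold
        for g in sub.co_genes:
            sub_profile[gene_index[g]] *= sub.co_fold
        sub_profile /= sub_profile.sum()
        effective[k] = (1 - sub.fraction) * profiles[k] + sub.fraction * sub_profile
    return GeneParams(
        gene_ids=gene_ids,
        baseline=baseline,
        markers=markers,
        profiles=profiles,
        effective_profiles=effective,
        cluster_names=names,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and size (dispersion) ``size``."""
    mean = np.maximum(mean, 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[GeneMatrix, CellAnnotation, GroundTruth]:
    """Simulate the single-cell reference with planted QC contaminants
    and the stress subpopulation."""
    params = gene_params(config)
    rng = np.random.default_rng([int(config.seed) % (2**31), 1])
    gene_index = {g: i for i, g in enumerate(params.gene_ids)}
    mito_idx = [gene_index[g] for g in MITO_GENES if g in gene_index]

    rows = []
    blocks = []
    for k, spec in enumerate(config.clusters):
        n = spec.n_cells
        base_profile = params.profiles[k]
        cell_profiles = np.tile(base_profile, (n, 1))

        is_sub = np.zeros(n, dtype=bool)
        sub = config.subpop
        if spec.name == sub.cluster and sub.fraction > 0:
            n_sub = int(round(sub.fraction * n))
            sub_cells = rng.choice(n, size=n_sub, replace=False)
            is_sub[sub_cells] = True
            cell_profiles[is_sub, gene_index[sub.gene]] *= sub.fold
            for g in sub.co_genes:
                cell_profiles[is_sub, gene_index[g]] *= sub.co_fold

        high_mito = rng.random(n) < config.high_mito_fraction
        if mito_idx and high_mito.any():
            boost = rng.uniform(20.0, 80.0, size=int(high_mito.sum()))
            cell_profiles[np.ix_(high_mito, mito_idx)] *= boost[:, None]

        cell_profiles /= cell_profiles.sum(axis=1, keepdims=True)

        library = rng.lognormal(
            mean=np.log(config.cell_library_mean), sigma=config.cell_library_sigma, size=n
        )
        low_q = rng.random(n) < config.low_quality_fraction
        library[low_q] *= 0.04  # debris-like cells with a few hundred counts

        means = library[:, None] * cell_profiles
        if config.deterministic:
            counts = np.round(means).astype(np.int64)
        else:
            counts = _nb_sample(rng, means, config.nb_size_cells)
        blocks.append(sp.csr_matrix(counts.T))
        for i in range(n):
            rows.append(
                {
                    "obs_id": f"cell-{spec.name}-{i:04d}",
                    "cluster": spec.name,
                    "sample": "ref",
                    "subpop": bool(is_sub[i]),
                    "high_mito": bool(high_mito[i]),
                    "low_quality": bool(low_q[i]),
                }
            )

    cells = pd.DataFrame(rows)
    counts_matrix = sp.hstack(blocks, format="csr")
    gm = GeneMatrix(counts_matrix, params.gene_ids, cells["obs_id"].tolist())
    annotation = CellAnnotation(
        table=cells[["obs_id", "cluster", "sample"]].copy(), classes=config.classes()
    )
    truth = GroundTruth(
        cells=cells,
        gene_params=params,
        planted={
            "markers": params.markers,
            "subpop": config.subpop,
            "chemokine": config.chemokine,
            "low_region": config.low_region,
            "coloc": config.coloc,
        },
    )
    return gm, annotation, truth


def spot_grid_table(config: SimulationConfig) -> SpotTable:
    return SpotTable(hex_grid(config.grid_rows, config.grid_cols, config.spacing_um))


def simulate_spots(
    config: SimulationConfig, reference_truth: GroundTruth | None = None
) -> tuple[GeneMatrix, SpotTable, GroundTruth]:
    """Simulate the spatial sample as NB counts around per-spot mixtures
    of the reference cluster profiles, with the planted colocalization,
    chemotactic gene, and low-expression region."""
    params = (
        reference_truth.gene_params
        if reference_truth is not None and reference_truth.gene_params is not None
        else gene_params(config)
    )
    rng = np.random.default_rng([int(config.seed) % (2**31), 2])
    spots = spot_grid_table(config)
    names = params.cluster_names
    gene_index = {g: i for i, g in enumerate(params.gene_ids)}

    masks: dict[str, RegionMask] = {}
    for reg in config.regions:
        mask = region_membership(spots, reg.circle, region_id=reg.region_id)
        if not mask.member_spots:
            raise ConfigError(f"region {reg.region_id!r} does not overlap the grid")
        masks[reg.region_id] = mask

    barcodes = spots.in_tissue_barcodes()
    region_of = pd.Series("rest", index=barcodes, name="region")
    for reg in config.regions:  # first region wins where circles overlap
        free = region_of == "rest"
        members = [b for b in masks[reg.region_id].member_spots if free.get(b, False)]
        region_of.loc[members] = reg.region_id

    alpha_by_region = {reg.region_id: reg.alpha for reg in config.regions}
    n_spots = len(barcodes)
    props = np.empty((n_spots, len(names)))
    for i, b in enumerate(barcodes):
        alpha = alpha_by_region.get(region_of[b], config.rest_alpha)
        props[i] = rng.dirichlet([alpha[n] for n in names])

    e_idx = names.index(config.coloc.epithelial)
    i_idx = names.index(config.coloc.immune)
    dominant = np.argmax(props, axis=1)

    coloc_region = config.coloc.region
    if config.coloc.fraction > 0 and coloc_region not in masks:
        raise ConfigError(f"planted coloc region {coloc_region!r} is not defined")
    in_region = region_of.to_numpy() == coloc_region
    e_dominant = dominant == e_idx
    candidates = np.flatnonzero(in_region & e_dominant)
    n_coloc = int(round(config.coloc.fraction * candidates.size))
    coloc_idx = (
        np.sort(rng.choice(candidates, size=n_coloc, replace=False))
        if n_coloc > 0
        else np.array([], dtype=int)
    )
    if coloc_idx.size:
        props[coloc_idx, i_idx] += config.coloc.weight
        props[coloc_idx] /= props[coloc_idx].sum(axis=1, keepdims=True)

    library = rng.lognormal(
        mean=np.log(config.spot_library_mean), sigma=config.spot_library_sigma, size=n_spots
    )
    low_mask = region_of.to_numpy() == config.low_region.region
    library[low_mask] *= config.low_region.scale

    means = library[:, None] * (props @ params.effective_profiles)
    chem_j = gene_index[config.chemokine.gene]
    if coloc_idx.size:
        means[coloc_idx, chem_j] *= config.chemokine.fold
    for g in config.low_region.injury_genes:
        means[low_mask, gene_index[g]] *= config.low_region.injury_fold

    if config.deterministic:
        counts = np.round(means).astype(np.int64)
    else:
        counts = _nb_sample(rng, means, config.nb_size_spots)

    gm = GeneMatrix(sp.csr_matrix(counts.T), params.gene_ids, barcodes)
    prop_df = pd.DataFrame(props, index=barcodes, columns=names)
    truth = GroundTruth(
        gene_params=params,
        spot_proportions=prop_df,
        spot_region=region_of,
        coloc_spots=[barcodes[i] for i in coloc_idx],
        epithelial_dominant_spots=[barcodes[i] for i in np.flatnonzero(e_dominant)],
        low_region_spots=[b for b, m in zip(barcodes, low_mask) if m],
        planted={
            "markers": params.markers,
            "coloc": config.coloc,
            "chemokine": config.chemokine,
            "low_region": config.low_region,
        },
    )
    return gm, spots, truth


def write_dataset(
    outdir,
    reference: GeneMatrix,
    annotation: CellAnnotation,
    spatial: GeneMatrix,
    spots: SpotTable,
    truth: GroundTruth,
) -> None:
    """Write the data_io formats plus ground-truth sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(reference, out / "ref_matrix.mtx", out / "ref_genes.txt", out / "ref_barcodes.txt")
    write_counts(spatial, out / "spatial_matrix.mtx", out / "spatial_genes.txt", out / "spatial_barcodes.txt")
    write_spot_table(spots, out / "spots.csv")
    annotation.table.to_csv(out / "cell_annotations.csv", index=False)
    if truth.spot_proportions is not None:
        truth.spot_proportions.rename_axis("barcode").to_csv(out / "truth_spot_proportions.csv")
    if truth.spot_region is not None:
        truth.spot_region.rename_axis("barcode").to_csv(out / "truth_spot_region.csv")
    with open(out / "truth_coloc_spots.txt", "w") as fh:
        for b in truth.coloc_spots:
            fh.write(f"{b}\n")
    markers = truth.planted.get("markers", {})
    pd.DataFrame(
        [(k, g) for k, genes in markers.items() for g in genes],
        columns=["cluster", "gene"],
    ).to_csv(out / "truth_markers.csv", index=False)
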