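"""Shared data model and on-disk formats.

The pipeline exchanges three kinds of files:

* sparse gene x observation count matrices in Matrix-Market coordinate
  format, accompanied by plain-text gene and barcode lists (one id per
  line, same order as the matrix axes);
* a per-spot table (CSV) carrying the hexagonal array indices and the
  physical spot-center coordinates in micrometres;
* region definitions (circles or simple polygons, coordinates in μm).

Conventions: genes are rows on disk (10x style); physical coordinates
have their origin at the top-left of the capture area with y increasing
downward; hex array indices are 0-based row-offset with odd rows shifted
right by half a spacing; regions are closed (boundary points belong to
the region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.prepared import prep as _shapely_prep

SPOT_DIAMETER_UM = 55.0

SPOT_TABLE_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"]


class FormatError(ValueError):
    """Raised when an on-disk file violates the declared format."""


class GeometryError(ValueError):
    """Raised for invalid region geometries (e.g. self-intersecting polygons)."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} identifiers")
    return ids


@dataclass
class GeneMatrix:
    """Sparse non-negative integer count matrix, genes x observations.

    ``values`` is stored CSR with genes as rows; ``obs_ids`` are cell or
    spot barcodes.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    obs_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        n_genes, n_obs = self.values.shape
        if n_genes != len(self.gene_ids) or n_obs != len(self.obs_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count encountered")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count encountered")
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def subset_obs(self, obs: Sequence[str]) -> "GeneMatrix":
        index = {b: i for i, b in enumerate(self.obs_ids)}
        cols = [index[b] for b in obs]
        return GeneMatrix(self.values[:, cols], list(self.gene_ids), list(obs))

    def to_adata(self) -> ad.AnnData:
        """Observations x genes AnnData view of the counts."""
        adata = ad.AnnData(
            X=self.values.T.tocsr().astype(np.float64),
            obs=pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        return adata

    def total_counts(self) -> pd.Series:
        """Per-observation total counts."""
        tot = np.asarray(self.values.sum(axis=0)).ravel()
        return pd.Series(tot, index=self.obs_ids, name="total_counts")


def read_counts(matrix_path, genes_path, barcodes_path) -> GeneMatrix:
    """Read a Matrix-Market triplet file plus gene/barcode id lists."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - normalize scipy's error types
        raise FormatError(f"could not parse {matrix_path}: {exc}") from exc
    genes = _read_id_list(genes_path)
    barcodes = _read_id_list(barcodes_path)
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header {mat.shape} does not match id lists "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return GeneMatrix(mat.tocsr(), genes, barcodes)


def write_counts(gm: GeneMatrix, matrix_path, genes_path, barcodes_path) -> None:
    scipy.io.mmwrite(
        str(matrix_path), gm.values.tocoo(), field="integer", symmetry="general"
    )
    _write_id_list(genes_path, gm.gene_ids)
    _write_id_list(barcodes_path, gm.obs_ids)


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_id_list(path, ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


@dataclass
class SpotTable:
    """Per-spot hex-grid and physical coordinates.

    One row per barcode: in-tissue flag, 0-based hex array row/col, and
    the spot center in μm. Spots are 55 μm in diameter.
    """

    table: pd.DataFrame
    diameter_um: float = SPOT_DIAMETER_UM

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"spot table missing columns: {missing}")
        self.table = self.table[SPOT_TABLE_COLUMNS].copy()
        self.table["barcode"] = self.table["barcode"].astype(str)
        if self.table["barcode"].duplicated().any():
            raise FormatError("duplicate spot barcodes")
        in_tissue = self.table["in_tissue"]
        if not set(np.unique(in_tissue)).issubset({0, 1, True, False}):
            raise FormatError("in_tissue must be 0/1")
        self.table["in_tissue"] = in_tissue.astype(bool)
        self.table["array_row"] = self.table["array_row"].astype(int)
        self.table["array_col"] = self.table["array_col"].astype(int)
        self.table = self.table.reset_index(drop=True)

    @property
    def barcodes(self) -> list[str]:
        return self.table["barcode"].tolist()

    def in_tissue_barcodes(self) -> list[str]:
        return self.table.loc[self.table["in_tissue"], "barcode"].tolist()

    def positions(self) -> pd.DataFrame:
        """x/y μm coordinates indexed by barcode."""
        return self.table.set_index("barcode")[["x_um", "y_um"]]


def read_spot_table(path) -> SpotTable:
    df = pd.read_csv(path)
    missing = [c for c in SPOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot table {path} missing columns: {missing}")
    if not set(df["in_tissue"].unique()).issubset({0, 1}):
        raise FormatError("in_tissue must be coded 0/1")
    return SpotTable(df)


def write_spot_table(spots: SpotTable, path) -> None:
    out = spots.table.copy()
    out["in_tissue"] = out["in_tissue"].astype(int)
    out.to_csv(path, index=False)


@dataclass
class CellAnnotation:
    """Per-cell cluster labels with their class partition.

    ``classes`` maps each cluster label to one of
    ``{"epithelial", "endothelial", "immune", "fibroblast", "other"}``.
    """

    table: pd.DataFrame  # columns: obs_id, cluster, sample
    classes: dict[str, str] = field(default_factory=dict)

    VALID_CLASSES = {"epithelial", "endothelial", "immune", "fibroblast", "other"}

    def __post_init__(self) -> None:
        for col in ("obs_id", "cluster", "sample"):
            if col not in self.table.columns:
                raise FormatError(f"cell annotation missing column {col!r}")
        bad = set(self.classes.values()) - self.VALID_CLASSES
        if bad:
            raise FormatError(f"unknown cluster classes: {sorted(bad)}")
        unknown = set(self.table["cluster"]) - set(self.classes)
        if self.classes and unknown:
            raise FormatError(f"clusters without a declared class: {sorted(unknown)}")
        self.table = self.table.reset_index(drop=True)

    def clusters_of_class(self, *classes: str) -> list[str]:
        return sorted(k for k, v in self.classes.items() if v in classes)

    def labels(self) -> pd.Series:
        return self.table.set_index("obs_id")["cluster"]


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    radius: float

    def area_mm2(self) -> float:
        return math.pi * self.radius**2 / 1e6


@dataclass(frozen=True)
class Polygon:
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise GeometryError("invalid (e.g. self-intersecting) polygon")

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def area_mm2(self) -> float:
        return self.shapely().area / 1e6


Geometry = Union[Circle, Polygon]


@dataclass
class RegionMask:
    region_id: str
    geometry: Geometry
    member_spots: list[str]

    def area_mm2(self) -> float:
        return self.geometry.area_mm2()


def region_membership(spots: SpotTable, geometry: Geometry, region_id: str = "region") -> RegionMask:
    """In-tissue spots whose centers lie inside (or on) the geometry."""
    tab = spots.table[spots.table["in_tissue"]]
    xs = tab["x_um"].to_numpy(dtype=float)
    ys = tab["y_um"].to_numpy(dtype=float)
    if isinstance(geometry, Circle):
        inside = (xs - geometry.cx) ** 2 + (ys - geometry.cy) ** 2 <= geometry.radius**2
    elif isinstance(geometry, Polygon):
        poly = _shapely_prep(geometry.shapely())
        # prepared.covers includes the boundary: the region is closed
        inside = np.array([poly.covers(_ShapelyPoint(x, y)) for x, y in zip(xs, ys)])
    else:
        raise GeometryError(f"unsupported geometry {type(geometry)!r}")
    members = tab.loc[inside, "barcode"].tolist()
    return RegionMask(region_id=region_id, geometry=geometry, member_spots=members)


def region_from_config(spots: SpotTable, cfg: dict) -> RegionMask:
    """Build a RegionMask from a config block.

    Circle: ``{id, type: circle, cx_um, cy_um, radius_um}``;
    polygon: ``{id, type: polygon, vertices_um: [[x, y], ...]}``.
    """
    kind = cfg.get("type")
    if kind == "circle":
        geom: Geometry = Circle(float(cfg["cx_um"]), float(cfg["cy_um"]), float(cfg["radius_um"]))
    elif kind == "polygon":
        geom = Polygon(tuple((float(x), float(y)) for x, y in cfg["vertices_um"]))
    else:
        raise GeometryError(f"unknown region type {kind!r}")
    return region_membership(spots, geom, region_id=str(cfg.get("id", "region")))


def hex_grid(rows: int, cols: int, spacing_um: float = 100.0) -> pd.DataFrame:
    """Row-offset hexagonal grid of spot centers (odd rows shifted right).

    Row pitch is spacing * sqrt(3)/2 so nearest neighbours across rows sit
    at the same distance as within-row neighbours.
    """
    rec = []
    for r in range(rows):
        for c in range(cols):
            x = c * spacing_um + (r % 2) * spacing_um / 2.0
            y = r * spacing_um * math.sqrt(3) / 2.0
            rec.append((r, c, x, y))
    df = pd.DataFrame(rec, columns=["array_row", "array_col", "x_um", "y_um"])
    df["barcode"] = [f"spot-{r:03d}-{c:03d}" for r, c in zip(df["array_row"], df["array_col"])]
    df["in_tissue"] = 1
    return df[SPOT_TABLE_COLUMNS]


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
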