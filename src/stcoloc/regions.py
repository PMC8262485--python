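"""Regional expression analysis.

Total-count maps per spot, differential expression between size-matched
regions pooled across all spots regardless of identity, per-cluster
spot-distribution shifts between regions (exact Fisher), and a generic
hypergeometric over-representation test for user-supplied gene sets
(GMT collections are inputs; no pathway database is bundled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exact_tests import fisher_exact_greater, fisher_exact_twosided
from .io import GeneMatrix, RegionMask, SpotTable
from .signatures import find_markers

SIZE_MATCH_TOLERANCE = 0.10


def total_counts_map(spots: GeneMatrix, table: SpotTable) -> pd.DataFrame:
    """Per-spot total read counts joined with spot coordinates."""
    totals = spots.total_counts()
    out = table.table.merge(
        totals.rename("total_counts"), left_on="barcode", right_index=True, how="left"
    )
    out["total_counts"] = out["total_counts"].fillna(0).astype(np.int64)
    return out[["barcode", "in_tissue", "x_um", "y_um", "total_counts"]]


def check_size_matched(a: RegionMask, b: RegionMask, tolerance: float = SIZE_MATCH_TOLERANCE) -> bool:
    """Warn when two 'size-matched' regions differ in area beyond tolerance."""
    area_a, area_b = a.area_mm2(), b.area_mm2()
    matched = abs(area_a - area_b) <= tolerance * max(area_a, area_b)
    if not matched:
        warnings.warn(
            f"regions {a.region_id!r} ({area_a:.3f} mm^2) and {b.region_id!r} "
            f"({area_b:.3f} mm^2) differ by more than {tolerance:.0%}"
        )
    return matched


def region_de(
    spots_normalized: ad.AnnData,
    region_a: RegionMask,
    region_b: RegionMask,
    min_spots: int = 3,
) -> pd.DataFrame:
    """Wilcoxon DE of region A vs region B across all spots, regardless
    of cluster identity."""
    obs = set(spots_normalized.obs_names)
    set_a = [b for b in region_a.member_spots if b in obs]
    set_b = [b for b in region_b.member_spots if b in obs]
    if set(set_a) & set(set_b):
        raise ValueError("regions overlap; region DE requires disjoint regions")
    if len(set_a) < min_spots or len(set_b) < min_spots:
        raise ValueError(f"both regions need >= {min_spots} spots with expression data")
    sub = spots_normalized[set_a + set_b]
    labels = pd.Series(["A"] * len(set_a) + ["B"] * len(set_b), index=set_a + set_b)
    return find_markers(sub, labels, "A", reference_group="B")


def spot_distribution_shift(
    dominant: pd.DataFrame, region_a: RegionMask, region_b: RegionMask
) -> pd.DataFrame:
    """Per-cluster Fisher test of spot-label frequency between regions.

    For each cluster the 2x2 table is (label = cluster vs not) x
    (region A vs B); the one-sided p is taken in the direction of the
    observed enrichment, the two-sided p is reported alongside.
    """
    dom = dominant.set_index("barcode")["dominant"]
    set_a = [b for b in region_a.member_spots if b in dom.index]
    set_b = [b for b in region_b.member_spots if b in dom.index]
    if set(set_a) & set(set_b):
        raise ValueError("regions must be disjoint")
    if not set_a or not set_b:
        raise ValueError("both regions must contain labeled spots")
    in_a, in_b = dom.loc[set_a], dom.loc[set_b]
    rows = []
    for cl in sorted(set(dom.loc[set_a + set_b].unique())):
        a = int((in_a == cl).sum())
        b = len(set_a) - a
        c = int((in_b == cl).sum())
        d = len(set_b) - c
        if a + c == 0:
            rows.append(
                {"cluster": cl, "n_a": a, "n_b": c, "enriched_in": "none",
                 "p_one_sided": 1.0, "p_two_sided": 1.0, "note": "empty cluster"}
            )
            continue
        freq_a, freq_b = a / len(set_a), c / len(set_b)
        if freq_a >= freq_b:
            p_one = fisher_exact_greater(a, b, c, d)
            direction = "A"
        else:
            p_one = fisher_exact_greater(c, d, a, b)
            direction = "B"
        rows.append(
            {
                "cluster": cl,
                "n_a": a,
                "n_b": c,
                "enriched_in": direction,
                "p_one_sided": p_one,
                "p_two_sided": fisher_exact_twosided(a, b, c, d),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def ora_hypergeometric(
    hits: Iterable[str], gene_set: Iterable[str], universe: Sequence[str]
) -> tuple[int, float]:
    """Over-representation of ``hits`` in ``gene_set`` within ``universe``.

    p = P(X >= overlap) with X ~ Hypergeometric(|universe|, |set|, |hits|).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hits = set(hits)
    gene_set = set(gene_set)
    if not hits <= uni:
        raise ValueError("hits must be a subset of the universe")
    if not gene_set <= uni:
        raise ValueError("gene set must be a subset of the universe")
    overlap = len(hits & gene_set)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(hits)))
    return overlap, min(1.0, p)


def ora_table(
    hits: Iterable[str], gene_sets: dict[str, Iterable[str]], universe: Sequence[str]
) -> pd.DataFrame:
    """ORA across a GMT-style collection with BH adjustment."""
    rows = []
    for name, gs in gene_sets.items():
        gs = [g for g in gs if g in set(universe)]
        overlap, p = ora_hypergeometric(hits, gs, universe)
        rows.append({"gene_set": name, "set_size": len(gs), "overlap": overlap, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


@dataclass
class RegionComparison:
    """Bundle of the region-level analyses for two size-matched regions."""

    region_a: RegionMask
    region_b: RegionMask
    de_table: pd.DataFrame
    shift_table: pd.DataFrame
    area_a_mm2: float
    area_b_mm2: float
    size_matched: bool
    nuclei_counts: pd.DataFrame | None = None  # optional, externally provided
    ora: pd.DataFrame | None = None


def compare_regions(
    spots_normalized: ad.AnnData,
    dominant: pd.DataFrame,
    region_a: RegionMask,
    region_b: RegionMask,
    gene_sets: dict[str, Iterable[str]] | None = None,
    de_alpha: float = 0.05,
    nuclei_counts: pd.DataFrame | None = None,
) -> RegionComparison:
    """Full region comparison: DE, spot-distribution shift, optional ORA
    of the Bonferroni-significant DE genes."""
    matched = check_size_matched(region_a, region_b)
    de = region_de(spots_normalized, region_a, region_b)
    shift = spot_distribution_shift(dominant, region_a, region_b)
    ora = None
    if gene_sets:
        hits = de.loc[de["p_adj"] < de_alpha, "gene"].tolist()
        ora = ora_table(hits, gene_sets, list(spots_normalized.var_names))
    return RegionComparison(
        region_a=region_a,
        region_b=region_b,
        de_table=de,
        shift_table=shift,
        area_a_mm2=region_a.area_mm2(),
        area_b_mm2=region_b.area_mm2(),
        size_matched=matched,
        nuclei_counts=nuclei_counts,
        ora=ora,
    )
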