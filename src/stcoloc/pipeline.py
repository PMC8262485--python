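"""End-to-end pipeline orchestration.

One configuration drives the full synthetic study: simulate a
single-cell reference plus a condition and a sham spatial sample, build
QC'd signatures, deconvolve and label every spot, compute colocalization
odds ratios (condition vs sham), run colocalization-conditioned marker
discovery and reference subclustering, and compare the low-expression
region with a size-matched preserved region. All tabular outputs are
CSV; a JSON manifest records seeds, parameters and output hashes so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coloc import coloc_table, compare_to_reference
from .coloc_markers import coloc_de, subcluster_and_profile
from .deconvolution import deconvolve, dominant_labels, spot_composition_report
from .io import Circle, read_gmt, region_membership
from .regions import compare_regions, total_counts_map
from .secondary import secondary_label, secondary_label_map
from .signatures import (
    ClusteringParams,
    QCThresholds,
    build_signature_matrix,
    normalize,
    qc_filter_cells,
)
from .simulate import (
    DEFAULT_PRESERVED_REGION,
    MITO_GENES,
    SimulationConfig,
    simulate_reference,
    simulate_spots,
    write_dataset,
)

SHAM_SEED_OFFSET = 500_009  # sham sample uses an independent stream


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimulationConfig = SimulationConfig()
    qc: QCThresholds = QCThresholds()
    clustering: ClusteringParams = ClusteringParams()
    top_n_markers: int = 60
    min_spots: int = 5
    control: str = "Fibroblast"
    two_sided: bool = False
    preserved_region: Circle = DEFAULT_PRESERVED_REGION
    gene_sets_path: str | None = None
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


def config_from_yaml(path) -> PipelineConfig:
    """Load a pipeline config from YAML; unspecified fields keep defaults.

    Recognized top-level keys: seed, top_n_markers, min_spots, control,
    two_sided, gene_sets_path, and nested ``sim``, ``qc``, ``clustering``
    blocks whose keys mirror the corresponding dataclass fields
    (scalar fields only).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    sim = cfg.sim
    if "sim" in raw:
        block = dict(raw["sim"])
        if "clusters" in block:
            from .simulate import ClusterSpec

            block["clusters"] = tuple(
                ClusterSpec(c["name"], c["cls"], int(c.get("n_cells", 150)))
                for c in block["clusters"]
            )
        if "regions" in block:
            from .simulate import RegionSpec

            block["regions"] = tuple(
                RegionSpec(
                    r["id"],
                    Circle(float(r["cx_um"]), float(r["cy_um"]), float(r["radius_um"])),
                    dict(r["alpha"]),
                )
                for r in block["regions"]
            )
        sim = sim.replace(**block)
    if "preserved_region" in raw:
        r = raw["preserved_region"]
        cfg = cfg.replace(
            preserved_region=Circle(float(r["cx_um"]), float(r["cy_um"]), float(r["radius_um"]))
        )
    qc = cfg.qc
    if "qc" in raw:
        qc = dataclasses.replace(qc, **raw["qc"])
    clustering = cfg.clustering
    if "clustering" in raw:
        clustering = dataclasses.replace(clustering, **raw["clustering"])
    scalars = {
        k: raw[k]
        for k in ("seed", "top_n_markers", "min_spots", "control", "two_sided", "gene_sets_path")
        if k in raw
    }
    cfg = cfg.replace(sim=sim, qc=qc, clustering=clustering, **scalars)
    if "seed" in raw:
        cfg = cfg.replace(sim=cfg.sim.replace(seed=int(raw["seed"])))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; write CSV outputs and a manifest into ``outdir``.

    Returns the manifest dict. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    sim = config.sim.replace(seed=config.seed)
    sham_sim = sim.replace(
        coloc=dataclasses.replace(sim.coloc, fraction=0.0),
        low_region=dataclasses.replace(sim.low_region, scale=1.0, injury_fold=1.0),
        seed=(config.seed + SHAM_SEED_OFFSET) % (2**31),
    )

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return result

        return deco

    # --- reference -------------------------------------------------------
    @stage("simulate_reference")
    def _ref():
        return simulate_reference(sim)

    ref_counts, annotation, ref_truth = _ref

    @stage("qc")
    def _qc():
        mito = [g for g in MITO_GENES if g in ref_counts.gene_ids]
        samples = annotation.table.set_index("obs_id")["sample"]
        return qc_filter_cells(ref_counts, mito, config.qc, samples=samples)

    kept, ledger = _qc
    manifest["stages"]["qc"] = {
        "cells_in": ref_counts.n_obs,
        "cells_out": kept.n_obs,
        "removed_by_rule": ledger["rule"].value_counts().to_dict(),
    }
    _write_csv(ledger, out / "qc_ledger.csv")

    @stage("signatures")
    def _sig():
        adata = normalize(kept)
        labels = annotation.labels().reindex(adata.obs_names)
        signature, markers = build_signature_matrix(adata, labels, config.top_n_markers)
        return adata, labels, signature, markers

    ref_adata, ref_labels, signature, marker_table = _sig
    _write_csv(signature.rename_axis("cluster"), out / "signature.csv", index=True)
    _write_csv(marker_table, out / "markers.csv")
    _write_csv(
        pd.DataFrame({"obs_id": ref_labels.index, "cluster": ref_labels.to_numpy()}),
        out / "cell_clusters.csv",
    )

    suppressed = annotation.clusters_of_class("epithelial", "endothelial")
    immune = annotation.clusters_of_class("immune")
    epithelial = annotation.clusters_of_class("epithelial")

    # --- spatial samples -------------------------------------------------
    samples = {}
    for name, s_cfg in (("condition", sim), ("sham", sham_sim)):

        @stage(f"simulate_spots[{name}]")
        def _spots(s_cfg=s_cfg):
            return simulate_spots(s_cfg, reference_truth=ref_truth if s_cfg is sim else None)

        counts, spot_table, truth = _spots

        @stage(f"deconvolve[{name}]")
        def _dec(counts=counts):
            adata = normalize(counts)
            scores = deconvolve(adata, signature)
            return adata, scores

        adata, scores = _dec
        dom = dominant_labels(scores)
        sec = secondary_label(scores, suppressed, immune, control=config.control)
        display, full = secondary_label_map(sec, spot_table)
        coloc = coloc_table(
            dom,
            sec,
            sample_id=name,
            epithelial=epithelial,
            immune=immune,
            min_spots=config.min_spots,
            two_sided=config.two_sided,
        )
        totals = total_counts_map(counts, spot_table)
        comp = spot_composition_report(scores)

        _write_csv(scores.scores.rename_axis("barcode"), out / f"scores_{name}.csv", index=True)
        _write_csv(dom, out / f"dominant_{name}.csv")
        _write_csv(full, out / f"secondary_{name}.csv")
        _write_csv(display, out / f"secondary_display_{name}.csv")
        _write_csv(coloc, out / f"coloc_{name}.csv")
        _write_csv(totals, out / f"total_counts_{name}.csv")
        _write_csv(comp, out / f"composition_{name}.csv")
        manifest["stages"][f"sample_{name}"] = {
            "spots": counts.n_obs,
            "assigned": int(scores.assigned.sum()),
            "coloc_pairs_tested": int(len(coloc)),
        }
        samples[name] = dict(
            counts=counts, spots=spot_table, truth=truth, adata=adata,
            scores=scores, dominant=dom, secondary=sec, coloc=coloc,
        )

    # --- condition vs sham ----------------------------------------------
    paired, dot = compare_to_reference(samples["condition"]["coloc"], samples["sham"]["coloc"])
    _write_csv(paired, out / "coloc_compare.csv")
    _write_csv(dot, out / "coloc_dotplot.csv")

    # --- coloc-conditioned markers ---------------------------------------
    @stage("coloc_de")
    def _cde():
        return coloc_de(
            samples["condition"]["adata"],
            samples["condition"]["dominant"],
            samples["condition"]["secondary"],
            epithelial=sim.coloc.epithelial,
            immune_cluster=sim.coloc.immune,
            immune=immune,
            control=config.control,
        )

    de_result = _cde
    if de_result.table is not None:
        _write_csv(de_result.table, out / "coloc_de.csv")
        _write_csv(de_result.volcano_export(), out / "coloc_de_volcano.csv")
    manifest["stages"]["coloc_de"] = {
        "n_coloc": de_result.n_coloc,
        "n_other": de_result.n_other,
        "insufficient": de_result.insufficient,
    }

    @stage("subcluster")
    def _sub():
        return subcluster_and_profile(
            ref_adata,
            ref_labels,
            [sim.subpop.cluster],
            gene=sim.subpop.gene,
            params=config.clustering,
        )

    subclusters = _sub
    _write_csv(subclusters, out / "subclusters.csv")

    # --- region analysis -------------------------------------------------
    @stage("regions")
    def _reg():
        spot_table = samples["condition"]["spots"]
        low_spec = next(r for r in sim.regions if r.region_id == sim.low_region.region)
        low_mask = region_membership(spot_table, low_spec.circle, region_id=low_spec.region_id)
        preserved = region_membership(spot_table, config.preserved_region, region_id="preserved")
        gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
        return compare_regions(
            samples["condition"]["adata"],
            samples["condition"]["dominant"],
            low_mask,
            preserved,
            gene_sets=gene_sets,
        )

    region_cmp = _reg
    _write_csv(region_cmp.de_table, out / "region_de.csv")
    _write_csv(region_cmp.shift_table, out / "region_shift.csv")
    if region_cmp.ora is not None:
        _write_csv(region_cmp.ora, out / "region_ora.csv")
    manifest["stages"]["regions"] = {
        "area_a_mm2": region_cmp.area_a_mm2,
        "area_b_mm2": region_cmp.area_b_mm2,
        "size_matched": region_cmp.size_matched,
        "spots_a": len(region_cmp.region_a.member_spots),
        "spots_b": len(region_cmp.region_b.member_spots),
    }

    for path in sorted(out.glob("*.csv")):
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_command(config: PipelineConfig, outdir) -> None:
    """Write the synthetic dataset (data_io formats + truth sidecars)."""
    sim = config.sim.replace(seed=config.seed)
    ref_counts, annotation, ref_truth = simulate_reference(sim)
    spatial, spot_table, truth = simulate_spots(sim, reference_truth=ref_truth)
    merged = dataclasses.replace(truth, cells=ref_truth.cells)
    write_dataset(outdir, ref_counts, annotation, spatial, spot_table, merged)
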