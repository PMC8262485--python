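"""QC the single-cell reference and build cluster signatures.

Applies the three-rule quality filter (mitochondrial fraction > 50%,
< 200 unique genes, per-sample 10%/5% unique-gene percentile band),
normalizes to log1p(CP10K), finds per-cluster Wilcoxon markers, and
writes the cluster x marker-gene signature matrix that the
deconvolution step uses as its regression design.
"""

from pathlib import Path

from stcoloc.signatures import build_signature_matrix, normalize, qc_filter_cells
from stcoloc.simulate import MITO_GENES, SimulationConfig, simulate_reference

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    counts, annotation, _ = simulate_reference(cfg)
    kept, ledger = qc_filter_cells(
        counts, list(MITO_GENES), samples=annotation.table.set_index("obs_id")["sample"]
    )
    print(f"QC: {counts.n_obs} cells in, {kept.n_obs} kept "
          f"({ledger['rule'].value_counts().to_dict()})")
    adata = normalize(kept)
    labels = annotation.labels().reindex(adata.obs_names)
    signature, markers = build_signature_matrix(adata, labels)
    ledger.to_csv(OUT / "qc_ledger.csv", index=False)
    signature.rename_axis("cluster").to_csv(OUT / "signature.csv")
    markers.to_csv(OUT / "markers.csv", index=False)
    print(f"signature: {signature.shape[0]} clusters x {signature.shape[1]} marker genes")
    top = markers[markers["selected"]].groupby("cluster")["gene"].first()
    print("top marker per cluster:")
    for cl, g in top.items():
        print(f"  {cl}: {g}")


if __name__ == "__main__":
    main()
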