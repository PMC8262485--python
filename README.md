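# stcoloc

Single-cell–informed deconvolution and immune–epithelial
colocalization analysis for spatial transcriptomics.

Spot-based platforms such as 10x Visium measure whole-transcriptome
expression at 55 μm capture spots, each overlying several cells. In
injured kidney (and any organ with regional pathology), the questions
that matter are compositional and spatial: which cell types contribute
to each spot, which immune cells co-occur with which epithelial
segments, what the epithelium expresses when immune cells are present,
and how regions of depressed expression differ from preserved tissue.
`stcoloc` implements that analysis chain as a reusable library with an
end-to-end synthetic study: every stage is exercised against generated
data with planted ground truth, so each statistic is validated against
an exact oracle or a known answer.

The pipeline:

1. **Reference signatures** — QC a single-cell reference
   (mitochondrial fraction > 50%, < 200 detected genes, per-sample
   10%/5% detected-gene percentile band), normalize to log1p(CP10K),
   find per-cluster Wilcoxon rank-sum markers, and build a
   cluster × marker-gene signature matrix.
2. **Spot deconvolution** — per spot *s*, solve
   min‖Sᵀw − y_s‖₂ s.t. w ≥ 0 (NNLS on the linear CP10K scale, where
   mixtures are additive) and renormalize to proportions; the argmax
   is the spot's dominant label.
3. **Secondary immune labeling** — suppress the dominant
   epithelial/endothelial clusters and assign the top-ranked immune
   identity wherever its score strictly exceeds a fibroblast control.
4. **Colocalization** — for each (epithelial E, immune I) pair, build
   the 2×2 table a,b,c,d of (dominant = E) × (secondary = I) and test
   OR = ad/bc > 1 with a one-sided exact Fisher test
   (P(A ≥ a) under the hypergeometric null), Haldane–Anscombe 95% CI,
   BH q-values across pairs; compare condition vs sham sample.
5. **Coloc-conditioned markers** — Wilcoxon DE between E spots
   colocalized with I and E spots colocalized with other immune cells
   or fibroblasts (chemotactic-factor candidates), plus reference
   subclustering at increased resolution to find the signaling
   subpopulation.
6. **Region analysis** — total-count maps, DE between size-matched
   regions across all spots, per-cluster spot-distribution shifts
   (exact Fisher), and hypergeometric over-representation over
   user-supplied GMT gene sets.

The synthetic generator emulates a murine acute-kidney-injury
experiment: a 9-cluster kidney reference (negative-binomial counts,
specific markers), a hex-grid spatial sample whose spots are Dirichlet
mixtures of cluster profiles, a planted neutrophil infiltration of the
PT-S3 territory ("outer stripe"), a chemotactic factor (*Mdk*, fold 4)
upregulated only in colocalized spots, a stress subpopulation (20% of
PT-S3 with *Atf3* ×6), and a low-expression region (library ×0.5) with
injury markers (*Havcr1*, *Lcn2*) ×4. See `docs/methods.md` for the
model and every default.

## Worked example

The numbered scripts under `analysis/` run the study end to end and
write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/03_deconvolve_and_label.py
python analysis/04_colocalization.py
python analysis/05_coloc_markers.py
python analysis/06_region_analysis.py
```

Output at seed 0 (abridged):

```
spots assigned: 1156/1156
mean absolute proportion error vs truth: 0.0097
dominant label agrees with true argmax for 96.4% of spots
secondary labels: {'none': 1067, 'Neutrophil': 54, 'Macrophage': 19, 'NK': 16}
Neutrophil labels inside 'outer_stripe': 83.3%

planted pair (PT-S3, Neutrophil): OR = 22.40 [9.49, 52.89], one-sided p = 8.16e-21
pairs enriched in condition vs sham: 1

planted chemotactic gene Mdk ranks #1 by p-value
  p = 1.16e-21, logFC = 1.26
subclustering PT-S3 at increased resolution: 12 subclusters
  expressing-fraction ratio vs remainder: 3.16

median total counts ratio, low region / rest: 0.508 (planted scale 0.5)
top region DE genes: Lcn2 (p=5.2e-74), Havcr1 (p=5.9e-74), ...
```

Reading these numbers: deconvolution recovers the planted spot
compositions to within ~0.01 mean absolute error; the planted
neutrophil–PT-S3 pair is the only colocalization flagged against the
sham, with an odds ratio far above 1; the planted chemotactic gene
tops the colocalization-conditioned DE table; reclustering PT-S3
isolates a subcluster whose *Atf3*-expressing fraction is ≥3× the
remaining cells; and the low region shows the planted halving of total
counts with its injury genes as the top regional DE hits.

The same stages are exposed as a CLI (`stcoloc simulate | signatures |
deconvolve | label | coloc | markers | regions | run-all`) driven by a
YAML config; `run-all` additionally simulates a matched sham sample,
writes every table plus a JSON manifest of seeds and output hashes,
and is byte-reproducible for a fixed config.

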