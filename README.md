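# ctscore

Quantifying directed flow between cell clusters from RNA-velocity streams.

RNA velocity overlays a low-dimensional embedding (typically UMAP) with
per-cell displacement arrows indicating where each cell's transcriptome is
heading. Reading transitions off such a stream plot by eye is subjective,
especially in 3D. `ctscore` turns the grid-aggregated velocity arrows of one
or more 2D perspectives into a single **composite transition score (CTS)**
matrix: a K × K table of non-negative scores quantifying the directed flow
from every cluster toward every other cluster.

The package is aimed at single-cell transcriptomics analysts who already have
an embedding, embedding-space velocity vectors, and cluster labels (from any
upstream toolchain — Seurat, scanpy, scVelo, velocyto), and want a
reproducible, quantitative summary of the stream plot. It also ships the
B-cell-oriented preprocessing companions: three-stage cell QC on raw count
matrices and immunoglobulin/TCR variable-gene pruning.

## The score

For each grid arrow *A<sub>i</sub>* with base *X<sub>i</sub>* and tip
*Y<sub>i</sub>* (the mean displacement of the cells in one rectangle of a
regular grid over the view), and each candidate destination cluster centroid
*Z<sub>j</sub>*, the alignment angle θ is taken from the triangle
(*X<sub>i</sub>*, *Y<sub>i</sub>*, *Z<sub>j</sub>*) by the law of cosines, and
the pair score is

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>i,j</sub>* = (1 − cos θ<sub>i,j</sub>) · |X<sub>i</sub>Y<sub>i</sub>| / |X<sub>i</sub>Z<sub>j</sub>|

with θ measured at the arrow tip (the default `endpoint` convention; an
`origin` convention measuring the angle at the base, scored with 1 + cos θ,
is also provided). S is maximal when a long arrow points straight at a nearby
centroid and zero when it points straight away. Each arrow's **starting
cluster** is the majority vote over the cells in its grid rectangle; pair
scores are summed per (starting cluster *j*₁, destination *j*₂) and scaled by
a per-destination min–max weighting of centroid distances *z*,

&nbsp;&nbsp;&nbsp;&nbsp;*w* = 1 − (z − min z) / (max z − min z),&nbsp;&nbsp;&nbsp;&nbsp;CTS<sub>j₁,j₂</sub> = *w* · Σ<sub>i∈j₁</sub> *S<sub>i,j₂</sub>*

so that flow toward a cluster's nearest neighbours weighs more than flow
toward distant ones. A 3D embedding is analysed through two 2D perspectives
(axes 0 × 2 and 1 × 2 by default, i.e. dimension 1 vs 3 and 2 vs 3); per-view
CTS matrices are summed. For display, positive entries are log2-transformed
and zero entries are masked.

## Worked example

Generate a synthetic 3D dataset with a known ground-truth transition chain
A → B → C → D (four Gaussian clusters, 200 cells each, displacement vectors of
unit speed pointing at each source's destination centre plus 10% noise), then
score it:

```sh
ctscore simulate --out demo --seed 7
ctscore cts --embedding demo/embedding.tsv --velocity demo/velocity.tsv \
            --labels demo/labels.tsv --out demo/cts
```

which reports `4 clusters, 2 view(s); skipped 0 degenerate pair(s)` and
writes `demo/cts/cts.tsv`:

| source | A | B | C | D |
|---|---|---|---|---|
| A | 0.00 | **13.98** | 0.00 | 4.01 |
| B | 5.56 | 0.00 | **12.20** | 1.86 |
| C | 0.11 | 4.28 | 0.00 | **15.90** |
| D | 0.43 | 0.00 | 0.67 | 0.00 |

Each row is a source cluster, each column a destination; the largest entry in
each of rows A, B and C correctly identifies the generating edge (A → B,
B → C, C → D), while the terminal cluster D shows only weak residual flow.
Alongside it are `raw_totals.tsv` (unweighted Σ S), `weights.tsv` (per-view
centroid distances and weights), `log2_display.tsv` (log2-scaled entries,
zeros masked), `skips.tsv` (degenerate-geometry drop counts) and a
`manifest.json` with the effective configuration and input checksums.

QC filtering and gene pruning run on a 10x-style MatrixMarket triplet:

```sh
ctscore qc --mtx counts/matrix.mtx --features counts/features.tsv \
           --barcodes counts/barcodes.tsv --genes variable_genes.txt --out qc
```

removing cells that (i) express any transcript of CD3E, GNLY, CD14, FCER1A,
FCGR3A, LYZ, PPBP or CD8A, (ii) detect fewer than 200 distinct genes, or
(iii) sit above the top-1% nearest-rank quantile of total counts; and pruning
Ig V/D/J (`IG[HKL][VDJ]`), TCR (`TR[ABGD][CV]`), IGLL and constant-region
genes from the supplied variable-gene list.

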