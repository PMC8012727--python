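# Methods

## Model and procedure

`ctscore` summarizes an embedding-space RNA-velocity field into a directed
cluster-to-cluster transition matrix. It deliberately operates *downstream*
of velocity estimation: the inputs are per-cell coordinates in a 2D or 3D
embedding, per-cell displacement vectors in that same space, and a cluster
assignment. How the velocities were estimated (spliced/unspliced kinetics,
kernel projection, …) is outside the model; the score only assumes the
displacement field is meaningful in the embedding's geometry.

The pipeline per 2D perspective:

1. **Grid aggregation.** The bounding box of the view coordinates, expanded
   by `margin_frac` per side, is partitioned into `n_grid × n_grid` equal
   rectangles. Every rectangle holding at least `min_cells` cells emits one
   arrow: base at the rectangle center, tip displaced by `arrow_scale` times
   the mean member displacement. This mirrors the grid overlay used by
   velocity stream plots, so the scored arrows are the plotted arrows.
2. **Starting cluster.** Majority vote over the member cells' labels; ties go
   to the lexicographically smallest label, making the vote deterministic and
   independent of cell order.
3. **Pair scoring.** For an arrow (X, Y) and destination centroid Z, the
   alignment cosine comes from the law of cosines on triangle (X, Y, Z) and
   the pair score is S = (1 − cos θ_Y) · |XY| / |XZ| (endpoint convention;
   see below). Self-pairs (destination = starting cluster) are excluded.
4. **Aggregation and weighting.** S is summed per (source, destination).
   For each destination, centroid distances z from all *other* clusters are
   min–max-scaled into w = 1 − (z − min z)/(max z − min z) ∈ [0, 1], and
   CTS = w · ΣS. Excluding the self-distance from z is necessary: the zero
   self-distance would otherwise pin min z = 0 and no genuine source could
   attain w = 1. When all candidate distances coincide (inevitably at K = 2)
   all weights are set to 1, as a single distance defines no relative
   penalty.
5. **Cross-view pooling.** A 3D embedding is analysed through two default
   perspectives, axes (0, 2) and (1, 2). Weights are view-specific — centroid
   distances only exist within a view's 2D geometry — so each view composes
   its own CTS and the per-view matrices are summed. Summation keeps the
   result additive in the arrows, matching the single-view semantics.

Centroids are arithmetic means of member-cell coordinates computed in the
view plane, the simplest estimator measured where the distances are.

### The two angle conventions

The score can anchor the triangle angle at either end of the arrow, and the
two readings need opposite cosine signs to reward alignment:

* **endpoint** (default): θ at the tip Y between Y→X and Y→Z; an arrow
  pointing straight at the centroid has cos θ = −1, so S uses (1 − cos θ),
  maximal (= 2·|XY|/|XZ|) at alignment, zero at anti-alignment.
* **origin**: θ at the base X between X→Y and X→Z; perfect alignment is the
  cos θ = 1 limit, so S uses (1 + cos θ).

Both are exposed via `convention=`; all invariants (S ≥ 0, maximal at
alignment, zero at anti-alignment, similarity invariance) hold for both. One
behavioral difference worth knowing: under the endpoint convention an arrow
that *overshoots* the centroid (Z strictly between X and Y) scores ≈ 0,
because the tip already looks back at both X and Z; the origin convention
still scores it highly. With grid arrows much shorter than inter-centroid
distances the case is rare.

### Numerical choices

* Law-of-cosines cosines are clamped to [−1, 1]; near-collinear triangles
  overshoot by ~1e−16. The form also loses precision when one triangle side
  is vanishingly small relative to the others (ratio below ~1e−6); such
  configurations do not arise from grid arrows at sane scales.
* Degenerate pairs — zero-length arrows (all member displacements cancel) or
  a centroid coinciding with the active triangle anchor — are skipped, not
  errors. Skips are counted per view in a `SkipLog` and surfaced in CLI
  output and manifests so silent data loss is detectable.
* The log2 display transform masks zero entries (NaN) rather than adding a
  pseudo-count: zero flow is qualitatively different from small flow, and a
  pseudo-count would fabricate an ordering among zeros.
* Grid assignment clips boundary cells into the last rectangle, and axes with
  zero positional extent are given unit span so the grid stays well defined.

### CTS invariances

The CTS matrix is invariant under rigid motions, reflections, and uniform
positive scalings applied jointly to arrows and centroids (both |XY|/|XZ|
and min–max-scaled distances are similarity-invariant), under permutation of
arrow and cell order, and is exactly additive in arrows (duplicating every
arrow doubles raw totals; weights are unchanged). These are enforced as
property tests.

## Preprocessing

Cell QC on a raw genes × cells count matrix applies three stages in a fixed
order:

1. remove cells expressing any transcript of the non-B-cell marker panel
   CD3E, GNLY, CD14, FCER1A, FCGR3A, LYZ, PPBP, CD8A (markers absent from
   the matrix are treated as all-zero and logged);
2. remove cells detecting fewer than `min_genes` (default 200) distinct
   genes;
3. remove cells whose total count strictly exceeds the nearest-rank
   (1 − p)-quantile — p defaulting to 0.01 — computed over the survivors of
   stages 1–2. Such high-count barcodes tend to carry several immunoglobulin
   V-gene families at once, indicating cell clumps.

The nearest-rank quantile is the ceil(q·n)-th order statistic; with few cells
it equals the maximum and nothing is removed, which makes the stage
degenerate-safe. The quantile stage is a *one-shot* rule: because the
threshold is recomputed from whatever population it is given, re-applying the
full filter to its own survivors can trim further. Stages 1–2 are exactly
idempotent.

The marker panel uses FCGR3A (CD16, the NK-cell marker); a `strict_symbols`
mode substitutes the variant symbol GCGR3A, which matches no standard human
gene annotation and therefore removes no cells — it exists so both symbol
choices are explicit and logged rather than silent.

Variable-gene pruning removes clonotype- and isotype-driven genes from an
ordered variable-gene list so dimensionality reduction does not cluster B
cells by antibody class or V-gene usage: symbols matching the start-anchored
regexes `IG[HKL][VDJ]` (all Ig V/D/J segments) or `TR[ABGD][CV]` (TCR V and
C segments), symbols with the IGLL prefix, and an explicit constant-region
list (IGHM, IGHD, IGHE, IGHA1-2, IGHG1-4, IGKC, IGLC1-7, AC233755.1).
Anchoring at the symbol start is deliberate — unanchored matching would also
delete unrelated genes containing the substring. Pruning preserves order and
is idempotent. Upstream variable-feature *selection* (e.g. vst top-2000) is
out of scope; any ordered symbol list can be pruned.

## Synthetic data generator

The generator emulates the geometry of a velocity stream over well-separated
cell populations, not the biology that produces it. Cells are drawn from
isotropic Gaussian clusters (`spread` standard deviation around each center);
each non-terminal cluster has directed edges (destination, speed), and a
member cell's displacement is speed × the unit vector from the cell toward
the destination's *center parameter*, plus isotropic Gaussian noise
(`noise_sd`). Aiming at the parameter rather than the empirical centroid
keeps the ground truth independent of sampling noise. Terminal clusters
receive pure noise. All draws derive from a single integer seed through
separate named streams, so datasets are bit-reproducible.

The default scenario is a 4-cluster chain A → B → C → D with 200 cells per
cluster, speed 1.0, noise_sd 0.1 (10% of speed) and spread 1.0 — one tenth of
the minimum center distance. The 3D centers A = (0,0,0), B = (8,6,0),
C = (8,12,8), D = (0,18,8) were chosen so that *both* default perspectives
separate all four clusters, including the flow directions: a layout can keep
clusters apart while a projected flow direction still points halfway toward a
bystander cluster, which no reasonable analyst would accept as a
"well-separated" view. Recovery — the fraction of non-terminal sources whose
argmax-CTS destination matches the generating edge, ties counting as
failure — is ≥ 0.95 averaged over 20 seeds in both the 2D and 3D
configurations, and non-increasing in noise.

What passing these tests does **not** show about real data: real embeddings
have non-Gaussian, curved, touching clusters; real velocity fields bend along
trajectories instead of pointing straight at a destination; and real
transition structure is rarely a clean chain. The synthetic results validate
the scoring machinery, not the biological interpretability of CTS values on
any particular dataset.

The toy count generator draws independent Poisson counts per gene
(rate 2.0 by default) and plants a configurable fraction of cells with
guaranteed nonzero forbidden-marker counts, so QC stage 1 has known ground
truth.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `n_grid` | 30 | rectangles/axis | grid resolution; arrow count ≤ n_grid² |
| `min_cells` | 2 | cells | rectangles below this emit no arrow |
| `margin_frac` | 0.02 | fraction | bounding-box expansion before gridding |
| `arrow_scale` | 1.0 | — | multiplier on mean displacement; CTS scales linearly with it |
| `convention` | endpoint | — | angle anchor, see above |
| `min_genes` | 200 | genes | QC stage 2 threshold ("at least") |
| `top_count_percentile` | 0.01 | fraction | QC stage 3 top-quantile cut |
| `spread` | 1.0 | embedding units | synthetic cluster s.d. |
| `noise_sd` | 0.1 | embedding units | synthetic displacement noise s.d. |

The upstream grid parameters (`n_grid`, `min_cells`, `arrow_scale`) have no
canonical values — stream-plot implementations choose their own — so they are
exposed rather than hidden, and every run's manifest records the effective
configuration.

## Known limitations

* CTS values carry no significance calibration; they rank transitions but a
  CTS of 14 vs 4 is not a probability statement.
* Scores depend on the embedding geometry (a 2D/3D UMAP); distortions of the
  embedding distort the scores, and different perspectives of the same 3D
  embedding contribute differently.
* The endpoint convention under-scores arrows overshooting a centroid (see
  above).
* The distance weighting is relative per destination: a destination with
  only distant sources still assigns w = 1 to the nearest of them.
* Problem sizes in the test suite (hundreds of cells, 4 clusters, 20 seeds)
  were chosen as the smallest instances that exercise every code path with
  stable statistics.
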