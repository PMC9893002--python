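# skelprune

Skeleton extraction and pruning-point identification for leafless
open-center orchard trees (e.g. dwarf jujube) from 3D point clouds.

Dormant (winter) pruning removes the distal, unproductive part of each
scaffold branch. Doing this robotically requires turning a raw point
cloud of a leafless tree into a small set of 3D cut positions. This
package implements that full pipeline:

1. **Preprocess** — distance-threshold cropping plus Statistical Outlier
   Removal: a point is dropped when its mean distance *d<sub>i</sub>* to
   its *k* nearest neighbors exceeds *μ + λσ* over the cloud
   (defaults *k* = 40, *λ* = 0.2).
2. **Register** two opposing views: least-squares sphere fits locate
   three target-ball markers, triangle congruence matches them, an SVD
   Procrustes solve gives the initial motion **R**<sub>i</sub>, and
   curvature-gated ICP (surface variation
   *λ*₀/(*λ*₀+*λ*₁+*λ*₂) of the local covariance) refines it to
   **R**<sub>f</sub>.
3. **Skeletonize** with the space colonization algorithm: attraction
   points within a search radius *R* pull their nearest skeleton node;
   growth follows the normalized sum of unit vectors toward the
   attractions inside a sector of half-angle *θ*; children are spawned
   at spacing *D<sub>s</sub>* and attractions within *R<sub>d</sub>* of
   new nodes are consumed (defaults *R* = 8.2 cm, *θ* = 22.5°,
   *D<sub>s</sub>* = 4.0 cm, *R<sub>d</sub>* = 6.0 cm).
4. **Analyze** the skeleton as a directed graph *G*(*C*, *E*): the trunk
   is traced from the lowest vertex by repeatedly taking the successor
   edge with the smallest turn angle *ψ* until *ψ* exceeds a threshold;
   primary (scaffold) branches are the maximal-arc-length
   (*L<sub>i</sub>*) origin-to-leaf paths from each trunk junction and
   the trunk top, with candidates under 50 cm rejected as false
   branches; the **pruning point** of each primary branch sits at
   arc-length 2/3·*L<sub>i</sub>* from its origin (the distal third is
   cut).
5. **Model** the pruned tree: the cut subtrees are removed and branch
   radii follow the pipe model *r*<sub>parent</sub><sup>*n*</sup> =
   Σ *r*<sub>child,i</sub><sup>*n*</sup> with *n* = 2, emitting a
   multi-segment cylinder (frustum) mesh.

A seeded synthetic-tree generator (`skelprune.synthetic`) produces
ground-truth open-center trees, sampled clouds, and two-view scenes with
markers, so the whole pipeline is testable without field data. All
coordinates are centimetres, z up.

## Worked example

```bash
skelprune synth --seed 1 --out-dir scene      # synthetic tree + ground truth
skelprune run --in scene/cloud.ply --out-dir result
```

prints

```
wrote scene/cloud.ply (9181 points)
plan: 3 pruning points -> result/plan.csv
```

and `result/plan.csv` holds one cut position per identified primary
branch, ready for a robot arm:

```
id,x,y,z,branch_id
0,-60.682073,-9.588069,108.397034,0
1,22.548318,-54.790680,110.499654,1
...
```

This tree has three ground-truth scaffolds; the generator's true pruning
point for the first is (−60.6, −9.6, 108.0) cm, so the identified cut
sits within the skeleton's node spacing of the truth. `result/` also
contains the merged cloud, the raw and pruned skeletons (JSON), the
per-edge trunk/primary/lateral labels, and `pruned.obj`, the pipe-model
cylinder mesh of the tree after pruning.

The same steps are available stage by stage (`skelprune preprocess`,
`register`, `skeletonize`, `analyze`, `model`) and as library functions;
see `docs/methods.md` for the model details and parameter meanings.

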