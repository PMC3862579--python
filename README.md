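# petalmorph

Quantitative phenotyping of flower and petal morphology for ornamental
crops, built around the kind of scan-and-measure workflow used for
cultivated carnation (*Dianthus caryophyllus*): flowers and flattened petals
are photographed as bright objects on a dark background, segmented on the
red channel, and reduced to a small set of interpretable shape descriptors,
a landmark-based petal shape model, and quantitative-genetic summaries over
clonally replicated cultivars.

## What it computes

**Shape descriptors** per object (flower `F*` / petal `P*` mnemonics):
area *A* and perimeter *P*, major/minor chord lengths of the
moments-equivalent ellipse, convex-hull area *A_H* and perimeter *P_H*, and
the dimensionless factors

- aspect ratio `AR = major / minor` (1 for a circular outline),
- solidity `S = A / A_H` (1 for convex objects; drops with lobing and
  irregular petal arrangement),
- convexity `C = P_H / P` (1 for entire margins; drops toward ~0.5 for
  strongly serrated margins — the serration descriptor).

**Petal shape model**: each petal outline is resampled to 96 landmarks at
equal arc-length spacing, anchored with the claw base tip at the origin
(translation only — size is retained), flattened to a 192-vector and
decomposed by covariance PCA:

    x ≈ x̄ + Σ_k s_k σ_k q_k

with orthonormal components `q_k`, score SDs `σ_k`, per-component variance
fractions, ±k·SD shape reconstruction and per-cultivar score ellipses.

**Quantitative genetics** on clonal trait tables via one-way ANOVA across
genotypes:

    V_E = MS_W,   V_G = (MS_A − MS_W) / n̄,   H² = V_G / (V_G + V_E),
    CV_G = 100·√V_G / x̄,   r_G = cov_G / √(V_G1 · V_G2)

where `n̄` is the average number of samples per genotype and `cov_G` is the
among-genotype covariance component from mean cross-products.  Reaction
norms across autumn/winter collections come from per-genotype least-squares
lines on standardized data.

**Integration**: Euclidean distances on the column-z-scored
cultivar × parameter mean matrix feed a Saitou–Nei neighbor-joining
dendrogram (deterministic tie-breaks, exact on additive distances) that
orders a red-to-white heatmap of cultivars against parameters.

Because no reference image collection ships with the package, the
`synthetic_fixtures` module generates ground-truthed petals, flower
rosettes, raster scans and simulated clonal populations; every measurement
path is validated against exact polygon geometry and known simulation
parameters.

## Worked example

```python
import numpy as np
from petalmorph import PetalSpec, measure_mask, segment_image
from petalmorph.synthetic_fixtures import (
    PopulationSpec, make_petal_polygon, rasterize, simulate_clonal_population)
from petalmorph.quantgen import genetic_correlation, heritability_table

# a serrated petal scanned at 800 dpi, segmented and measured
poly, truth = make_petal_polygon(
    PetalSpec(serration_amplitude=0.15, serration_count=8))
img, _ = rasterize(poly, dpi=800)
mask, contour = segment_image(img, threshold=100)
for name, value in measure_mask(mask, object_kind="petal").to_dict().items():
    print(f"{name:>16s}  {value:.4f}")

# a simulated clonal population: 55 genotypes x 5 replicates
spec = PopulationSpec(corr=np.array([[1.0, -0.3], [-0.3, 1.0]]))
table, sim_truth = simulate_clonal_population(spec, seed=42)
print(heritability_table(table, ["area", "convexity"]).round(3))
print("r_G =", round(genetic_correlation(table, "area", "convexity").r_g, 3))
```

prints

```
              PA  7.5481
              PP  14.0611
             PEM  4.5128
             PEN  2.7863
             PHA  9.8103
             PHP  13.0058
             PAR  1.6197
              PS  0.7694
 petal_convexity  0.9249
    trait    H2   CV_G    V_G    V_E
     area 0.616 14.244 22.647 14.118
convexity 0.721 13.505  0.011  0.004
r_G = -0.559
```

The measured petal area (7.5481 cm²) and convexity (0.9249) agree with the
generator's exact polygon values (7.5484 cm², 0.9262); the petal's 8
marginal teeth pull convexity below 1 while solidity stays high.  The
heritability table is one realization of a design whose true H² values are
0.748 (area) and 0.830 (convexity); at 55 genotypes × 5 replicates single
estimates scatter around the truth, and the planted genetic correlation of
−0.3 is recovered with similar sampling spread (averages converge — see the
recovery numbers below).

The command-line interface mirrors the library
(`petalmorph segment|measure|landmarks|pca|heritability|norms|cluster|simulate`).

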