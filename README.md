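# cme — Cell Morphological Entropy

`cme` quantifies the 2-D morphology of nuclei, single cells and tumor
spheroids in time-lapse microscopy with a single, physically interpretable
descriptor: the normalized Shannon entropy of boundary-displacement
distributions. It is aimed at cell-migration and tumor-invasion studies
where shape dynamics encode behavior — a nucleus squeezing through a
confining channel, a cell extending protrusions, a spheroid switching from
proliferation to invasion — and where a stack of hand-picked shape features
is hard to interpret.

## The descriptor

For each frame, the object is segmented (Otsu threshold, hole filling,
largest connected component), its boundary traced as an ordered pixel
chain, and mapped to polar coordinates (rᵢ, θᵢ), i = 1…N, about the area
centroid. A lag *dN* subsamples the chain to suppress pixel-level burrs,
keeping points j = dN, 2·dN, …, floor(N/dN)·dN. Consecutive displacements
Δr_j = r_j − r_{j−1} and Δθ_j (wrapped to (−π, π]) are histogrammed into
n equal-width bins and each histogram p₁…pₙ is summarized by

    H = −Σᵢ pᵢ log₂ pᵢ,     H̃ = H / log₂ n  ∈ [0, 1].

H̃ of the angular component is **CMEa**, of the radial component **CMEr**;
their mean is the averaged CME. A perfect circle scores 0; the more
heterogeneous the boundary features (in placement for CMEa, in length for
CMEr), the closer to 1. By default each component is binned over a fixed
range in its natural units (Δr as a dimensionless radial slope per
boundary step, Δθ in units of the mean angular step 2π/N), which makes the
descriptor invariant to object scale, rotation and image resolution while
still responding to feature amplitude (see `docs/methods.md`).

On top of the per-frame descriptor the package provides the
moment-ellipse aspect ratio, the radial–angular cross-correlation
C_rθ(n), correlation with automatic Pearson/Spearman choice, K-means
clustering of the (CMEa, CMEr) scatter with dwell-time ratios, group
comparison through a normality/equal-variance decision tree (t-test /
ANOVA / Wilcoxon rank sum / Kruskal–Wallis, with an arccos transform for
[−1, 1]-bounded data), and proliferation→invasion transition detection by
a two-segment piecewise-linear changepoint.

A seeded synthetic generator (`cme.synthetic`) produces analytic
boundaries (circles, ellipses, rods, bleb-covered "ameboid" and
protrusive "mesenchymal" outlines, fingered spheroids), rasterized masks,
and three full time-lapse scenarios with ground truth, so the entire
pipeline is testable without any imagery.

## Worked example

Generate a synthetic spheroid that grows for ~23 h and then sprouts
invasion fingers, analyze it, and locate the transition:

```bash
cme synth --scenario spheroid --frames 40 --seed 11 --out demo
cme analyze --input demo/spheroid.tif --masks --dn 5 \
    --frame-interval 60 --pixel-size 3.0 --out demo/out
cme stats transition demo/out/frames.csv --out demo/out
```

`frames.csv` holds one row per frame (selected rows):

```
 frame  time_min  cmea  cmer  cme_avg  aspect_ratio
     0       0.0 0.000 0.313    0.156         1.007
    10     600.0 0.000 0.288    0.144         1.005
    20    1200.0 0.000 0.341    0.171         1.006
    30    1800.0 0.279 0.683    0.481         1.063
    39    2340.0 0.386 0.720    0.553         1.032
```

While the spheroid proliferates, CMEa stays at 0 (a near-circular outline
has perfectly regular angular steps) and CMEr reflects only boundary
noise. Once fingers sprout, both components climb: finger placement makes
the angular steps heterogeneous and finger length spreads the radial
displacements. The transition step prints

```
 breakpoint_min  slope_pre  slope_post  transition
         1260.0    0.00001    0.000491        True
```

a breakpoint at 1260 min against a planted transition at 1380 min — within
two frames of the ground truth recorded in `demo/truth.csv`, with the
post-transition slope ~50× the pre-transition slope. (The aspect ratio
stays ≈ 1 throughout: radially symmetric invasion is invisible to
elongation metrics, which is precisely the descriptor's selling point.)

The same CLI covers nuclei under confinement (`--scenario squeeze`) and
alternating cell pairs (`--scenario pair`); `cme stats cluster` and
`cme stats compare` reproduce the scatter-clustering and group-comparison
analyses.

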