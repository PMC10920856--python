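# Methods

## The morphological-entropy descriptor

The package measures the irregularity of a closed 2-D outline by the
Shannon entropy of its boundary-displacement distributions. The pipeline
per frame:

1. **Segmentation.** The grayscale frame is optionally smoothed by a
   single Gaussian pass (σ = `smoothing_radius`, default 1 px, 0
   disables), thresholded by Otsu's criterion (bright foreground by
   default; `invert` for brightfield), holes are filled, and the largest
   8-connected component is kept. A component below `min_area`
   (default 50 px²) is rejected.
2. **Boundary.** The boundary is traced as an ordered pixel chain by
   Moore-neighbor tracing with Jacob's stopping criterion, oriented
   counterclockwise in the mathematical frame. Subpixel contouring is
   deliberately not used: displacements live on the pixel lattice, and
   the lag subsampling below is the intended burr filter. The centroid is
   the mean of foreground pixel coordinates; coordinates are
   x = column, y = row (y down) internally, with angles reported in the
   mathematical convention by negating y.
3. **Polar map and lag.** Boundary points become (rᵢ, θᵢ) about the
   centroid (θ ∈ (−π, π]). The chain is subsampled at 1-based indices
   dN, 2·dN, …, floor(N/dN)·dN. Conventional lags: dN = 4 for single
   cells, 2 for nuclei and cell pairs, 5 for spheroids
   (`cme.polar.DEFAULT_LAG`); `suggest_lag` offers a non-canonical
   stability heuristic (smallest dN whose averaged CME changes < 2%
   against dN+1 on a calibration frame).
4. **Displacements.** Δr_j = r_j − r_{j−1} and Δθ_j = wrap(θ_j − θ_{j−1}),
   wrapped to (−π, π] so steps across the ±π cut do not inject ±2π
   outliers. The chain is open: m = N' − 1 displacements, no closing
   term.
5. **Entropy.** Each component is histogrammed into `n_bins` equal-width
   bins (default 16), normalized to a PMF, and summarized by
   H = −Σ pᵢ log₂ pᵢ (0·log 0 = 0), then divided by log₂ n_bins and
   clipped to [0, 1]. Normalization uses the *total* bin count, not the
   occupied count: an outline concentrating all displacements in one bin
   must score 0, and occupied-bin normalization would destroy
   monotonicity in feature amplitude. Because the magnitude of H̃ depends
   on the bin count, `n_bins` is frozen per study and recorded in every
   output row.

CMEa (angular) tracks the heterogeneity of feature *placement* around the
outline; CMEr (radial) tracks the heterogeneity of feature *lengths*.
Their unweighted mean `cme_avg` is the per-frame summary used for
staging and transition detection.

## Bin-range policy

The bin range is the one genuinely open design choice, and it decides
what the entropy measures.

* **`fixed` (default).** Each component is binned over a fixed range in
  its natural units, with out-of-range values clipped into the edge
  bins. The angular unit is the mean angular step δ = 2π/N′ of a closed
  boundary of N′ subsampled points; the range is (−4, 6) δ: steps
  concentrate at 1 δ for a circle, go negative on concave wiggles, and
  grow where the boundary sweeps close to the centroid. The radial unit
  is the mean arc length per step, r̄·δ, making Δr a dimensionless radial
  slope (dr/ds); the range is (−3, 3): |slope| = 1 is a 45° flank and 3
  bounds a near-radial invasion strand. Both ranges are shifted by a
  fraction of a bin so the concentration point of a regular outline
  (0 for the slope, 1 δ for the angular step) falls mid-bin — otherwise
  floating-point noise would straddle a bin edge and a perfect circle
  would not score exactly 0.

  This policy is scale-, rotation- and resolution-invariant yet responds
  to feature *amplitude*: growing a protrusion spreads the normalized
  displacements over more bins and the entropy rises. Min–max binning
  cannot do this — it sees only the shape of the distribution, saturates
  near 1 on rasterized boundaries (lattice noise alone fills all bins),
  and is blind to a finger that doubles in length, which would defeat
  confinement profiling and transition detection alike. That failure
  mode, measured during development, is why `fixed` is the default.
* **`per_frame`.** Min–max binning over each sample, retained because it
  makes scale invariance exact by construction and isolates
  distribution-shape effects.
* **`global`.** One min–max range across a whole time series, for
  cross-frame comparability in the min–max style.

Numerically constant samples (spread below 10⁻⁹ relative) collapse to a
single bin in the min–max modes, so analytic ideal shapes score exactly 0
there too.

## Complementary metrics

* **Aspect ratio.** Major/minor axis of the moment-equivalent ellipse
  (axes = 4·√eigenvalue of the foreground-coordinate covariance).
  AR ≥ 1; a 1-px line is degenerate and rejected.
* **Cross-correlation.** C_rθ(n) = ⟨(Δr_j − Δr̄)(Δθ_{j+n} − Δθ̄)⟩_j /
  (σ_r σ_θ), averaged over the overlapping j at each lag (no padding),
  with means and variances computed once over the full series.

## Downstream statistics

* **Correlation.** Pearson when both series pass Lilliefors normality at
  α = 0.05, Spearman otherwise; the choice is reported.
* **Group comparison.** Lilliefors on every group plus Bartlett across
  groups. Pass → t-test (2 groups) / one-way ANOVA. Fail → if every value
  lies in [−1, 1] (CME components do), the bijective arccos transform is
  applied and the criteria retested; if they still fail, Wilcoxon rank
  sum / Kruskal–Wallis on the raw data. Two-tailed, stars at
  0.05/0.01/0.001; every branch decision is recorded in the result. The
  domain guard on the arccos transform is this package's addition.
* **Clustering.** K-means on raw (CMEa, CMEr) pairs (no standardization),
  10 restarts, fixed seed, clusters relabeled by ascending mean CMEa so
  cluster I is always the least angularly heterogeneous state.
  Percentages double as dwell times at a fixed sampling interval; the
  three-cluster ratios I/III, II/III, I/(II+III) are reported to 2
  significant figures.
* **Transition detection.** Continuous two-segment piecewise-linear least
  squares over all candidate breakpoints (observed times with ≥ 3 points
  per side); the total-SSE minimizer wins. A transition is declared when
  the slope increase exceeds 3.5× its standard error from the piecewise
  fit. The factor compensates for breakpoint selection: on 300 simulated
  flat noisy profiles the maximized slope-change t-statistic reaches ≈ 3
  at the 99th percentile, so 3.5 holds spurious transitions below 1%
  while planted changepoints in the synthetic spheroid scenes score
  t > 30. (A threshold tied to the pre-segment slope error alone admitted
  ≈ 10% false transitions in the same simulation.) The method is one
  concrete realization of a slope/inflection criterion and is tagged
  non-canonical in reports.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their spec and seed. Shapes are
star-convex radial profiles r(φ) = base·(1 + Σ bumps + noise) sampled at
equal angles: raised-cosine bumps model blebs (many, small), protrusions
(few, large) and invasion fingers (narrow, growing); ellipse and
flat-sided superellipse ("rod") profiles model elongation under
confinement; noise is smooth correlated radial jitter. Rasterization
marks pixels whose centers fall inside the polygon.

Scenario defaults are chosen to mirror the experimental settings the
descriptor is aimed at:

* **squeeze** — a nucleus of 14 µm equivalent diameter traversing four
  18-µm channels separated by 23-µm chambers at constant speed, imaged at
  0.25 µm/px every 5 min. The traversed channels pinch the nucleus to rod
  widths narrowing 8.4 → 6.6 µm (the wider array tapers 11.2 → 1.7 µm
  overall; a 14-µm nucleus is unaffected by an 11.2-µm channel, so only
  the constricting stretch is emulated). Target elongation is
  diameter/width, capped at 4.5, approached with first-order relaxation;
  half-length entry/exit chambers bracket the run so each passage is an
  interior CME peak.
* **pair** — two protrusive cells whose protrusion amplitudes oscillate
  in exact antiphase (base 0.35 ± 0.25 of the radius, 60-min period,
  2-min frames), the morphological signature of mechanically coupled
  neighbors.
* **spheroid** — a disk of 150 µm initial radius growing 0.4% per frame
  at 3 µm/px and 60-min frames; after `transition_frac` of the window
  (0.6 by default; 0.85 emulates an invasion-inhibited culture) eight
  fingers grow linearly with per-finger rate multipliers, capped at 0.38
  of the radius. Ground truth (structure labels, planted transition time,
  finger lengths) is always emitted alongside.

The generator reproduces geometry and ordinal contrasts, not microscopy:
no point-spread function, shot noise, debris, touching objects, focus
drift or segmentation ambiguity. Passing tests therefore demonstrate that
the *method* recovers planted morphodynamics through the full
segmentation–entropy–statistics chain, not that segmentation is robust on
difficult real images. Absolute CME values also depend on the frozen bin
count and range policy, so only orderings, trends and ratios — not
absolute magnitudes — should be compared across implementations.

## Numerical choices and edge cases

* 0·log 0 = 0; probabilities validated to Σp = 1 within 10⁻¹².
* Degenerate histogram sample (all values equal) → all mass in one bin →
  H = 0, by convention.
* A sample shorter than the bin count warns (spheroid frames at dN = 5
  can be short) but is not an error.
* Angular wrap maps to (−π, π], ties at ±π resolved to +π; θ from the
  polar map uses the same convention.
* Boundary tracing rejects objects with no 2×2 foreground block
  (single pixels, 1-px lines) and chains shorter than 8 points.
* Identical groups in the comparison tree return p = 1 ("n.s.");
  constant groups are routed to the nonparametric branch.
* K-means percentages are exact multiples of 100/n; ratios are rounded
  to 2 significant figures only at the reporting boundary.

## Problem sizes

Default test and acceptance runs use 40-frame scenes at 128–192 px,
boundaries of 300–900 points, 100 seeded repetitions for the
transition-recovery and ordering rates, and 200 null simulations per
statistical branch — sizes at which every planted effect is comfortably
resolved while a full run stays in the minutes range on a single core.

## Known limitations

* Single object per field; no tracking, splitting or 3-D geometry.
* The entropy is a plug-in estimate; with m ≈ 100–200 displacements per
  frame its per-frame sampling noise is a few percent, so individual
  CME components fluctuate up to ~5% under re-rasterization (e.g.
  rotation on the pixel lattice) while the averaged CME is roughly twice
  as stable. Comparisons should lean on series, stages and clusters, not
  single frames.
* Non-star-shaped outlines are handled (the traced order is used, not
  angular sorting), but strongly self-occluding shapes make the polar
  parameterization multivalued in angle and the angular component harder
  to interpret.
* Stage boundaries for staged averaging are user input, not detected.
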