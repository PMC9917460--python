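# Methods

## Measurement model

The package treats a mosaic epithelium as a calibrated 2D field
(`pixel_size_um`, isotropic) with four channels: a nuclear stain (DAPI),
a clone marker (GFP), an interface-signalling reporter (TRE), and an
apoptosis marker (cleaved-Dcp1 puncta). Z-stacks are reduced beforehand
by maximum projection over a chosen slice range (`max_project`).

### Segmentation chains

All three masks come from filter-and-threshold chains whose parameters
are explicit in `SegmentationParams`:

| step | chain | defaults |
|---|---|---|
| disc mask | Gaussian blur → dark threshold → fill holes → largest 8-connected component | σ = 4 px, triangle |
| clone labels | max/min closing → dark threshold → 3×3 median ("despeckle") → fill holes → ∩ disc → components → area filter | radius 2 px, Otsu (isodata available), ≥ 10 µm² |
| particle mask | max/min closing → dark threshold on within-disc histogram → ∩ disc | radius 1 px, intermodes |

Filter sizes are in pixels by default (the convention of the interactive
tool this chain descends from); `sizes_in_um=True` converts them through
the calibration, which is what scale-comparison studies should use.

Thresholds operate on 256-level histograms. Intensities that fit the
8-bit range [0, 255] are binned on that absolute scale; wider ranges are
binned min-to-max. All methods use "dark background" polarity:
foreground is strictly *above* the returned level, ties go to
background. Definitions:

- **otsu** — argmax of between-class variance over all splits;
- **isodata** — Ridler–Calvard fixed point `t = round((µ_below+µ_above)/2)`;
  when several fixed points coexist the lowest is returned (this matches
  scikit-image's implementation to ≤ 1 level on every histogram we
  generate, asserted in the suite);
- **triangle** — maximal distance below the chord from the histogram peak
  to the far end of its longer tail. Triangle thresholds at the *foot*
  of the dominant peak: on real, broadly distributed nuclear signal this
  is a sensible permissive tissue mask, but on a clean two-level
  synthetic image it lands just above background and dilates the mask by
  the blur skirt. The suite therefore checks tight disc recovery with
  the `minimum` method (also part of the chain's repertoire) and checks
  `triangle` for what it is: a permissive cover of the true tissue.
- **intermodes / minimum** — iterate 3-tap mean smoothing until exactly
  two interior strict maxima remain (the classical bimodality test;
  endpoint bins never count as modes), then return `⌊(m1+m2)/2⌋`
  (intermodes) or the lowest minimal level strictly between the modes
  (minimum). An iteration cap of 10 000 turns pathological histograms
  into a convergence error carrying the smoothed histogram for
  diagnosis.

Particle detection additionally requires *real* bimodality: if the
smoothed within-disc histogram is unimodal, or its two modes sit fewer
than 8 of 256 levels apart, the field is declared particle-free (empty
mask, warning). Without this, a puncta-free noise field would be
thresholded inside its own noise. A
`particle_threshold_multiplier` (default 1.0) scales the automatic
threshold and is recorded in provenance — the programmatic analogue of
the operator's "only high-intensity particles" adjustment.

### Zone system

Cell rows are approximated as bands of fixed physical width,
`band_width_um = 4.0` (one cell row: mean nuclear diameter 3.75 µm plus
cytoplasm). The `ZoneMap` partitions every pixel into exactly one of:
outside-disc, wild-type background, wild-type row 2, wild-type
interface, clone interface, clone interior, or small-clone. Distances
are exact Euclidean distances between pixel centres in µm; band
membership is half-open `0 < d ≤ w` (a clone's boundary pixels belong to
the clone). Clone interiors exist only for clones ≥
`interior_min_area_um2 = 180`; smaller clones are kept whole as a
separate class, mirroring how small clones are measured whole.

Implementation: per-label exact Euclidean distance transforms with
squared distances rounded back to integers (EDT values are square roots
of integer px², so the round-trip is exact), which makes band boundaries
bit-reproducible against brute-force integer-distance oracles. Outward
bands are owned by the nearest clone, ties to the smaller label — unlike
the interactive tool's composite "enlarge", which silently merges
neighbouring bands; pooled (ownership-ignored) statistics remain
available and reproduce the composite behaviour. Wild-type row 2 yields
to any clone's order-1 band (both derive from a single nearest-clone
distance field, so the priority is automatic). Clones touching the disc
border are flagged and excluded from per-clone statistics by default.
`restrict_to_nuclei` intersects all zones with a nuclear mask for
nuclear reporters.

### Measurements

`zone_intensity` reports mean/median/sd per zone (pooled and per owning
clone). `percent_apoptotic` is an **area** fraction: 100 × (particle ∩
zone)/zone, so zone areas weighted by their percentages recompose the
total particle area exactly — an identity the suite asserts at pixel
level. Clone areas bin half-open: small [10, 140), medium [140, 650),
large [650, ∞) µm². Genotype splitting of particles is pixel-wise AND /
subtraction. Apical/basal clone counting uses the centroid-in-pouch rule
and does not track identity between sections. Buckling-vs-planar
comparisons take analyst-supplied elliptical regions (centre, semi-axes,
angle in µm) and refuse regions that leave their clone or planar regions
touching the clone's boundary band. Reference-matched clone selection
classifies a clone as `matched` when its reference-channel mean is
within ±20 AU (configurable) of its band's mean.

## Contact-topology model

Clones are sets of axial coordinates on a 6-neighbour hexagonal lattice.
`grow_clone` offers a deterministic ring spiral (compact) and seeded
random boundary accretion (Eden growth, ragged). `contact_profile`
counts, for every clone cell, its outside neighbours, and for every
outside cell adjacent to the clone, its inside neighbours; the two
totals are equal edge counts by construction. `predicted_activation`
maps contacts to signal linearly (`base + g·contacts`) or through an
optional saturating form `base + s·(1 − e^{−k·contacts})`, since the
biology constrains only the direction of scaling, not its functional
form. No apoptotic feedback (cell removal) is modelled.

For compact clones the clone-side mean falls 6 → 4 → 3.5 → … → ≈ 2.1
with ring number while the wild-type side rises slowly toward 2 — the
asymmetry that concentrates signalling on small clones and spares large
fate compartments.

## Synthetic tissue generator

The generator exists because the measurement procedure has no public
raw images; it renders fields whose truth is known by construction.

- **Geometry.** Elliptical disc (default semi-axes 220 × 170 µm in a
  512×512 px field at 1 µm/px); cells are Voronoi regions of a jittered
  hexagonal point set with mean cell diameter 3.75 µm (the measured
  nuclear scale); zero jitter gives exact hexagons.
- **Clones.** Seeds drawn uniformly among cells; each clone accretes one
  neighbouring cell per growth step. Accretion weight is the squared
  count of already-clonal neighbours (`clone_compactness = 2`),
  emulating the interface smoothening that contractile clone borders
  impose in tissue; 0 recovers fully random ragged growth. Growth
  ranges (default 5–40 steps; size-scaling studies use 0–120) spread
  areas across the three bins. Clones that grow into contact merge.
- **Channels.** DAPI: Gaussian nuclei (diameter 3.75 µm) at cell
  centres, amplitude 100. GFP: uniform 100 over clone pixels. Reporter:
  either `base·E` within λ of the true interface on both sides (defaults
  E = 2, λ = 4 µm, base 20) or per-cell `base + g·heterotypic contacts`
  (g = 10). cDcp1: 2 µm disk spots over a background of 5, amplitude
  150, with expected per-zone area fractions set directly (defaults:
  clone interface 10 %, clone interior 2 %, small clones 10 %, wild-type
  interface 4 %, row 2 1 %, background 0.5 %); spots are placed wholly
  inside their zone when it is thick enough, otherwise attributed by
  centre. Gaussian noise (sd 10 → SNR 10 for the 100-amplitude signals)
  is added last and clipped at zero; one seed fixes everything.
- **Ground truth** records the cell and genotype maps, per-cell
  heterotypic contact counts, the zone map built from the *true*
  geometry, and the spot table.

What the generator does **not** emulate: pseudostratified 3D nuclei,
folds and hinge anatomy, illumination gradients, photobleaching, PSF
blur, and mechanical buckling. Passing recovery tests therefore show the
*measurement chain* is faithful on idealized tissue of the right scales
and noise level — not that segmentation is robust to every real-world
artefact.

## Numerical choices and known behaviour

- Band/interior boundary comparisons use integer squared pixel distances
  (exact); thresholds and bin edges are half-open as stated above; ties
  at a threshold level go to background, equidistant band pixels to the
  smaller clone label.
- Segmentation is deterministic: identical input and parameters give
  bit-identical masks; the pipeline embeds a config hash and seed in
  every CSV header, and identical configs rerun byte-identically.
- The closing steps fill concave notches of ragged clones, so segmented
  clone outlines are slightly smoother than truth; at 1 µm/px this costs
  small clones noticeable IoU (boundary error is a fixed ~1 px), at
  0.5 µm/px per-clone IoU is ≥ 0.9 for clones ≥ 20 µm². Recovered
  interior apoptosis runs ~1 percentage point above its generating rate
  because the segmented interior boundary sits a pixel or two inside the
  true one, adjacent to the high-rate interface band.
- Statistical tests are thin wrappers over scipy/statsmodels: paired t,
  one-way ANOVA (F = 0 returned for identical constant groups), two-way
  fixed-effects ANOVA with type-II sums of squares (types agree on the
  balanced designs the generator produces; unbalanced tables log a
  notice), Spearman, and least-squares `y = a + b·log₁₀(x)`. Means are
  reported with t-based 95 % CIs. No multiple-testing correction is
  applied anywhere, and the output says so.

## Problem sizes

The test suite and acceptance script run the geometry oracles on 100
random 64×64 fields, the partition/conservation audit on 50–100
160×160 discs, recovery studies on 512×512 fields, lattice symmetry on
1000 random clones up to n = 500, and null calibration with 1000
simulations per test — sizes at which every check completes in seconds
to a couple of minutes on a single CPU while keeping binomial counting
error well inside the asserted tolerances.
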