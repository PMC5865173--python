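# Methods

This note documents the models behind `eaekit`: what the synthetic
generators emulate, how each analysis stage works, the parameters that
matter, and the choices made where the design was genuinely open.

## Synthetic cytometry model

Each of the 15 populations (Jurkat spike-in, B, NK, CD8/CD4 T cells,
neutrophils, resting/activated microglia, cDC1/2, monocytes P1, moDCs
P2/P3, macrophages P4/P5) is a product of independent log10-normal marker
intensities: log10 I ~ N(μ_level, σ) with σ = 0.18 and shared level means
neg = 1.0, dim = 1.9, int = 2.7, pos = 3.3, high = 4.1 (log10 arbitrary
units).  Adjacent levels that form gate boundaries are therefore 3.3–4.4 σ
apart: populations are separable, but their tails overlap, so the gating
tree is exercised nontrivially (the residual ~0.2% misclassification sits
at the CD45 dim/int and neg/dim boundaries, i.e. between adjacent
activation states, as in real data).  Fluorescent-protein status
(EGFP-only / EYFP-only / double / none) is drawn per event from
per-population probabilities; positive FP channels are log-normal at the
`pos` level.

Compositions (fractions of CD45⁺ events per condition, tissue and day)
are shipped as plain-text YAML.  The headline structure they encode: a
70:30 neutrophil:monocyte split among EGFP⁺ cells, moDCs absent at day 8,
appearing at day 13 and reaching 30% of the infiltrate by day 17 with a
70:30 P3:P2 maturation split, EYFP⁺ (EGFP⁻) events >90% microglial at
day 17, and small macrophage/cDC/B/NK fractions throughout.  Minor
population fractions, control conditions and blood are qualitative
approximations (flagged `approx: true`); two reported constraints — EYFP
expression in up to half of the (brain) macrophages, versus the >90%
microglial purity and <6% overall share of the EYFP⁺ channel in spinal
cord — cannot hold simultaneously with a single per-population EYFP rate,
so the packaged macrophage EYFP rate (0.20) favors the spinal-cord purity
constraint.

The chimera mode adds congenic CD45.1/CD45.2 channels.  Origin is
Bernoulli per population: microglia host (p_donor = 0), CD44⁺
monocyte-derived populations donor (p_donor = 1), CD44⁻ macrophages
p_donor = 0.91.  Dead cells are flagged (viability dye) independently
with a default rate of 0.05; doublets and spectral spillover are
deliberately not modeled.

## Automatic thresholds

Manual gating is replaced by a per-channel mode analysis on the
asinh-transformed intensities (cofactor 150, a typical fluorescence
scale).  Mode weights are extremely unbalanced — a 0.5% B-cell mode may
face a 90% negative mode — so a fixed-size mixture fit is unreliable;
instead, modes are located on a smoothed 512-bin histogram (Gaussian
kernel, 3 bins).  Local maxima are accepted as modes in descending height
order; a candidate counts as a separate mode only when the density valley
towards each already-accepted neighbour drops below 0.75 of the
candidate's own height, which absorbs Poisson ripples inside a cluster
and low bumps bridging two modes.  Modes of negligible mass (< 20 events)
are folded into their neighbours, surplus modes are merged
smallest-mass-first, and cutpoints are placed at the density valleys
(middle of a flat valley) between the retained modes.  Channels without a
positive mode fall back to the 99.5th percentile of the (negative)
values; for the tri-level channels (CD45 with neg/dim/int/high, MHCII
with neg/pos/hi) unresolved modes are an error — threshold derivation
therefore needs a control sample containing all levels, which in practice
is any spiked sample with microglia and leukocytes present.  The
procedure is deterministic given the subsampling seed.

## Gating tree

Strict sequential exclusion in the listed order; an event matching no
terminal predicate becomes `other`, never silently dropped, so terminal
labels partition the live events.  The cDC2 gate is carved from the
CD11b⁺ branch *before* the Ly6C/CD64 gate by default; the opposite order
is one flag away (`cdc2_before_r9=False`) since the source material does
not fix it.  F4/80 is carried in the data model but unused by the tree.
Spike-in calibration is the ratio estimator N̂ = n·N_spiked/n_Jurkat,
which is invariant in expectation to uniform acquisition subsampling.

## Slices and the standardized disk

The synthetic cord boundary is an ellipse (a = 1.3 b, b = 500 µm) with a
Gaussian dorsal median indentation (depth 0.22, width 0.18 rad); +y is
dorsal.  Plaque counts are Poisson per sector with means (dorsal 1,
ventro-lateral 4) at the inflammatory peak; centers are uniform over the
white-matter annulus (normalized radii 0.55–0.95) of their sector with a
minimum pairwise separation of 0.25 normalized units so that plaques are
distinct, countable lesions — without it the fixed clustering scale
(eps = 0.03 vs plaque σ = 0.04) merges ~10% of plaque pairs and biases
recovered counts low.  Plaque cells are isotropic Gaussians (σ = 0.04);
diffuse EGFP⁺/double cells are confined to white matter, EYFP⁺ and
unlabeled cells are disk-wide.  Immunostain flags (Ly6G, MHCII-high,
CX3CR1) are Bernoulli per channel.  Diffuse densities are kept below ~150
cells per unit normalized area so that the random-geometric-graph
percolation regime is avoided and spurious ≥10-cell chains are rare
(<0.1 per slice).

Standardization uses the polygon area centroid as center and exact
polygon–ray intersection for R(θ); if the centroid leaves >1% of cells
beyond their first boundary crossing (non-star-shaped section) it falls
back to the pole of inaccessibility and logs the event.  Equal-area bands
use edges r_k = √(k/K), K = 20 by default, each of area π/K.  Density
maps are per-slice 2-D histograms on a 64×64 grid over [−1, 1]²,
optionally Gaussian-smoothed, masked to the disk and rescaled so each
slice's integral equals its cell count exactly (smoothing would otherwise
leak a few percent of boundary mass off the disk), then averaged.
Overlap maps binarize two maps at a quantile of their positive values
(default median) and intersect them.  Plaque detection links cells within
eps and keeps connected components of ≥ min_cells — deliberately the
plain distance-linkage definition rather than DBSCAN's core-point
variant, so the detected set is exactly the transitive closure of the eps
relation and permutation invariant.  Sector boundaries (dorsal
[45°, 135°]) are configuration, not anatomy.

## Masks and morphometry

Generated masks (96×96 px) realize the three morphology classes: ameboid
= ellipse of mild aspect (1.0–1.5); elongated = capsule of aspect ~4–8
(the "bipolar" cells seen along vessels and axons); ramified = a central
body with 3–6 thin processes at jittered equal spacing.  Phagocytic cells
carry 1–3 dark inclusions (intensity 0.15 vs ~1.0 foreground) placed
where the distance transform guarantees full enclosure.  Solidity uses
the convex hull of pixel corners — for a rasterized disk this sits a few
percent below 1 by construction, and for one-pixel-wide processes it
avoids the zero-area degeneracy of center-point hulls.  Eccentricity
comes from the covariance eigenvalues of the foreground pixel
coordinates.  The classification cascade (ramified if solidity < 0.75,
else elongated if eccentricity ≥ 0.90, else ameboid) was calibrated on
the generator by a grid sweep (`scripts/calibrate_morphology.py`); on
generator output its accuracy is effectively 100%, so recovered class
fractions track the generating mixture to within binomial noise.  Real
microscopy masks are noisier than the generator's clean shapes; passing
recovery here validates the measurement/classification machinery, not
robustness to segmentation artifacts.  All morphometry is explicitly
2-D.

## Time courses and statistics

The longitudinal generator draws per-mouse log-normal random effects
(σ = 0.25) and log-normal measurement noise (σ = 0.15) around per-day
multipliers of a pre-induction baseline: EGFP⁺ density rises from day
10–11 and peaks at day 13 (×6), double-labeled cells peak at day 17 (×8),
EYFP⁺ drifts up mildly, axon counts (Poisson, baseline 120 per field)
drop to ~0.7× at day 13 and stabilize, and clinical scores (0–5 scale)
rise reciprocally — making scores and axon counts negatively correlated
by construction.  Densities are per 424×424 µm field of view.

Registration maximizes the zero-mean cross-correlation over integer
shifts within ±max_shift (default 10 px, exhaustive via FFT), with the
first frame as reference (configurable); noise-free constructed stacks
are recovered exactly.  Relative densities divide two-day bin means
(default bins 8–9, 10–11, 13–14, 15–16, 17–18, 21–22, 23–24) by the
day-0 value per mouse; mice with a zero baseline are excluded with a
warning.  The test battery mirrors the study: Mann-Whitney with midrank
ties, exact by enumeration when n+m ≤ 12 and tie-free, otherwise the
tie-corrected normal approximation; Kruskal-Wallis with chi-square
reference; classical uncorrected one-way ANOVA; Spearman correlation with
a seeded permutation p (≤10⁴ permutations).  Tests are two-sided at
α = 0.05 with no multiple-testing correction by default, matching the
study's uncorrected reporting; a Holm adjustment (`holm_correction`) is
available but off by default.  The meningeal/parenchymal depth boundary
(30 µm below the dura) is a documented convention, not a measured value.

## Reproduction scale and determinism

All randomness flows from explicit seeds through `numpy` Generators; a
fixed seed reproduces every sample bit for bit, and the pipeline report
is byte-identical across runs of the same configuration.  The headline
recovery runs use 50,000 events per cytometry sample (with a 2,500-cell
Jurkat spike and 5% dead events), 2,000 masks per channel, 200 slices for
plaque rates and ~20–200 slices for immunostain fractions — sizes at
which binomial sampling error is well below the recovery tolerances while
a full run completes in well under a minute.

## Known limitations

No spectral spillover/compensation, doublet modeling or acquisition
drift in the cytometry generator; no white/grey-matter anatomy beyond the
configurable annulus; no 3-D morphometry or motility analysis; no
mixed-effects longitudinal modeling.  The synthetic data are cleaner than
real measurements in exactly the ways listed above, so recovery results
bound algorithmic correctness, not end-to-end performance on raw
microscopy or cytometry files.
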