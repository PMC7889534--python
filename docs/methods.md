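# Methods notes

This note records the models, parameter choices, and numerical decisions
behind `fishdist`, and what the simulator-based validation does and does
not establish about real microscopy data.

## Imaging model and coordinate conventions

Stacks are anisotropic 3D arrays indexed `[z, y, x]`; the default voxel
pitch is 108 × 108 × 293 nm (60×/NA 1.4 widefield with a CMOS camera;
stacks over-range in z by design, so axial truncation of nuclei is not
expected). Physical positions are (x, y, z) vectors in μm, with the voxel
centre at `(index + 0.5) × pitch`; voxel indices are 0-based, bounding
boxes half-open. All distances are reported in μm.

## The synthetic-data generator

The simulator (`fishdist.synth`) emulates one field of view of the assay:

* **Nuclei**: ellipsoids with semi-axes 7 × 5 × 2.5 μm (volume ≈ 370 μm³,
  a flattened fibroblast nucleus) jittered by 8% per axis, placed on
  non-overlapping 45 μm slots (the seeding-density constraint the
  segmentation's one-maximum-per-box rule assumes). DAPI is rendered as
  the ellipsoid indicator smoothed with a 0.5 μm Gaussian plus 10%
  multiplicative speckle, so slice-wise thresholding is not trivially
  easy.
* **Spot pairs**: two FITC anchors per nucleus (the two alleles), at
  least 3 μm apart, uniform in the inner 90% of the ellipsoid. Each TRITC
  partner sits at a distance drawn from a two-regime mixture: with
  probability `p_int` (default 0.9) a half-normal law with 120 nm scale —
  essentially all interacting distances below 500 nm, i.e. within one
  PSF — otherwise uniform on 0.5–3 μm. Defaults follow the biology of a
  predominantly interacting young-cell population; the mixture is the
  generative counterpart of the main-lobe/long-tail shape the Rosin split
  assumes.
* **Optics**: spots are anisotropic 3D Gaussians (σ_xy = 150 nm,
  σ_z = 400 nm, plausible for this objective; no depth-dependent blur or
  aberration fields), rendered by voxel-integrated erf profiles so the
  photon integral is conserved to <1% for spots ≥4σ from borders. The
  TRITC channel is displaced by a constant chromatic offset (default
  (120, −80, 150) nm, a typical residual after bead-based coarse
  alignment). Per-channel clutter spots (bright probe debris) are placed
  outside every nucleus.
* **Noise**: Poisson shot noise on the photon image, then additive
  Gaussian read noise (s.d. 3 photons); both can be disabled. Background
  is 50 photons/voxel in the FISH channels. Real-data spot brightness and
  background statistics vary by probe and batch and are not fitted here,
  so tests parameterise brightness as a multiple of the per-voxel noise
  s.d. (`photons_for_peak` / `noise_sd`).
* **Determinism**: all draws pass through child streams of one seeded
  generator (truth / DAPI texture / measurement noise are independent),
  so ground truth is bit-stable and invariant to which channels are
  rendered.

What the simulator does **not** emulate: nonuniform intrachromatin DAPI
texture, autofluorescence gradients, touching or mitotic nuclei,
depth-dependent PSF broadening, camera fixed-pattern noise, or
hybridisation failure modes (missing/split probes). Passing tests
therefore demonstrate correctness of the algorithms under the stated
imaging model, not robustness to every real-world artefact.

## Segmentation

Seeding works on the σ = 3.75 μm-filtered MIP; connected equal-valued
plateaus of the filtered image are merged into one maximum (flat-topped
nuclei otherwise produce spurious double maxima), and a prominence floor
of 5% of the dynamic range suppresses background maxima. The multi-scale
2D segmentation uses Gaussian scales {0.5, 1.0, 2.0} μm with a per-scale
Otsu threshold and a strict-majority vote (≥2 of 3); flat slices
contribute no foreground vote. The 3D refinement removes voxels below
0.6 × the global Otsu threshold of the box, which deletes the blurred
out-of-focus caps. The connected component under the seed is kept — no
declumping/watershed, since the box rule already rejects crowded seeds.
Volume bounds default to 200–4000 μm³ (generous for fibroblast nuclei);
the border test applies to lateral borders only. On noise-free simulated
nuclei the mask-vs-truth IoU is ≈0.87; the residual disagreement is the
smoothed boundary shell, which biases volumes slightly but hardly moves
spot-distance measurements (masks only gate detection).

## Spot detection

Detection is per nucleus because the fluorescent background varies
strongly between nuclei. Candidates are local maxima of the
background-subtracted matched filter (background = 5×PSF smoothing)
above 3 robust s.d. of the in-mask response. For each candidate a
fixed-σ voxel-integrated Gaussian plus constant is fitted linearly; the
one-sided t-test of A > 0 uses the within-window residual s.d.
(df = n − 3). The test is exactly calibrated at non-selected positions
(fraction of p ≤ α equals α); at max-selected candidates it is
deliberately permissive — essentially every candidate above the floor
passes at α = 0.05–0.1. This is a feature of the protocol, not a defect:
false negatives are expensive (a missed allele voids the nucleus) while
false positives are cheap, because dim spurious spots carry large pairing
scores `d/√(I_i I_j)` and are eliminated by the top-2 selection and the
score-ratio acceptance rule. The intensity fed to pairing is the fitted
amplitude A above local background, not the integrated intensity — the
two differ by a constant factor at fixed σ, and the acceptance ratio test
is invariant to that choice. Subvoxel refinement re-fits (x₀, A, c) with
analytic gradients; at 10× noise amplitude the localisation RMSE is
≈0.07 voxel per axis.

## Pairing and chromatic correction

The top-2 assignment is solved by score-ordered search over disjoint
edge couples with a lower-bound cutoff; for the graphs this assay
produces (a handful of real spots plus dim clutter) this is effectively
linear, and it is verified exactly against exhaustive enumeration. Ties
are broken lexicographically on (i, j) for reproducibility. The "50%
smaller" rule is operationalised as `max(S_A, S_B) ≤ 0.5 × S_next` with
S_next the smallest non-selected candidate score; boundary equality is
accepted, and a nucleus with no third candidate is vacuously accepted.
The alternative reading (per-rank comparison) differs only when the two
selected scores straddle the next score, a configuration the acceptance
rule rejects under either reading in practice.

Chromatic correction subtracts the cohort-mean displacement (default
cohort: one slide, parsed from the file name; configurable). Only
accepted pairings enter the mean — rejected nuclei are precisely those
whose displacements are unreliable. The correction is exact by
construction (corrected mean = 0 to machine precision) and recovers an
injected offset to within sampling error (≈30 nm at ~100 pairs); its
accuracy therefore scales as the s.d. of true displacements divided by
√n, which is why experiments pool hundreds of nuclei per slide. The
underlying assumption — displacements are short and isotropic for most
pairs — holds whenever most pairs interact, and degrades for conditions
where it does not.

## Distance statistics

The KS statistic is the exact ECDF sup-gap; the p-value uses the
classical Kolmogorov asymptotic law `Q(√(mn/(m+n))·D)`. For the sample
sizes of this assay (hundreds of cells) the asymptotic law is accurate;
below n ≈ 10 it is conservative, which only makes the bootstrap criterion
harder to reach.

The Rosin threshold is computed on a fixed-width histogram (0.1 μm bins,
matching the visual binning of such distance data): the bin centre
maximising perpendicular distance to the chord from the peak bin to the
last nonempty bin. Distances exactly at a threshold count as interacting.
Degenerate histograms (single occupied bin, or peak at the tail end)
raise instead of returning an arbitrary split.

The bootstrap resamples **cells** (each cell contributing both of its
allele distances), not pooled distances, at 500 resamples per grid size
with KS significance at α = 0.001 and a 98% criterion — the standard
operating point of the assay. Per-nucleus distances are otherwise treated
as exchangeable; condition summaries record both the distance count and
the cell count so either unit can be reported.

## ITS scanning

Maximal runs of TTAGGG/CCCTAA are found by greedy regex matching
(verified exactly against a naive sliding-window scan); coordinates are
1-based inclusive with optional genomic offset, converted to 0-based
half-open in BED output. `N` never matches; degenerate motifs are out of
scope. Flank lengths are a free parameter of the region the user
supplies; when a total flank budget is split around a gene, the split is
symmetric by default since no convention dictates otherwise.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run on scaled-down study
conditions chosen to keep a full validation in minutes on one core:
single-nucleus fields of 170 × 170 × 42 voxels (≈18 × 18 × 12 μm) for
detection/pairing cohorts (50 nuclei at 10× noise, 100 at 5×), two
4-nucleus 400 × 400 × 50 fields for the end-to-end pipeline (with 20 μm
seed boxes matched to the denser packing), 200 random assignment
instances with ≤5 spots per channel, 2000-sample mixtures for the Rosin
split, bootstrap grids up to 300 cells at the full 500 resamples, and
1000 random sequences for the ITS oracle. Detection/pairing cohorts use
analytic ground-truth nucleus masks so those measurements isolate the
stages under test; segmentation is validated separately and end-to-end.

## Known limitations

* No declumping of touching nuclei; crowded fields lose both neighbours.
* Fixed-σ spot model: strongly defocused or merged spots (two loci within
  one PSF in the *same* channel) are fitted as one emitter.
* One mean shift vector per cohort: field-dependent chromatic aberration
  is not modelled (hardware bead calibration is assumed upstream).
* The KS p-value is asymptotic; the Rosin split depends (weakly) on the
  histogram bin width.
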