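# fishdist

Single-cell quantification of telomere–gene proximity from dual-colour 3D
FISH image stacks.

Genes within ~10 Mb of a telomere can be silenced by direct physical
contact with the telomere loop ("telomere position effect over long
distance"); as telomeres shorten with replicative age, the contact is
lost and expression changes. The readout is geometric: label a
chromosome-specific subtelomeric sequence (TRITC) and a target gene locus
(FITC) in fixed nuclei (DAPI), and measure the 3D distance between the
paired spots, cell by cell, across hundreds of nuclei per condition.
`fishdist` is the analysis side of that assay, intended for microscopists
and image analysts running such screens: it turns raw multi-channel
stacks into per-nucleus corrected pair distances and condition-level
statistics, and ships a seeded simulator that provides ground truth for
every stage.

## Methods at a glance

* **Nucleus segmentation (DAPI).** Channels are min/max-normalised to
  [0, 1]. The DAPI maximum-intensity projection is smoothed with a
  σ = 3.75 μm Gaussian; local maxima seed 45 × 45 μm² boxes, and boxes
  capturing more than one maximum are discarded. Each box is segmented
  slice-by-slice (three Gaussian scales × Otsu, majority vote), the 3D
  mask is refined by removing voxels below 0.6 × the global (Otsu)
  threshold, and nuclei with extreme volumes or touching the lateral
  border are rejected.
* **Spot detection (FITC/TRITC), per nucleus.** Matched filtering at the
  PSF scale, candidate local maxima, then a statistical amplitude test: a
  fixed-σ 3D Gaussian `A·G(x − x₀) + c` is fitted in a local window and a
  candidate is kept when the one-sided test of A > 0 against the window's
  residual noise is significant (α = 0.05–0.1, deliberately permissive).
  Retained spots are localised to subvoxel precision by least squares.
* **Spot pairing.** All cross-channel pairs (i, j) with dᵢⱼ < 5 μm are
  scored `S_ij = d_ij / sqrt(I_i · I_j)`; the two mutually exclusive pairs
  with the smallest score sum are selected (the two alleles), and the
  nucleus is accepted only if `max(S_A, S_B) ≤ 0.5 · S_next`, the best
  remaining candidate score.
* **Chromatic-shift correction.** Per experiment, the mean FITC→TRITC
  displacement vector is subtracted from every displacement, so the
  corrected displacement distribution has mean [0, 0, 0] exactly.
* **Statistics.** Two-sample Kolmogorov–Smirnov comparison of corrected
  distance distributions; interacting/non-interacting split by Rosin's
  unimodal threshold (or fixed cutoffs such as 0.9/1.3 μm); and a
  bootstrap sample-size analysis — 500 resamples of N cells per condition
  per grid size, minimum N at which ≥ 98% of resample pairs test
  significantly different.
* **ITS scanning.** Maximal runs of TTAGGG and its complement CCCTAA in a
  gene-plus-flanks region, reported relative to the gene span, with BED
  output — candidate anchor points for telomere looping.

## Worked example

```python
import numpy as np
import pandas as pd
from fishdist import (DistanceDataset, PipelineConfig, SegmentationParams,
                      SimParams, compare_conditions, run_pipeline,
                      simulate_fov)
from fishdist.pipeline import dataset_from_pairings

# simulate two small fields of view (4 nuclei each) and analyse them
stacks = {}
for k in range(2):
    params = SimParams(field_shape=(400, 400, 50), n_nuclei=4,
                       box_side_um=20.0, seed=40 + k)
    stacks[f"slideA_fov{k}"], _ = simulate_fov(params)

cfg = PipelineConfig(segmentation=SegmentationParams(box_side_um=20.0),
                     outdir="scratch/demo_run")
manifest = run_pipeline(cfg, stacks=stacks)
print("totals:", manifest.totals)

pairs = pd.read_csv("scratch/demo_run/pairings.csv")
young = dataset_from_pairings(pairs, "young-like")
print("median corrected distance: %.3f um" % np.median(young.distances_um))

# compare against an older-like condition with fewer interacting pairs
rng = np.random.default_rng(0)
n = 800
d_old = np.where(rng.random(n) < 0.55, np.abs(rng.normal(0, 0.12, n)),
                 rng.uniform(0.5, 3.0, n))
old = DistanceDataset("old-like", d_old, np.repeat(np.arange(n // 2), 2))
report = compare_conditions(young, old)
print("KS D = %.3f, p = %.2e" % (report["ks"]["D"], report["ks"]["p"]))
print("interacting fraction (0.9 um cutoff): young %.2f vs old %.2f"
      % (report["split_a"]["fixed"]["interacting_fraction"],
         report["split_b"]["fixed"]["interacting_fraction"]))
```

Output:

```
totals: {'fovs': 2, 'nuclei_accepted': 8, 'pairings_accepted': 8, 'spots': 473}
median corrected distance: 0.116 um
KS D = 0.440, p = 4.61e-03
interacting fraction (0.9 um cutoff): young 1.00 vs old 0.60
```

All 8 simulated nuclei were segmented, passed the quality filters, and
yielded an accepted allele pair; the median corrected pair distance of
0.116 μm reflects the predominantly interacting (sub-500 nm) population,
and the KS test separates the young-like from the old-like condition
while the 0.9 μm cutoff quantifies the shift in interacting fraction
(100% vs 60%).

A CLI mirrors the stages: `fishdist simulate | run | segment | detect |
pair | stats | compare | its`. For instance
`fishdist its region.fa --gene-start 2800 --gene-end 4500 --bed hits.bed`
scans a FASTA region for interstitial telomeric repeats.

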