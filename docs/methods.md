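# Methods

This note documents the models, algorithms, parameter choices and
limitations of `ieegconn`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Network construction

**Nodes.** Both networks share one node set per patient: the electrode
contacts placed in grey matter with clean signals (`included` flag).  All
adjacency matrices are symmetric, boolean, zero-diagonal, with a fixed
label order (`BinaryNetwork`).

**Contact areas (structural nodes).** Each included contact claims its
`max_voxels` (default 64) nearest boundary voxels within a 20 mm search
radius (Euclidean distance from the contact mm coordinate to voxel
centres, NIfTI affine convention, 0-based indices).  Voxels claimed by
several contacts go to the strictly nearest contact, ties to the lowest
contact index; areas are *not* refilled afterwards, so contested areas
shrink below 64 mm³ — this shrinkage is a genuine feature of densely
spaced implants, and the resulting VEA enters both the density
normalization and the group model.  The 20 mm radius is this package's
choice: contacts farther than that from any boundary voxel are flagged and
dropped from the structural network rather than projected across
implausible distances.

**Structural edges.** A streamline contributes to count(i, j) iff its
first point falls in a voxel of area i and its last point in a voxel of
area j (i ≠ j); unordered pairs, no self-loops, endpoints outside every
area ignored.  Density divides the count by the **sum** of the two VEAs.
"The volume of the two involved contact areas" admits several readings
(sum, mean, product); the sum is symmetric and bounded and keeps the 0.1
threshold on a per-mm³ scale, and `streamline_density(..., denominator=)`
exposes the mean alternative so the choice is never silent.  Binarization
uses a strict `> 0.1` ("exceeded").  Upstream tractography parameters
(seeding density, FOD cutoff, angle and length constraints) belong to the
tool that produced the TCK file and are not re-executed here.

**Effective edges.** Per stimulus pair: epochs are half-open sample
intervals `[onset − 2 s·fs, onset + 2 s·fs)` with event times snapped to
the nearest sample (bit-reproducible epoching).  Re-referencing subtracts,
per sample and epoch, the median of the `max(1, round(0.10·n))`
non-stimulated channels with the lowest trial variance.  The epochs are
averaged; the baseline median over −2 s…−0.1 s is subtracted and the
baseline SD computed on the corrected average.  The final 100 ms before
the stimulus are excluded from the baseline as a guard against artifact
bleed (configurable).  Detection takes the signed extremum in 9–100 ms —
most negative sample for ECoG ("negative sharp potential"), largest
|deflection| for sEEG — and declares a CCEP when |extremum| > k·SD with
k = 2.6 (ECoG) / 3.5 (sEEG).  Morphology rules of dedicated CCEP
detectors beyond threshold + window + polarity are deliberately not
reproduced; the detector interface accepts a custom `k` and window.
Stimulated channels are excluded from detection in their own trials
(saturation makes them uninterpretable), including the partner contact.
Each detected CCEP draws undirected edges from *both* stimulated contacts
to the responding channel; direction is discarded to make the network
comparable with the structural one.

## Similarity statistics

Densities, Jaccard index, expected Jaccard and the symmetric-difference
log-ratio follow the formulas in the README, all over unordered pairs.
Degenerate cases are explicit: JI of two empty networks returns a flagged
0; the ratio returns ±inf when one exclusive set is empty and NaN (with a
warning) when both are.

The significance test is a density-preserving permutation test: each of B
(default 10,000) permutations places the two observed edge counts
uniformly at random over the unordered node pairs and recomputes the JI;
p = (1 + #{JI_perm ≥ JI_obs}) / (B + 1).  The closed-form expected JI is
the analytic mean of this null (up to O(1/M) ratio-of-expectations error),
which the test suite verifies to within 0.01 — a published
Jaccard/Tanimoto test package would be an alternative backend, but an
explicit permutation null is transparent and oracle-checkable.  The
permutation p-value is discrete and slightly conservative by construction
(the +1 correction); with B limiting resolution, values below 1/(B+1)
are reported at that floor, i.e. "p < 0.0001" at the default B.

## Topology and the multilevel model

Degree is the adjacency row sum.  Betweenness centrality is unnormalized
and counted over unordered pairs (computed via networkx, verified against
an exhaustive BFS path-counting oracle); within-patient comparisons use
Spearman rank correlations, which are normalization-invariant, corrected
across patients with Benjamini–Hochberg FDR at q = 0.05.

The group model is a linear mixed model with a random intercept per
patient, fit by REML (statsmodels `MixedLM`; a derivative-free Powell
restart handles fits where the random-intercept variance sits on the
boundary).  Conventions:

* **Standardization** (default on, switchable): outcome and continuous
  predictors are z-scored over all pooled rows; the binary SOZ flag is
  left as is.  Standardized coefficients make effects comparable across
  predictors with different units.
* **Inference**: Wald t = β/SE with residual degrees of freedom
  `n − p − n_patients`; 95 % CIs are t-based.  Satterthwaite-type df are a
  known alternative; at ~850 residual df the difference is negligible.
* **R²**: variance-partition (Nakagawa) marginal and conditional R² from
  the fixed-effect linear predictor variance and the two variance
  components.
* **ICC** from the intercept-only model:
  σ²_inter / (σ²_inter + σ²_intra).
* **Backward elimination**: iteratively drop the predictor with the
  largest p > 0.05 and refit until all retained predictors are
  significant; the removal path is recorded.  If everything is dropped the
  intercept-only fit is returned flagged.
* **SOZ models**: patients without a delineated SOZ (all-NA column) are
  excluded from fits that include the SOZ predictor, and only from those.

## The synthetic-data generator

The generator emulates the study conditions so that every stage has a
known ground truth.

**Geometry.** ECoG: coplanar grids at 10 mm pitch (default 8×8).  sEEG:
parallel shafts of collinear contacts at 3.5 mm (DIXI-style) or 5 mm
(Ad-Tech-style) pitch, 12 mm apart (default 8 shafts × 8 contacts ≈ the
~66 included contacts per patient of a clinical implant).  The boundary
mask is a voxel shell 2–6 mm from each contact at 1 mm isotropic
resolution — guaranteeing ≥ 64 constructible voxels per contact while
still producing realistic area shrinkage between close neighbours.

**Planted networks.** Target densities default to the clinical medians
d_SC = 0.20, d_EC = 0.23, and the overlap fraction (planted intersection /
min edge count) defaults to 0.43, which yields a planted JI ≈ 0.25.  Edge
counts are rounded to the nearest feasible integers and the intersection
is drawn from the effective edges, so the planted JI is exact by
construction and infeasible (d_SC, d_EC, overlap) triples raise an error.

Stimulation is pairwise and reconstruction draws edges from both pair
members, so pairwise SPES identifies connectivity only at the resolution
of stimulation-pair blocks.  The generator therefore stimulates disjoint
adjacent pairs (1-2, 3-4, … within each row/shaft) and plants the
effective truth block-structured over those pairs, with no within-pair
edges (they are undetectable: the partner contact is excluded during its
own trial).  This is an identifiability property of the measurement, not
a simplification of the generator.

**Streamline counts.** For true structural edges, counts are drawn above
`0.1·(VEA_i + VEA_j)` (plus Poisson headroom); non-edges stay at or below
the threshold except a Bernoulli(fp_rate) fraction planted as false
positives.  `generate_streamlines` can expand a count matrix into actual
three-point streamlines for TCK round-trips.

**SPES recordings.** Ten pulses per pair at 0.2 Hz (defaults; fs = 2048 Hz
clinical, ≥ 512 Hz accepted).  Responses are negative damped half-sines
(~20 ms wide, default 500 µV at 30 ms) on every channel connected to
either stimulated contact; a stimulus-artifact spike marks t = 0; optional
white Gaussian noise (default 5 µV SD) is added on top of the background.

The background deserves a note.  The detector's z-statistic is invariant
to the amplitude of a Gaussian background (both the window extremum and
the baseline SD scale with it), so with *any* purely Gaussian background
the false-alarm probability of an extremum-over-window detector does not
vanish as the noise level goes to zero — and at exactly zero noise the
baseline SD is zero and detection is undefined.  A "noiseless" recording
therefore needs a deterministic background with a bounded extremum-to-SD
ratio.  The generator uses a common-frequency (10 Hz, alpha-band)
sinusoidal rhythm with channel-specific amplitudes drawn from a grid that
no reference median can exactly cancel: after re-referencing and
averaging, every non-connected channel retains a pure sinusoid whose
extremum/SD ratio is exactly √2 < 2.6, and every connected channel's
response dwarfs it.  With `noise_uv = 0` the round trip is exact by
construction; with noise on, the recording behaves like a normal noisy
measurement.  What this background does *not* emulate: 1/f spectra,
epileptiform transients, line noise, non-stationarity — so a passing
round-trip certifies the pipeline's correctness, not the detector's
clinical operating characteristics.

**Cohort tables.** Node rows follow
`SCD = β_ECD·ECD + β_NP·NP + u_patient + ε` with u ~ N(0, σ²_inter),
ε ~ N(0, σ²_intra); defaults β = ±0.13, σ²_inter = 0.37, σ²_intra = 0.63,
13 patients × 66 nodes.  ECD and NP are iid standard normal (already
standardized, no patient-level structure), so the planted variance split
maps directly onto the ICC formula; VEA (uniform 40–64 mm³) and SOZ
(Bernoulli 0.18) carry zero true effect.  Note the intercept-only ICC of
such a cohort is σ²_inter / (σ²_inter + σ²_intra + β²-variance) ≈ 0.358
with the default βs, since the intercept-only model absorbs the
fixed-effect variance into the residual.

## Verification strategy and problem sizes

* Exhaustive oracles: betweenness vs brute-force BFS path counting on all
  random graphs up to 8 nodes; contact-area assignment vs a per-voxel
  nearest-contact check; streamline counting vs per-endpoint membership.
* Closed-form cross-checks: permutation-null mean of the JI vs the
  analytic expected JI (|Δ| < 0.01 at B = 10,000).
* Round trips: noiseless synthetic patient (4×4 ECoG grid at 512 Hz — a
  size chosen so the full SPES simulation runs in seconds) recovered edge
  for edge through the complete pipeline, including the file formats
  (BrainVision via an independent reader, NIfTI, TCK, TSV).
* Detector calibration: on 10,000 pure-noise averaged responses the
  z-statistic at a fixed candidate latency exceeds k at the Gaussian tail
  rate (one-sided 2.6 / two-sided 3.5), verifying the baseline-SD
  estimation; the full window search alarms at its order-statistics rate
  `1 − (1 − tail)^W`, which is necessarily far above the single-sample
  tail — a reminder that the clinical thresholds only make sense together
  with waveform morphology constraints and non-white noise.
* Parameter recovery: 200 cohorts at the 13 × 66 scale; 95 % CI coverage
  of each planted β within [0.90, 0.99], median intercept-only ICC within
  0.05 of 0.37, and backward elimination retaining exactly the two planted
  predictors in ≥ 80 % of replicates.

## Known limitations

* Tractography, DWI preprocessing and image co-registration are upstream:
  the package consumes streamlines (or count tables) and mm-space
  transforms, never estimates them.
* Streamline counting treats endpoint pairs as unordered; a
  direction-sensitive seed→termination convention before symmetrization
  would give the same binary network but different counts for asymmetric
  seeding.
* The CCEP detector implements threshold + window + polarity only; it will
  over-detect on broadband-noisy channels relative to detectors with
  sharpness/morphology checks.
* The synthetic cohort can match cohort-level summaries (densities,
  planted JI, variance split) but not any particular patient's network,
  and its background model omits most of the spectral structure of real
  iEEG (see above).
* The permutation null preserves edge *counts* but not degree sequences;
  a degree-preserving rewiring null would be stricter for hub-dominated
  networks.
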