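# Methods

## Problem and pipeline

Median-nerve stimulation evokes a cortical response whose polarity flips
across the central sulcus (CS): postcentral (S1) contacts record the
N20–P25–P30 sequence, precentral (M1) contacts the mirrored P20 followed
by a late negativity. `sulcimap` turns a continuous grid recording into
per-channel averaged SSEP traces, quantifies anterior/posterior
separability over time, renders spatial heat maps, and groups channels
unsupervised by waveform morphology. All analysis operates on the
10–50 ms post-stimulus window (inclusive–exclusive, t = 0 at the trigger
sample).

## Preprocessing

* **Trigger detection.** The stimulator leaves a large single-sample
  artifact on the bipolar EMG. Onsets are threshold crossings of
  `|emg − median| > 8·MAD`, collapsed with a refractory period of half
  the stimulation interval. The 8·MAD threshold (≈5.4 σ for Gaussian
  baseline) keeps the per-session false-trigger expectation ≪ 1 while
  tolerating baseline drift.
* **Filtering.** 2nd-order Butterworth high-pass at 30 Hz applied
  forward–backward (`sosfiltfilt`): zero net phase shift, squared
  magnitude response. Filtering precedes epoching so edge transients fall
  outside the analysis window.
* **Averaging and smoothing.** Epochs aligned to triggers are averaged;
  the average is smoothed with a Savitzky–Golay filter, polynomial
  degree 3, 5 ms window (13 samples at 2.4 kHz, rounded up to odd). A
  5 ms cubic window does not flatten the ~2 ms-wide components (it
  reproduces any cubic exactly) while suppressing residual sample-scale
  noise.
* **Corrupted channels.** Clean averaged SSEPs are smooth at the few-ms
  scale, but their *total* variance spans more than a decade across the
  grid purely from the distance-dependent amplitude. The outlier
  statistic is therefore the variance of the residual after a cubic
  Savitzky–Golay fit — a per-channel noise/artifact floor that is
  homogeneous across clean channels. Channels whose log residual
  variance has robust z (median/MAD, normal-consistent 0.6745 scaling,
  MAD floored at 0.05 log units) above 3.5, or zero total variance, are
  excluded from all downstream stages. The threshold is this package's
  convention; published pipelines describe corrupted contacts only as
  "large variance" outliers.
* **Flavors.** `raw` (smoothed average, μV), `derivative` (central
  differences, one-sided at the edges, μV/ms — latency-preserving, unlike
  a forward difference), `zscored` and `zscored_derivative` (per-channel
  zero mean, unit variance over the window, n−1 denominator).
  Zero-variance channels are flagged as corrupted rather than divided.

## Discriminative time points

`F(t) = (μ_A − μ_P)² / (σ²_A + σ²_P)` with sample (n−1) class variances;
any consistent variance convention rescales F monotonically and leaves
the argmax unchanged at fixed class sizes. Degenerate time points with
zero pooled variance yield F = 0 (equal means) or +∞ with a flag.
Windowed maxima are reported in the 17–25 ms (N20-like) and 27–40 ms
(P30-like) search windows.

Peaks per channel: 1st N = minimum in 17–25 ms, 2nd P = maximum in
27–40 ms; amplitude is measured trough-to-peak against the nearest
preceding opposite-polarity local extremum (window-start value if none
precedes), and a boundary extremum is flagged low-confidence. The
intermediate 22–30 ms positivity (anterior P20 / posterior P25
superposition) is located but excluded from statistics. AUC at a time
point treats channel amplitudes as scores for the anterior/posterior
labels, midrank tie handling (= Mann–Whitney probability), reported as
`max(AUC, 1 − AUC)` with the winning polarity since the informative sign
differs between the N- and P-windows.

## Spectral clustering

Affinity `W_ij = exp(−‖x_i − x_j‖²/2σ²)` between whole z-scored
waveforms, σ = 2 by default (configurable; a σ sweep is available through
the estimator parameters). Random-walk Laplacian `L = I − D⁻¹W`;
eigenpairs are computed on the symmetric equivalent
`I − D^{−1/2} W D^{−1/2}` (identical eigenvalues, eigenvectors mapped
back by `D^{−1/2}`), with symmetrization `W ← (W + Wᵀ)/2` and eigenvalue
clipping at −1e−10. Cluster count: largest successive eigengap among the
first `k_max + 1 = 5` ascending eigenvalues; if the winning gap exceeds
the runner-up by less than `gap_floor = 0.05`, the smaller k wins
(tie-break toward fewer clusters — a weak elbow should not invent
structure). k-means runs on the entries of the second-smallest
eigenvector (1-D embedding) with a deterministic sorted-quantile
initialization plus 50 seeded random restarts; cluster ids are relabelled
by ascending center so results are reproducible given the seed. k = 1 is
a meaningful outcome: no CS crossing (or no clear phase reversal).

Region assignment for k = 2: with ground truth, the cluster→region
mapping maximizing `accuracy = 100 · CHL_CL / N` over the two
permutations (CHL_CL = correctly clustered channels); without ground
truth, the cluster whose mean trace has the more negative 17–25 ms
extremum is posterior (the N20 side).

**Grid resampling.** Every 1 × N strip (one medial–lateral row taken
along the anterior–posterior axis) and every adjacent 2 × N pair is
re-clustered and scored; subsets with fewer than 3 usable channels are
skipped and logged. Subsets returning k = 1 are scored as the
majority-class fraction (a single-cluster call on a CS-crossing strip is
penalized); k > 2 subsets are scored by purity.

## Heat maps

Sibson natural-neighbor interpolation, computed exactly: the Voronoi
cells of the electrodes are convex polygons; inserting a query point
creates a cell whose area is "stolen" from neighboring cells, and the
stolen fractions are the weights. Implemented with half-plane clipping of
convex polygons; exact at the electrodes (node tolerance 1e−9), linear
precision inside the convex hull, NaN outside. Raster default
0.25 mm/px for single frames, 1 mm/px for animations (frames every 2 ms
across the window on a shared symmetric color scale). An all-collinear
layout (1 × N strip) falls back to 1-D linear interpolation rendered as a
ribbon, with a warning. Symmetric scale uses a zero-centered diverging
palette, asymmetric a sequential one; both configurable.

## Synthetic sessions

The simulator emulates the acquisition this pipeline targets: 0.6 Hz
stimulation trains, 2.4 kHz sampling, a rectangular grid (default 4 rows
medial→lateral × 8 columns anterior→posterior, 5 mm pitch — the
high-density-grid regime) crossing a straight CS line (offset 16.5 mm,
tilt 8°), and a hand-knob-like source posterior-lateral of the line.

* **Waveforms.** Unit-peak Gaussian bumps (σ = 2 ms; the literature
  reports peak latencies and polarities, not analytic shapes — a smooth,
  latency-preserving, analytically checkable stand-in). Posterior:
  −N20·g(20) + P25·g(25) + P30·g(30) with default amplitudes 10/3/8 μV.
  Anterior: +P20·g(20) − 4 μV·g(33). N20 and P30 latencies are validated
  against the 17–25 / 27–40 ms search windows.
* **Spatial model.** Regional components scale as `exp(−d/15 mm)` from
  the source. A stimulus-locked slow far-field bump (default 10 μV,
  σ = 5 ms, 28 ms) is added *uniformly* — volume-conducted far-field
  activity reaches every contact at similar amplitude. Being broad, it
  dominates raw traces on low-gain channels but is ~width-fold weaker in
  the derivative; at 25 μV it reproduces the clinically observed failure
  mode in which raw-trace clustering degenerates (often to a single
  cluster) while derivative clustering still recovers the CS. An optional
  sigmoid blend of the two regional templates in the signed distance to
  the CS (`cs_mixing_mm`, default 0 = hard switch) models morphology
  blurring near the sulcus.
* **Noise and artifacts.** Per-sample Gaussian trial noise (default
  1 μV: after 100-trial averaging the 0.1 μV residual matches the noise
  floor of clinical averaged SSEPs, while single trials remain
  signal-starved enough to require averaging); shared per-trial latency
  jitter (SD 0.5 ms, conduction-time variability); EMG baseline noise
  with a one-sample 50× spike per stimulus (a 200 μs pulse is below one
  sample at 2.4 kHz). Corrupted channels are white noise with
  `20 · noise_sd · √n_trials` continuous SD, i.e. 20× the clean noise
  floor *after averaging* — emulating broken contacts whose artifacts do
  not average out, and keeping them detectable on the averaged trace as
  in practice.

What the simulator does **not** model: biophysical dipole geometry and
realistic volume conduction, per-channel morphology variability beyond
the amplitude gain, non-stationary background (bursts, line noise),
sedation-state differences, MRI-derived geometry. Consequently, passing
tests demonstrate the pipeline's correctness and its behavior under the
stated conditions — not clinical performance on patient data; in
particular the simulator's clean conditions make large-grid clustering
essentially perfect, whereas real recordings leave headroom.

## Numerical choices and edge cases

* Epoch window endpoints `[10, 50)` ms; epochs running past the record
  are dropped and counted.
* The zero-phase filter leaves a deterministic early-window transient
  that is class-dependent on synthetic data; on real data per-channel
  variability masks it, on synthetic data it can dominate the raw-trace
  F(t) near the window edge. The Fisher windowed peaks (17–25, 27–40 ms)
  are unaffected; property tests of the argmax use the unfiltered chain.
* F(t) windowed peaks sit on component flanks (within-class
  amplitude-spread variance is maximal at the peak itself), typically
  1–2 ms from the generating latency.
* `paired_ttest`: identical inputs → (t = 0, p = 1); constant nonzero
  differences → ±∞ with a warning rather than an exception.
* Degenerate second eigenvector (constant) → fall back to k = 1 with a
  warning.
* Reference problem sizes: ensembles of 20 seeds (10 for the no-crossing
  rate) at 100 trials/session, chosen to estimate rates and means with
  ~±10 % resolution while a full run stays under a minute.

## Interfaces

Sessions are written as EDF+C (one signal per electrode, an `EMG`
channel, stimulation onsets as annotations; 16-bit with per-signal
physical scaling — the writer is a minimal EDF+ implementation and round
trips through MNE's independent reader) and as a lossless fixture bundle
(`data.npy`/`emg.npy` + JSON sidecar with geometry, ground truth and
parameters). Traces are CSV (rows = channels, columns = time in ms) with
a JSON sidecar; geometry JSON carries rows/cols/spacing, positions, the
CS polyline and region labels. The CLI (`sulcimap simulate | preprocess |
fisher | peaks | cluster | heatmap | evaluate | run`) records seed,
configuration hash and per-stage status in a run manifest, making every
numeric output reproducible from the manifest alone.
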