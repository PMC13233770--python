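# Methods

This note documents the models and procedures implemented in `cionakit`,
the defaults they use, and the design choices made where the problem was
genuinely open. Problem sizes quoted for tests and the acceptance script
are the package's own reference scales.

## Input model

A recording is a T×18×2 array of pixel coordinates (image convention:
x right, y down) with per-point tracking likelihoods, sampled at 20 Hz,
one animal per file. The 18 points trace a single closed walk around the
body outline: four around the oral siphon (dorsal/ventral rim + bases),
four around the atrial siphon, and ten along the trunk down to the
holdfast. Pixels convert to millimeters at 0.254 mm/px (the calibrated
scale of the reference recordings). Points below the 0.6 likelihood
cutoff are treated as missing; analysis runs at 4 Hz after 1:5
decimation (decimation, not averaging, preserves event sharpness).

## Morphometric channels and trends

Six channels per frame: whole-body polygon area (shoelace), trunk polygon
area (outline minus the four siphon rim points), the two siphon opening
widths (rim-pair Euclidean distances) and the two four-point siphon
areas. A recording is retained only if every channel is ≥ 20 % finite
(inclusive).

Cleaning: each channel is divided by its own median (per animal);
deviations from the normalized median larger than **max(5·MAD, 1.0)** are
treated as tracking artifacts and set missing. The floor of 1.0
(= 100 % of the median) matters: in quiescence-dominated recordings the
MAD reflects only tracking noise (≈ 1 %), while genuine contractions
shrink a channel by 30–50 % — a pure k·MAD rule would delete the signal
of interest, whereas real glitches (landmark swaps) overshoot the median
by several multiples. Missing runs of ≤ 20 frames are linearly
interpolated; longer runs stay missing.

Trend extraction is the classical additive decomposition with a 50-frame
period (`statsmodels.seasonal_decompose`): the trend is the centered
50-frame moving average, the seasonal component the period-averaged
detrended mean. The trend is z-scored per channel; the undefined leading
and trailing half-windows are reconstructed by a linear fit over the
first/last 25 valid trend frames, and interior trend gaps of ≤ 200
frames are interpolated. First/last defined frames are recorded so
boundary artifacts can be excluded downstream.

## Contraction events and the three engagement states

All six channels *shrink* during a contraction, so events are detected as
minima: the z-scored trend is Savitzky–Golay smoothed (window 11, order
3 — ≈ 2.75 s at 4 Hz, wide enough to stabilize detection yet narrower
than the 5-frame minimum event width), negated, and searched with
prominence ≥ 0.7 z and width ≥ 5 frames.

Event spans need care because the 50-frame moving average widens every
dip by roughly half the window on each side. Onset and offset are placed
at the half-prominence crossings flanking the peak, bounded by the
nearest *prominent* (≥ 0.35 z) local maximum of the trend (so trains of
incompletely relaxed contractions split into adjacent spans while
micro-wiggles inside one dip cannot truncate it) and by a ±50-frame
footprint cap (a single contraction's trend footprint is finite; slow
baseline drift must not stretch spans indefinitely); finally both ends
are pulled 18 frames toward the peak, undoing the moving-average
shoulder. These three constants (0.35 z, 50, 18 frames) are deconvolution
allowances tied to the decomposition window, exposed as parameters.

Events are graded **major** if their prominence reaches 70 % of the
animal's maximum prominence in that channel (a single event is its own
maximum). Frames are then labeled using the three informative channels
(trunk area, OS width, AS width):

* **DPE** — covered by major events in all three channels simultaneously
  (a synchronized full-body contraction);
* **SePE** — covered by any event span without meeting the DPE rule;
* **StaPE** — no event coverage and |z − median(z)| < 0.5 in all three
  channels. Quiescence is judged against the trend *median* rather than
  z = 0 because contraction dips drag the mean below the resting level —
  the median tracks the quiescent baseline.

Unlabeled frames inherit the nearest preceding label. Bouts shorter than
2 s are merged into the longer adjacent bout (ties to the preceding one),
iterating shortest-first until stable. Event kinematics are computed on
the micrometer-scale channels: amplitude = value(onset) − value(peak),
contraction/relaxation speed = amplitude over the respective segment
duration.

On the reference synthetic cohort (8 recordings × 15 min, 1 px tracking
jitter) the full chain recovers the ground-truth frame labels at a
cohort mean of 0.90, degrading monotonically as jitter grows.

## Eigenciona shape space

Each valid outline (all 18 points finite, polygon simple — incomplete or
self-intersecting frames are rejected with a reason) is expanded in
elliptic Fourier descriptors at order 30. Coefficients are computed in
closed form for the piecewise-linear contour (no resampling); the
dense-quadrature oracle in the test suite agrees to < 1e-6 relative.
Normalization follows the standard procedure: phase rotation onto the
first harmonic's major axis, spatial rotation onto that axis, division by
the semi-major axis, and a mirror convention (first-harmonic minor-axis
coefficient non-negative; violated frames are reflected). The amplitude
spectrum Aₙ is invariant to rotation, translation, scale, starting vertex
and mirroring — each a property test.

The harmonic count is chosen as the smallest n whose frame-averaged
cumulative squared-amplitude fraction reaches 99.9 % ("shape
information" = amplitude energy, the standard EFD power criterion);
10 harmonics suffice on reference data. PCA runs on z-scored spectra
(correlation structure); k is the smallest component count explaining
≥ 85 % of variance, with deterministic loading signs. Dynamic modes use
within-animal first differences (never across animal boundaries).

**Identifiability of latent modes.** PCA recovers the latent *subspace*,
not individual modes: unrotated components align with generative modes
only if the modes' amplitude-spectrum signatures are orthogonal in the
z-scored metric and their variances are separated. The anatomical modes
of the generator (trunk contraction, siphon closures, bend, stretch)
have strongly collinear signatures — the EFD size normalization and
chord-length reparameterization funnel all of them partly through a
common direction — so per-mode score-weight correlations are low even
though a linear decoder recovers every mode weight from the full
spectrum at R² 0.86–1.0. The package therefore ships
`synthetic.orthogonal_mode_fields()`, an SVD-orthogonalized
radial-harmonic basis for identifiability experiments; on such cohorts
the leading canonical correlations between EC scores and true weights
are ≥ 0.98, which is what the mode-recovery test asserts. Conclusions
about *individual* eigencionas on real data should likewise be read as
subspace statements.

## Behavioral space

Clustering uses the five static EC scores. A balanced discovery subset
(equal frames per condition, shortfalls redistributed) bounds the cost;
an HDBSCAN scan over (min_cluster_size, min_samples) maps the noise
fraction so a stable regime can be chosen; Gaussian mixtures (full
covariance, 5 EM restarts) over the K range are compared by BIC (AIC
reported). Labels propagate to remaining frames by kNN majority vote
(k = 15, Euclidean, ties to the smallest cluster id). The UMAP embedding
(neighbors 50, min_dist 0.7, fixed seed) is visualization only — cluster
assignment never depends on it. Occupancy is summarized per condition as
a Gaussian KDE (Scott's rule) over the embedding plus per-animal seconds
per cluster (rows sum to each animal's labeled duration).

## Hidden-Markov state dynamics

Features per frame: EC1–EC5, their within-animal first differences,
postural speed (norm of the first difference) and acceleration (norm of
the second difference), all z-scored within animal; the first two frames
of each animal are masked. One Gaussian HMM (8 states, diagonal
emissions — robust at these feature counts; full covariance available)
is trained on the pooled conditions by EM (default 10 restarts,
tolerance 1e-4, 500 iterations, seeded) keeping the best likelihood,
then Viterbi-decoded per animal. Decoded bouts shorter than 5 frames are
merged into the neighboring state with higher posterior mass. States are
relabeled deterministically by the ascending mean of a caller-supplied
ordering signal (by convention the whole-body-area z-trend: S0 most
relaxed … S7 most contracted). Transition statistics are computed
frame-to-frame (self-transitions are meaningful persistence terms);
bout-level matrices are exported as well. Occupancy, median bout
duration and their fold changes versus a baseline condition feed the
radar-style exports. Parameter-recovery tests: 2-state data at 6 sd
separation decodes at ≥ 98 % (≥ 95 % at 4 sd), and an 8-state generative
transition matrix is recovered within 0.05 per entry at 15,000 frames.

## Group statistics

Two-sided Mann–Whitney U (exact for n ≤ 8 without ties — verified against
full enumeration for n ≤ 6 — normal approximation with tie correction
otherwise) and Kruskal–Wallis with tie correction. Star codes follow the
reporting thresholds * p < 0.05, ** p < 0.005, *** p < 0.0001; no
multiple-testing correction is applied. Percent change is
100·(condition − baseline)/baseline on condition-level summaries
(animal-level medians by default).

## The synthetic generator

The generator defines the study conditions for every test. A recording
is built from:

1. **State dynamics** — a semi-Markov chain over DPE/SePE/StaPE routed
   DPE ↔ SePE ↔ StaPE only. Dwell times are gamma with realistic caps:
   DPE mean 5.5 s* (shape 40 — a stereotyped full contraction), SePE
   mean 15 s (shape 2.5, caps 8–60 s), StaPE mean 60 s (shape 2.5, caps
   5–150 s). SePE branches to DPE with probability 0.2, making DPE the
   rarest and shortest state. (*The rendered full-contraction pulse
   spans the whole DPE bout, so realized DPE bouts run ≈ 7–13 s.)
2. **Shape** — a fixed 18-point template (animal ≈ 11 cm tall at
   0.254 mm/px, vertically mounted, both siphons up) plus five latent
   displacement modes: trunk contraction toward the trunk centroid,
   oral- and atrial-siphon closure (rim pairs move together; closure
   fraction = mode weight), a lateral bend and a vertical stretch. The
   slow modes are constructed to be invisible to the six channels — the
   bend is a shear saturating above mid-body, the stretch is
   area-compensated, and both translate each siphon quad rigidly — so
   quiescent fluctuation stays sub-threshold by construction, as the
   state definitions require. Contraction events are raised-cosine
   pulses in the weights of modes 1–3: one bout-spanning synchronous
   pulse in all three regions per DPE bout (amplitudes ≈ 0.45/0.75/0.65
   for trunk/OS/AS), sparser partial-subset pulses (rise 0.8 s, decay
   4 s) during SePE, nothing during StaPE beyond AR(1) background drift
   (per-mode sd 0.001–0.12, τ = 4 s). Event amplitudes are calibrated to
   reproduce qualitative orderings only — the source recordings publish
   no quantitative amplitude distributions.
3. **Noise** — Gaussian landmark jitter (reference sd 1 px, the
   effective post-filtering tracking error) and per-landmark NaN dropout
   runs (start probability 0.002/frame, runs ≤ 10 frames, likelihood 0),
   matching filtered-tracker output semantics. Frames whose outline
   self-intersects after jitter are re-jittered (≤ 20 draws).

What the generator does *not* emulate: real contour deformation between
landmarks, camera-angle (3-D) distortion, occlusion-correlated tracking
failure, inter-animal shape variability, and physiological rhythms other
than the event/drift structure. Passing tests therefore demonstrate that
the pipeline recovers the constructs it defines under controlled noise,
not that the biological conclusions transfer to any particular real
recording.

## Numerical conventions and edge cases

Frames are 0-based; time = frame/fps. Downsampling rescales stimulus
onsets by floor division. Degenerate inputs are values, not crashes:
incomplete/self-intersecting contours are rejected records, zero-median
channels are flagged, zero-duration event segments give NaN speeds,
empty conditions are skipped with warnings, and single-bout recordings
yield empty transition matrices. All stochastic steps (generator, GMM,
UMAP, HMM restarts, subset draws) take explicit seeds; identical
configuration and seed reproduce artifacts byte-for-byte.

## Reference scales

The test suite simulates cohorts of 2–8 recordings of 1,600–18,000
frames; the acceptance script uses 200 noise-free frames (reconstruction
error), 5 × 3,600 frames (harmonic energy) and 10 × 3,600 frames
(eigenciona variance). These sizes give stable estimates of every
reported quantity while keeping a full run in minutes on one CPU.
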