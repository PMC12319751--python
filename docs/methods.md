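# Methods

## The measurement model and the cleaning procedure

The pipeline assumes the standard linear instantaneous mixture: the
gradiometer data `X ∈ R^{C×T}` are

    X = A_n S_n + A_a S_a + E

with neural sources `S_n`, myogenic artefact sources `S_a` (facial muscles
and tongue during speech or deliberate gestures), fixed topographies
`A_n, A_a`, and instrument noise `E`. Speech artefacts are broadband,
high-frequency, and focal over the frontotemporal sensors; they dwarf the
neural signal during vocalization.

Cleaning proceeds in four stages.

**Whitening and ICA.** The gradiometer data (all naming runs concatenated,
optionally preceded by the gesture task; run seams are recorded so no epoch
or analysis window straddles them) are centred and projected onto the
smallest number of principal components whose cumulative explained variance
reaches 99.99 %. On interference-suppressed MEG this threshold keeps
essentially the physiological rank of the data. FastICA (log-cosh contrast,
symmetric decorrelation, fixed seed) then estimates one independent
component per retained PC. A non-convergent fit is returned with an honest
`converged=False` flag rather than silently retried, to keep runs
reproducible.

**MI matrix.** The EMG of each informative task (the gesture task, and the
vocal-naming task; silent naming and observation carry no muscle activity
and are excluded) is decomposed with a per-task PCA into as many components
as channels — rotation only, since the subsequent statistic is invariant to
monotone marginal transforms. For every (IC, EMG-PC) pair the mutual
information is estimated over the concatenated task samples with the KSG
k-nearest-neighbour estimator (algorithm 1):

    I = ψ(k) + ψ(n) − ⟨ψ(n_x + 1) + ψ(n_y + 1)⟩,   k = 3,

with Chebyshev-ball neighbour counts, after a rank-to-normal marginal
transform (a numerical-conditioning step the estimate is theoretically
invariant to; a flag disables it) and infinitesimal seeded tie-breaking
jitter. Series longer than 20 000 samples are uniformly subsampled
(seeded). Estimates are clipped below at zero and mapped to the MI
correlation coefficient ρ = 1 − exp(−2I) ∈ [0, 1). One value per pair per
task is computed — the simplest reading consistent with matrix shapes of
4 × n_IC (variant N) and 8 × n_IC (variant GN).

**Selection.** Components are clustered by k-means (k = 5, 10 seeded
restarts, best inertia) on their ρ-profile vectors; clustering the vectors
rather than the scalar MI sums keeps components with different task
signatures apart. The cluster with the highest mean per-IC MI sum (sum of ρ
over rows) is elected; ties break toward the higher maximum MI sum, then
the lower cluster id. The MI sum uses ρ rather than raw I so rows are
bounded and comparable across tasks (flag available). Two warnings guard
the degenerate regimes: `oversize` if the elected cluster holds more than
25 % of the components (many removals historically indicate failure), and
`low_contrast` if the elected cluster's mean MI sum does not exceed the
median component's by at least 0.1 per matrix row — the expected outcome on
artefact-free data, where no selection should be trusted. The elbow curve
(inertia over k = 2…20) is exposed for cluster-count diagnostics.

**Removal and evaluation.** The recording is reconstructed from the
non-elected components (plus channel means); the excluded directions are
projected out exactly, and removal composes: excluding A∪B equals excluding
A then B. Evaluation follows a fixed operation order: epoch (0–1.5 s after
picture onset, half-open windows, no baseline correction by default),
average, combine each gradiometer pair as sqrt((a² + b²)/2) per time point,
normalize by the whole-head maximum, then per pair

    RMSD_ch = sqrt( Σ_i (EVhat_i,ch − EV_i,ch)² / t ).

The mean-square (not sum) convention under the root makes a pair of equal
channels return that amplitude. Statistical comparison uses a two-sample
cluster-based permutation test on pair-combined epochs, each epoch scaled
by its own maximum: pointwise t maps thresholded at the two-sided t
quantile (cluster-forming p = 0.05), spatio-temporal clusters under layout
adjacency × temporal contiguity, summed-t cluster statistics, and a
max-cluster-statistic permutation null. P-values include the observed
labelling, p = (1 + #{null ≥ obs}) / (n_perm + 1), so the attainable floor
with 1000 permutations is 1/1001 — just below the 0.001 operating point.
The test is run across epochs within one dataset (a single-subject reading;
a group-level test across subjects would be exchangeable over subjects
instead).

## The synthetic generator

The generator emulates the full experimental design — gesture sets of
randomized gesture order with consecutive repetitions, naming runs of six
pseudorandomly ordered task blocks (predetermined order configurations,
18–19 pictures per block summing to 110 per task at full scale), cue and
picture timing to the sample — and the measurement model above, exactly
linearly (the stored truth reproduces the data to machine precision).

EMG: each gesture cue or vocal picture triggers a burst of 20–95 Hz
band-limited noise under a smooth fast-rise/slow-decay envelope, with a
per-(gesture, muscle) gain matrix encoding which muscles each gesture
recruits (overlapping, never isolated), per-event-per-channel lognormal
amplitude jitter, onset jitter, and a low baseline noise floor. Silent
naming and observation trigger nothing.

Artefact sources: three sources with unit-norm Gaussian-bump topographies
over the left frontotemporal, right frontotemporal, and frontal-midline
(glossokinetic/tongue) layout positions. Each source is an independent
55–95 Hz carrier amplitude-modulated by the rectified, 8-Hz-low-passed
envelope of a weighted EMG combination — so artefact components share MI
with the EMG while resembling it in waveform not at all, which is precisely
the regime that motivates MI over correlation. Two deliberate design
choices balance two competing requirements:

- *Uniform EMG weights with an independent band-limited (0.3–1.5 Hz,
  log-sd 0.35) contraction-strength drift per source.* All sources follow
  the common muscular drive, so their long-run MI profiles against the EMG
  PCs are nearly identical and k-means groups them as one cluster; the
  drift varies the instantaneous amplitude ratios, which is what makes
  comodulated modulated-noise sources mutually identifiable to ICA at all
  (with identical envelopes the artefact subspace is spherically symmetric
  and no rotation is preferred). Band-limiting the drift keeps its realized
  energy stable within a task so it does not differentiate the profiles.
- *Orthogonalized neural topographies.* Fourteen neural generators
  (1/f background with slow amplitude modulation plus stimulus-locked
  transients whose per-source involvement is geometrically graded) have
  bump-plus-random patterns orthogonalized against the artefact patterns
  and each other. On a coarse 10-pair desk array this keeps the 17-column
  source geometry well conditioned, so the 99.99 % PCA always retains every
  physiological dimension — mirroring real interference-suppressed
  recordings, whose retained PC space is physiological almost entirely.
  The graded evoked involvement also gives the non-artefact components a
  realistic continuum of weak EMG dependence (evoked responses are
  event-locked, as are the muscle bursts), rather than an implausibly
  uniform zero.

Instrument noise is mildly heavy-tailed (Student-t, 8 d.o.f.) at σ = 0.01
sensor units. All randomness descends from one seed through named
substreams (schedule, EMG, MEG, topographies); identical seeds give
bitwise-identical datasets.

Built-in scenarios: `GN` (gesture + naming; the default study condition),
`N` (naming only), `reduced-snr` (vocal burst gains × 0.25 with intact
gestures — a faint speech artefact, the regime in which adding the gesture
paradigm should pay off), `null` (no artefact sources), and `full` (the
complete 102-pair, full-duration design). Desk-scale defaults — 10
gradiometer pairs + 4 EMG at 200 Hz, 2 gesture sets × 3 repetitions at 2 s
cue spacing, 35 pictures per naming task — were chosen once to keep an
entire selection run in single-digit seconds on one core while preserving
every structural feature of the design; the `full` scenario preserves the
printed sizes.

## What the synthetic tests do and do not show

Passing the end-to-end recovery experiments demonstrates that the
implementation of the selection logic is sound under the model's own
assumptions: exact linear mixing, stationary topographies, artefact sources
genuinely independent of the neural sources, and EMG that records the same
muscular drive that generates the MEG artefact. Real recordings violate all
of these gracefully — head movement bends topographies, ICA is never exact,
and surface EMG misses deep muscles — so synthetic recovery rates are an
upper bound, not a forecast. The generator also does not model ocular or
cardiac artefacts (assumed removed upstream), realistic lead fields, or
source-level analysis.

## Numerical choices and degenerate inputs

- Epochs use 0-based sample indexing and half-open windows [tmin, tmax);
  epochs outside the data or straddling run seams are dropped with a
  logged warning.
- Downsampling applies a zero-phase FIR anti-alias filter with its passband
  edge at 0.9× the target Nyquist before decimation; event onsets rescale
  with round-half-to-even.
- Whitening keeps the full numerical rank with a warning when the variance
  threshold is unreachable; constant EMG channels yield zero-variance PCs,
  retained with a warning; constant MI inputs return 0 with a warning;
  negative MI estimates clip to 0.
- `remove_components` refuses to exclude every component; an empty
  exclusion returns the PCA-truncated reconstruction (not the identity).
- The k-means election is fully seeded; the permutation test seeds its
  label shuffles; the CLI threads one seed through every stage and echoes
  the fully resolved configuration on each run, exiting with code 3 when a
  selection carries warnings.

## Known limitations

Single-dataset (within-session) statistics only; no automatic per-dataset
choice of the cluster count k (the elbow curve is descriptive); the FIF
reader ingests recordings and trigger events but does not write FIF; and
the desk-scale array's planar-gradiometer pairs share a position rather
than encoding two orthogonal derivative directions, which is immaterial to
every statistic computed here but means no physical field model underlies
the synthetic topographies.
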