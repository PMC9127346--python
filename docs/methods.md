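# Methods

`adeeg` implements one analysis chain for staging Alzheimer's disease
from multichannel EEG: phase-locking-value (PLV) connectivity networks
with weighted graph metrics, common-spatial-pattern (CSP) features, a
no-threshold recurrence-plot image transform classified by a residual
convolutional network, and decision-level fusion of the two signal
branches with screened clinical covariates. This note records the models,
the defaults and why, and the choices made where the design was open.

## Synthetic EEG generator

No clinical recordings ship with the package; every experiment runs on
synthetic data with known ground truth, so each stage can be tested
against the structure it is supposed to recover.

**Signal model.** Channel *i* is an amplitude-modulated cosine plus white
sensor noise, band-passed to the analysis band (8–30 Hz by default):

    x_i(t) = A_i(t) · cos(2π f₀ t + φ_i(t)) + w_i(t),   f₀ = band centre.

The instantaneous phase is a convex mixture of an independent phase
random walk u_i and a walk s shared within the channel's coupling group:

    φ_i(t) = (1 − κ_i) u_i(t) + κ_i s(t) + θ_i,

with per-sample walk std 0.35 rad. Groups are the connected components
of the coupling matrix κ; a channel's effective coupling κ_i is its
strongest pairwise entry. κ → 1 freezes pairwise phase differences
(PLV → 1); κ = 0 lets them diffuse over many cycles, leaving only the
finite-sample PLV floor. The walk std sets both the decorrelation speed
of uncoupled channels and each channel's intrinsic bandwidth (~1–2 Hz,
comfortably inside the 8–30 Hz band at the 128 Hz default rate).

**Disease states.** The three clinician-defined states are emulated by
two monotone trends, both chosen once as the study conditions:

| state        | envelope gain (µV) | envelope volatility | coupling scale |
|--------------|--------------------|---------------------|----------------|
| calm         | 1.0                | 0.1                 | 1.0            |
| transitional | 2.0                | 0.3                 | 0.6            |
| morbidity    | 4.0                | 0.6                 | 0.3            |

Amplitude and its volatility grow with disease severity (the narrative
the recurrence-plot branch relies on), and pairwise synchrony degrades
with severity. The coupling trend is the package's own design choice: a
generator in which states differ only in amplitude would leave the
PLV-network and (scale-invariant) CSP features with no class signal at
all, making the PE branch unlearnable by construction; degrading
synchrony with progression is also the direction reported for AD
functional connectivity. Sensor noise is 0.3 µV regardless of state, so
relative SNR falls from morbidity to calm.

**Clinical covariates.** Age and eye-movement score are Gaussian with a
per-state shift of 1.0 standard deviation per severity step; diabetes is
Bernoulli with rate 0.2/0.5/0.8 across states (risk difference 0.3 per
step). Sex, hypertension (rate 0.4) and hyperlipidemia (0.35) are drawn
independently of the label. Effects of this size are detected with power
≈ 1 at n = 100, so screening outcomes are governed by the null features.

**What the generator does not emulate:** eye-blink/EMG artifacts, volume
conduction, 1/f background spectra, non-stationary coupling, or realistic
62-channel montages (4 frontal channels by default; more are supported).
Passing tests therefore show that each algorithm recovers the structure
it targets under controlled conditions, not that the pipeline is
clinically validated.

## Phase synchronization

Phase is extracted with a 4th-order Butterworth band-pass applied
forward–backward (zero phase) followed by the analytic-signal angle from
the Hilbert transform — the standard PLV construction; the source
narrative never states one. PLV is the modulus of the mean unit phasor of
the phase difference over the full window, with Δt taken as one sample
period. The 1/N-inside-vs-outside-the-modulus ambiguity in the usual
typography is immaterial (N is real positive); the modulus of the mean is
computed. An optional flag trims the first and last 5% of samples before
averaging to limit filter transients (off by default); a sliding-window
variant exists for exploration. A constant (all-zero) channel yields an
all-zero phase rather than NaN.

For independent uniform phases the finite-sample PLV floor is the mean
modulus of a 2-D random-walk average, √π/(2√N) ≈ 0.028 at N = 1000; the
calibration tests check this against Monte Carlo.

## Brain-network metrics

The PLV matrix with zeroed diagonal is the weighted adjacency c_ij. Edge
length for shortest paths is 1/c_ij (strong synchrony = short functional
distance), with a hop-count mode available; a printed formula that
conflates "number of edges" with the weighted network is resolved in
favour of weighted lengths. Metrics:

- weighted clustering C_i = Σ c_ik c_il c_kl / Σ c_ik c_il (closed over
  open weighted triples), 0 when the denominator vanishes;
- characteristic path length L = mean shortest-path length over ordered
  pairs. The printed normalization (N(N−1) multiplying a sum of
  reciprocals) duplicates the efficiency formula up to scale and
  contradicts its own prose, so the standard mean path length is
  implemented, with global efficiency covering the reciprocal form;
- global efficiency G = mean of 1/L_ij, disconnected pairs contributing
  0 (they are excluded from the L mean — the documented
  disconnected-pair policy);
- local efficiency of node i = global efficiency of the subgraph induced
  by its neighbours (node excluded), 0 with fewer than two neighbours;
- betweenness: Brandes-style fractional through-counts over unordered
  pairs; path lengths tied within 1e-9 relative tolerance all count as
  shortest.

Besides the standard normalization, a `traffic_share` mode reproduces the
worked two-branch example in which the relay node on one of two parallel
branches scores one half: the node's per-pair share of shortest-path
traffic, averaged over endpoint pairs whose shortest paths use at least
one intermediary. The printed arithmetic for that example is typeset
corruptly; the implementation reproduces its numerator/denominator
structure ((0.5+0.5)/(0.5+0.5+1.0) = 1/2) and reduces to 1.0 for a pure
relay. The two-branch graph itself is the minimal reconstruction
consistent with that arithmetic.

The feature vector for the PE classifier is the deterministic layout
[C_1..C_N, L, G, Le_1..Le_N, b_1..b_N] (length 3N + 2); an infinite L
(fully disconnected network) is encoded as 0.

## Common spatial patterns

Classic two-class CSP: trace-normalized covariances R_i = XXᵀ/tr(XXᵀ)
averaged per class, composite Rc = R̄1 + R̄2 eigendecomposed, whitening
P = Λc^{-1/2} Ucᵀ. A printed variant of the whitening (Ucᵀ Λc) cannot
satisfy the simultaneous-diagonalization constraint Λ1 + Λ2 = I that the
same derivation imposes, so the standard form is used. The whitened
class-1 covariance is rotated by its eigenvectors B; W = Bᵀ P with rows
as filters, sorted by the class-1 eigenvalue descending, each row's
largest-magnitude entry made positive for reproducibility. A ridge
λ = 1e-6·tr(Rc)/M guards rank deficiency (flag to disable; it perturbs
eigenvalues at the 1e-7 level, which the degeneracy tests account for).

Feature readout from Z = WX uses the first and last m rows. Two
selectors exist because the source phrase "maximum values of 2m rows" is
ambiguous: `row_max` (literal row maxima of |Z|, scales with signal
amplitude) and the standard `log_variance` (log of normalized row
variances, scale-invariant), the default. The three-state problem is
handled one-vs-rest — CSP as derived is strictly two-class — giving
three banks and 6m concatenated features.

## Recurrence representations

A series is delay-embedded (dimension m, delay τ), pairwise state
distances r_ij are measured (Euclidean default; Chebyshev/Manhattan
options), and either the binary plot R_ij = step(ε − r_ij) or the
no-threshold variant ER_ij = |ε − r_ij| is formed. Defaults: m = 3,
τ = 4 for embedded work; m = 1, τ = 1 for the faithful full-resolution
mode in which 1,000 samples give a 1000×1000 matrix. ε defaults to 0 in
the no-threshold variant — ER is then exactly the distance matrix, the
maximally information-preserving choice; the source keeps ε in the
formula but never assigns it a value, so 0 is a package choice (absolute
or quantile settings are available).

Images for the CNN are block-mean downsampled (near-equal blocks) and
scaled to [0, 1]. Per-image min–max is the module default; the pipeline
instead uses a global scale fitted as the 97.5th percentile of training
distances, because the discriminative signal across disease states is
absolute amplitude, which per-image scaling would discard.

## Residual classifier

The classifier follows the staged table: 7×7/64 stride-2 stem; residual
pairs of 3×3 convolutions with widths 64, 64, 128, 128, 256, 256, 512,
128 (the non-monotone final contraction is kept as printed, with a
monotone variant flag), max pooling after the first two pairs; global
average pooling and a 3-way softmax head (the head is absent from the
table and is the standard choice). "D = 2" is read as stride 2: a
dilation reading would never reduce resolution despite three D = 2
entries plus two poolings. Shortcuts are identity where shapes agree and
1×1 strided projections where the width changes; a width change also
halves resolution by default (standard residual-network practice — the
table is silent on it, and `downsample_on_change=False` restores
stride-1 everywhere). Each "(3,3,C)×2" entry is one residual block; the
figure does not resolve whether shortcuts span one or two pairs.

Layers are implemented directly over NumPy (im2col GEMM convolutions,
explicit backpropagation, batch normalization, Adam); training is plain
cross-entropy, defaults lr 1e-3, batch 16, 30 epochs, none of which the
source states. Everything is float32 and seeded; on a fixed BLAS, runs
are bit-reproducible, and the documented tolerance across platforms is
1e-4 on final losses. Inputs are single-channel images, side 64 by
default (32, 128 and 1000 are supported; the stride schedule needs at
least 32).

## Screening, branch classifiers, fusion

Clinical covariates are screened across the three states at α = 0.05
with no multiplicity correction (a Bonferroni flag exists, off by
default): Kruskal–Wallis for continuous features; for binary features an
exact conditional test on the 2×3 contingency table (multivariate
hypergeometric enumeration, Fisher's ordering-by-probability rule)
rather than the asymptotic chi-squared — at ~33 patients per state the
exact test is the statistically correct choice and costs microseconds
(`exact_binary=False` restores chi-squared). Constant features warn and
get p = 1. Note a structural consequence: with three null covariates
each tested at a calibrated level of 0.05, the probability that the
selected set is *exactly* the three real effects is bounded by
(1 − 0.05)³ ≈ 0.86 no matter how powerful the tests are; the package's
measured exact-recovery rate at n = 100 is ≈ 0.88 (400 seeds), with the
three injected effects recovered at every seed.

The PE classifier is a seeded, L2-regularized multinomial logistic
regression over the concatenated CSP features and network metric vector
("input into the constructed PLV network" is read as classification on
the PLV-network-derived features; a literal graph-network reading has no
textual support). The clinical branch is the same model family over the
screened covariates only (z-scored), falling back to the uniform vector
when nothing is screened. Fusion operates on the (PE, RE, clinical)
probability vectors: arithmetic mean, fixed convex weights, or the
default stacked logistic meta-classifier fitted on a held-out fold.
Evaluation reports the fraction of correct 3-way decisions, per-class
one-vs-rest confusion counts with (TP+TN)/total accuracy, and per-class
one-vs-rest ROC/AUC. The class order is fixed as (calm, transitional,
morbidity) everywhere.

## Pipeline and problem sizes

`run_pipeline` wires the stages together on synthetic data: 150
recordings (50 per state, 4 channels, 1,000 samples at 128 Hz), a
stratified 30% test split, and a quarter of the training set held out
for the fusion meta-classifier. The recurrence branch uses one frontal
channel (F3) by default as the desk-scale setting — per-channel images
averaged at the probability level are supported (`rp_channels=("all",)`)
but quadruple the training cost. The acceptance script runs the full
study at these sizes: three training seeds for the recurrence
classifier, one label-shuffled control, 50 seeds per coupling level, 100
screening seeds, and one full pipeline run.

## Known limitations

- Two-class CSP applied one-vs-rest is a heuristic for three classes;
  joint-diagonalization variants are out of scope.
- The recurrence classifier's task difficulty is set by the generator;
  on per-image min–max scaling the problem becomes texture-only and
  materially harder.
- Subject-level effects are not modelled (each recording is an
  independent subject), so the train/test split question that real
  cohorts raise does not arise here; `subject_id` is carried so either
  policy can be exercised with real data.
- EDF import requires the optional `mne` dependency and maps the file
  into the same in-memory recording type; no preprocessing beyond unit
  conversion is applied.
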