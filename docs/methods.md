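# Methods

This note documents the models implemented in `oddball_stda`, their
parameters (with units, defaults, and rationale), what the synthetic-data
generator does and does not emulate, the numerical choices behind the
statistics and the inverse solution, and the package's limitations.
Every quantitative statement here is either a design parameter or a
number computed by the test suite / acceptance script.

## 1. Forward model (`forward_model`)

### Head and montage

The head is a single homogeneous conducting sphere:

| parameter | default | unit | rationale |
|---|---|---|---|
| head radius `R` | 9.2 | cm | adult head scale |
| conductivity `σ` | 0.33 | S/m | standard scalp/brain value |

The 64-channel montage is an *idealized* 10/10 layout constructed
analytically on the sphere by azimuthal-equidistant ("flat-map")
interpolation: midline electrodes sit at 18°-spaced inclinations from Fpz
(72° anterior) to Oz (72° posterior) with Cz exactly at the apex; the
outer ring lies at 72° inclination at 18° azimuth steps; intermediate
rows interpolate linearly in the flat chart. M1/M2 (mastoids) sit below
the equator at 108° inclination, ±100° azimuth. The construction is
exactly mirror-symmetric about the sagittal plane, which the tests assert
to 1e-8; a cross-check against a realistic published template shows
angular agreement to within ~25° for all electrodes (the residual is the
difference between an idealized sphere and a real head shape).

### Source space

Cubic grid with 10 mm spacing inside a concentric "cortical" sphere of
radius 7.8 cm → 1935 voxels. Spacing larger than the sphere diameter
raises an empty-grid error.

### Lead field

The potential of a current dipole **q** (nA·m) at eccentricity *f = b/R*
in a homogeneous sphere has the closed form (electrode at angle
θ = cos⁻¹x from the dipole axis, ê the in-plane unit vector):

V = 1/(4πσR²) · [ (q·b̂)·A(x, f) + (q·(ê − x b̂))·B′(x, f) ]

with g = √(1 − 2fx + f²),
A = 2(x − f)/g³ + (1/g − 1)/f and
B′ = 2/g³ + ((f − x)/g + x)/(f(1 − x²)),
obtained by summing the Legendre expansion with generating-function
identities. The x → ±1 (electrode aligned with the dipole) and f → 0
(central dipole) limits are handled explicitly. Units: µV per nA·m.

*Verification*: an independent truncated Legendre-series oracle
(`scipy.special`) agrees to ~1e-15 µV, including at the limits; a CAR
lead field's columns sum to zero (&lt;1e-10); mirror-symmetric dipoles
produce mirror potentials (1e-8).

Reference schemes: infinite (raw), common average (CAR), linked mastoid.
Dipoles at the exact electrode radius or outside the sphere raise
`SingularGeometryError`.

## 2. Synthetic data (`synthetic_data`)

### Paradigm

| parameter | default | unit |
|---|---|---|
| trials per block | 400 (325 standards + 75 deviants) | — |
| inter-stimulus interval | 950 | ms |
| tone duration / fade | 50 / 5 | ms |
| standard / deviant pitch | 500 / 1000 | Hz |
| tasks | passive, then active | — |
| min. standards between deviants | 1 | — |

Deviant positions are drawn uniformly from all sequences satisfying the
spacing constraint (stars-and-bars construction; the tests verify exact
uniformity by complete enumeration at small sizes).

### ERP components

Each component is a fixed dipole with a unit-peak Gaussian time course
`exp(−(t − t₀)²/2s²)` and a moment per (condition, task) cell:

| component | peak t₀ (ms) | sd s (ms) | position (cm) | orientation | moment (nA·m) |
|---|---|---|---|---|---|
| N1 | 95 | 15 | (5.2, 0.5, 3.0) | tangential, away from vertex | 30 all cells |
| MMN | 100 | 18 | (5.2, 1.0, 3.2) | tangential, away from vertex | 25 deviants only |
| P3 | 300 | 45 | (0, −2, 5) | radial | 20 deviant-passive, 40 deviant-active |

The tangential superior-temporal orientation produces the MMN's
fronto-central negativity with mastoid polarity inversion; the radial
centro-parietal P3 source produces a broad Pz-maximal positivity. The
doubled active-task P3 moment implements the strong task modulation of
target detection. Moments were chosen once, before any statistics were
run, to give physiological scalp amplitudes (MMN difference-wave ~1–3 µV,
P3 ~5–10 µV at Pz).

### Noise model

| parameter | default | unit | role |
|---|---|---|---|
| background dipoles | 200 | — | spatially correlated brain noise |
| background moment sd | 12 | nA·m | per dipole, per sample |
| background low-pass | 12 | Hz | 1/f-like temporal smoothness |
| sensor white noise sd | 4 | µV | electrode/amplifier noise |
| subject amplitude gain sd | 0.2 | — | between-subject variability |

Background noise is white dipole noise projected through the lead field
and zero-phase low-pass filtered; the filter's effect on the variance is
normalized analytically by the zero-phase gain √(mean |H(ω)|⁴) so that
the nominal moment sd is exact in every trial (no per-chunk empirical
rescaling, which would couple trials). Single-trial scalp rms is ~12 µV,
so the ±100 µV artifact threshold rejects a realistic few percent of
trials. Per-subject multiplicative gains `1 + 0.2·N(0,1)` (clipped at
0.1) on each component's moment give group-level sensor t-statistics in
the 4–15 range typical of 12-subject ERP studies.

Behavior in the active task: per-deviant hit indicator (P(hit) = 74.8/75)
and truncated-normal reaction times, location 285.6 ms, scale 38.5 ms,
truncated to [223, 379] ms. Note the truncation is asymmetric about the
location, so the distribution's true mean is 289.09 ms.

### What the generator does and does not emulate

It **does** produce: stimulus-locked dipolar components with realistic
topographies and latencies, spatially correlated band-limited background
EEG plus white sensor noise, between-subject amplitude variability,
artifact-scale outliers (via noise tails), mains interference only in the
sense that the notch stage is exercised on synthetic 50 Hz when tested.

It does **not** emulate: ocular/muscle artifacts with their specific
topographies, latency jitter or amplitude habituation across trials,
overlapping responses from the 1000 ms stimulus-onset asynchrony,
non-Gaussian background statistics, electrode drift or impedance changes,
or any cortical folding (all sources are free dipoles in a sphere).
Between-subject variability is amplitude-only (no per-subject head or
source-position differences) — a deliberate simplification; its main
visible consequence at the source level is discussed in §6.

Two generation paths exist: `full` synthesizes continuous 2048 Hz
recordings that go through the entire preprocessing chain, and `fast`
generates baseline-corrected 512 Hz epochs directly (identical
statistical structure; used for desk-scale studies and tests).

## 3. Preprocessing (`preprocessing`)

Zero-phase (forward–backward) 2nd-order Butterworth band-pass 0.5–20 Hz
(24 dB/oct effective roll-off), 50 Hz IIR notch (Q = 30), polyphase
resampling 2048 → 512 Hz, re-referencing (CAR = mean of the 62 scalp
channels, subtracted from all 64; or linked mastoids), epoching −100 to
+700 ms with the sample grid anchored at −100 ms (sample k has latency
tmin + k·1000/srate — this convention makes the 50–150 ms window at
512 Hz contain exactly 52 samples, hence 62 × 52 = 3224 comparisons),
baseline correction by the mean over the closed interval [−100, 0] ms,
and rejection of epochs exceeding ±100 µV in 0–400 ms. Events too close
to the recording edges are skipped with a warning. Filters are verified
against their frequency-response specifications (±0.5 dB at 10 Hz,
≥30 dB at 50 Hz).

Zero-phase filtering is a choice: it preserves component latencies
(causal filtering would delay them) at the cost of acausal smearing.

## 4. Sensor statistics (`mass_univariate`, `cluster_perm`, `erp_analysis`)

All tests are paired sign-flip permutation tests on subject-level
condition differences. Conventions:

- **Enumeration**: with S subjects, all 2^S sign assignments are used
  whenever 2^S ≤ n_perm (S = 12 → 4096 ≥ most defaults); otherwise
  n_perm random assignments. The observed (all-ones) assignment is always
  a row, so p ≥ 1/N; the global flip ties the observed statistic exactly,
  so in enumeration p ≥ 2/2^S.
- **One t formula**: the permutation t is computed from the flip-invariant
  sum of squares, t = m̄/√((SS/n − m̄²)/(n−1)·1/n) vectorized over sign
  matrices (a GEMM), and the *observed* t uses the same formula (all-ones
  sign row). Using a different (algebraically equal) formula for the
  observed statistic can break the identity-row tie by catastrophic
  cancellation on near-degenerate data and produce spurious p = 0; this
  is why `signflip_t` is shared by the point-wise, cluster, and SnPM
  tests. Ties are compared with a 1e-12 absolute guard.
- **Degenerate cells** (all differences zero): t = 0, p = 1.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels) jointly over all
  channel × sample cells of the analysis window.
- **Window of maximum significance**: per-sample significant-electrode
  counts; the longest contiguous run of samples with count ≥ 90% of the
  global maximum (earliest run on ties), plus the electrodes significant
  anywhere in it.
- **Cluster test**: inclusion threshold t at two-tailed α = 0.01 with
  S−1 df; adjacency = scalp electrodes within 5.44 cm (chosen to give
  first-and-second-neighbor connectivity on the idealized montage;
  mastoids excluded); edges connect spatial neighbors at the same sample
  and the same electrode at adjacent samples; positive and negative
  excursions cluster separately; cluster mass = sum of member t-scores;
  the max-|mass| permutation distribution calibrates family-wise error;
  member cells inherit the cluster p, cells outside any cluster get p = 1.
- **Effect size**: paired Cohen's d = mean(diff)/sd(diff).
- **MMN checks**: difference wave = deviant − standard evoked; polarity
  check (on CAR data) requires strictly negative window means at Fz, FCz,
  Cz *and* strictly positive means at M1, M2 in 70–130 ms. Peak
  description returns the extremum of stated polarity (earliest on ties)
  and its half-maximum extent.

Analysis windows: early 50–150 ms (N1/MMN), late 200–450 ms (P3),
post-stimulus 0–700 ms (task contrasts).

*Measured calibration* (acceptance suite, null Gaussian data): point-wise
per-cell type-I error 0.049 over 500 simulations; cluster-mass FWER 0.07
and SnPM FWER 0.05 over 200 simulations each at nominal 0.05; BH mean
false-discovery proportion 0.042 with 10% true effects of d = 1.5 over
200 simulations. A 300-simulation null distribution of the minimum
cluster p is uniform to Monte-Carlo precision (P(p ≤ 0.05) = 0.043
against an attainable 0.0499), so a 200-simulation FWER estimate carries
an MC standard deviation of ~0.015.

## 5. sLORETA (`sloreta`)

Minimum-norm kernel with Tikhonov regularization and average-reference
centering, standardized by the resolution matrix:

- T = Kᵀ(K Kᵀ + α·tr(K Kᵀ)/C · H)⁺, K the (C × 3V) CAR lead field, H the
  centering matrix, α = 1e-3 (relative regularization; default chosen as
  a conventional small value, not tuned).
- The pseudo-inverse is computed by symmetric eigendecomposition keeping
  eigenvalues > 1e-12 × max. This matters: the CAR Gram matrix is rank
  deficient, and a generic SVD pinv can retain junk near-null directions
  that bias the kernel at the 1e-2 level.
- Resolution blocks R_vv = (T K)_vv (3×3 per voxel) are symmetrized and
  pseudo-inverted with an eigenvalue floor of 1e-10 relative to each
  block's largest eigenvalue; the standardized power at voxel v is
  ĵ_vᵀ R_vv⁺ ĵ_v (unitless; invariant to overall data scaling).
- Orientation modes: `free` (3D moments) or `fixed-radial`.

*Verified properties*: exact zero localization error — for a noiseless
single-dipole topography at each of the 1935 grid voxels with random
moment, the standardized image argmax is the true voxel in 100% of
voxels (the acceptance suite requires ≥99%); agreement with an independently coded
textbook operator at 1e-8; mirror symmetry; invariance to input units.

## 6. SnPM (`snpm`) and source-level recovery

Voxel-wise paired sign-flip t-tests with maximum-statistic correction:
t_crit(α) is the (c+1)-th largest value of the permutation max-|t|
distribution with c = ⌊α·N⌋ (the observed assignment is one of the N
rows); a voxel with |t| strictly above t_crit has corrected p < α.
Suprathreshold voxels form 6-connected (face-adjacent) lattice regions;
regions of fewer than 9 voxels are discarded (the study-style reporting
rule). Region tables report hemisphere, peak coordinates, signed max/min
member t, and voxel count.

**Source leakage and the recovery metric.** On a homogeneous sphere,
sLORETA's point-spread for a focal source is very smooth, and with
multiplicative between-subject amplitude variability the voxel-wise
paired t-map is approximately constant-CV across the leakage blob: the
suprathreshold region of an implanted P3 source spans a large fraction of
the source space (measured region sizes ~900–1600 of 1935 voxels across
20 replicates) and the location of its maximum-t voxel scatters within
the blob (~3–4 cm from the source). The *group-mean image* argmax, by
contrast, is exact. Consequently a "region centroid within 2 voxels of
the truth" criterion is not meaningful in this geometry — compact
regions require a cortically constrained solution space and richer
inter-subject heterogeneity, both out of scope. The recovery quantity
reported by the package is therefore the distance from the implanted
source to the **nearest member voxel of the peak (max-|t|) region** —
i.e., does the detected region cover or abut the true source — with the
peak-voxel distance reported as a secondary number. Measured over 20
replicate 12-subject studies: median nearest-member distance 0.00 cm
(the region contains the source in every replicate); median peak-voxel
distance ~3.1–3.7 cm.

The replicate experiment uses an exact distributional shortcut: because
the generator's noise is Gaussian and averaging is linear, an N-trial
evoked's noise equals (in distribution) a single draw scaled by 1/√N;
this reduces each replicate group study to 12 topography pairs without
changing any distribution.

## 7. Pipeline (`pipeline`, `calibration`, `cli`)

`run_study` chains: forward model → per-subject simulation (+full
preprocessing in `full` mode; linked-mastoid re-referencing + rejection
in `fast` mode) → condition evokeds (linked-mastoid for sensor stats,
CAR copies for polarity and sources) → grand averages and polarity
checks → for each contrast and window: point-wise permutation maps, FDR
window of maximum significance, cluster-mass test, Cohen's d → for each
significant sensor window: per-subject window-averaged CAR topographies,
sLORETA images, SnPM contrast, region tables. If no sensor window is
significant the source stage for that contrast is skipped with a logged
notice. Everything derives from a single integer seed (per-stage
sub-seeds via `numpy` SeedSequence lists and CRC32 of subject labels, so
runs are bit-identical across processes).

Default sizes mirror a realistic study and are package choices: 12
subjects, 5000 point-wise permutations (enumeration caps at 2^12 = 4096),
2500 cluster permutations, 5000 SnPM permutations, q = 0.05,
family α = 0.05, SnPM α ∈ {0.05, 0.01}, minimum region size 9 voxels.

A note on small studies: with S subjects the permutation p-floor is
2/2^S; over thousands of FDR cells the BH cutoff at the floor requires
hundreds of floor-level cells, so FDR windows are generally only
attainable with the full 12-subject enumeration (the 8-subject example
honestly reports "no window").

`calibration` holds the Monte-Carlo experiments behind §4–§5's measured
numbers. The CLI (`oddball-stda simulate|preprocess|stats|sources|run-all`)
drives the same functions from YAML configurations.

## 8. Limitations

- Single-sphere homogeneous head: no skull/scalp conductivity layers, no
  realistic geometry; absolute potentials and localization blur are not
  quantitatively comparable to real heads.
- Source space is a volumetric grid of free dipoles, not a cortical
  surface; SnPM regions are therefore large (§6).
- Between-subject variability is amplitude-only; real inter-subject
  latency/topography variability would lower sensor t-values further and
  break the constant-CV plateau differently.
- The generator's Gaussianity is what makes the evoked-noise 1/√N
  shortcut exact; with non-Gaussian noise it would be approximate.
- Behavioral simulation is descriptive (truncated-normal RTs, Bernoulli
  hits); it carries no latent decision model.
- Permutation tests assume exchangeability of paired differences under
  sign flips (exact here by construction of the generator).
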