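# oddball-stda

**Spatio-temporal deviance and target detection analysis for auditory
oddball EEG** — a simulation and inference toolbox covering the full
pipeline of a classic passive/active oddball group study: forward
modeling, synthetic data generation, preprocessing, ERP extraction,
mass-univariate and cluster-based permutation statistics, sLORETA source
imaging, and statistical non-parametric mapping (SnPM).

## The scientific problem

In the auditory oddball paradigm a stream of frequent *standard* tones
(500 Hz) is interrupted by rare *deviant* tones (1000 Hz). Deviants evoke
the **mismatch negativity (MMN)**, a fronto-central negativity around
100 ms that inverts polarity at the mastoids, and — when the listener
actively responds to deviants — a large centro-parietal **P3** positivity
around 300 ms. A group study asks:

1. *Where and when* do deviant and standard ERPs differ, with principled
   control of the thousands of electrode × time comparisons?
2. *Does the task* (passive listening vs. active target detection)
   modulate early (N1/MMN) or only late (P3) processing?
3. *Which sources* generate the effects, inferred from scalp topographies?

Real studies answer these with non-parametric paired permutation tests
(FDR-corrected point-wise maps and cluster-mass tests), distributed
inverse solutions (sLORETA), and max-statistic SnPM on the source images.
This package implements all of those pieces with exhaustively testable
numerics, plus a forward simulator that generates EEG with known ground
truth so every inferential claim can be validated against the truth that
produced the data.

## The model

- **Head / forward model** — homogeneous conducting sphere (radius
  9.2 cm, conductivity 0.33 S/m) with the closed-form current-dipole
  potential; an idealized 64-channel 10/10 montage (62 scalp + 2
  mastoids); cubic source grid (1 cm spacing, 1935 voxels) inside a
  7.8 cm "cortical" sphere. Infinite, common-average, and linked-mastoid
  references.
- **Synthetic data** — three dipolar components with Gaussian time
  courses: N1 (95 ms, both conditions), MMN (100 ms, deviants only,
  tangential superior-temporal source), P3 (300 ms, deviants only,
  doubled amplitude in the active task); background noise from hundreds
  of random low-pass-filtered brain dipoles plus white sensor noise;
  per-subject amplitude gains; truncated-normal reaction times.
- **Preprocessing** — zero-phase 0.5–20 Hz band-pass, 50 Hz notch,
  downsampling to 512 Hz, re-referencing, epoching (−100…700 ms),
  baseline correction, ±100 µV artifact rejection.
- **Inference** — paired sign-flip permutation t-tests (exhaustive 2^S
  enumeration when feasible), BH-FDR over all electrode × time cells,
  spatio-temporal cluster-mass tests with electrode-distance adjacency,
  paired Cohen's d; sLORETA standardized inverse with exact zero
  localization error for noiseless point sources; SnPM max-|t| corrected
  thresholds and 6-connected suprathreshold regions.

See [docs/methods.md](docs/methods.md) for equations, parameter tables,
and numerical choices.

## Worked example

Simulate a 6-subject passive oddball group (400 trials each, 75
deviants), extract the deviant-minus-standard difference wave, and check
the MMN's mastoid polarity inversion
([examples/02_simulate_and_erp.py](examples/02_simulate_and_erp.py)):

```text
epochs per subject: 400 trials x 64 channels x 410 samples at 512 Hz
MMN at FCz: peak -1.73 uV at 81.6 ms, half-max window 58.2-103.1 ms
mastoid polarity inversion: PASS
  Fz  window mean: -0.21 uV
  FCz window mean: -0.86 uV
  Cz  window mean: -0.83 uV
  M1  window mean: +0.37 uV
  M2  window mean: +3.42 uV

active-block behavior: 75/75 hits, mean RT 285.0 ms
```

Group sensor statistics on a desk-scale 8-subject study
([examples/03_sensor_statistics.py](examples/03_sensor_statistics.py)) —
the deviance effect appears as a large negative cluster in the MMN range
and the task effect is late-only, as expected for a P3 modulation:

```text
clusters, deviant vs standard (passive), 50-150 ms:
 sign         mass  p_value  n_points  t_start_ms   t_end_ms
   -1 -1120.914562 0.015625       249   83.593750 130.468750
    1   229.512502 0.039062        43   73.828125 112.890625
   ...

task comparison (deviants active vs passive):
  early_effect: False
  late_effect: True
  late_onsets_ms: [275.0]
  late_p_values: [0.0078125]
```

Source imaging
([examples/04_source_imaging.py](examples/04_source_imaging.py)) —
sLORETA localizes a noiseless dipole exactly, and the SnPM group test
recovers the implanted P3 source inside its peak suprathreshold region in
every replicate:

```text
noiseless dipole: true voxel 942, image peak 942, localization error 0.00 cm

group SnPM recovery of the implanted P3 source (20 replicates):
  true source position (cm): [0.0, -2.0, 5.0]
  median distance to nearest voxel of the peak region: 0.00 cm (0.00 grid spacings)
  median distance to the region's peak voxel: 3.74 cm
  region sizes: min 912, max 1598 of 1935 voxels
```

(On a homogeneous sphere the suprathreshold region is necessarily broad —
see the "source leakage" discussion in docs/methods.md.)

The same pipeline runs from the shell:

```bash
oddball-stda run-all --config study.yaml --seed 3 --out results/
# subcommands: simulate | preprocess | stats | sources | run-all
```

## Repository layout

```
src/oddball_stda/    library (forward_model, synthetic_data, preprocessing,
                     erp_analysis, mass_univariate, cluster_perm, sloreta,
                     snpm, calibration, pipeline, cli)
examples/            narrative scripts 01-05, one per capability
tests/               pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py  headline-quantity runner (JSON output)
docs/methods.md      models, parameters, numerics, limitations
```
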