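"""Simulate a small oddball group and extract ERPs.

Generates epoched EEG for the passive block (400 tones, 75 deviants per
subject) with the default N1/MMN/P3 components and background noise,
averages the two conditions per subject, grand-averages across subjects,
forms the deviant-minus-standard difference wave, and checks the mastoid
polarity inversion of the MMN.
"""

import numpy as np

from oddball_stda.erp_analysis import (
    average_evoked,
    describe_peak,
    difference_wave,
    grand_average,
    mmn_polarity_check,
)
from oddball_stda.forward_model import (
    build_source_grid,
    compute_leadfield,
    standard_montage_1010,
)
from oddball_stda.synthetic_data import (
    NoiseModel,
    ParadigmConfig,
    _subject_gains,
    default_components,
    simulate_behavior,
    simulate_epochs,
)

montage = standard_montage_1010()
grid = build_source_grid()
leadfield = compute_leadfield(montage, grid, reference="CAR")

cfg = ParadigmConfig()  # 400 trials, 75 deviants, ISI 950 ms
components = default_components()
n_subjects = 6
gains = _subject_gains(components, n_subjects, 0.2, seed=7)
devs, stds = [], []
for s in range(n_subjects):
    epochs = simulate_epochs(cfg, components, NoiseModel(), montage, leadfield,
                             task="passive", subject=f"S{s:02d}",
                             subject_gain=gains[s], seed=7)
    devs.append(average_evoked(epochs, "deviant", "passive"))
    stds.append(average_evoked(epochs, "standard", "passive"))
print(f"epochs per subject: {epochs.n_trials} trials x "
      f"{len(epochs.channel_labels)} channels x {epochs.n_samples} samples "
      f"at {epochs.srate_hz:g} Hz")

diff = difference_wave(grand_average(devs), grand_average(stds))

peak = describe_peak(diff, "FCz", "negative", (50.0, 150.0))
lo, hi = peak["halfmax_window_ms"]
print(f"MMN at FCz: peak {peak['amplitude_uV']:+.2f} uV at "
      f"{peak['latency_ms']:.1f} ms, half-max window {lo:.1f}-{hi:.1f} ms")

ok, means = mmn_polarity_check(diff)
print("mastoid polarity inversion:", "PASS" if ok else "FAIL")
for label, v in means.items():
    print(f"  {label:3s} window mean: {v:+.2f} uV")

behavior = simulate_behavior(cfg, seed=7)
print(f"\nactive-block behavior: {behavior.n_hits}/{behavior.hit.size} hits, "
      f"mean RT {behavior.rt_ms[behavior.hit].mean():.1f} ms")
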