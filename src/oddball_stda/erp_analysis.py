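"""Condition averaging, difference waves (MMN / P3 effects), peak description,
and the mastoid polarity-inversion check for the mismatch negativity.

A difference wave is the elementwise subtraction of two condition-averaged
ERPs (deviant minus standard); under a common average reference a genuine
MMN generated in the supratemporal plane is negative at fronto-central
sites and inverts polarity at the mastoids below the Sylvian fissure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

__all__ = [
    "Evoked",
    "DifferenceWave",
    "average_evoked",
    "grand_average",
    "difference_wave",
    "mmn_polarity_check",
    "describe_peak",
]


@dataclass
class _Waveform:
    data: np.ndarray  # (n_channels, n_samples), uV
    srate_hz: float
    tmin_ms: float
    channel_labels: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.srate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        t = self.times_ms
        return (t >= lo_ms) & (t <= hi_ms)

    def to_frame(self) -> pd.DataFrame:
        """time x channels table for export/plotting."""
        df = pd.DataFrame(self.data.T, columns=list(self.channel_labels))
        df.insert(0, "time_ms", self.times_ms)
        return df


@dataclass
class Evoked(_Waveform):
    """Trial-averaged ERP for one (condition, task) cell of one subject."""

    n_trials: int = 1
    condition: str = ""
    task: str = ""
    subject: str = ""

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("an Evoked must average at least one trial")


@dataclass
class DifferenceWave(_Waveform):
    """Elementwise difference of two Evoked waveforms (minuend - subtrahend)."""

    minuend: str = "deviant"
    subtrahend: str = "standard"
    task: str = ""
    subject: str = ""


def average_evoked(epochs: EpochSet, condition: str, task: str) -> Evoked:
    """Arithmetic mean over all epochs matching (condition, task)."""
    sel = epochs.select(condition=condition, task=task)
    if sel.n_trials == 0:
        raise ValueError(f"no epochs match condition={condition!r}, task={task!r}")
    return Evoked(sel.data.mean(axis=0), epochs.srate_hz, epochs.tmin_ms,
                  epochs.channel_labels, n_trials=sel.n_trials,
                  condition=condition, task=task, subject=epochs.subject)


def grand_average(evokeds: list[Evoked]) -> Evoked:
    """Equal-weight average over subjects (conventional grand average)."""
    if not evokeds:
        raise ValueError("no evokeds to average")
    first = evokeds[0]
    for e in evokeds[1:]:
        _check_axes(first, e)
    data = np.mean([e.data for e in evokeds], axis=0)
    return Evoked(data, first.srate_hz, first.tmin_ms, first.channel_labels,
                  n_trials=sum(e.n_trials for e in evokeds),
                  condition=first.condition, task=first.task, subject="grand")


def _check_axes(a: _Waveform, b: _Waveform) -> None:
    if (a.data.shape != b.data.shape or a.srate_hz != b.srate_hz
            or a.tmin_ms != b.tmin_ms or a.channel_labels != b.channel_labels):
        raise ValueError("waveforms have mismatched channel/time axes")


def difference_wave(dev: Evoked, std: Evoked) -> DifferenceWave:
    """Deviant-minus-standard difference wave."""
    _check_axes(dev, std)
    return DifferenceWave(dev.data - std.data, dev.srate_hz, dev.tmin_ms,
                          dev.channel_labels, minuend=dev.condition,
                          subtrahend=std.condition, task=dev.task,
                          subject=dev.subject)


def mmn_polarity_check(diff: DifferenceWave,
                       frontocentral: tuple[str, ...] = ("Fz", "FCz", "Cz"),
                       mastoids: tuple[str, ...] = ("M1", "M2"),
                       window_ms: tuple[float, float] = (70.0, 130.0),
                       ) -> tuple[bool, dict]:
    """Mastoid polarity-inversion check on a CAR-referenced difference wave.

    True iff the window-mean is strictly negative at every fronto-central
    probe and strictly positive at both mastoids.  Returns the decision and
    the per-channel window means.
    """
    mask = diff.time_mask(*window_ms)
    if not mask.any():
        raise ValueError("window contains no samples")
    means = {}
    for label in (*frontocentral, *mastoids):
        means[label] = float(diff.data[diff.channel_index(label), mask].mean())
    ok = (all(means[l] < 0 for l in frontocentral)
          and all(means[l] > 0 for l in mastoids))
    return ok, means


def describe_peak(wave: _Waveform, channel: str, polarity: str,
                  search_window_ms: tuple[float, float]) -> dict:
    """Extremum of the stated polarity within the window, plus half-max extent.

    polarity "negative" finds the minimum, "positive" the maximum.  Ties
    break to the earliest sample.  The half-max window is the contiguous run
    of samples around the peak whose amplitude stays >= 50% of |peak|.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    mask = wave.time_mask(*search_window_ms)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("empty search window")
    ch = wave.channel_index(channel)
    trace = wave.data[ch]
    signed = trace if polarity == "positive" else -trace
    k_local = int(np.argmax(signed[idx]))  # argmax returns the first maximum
    k = idx[k_local]
    peak_amp = trace[k]
    half = abs(peak_amp) / 2.0
    lo = k
    while lo - 1 >= 0 and signed[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi + 1 < wave.n_samples and signed[hi + 1] >= half:
        hi += 1
    t = wave.times_ms
    return {
        "channel": channel,
        "latency_ms": float(t[k]),
        "amplitude_uV": float(peak_amp),
        "halfmax_window_ms": (float(t[lo]), float(t[hi])),
    }
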