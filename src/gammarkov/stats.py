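"""Spike-train statistics: firing rates, synchrony, spectra, correlograms,
and multiple-firing-event (spiking volley) detection.

All statistics operate on :class:`~gammarkov.containers.SpikeTrain` and are
invariant under a global time shift of the train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import POP_E, POP_I, SpikeTrain

__all__ = [
    "PSDResult",
    "MFEList",
    "firing_rates",
    "ssi",
    "psd",
    "psd_peak",
    "spectrogram",
    "correlation_diagram",
    "detect_mfes",
]


def firing_rates(train: SpikeTrain, n_e: int, n_i: int,
                 t_start: float = 1000.0,
                 t_end: float | None = None) -> tuple[float, float]:
    """Mean firing rates (Hz): spikes per neuron per second, by population.

    By default the first second is discarded to wash out the initial
    condition; the analysis window must be non-empty and lie within the
    simulated span.
    """
    if t_end is None:
        t_end = train.duration
    if not (0.0 <= t_start < t_end <= train.duration + 1e-9):
        raise ValueError(
            f"empty or out-of-range analysis window [{t_start}, {t_end}] "
            f"for a {train.duration} ms train"
        )
    sel = (train.times >= t_start) & (train.times < t_end)
    secs = (t_end - t_start) / 1000.0
    n_e_spk = int((train.pops[sel] == POP_E).sum())
    n_i_spk = int((train.pops[sel] == POP_I).sum())
    return n_e_spk / (n_e * secs), n_i_spk / (n_i * secs)


def ssi(train: SpikeTrain, n_neurons: int | None = None,
        w: float = 5.0) -> float | None:
    """Spike synchrony index.

    For each spike at time ``t``, the fraction of all neurons in the
    network with at least one spike in the open window
    ``(t - w/2, t + w/2)`` — the reference neuron included — averaged over
    all spikes.  Equals 1 for full population synchrony and is near 0 for
    sparse uncorrelated firing.  Returns ``None`` for an empty train.
    """
    if len(train) == 0:
        return None
    n = train.n_neurons if n_neurons is None else n_neurons
    t = train.times
    ids = train.neurons
    total = 0.0
    half = w / 2.0
    lo_all = np.searchsorted(t, t - half, side="right")
    hi_all = np.searchsorted(t, t + half, side="left")
    for k in range(t.size):
        total += np.unique(ids[lo_all[k]:hi_all[k]]).size
    return total / (t.size * n)


@dataclass
class PSDResult:
    """Population power spectral density.

    ``power[k]`` is ``|mu_hat(f_k)|**2`` where ``mu_hat`` is the DFT of
    the per-bin, per-neuron spike density; the frequency grid consists of
    multiples of ``1/T``.
    """

    frequencies: np.ndarray  # Hz
    power: np.ndarray
    dt: float  # bin width, ms
    interval: tuple[float, float]  # analysis interval, ms


def psd(train: SpikeTrain, dt: float = 1.0,
        interval: tuple[float, float] | None = None) -> PSDResult:
    """Population PSD from 1-ms-binned spike density.

    The density is ``mu_n = m_n / (N dt)`` with ``m_n`` the network spike
    count in bin ``n``; the spectrum is ``|(1/T) sum_n mu_n dt
    exp(-2 pi i f n dt)|**2`` on the grid ``f = k/T``.  An interval that is
    not a whole number of bins is trimmed.
    """
    if interval is None:
        interval = (0.0, train.duration)
    t0, t1 = interval
    n_bins = int((t1 - t0) / dt)
    if n_bins < 1:
        raise ValueError("analysis interval shorter than one bin")
    t1 = t0 + n_bins * dt
    counts, _ = np.histogram(train.times, bins=n_bins, range=(t0, t1))
    dt_s = dt / 1000.0
    T_s = n_bins * dt_s
    mu = counts / (train.n_neurons * dt_s)  # spikes per neuron per second
    mu_hat = np.fft.rfft(mu) * dt_s / T_s
    freqs = np.fft.rfftfreq(n_bins, dt_s)
    return PSDResult(frequencies=freqs, power=np.abs(mu_hat) ** 2,
                     dt=dt, interval=(t0, t1))


def psd_peak(result: PSDResult, f_min: float = 15.0) -> float:
    """Frequency (Hz) of the maximum PSD power at or above ``f_min``
    (excluding the DC/slow trend)."""
    m = result.frequencies >= f_min
    if not m.any():
        raise ValueError("no frequencies at or above f_min")
    return float(result.frequencies[m][np.argmax(result.power[m])])


def spectrogram(train: SpikeTrain, window: float = 256.0,
                stride: float = 10.0, dt: float = 1.0):
    """Sliding-window PSD: ``(window_start_times, frequencies, power)``
    with ``power[i, k]`` the PSD of window ``i``."""
    starts = np.arange(0.0, train.duration - window + 1e-9, stride)
    if starts.size == 0:
        raise ValueError("train shorter than one spectrogram window")
    rows = []
    freqs = None
    for s in starts:
        r = psd(train, dt=dt, interval=(s, s + window))
        freqs = r.frequencies
        rows.append(r.power)
    return starts, freqs, np.array(rows)


def correlation_diagram(train: SpikeTrain, ref_pop: int, target_pop: int,
                        half_window: float = 15.0,
                        bin_width: float = 1.0):
    """Spike-timing correlogram conditioned on reference-population spikes.

    For each reference spike at ``t``, target-population spikes in
    ``[t - half_window, t + half_window]`` are binned into ``bin_width``-ms
    bins as fractions of the target spikes in that window, then averaged
    over reference spikes (windows with no target spike contribute zeros).
    Returns ``(lag_bin_centers_ms, mean_fraction_profile)``; ``None`` if
    the reference population never fires.
    """
    ref_t = train.times[train.pops == ref_pop]
    tgt_t = train.times[train.pops == target_pop]
    n_bins = int(round(2 * half_window / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width - half_window
    if ref_t.size == 0:
        return None
    profile = np.zeros(n_bins)
    lo = np.searchsorted(tgt_t, ref_t - half_window, side="left")
    hi = np.searchsorted(tgt_t, ref_t + half_window, side="right")
    for k in range(ref_t.size):
        seg = tgt_t[lo[k]:hi[k]] - ref_t[k]
        if seg.size == 0:
            continue
        counts, _ = np.histogram(seg, bins=n_bins,
                                 range=(-half_window, half_window))
        profile += counts / seg.size
    return centers, profile / ref_t.size


@dataclass
class MFEList:
    """Detected multiple firing events (spiking volleys).

    ``intervals[k] = (start_ms, end_ms)``; ``counts[k]`` is the spike count
    inside.  Waiting times are start-to-start gaps.
    """

    intervals: np.ndarray  # (n, 2) ms
    counts: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def durations(self) -> np.ndarray:
        if len(self) == 0:
            return np.empty(0)
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def waiting_times(self) -> np.ndarray:
        if len(self) < 2:
            return np.empty(0)
        return np.diff(self.intervals[:, 0])


def detect_mfes(train: SpikeTrain, bin_width: float = 1.0,
                delta: float = 0.33, epsilon: int = 8,
                gap_tolerance: int = 1) -> MFEList:
    """Detect spiking volleys from the binned population spike count.

    A bin is *elevated* when its count exceeds ``(1 + delta)`` times the
    mean bin count; an MFE is a maximal run of elevated bins (interrupted
    by at most ``gap_tolerance`` quiet bins) whose total spike count is at
    least ``epsilon``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(train) == 0:
        return MFEList(np.empty((0, 2)), np.empty(0, dtype=np.int64))
    # bins anchored at the first spike, covering the spike span, so the
    # detection is invariant under a global time shift of the train
    t0 = float(train.times.min())
    span = float(train.times.max()) - t0
    n_bins = max(int(np.ceil(span / bin_width)), 1)
    counts, _ = np.histogram(train.times, bins=n_bins,
                             range=(t0, t0 + n_bins * bin_width))
    threshold = (1.0 + delta) * counts.mean()
    elevated = counts > threshold
    intervals = []
    mfe_counts = []
    k = 0
    while k < n_bins:
        if not elevated[k]:
            k += 1
            continue
        start = k
        end = k
        j = k + 1
        gap = 0
        while j < n_bins:
            if elevated[j]:
                end = j
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
            j += 1
        total = int(counts[start:end + 1].sum())
        if total >= epsilon:
            intervals.append((t0 + start * bin_width,
                              t0 + (end + 1) * bin_width))
            mfe_counts.append(total)
        k = end + 1 + gap_tolerance + 1
    if not intervals:
        return MFEList(np.empty((0, 2)), np.empty(0, dtype=np.int64))
    return MFEList(np.array(intervals), np.array(mfe_counts, dtype=np.int64))
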