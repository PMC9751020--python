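"""Spike detection and response metrics."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np


def detect_spikes(
    t: np.ndarray,
    vm: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 1e-3,
) -> np.ndarray:
    """Upward threshold crossings separated by at least ``refractory``.

    ``t`` must be uniformly sampled; ``vm`` and ``threshold`` share units
    (volts in this package).  Returns crossing times (possibly empty).
    """
    t = np.asarray(t, float)
    vm = np.asarray(vm, float)
    if t.size != vm.size:
        raise ValueError("t and vm must have equal length")
    if t.size < 2:
        return np.empty(0)
    crossings = np.where((vm[:-1] < threshold) & (vm[1:] >= threshold))[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = t[crossings]
    kept = [times[0]]
    for ts in times[1:]:
        if ts - kept[-1] >= refractory:
            kept.append(ts)
    return np.asarray(kept)


def compute_latency(spike_times: Sequence[float], onset: float) -> Optional[float]:
    """Delay from stimulus onset to the first subsequent spike (or None)."""
    if onset < 0:
        raise ValueError("onset must be >= 0")
    spikes = np.asarray(spike_times, float)
    spikes = spikes[spikes >= onset]
    if spikes.size == 0:
        return None
    return float(spikes[0] - onset)


def compute_firing_rate(
    spike_times: Sequence[float],
    stim_window: Tuple[float, float],
) -> Optional[float]:
    """Mean of reciprocal inter-spike intervals inside the window.

    Consecutive spike pairs with both spikes in ``stim_window`` count;
    returns None when fewer than two spikes fall inside it.
    """
    t0, t1 = stim_window
    spikes = np.asarray(spike_times, float)
    spikes = spikes[(spikes >= t0) & (spikes <= t1)]
    if spikes.size < 2:
        return None
    isi = np.diff(spikes)
    return float(np.mean(1.0 / isi))
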