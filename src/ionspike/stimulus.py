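"""Synaptic input generation and current-clamp protocols.

Spike trains are homogeneous Poisson processes, the standard model of
spiking activity arriving from other neurons in the network.  Multi-site
input is either *uncorrelated* (one independent train per site, drawn from
disjoint sub-streams of the seed) or *correlated* (a single mother train
shared by all sites, optionally jittered per site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in milliseconds within [t_start, t_stop]."""

    times: np.ndarray
    t_start: float = 0.0
    t_stop: float = 1000.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size:
            if np.any(np.diff(t) <= 1e-9):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < self.t_start or t[-1] > self.t_stop:
                raise ValueError("spike times outside the window")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CurrentClampSpec:
    """Square current pulse: ``amplitude`` pA injected during [onset, onset+duration)."""

    amplitude_pA: float
    onset_ms: float = 0.0
    duration_ms: float = 1e9

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("clamp duration must be > 0")

    def current_pA(self, t: float) -> float:
        on = self.onset_ms <= t < self.onset_ms + self.duration_ms
        return self.amplitude_pA if on else 0.0


def poisson_train(
    rate_hz: float,
    window: tuple[float, float] = (0.0, 1000.0),
    rng_seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Sample a homogeneous Poisson spike train at ``rate_hz`` over ``window`` (ms).

    Uses the conditional-uniform construction: the event count is Poisson
    with mean rate × duration, and event times are iid uniform in the window.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    rng = np.random.default_rng(rng_seed)
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    times = np.sort(rng.uniform(t0, t1, size=n))
    # collapse numerically coincident events (probability ~0)
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > 1e-9])
        times = times[keep]
    return SpikeTrain(times=times, t_start=t0, t_stop=t1)


def make_inputs(
    n_sites: int,
    rate_hz: float,
    window: tuple[float, float] = (0.0, 1000.0),
    correlated: bool = False,
    jitter_sd_ms: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
) -> list[SpikeTrain]:
    """Spike trains for ``n_sites`` synapses.

    Uncorrelated: independent Poisson trains from disjoint child streams of
    the seed.  Correlated: one mother train replicated to every site; with
    ``jitter_sd_ms > 0`` each site receives an independently Gaussian-jittered
    copy (clipped to the window, re-sorted).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    seq = (rng_seed.spawn(1)[0] if isinstance(rng_seed, np.random.SeedSequence)
           else np.random.SeedSequence(rng_seed))
    children = seq.spawn(n_sites + 1)
    if not correlated:
        return [poisson_train(rate_hz, window, np.random.default_rng(children[i]))
                for i in range(n_sites)]
    mother = poisson_train(rate_hz, window, np.random.default_rng(children[-1]))
    if jitter_sd_ms == 0.0:
        return [mother] * n_sites
    out = []
    for i in range(n_sites):
        rng = np.random.default_rng(children[i])
        t = mother.times + rng.normal(0.0, jitter_sd_ms, size=mother.times.size)
        t = np.sort(np.clip(t, window[0], window[1]))
        if t.size > 1:  # enforce strict increase after jitter
            for k in range(1, t.size):
                if t[k] <= t[k - 1]:
                    t[k] = t[k - 1] + 1e-6
        t = t[t <= window[1]]
        out.append(SpikeTrain(times=t, t_start=window[0], t_stop=window[1]))
    return out


def trains_to_csv(trains: list[SpikeTrain], path) -> None:
    """Write trains as CSV rows (site_id, spike_time_ms)."""
    import pandas as pd

    rows = [(i, t) for i, tr in enumerate(trains) for t in tr.times]
    pd.DataFrame(rows, columns=["site_id", "spike_time_ms"]).to_csv(path, index=False)


def trains_from_csv(path, window: tuple[float, float] = (0.0, 1000.0)) -> list[SpikeTrain]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for site in sorted(df["site_id"].unique()):
        t = np.sort(df.loc[df.site_id == site, "spike_time_ms"].to_numpy())
        out.append(SpikeTrain(times=t, t_start=window[0], t_stop=window[1]))
    return out
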