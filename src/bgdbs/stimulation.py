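"""DBS protocols and the axon-override stimulation model.

Stimulation is represented phenomenologically: a fraction ``alpha`` of STN
neurons is "recruited" by the electrode, and the spike trains travelling
along their efferent axons are replaced by the DBS pulse train.  Somatic
dynamics of recruited neurons are untouched — their membrane potentials
still integrate synaptic input and their somatic spikes still count toward
the STN population rate — but their pallidal targets receive only the
imposed pulses (after the normal axonal conduction delay), and the
short-term-plasticity state of those synapses is driven by the pulse train.

Recruitment grows with intensity by nested selection: when the fraction is
raised, previously selected neurons are retained and the additional ones are
drawn at random, mimicking the progressive spatial spread of activation
around a fixed electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DBSProtocol", "select_stimulated", "dbs_pulse_times",
           "round_half_away"]


def round_half_away(x: float) -> int:
    """Round half away from zero (so sweeps over fractions are reproducible)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class DBSProtocol:
    """Stimulation settings.

    ``mode`` is ``"off"``, ``"regular"`` (periodic pulses every ``t_dbs``
    ms) or ``"poisson"`` (homogeneous Poisson train with mean inter-pulse
    interval ``t_dbs``).  ``fraction`` is the recruited share of STN
    neurons.  Pulses cover [t_start, t_end]; by default stimulation runs for
    the whole simulation (t_end=None means "until the end").  The default
    interval of 7 ms corresponds to the clinical 143 Hz setting.
    """

    mode: str = "off"
    t_dbs: float = 7.0
    fraction: float = 0.0
    t_start: float = 0.0
    t_end: float | None = None
    shared_train: bool = True  # one pulse train shared by all recruited axons

    def __post_init__(self) -> None:
        if self.mode not in ("off", "regular", "poisson"):
            raise ValueError(f"unknown DBS mode {self.mode!r}")
        if self.mode != "off" and self.t_dbs <= 0:
            raise ValueError("t_dbs must be positive")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")

    @classmethod
    def regular(cls, frequency_hz: float, fraction: float, **kw) -> "DBSProtocol":
        """Protocol from a stimulation frequency in Hz."""
        return cls(mode="regular", t_dbs=1000.0 / frequency_hz,
                   fraction=fraction, **kw)

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.t_dbs


def select_stimulated(
    n_stn: int, fraction: float,
    previous: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Recruit ``round(fraction * n_stn)`` STN neurons, nesting ``previous``.

    Returns a sorted index array that is a superset of ``previous``; the
    extra members are drawn uniformly without replacement from the
    remainder.  Raising the fraction therefore grows the recruited set
    monotonically, as under an electrode of increasing intensity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    prev = (np.asarray(previous, dtype=np.int64) if previous is not None
            else np.empty(0, dtype=np.int64))
    target = round_half_away(fraction * n_stn)
    if prev.size > target:
        raise ValueError("previous selection larger than the requested one")
    pool = np.setdiff1d(np.arange(n_stn), prev)
    extra = rng.choice(pool, size=target - prev.size, replace=False)
    return np.sort(np.concatenate([prev, extra]))


def dbs_pulse_times(
    protocol: DBSProtocol, t_end: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pulse times (ms) on [t_start, t_end] for an active protocol.

    Regular mode: t_start, t_start + t_dbs, ... up to and including t_end.
    Poisson mode: a homogeneous Poisson process with mean interval
    ``t_dbs``; one draw shared by all recruited axons (a single electrode
    entrains them synchronously).
    """
    if protocol.mode == "off":
        raise ValueError("protocol is off")
    stop = protocol.t_end if protocol.t_end is not None else t_end
    stop = min(stop, t_end)
    if protocol.mode == "regular":
        n = int(np.floor((stop - protocol.t_start) / protocol.t_dbs + 1e-9)) + 1
        return protocol.t_start + protocol.t_dbs * np.arange(n)
    rng = rng or np.random.default_rng()
    # Poisson: draw gaps until past the window; expected count ~ span/t_dbs.
    span = stop - protocol.t_start
    n_guess = max(16, int(span / protocol.t_dbs * 1.5) + 64)
    gaps = rng.exponential(protocol.t_dbs, size=n_guess)
    times = np.cumsum(gaps)
    while times[-1] < span:
        gaps = rng.exponential(protocol.t_dbs, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(gaps)])
    return protocol.t_start + times[times <= span]
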