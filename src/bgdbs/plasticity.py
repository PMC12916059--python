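"""Short-term plasticity (STP) of the subthalamo-pallidal projections.

STN -> GPe synapses carry the Hanson-Jaeger facilitation/depression model:
two unitless variables, F (facilitation, >= 1, bounded by ``F_bound``) and D
(depression, in (0, 1]), relax exponentially toward 1 between presynaptic
events and jump at each event.  The conductance increment transmitted by
event *i* is the static weight scaled by the efficacy ``D * F`` evaluated at
the pre-jump values, so the first pulse of a train always transmits at
baseline efficacy 1.

Each STN -> GPe synapse is independently assigned one of three parameter
classes (facilitation-dominant, depression-dominant, pseudo-linear) with
equal probability.

Between events both variables obey a linear ODE, so the module uses the
closed-form exponential relaxation rather than stepping an integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NEURON_PARAMS, PROJECTIONS, STP_CLASSES, STP_CLASS_NAMES, STPParams
from .neurons import integrate_single_neuron

__all__ = [
    "STPState", "static_conductance_decay", "stp_relax", "stp_spike_jump",
    "assign_stp_class", "periodic_steady_state", "single_synapse_protocol",
    "envelope_peak_time", "envelope_steady_state_time",
]


@dataclass
class STPState:
    """Facilitation and depression variables of one plastic synapse."""

    F: float = 1.0
    D: float = 1.0


def static_conductance_decay(g: float, tau: float, dt: float) -> float:
    """Exponential decay of a static synaptic conductance over ``dt`` ms."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return g * np.exp(-dt / tau)


def stp_relax(state: STPState, params: STPParams, dt: float) -> STPState:
    """Relax F and D toward their resting value 1 over ``dt`` ms."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return STPState(
        F=1.0 + (state.F - 1.0) * np.exp(-dt / params.tau_F),
        D=1.0 + (state.D - 1.0) * np.exp(-dt / params.tau_D),
    )


def stp_spike_jump(state: STPState, params: STPParams) -> tuple[STPState, float]:
    """Apply the at-event jump; return (new state, transmitted efficacy).

    The efficacy is ``D * F`` at the pre-jump values.  Both jump factors use
    the pre-jump state atomically:

    * ``F <- F + F (Inc_F - 1) (F_bound - F) / (F_bound - 1)`` — the jump
      vanishes as F approaches ``F_bound``;
    * ``D <- D * Inc_D``.
    """
    F, D = state.F, state.D
    efficacy = D * F
    F_new = F + F * (params.Inc_F - 1.0) * (params.F_bound - F) / (params.F_bound - 1.0)
    D_new = D * params.Inc_D
    return STPState(F=F_new, D=D_new), efficacy


def assign_stp_class(rng: np.random.Generator, size: int | None = None):
    """Draw STP class names uniformly over the three classes.

    With ``size=None`` returns a single class name, otherwise an array of
    ``size`` names.  Used once per plastic synapse at network construction.
    """
    idx = rng.integers(0, len(STP_CLASS_NAMES), size=size)
    names = np.asarray(STP_CLASS_NAMES, dtype=object)
    return names[idx] if size is not None else str(names[idx])


def periodic_steady_state(
    params: STPParams, ipi: float, n_iter: int = 2000, tol: float = 1e-12
) -> tuple[STPState, float]:
    """Fixed point of the relax+jump map under periodic drive.

    Iterates one inter-pulse interval of relaxation followed by one jump
    until (F, D) sampled just before the jump converge.  Returns the
    pre-jump state and its per-pulse efficacy ``D * F``.
    """
    state = STPState()
    prev = (state.F, state.D)
    for _ in range(n_iter):
        jumped, _ = stp_spike_jump(state, params)
        state = stp_relax(jumped, params, ipi)
        if abs(state.F - prev[0]) < tol and abs(state.D - prev[1]) < tol:
            break
        prev = (state.F, state.D)
    return state, state.F * state.D


def _resolve_stp(stp_class: str | None, tau_scale: float) -> STPParams | None:
    if stp_class is None or stp_class == "static":
        return None
    try:
        base = STP_CLASSES[stp_class]
    except KeyError:
        raise ValueError(f"unknown STP class {stp_class!r}") from None
    return base.scaled(tau_scale)


def single_synapse_protocol(
    stp_class: str | None,
    ipi: float = 7.0,
    t_on: float = 100.0,
    t_off: float = 600.0,
    duration: float = 700.0,
    dt: float = 0.04,
    weight: float = 0.42,
    tau_scale: float = 1.0,
) -> dict:
    """Drive one GPe-TI neuron through a single plastic synapse.

    Pulses arrive every ``ipi`` ms from ``t_on`` to ``t_off`` (inclusive).
    The synapse carries the STN -> GPe-TI static weight (0.42 nS) scaled by
    the per-pulse STP efficacy of ``stp_class`` (``None``/"static" disables
    plasticity: every pulse transmits the full weight).  The postsynaptic
    neuron is integrated with RK4 at step ``dt``.

    Returns a dict with the membrane trace (``t``, ``v``, ``g_ex``), the
    per-pulse records (``pulse_times``, ``F``, ``D``, ``efficacy``,
    ``envelope`` = conductance immediately after each pulse), and full
    ``F_trace``/``D_trace`` sampled on the time grid.
    """
    if t_off <= t_on:
        raise ValueError("t_off must exceed t_on")
    gpe_ti = NEURON_PARAMS["GPe_TI"]
    pulse_times = np.arange(t_on, t_off + 1e-9, ipi)
    stp = _resolve_stp(stp_class, tau_scale)

    # Per-pulse STP bookkeeping in closed form.
    state = STPState()
    F_pre = np.ones(pulse_times.size)
    D_pre = np.ones(pulse_times.size)
    eff = np.ones(pulse_times.size)
    if stp is not None:
        for i, _ in enumerate(pulse_times):
            if i > 0:
                state = stp_relax(state, stp, ipi)
            F_pre[i], D_pre[i] = state.F, state.D
            state, eff[i] = stp_spike_jump(state, stp)

    increments = weight * eff
    trace = integrate_single_neuron(
        gpe_ti, duration=duration, dt=dt,
        g_ex_events=(pulse_times, increments), record=True)

    # Conductance envelope: value right after each pulse's jump.
    dex = np.exp(-ipi / gpe_ti.tau_ex)
    env = np.empty(pulse_times.size)
    g = 0.0
    for i, inc in enumerate(increments):
        if i > 0:
            g *= dex
        g += inc
        env[i] = g

    # Dense F/D traces for plotting/inspection.
    t = trace["t"]
    F_trace = np.ones_like(t)
    D_trace = np.ones_like(t)
    if stp is not None:
        state = STPState()
        last = None
        seg = t < pulse_times[0]
        for i, tp in enumerate(pulse_times):
            if last is not None:
                seg = (t >= last) & (t < tp)
                dt_seg = t[seg] - last
                F_trace[seg] = 1 + (state.F - 1) * np.exp(-dt_seg / stp.tau_F)
                D_trace[seg] = 1 + (state.D - 1) * np.exp(-dt_seg / stp.tau_D)
                state = stp_relax(state, stp, tp - last)
            state, _ = stp_spike_jump(state, stp)
            last = tp
        seg = t >= last
        dt_seg = t[seg] - last
        F_trace[seg] = 1 + (state.F - 1) * np.exp(-dt_seg / stp.tau_F)
        D_trace[seg] = 1 + (state.D - 1) * np.exp(-dt_seg / stp.tau_D)

    return {
        "t": t, "v": trace["v"], "g_ex": trace["g_ex"],
        "F": F_trace, "D": D_trace,
        "pulse_times": pulse_times, "F_pre": F_pre, "D_pre": D_pre,
        "efficacy": eff, "envelope": env, "spikes": trace["spikes"],
    }


def envelope_peak_time(result: dict) -> float:
    """Time (ms) at which the per-pulse conductance envelope is maximal."""
    i = int(np.argmax(result["envelope"]))
    return float(result["pulse_times"][i])


def envelope_steady_state_time(result: dict, rel_tol: float = 0.02) -> float:
    """First pulse time after which the envelope changes < ``rel_tol`` per pulse.

    The steady state is declared at the earliest pulse such that every
    subsequent per-pulse relative change of the conductance envelope stays
    below ``rel_tol``.
    """
    env = result["envelope"]
    times = result["pulse_times"]
    rel = np.abs(np.diff(env)) / env[:-1]
    settled = rel < rel_tol
    # last index where the tolerance is violated
    bad = np.nonzero(~settled)[0]
    if bad.size == 0:
        return float(times[0])
    if bad[-1] + 1 >= times.size:
        raise ValueError("envelope never settles within the train")
    return float(times[bad[-1] + 1])


def protocol_to_frame(result: dict):
    """Tabulate a protocol run as a DataFrame (t, F, D, g_ex, v)."""
    import pandas as pd

    return pd.DataFrame({
        "t": result["t"], "F": result["F"], "D": result["D"],
        "g_ex": result["g_ex"], "v": result["v"],
    })
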