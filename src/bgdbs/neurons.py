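"""Membrane dynamics of the three neuron classes.

All populations are conductance-based adaptive point neurons with a membrane
potential ``v`` (mV), a slow adaptation current ``w`` (pA) and exponentially
decaying excitatory/inhibitory conductances.  STN and GPe use the adaptive
exponential (AdEx) form; D1/D2 medium spiny neurons use the adaptive
quadratic form; fast-spiking interneurons use the quadratic form with a
cubic recovery current active below ``Vb``.

The functions here are the scalar reference implementations: they define the
model and back the tests and the single-neuron protocols.  The network
engine (:mod:`bgdbs.engine`) re-expresses the same equations inside a
compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NeuronParams

__all__ = [
    "NeuronState", "EXP_ARG_MAX", "V_JUMP_MAX", "exp_arg_cap",
    "adex_rhs", "quadratic_rhs", "fsn_rhs", "neuron_rhs",
    "threshold_reset", "rk4_step", "integrate_single_neuron",
]

#: Default clamp for the AdEx exponential argument in the bare
#: right-hand-side functions (sub-threshold evaluations never reach it).
EXP_ARG_MAX = 30.0

#: Bound on the voltage change one capped upstroke step may produce (mV).
#: The AdEx exponential diverges in finite time; a fixed-step integrator
#: must cap it so that a supra-threshold step lands a bounded distance
#: above Vpeak, where the reset takes over.  The trajectory shape above
#: threshold is irrelevant (the spike is the reset), but an uncapped stage
#: destabilizes RK4 catastrophically.
V_JUMP_MAX = 100.0


def exp_arg_cap(params: NeuronParams, dt: float,
                v_jump: float = V_JUMP_MAX) -> float:
    """Stage-stability clamp for the AdEx exponential argument.

    Chosen so the capped upstroke current moves v by at most ``v_jump`` mV
    per step of size ``dt``: ``cap = ln(v_jump * Cm / (dt * gL * DeltaT))``.
    """
    return float(np.log(v_jump * params.Cm / (dt * params.gL * params.DeltaT)))


@dataclass
class NeuronState:
    """Dynamic variables of one neuron.

    ``g_rec`` is the dedicated recurrent-inhibition conductance used only by
    GPe-TI (time constant ``tau_rec``); it stays 0 elsewhere.
    """

    v: float
    w: float = 0.0
    g_ex: float = 0.0
    g_in: float = 0.0
    g_rec: float = 0.0


def _check_finite(state: NeuronState) -> None:
    if not (np.isfinite(state.v) and np.isfinite(state.w)):
        raise FloatingPointError(
            f"non-finite neuron state v={state.v} w={state.w}; "
            "numerical blow-up (v should be capped at Vpeak by the reset)")


def adex_rhs(state: NeuronState, params: NeuronParams,
             arg_cap: float = EXP_ARG_MAX) -> tuple[float, float]:
    """Adaptive exponential membrane equation (STN, GPe).

    Returns (dv/dt, dw/dt) in (mV/ms, pA/ms).  The spike upstroke term
    ``gL * DeltaT * exp((v - Vth)/DeltaT)`` has its argument clamped at
    ``arg_cap``; integrators pass the step-size-dependent stability cap
    from :func:`exp_arg_cap`.
    """
    _check_finite(state)
    v, w = state.v, state.w
    arg = min((v - params.Vth) / params.DeltaT, arg_cap)
    I_syn = (-state.g_ex * (v - params.Eex)
             - state.g_in * (v - params.Ein)
             - state.g_rec * (v - params.Ein))
    dv = (-params.gL * (v - params.EL) + I_syn
          + params.gL * params.DeltaT * np.exp(arg)
          - w + params.Ie) / params.Cm
    dw = (-w + params.a * (v - params.EL)) / params.tau_w
    return dv, dw


def quadratic_rhs(state: NeuronState, params: NeuronParams) -> tuple[float, float]:
    """Adaptive quadratic membrane equation (D1/D2 medium spiny neurons)."""
    _check_finite(state)
    v, w = state.v, state.w
    I_syn = (-state.g_ex * (v - params.Eex)
             - state.g_in * (v - params.Ein))
    dv = (I_syn + params.k * (v - params.EL) * (v - params.Vth)
          - w + params.Ie) / params.Cm
    dw = (-w + params.a * (v - params.EL)) / params.tau_w
    return dv, dw


def fsn_rhs(state: NeuronState, params: NeuronParams) -> tuple[float, float]:
    """Fast-spiking interneuron: quadratic v, cubic recovery below ``Vb``.

    The recovery current follows ``a (v - Vb)^3`` only for ``v < Vb``
    (strictly); at and above ``Vb`` the adaptation current decays freely.
    """
    _check_finite(state)
    v, w = state.v, state.w
    I_syn = (-state.g_ex * (v - params.Eex)
             - state.g_in * (v - params.Ein))
    dv = (I_syn + params.k * (v - params.EL) * (v - params.Vth)
          - w + params.Ie) / params.Cm
    if v < params.Vb:
        dw = (-w + params.a * (v - params.Vb) ** 3) / params.tau_w
    else:
        dw = -w / params.tau_w
    return dv, dw


_RHS = {"adex": adex_rhs, "quadratic": quadratic_rhs, "fsn": fsn_rhs}


def neuron_rhs(state: NeuronState, params: NeuronParams) -> tuple[float, float]:
    """Dispatch to the membrane equation selected by ``params.model_kind``."""
    return _RHS[params.model_kind](state, params)


def threshold_reset(state: NeuronState, params: NeuronParams) -> bool:
    """Apply the spike/reset rule in place; return True if a spike occurred.

    A spike is registered when ``v > Vpeak`` (strict); then ``v`` is set to
    ``Vreset`` and the spike-triggered adaptation ``b`` is added to ``w``.
    There is no refractory period.
    """
    if state.v > params.Vpeak:
        state.v = params.Vreset
        state.w += params.b
        return True
    return False


def rk4_step(state: NeuronState, params: NeuronParams, dt: float) -> None:
    """Advance (v, w) jointly by one classical RK4 step, in place.

    Conductances are held fixed during the step (they decay analytically
    between steps in the callers), so the stage evaluations only revisit
    (v, w).  AdEx neurons use the dt-dependent upstroke clamp.
    """
    if params.model_kind == "adex":
        cap = exp_arg_cap(params, dt)

        def rhs(s, p):
            return adex_rhs(s, p, cap)
    else:
        rhs = _RHS[params.model_kind]
    v0, w0 = state.v, state.w
    k1v, k1w = rhs(state, params)
    state.v, state.w = v0 + 0.5 * dt * k1v, w0 + 0.5 * dt * k1w
    k2v, k2w = rhs(state, params)
    state.v, state.w = v0 + 0.5 * dt * k2v, w0 + 0.5 * dt * k2w
    k3v, k3w = rhs(state, params)
    state.v, state.w = v0 + dt * k3v, w0 + dt * k3w
    k4v, k4w = rhs(state, params)
    state.v = v0 + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    state.w = w0 + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)


def integrate_single_neuron(
    params: NeuronParams,
    duration: float,
    dt: float = 0.04,
    v0: float | None = None,
    w0: float = 0.0,
    g_ex_events: tuple[np.ndarray, np.ndarray] | None = None,
    record: bool = True,
) -> dict:
    """Integrate one isolated neuron, optionally with timed conductance jumps.

    ``g_ex_events`` is an optional pair ``(times_ms, increments_nS)``; each
    event adds its increment to the excitatory conductance at the first step
    boundary at or after its time.  Returns a dict with spike times and, if
    ``record``, the full ``t``, ``v``, ``w`` and ``g_ex`` traces (sampled at
    step boundaries, after event delivery).
    """
    n_steps = int(round(duration / dt))
    state = NeuronState(v=params.EL if v0 is None else v0, w=w0)
    dex = float(np.exp(-dt / params.tau_ex))

    if g_ex_events is not None:
        ev_t = np.asarray(g_ex_events[0], dtype=float)
        ev_w = np.asarray(g_ex_events[1], dtype=float)
        ev_steps = np.ceil(ev_t / dt - 1e-9).astype(np.int64)
    else:
        ev_steps = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0)

    spikes: list[float] = []
    if record:
        t_out = np.arange(n_steps + 1) * dt
        v_out = np.empty(n_steps + 1)
        g_out = np.empty(n_steps + 1)
        w_out = np.empty(n_steps + 1)
        v_out[0], w_out[0], g_out[0] = state.v, state.w, state.g_ex

    ev_ptr = 0
    for s in range(n_steps):
        while ev_ptr < ev_steps.size and ev_steps[ev_ptr] == s:
            state.g_ex += ev_w[ev_ptr]
            ev_ptr += 1
        rk4_step(state, params, dt)
        if threshold_reset(state, params):
            spikes.append((s + 1) * dt)
        state.g_ex *= dex
        state.g_in *= np.exp(-dt / params.tau_in)
        if record:
            v_out[s + 1], w_out[s + 1], g_out[s + 1] = state.v, state.w, state.g_ex

    out = {"spikes": np.asarray(spikes)}
    if record:
        out.update(t=t_out, v=v_out, w=w_out, g_ex=g_out)
    return out
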