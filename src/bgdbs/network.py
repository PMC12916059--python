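"""Construction of the six-population basal-ganglia network.

The builder realizes the random directed graph defined by the connectivity
table (Bernoulli per ordered neuron pair, no autapses), attaches the
external Poisson drive, applies the dopamine-depletion model (a scaling of
the D2 external input rate, optionally supplemented by projection-specific
synaptic alterations), and assigns an STP class to every subthalamo-pallidal
synapse.

Two independent random streams keep paired experiments comparable:
``seed_network`` drives wiring, STP-class assignment and DBS neuron
selection, while ``seed_noise`` drives the Poisson input and initial
conditions.  The same ``seed_network`` therefore yields byte-identical
wiring across healthy / Parkinsonian / DBS conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import params as tables
from .params import (
    EXTERNAL_INPUT, NEURON_PARAMS, POPULATION_SIZES, POPULATIONS,
    PROJECTIONS, STP_CLASS_NAMES, DEPLETION_BETAS, NeuronParams,
    ProjectionSpec,
)

__all__ = [
    "PopulationSpec", "NetworkConfig", "Network",
    "dopamine_input_rate", "apply_synaptic_alterations", "build_network",
    "external_poisson_increments",
]

_CLASS_INDEX = {name: i for i, name in enumerate(STP_CLASS_NAMES)}


@dataclass(frozen=True)
class PopulationSpec:
    """One population: size, biophysics, and external drive."""

    name: str
    size: int
    params: NeuronParams
    v_ext: float      # kHz
    ext_weight: float  # nS


@dataclass(frozen=True)
class NetworkConfig:
    """Build-time configuration.

    ``Dd`` is the dopamine-depletion severity scaling the D2 external input
    rate by ``0.3 Dd + 0.75`` (0.166 healthy, 0.5 Parkinsonian).
    ``phi_alpha_d`` (<= 0, default 0 = off) additionally scales the
    projection parameters listed in the depletion table by
    ``1 + beta_p * phi``.  ``plasticity_mode`` selects which STN -> GPe
    synapses are plastic: ``full``, ``none``, ``only_TI``, ``only_TA`` or
    ``single_class:<class_name>``.  ``stp_tau_scale`` multiplies both STP
    time constants of every class (robustness checks use 0.75 / 1.25).
    """

    Dd: float = 0.166
    phi_alpha_d: float = 0.0
    plasticity_mode: str = "full"
    stp_tau_scale: float = 1.0
    seed_network: int = 1
    seed_noise: int = 1
    sizes: dict = field(default_factory=lambda: dict(POPULATION_SIZES))

    def __post_init__(self) -> None:
        if not 0.0 <= self.Dd <= 1.0:
            raise ValueError("Dd must lie in [0, 1]")
        if not -1.0 <= self.phi_alpha_d <= 0.0:
            raise ValueError("phi_alpha_d must lie in [-1, 0]")
        mode = self.plasticity_mode
        if mode not in ("full", "none", "only_TI", "only_TA") and not (
                mode.startswith("single_class:")
                and mode.split(":", 1)[1] in STP_CLASS_NAMES):
            raise ValueError(f"unknown plasticity_mode {mode!r}")
        for name in self.sizes:
            if name not in POPULATIONS:
                raise ValueError(f"unknown population {name!r}")


@dataclass
class Network:
    """A realized network as flat arrays over a global neuron index.

    Neurons are numbered population by population in the canonical order
    (D1, D2, FSN, GPe_TA, GPe_TI, STN); ``pop_slices`` maps names to index
    ranges.  Synapse arrays are parallel: ``syn_pre[i] -> syn_post[i]`` with
    weight (nS), delay (ms), conductance channel (0 excitatory, 1
    inhibitory, 2 GPe-TI recurrent) and STP class (-1 static, otherwise an
    index into the three STP classes).
    """

    config: NetworkConfig
    pop_slices: dict
    neuron_params: dict          # per-neuron float arrays + "kind" int array
    ext_rate: np.ndarray         # kHz, per neuron
    ext_weight: np.ndarray       # nS, per neuron
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_weight: np.ndarray
    syn_delay: np.ndarray
    syn_chan: np.ndarray
    syn_stp_class: np.ndarray
    stimulated_mask: np.ndarray  # bool per neuron; set by the DBS layer

    @property
    def n_neurons(self) -> int:
        return int(self.ext_rate.size)

    @property
    def n_synapses(self) -> int:
        return int(self.syn_pre.size)

    def population_of(self, name: str) -> slice:
        return self.pop_slices[name]

    def synapse_mask(self, source: str, target: str) -> np.ndarray:
        s, t = self.pop_slices[source], self.pop_slices[target]
        return ((self.syn_pre >= s.start) & (self.syn_pre < s.stop)
                & (self.syn_post >= t.start) & (self.syn_post < t.stop))


def dopamine_input_rate(Dd: float, v_ext0: float) -> float:
    """D2 external input rate (kHz) under depletion severity ``Dd``.

    The factor ``0.3 Dd + 0.75`` raises D2 drive monotonically with
    depletion; at ``Dd = 5/6`` the rate equals its reference value.
    """
    return v_ext0 * (0.3 * Dd + 0.75)


def apply_synaptic_alterations(
    projections: tuple[ProjectionSpec, ...], phi_alpha_d: float
) -> tuple[ProjectionSpec, ...]:
    """Scale projection weights/probabilities by ``1 + beta_p * phi``.

    Operates on the (healthy) base table before wiring; probabilities that
    leave [0, 1] are clamped with a warning.  ``phi = 0`` returns the table
    unchanged.
    """
    if phi_alpha_d > 0:
        raise ValueError("phi_alpha_d must be <= 0")
    if phi_alpha_d == 0:
        return projections
    out = list(projections)
    for row in DEPLETION_BETAS:
        factor = 1.0 + row["beta"] * phi_alpha_d
        for i, proj in enumerate(out):
            if (proj.source, proj.target) not in row["pairs"]:
                continue
            if row["kind"] == "weight":
                out[i] = replace(proj, weight=proj.weight * factor)
            else:
                p = proj.probability * factor
                if not 0.0 <= p <= 1.0:
                    warnings.warn(
                        f"altered probability {p:.4f} for "
                        f"{proj.source}->{proj.target} clamped to [0, 1]")
                    p = min(max(p, 0.0), 1.0)
                out[i] = replace(proj, probability=p)
    return tuple(out)


_KIND_CODE = {"adex": 0, "quadratic": 1, "fsn": 2}

_PARAM_FIELDS = ("Cm", "EL", "Eex", "Ein", "tau_ex", "tau_in", "Vth", "Ie",
                 "Vreset", "a", "b", "tau_w", "Vpeak", "DeltaT", "gL", "k",
                 "Vb", "tau_rec")


def _wire_projection(
    rng: np.random.Generator, proj: ProjectionSpec,
    src: slice, tgt: slice,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli wiring of one projection; excludes autapses.

    Each ordered (pre, post) pair connects independently with the row
    probability.  Sampling walks the flattened pair index with geometric
    gaps, which realizes exactly the same product-Bernoulli law as testing
    every pair but costs O(edges).
    """
    n_src = src.stop - src.start
    n_tgt = tgt.stop - tgt.start
    p = proj.probability
    if p <= 0:
        z = np.empty(0, dtype=np.int32)
        return z, z.copy()
    total = n_src * n_tgt
    pos_parts = []
    last = -1
    while True:
        need = int((total - last) * p * 1.1) + 64
        gaps = rng.geometric(p, size=need)
        pos = last + np.cumsum(gaps)
        pos_parts.append(pos[pos < total])
        if pos[-1] >= total:
            break
        last = int(pos[-1])
    pos = np.concatenate(pos_parts)
    pre = (pos // n_tgt).astype(np.int32)
    post = (pos - pre.astype(np.int64) * n_tgt).astype(np.int32)
    if src.start == tgt.start:  # same population: drop autapses
        keep = pre != post
        pre, post = pre[keep], post[keep]
    return pre + src.start, post + tgt.start


def build_network(config: NetworkConfig | None = None) -> Network:
    """Realize a network from the configuration (deterministic per seed)."""
    config = config or NetworkConfig()
    rng = np.random.default_rng(config.seed_network)

    sizes = {name: config.sizes.get(name, POPULATION_SIZES[name])
             for name in POPULATIONS}
    offsets, total = {}, 0
    for name in POPULATIONS:
        offsets[name] = slice(total, total + sizes[name])
        total += sizes[name]

    # Per-neuron parameter arrays.
    neuron_params = {f: np.empty(total) for f in _PARAM_FIELDS}
    neuron_params["kind"] = np.empty(total, dtype=np.int8)
    ext_rate = np.empty(total)
    ext_weight = np.empty(total)
    for name in POPULATIONS:
        sl = offsets[name]
        p = NEURON_PARAMS[name]
        for f in _PARAM_FIELDS:
            neuron_params[f][sl] = getattr(p, f)
        neuron_params["kind"][sl] = _KIND_CODE[p.model_kind]
        rate, w = EXTERNAL_INPUT[name]
        if name == "D2":
            rate = dopamine_input_rate(config.Dd, rate)
        ext_rate[sl] = rate
        ext_weight[sl] = w

    projections = apply_synaptic_alterations(PROJECTIONS, config.phi_alpha_d)

    pre_list, post_list, w_list, d_list, c_list, s_list = [], [], [], [], [], []
    plastic_flags = []
    for proj in projections:
        pre, post = _wire_projection(rng, proj, offsets[proj.source],
                                     offsets[proj.target])
        n = pre.size
        pre_list.append(pre)
        post_list.append(post)
        w_list.append(np.full(n, proj.weight))
        d_list.append(np.full(n, proj.delay))
        if proj.recurrent_channel:
            chan = 2
        elif proj.sign == "excitatory":
            chan = 0
        else:
            chan = 1
        c_list.append(np.full(n, chan, dtype=np.int8))
        plastic_flags.append(np.full(
            n, proj.plastic and proj.target == "GPe_TI", dtype=np.int8) * 1
            + np.full(n, proj.plastic and proj.target == "GPe_TA",
                      dtype=np.int8) * 2)

    syn_pre = np.concatenate(pre_list)
    syn_post = np.concatenate(post_list)
    syn_weight = np.concatenate(w_list)
    syn_delay = np.concatenate(d_list)
    syn_chan = np.concatenate(c_list)
    plastic = np.concatenate(plastic_flags)  # 0 static, 1 ->GPe_TI, 2 ->GPe_TA

    # STP class assignment (drawn for every plastic synapse regardless of
    # mode, so the wiring stream stays aligned across plasticity modes).
    stp_class = np.full(syn_pre.size, -1, dtype=np.int8)
    plastic_idx = np.nonzero(plastic > 0)[0]
    draws = rng.integers(0, len(STP_CLASS_NAMES), size=plastic_idx.size)
    mode = config.plasticity_mode
    if mode == "full":
        keep = np.ones(plastic_idx.size, dtype=bool)
    elif mode == "none":
        keep = np.zeros(plastic_idx.size, dtype=bool)
    elif mode == "only_TI":
        keep = plastic[plastic_idx] == 1
    elif mode == "only_TA":
        keep = plastic[plastic_idx] == 2
    else:
        cls = mode.split(":", 1)[1]
        draws = np.full(plastic_idx.size, _CLASS_INDEX[cls])
        keep = np.ones(plastic_idx.size, dtype=bool)
    stp_class[plastic_idx[keep]] = draws[keep].astype(np.int8)

    return Network(
        config=config,
        pop_slices=offsets,
        neuron_params=neuron_params,
        ext_rate=ext_rate,
        ext_weight=ext_weight,
        syn_pre=syn_pre,
        syn_post=syn_post,
        syn_weight=syn_weight,
        syn_delay=syn_delay,
        syn_chan=syn_chan,
        syn_stp_class=stp_class,
        stimulated_mask=np.zeros(total, dtype=bool),
    )


def external_poisson_increments(
    rate: float, dt: float, n_steps: int, rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Per-step external event counts, shape (n_steps, size).

    Counts are i.i.d. Poisson with mean ``rate * dt`` (rate in kHz, dt in
    ms); each event adds the external weight to the target's excitatory
    conductance with zero delay.  The engine uses an equivalent event-time
    formulation internally; this helper exposes the law for direct use and
    testing.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rng.poisson(rate * dt, size=(n_steps, size))
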