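"""Default parameter tables for the basal-ganglia network model.

The model comprises six populations: striatal medium spiny neurons expressing
D1 or D2 dopamine receptors (``D1``, ``D2``), striatal fast-spiking
interneurons (``FSN``), the arkypallidal and prototypic subpopulations of the
external globus pallidus (``GPe_TA``, ``GPe_TI``), and the subthalamic nucleus
(``STN``).  All biophysical constants, connection probabilities, delays and
synaptic weights below are the model's published reference values; they are
the single source of truth consumed by :mod:`bgdbs.network`.

Units follow the conductance-based adaptive integrate-and-fire convention:
capacitance in pF, potentials in mV, conductances in nS, currents in pA,
times in ms, and external Poisson rates in kHz (events per ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "POPULATIONS",
    "POPULATION_SIZES",
    "NeuronParams",
    "NEURON_PARAMS",
    "ProjectionSpec",
    "PROJECTIONS",
    "EXTERNAL_INPUT",
    "STPParams",
    "STP_CLASSES",
    "STP_CLASS_NAMES",
    "DEPLETION_BETAS",
    "FIRING_RATE_WINDOWS_HZ",
    "BETA_BAND", "GAMMA_BAND",
]

#: Canonical population ordering used for flat neuron indexing.
POPULATIONS = ("D1", "D2", "FSN", "GPe_TA", "GPe_TI", "STN")

POPULATION_SIZES = {
    "D1": 6000,
    "D2": 6000,
    "FSN": 420,
    "GPe_TA": 264,
    "GPe_TI": 780,
    "STN": 408,
}

#: Murine in-vivo mean firing-rate windows (Hz) the healthy network targets.
FIRING_RATE_WINDOWS_HZ = {
    "FSN": (10.0, 20.0),
    "D1": (0.5, 2.5),
    "D2": (0.5, 2.5),
    "GPe_TI": (30.0, 60.0),
    "GPe_TA": (10.0, 20.0),
    "STN": (12.0, 20.0),
}

BETA_BAND = (12.0, 30.0)
GAMMA_BAND = (30.0, 150.0)


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of one population.

    ``model_kind`` selects the membrane equation: ``"adex"`` (adaptive
    exponential; STN and GPe), ``"quadratic"`` (adaptive quadratic; D1/D2) or
    ``"fsn"`` (adaptive quadratic with a cubic recovery current below ``Vb``).
    For FSN the subthreshold adaptation ``a`` is in nS/mV^2; elsewhere nS.
    ``tau_rec`` is the time constant of the separate recurrent-inhibition
    conductance channel (GPe-TI self-inhibition only).
    """

    model_kind: str
    Cm: float          # pF
    EL: float          # mV
    Eex: float = 0.0   # mV
    Ein: float = -74.0  # mV
    tau_ex: float = 12.0  # ms
    tau_in: float = 10.0  # ms
    Vth: float = -29.7  # mV
    Ie: float = 0.0    # pA
    Vreset: float = -60.0  # mV
    a: float = 0.0     # nS (FSN: nS/mV^2)
    b: float = 0.0     # pA
    tau_w: float = 100.0  # ms
    Vpeak: float = 40.0   # mV
    DeltaT: float = 0.0   # mV (adex only)
    gL: float = 0.0       # nS (adex only)
    k: float = 0.0        # nS/mV (quadratic/fsn only)
    Vb: float = 0.0       # mV (fsn only)
    tau_rec: float = 0.0  # ms (GPe-TI recurrent channel only)

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.tau_ex <= 0 or self.tau_in <= 0 or self.tau_w <= 0:
            raise ValueError("Cm and time constants must be positive")
        if self.Vreset >= self.Vpeak:
            raise ValueError("Vreset must lie below Vpeak")
        if self.model_kind == "adex" and self.gL <= 0:
            raise ValueError("adex neurons require gL > 0")
        if self.model_kind in ("quadratic", "fsn") and self.k <= 0:
            raise ValueError("quadratic neurons require k > 0")


NEURON_PARAMS = {
    "D1": NeuronParams(
        model_kind="quadratic", Cm=15.2, EL=-78.2, Ein=-74.0, tau_ex=12.0,
        tau_in=10.0, Vth=-29.7, Ie=0.0, Vreset=-60.0, a=-20.0, b=67.0,
        tau_w=100.0, Vpeak=40.0, k=1.0,
    ),
    "D2": NeuronParams(
        model_kind="quadratic", Cm=15.2, EL=-80.0, Ein=-74.0, tau_ex=12.0,
        tau_in=10.0, Vth=-29.7, Ie=0.0, Vreset=-60.0, a=-20.0, b=91.0,
        tau_w=100.0, Vpeak=40.0, k=1.0,
    ),
    "FSN": NeuronParams(
        model_kind="fsn", Cm=80.0, EL=-80.0, Ein=-74.0, tau_ex=12.0,
        tau_in=10.0, Vth=-50.0, Ie=0.0, Vreset=-60.0, a=0.025, b=0.0,
        tau_w=5.0, Vpeak=25.0, k=1.0, Vb=-55.0,
    ),
    "GPe_TI": NeuronParams(
        model_kind="adex", Cm=40.0, EL=-55.1, Ein=-65.0, tau_ex=10.0,
        tau_in=5.5, Vth=-54.7, Ie=12.0, Vreset=-60.0, a=2.5, b=70.0,
        tau_w=20.0, Vpeak=15.0, DeltaT=1.7, gL=1.0, tau_rec=7.0,
    ),
    "GPe_TA": NeuronParams(
        model_kind="adex", Cm=60.0, EL=-55.1, Ein=-65.0, tau_ex=10.0,
        tau_in=5.5, Vth=-54.7, Ie=1.0, Vreset=-60.0, a=2.5, b=105.0,
        tau_w=20.0, Vpeak=15.0, DeltaT=2.55, gL=1.0,
    ),
    "STN": NeuronParams(
        model_kind="adex", Cm=60.0, EL=-80.2, Ein=-84.0, tau_ex=4.0,
        tau_in=8.0, Vth=-64.0, Ie=5.0, Vreset=-70.0, a=0.0, b=0.05,
        tau_w=333.0, Vpeak=15.0, DeltaT=16.2, gL=10.0,
    ),
}


@dataclass(frozen=True)
class ProjectionSpec:
    """One directed projection between populations.

    ``plastic`` marks the two subthalamo-pallidal projections that carry
    short-term plasticity; ``recurrent_channel`` routes GPe-TI self-inhibition
    into its dedicated conductance variable (tau_rec = 7 ms).
    """

    source: str
    target: str
    probability: float
    delay: float       # ms
    sign: str          # "excitatory" | "inhibitory"
    weight: float      # nS
    plastic: bool = False
    recurrent_channel: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("connection probability outside [0, 1]")
        if self.delay < 0:
            raise ValueError("negative delay")


PROJECTIONS = (
    ProjectionSpec("D1", "D1", 0.0607, 1.7, "inhibitory", 0.12),
    ProjectionSpec("D1", "D2", 0.0140, 1.7, "inhibitory", 0.30),
    ProjectionSpec("D2", "D1", 0.0653, 1.7, "inhibitory", 0.36),
    ProjectionSpec("D2", "D2", 0.0840, 1.7, "inhibitory", 0.20),
    ProjectionSpec("D2", "GPe_TI", 0.0833, 7.0, "inhibitory", 1.28),
    ProjectionSpec("FSN", "D1", 0.0381, 1.7, "inhibitory", 6.60),
    ProjectionSpec("FSN", "FSN", 0.0238, 1.0, "inhibitory", 0.50),
    ProjectionSpec("FSN", "D2", 0.0262, 1.7, "inhibitory", 4.80),
    ProjectionSpec("GPe_TI", "GPe_TI", 0.0321, 1.8, "inhibitory", 1.10,
                   recurrent_channel=True),
    ProjectionSpec("GPe_TI", "GPe_TA", 0.0321, 1.8, "inhibitory", 0.35),
    ProjectionSpec("GPe_TI", "FSN", 0.0128, 7.0, "inhibitory", 1.60),
    ProjectionSpec("GPe_TI", "STN", 0.0385, 1.8, "inhibitory", 0.08),
    ProjectionSpec("GPe_TA", "D1", 0.0379, 7.0, "inhibitory", 0.35),
    ProjectionSpec("GPe_TA", "D2", 0.0379, 7.0, "inhibitory", 0.61),
    ProjectionSpec("GPe_TA", "FSN", 0.0379, 7.0, "inhibitory", 1.85),
    ProjectionSpec("GPe_TA", "GPe_TA", 0.0189, 1.8, "inhibitory", 0.35),
    ProjectionSpec("GPe_TA", "GPe_TI", 0.0189, 1.8, "inhibitory", 1.20),
    ProjectionSpec("STN", "GPe_TA", 0.0735, 2.0, "excitatory", 0.13,
                   plastic=True),
    ProjectionSpec("STN", "GPe_TI", 0.0735, 2.0, "excitatory", 0.42,
                   plastic=True),
)

#: External excitatory Poisson drive: (rate kHz, weight nS) per population.
EXTERNAL_INPUT = {
    "D1": (1.12, 0.45),
    "D2": (1.08, 0.45),
    "FSN": (0.94, 0.50),
    "GPe_TI": (0.82, 0.25),
    "GPe_TA": (0.10, 0.15),
    "STN": (0.50, 0.25),
}


@dataclass(frozen=True)
class STPParams:
    """Facilitation/depression parameters of one short-term-plasticity class.

    The facilitation variable F jumps toward ``F_bound`` at each presynaptic
    event with strength ``Inc_F`` and relaxes to 1 with time constant
    ``tau_F``; the depression variable D is multiplied by ``Inc_D`` at each
    event and relaxes to 1 with ``tau_D``.
    """

    tau_F: float   # ms
    tau_D: float   # ms
    Inc_F: float
    Inc_D: float
    F_bound: float

    def __post_init__(self) -> None:
        if self.tau_F <= 0 or self.tau_D <= 0:
            raise ValueError("STP time constants must be positive")
        if self.F_bound <= 1:
            raise ValueError("F_bound must exceed 1")

    def scaled(self, tau_scale: float) -> "STPParams":
        """Return a copy with both time constants multiplied by ``tau_scale``."""
        return replace(self, tau_F=self.tau_F * tau_scale,
                       tau_D=self.tau_D * tau_scale)


STP_CLASS_NAMES = ("facilitation_dominant", "depression_dominant",
                   "pseudo_linear")

STP_CLASSES = {
    "facilitation_dominant": STPParams(tau_F=241.0, tau_D=491.0,
                                       Inc_F=1.40, Inc_D=0.90, F_bound=5.0),
    "depression_dominant": STPParams(tau_F=148.0, tau_D=764.0,
                                     Inc_F=1.64, Inc_D=0.55, F_bound=5.0),
    "pseudo_linear": STPParams(tau_F=345.0, tau_D=700.0,
                               Inc_F=1.34, Inc_D=0.86, F_bound=5.0),
}

#: Dopamine-depletion synaptic-alteration coefficients beta_p.  Each entry
#: scales the named parameter by (1 + beta_p * phi) where phi <= 0 sets the
#: global depletion level.  ``kind`` is "weight" or "probability"; the
#: (source, target) pairs list every projection the row covers.
DEPLETION_BETAS = (
    {"kind": "weight", "beta": -1.27, "pairs": (("FSN", "FSN"),)},
    {"kind": "weight", "beta": -0.53, "pairs": (("GPe_TA", "FSN"),)},
    {"kind": "weight", "beta": -0.83, "pairs": (
        ("GPe_TI", "GPe_TI"), ("GPe_TI", "GPe_TA"),
        ("GPe_TA", "GPe_TA"), ("GPe_TA", "GPe_TI"))},
    {"kind": "weight", "beta": -0.83, "pairs": (("D2", "GPe_TI"),)},
    {"kind": "weight", "beta": -0.45, "pairs": (
        ("STN", "GPe_TI"), ("STN", "GPe_TA"))},
    {"kind": "probability", "beta": -0.90, "pairs": (("FSN", "D2"),)},
    {"kind": "weight", "beta": 0.88, "pairs": (
        ("D1", "D1"), ("D1", "D2"), ("D2", "D1"), ("D2", "D2"))},
    {"kind": "probability", "beta": 0.88, "pairs": (
        ("D1", "D1"), ("D1", "D2"), ("D2", "D1"), ("D2", "D2"))},
    {"kind": "weight", "beta": -1.22, "pairs": (("GPe_TA", "D1"),)},
    {"kind": "weight", "beta": -1.15, "pairs": (("GPe_TA", "D2"),)},
    {"kind": "weight", "beta": -0.24, "pairs": (("GPe_TI", "STN"),)},
)
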