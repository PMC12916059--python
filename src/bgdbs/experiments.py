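"""Experiment drivers: condition contrasts, intensity sweeps and the
frequency x intensity stimulation-parameter map.

All drivers share a :class:`Study`, which owns the paired-seed design: every
condition (healthy / Parkinsonian / DBS at any setting, with or without
plasticity) reuses the same per-realization wiring seeds, so contrasts
isolate the manipulated factor.  Recruited STN sets are nested across
fractions within each realization, mirroring how a fixed electrode recruits
a growing neighbourhood as intensity rises.  Simulations are cached by
their full parameter key, so overlapping drivers (e.g. the 143 Hz column of
the frequency map and the intensity sweep) never recompute a run.

Summary statistics per run: corrected beta and gamma band power and mean
firing rate per population, the STN-D2 beta phase-locking value, and the
STN/D2 mean beta frequencies.  Sweep results carry one row per grid cell
per realization; aggregation reports mean +/- standard error over
realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    BETA_BAND, GAMMA_BAND, beta_phase, mean_band_frequency, mean_band_power,
    plv, population_rate, psd_welch,
)
from .engine import CONDITIONS, SimulationSpec, simulate
from .network import NetworkConfig, build_network
from .params import POPULATIONS
from .stimulation import DBSProtocol, select_stimulated

__all__ = ["Study", "SweepResult", "BoundaryCurve", "intensity_sweep",
           "minimal_normalizing_fraction", "condition_contrast",
           "frequency_intensity_map", "therapeutic_boundary",
           "d2d1_boundary", "poisson_dbs_sweep", "DEFAULT_DBS_HZ"]

DEFAULT_DBS_HZ = 1000.0 / 7.0   # 7-ms inter-pulse interval (143 Hz)


@dataclass
class SweepResult:
    """Per-cell, per-realization statistics of a sweep.

    ``table`` has one row per (axis values, realization) with columns
    ``<pop>_beta``, ``<pop>_gamma``, ``<pop>_rate`` for each population plus
    ``plv_stn_d2``; ``refs`` holds matched-seed healthy/PD reference tables.
    """

    table: pd.DataFrame
    refs: dict = field(default_factory=dict)

    def aggregate(self, by: list[str]) -> pd.DataFrame:
        """Mean and standard error over realizations, grouped by ``by``."""
        g = self.table.groupby(by)
        mean = g.mean(numeric_only=True)
        se = g.sem(numeric_only=True, ddof=1)
        out = mean.join(se, lsuffix="", rsuffix="_se")
        return out.drop(columns=[c for c in out.columns
                                 if c.startswith("realization")])


@dataclass
class BoundaryCurve:
    """Per-frequency minimal qualifying fraction (NaN where unmet)."""

    frequencies: np.ndarray
    fractions: np.ndarray
    criterion: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.frequencies,
                         name=self.criterion)


def _run_metrics(spikes, window, rng, stim_freq_hz: float | None = None) -> dict:
    """Band powers, rates and loop synchrony of one simulation.

    With ``stim_freq_hz`` set, also reports ``<pop>_stim_peak``: the PSD
    maximum within +/-3 Hz of the stimulation frequency divided by the
    median PSD over 100-200 Hz — a sharpness measure for the entrainment
    peak that direct STN targets show and striatal populations lack.
    """
    out = {}
    rates = {}
    for pop in POPULATIONS:
        rs = population_rate(spikes, pop, window)
        rates[pop] = rs
        psd = psd_welch(rs)
        if stim_freq_hz is not None:
            f, p = psd.frequencies, psd.power
            near = (f >= stim_freq_hz - 3) & (f <= stim_freq_hz + 3)
            ref = np.median(p[(f >= 100) & (f <= 200)])
            out[f"{pop}_stim_peak"] = float(p[near].max() / ref)
        raw_beta = mean_band_power(psd, *BETA_BAND)
        raw_gamma = mean_band_power(psd, *GAMMA_BAND)
        # one set of baseline draws serves both bands
        v0 = float(rs.counts.mean()) / rs.n_neurons
        qb = qg = 0.0
        if v0 > 0:
            from .analysis import BASELINE_DRAWS
            for _ in range(BASELINE_DRAWS):
                aux = rng.binomial(rs.n_neurons, v0, size=rs.counts.size)
                psd_aux = psd_welch(aux)
                qb += mean_band_power(psd_aux, *BETA_BAND)
                qg += mean_band_power(psd_aux, *GAMMA_BAND)
            qb /= BASELINE_DRAWS
            qg /= BASELINE_DRAWS
        out[f"{pop}_beta"] = raw_beta - qb
        out[f"{pop}_gamma"] = raw_gamma - qg
        out[f"{pop}_rate"] = rs.mean_rate_hz
        if pop in ("STN", "D2"):
            try:
                out[f"{pop}_beta_centroid"] = mean_band_frequency(psd)
            except ValueError:
                out[f"{pop}_beta_centroid"] = np.nan
    out["plv_stn_d2"] = plv(beta_phase(rates["STN"]), beta_phase(rates["D2"]))
    return out


class Study:
    """Paired-seed simulation cache for all experiment drivers."""

    def __init__(
        self,
        spec: SimulationSpec | None = None,
        config: NetworkConfig | None = None,
        network_seeds: list[int] | None = None,
    ):
        self.spec = spec or SimulationSpec()
        self.base_config = config or NetworkConfig()
        n = self.spec.n_realizations
        self.network_seeds = network_seeds or list(range(1, n + 1))
        self._cache: dict = {}
        self._stim_sets: dict = {}   # (seed, tuple of fractions seen) nesting

    # -- stimulated-set bookkeeping -------------------------------------
    def _stimulated(self, seed_network: int, fraction: float) -> np.ndarray:
        """Nested recruited set for this wiring seed and fraction."""
        key = seed_network
        if key not in self._stim_sets:
            self._stim_sets[key] = {
                "rng": np.random.default_rng((seed_network, 0xD135)),
                "sets": {0.0: np.empty(0, dtype=np.int64)},
            }
        entry = self._stim_sets[key]
        if fraction in entry["sets"]:
            return entry["sets"][fraction]
        known = sorted(entry["sets"])
        below = [f for f in known if f < fraction]
        prev = entry["sets"][max(below)] if below else None
        n_stn = (self.base_config.sizes or {}).get("STN", 408)
        sel = select_stimulated(n_stn, fraction, previous=prev,
                                rng=entry["rng"])
        entry["sets"][fraction] = sel
        return sel

    # -- core run -------------------------------------------------------
    def run(
        self,
        condition: str,
        fraction: float = 0.0,
        frequency_hz: float = DEFAULT_DBS_HZ,
        dbs_mode: str = "regular",
        plasticity_mode: str | None = None,
        realization: int = 0,
    ) -> dict:
        """Metrics of one realization of one condition (cached)."""
        info = CONDITIONS[condition]
        pmode = plasticity_mode or self.base_config.plasticity_mode
        key = (condition, round(fraction, 6), round(frequency_hz, 3),
               dbs_mode, pmode, realization)
        if key in self._cache:
            return self._cache[key]

        seed_net = self.network_seeds[realization]
        seed_noise = seed_net * 1000 + {"healthy": 1, "pd": 2,
                                        "pd_dbs": 3}[condition]
        cfg = replace(self.base_config, Dd=info["Dd"],
                      plasticity_mode=pmode, seed_network=seed_net,
                      seed_noise=seed_noise)
        net = build_network(cfg)
        if info["dbs"] and fraction > 0:
            protocol = DBSProtocol(mode=dbs_mode,
                                   t_dbs=1000.0 / frequency_hz,
                                   fraction=fraction)
            stim = self._stimulated(seed_net, fraction)
        else:
            protocol = DBSProtocol()
            stim = None
        spikes = simulate(net, protocol, self.spec, stimulated=stim)
        rng = np.random.default_rng((seed_noise, 0xBA5E))
        stim_freq = (frequency_hz if info["dbs"] and fraction > 0
                     and dbs_mode == "regular" else None)
        metrics = _run_metrics(spikes, self.spec.analysis_window, rng,
                               stim_freq_hz=stim_freq)
        metrics.update(condition=condition, fraction=fraction,
                       frequency_hz=(frequency_hz if info["dbs"] else np.nan),
                       dbs_mode=(dbs_mode if info["dbs"] else "off"),
                       plasticity_mode=pmode, realization=realization)
        self._cache[key] = metrics
        return metrics

    def runs(self, condition: str, **kw) -> pd.DataFrame:
        rows = [self.run(condition, realization=r, **kw)
                for r in range(self.spec.n_realizations)]
        return pd.DataFrame(rows)

    def reference(self, condition: str,
                  plasticity_mode: str | None = None) -> pd.DataFrame:
        """Healthy or PD reference table (no DBS), matched seeds."""
        return self.runs(condition, plasticity_mode=plasticity_mode)


def _healthy_threshold(healthy: pd.DataFrame, column: str) -> float:
    """'Within the healthy range' cut: healthy mean + 1 SE."""
    return float(healthy[column].mean()
                 + healthy[column].sem(ddof=1 if len(healthy) > 1 else 0))


def intensity_sweep(
    study: Study,
    fractions,
    frequency_hz: float = DEFAULT_DBS_HZ,
    plasticity_mode: str | None = None,
    dbs_mode: str = "regular",
) -> SweepResult:
    """Beta power, rates and PLV versus the stimulated STN fraction.

    Fraction 0 rows are the PD reference itself.  ``refs`` carries
    matched-seed healthy and PD tables for the same plasticity mode.
    """
    fractions = sorted(fractions)
    rows = []
    for f in fractions:
        if f == 0:
            df = study.runs("pd", plasticity_mode=plasticity_mode)
        else:
            df = study.runs("pd_dbs", fraction=f, frequency_hz=frequency_hz,
                            dbs_mode=dbs_mode,
                            plasticity_mode=plasticity_mode)
        df = df.copy()
        df["fraction"] = f
        rows.append(df)
    refs = {
        "healthy": study.reference("healthy", plasticity_mode),
        "pd": study.reference("pd", plasticity_mode),
    }
    return SweepResult(table=pd.concat(rows, ignore_index=True), refs=refs)


def minimal_normalizing_fraction(
    sweep: SweepResult, column: str = "STN_beta",
    healthy: pd.DataFrame | None = None,
) -> float:
    """Smallest swept fraction whose mean ``column`` stays at or below the
    healthy threshold for itself and every larger fraction (NaN if none)."""
    healthy = healthy if healthy is not None else sweep.refs["healthy"]
    thr = _healthy_threshold(healthy, column)
    agg = sweep.table.groupby("fraction")[column].mean().sort_index()
    fr = agg.index.to_numpy(dtype=float)
    ok = agg.to_numpy() <= thr
    # require the criterion to hold from the candidate upward
    good_from = np.logical_and.accumulate(ok[::-1])[::-1]
    hit = np.nonzero(good_from & (fr > 0))[0]
    return float(fr[hit[0]]) if hit.size else float("nan")


def condition_contrast(
    study: Study,
    fraction: float = 0.4,
    frequency_hz: float = DEFAULT_DBS_HZ,
) -> pd.DataFrame:
    """Percent change of band powers and rates: PD+DBS versus PD.

    Changes are computed on realization-mean quantities,
    100 (x_dbs - x_pd) / x_pd; cells whose PD baseline is ~0 are reported
    as NaN rather than a spurious infinity.
    """
    pd_ref = study.reference("pd")
    dbs = study.runs("pd_dbs", fraction=fraction, frequency_hz=frequency_hz)
    cols = [c for c in pd_ref.columns
            if c.endswith(("_beta", "_gamma", "_rate"))]
    rows = {}
    for c in cols:
        base = pd_ref[c].mean()
        new = dbs[c].mean()
        if abs(base) < 1e-12:
            rows[c] = np.nan
        else:
            rows[c] = 100.0 * (new - base) / base
    return pd.DataFrame({"percent_change": rows})


def frequency_intensity_map(
    study: Study,
    frequencies_hz=None,
    fractions=None,
) -> SweepResult:
    """STN beta power (plus rates) over the frequency x fraction grid.

    Defaults reproduce the full stimulation-parameter landscape: 60-150 Hz
    in 5 Hz steps by 2%-60% recruited fraction in 2% steps; pass smaller
    grids for spot checks.
    """
    if frequencies_hz is None:
        frequencies_hz = np.arange(60, 151, 5)
    if fractions is None:
        fractions = np.round(np.arange(0.02, 0.601, 0.02), 2)
    rows = []
    for fhz in frequencies_hz:
        for fr in fractions:
            df = study.runs("pd_dbs", fraction=float(fr),
                            frequency_hz=float(fhz))
            df = df.copy()
            df["fraction"] = float(fr)
            df["frequency_hz"] = float(fhz)
            rows.append(df)
    refs = {"healthy": study.reference("healthy"),
            "pd": study.reference("pd")}
    return SweepResult(table=pd.concat(rows, ignore_index=True), refs=refs)


def therapeutic_boundary(
    map_result: SweepResult,
    healthy: pd.DataFrame | None = None,
    column: str = "STN_beta",
) -> BoundaryCurve:
    """Minimal fraction per frequency keeping beta at/below healthy level.

    A fraction qualifies only if its mean beta power and that of every
    larger swept fraction stay at or below the healthy threshold (mean +
    1 SE); frequencies with no qualifying fraction are NaN.
    """
    healthy = healthy if healthy is not None else map_result.refs["healthy"]
    thr = _healthy_threshold(healthy, column)
    agg = (map_result.table.groupby(["frequency_hz", "fraction"])[column]
           .mean().unstack())
    freqs = agg.index.to_numpy(dtype=float)
    out = np.full(freqs.size, np.nan)
    fr = agg.columns.to_numpy(dtype=float)
    for i, f in enumerate(freqs):
        ok = agg.loc[f].to_numpy() <= thr
        good_from = np.logical_and.accumulate(ok[::-1])[::-1]
        hit = np.nonzero(good_from)[0]
        if hit.size:
            out[i] = fr[hit[0]]
    return BoundaryCurve(frequencies=freqs, fractions=out,
                         criterion="beta_therapeutic")


def d2d1_boundary(map_result: SweepResult) -> BoundaryCurve:
    """Minimal fraction per frequency with mean D2 rate / D1 rate < 1."""
    t = map_result.table
    agg = t.groupby(["frequency_hz", "fraction"])[["D1_rate", "D2_rate"]].mean()
    ratio = (agg["D2_rate"] / agg["D1_rate"].where(agg["D1_rate"] > 0)
             ).unstack()
    freqs = ratio.index.to_numpy(dtype=float)
    fr = ratio.columns.to_numpy(dtype=float)
    out = np.full(freqs.size, np.nan)
    for i, f in enumerate(freqs):
        vals = ratio.loc[f].to_numpy()
        hit = np.nonzero(vals < 1.0)[0]
        if hit.size:
            out[i] = fr[hit[0]]
    return BoundaryCurve(frequencies=freqs, fractions=out,
                         criterion="d2d1_ratio")


def poisson_dbs_sweep(
    study: Study,
    fractions,
    mean_ipi_ms: float = 7.0,
) -> SweepResult:
    """Intensity sweep with Poissonian pulse trains (mean interval 7 ms)."""
    return intensity_sweep(study, fractions,
                           frequency_hz=1000.0 / mean_ipi_ms,
                           dbs_mode="poisson")
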