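"""The four cholinergic-deficiency experiments and transition detection.

Acetylcholine deficiency is emulated by lowering one connectivity weight at
a time while everything else stays at its reference value:

* ``C_tde`` — excitatory cholinergic drive PNN -> TRC (M1/M3 receptors),
  swept 100 -> 60;
* ``C_idi`` — inhibitory cholinergic drive PNN -> IN (M2), swept 18 -> 1;
* ``C_ndi`` — inhibitory cholinergic drive PNN -> TRN (M2), swept 10 -> 0.5;
* ``C_dpe`` — descending glutamatergic drive PY -> PNN, the indirect route,
  swept 78 -> 38.

For each grid value one realization is simulated, filtered and summarised
(dominant frequency, relative alpha/theta power, amplitude); amplitude
distributions at selected exemplar values are estimated from independent
realization batches.  A sweep's *critical value* is the largest grid value
whose dominant frequency has left the alpha band (< 8 Hz).

Any other connectivity weight (e.g. the thalamocortical PY -> TRC edge) can
be swept through the same machinery by naming its key in a
:class:`SweepSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import default_config, model_from_config
from .model_core import BTCModel, ModelValidationError, _edge_from_key
from .signal_metrics import (
    ALPHA_BAND,
    THETA_BAND,
    amplitude_statistic,
    bandpass,
    envelope_amplitude,
    fit_amplitude_distribution,
    summarize_spectrum,
)
from .simulator import SimulationConfig, batch_integrate, sweep_outputs

__all__ = [
    "SweepSpec",
    "TransitionReport",
    "ExperimentBundle",
    "SWEEP_COLUMNS",
    "REFERENCE_DOMINANT_FREQUENCY",
    "REFERENCE_AMPLITUDE_MEAN",
    "REFERENCE_CRITICAL_VALUE",
    "canonical_sweep_specs",
    "run_sweep",
    "detect_transition",
    "exemplar_amplitudes",
    "run_all_experiments",
]

SWEEP_COLUMNS = (
    "param",
    "value",
    "dominant_freq_hz",
    "rel_alpha",
    "rel_theta",
    "amp_mean_mv",
    "amp_sd_mv",
)

# Published single-trace dominant frequencies (Hz) at the exemplar weights,
# used as the comparison sheet for the reproduction run.
REFERENCE_DOMINANT_FREQUENCY: dict[str, dict[float, float]] = {
    "C_tde": {100.0: 9.25, 82.0: 8.5, 70.0: 7.0, 60.0: 6.0},
    "C_idi": {10.0: 9.25, 6.0: 8.25, 3.0: 7.0, 1.0: 6.0},
    "C_ndi": {7.0: 9.25, 3.0: 8.5, 1.5: 7.5, 0.5: 7.25},
    "C_dpe": {65.0: 9.25, 48.0: 8.5, 41.0: 7.0, 38.0: 6.5},
}

# Published fitted means (mV) of the 500-realization amplitude distributions.
# For C_dpe the published value list and weight list are paired by the
# monotone ordering (larger weight, larger amplitude) shared by the other
# three experiments.
REFERENCE_AMPLITUDE_MEAN: dict[str, dict[float, float]] = {
    "C_tde": {100.0: 11.04, 82.0: 8.68, 70.0: 5.87, 60.0: 3.43},
    "C_idi": {10.0: 9.58, 6.0: 8.66, 3.0: 6.92, 1.0: 5.41},
    "C_ndi": {7.0: 9.83, 3.0: 8.82, 1.5: 7.76, 0.5: 6.89},
    "C_dpe": {65.0: 9.63, 48.0: 8.96, 41.0: 6.57, 38.0: 4.83},
}

# Published approximate alpha->theta critical values of each sweep.
REFERENCE_CRITICAL_VALUE: dict[str, float] = {
    "C_tde": 80.0,
    "C_idi": 5.0,
    "C_ndi": 2.0,
    "C_dpe": 45.0,
}


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: which weight, over which descending grid.

    ``n_realizations`` controls how many realizations feed the per-row
    amplitude statistic (1 = single-trace, like the frequency metrics).
    """

    parameter: str
    values: tuple[float, ...]
    n_realizations: int = 1
    base_seed: int | None = None

    def __post_init__(self) -> None:
        _edge_from_key(self.parameter)  # validates the key
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise ValueError("sweep grid is empty")
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("sweep grid must be descending")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class TransitionReport:
    """Alpha->theta transition of one sweep.

    ``critical_value`` is the largest grid value whose dominant frequency
    lies below 8 Hz, or None when the whole sweep stays in the alpha band.
    """

    parameter: str
    critical_value: float | None
    band_before: str
    band_after: str


@dataclass
class ExperimentBundle:
    """Everything the reproduction run produces."""

    sweeps: dict[str, pd.DataFrame]
    transitions: dict[str, TransitionReport]
    amplitude_tables: dict[str, pd.DataFrame]
    comparison: pd.DataFrame
    meta: dict = field(default_factory=dict)


def canonical_sweep_specs(config: Mapping | None = None) -> dict[str, SweepSpec]:
    """The four named cholinergic-deficiency sweeps from the configuration."""
    cfg = config if config is not None else default_config()
    specs = {}
    for name, section in cfg["experiments"].items():
        start, stop, step = float(section["start"]), float(section["stop"]), float(section["step"])
        n = int(round((start - stop) / step))
        values = tuple(np.round(start - step * np.arange(n + 1), 10))
        specs[name] = SweepSpec(parameter=name, values=values)
    return specs


def _epoch_metrics(epoch: np.ndarray, fs: float) -> dict[str, float]:
    filtered = bandpass(epoch, fs)
    spec = summarize_spectrum(filtered, fs)
    return {
        "dominant_freq_hz": spec.dominant_frequency,
        "rel_alpha": spec.rel_power[ALPHA_BAND.name],
        "rel_theta": spec.rel_power[THETA_BAND.name],
        "amp_mean_mv": amplitude_statistic(filtered),
    }


def run_sweep(model: BTCModel, spec: SweepSpec, config: SimulationConfig) -> pd.DataFrame:
    """Simulate every grid value of one weight and tabulate all metrics.

    Frequency and band-power metrics come from one realization per grid
    value (all values sharing the seed's noise path, which removes sampling
    jitter between neighbouring grid points); when ``spec.n_realizations``
    exceeds one, the amplitude columns are refit from that many independent
    realizations per value.
    """
    if spec.base_seed is not None:
        config = SimulationConfig(
            dt=config.dt, duration=config.duration, transient=config.transient,
            seed=spec.base_seed, n_realizations=config.n_realizations,
            blowup_bound=config.blowup_bound,
        )
    _check_values(model, spec)
    epochs = sweep_outputs(model, config, spec.parameter, spec.values)
    fs = config.fs
    rows = []
    for value, epoch in zip(spec.values, epochs):
        row = {"param": spec.parameter, "value": value}
        row.update(_epoch_metrics(epoch, fs))
        row["amp_sd_mv"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
    if spec.n_realizations > 1:
        for k, value in enumerate(spec.values):
            summary = exemplar_amplitudes(
                model, config, spec.parameter, value, n=spec.n_realizations
            )
            table.loc[k, "amp_mean_mv"] = summary.fitted_mean
            table.loc[k, "amp_sd_mv"] = summary.fitted_sd
    return table


def _check_values(model: BTCModel, spec: SweepSpec) -> None:
    for v in spec.values:
        if not np.isfinite(v) or v < 0:
            raise ModelValidationError(
                f"sweep value {v!r} for {spec.parameter} is outside validation bounds"
            )


def detect_transition(table: pd.DataFrame, boundary_hz: float = 8.0) -> TransitionReport:
    """Largest grid value whose dominant frequency sits below the alpha floor.

    The table must be sorted by descending parameter value (as produced by
    :func:`run_sweep`).
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    values = table["value"].to_numpy(dtype=float)
    if np.any(np.diff(values) > 0):
        raise ValueError("sweep table must be sorted by descending parameter value")
    freqs = table["dominant_freq_hz"].to_numpy(dtype=float)
    parameter = str(table["param"].iloc[0])
    below = freqs < boundary_hz
    band_before = "alpha" if freqs[0] >= boundary_hz else "theta"
    band_after = "theta" if below.any() else band_before
    critical = float(values[below][0]) if below.any() else None
    return TransitionReport(
        parameter=parameter,
        critical_value=critical,
        band_before=band_before,
        band_after=band_after,
    )


def exemplar_amplitudes(
    model: BTCModel,
    config: SimulationConfig,
    parameter: str,
    value: float,
    n: int | None = None,
):
    """Amplitude distribution of one weight setting from an n-realization batch.

    Each realization's filtered epoch is reduced to its mean half
    peak-to-trough amplitude; the batch is then fitted with a normal density
    (maximum likelihood).  Returns an
    :class:`~btcmodel.signal_metrics.AmplitudeSummary`.
    """
    perturbed = BTCModel(
        populations=model.populations,
        connectivity=model.connectivity.replace(parameter, value),
        sigmoid_params=model.sigmoid_params,
        noise=model.noise,
    )
    epochs = batch_integrate(perturbed, config, n=n)
    fs = config.fs
    amps = [amplitude_statistic(bandpass(e, fs)) for e in epochs]
    return fit_amplitude_distribution(amps)


def run_all_experiments(
    config: Mapping | None = None,
    n_realizations: int | None = None,
    seed: int | None = None,
) -> ExperimentBundle:
    """Run the four canonical sweeps plus exemplar amplitude batches.

    Returns sweep tables, transition reports, per-exemplar amplitude tables
    (model fit next to the published means) and a comparison sheet of
    dominant frequencies at all exemplar weights.  ``n_realizations``
    overrides the configured batch size (500); 100 is a practical choice for
    quick runs.
    """
    cfg = dict(config) if config is not None else default_config()
    model = model_from_config(cfg)
    sim = SimulationConfig.from_mapping(cfg["simulation"])
    if seed is not None:
        sim = SimulationConfig(
            dt=sim.dt, duration=sim.duration, transient=sim.transient, seed=seed,
            n_realizations=sim.n_realizations, blowup_bound=sim.blowup_bound,
        )
    n_amp = n_realizations if n_realizations is not None else sim.n_realizations

    specs = canonical_sweep_specs(cfg)
    sweeps: dict[str, pd.DataFrame] = {}
    transitions: dict[str, TransitionReport] = {}
    amplitude_tables: dict[str, pd.DataFrame] = {}
    comparison_rows = []

    for name, spec in specs.items():
        table = run_sweep(model, spec, sim)
        sweeps[name] = table
        transitions[name] = detect_transition(table)

        exemplars = [float(v) for v in cfg["experiments"][name]["exemplars"]]
        amp_rows = []
        for value in exemplars:
            summary = exemplar_amplitudes(model, sim, name, value, n=n_amp)
            amp_rows.append(
                {
                    "param": name,
                    "value": value,
                    "amp_mean_mv": summary.fitted_mean,
                    "amp_sd_mv": summary.fitted_sd,
                    "n_realizations": len(summary.per_realization),
                    "reference_amp_mean_mv": REFERENCE_AMPLITUDE_MEAN[name].get(value),
                }
            )
            row = table.loc[np.isclose(table["value"], value)].iloc[0]
            comparison_rows.append(
                {
                    "param": name,
                    "value": value,
                    "dominant_freq_hz": row["dominant_freq_hz"],
                    "reference_freq_hz": REFERENCE_DOMINANT_FREQUENCY[name].get(value),
                    "amp_mean_mv": summary.fitted_mean,
                    "reference_amp_mean_mv": REFERENCE_AMPLITUDE_MEAN[name].get(value),
                }
            )
        amplitude_tables[name] = pd.DataFrame(amp_rows)

    comparison = pd.DataFrame(comparison_rows)
    comparison["freq_error_hz"] = comparison["dominant_freq_hz"] - comparison["reference_freq_hz"]
    comparison["amp_error_mv"] = comparison["amp_mean_mv"] - comparison["reference_amp_mean_mv"]
    return ExperimentBundle(
        sweeps=sweeps,
        transitions=transitions,
        amplitude_tables=amplitude_tables,
        comparison=comparison,
        meta={"seed": sim.seed, "n_realizations": n_amp},
    )
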