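"""Fixed-step Euler integration of the stochastic BTC system.

The model is integrated with the forward Euler method at a fixed step
(default 1/256 s).  At every step the retinal and adjacent-cortex firing
rates are fresh independent Gaussian draws ``N(mu, sqrt(eps))`` — i.e. the
noise is piecewise constant over one step, the band-limited convention of
the neural-mass literature; no 1/sqrt(dt) diffusion scaling is applied.

Trajectories start from the all-zero rest state; a transient (default the
first 20 s) is discarded before any analysis, which absorbs initialisation
effects.  The model output is the summated postsynaptic potential ``V_t`` of
the thalamic relay nucleus.

Reproducibility contract: a run is a pure function of (model, config); the
same seed yields a bit-identical trajectory.  Batch runs give realization
``k`` its own generator seeded ``base_seed + k``, so a batch is reproducible
independent of batch size or ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .model_core import BTCModel, POPULATION_ORDER, _edge_from_key, TOPOLOGY, EXCITATORY

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationBlowupError",
    "integrate",
    "extract_epoch",
    "batch_integrate",
    "sweep_outputs",
]

_CHUNK = 2048  # steps per noise block; trades rng call overhead against memory


class SimulationBlowupError(RuntimeError):
    """Numerical divergence: some |state| exceeded the configured bound."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt             : Euler step (s); the sampling rate is 1/dt.
    duration       : total simulated time (s).
    transient      : initial interval discarded from analysis (s).
    seed           : base seed for the Gaussian drives.
    n_realizations : default batch size for amplitude statistics.
    blowup_bound   : |state| (mV) beyond which integration aborts.
    """

    dt: float = 1.0 / 256.0
    duration: float = 120.0
    transient: float = 20.0
    seed: int = 42
    n_realizations: int = 500
    blowup_bound: float = 1e6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.transient < self.duration):
            raise ValueError("transient must satisfy 0 <= transient < duration")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")

    @property
    def fs(self) -> float:
        """Sampling rate (Hz)."""
        return 1.0 / self.dt

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @classmethod
    def from_mapping(cls, section) -> "SimulationConfig":
        fields = cls.__dataclass_fields__  # type: ignore[attr-defined]
        kwargs = {}
        for k, v in dict(section).items():
            if k in fields:
                kwargs[k] = int(v) if fields[k].type == "int" else float(v)
        return cls(**kwargs)


@dataclass
class SimulationResult:
    """One realization: sample grid, per-population traces and the TRC output.

    ``psp`` rows are the kernel outputs ``x_a`` and ``potentials`` rows the
    summated potentials ``V_a``, both in :data:`POPULATION_ORDER`; ``output``
    is the TRC row of ``potentials`` (the model's EEG-like observable).
    """

    times: np.ndarray
    psp: np.ndarray         # (11, n_samples)
    potentials: np.ndarray  # (11, n_samples)
    output: np.ndarray      # (n_samples,)
    config: SimulationConfig
    meta: dict = field(default_factory=dict)


def _resolve_override(model: BTCModel, weight_override):
    """Translate ('C_xyz', values) into matrix indices and signed values."""
    if weight_override is None:
        return None
    key, values = weight_override
    target, source = _edge_from_key(key)
    sign = 1.0 if TOPOLOGY[(target, source)] == EXCITATORY else -1.0
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError(f"override values for {key} must be finite and >= 0")
    idx = model.index
    return idx[target], idx[source], sign * vals


def _euler_paths(
    model: BTCModel,
    config: SimulationConfig,
    noise_chunks: Iterator[tuple[np.ndarray, np.ndarray]],
    m: int,
    weight_override=None,
    record_full: bool = False,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Advance ``m`` paths with one shared Euler loop.

    Returns ``(vt, psp, potentials)`` where ``vt`` has shape
    ``(m, n_steps + 1)``; the full traces are recorded only when
    ``record_full`` (and then ``m`` must be 1).
    """
    n_pop = len(POPULATION_ORDER)
    idx = model.index
    t_idx, r_idx, c_idx = idx["t"], idx["r"], idx["c"]
    w = model.connectivity.signed_matrix()
    override = _resolve_override(model, weight_override)
    if override is not None:
        o_tgt, o_src, o_vals = override
        w[o_tgt, o_src] = 0.0
    gains, taus = model.kinetics_arrays()
    a_tau = (gains * taus)[:, None]
    two_tau = (2.0 * taus)[:, None]
    inv_tau2 = (1.0 / (taus * taus))[:, None]
    sp = model.sigmoid_params
    neural = np.array([p.drive == "sigmoid" for p in model.populations])

    dt = config.dt
    n_steps = config.n_steps
    x = np.zeros((n_pop, m))
    y = np.zeros((n_pop, m))
    vt = np.empty((m, n_steps + 1))
    psp = np.empty((n_pop, n_steps + 1)) if record_full else None
    pots = np.empty((n_pop, n_steps + 1)) if record_full else None
    if record_full and m != 1:
        raise ValueError("full traces are recorded for single runs only")

    step = 0
    bound = config.blowup_bound
    x_extreme = 0.0
    for phi_r, phi_c in noise_chunks:
        k_chunk = phi_r.shape[1]
        for j in range(k_chunk):
            v = w @ x
            if override is not None:
                v[o_tgt] += o_vals * x[o_src]
            vt[:, step] = v[t_idx]
            if record_full:
                psp[:, step] = x[:, 0]
                pots[:, step] = v[:, 0]
            phi = 2.0 * sp.e0 / (1.0 + np.exp(np.minimum(sp.sigma * (sp.v0 - v), 700.0)))
            phi[r_idx] = phi_r[:, j]
            phi[c_idx] = phi_c[:, j]
            dy = (a_tau * phi - two_tau * y - x) * inv_tau2
            x = x + dt * y
            y = y + dt * dy
            if step % 4 == 0:  # guard at 64 Hz: kernels cannot swing past it unseen
                x_extreme = max(x_extreme, float(np.max(np.abs(x))))
            step += 1
            if step > n_steps:
                break
        if not np.isfinite(x_extreme) or x_extreme > bound:
            raise SimulationBlowupError(
                f"state reached {x_extreme:.3g} mV (bound {bound:g}) near step {step} "
                f"(t = {step * dt:.3f} s); "
                f"override={weight_override[0] if weight_override else None}"
            )
        if step > n_steps:
            break
    if step != n_steps + 1:
        # final sample at t = duration
        v = w @ x
        if override is not None:
            v[o_tgt] += o_vals * x[o_src]
        vt[:, n_steps] = v[t_idx]
        if record_full:
            psp[:, n_steps] = x[:, 0]
            pots[:, n_steps] = v[:, 0]
    return vt, psp, pots


def _single_stream_chunks(model: BTCModel, config: SimulationConfig, rng: np.random.Generator, width: int = 1):
    """Noise chunks from one generator, shared across all paths (shape (width, k))."""
    mu1, s1 = model.noise.mu1, np.sqrt(model.noise.eps1)
    mu2, s2 = model.noise.mu2, np.sqrt(model.noise.eps2)
    remaining = config.n_steps + 1
    while remaining > 0:
        k = min(_CHUNK, remaining)
        yield (
            rng.normal(mu1, s1, size=(width, k)),
            rng.normal(mu2, s2, size=(width, k)),
        )
        remaining -= k


def _per_realization_chunks(model: BTCModel, config: SimulationConfig, seeds: list[int]):
    """Noise chunks where column ``j`` comes from its own generator (seed schedule)."""
    gens = [np.random.default_rng(s) for s in seeds]
    mu1, s1 = model.noise.mu1, np.sqrt(model.noise.eps1)
    mu2, s2 = model.noise.mu2, np.sqrt(model.noise.eps2)
    remaining = config.n_steps + 1
    while remaining > 0:
        k = min(_CHUNK, remaining)
        r = np.empty((len(gens), k))
        c = np.empty((len(gens), k))
        for j, g in enumerate(gens):
            r[j] = g.normal(mu1, s1, size=k)
            c[j] = g.normal(mu2, s2, size=k)
        yield r, c
        remaining -= k


def integrate(model: BTCModel, config: SimulationConfig) -> SimulationResult:
    """Integrate one realization and record full traces.

    Identical (model, config) including the seed yields a bit-identical
    result.  Raises :class:`SimulationBlowupError` on numerical divergence.
    """
    rng = np.random.default_rng(config.seed)
    chunks = _single_stream_chunks(model, config, rng, width=1)
    vt, psp, pots = _euler_paths(model, config, chunks, m=1, record_full=True)
    times = np.arange(config.n_steps + 1) * config.dt
    return SimulationResult(
        times=times,
        psp=psp,
        potentials=pots,
        output=vt[0],
        config=config,
        meta={"seed": config.seed},
    )


def extract_epoch(result: SimulationResult, config: SimulationConfig | None = None) -> np.ndarray:
    """Output restricted to the analysis window [transient, duration]."""
    cfg = config if config is not None else result.config
    if cfg.transient >= cfg.duration:
        raise ValueError("transient must be smaller than duration")
    start = round(cfg.transient / cfg.dt)
    n_epoch = round((cfg.duration - cfg.transient) / cfg.dt)
    return result.output[start:start + n_epoch]


def batch_integrate(model: BTCModel, config: SimulationConfig, n: int | None = None) -> np.ndarray:
    """``n`` independent epochs, realization ``k`` seeded ``config.seed + k``.

    Returns an array of shape ``(n, epoch_length)`` holding the TRC output
    over the analysis window for each realization.  All realizations advance
    through one shared vectorised Euler loop, so a batch costs little more
    than a single run.
    """
    n = config.n_realizations if n is None else int(n)
    if n < 1:
        raise ValueError("need at least one realization")
    seeds = [config.seed + k for k in range(n)]
    chunks = _per_realization_chunks(model, config, seeds)
    vt, _, _ = _euler_paths(model, config, chunks, m=n)
    start = round(config.transient / config.dt)
    n_epoch = round((config.duration - config.transient) / config.dt)
    return vt[:, start:start + n_epoch]


def sweep_outputs(
    model: BTCModel,
    config: SimulationConfig,
    parameter: str,
    values,
) -> np.ndarray:
    """Epochs for a grid of values of one connectivity weight, shared noise.

    Every grid point sees the identical noise path generated from
    ``config.seed``, so each column is exactly the single run one would get
    from :func:`integrate` after setting the weight — the grid is integrated
    in one vectorised pass.  Returns shape ``(len(values), epoch_length)``.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    rng = np.random.default_rng(config.seed)
    chunks = _single_stream_chunks(model, config, rng, width=1)
    vt, _, _ = _euler_paths(
        model, config, chunks, m=len(values), weight_override=(parameter, values)
    )
    start = round(config.transient / config.dt)
    n_epoch = round((config.duration - config.transient) / config.dt)
    return vt[:, start:start + n_epoch]
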