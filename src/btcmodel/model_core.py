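"""Core data types and equations of the brainstem-thalamus-cortex (BTC) neural mass model.

The model lumps eleven neuronal ensembles into mean-field populations spanning
three interacting brain structures:

* brainstem   -- superior colliculus (SC, ``s``) and pedunculopontine nucleus
  (PNN, ``d``), the cholinergic source;
* thalamus    -- thalamic relay nucleus (TRC, ``t``), local inhibitory
  interneurons (IN, ``i``) and the thalamic reticular nucleus (TRN, ``n``);
* cortex      -- pyramidal cells (PY, ``p``), excitatory interneurons
  (eIN, ``h``), fast GABAergic interneurons (fIN, ``f``) and slow GABAergic
  interneurons (sIN, ``l``).

Two further channels, retinal input (Ret, ``r``) and adjacent-cortex input
(Cor, ``c``), are driven by Gaussian white noise instead of a sigmoid and
provide the stochastic forcing that sustains the alpha rhythm.

Each population obeys the classical two-operation neural mass scheme:

1. a static sigmoid converts the average membrane potential ``V`` into an
   average firing rate ``phi = 2 e0 / (1 + exp(sigma (V0 - V)))``;
2. a critically damped second-order synaptic kernel converts the presynaptic
   rate into a postsynaptic potential ``x``:
   ``tau^2 x'' = A tau phi - 2 tau x' - x``.

Membrane potentials are signed sums of presynaptic PSPs over the directed
connectivity graph: ``V_a = sum_b C_abe x_b - sum_d C_adi x_d``.  Synaptic
kernels are always positive; inhibition lives exclusively in the minus sign
of the summation, so the cholinergic PNN population emits a single PSP that
acts excitatorily on TRC (M1/M3 muscarinic receptors) and inhibitorily on IN
and TRN (M2 receptors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "POPULATION_ORDER",
    "POPULATION_NAMES",
    "NOISE_POPULATIONS",
    "TOPOLOGY",
    "EXCITATORY",
    "INHIBITORY",
    "SigmoidParams",
    "SynapticKinetics",
    "PopulationSpec",
    "NoiseSpec",
    "ConnectivityTable",
    "ModelState",
    "BTCModel",
    "ModelValidationError",
    "sigmoid",
    "membrane_potential",
    "psp_derivatives",
    "build_btc_model",
    "drift",
    "connectivity_key",
]

# Canonical population ordering used for all state vectors and matrices.
POPULATION_ORDER: tuple[str, ...] = ("s", "d", "i", "t", "n", "h", "p", "f", "l", "r", "c")

POPULATION_NAMES: dict[str, str] = {
    "s": "SC",
    "d": "PNN",
    "i": "IN",
    "t": "TRC",
    "n": "TRN",
    "h": "eIN",
    "p": "PY",
    "f": "fIN",
    "l": "sIN",
    "r": "Ret",
    "c": "Cor",
}

#: The two noise-driven channels (retinal and adjacent-cortex input).
NOISE_POPULATIONS: frozenset[str] = frozenset({"r", "c"})

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

# Fixed synaptic topology: (target, source) -> sign.  This is the complete
# directed edge set of the model; configurations may scale weights but may
# neither add edges outside this set nor drop any of them.
TOPOLOGY: dict[tuple[str, str], str] = {
    # brainstem
    ("s", "d"): EXCITATORY,   # PNN -> SC
    ("s", "p"): EXCITATORY,   # PY -> SC (descending)
    ("s", "r"): EXCITATORY,   # Ret -> SC
    ("d", "p"): EXCITATORY,   # PY -> PNN (descending glutamatergic; C_dpe)
    # thalamic relay nucleus
    ("t", "d"): EXCITATORY,   # PNN -> TRC (M1/M3 cholinergic; C_tde)
    ("t", "s"): EXCITATORY,   # SC -> TRC (glutamatergic)
    ("t", "i"): INHIBITORY,   # IN -> TRC
    ("t", "n"): INHIBITORY,   # TRN -> TRC
    ("t", "p"): EXCITATORY,   # PY -> TRC (corticothalamic)
    ("t", "r"): EXCITATORY,   # Ret -> TRC
    # thalamic interneurons
    ("i", "d"): INHIBITORY,   # PNN -> IN (M2 cholinergic; C_idi)
    ("i", "s"): EXCITATORY,   # SC -> IN
    ("i", "i"): INHIBITORY,   # IN self-inhibition
    ("i", "p"): EXCITATORY,   # PY -> IN
    ("i", "r"): EXCITATORY,   # Ret -> IN
    # thalamic reticular nucleus
    ("n", "d"): INHIBITORY,   # PNN -> TRN (M2 cholinergic; C_ndi)
    ("n", "t"): EXCITATORY,   # TRC -> TRN
    ("n", "n"): INHIBITORY,   # TRN self-inhibition
    ("n", "p"): EXCITATORY,   # PY -> TRN
    # cortex
    ("p", "t"): EXCITATORY,   # TRC -> PY (thalamocortical relay)
    ("p", "h"): EXCITATORY,   # eIN -> PY
    ("p", "f"): INHIBITORY,   # fIN -> PY
    ("p", "l"): INHIBITORY,   # sIN -> PY
    ("p", "c"): EXCITATORY,   # Cor -> PY (adjacent cortex noise)
    ("h", "p"): EXCITATORY,   # PY -> eIN
    ("h", "t"): EXCITATORY,   # TRC -> eIN
    ("f", "p"): EXCITATORY,   # PY -> fIN
    ("f", "t"): EXCITATORY,   # TRC -> fIN
    ("f", "l"): INHIBITORY,   # sIN -> fIN
    ("l", "p"): EXCITATORY,   # PY -> sIN
    ("l", "t"): EXCITATORY,   # TRC -> sIN
    ("l", "f"): INHIBITORY,   # fIN -> sIN
}


class ModelValidationError(ValueError):
    """Raised when a configuration violates the model's structural contract."""


def connectivity_key(target: str, source: str) -> str:
    """Symbolic name of an edge weight, e.g. ``C_tde`` for PNN -> TRC.

    The convention is ``C_<target><source><e|i>``: first letter the
    postsynaptic population, second the presynaptic one, last the sign.
    """
    sign = TOPOLOGY.get((target, source))
    if sign is None:
        raise ModelValidationError(
            f"no edge {POPULATION_NAMES.get(source, source)} -> "
            f"{POPULATION_NAMES.get(target, target)} in the BTC topology"
        )
    return f"C_{target}{source}{'e' if sign == EXCITATORY else 'i'}"


def _edge_from_key(key: str) -> tuple[str, str]:
    if len(key) != 5 or not key.startswith("C_") or key[4] not in "ei":
        raise ModelValidationError(f"malformed connectivity key {key!r}")
    target, source = key[2], key[3]
    if (target, source) not in TOPOLOGY:
        raise ModelValidationError(f"connectivity key {key!r} names an edge outside the topology")
    expected = connectivity_key(target, source)
    if expected != key:
        raise ModelValidationError(f"{key!r} has the wrong sign suffix; expected {expected!r}")
    return target, source


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the rate sigmoid ``phi(V) = 2 e0 / (1 + exp(sigma (V0 - V)))``.

    e0    : half of the maximum firing rate (spikes/s)
    v0    : potential at which the rate equals ``e0`` (mV)
    sigma : steepness at the threshold (1/mV)
    """

    e0: float
    v0: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.e0 > 0 and self.sigma > 0):
            raise ModelValidationError("sigmoid requires e0 > 0 and sigma > 0")


@dataclass(frozen=True)
class SynapticKinetics:
    """Second-order PSP kernel: gain ``A`` (mV) and time constant ``tau`` (s).

    The kernel itself is always positive; whether a population excites or
    inhibits its targets is decided by the connectivity sign.
    """

    gain: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ModelValidationError("synaptic time constant must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """One of the eleven populations: its id, kinetics and drive mode."""

    id: str
    kinetics: SynapticKinetics
    drive: str = "sigmoid"  # "sigmoid" for neural populations, "noise" for Ret/Cor

    def __post_init__(self) -> None:
        if self.id not in POPULATION_ORDER:
            raise ModelValidationError(f"unknown population id {self.id!r}")
        expected = "noise" if self.id in NOISE_POPULATIONS else "sigmoid"
        if self.drive != expected:
            raise ModelValidationError(
                f"population {POPULATION_NAMES[self.id]} must have drive={expected!r}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white-noise drives: retinal (mu1, eps1) and cortical (mu2, eps2).

    Means are firing rates (spikes/s); eps1/eps2 are variances ((spikes/s)^2).
    Each Euler step draws a fresh independent rate sample per channel.
    """

    mu1: float
    eps1: float
    mu2: float
    eps2: float

    def __post_init__(self) -> None:
        if self.eps1 < 0 or self.eps2 < 0:
            raise ModelValidationError("noise variances must be non-negative")


@dataclass(frozen=True)
class ConnectivityTable:
    """Signed, weighted, directed edges among the eleven populations.

    ``weights`` maps each topology edge ``(target, source)`` to a
    non-negative weight.  The table is complete by construction: every edge
    of the fixed topology is present, and no other edge may appear.
    """

    weights: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        extra = set(self.weights) - set(TOPOLOGY)
        if extra:
            t, s = sorted(extra)[0]
            raise ModelValidationError(
                f"edge {POPULATION_NAMES.get(s, s)} -> {POPULATION_NAMES.get(t, t)} "
                "is not part of the BTC topology"
            )
        missing = set(TOPOLOGY) - set(self.weights)
        if missing:
            keys = ", ".join(sorted(connectivity_key(t, s) for t, s in missing))
            raise ModelValidationError(f"missing connectivity entries: {keys}")
        for (t, s), w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ModelValidationError(
                    f"weight {connectivity_key(t, s)} must be finite and >= 0, got {w!r}"
                )
        object.__setattr__(self, "weights", dict(self.weights))

    @classmethod
    def from_keys(cls, named: Mapping[str, float]) -> "ConnectivityTable":
        """Build from symbolic keys (``C_tde`` etc.)."""
        return cls({_edge_from_key(k): float(v) for k, v in named.items()})

    def to_keys(self) -> dict[str, float]:
        return {connectivity_key(t, s): w for (t, s), w in sorted(self.weights.items())}

    def weight(self, target: str, source: str) -> float:
        sign = TOPOLOGY.get((target, source))
        if sign is None:
            raise ModelValidationError(
                f"no edge {source} -> {target} in the topology"
            )
        return self.weights[(target, source)]

    def sign(self, target: str, source: str) -> str:
        return TOPOLOGY[(target, source)]

    def replace(self, key: str, value: float) -> "ConnectivityTable":
        """Return a new table with one symbolic weight replaced."""
        edge = _edge_from_key(key)
        if not np.isfinite(value) or value < 0:
            raise ModelValidationError(f"{key} must be finite and >= 0, got {value!r}")
        new = dict(self.weights)
        new[edge] = float(value)
        return ConnectivityTable(new)

    def signed_matrix(self) -> np.ndarray:
        """11x11 signed weight matrix W with W[a, b] = +/- C_ab (target row, source column)."""
        n = len(POPULATION_ORDER)
        idx = {p: k for k, p in enumerate(POPULATION_ORDER)}
        w = np.zeros((n, n))
        for (t, s), c in self.weights.items():
            w[idx[t], idx[s]] = c if TOPOLOGY[(t, s)] == EXCITATORY else -c
        return w

    def incoming(self, target: str) -> list[tuple[str, str, float]]:
        """Incoming edges of ``target`` as (source, sign, weight)."""
        return [
            (s, TOPOLOGY[(t, s)], w)
            for (t, s), w in sorted(self.weights.items())
            if t == target
        ]


@dataclass
class ModelState:
    """PSP outputs ``x`` (mV) and their derivatives ``y`` (mV/s), one pair per population.

    Arrays follow :data:`POPULATION_ORDER`.  The all-zero state is the rest
    state of the unforced model.
    """

    x: np.ndarray = field(default_factory=lambda: np.zeros(len(POPULATION_ORDER)))
    y: np.ndarray = field(default_factory=lambda: np.zeros(len(POPULATION_ORDER)))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.shape[0] != len(POPULATION_ORDER):
            raise ModelValidationError("state must carry one (x, y) pair per population")


@dataclass(frozen=True)
class BTCModel:
    """A validated BTC model: populations, connectivity, sigmoid and noise parameters."""

    populations: tuple[PopulationSpec, ...]
    connectivity: ConnectivityTable
    sigmoid_params: SigmoidParams
    noise: NoiseSpec

    def __post_init__(self) -> None:
        ids = tuple(p.id for p in self.populations)
        if ids != POPULATION_ORDER:
            raise ModelValidationError(
                f"exactly the 11 populations {POPULATION_ORDER} are required, in order; got {ids}"
            )

    @property
    def index(self) -> dict[str, int]:
        return {p: k for k, p in enumerate(POPULATION_ORDER)}

    def kinetics_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of gains A_a and time constants tau_a in population order."""
        gains = np.array([p.kinetics.gain for p in self.populations])
        taus = np.array([p.kinetics.tau for p in self.populations])
        return gains, taus

    def population(self, pid: str) -> PopulationSpec:
        return self.populations[self.index[pid]]


def sigmoid(v, p: SigmoidParams):
    """Average firing rate as a function of membrane potential.

    ``phi(V) = 2 e0 / (1 + exp(sigma (V0 - V)))`` -- strictly increasing,
    bounded in (0, 2 e0), equal to ``e0`` at the threshold ``V0``.
    Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential passed to sigmoid")
    out = 2.0 * p.e0 / (1.0 + np.exp(np.minimum(p.sigma * (p.v0 - v), 700.0)))
    return float(out) if out.ndim == 0 else out


def membrane_potential(target: str, psp: Mapping[str, float], conn: ConnectivityTable) -> float:
    """Signed synaptic summation ``V_a = sum_b C_abe x_b - sum_d C_adi x_d``.

    Only the target's incoming edges contribute; a missing PSP value for a
    connected source is an error.
    """
    total = 0.0
    for source, sign, weight in conn.incoming(target):
        if source not in psp:
            raise KeyError(
                f"PSP value for source {POPULATION_NAMES[source]} required by target "
                f"{POPULATION_NAMES[target]} is missing"
            )
        contrib = weight * psp[source]
        total += contrib if sign == EXCITATORY else -contrib
    return total


def psp_derivatives(x, y, phi, k: SynapticKinetics):
    """First-order form of the synaptic kernel ODE.

    ``tau^2 x'' = A tau phi - 2 tau x' - x`` becomes
    ``dx = y`` and ``dy = (A tau phi - 2 tau y - x) / tau^2``.
    For constant phi the fixed point is ``x* = A tau phi``; the impulse
    response from rest is the alpha function ``(A/tau) t exp(-t/tau)``.
    """
    dy = (k.gain * k.tau * phi - 2.0 * k.tau * y - x) / (k.tau * k.tau)
    return y, dy


def _build_connectivity(section: Mapping[str, float]) -> ConnectivityTable:
    return ConnectivityTable.from_keys(section)


def build_btc_model(config: Mapping) -> BTCModel:
    """Assemble and validate a :class:`BTCModel` from a configuration mapping.

    Expects sections ``populations`` (per-id ``gain``/``tau``),
    ``connectivity`` (symbolic ``C_*`` keys), ``sigmoid`` (``e0``, ``v0``,
    ``sigma``) and ``noise`` (``mu1``, ``eps1``, ``mu2``, ``eps2``).  Any
    unknown population, edge outside the fixed topology, missing edge or
    negative weight raises :class:`ModelValidationError`.
    """
    try:
        pops_cfg = config["populations"]
        conn_cfg = config["connectivity"]
        sig_cfg = config["sigmoid"]
        noise_cfg = config["noise"]
    except KeyError as exc:
        raise ModelValidationError(f"configuration section {exc.args[0]!r} is missing") from exc

    unknown = set(pops_cfg) - set(POPULATION_ORDER)
    if unknown:
        raise ModelValidationError(f"unknown population id(s): {sorted(unknown)}")
    missing = set(POPULATION_ORDER) - set(pops_cfg)
    if missing:
        raise ModelValidationError(f"missing population definition(s): {sorted(missing)}")

    populations = tuple(
        PopulationSpec(
            id=pid,
            kinetics=SynapticKinetics(
                gain=float(pops_cfg[pid]["gain"]), tau=float(pops_cfg[pid]["tau"])
            ),
            drive="noise" if pid in NOISE_POPULATIONS else "sigmoid",
        )
        for pid in POPULATION_ORDER
    )
    model = BTCModel(
        populations=populations,
        connectivity=_build_connectivity(conn_cfg),
        sigmoid_params=SigmoidParams(
            e0=float(sig_cfg["e0"]), v0=float(sig_cfg["v0"]), sigma=float(sig_cfg["sigma"])
        ),
        noise=NoiseSpec(
            mu1=float(noise_cfg["mu1"]),
            eps1=float(noise_cfg["eps1"]),
            mu2=float(noise_cfg["mu2"]),
            eps2=float(noise_cfg["eps2"]),
        ),
    )
    return model


def drift(state: ModelState, p1: float, p2: float, model: BTCModel) -> ModelState:
    """Deterministic derivative of the full 22-dimensional state for given noise draws.

    For each neural population the firing rate is the sigmoid of its signed
    PSP summation; for Ret and Cor the rate is the supplied draw ``p1`` or
    ``p2``.  Returns a :class:`ModelState` whose ``x`` field holds dx/dt and
    ``y`` field dy/dt.  Pure function of its inputs.
    """
    w = model.connectivity.signed_matrix()
    gains, taus = model.kinetics_arrays()
    v = w @ state.x
    phi = sigmoid(v, model.sigmoid_params)
    phi = np.asarray(phi, dtype=float)
    idx = model.index
    phi[idx["r"]] = p1
    phi[idx["c"]] = p2
    dy = (gains * taus * phi - 2.0 * taus * state.y - state.x) / (taus * taus)
    return ModelState(x=state.y.copy(), y=dy)
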