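"""Fixed-step simulation of conductance-based AdEx networks.

Each unit follows the adaptive exponential integrate-and-fire equations

    C dV/dt = -g_l (V - E_l) + g_l * Delta_T * exp((V - V_T)/Delta_T)
              - g_e (V - E_e) - g_i (V - E_i) - g_p (V - E_e) - w
    tau_w dw/dt = a (V - E_l) - w

with excitatory, inhibitory, and stimulus conductances g_e, g_i, g_p each
decaying exponentially with its own time constant.  When V crosses the spike
detection threshold V_t the unit's voltage is reset to E_l, its adaptation
current is incremented by b, and every downstream unit's g_e (excitatory
source) or g_i (inhibitory source) is incremented by the synaptic weight.
Stimulus spikes increment g_p, which also reverses at E_e.

A run halts either at ``max_duration`` (a *sustained* run) or as soon as the
network has been silent for 100 ms (a *truncated* run).  Integration is
forward Euler at dt = 0.1 ms with the conductance decay applied exactly; the
exponential spike-initiation term is clipped to keep the state finite in the
single step between threshold crossing and reset.

Units: time in ms, voltage in mV, conductance in nS, current in pA,
capacitance in pF (so nS*mV = pA and pA/pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .netbuild import SynapticNetwork

SILENCE_MS = 100.0       # halting criterion: no network spike for this long
_EXP_ARG_CEIL = 16.0     # clip on (V - V_T)/Delta_T before exponentiation


class NumericalInstabilityError(RuntimeError):
    def __init__(self, unit: int, time_ms: float):
        super().__init__(
            f"non-finite state at unit {unit}, t = {time_ms:.1f} ms")
        self.unit = unit
        self.time_ms = time_ms


@dataclass(frozen=True)
class NeuronParams:
    """AdEx unit parameters (published tonic-firing set by default)."""

    C: float = 281.0          # pF
    g_l: float = 30.0         # nS
    E_l: float = -70.6        # mV; also the post-spike reset potential
    V_T: float = -50.4        # mV, exponential threshold
    delta_T: float = 2.0      # mV, slope factor
    V_t: float = -40.0        # mV, spike detection threshold
    E_e: float = 0.0          # mV
    E_i: float = -80.0        # mV
    tau_w: float = 144.0      # ms
    tau_e: float = 5.0        # ms
    tau_i: float = 10.0       # ms
    tau_p: float = 5.0        # ms
    a: float = 4.0            # nS, subthreshold adaptation
    b: float = 80.5           # pA, spike-triggered adaptation
    t_ref: float = 0.0        # ms, absolute refractory period after reset

    def __post_init__(self) -> None:
        if min(self.tau_w, self.tau_e, self.tau_i, self.tau_p) <= 0:
            raise ValueError("time constants must be positive")
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if self.E_i >= self.E_e:
            raise ValueError("E_i must be below E_e")
        if self.V_t <= self.V_T:
            raise ValueError("V_t must exceed V_T")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class StimulusConfig:
    """Poisson kick-start: independent trains onto a fixed set of
    excitatory target units during the first ``duration_ms`` of a run."""

    n_input_units: int = 500
    rate_hz: float = 20.0
    duration_ms: float = 30.0
    input_weight_ns: float = 60.0   # g_p increment per stimulus spike
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or self.duration_ms < 0:
            raise ValueError("rate and duration must be non-negative")


@dataclass
class PoissonInput:
    """Realised stimulus: per-target spike-time arrays (ms)."""

    targets: np.ndarray                 # unit ids receiving input
    trains: list[np.ndarray]            # spike times per target, ms
    config: StimulusConfig

    @property
    def total_spikes(self) -> int:
        return sum(len(t) for t in self.trains)


@dataclass
class SimulationRun:
    """Spike raster and provenance of one simulation."""

    units: np.ndarray                   # spiking unit ids
    times: np.ndarray                   # spike times, ms (0.1 ms grid)
    n_units: int
    n_excitatory: int
    max_duration_ms: float
    outcome: str                        # "sustained" | "truncated"
    truncation_time_ms: float           # last spike time if truncated
    init_voltages: Optional[np.ndarray] = None
    stimulus: Optional[PoissonInput] = None
    seeds: dict = field(default_factory=dict)

    @property
    def sustained(self) -> bool:
        return self.outcome == "sustained"

    def last_spike_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


def init_voltages(n_units: int, seed: int | np.random.Generator = 0,
                  low: float = -60.0, high: float = -50.0) -> np.ndarray:
    """Uniform random initial membrane voltages on [low, high] mV."""
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n_units)


def choose_input_targets(network: SynapticNetwork, n_input_units: int,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random excitatory target set for the Poisson kick."""
    rng = np.random.default_rng(seed)
    return rng.choice(network.n_excitatory, size=n_input_units, replace=False)


def make_poisson_input(config: StimulusConfig,
                       targets: np.ndarray) -> PoissonInput:
    """Independent homogeneous Poisson trains over the stimulus window."""
    rng = np.random.default_rng(config.seed)
    rate_per_ms = config.rate_hz / 1000.0
    trains = []
    for _ in range(len(targets)):
        n = rng.poisson(rate_per_ms * config.duration_ms)
        trains.append(np.sort(rng.uniform(0.0, config.duration_ms, size=n)))
    return PoissonInput(targets=np.asarray(targets), trains=trains,
                        config=config)


def _stimulus_step_increments(stimulus: PoissonInput, dt: float,
                              n_steps: int, n_units: int):
    """Precompute, per integration step, which units receive stimulus and by
    how much g_p is incremented."""
    steps, units, amounts = [], [], []
    w = stimulus.config.input_weight_ns
    for target, train in zip(stimulus.targets, stimulus.trains):
        if len(train) == 0:
            continue
        k = np.minimum((train / dt).astype(np.int64), n_steps - 1)
        steps.append(k)
        units.append(np.full(len(k), target, dtype=np.int64))
        amounts.append(np.full(len(k), w))
    if not steps:
        return {}
    steps = np.concatenate(steps)
    units = np.concatenate(units)
    amounts = np.concatenate(amounts)
    order = np.argsort(steps, kind="stable")
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    steps, units, amounts = steps[order], units[order], amounts[order]
    bounds = np.flatnonzero(np.diff(steps)) + 1
    for chunk_u, chunk_a, s in zip(np.split(units, bounds),
                                   np.split(amounts, bounds),
                                   steps[np.r_[0, bounds]]):
        out[int(s)] = (chunk_u, chunk_a)
    return out


def simulate_run(
    network: SynapticNetwork,
    params: NeuronParams,
    stimulus: Optional[PoissonInput],
    init_v: np.ndarray,
    max_duration_ms: float = 1000.0,
    dt: float = 0.1,
    record_voltages: bool = False,
    voltage_sample_every: int = 10,
) -> SimulationRun:
    """Forward-integrate the network and return its spike raster.

    ``record_voltages`` stores excitatory voltage traces sampled every
    ``voltage_sample_every`` steps (used by the synchrony heuristic).
    """
    n = network.n_units
    if len(init_v) != n:
        raise ValueError("init_v length does not match network size")
    if dt <= 0:
        raise ValueError("dt must be positive")

    W = network.weights.tocsr()
    indptr, indices, data = W.indptr, W.indices, W.data
    ne = network.n_excitatory

    V = np.asarray(init_v, dtype=np.float64).copy()
    w = np.zeros(n)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    g_p = np.zeros(n)

    n_steps = int(round(max_duration_ms / dt))
    dec_e = np.exp(-dt / params.tau_e)
    dec_i = np.exp(-dt / params.tau_i)
    dec_p = np.exp(-dt / params.tau_p)
    inv_C = dt / params.C
    dt_over_tw = dt / params.tau_w

    stim_steps = (_stimulus_step_increments(stimulus, dt, n_steps, n)
                  if stimulus is not None else {})
    stim_end_step = max(stim_steps) if stim_steps else 0

    spike_units: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []
    voltage_samples: list[np.ndarray] = []
    voltage_sample_steps: list[int] = []

    last_spike_step = -1
    silence_steps = int(round(SILENCE_MS / dt))
    exc_mask = np.zeros(n, dtype=bool)
    exc_mask[:ne] = True

    n_ref_steps = int(round(params.t_ref / dt))
    ref_until = np.full(n, -1, dtype=np.int64)

    halted_step = n_steps
    for step in range(n_steps):
        inc = stim_steps.get(step)
        if inc is not None:
            np.add.at(g_p, inc[0], inc[1])

        arg = np.minimum((V - params.V_T) / params.delta_T, _EXP_ARG_CEIL)
        I = (-params.g_l * (V - params.E_l)
             + params.g_l * params.delta_T * np.exp(arg)
             - g_e * (V - params.E_e)
             - g_i * (V - params.E_i)
             - g_p * (V - params.E_e)
             - w)
        dV = inv_C * I
        if n_ref_steps:
            dV[ref_until > step] = 0.0    # voltage clamped at reset
        V += dV
        w += dt_over_tw * (params.a * (V - params.E_l) - w)
        g_e *= dec_e
        g_i *= dec_i
        g_p *= dec_p

        spikers = np.flatnonzero(V > params.V_t)
        if len(spikers):
            V[spikers] = params.E_l
            w[spikers] += params.b
            if n_ref_steps:
                ref_until[spikers] = step + n_ref_steps
            for s in spikers:
                lo, hi = indptr[s], indptr[s + 1]
                if hi > lo:
                    if s < ne:
                        np.add.at(g_e, indices[lo:hi], data[lo:hi])
                    else:
                        np.add.at(g_i, indices[lo:hi], data[lo:hi])
            spike_units.append(spikers.astype(np.int64))
            spike_steps.append(np.full(len(spikers), step, dtype=np.int64))
            last_spike_step = step

        if record_voltages and step % voltage_sample_every == 0:
            voltage_samples.append(V[:ne].copy())
            voltage_sample_steps.append(step)

        if step % 200 == 199 and not np.isfinite(V).all():
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise NumericalInstabilityError(bad, (step + 1) * dt)

        if last_spike_step >= 0 and step - last_spike_step >= silence_steps:
            halted_step = step
            break
        if last_spike_step < 0 and step - stim_end_step >= silence_steps:
            halted_step = step
            break

    if spike_units:
        units = np.concatenate(spike_units)
        times = (np.concatenate(spike_steps) + 1) * dt
    else:
        units = np.empty(0, dtype=np.int64)
        times = np.empty(0)

    last_t = float(times[-1]) if len(times) else 0.0
    sustained = halted_step >= n_steps
    run = SimulationRun(
        units=units, times=times, n_units=n, n_excitatory=ne,
        max_duration_ms=max_duration_ms,
        outcome="sustained" if sustained else "truncated",
        truncation_time_ms=max_duration_ms if sustained else last_t,
        init_voltages=np.asarray(init_v, dtype=np.float64),
        stimulus=stimulus,
    )
    if record_voltages:
        run.seeds["voltage_traces"] = np.asarray(voltage_samples).T
        run.seeds["voltage_times_ms"] = (
            np.asarray(voltage_sample_steps, dtype=np.float64) * dt)
    return run


def classify_outcome(run: SimulationRun,
                     silence_ms: float = SILENCE_MS) -> str:
    """Sustained iff spiking persists to within one silence window of the
    maximum duration; otherwise truncated at the last spike time."""
    if run.last_spike_time() >= run.max_duration_ms - silence_ms:
        return "sustained"
    return "truncated"
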