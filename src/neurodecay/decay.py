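"""Time-stepped synaptic degeneration on a directed weighted network.

Each day ``t``, every healthy link independently becomes *affected*
with probability ``p(t) = min(1, p0 + p1 * t)``; the slow growth of
``p`` captures the net progressive worsening (loss dominating repair).
An affected link's strength decays exponentially from its affection day
``t_a``::

    eps(t) = eps0 * exp(-(t - t_a) / tau)

and the link is removed (totally non-functional) once its strength has
fallen to ``1/e`` of its initial value -- i.e. exactly at day
``t_a + tau`` when ``tau`` is an integer multiple of the step.
Strengths are always recomputed from ``eps0`` and the elapsed time,
never by repeated multiplication, so the ``1/e`` crossing is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .network import AFFECTED, HEALTHY, INV_E, REMOVED, DirectedWeightedNetwork
from .netgen import ParameterError, SmallWorldSpec, WeightInitSpec, \
    assign_weights, generate_small_world

#: columns recorded every step; expensive metrics are NaN off-cadence
TRACE_COLUMNS = ["t", "f_lscc", "global_efficiency", "total_strength",
                 "clustering", "path_length",
                 "n_healthy", "n_affected", "n_removed"]

EXPENSIVE_METRICS = ("global_efficiency", "clustering", "path_length")


@dataclass(frozen=True)
class DecayParameters:
    """Parameters of the degeneration process (times in days)."""

    p0: float = 0.01         # initial per-link affection probability
    p1: float = 0.0001       # daily increment of the affection probability
    tau: float = 30.0        # exponential decay timescale of strengths
    dt: float = 1.0          # time step (one day)
    horizon: float = 400.0   # maximum simulated day
    seed: int = 0
    metric_cadence: int = 1  # days between expensive metric evaluations
    remove_at_threshold: bool = True  # disable to study pure decay

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ParameterError("p0 must lie in [0, 1]")
        if self.p1 < 0:
            raise ParameterError("p1 must be non-negative")
        if self.tau <= 0 or self.dt <= 0 or self.horizon < self.dt:
            raise ParameterError("require tau > 0, dt > 0, horizon >= dt")
        if self.metric_cadence < 1:
            raise ParameterError("metric_cadence must be a positive integer")

    def affection_probability(self, t: float) -> float:
        return min(1.0, self.p0 + self.p1 * t)


@dataclass
class SimulationTrace:
    """Per-day record of network observables along one run (or a mean)."""

    records: pd.DataFrame
    node_count: int
    edge_count: int

    @property
    def t(self) -> np.ndarray:
        return self.records["t"].to_numpy()

    @property
    def f(self) -> np.ndarray:
        return self.records["f_lscc"].to_numpy()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, node_count: int, edge_count: int = -1
                 ) -> "SimulationTrace":
        return cls(pd.read_csv(path), node_count, edge_count)


# ----------------------------------------------------------------------
def step(network: DirectedWeightedNetwork, t: float,
         params: DecayParameters, rng: np.random.Generator) -> dict:
    """Advance the degeneration state to day ``t`` (in place).

    Draws new affections among healthy links at probability ``p(t)``,
    recomputes every affected link's strength from its affection day,
    and removes links at or below the ``1/e`` threshold.  Returns a
    summary ``{"newly_affected": ..., "newly_removed": ...}``.
    """
    if t < 0:
        raise ParameterError("time must be non-negative")
    p = params.affection_probability(t)
    healthy = network.state == HEALTHY
    n_healthy = int(np.count_nonzero(healthy))
    newly_affected = 0
    if n_healthy and p > 0:
        hit = np.flatnonzero(healthy)[rng.random(n_healthy) < p]
        network.state[hit] = AFFECTED
        network.affected_at[hit] = int(round(t))
        newly_affected = hit.size

    live = network.state == AFFECTED
    if np.any(live):
        age = (t - network.affected_at[live]) / params.tau
        network.eps[live] = network.eps0[live] * np.exp(-age)

    newly_removed = 0
    if params.remove_at_threshold:
        live_idx = np.flatnonzero(live)
        below = network.eps[live_idx] <= network.eps0[live_idx] * INV_E
        gone = live_idx[below]
        network.state[gone] = REMOVED
        newly_removed = gone.size
    return {"newly_affected": int(newly_affected),
            "newly_removed": int(newly_removed)}


def _record(network: DirectedWeightedNetwork, t: float, wanted,
            full_metrics: bool) -> dict:
    nh, na, nr = network.counts()
    rec = {"t": t,
           "f_lscc": _metrics.lscc_fraction(network),
           "total_strength": _metrics.total_strength(network),
           "global_efficiency": math.nan,
           "clustering": math.nan,
           "path_length": math.nan,
           "n_healthy": nh, "n_affected": na, "n_removed": nr}
    if full_metrics:
        if "global_efficiency" in wanted:
            rec["global_efficiency"] = _metrics.global_efficiency(network)
        if "clustering" in wanted:
            rec["clustering"] = _metrics.clustering_coefficient(network)
        if "path_length" in wanted:
            apl = _metrics.average_path_length(network)
            rec["path_length"] = math.nan if apl is None else apl
    return rec


def run(network: DirectedWeightedNetwork, params: DecayParameters,
        metrics: tuple = (), copy: bool = True,
        snapshot_days: tuple = ()) -> SimulationTrace:
    """Simulate the full degeneration of one network.

    Iterates :func:`step` from day 0 to the horizon, stopping early
    once the LSCC has collapsed to a single node.  The LSCC fraction,
    strength total and edge-state counters are recorded every step;
    metrics named in ``metrics`` (any of ``global_efficiency``,
    ``clustering``, ``path_length``) every ``params.metric_cadence``
    days.  ``snapshot_days`` asks for copies of the network state at
    the given days, returned on ``trace.snapshots``.
    """
    net = network.copy() if copy else network
    rng = np.random.default_rng(params.seed)
    rows = []
    snapshots: dict = {}
    t = 0.0
    while t <= params.horizon + 1e-9:
        step(net, t, params, rng)
        day = int(round(t / params.dt))
        rec = _record(net, t, metrics,
                      full_metrics=(day % params.metric_cadence == 0))
        rows.append(rec)
        if day in set(int(d) for d in snapshot_days):
            snapshots[day] = net.copy()
        if rec["f_lscc"] * net.n <= 1.0:
            break
        t += params.dt
    trace = SimulationTrace(pd.DataFrame(rows, columns=TRACE_COLUMNS),
                            node_count=net.n, edge_count=net.m)
    trace.snapshots = snapshots
    return trace


# ----------------------------------------------------------------------
def derive_seed(base_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic, collision-free child seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(index), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class EnsembleResult:
    """Pointwise mean/dispersion of an ensemble of degeneration runs.

    Traces of different lengths are aligned on the common day grid;
    after a realisation's early stop its final values are carried
    forward (the network stays collapsed).
    """

    mean: SimulationTrace
    std: pd.DataFrame
    traces: list


def aggregate_traces(traces: list) -> EnsembleResult:
    tmax = max(tr.records["t"].iloc[-1] for tr in traces)
    dt = float(traces[0].records["t"].diff().iloc[-1]) if len(
        traces[0].records) > 1 else 1.0
    grid = np.arange(0.0, tmax + dt / 2, dt)
    aligned = []
    for tr in traces:
        df = tr.records.set_index("t").reindex(grid).ffill()
        aligned.append(df)
    stack = np.stack([df.to_numpy(dtype=float) for df in aligned])
    cols = aligned[0].columns
    with warnings.catch_warnings():
        # off-cadence metric rows are NaN in every trace by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = pd.DataFrame(np.nanmean(stack, axis=0), columns=cols)
        std = pd.DataFrame(np.nanstd(stack, axis=0), columns=cols)
    mean.insert(0, "t", grid)
    std.insert(0, "t", grid)
    mean_trace = SimulationTrace(mean, node_count=traces[0].node_count,
                                 edge_count=traces[0].edge_count)
    return EnsembleResult(mean=mean_trace, std=std,
                          traces=list(traces))


def run_ensemble(spec: SmallWorldSpec, weight_spec: WeightInitSpec,
                 params: DecayParameters, n_realizations: int,
                 base_seed: int = 0, metrics: tuple = ()) -> EnsembleResult:
    """Independent seeded realisations of network generation + decay.

    Each realisation draws its own network, weights and decay
    randomness from seeds derived via a counter-based scheme from
    ``(base_seed, index)``, so the ensemble is reproducible and its
    members independent.
    """
    if n_realizations < 1:
        raise ParameterError("need at least one realization")
    traces = []
    for r in range(n_realizations):
        net = generate_small_world(
            replace(spec, seed=derive_seed(base_seed, r, 0)))
        assign_weights(net, weight_spec, seed=derive_seed(base_seed, r, 1))
        p = replace(params, seed=derive_seed(base_seed, r, 2))
        traces.append(run(net, p, metrics=metrics, copy=False))
    return aggregate_traces(traces)


def calibrate_tau(remaining_fraction: float, duration: float) -> float:
    """Decay timescale from an observed strength loss over a duration.

    Inverts ``exp(-duration / tau) = remaining_fraction``.  E.g. a 50%
    loss of spine density over 3 weeks gives
    ``calibrate_tau(0.5, 21) = 21 / ln 2 ~ 30.3`` days.
    """
    if not 0.0 < remaining_fraction < 1.0:
        raise ParameterError("remaining_fraction must lie in (0, 1)")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    return -duration / math.log(remaining_fraction)
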