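"""Coupled spike-train generator with known ground-truth connectivity.

Spike trains are simulated as a multivariate modulated renewal process whose
conditional intensity for node ``i`` is

    lambda_i(t) = lambda0_i(u_i(t)) * exp( sum_j w_ji * Z_j(t) )

where ``u_i(t)`` is node i's backward recurrence time (time since its last
spike), ``lambda0_i`` is a renewal baseline hazard (Poisson or gamma), the
sum runs over ground-truth edges ``j -> i``, and ``Z_j(t)`` is an
exponentially decaying influence covariate of the reference train,
``Z_j(t) = exp(-u_j(t)/tau)`` (zero before j's first spike).  This is
exactly the intensity assumed by the Cox connectivity estimator in
:mod:`spikegraph.cox`, so parameter recovery on simulated data is a
well-posed test of that estimator.

Simulation is exact (no time discretization) by Ogata-style thinning: every
node's intensity is dominated by a constant bound -- the baseline hazard's
supremum times ``exp(sum of positive incoming weights)``, since the gamma
hazard is increasing and bounded for shape >= 1 and ``Z_j <= 1`` -- and
candidate points from the bounding Poisson superposition are accepted with
probability ``lambda_i(t) / bound_i``.  Rejected candidates advance time
without changing state.

The module also samples Holland-Leinhardt P1 random digraphs (independent
dyads with density, reciprocity, and per-node expansiveness/attractiveness
effects) for testing the P1 fitter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import ParameterError, SimulationError
from .spike_trains import SpikeTrainSet, StimulusSchedule

logger = logging.getLogger(__name__)

# exponent cap for the per-node thinning bound; beyond this the acceptance
# probability underflows and the simulation is effectively intractable
_MAX_LOG_BOUND = 30.0


@dataclass(frozen=True)
class GroundTruthGraph:
    """Directed coupling graph: edges (source, target) with log-hazard-ratio weights."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ParameterError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ParameterError(f"edge ({i},{j}) outside node range")
        if set(self.weights) != set(self.edges):
            raise ParameterError("weights must be given for exactly the edge set")
        if not all(math.isfinite(w) for w in self.weights.values()):
            raise ParameterError("weights must be finite")

    def parents(self, node: int) -> list[tuple[int, float]]:
        return [(i, self.weights[(i, j)]) for (i, j) in self.edges if j == node]

    def to_adjacency(self, labels: Sequence[int] | None = None) -> pd.DataFrame:
        labels = list(labels) if labels is not None else list(range(self.n_nodes))
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for i, j in self.edges:
            a[i, j] = 1
        return pd.DataFrame(a, index=labels, columns=labels)

    def to_edge_list(self) -> pd.DataFrame:
        rows = sorted((i, j, self.weights[(i, j)]) for (i, j) in self.edges)
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass(frozen=True)
class BaselineConfig:
    """Renewal baseline for one node.

    ``poisson`` gives a constant hazard equal to ``target_rate_hz``; ``gamma``
    gives a gamma-ISI renewal process with the given shape (>= 1 so the
    hazard is increasing and bounded) and mean ISI ``1/target_rate_hz``.
    """

    isi_family: str = "gamma"
    target_rate_hz: float = 8.0
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.isi_family not in ("poisson", "gamma"):
            raise ParameterError(f"unknown isi_family {self.isi_family!r}")
        if self.target_rate_hz <= 0:
            raise ParameterError("target_rate_hz must be positive")
        if self.isi_family == "gamma" and self.gamma_shape < 1:
            raise ParameterError("gamma_shape must be >= 1 (bounded hazard)")

    @property
    def hazard_sup(self) -> float:
        """Supremum of the baseline hazard over age."""
        if self.isi_family == "poisson":
            return self.target_rate_hz
        # gamma(k, scale=1/(k*r)): hazard increases to the asymptote 1/scale
        return self.gamma_shape * self.target_rate_hz

    def hazard(self, age: float) -> float:
        """Baseline hazard lambda0(age) = pdf(age) / sf(age)."""
        r = self.target_rate_hz
        if self.isi_family == "poisson":
            return r
        k = self.gamma_shape
        scale = 1.0 / (k * r)
        x = age / scale
        if x <= 0.0:
            return r if k == 1.0 else 0.0
        sf = special.gammaincc(k, x)
        if sf <= 0.0:
            return 1.0 / scale  # asymptotic hazard
        log_pdf = (k - 1.0) * math.log(x) - x - special.gammaln(k) - math.log(scale)
        return math.exp(log_pdf) / sf


@dataclass(frozen=True)
class KernelConfig:
    """Influence kernel applied to each reference train's backward recurrence time."""

    form: str = "exp_decay"
    tau_s: float = 0.01

    def __post_init__(self) -> None:
        if self.form != "exp_decay":
            raise ParameterError(f"unknown kernel form {self.form!r}")
        if self.tau_s <= 0:
            raise ParameterError("tau_s must be positive")


@dataclass
class SimulationResult:
    spikes: SpikeTrainSet
    truth: GroundTruthGraph
    seed: int


def make_ground_truth_graph(
    n_nodes: int,
    density: float,
    weight_range: tuple[float, float] = (0.8, 1.5),
    seed: int = 0,
) -> GroundTruthGraph:
    """Uniform random digraph at a given density with uniform edge weights.

    The edge count is ``round(density * n_nodes * (n_nodes - 1))``, sampled
    without replacement among ordered non-self pairs.
    """
    if n_nodes < 2:
        raise ParameterError("n_nodes must be >= 2")
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must be in [0, 1]")
    lo, hi = weight_range
    if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
        raise ParameterError("weight_range must be a finite interval")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    m = int(round(density * n_nodes * (n_nodes - 1)))
    idx = rng.choice(len(pairs), size=m, replace=False)
    edges = frozenset(pairs[k] for k in idx)
    weights = {e: float(w) for e, w in zip(sorted(edges), rng.uniform(lo, hi, size=m))}
    return GroundTruthGraph(n_nodes=n_nodes, edges=edges, weights=weights)


def _as_baseline_list(
    baseline: BaselineConfig | Sequence[BaselineConfig] | Mapping[int, BaselineConfig],
    n_nodes: int,
) -> list[BaselineConfig]:
    if isinstance(baseline, BaselineConfig):
        return [baseline] * n_nodes
    if isinstance(baseline, Mapping):
        return [baseline[i] for i in range(n_nodes)]
    baseline = list(baseline)
    if len(baseline) != n_nodes:
        raise ParameterError("need one BaselineConfig per node")
    return baseline


def simulate_spike_trains(
    truth: GroundTruthGraph,
    baseline: BaselineConfig | Sequence[BaselineConfig] | Mapping[int, BaselineConfig],
    kernel: KernelConfig,
    duration_s: float,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> SimulationResult:
    """Simulate the coupled modulated renewal process by thinning.

    The origin is treated as a virtual renewal epoch for every node (each
    node's age runs from time 0), but influence covariates are zero until a
    reference actually fires.  Identical (inputs, seed) give identical
    output.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n = truth.n_nodes
    baselines = _as_baseline_list(baseline, n)
    labels = list(labels) if labels is not None else list(range(n))
    if len(labels) != n:
        raise ParameterError("need one label per node")
    rng = np.random.default_rng(seed)
    tau = kernel.tau_s

    parents: list[list[tuple[int, float]]] = [truth.parents(i) for i in range(n)]
    log_bounds = np.array(
        [
            math.log(baselines[i].hazard_sup) + sum(max(0.0, w) for _, w in parents[i])
            for i in range(n)
        ]
    )
    for i in range(n):
        if log_bounds[i] > _MAX_LOG_BOUND:
            raise SimulationError(
                f"node {labels[i]}: thinning bound exp({log_bounds[i]:.1f}) is "
                "intractably large; reduce incoming excitatory weights"
            )
    bounds = np.exp(log_bounds)
    total = float(bounds.sum())
    cum = np.cumsum(bounds) / total

    last = np.zeros(n)  # virtual renewal epoch at t=0
    has_spiked = np.zeros(n, dtype=bool)
    out: list[list[float]] = [[] for _ in range(n)]

    t = 0.0
    while True:
        t += rng.exponential(1.0 / total)
        if t >= duration_s:
            break
        i = int(np.searchsorted(cum, rng.random(), side="right"))
        lam = baselines[i].hazard(t - last[i])
        if parents[i]:
            s = 0.0
            for j, w in parents[i]:
                if has_spiked[j]:
                    s += w * math.exp(-(t - last[j]) / tau)
            lam *= math.exp(s)
        if rng.random() * bounds[i] < lam:
            out[i].append(t)
            last[i] = t
            has_spiked[i] = True

    spikes = SpikeTrainSet(
        channel_ids=labels,
        spikes={lab: np.asarray(out[i]) for i, lab in enumerate(labels)},
        duration_s=float(duration_s),
    )
    return SimulationResult(spikes=spikes, truth=truth, seed=seed)


def simulate_stimulus_session(
    truth_per_stimulus: Mapping[int, GroundTruthGraph],
    baseline: BaselineConfig | Sequence[BaselineConfig],
    kernel: KernelConfig,
    n_trials: int = 20,
    trial_s: float = 6.0,
    gap_s: float = 1.0,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> tuple[SpikeTrainSet, StimulusSchedule]:
    """Interleave randomized trials of each stimulus into one session.

    Every stimulus gets ``n_trials`` trials of ``trial_s`` seconds; the
    presentation order is a random permutation of all trials, with silent
    gaps of ``gap_s`` between consecutive trials.  Within a trial the spike
    trains follow that stimulus's ground-truth graph (each trial is an
    independent realization).
    """
    if not truth_per_stimulus:
        raise ParameterError("truth_per_stimulus must not be empty")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if trial_s <= 0:
        raise ParameterError("trial_s must be positive")
    if gap_s < 0:
        raise ParameterError("gap_s must be non-negative")
    n_nodes = {g.n_nodes for g in truth_per_stimulus.values()}
    if len(n_nodes) != 1:
        raise ParameterError("all stimuli must share the same node set")
    n = n_nodes.pop()
    labels = list(labels) if labels is not None else list(range(n))

    rng = np.random.default_rng(seed)
    slots = [(stim, k) for stim in sorted(truth_per_stimulus) for k in range(n_trials)]
    rng.shuffle(slots)

    per_channel: dict[int, list[np.ndarray]] = {lab: [] for lab in labels}
    entries = []
    t0 = 0.0
    for stim, trial_idx in slots:
        child_seed = int(rng.integers(0, 2**31 - 1))
        res = simulate_spike_trains(
            truth_per_stimulus[stim], baseline, kernel, trial_s, seed=child_seed, labels=labels
        )
        for lab in labels:
            per_channel[lab].append(res.spikes.spikes[lab] + t0)
        entries.append((stim, trial_idx, t0, t0 + trial_s))
        t0 += trial_s + gap_s
    duration = t0 - gap_s if gap_s > 0 else t0
    schedule = StimulusSchedule(
        entries=pd.DataFrame(entries, columns=["stimulus_id", "trial_index", "start_s", "end_s"])
    )
    spikes = SpikeTrainSet(
        channel_ids=labels,
        spikes={lab: np.concatenate(per_channel[lab]) for lab in labels},
        duration_s=max(duration, trial_s),
    )
    return spikes, schedule


def sample_p1_network(
    theta: float,
    rho: float,
    alpha: Sequence[float],
    beta_attr: Sequence[float],
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sample a digraph from the Holland-Leinhardt P1 model.

    Dyads are independent; for each unordered pair {i, j} the four states
    have probabilities proportional to::

        null:    1
        i -> j:  exp(theta + alpha_i + beta_j)
        j -> i:  exp(theta + alpha_j + beta_i)
        mutual:  exp(2*theta + rho + alpha_i + alpha_j + beta_i + beta_j)

    Returns the adjacency as a labelled DataFrame (rows = sources).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta_attr = np.asarray(beta_attr, dtype=float)
    if alpha.shape != beta_attr.shape or alpha.ndim != 1 or alpha.size < 2:
        raise ParameterError("alpha and beta_attr must be equal-length vectors, n >= 2")
    if not (np.isfinite(alpha).all() and np.isfinite(beta_attr).all()
            and math.isfinite(theta) and math.isfinite(rho)):
        raise ParameterError("P1 parameters must be finite")
    n = alpha.size
    labels = list(labels) if labels is not None else list(range(n))
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            logw = np.array(
                [
                    0.0,
                    theta + alpha[i] + beta_attr[j],
                    theta + alpha[j] + beta_attr[i],
                    2 * theta + rho + alpha[i] + alpha[j] + beta_attr[i] + beta_attr[j],
                ]
            )
            w = np.exp(logw - logw.max())
            state = rng.choice(4, p=w / w.sum())
            if state in (1, 3):
                a[i, j] = 1
            if state in (2, 3):
                a[j, i] = 1
    return pd.DataFrame(a, index=labels, columns=labels)


def p1_dyad_probabilities(
    theta: float, rho: float, alpha_i: float, alpha_j: float, beta_i: float, beta_j: float
) -> np.ndarray:
    """Analytic four-cell dyad distribution (null, i->j, j->i, mutual)."""
    logw = np.array(
        [
            0.0,
            theta + alpha_i + beta_j,
            theta + alpha_j + beta_i,
            2 * theta + rho + alpha_i + alpha_j + beta_i + beta_j,
        ]
    )
    w = np.exp(logw - logw.max())
    return w / w.sum()
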