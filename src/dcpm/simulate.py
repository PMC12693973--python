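"""Synthetic multi-subject datasets with planted predictive subnetworks.

The generator emulates a trial-structured fMRI study design: each subject
contributes one node-by-time matrix per session/run, node signals are
band-limited Gaussian noise, and during each trial window a shared
band-limited component is injected into both endpoints of every planted
edge.  The injected amplitude increases with the trial's behavior value for
positive edges and decreases for negative edges, so trial-averaged phase
synchrony at the planted edges correlates with behavior — and, in
expectation, nowhere else.  Behavior itself comes from a latent Gaussian
per trial: the arousal rating is the latent discretized to 1-4 at its
quartiles, and the memory outcome is Bernoulli with log-odds linear in the
latent, which makes the correlation between the two constructs tunable.

There is no hemodynamic forward model: coupling is injected directly into
the band-limited signal, and the downstream hemodynamic shift simply has to
be consistent with where the generator places the coupling (the injected
window covers the shifted averaging window used by the analysis defaults).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .connectivity import DEFAULT_BAND, NodeTimeSeries, edge_pairs, n_edges

logger = logging.getLogger("dcpm")

SESSION_LABELS = ("cortisol", "placebo")
RUN_LABELS = ("emotional", "neutral")

Edge = tuple[int, int]


def _canon(edges) -> frozenset[Edge]:
    return frozenset((min(i, j), max(i, j)) for i, j in edges)


@dataclass
class SimulationSpec:
    """Design and signal parameters for one synthetic dataset.

    coupling_strength is the amplitude of the injected shared component in
    units of the node noise standard deviation; behavior_model names the
    construct whose value drives the planted coupling ("binary" = memory,
    "ordinal" = arousal).  secondary planted sets are driven by the other
    construct, which is what cross-construct generalization tests need.
    """

    n_subjects: int = 10
    n_nodes: int = 100
    n_sessions: int = 2
    n_runs_per_session: int = 2
    n_trials_per_run: int = 20
    sampling_interval: float = 1.0
    trial_duration: int = 16       # samples with injected coupling
    inter_trial_interval: int = 4  # samples between trial windows
    pre_pad: int = 20              # baseline samples before the first onset
    post_pad: int = 20
    band: tuple[float, float] = DEFAULT_BAND
    planted_positive_edges: frozenset[Edge] = frozenset()
    planted_negative_edges: frozenset[Edge] = frozenset()
    secondary_positive_edges: frozenset[Edge] = frozenset()
    secondary_negative_edges: frozenset[Edge] = frozenset()
    coupling_strength: float = 0.0
    noise_sd: float = 1.0
    behavior_model: str = "ordinal"     # "binary" (memory) or "ordinal" (arousal)
    memory_slope: float = 1.5           # log-odds of memory per latent unit
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_positive_edges = _canon(self.planted_positive_edges)
        self.planted_negative_edges = _canon(self.planted_negative_edges)
        self.secondary_positive_edges = _canon(self.secondary_positive_edges)
        self.secondary_negative_edges = _canon(self.secondary_negative_edges)
        self.validate()

    @property
    def n_runs_per_subject(self) -> int:
        return self.n_sessions * self.n_runs_per_session

    @property
    def run_length(self) -> int:
        period = self.trial_duration + self.inter_trial_interval
        return self.pre_pad + self.n_trials_per_run * period + self.post_pad

    @property
    def onsets(self) -> np.ndarray:
        period = self.trial_duration + self.inter_trial_interval
        return self.pre_pad + period * np.arange(self.n_trials_per_run)

    def validate(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_sessions",
                     "n_runs_per_session", "n_trials_per_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"invariant violated: {name} must be >= 1")
        if self.n_nodes < 2:
            raise ValueError("invariant violated: n_nodes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("invariant violated: noise_sd must be > 0")
        if self.coupling_strength < 0:
            raise ValueError("invariant violated: coupling_strength must be >= 0")
        if self.behavior_model not in ("binary", "ordinal"):
            raise ValueError(
                "invariant violated: behavior_model must be 'binary' or 'ordinal'"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("invariant violated: missing_fraction must be in [0, 1)")
        if self.planted_positive_edges & self.planted_negative_edges:
            raise ValueError(
                "invariant violated: planted positive and negative edge sets overlap"
            )
        for es in (self.planted_positive_edges, self.planted_negative_edges,
                   self.secondary_positive_edges, self.secondary_negative_edges):
            for i, j in es:
                if i == j:
                    raise ValueError("invariant violated: self-pair planted edge")
                if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                    raise ValueError(
                        f"invariant violated: planted edge ({i}, {j}) has a node "
                        f"index >= n_nodes ({self.n_nodes})"
                    )
        nyq = 0.5 / self.sampling_interval
        if not (0 < self.band[0] < self.band[1] < nyq):
            raise ValueError("invariant violated: band outside (0, Nyquist)")
        if self.onsets[-1] + self.trial_duration > self.run_length:
            raise ValueError("invariant violated: trial windows exceed run length")


@dataclass
class GroundTruth:
    """What the generator planted: behavior, edges, per-trial amplitudes."""

    trials: pd.DataFrame
    planted_positive_edges: frozenset[Edge]
    planted_negative_edges: frozenset[Edge]
    secondary_positive_edges: frozenset[Edge] = frozenset()
    secondary_negative_edges: frozenset[Edge] = frozenset()
    amplitudes: pd.DataFrame = field(default=None)  # per trial x edge-class


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, int],
                       band: tuple[float, float], fs: float) -> np.ndarray:
    """White Gaussian noise filtered to the analysis band, unit sd per row."""
    white = rng.standard_normal(shape)
    b, a = butter(2, list(band), btype="bandpass", fs=fs)
    x = filtfilt(b, a, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _draw_behavior(rng: np.random.Generator, n: int, memory_slope: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent Gaussian -> (latent, arousal 1-4, memory 0/1)."""
    z = rng.standard_normal(n)
    # quartile cutpoints of the standard normal -> roughly balanced ratings
    cuts = np.array([-0.6744897501960817, 0.0, 0.6744897501960817])
    arousal = 1 + np.searchsorted(cuts, z)
    p = 1.0 / (1.0 + np.exp(-memory_slope * z))
    memory = (rng.random(n) < p).astype(int)
    return z, arousal.astype(int), memory


def _b_norm(construct: str, arousal: np.ndarray, memory: np.ndarray) -> np.ndarray:
    if construct == "binary":
        return memory.astype(float)
    return (arousal - 1) / 3.0


def simulate_dataset(spec: SimulationSpec
                     ) -> tuple[list[NodeTimeSeries], pd.DataFrame, GroundTruth]:
    """Generate node time series, a trial table, and the planted ground truth.

    Identical spec (including seed) gives bit-identical output.  Behavior is
    drawn per trial; planted positive edges receive a shared band-limited
    component at amplitude ``coupling_strength * b`` (b the construct value
    normalized to [0, 1]) during the trial window, negative edges at
    ``coupling_strength * (1 - b)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = 1.0 / spec.sampling_interval
    onsets = spec.onsets
    run_len = spec.run_length

    pos_edges = sorted(spec.planted_positive_edges)
    neg_edges = sorted(spec.planted_negative_edges)
    sec_pos = sorted(spec.secondary_positive_edges)
    sec_neg = sorted(spec.secondary_negative_edges)
    primary = spec.behavior_model
    secondary = "ordinal" if primary == "binary" else "binary"

    series: list[NodeTimeSeries] = []
    rows: list[dict] = []
    amp_rows: list[dict] = []

    sessions = [SESSION_LABELS[i] if spec.n_sessions <= 2 else f"session{i}"
                for i in range(spec.n_sessions)]
    runs = [RUN_LABELS[i] if spec.n_runs_per_session <= 2 else f"run{i}"
            for i in range(spec.n_runs_per_session)]

    for s in range(spec.n_subjects):
        subject = f"sub{s:03d}"
        for sess in sessions:
            for run in runs:
                x = spec.noise_sd * _bandlimited_noise(
                    rng, (spec.n_nodes, run_len), spec.band, fs)
                z, arousal, memory = _draw_behavior(
                    rng, spec.n_trials_per_run, spec.memory_slope)
                b_prim = _b_norm(primary, arousal, memory)
                b_sec = _b_norm(secondary, arousal, memory)

                all_edges = pos_edges + neg_edges + sec_pos + sec_neg
                if all_edges and spec.coupling_strength > 0:
                    shared = _bandlimited_noise(
                        rng, (len(all_edges), run_len), spec.band, fs)
                    for k, onset in enumerate(onsets):
                        sl = slice(onset, onset + spec.trial_duration)
                        amps = np.concatenate([
                            np.full(len(pos_edges), b_prim[k]),
                            np.full(len(neg_edges), 1.0 - b_prim[k]),
                            np.full(len(sec_pos), b_sec[k]),
                            np.full(len(sec_neg), 1.0 - b_sec[k]),
                        ]) * spec.coupling_strength
                        for (i, j), amp, comp in zip(all_edges, amps, shared):
                            if amp > 0:
                                x[i, sl] += amp * comp[sl]
                                x[j, sl] += amp * comp[sl]
                        amp_rows.append({
                            "subject": subject, "session": sess, "run": run,
                            "trial": k,
                            "amp_positive": spec.coupling_strength * b_prim[k],
                            "amp_negative": spec.coupling_strength * (1 - b_prim[k]),
                        })

                series.append(NodeTimeSeries(
                    subject=subject, session=sess, run=run, values=x,
                    sampling_interval=spec.sampling_interval))
                for k, onset in enumerate(onsets):
                    rows.append({
                        "subject": subject, "session": sess, "run": run,
                        "onset_sample": int(onset),
                        "memory": int(memory[k]), "arousal": int(arousal[k]),
                        "latent": float(z[k]),
                    })

    trials = pd.DataFrame(rows)
    if spec.missing_fraction > 0:
        for col in ("memory", "arousal"):
            mask = rng.random(len(trials)) < spec.missing_fraction
            trials[col] = trials[col].astype(float)
            trials.loc[mask, col] = np.nan

    truth = GroundTruth(
        trials=trials.copy(),
        planted_positive_edges=spec.planted_positive_edges,
        planted_negative_edges=spec.planted_negative_edges,
        secondary_positive_edges=spec.secondary_positive_edges,
        secondary_negative_edges=spec.secondary_negative_edges,
        amplitudes=pd.DataFrame(amp_rows) if amp_rows else None,
    )
    return series, trials, truth


def random_planted_edges(n_nodes: int, n_positive: int, n_negative: int,
                         seed: int = 0
                         ) -> tuple[frozenset[Edge], frozenset[Edge]]:
    """Disjoint positive/negative edge sets drawn uniformly from the universe."""
    rng = np.random.default_rng(seed)
    pairs = edge_pairs(n_nodes)
    if n_positive + n_negative > len(pairs):
        raise ValueError("more planted edges requested than the universe holds")
    pick = rng.choice(len(pairs), size=n_positive + n_negative, replace=False)
    pos = _canon(map(tuple, pairs[pick[:n_positive]]))
    neg = _canon(map(tuple, pairs[pick[n_positive:]]))
    return pos, neg


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def design_preset_paper(seed: int = 0) -> SimulationSpec:
    """The reference study design: 26 subjects x 2 sessions x 2 runs x 40
    trials, 377 nodes (368-node functional atlas plus 9 stress-system
    nodes), 1-s sampling.  No planted coupling by default."""
    return SimulationSpec(
        n_subjects=26, n_nodes=377, n_sessions=2, n_runs_per_session=2,
        n_trials_per_run=40, sampling_interval=1.0, seed=seed,
    )


def design_preset_desk(seed: int = 0, coupling_strength: float = 0.0,
                       n_planted: int = 15) -> SimulationSpec:
    """Desk-scale preset: 10 subjects, 100 nodes, 20 trials/run."""
    pos, neg = (frozenset(), frozenset())
    if coupling_strength > 0:
        pos, neg = random_planted_edges(100, n_planted, n_planted, seed=seed + 1)
    return SimulationSpec(
        n_subjects=10, n_nodes=100, n_sessions=2, n_runs_per_session=2,
        n_trials_per_run=20, planted_positive_edges=pos,
        planted_negative_edges=neg, coupling_strength=coupling_strength,
        seed=seed,
    )


def preset_null_small(seed: int = 0, n_subjects: int = 6, n_nodes: int = 40,
                      n_trials_per_run: int = 15) -> SimulationSpec:
    """Compact single-run null preset for calibration studies."""
    return SimulationSpec(
        n_subjects=n_subjects, n_nodes=n_nodes, n_sessions=1,
        n_runs_per_session=1, n_trials_per_run=n_trials_per_run,
        coupling_strength=0.0, seed=seed,
    )


def preset_generalization(shared: bool, seed: int = 0, n_subjects: int = 10,
                          n_nodes: int = 40, n_trials_per_run: int = 30,
                          coupling_strength: float = 2.0,
                          n_planted: int = 20) -> SimulationSpec:
    """Preset pair for cross-construct generalization studies.

    ``shared=True``: one planted network driven by arousal, with the memory
    outcome correlated with arousal (rho ~ 0.7) through the shared latent,
    so a memory-selected network should transfer to arousal prediction.
    ``shared=False``: arousal and memory are independent (memory slope 0)
    and drive disjoint planted networks, so cross-construct transfer should
    sit in the permutation null.
    """
    rng_seed = seed + 1
    if shared:
        pos, neg = random_planted_edges(n_nodes, n_planted, n_planted,
                                        seed=rng_seed)
        return SimulationSpec(
            n_subjects=n_subjects, n_nodes=n_nodes, n_sessions=1,
            n_runs_per_session=1, n_trials_per_run=n_trials_per_run,
            planted_positive_edges=pos, planted_negative_edges=neg,
            coupling_strength=coupling_strength, behavior_model="ordinal",
            memory_slope=3.0, seed=seed,
        )
    # node-disjoint networks: injected components perturb the phases of the
    # nodes they touch, so sharing a node would couple the constructs even
    # with independent behaviors
    half = n_nodes // 2
    rng = np.random.default_rng(rng_seed)

    def _draw(nodes: np.ndarray, k: int) -> list[frozenset[Edge]]:
        pool = [(int(nodes[a]), int(nodes[b]))
                for a in range(len(nodes)) for b in range(a + 1, len(nodes))]
        pick = rng.choice(len(pool), size=2 * k, replace=False)
        return [_canon(pool[q] for q in pick[:k]),
                _canon(pool[q] for q in pick[k:])]

    a_pos, a_neg = _draw(np.arange(half), n_planted)
    m_pos, m_neg = _draw(np.arange(half, n_nodes), n_planted)
    return SimulationSpec(
        n_subjects=n_subjects, n_nodes=n_nodes, n_sessions=1,
        n_runs_per_session=1, n_trials_per_run=n_trials_per_run,
        planted_positive_edges=a_pos, planted_negative_edges=a_neg,
        secondary_positive_edges=m_pos, secondary_negative_edges=m_neg,
        coupling_strength=coupling_strength, behavior_model="ordinal",
        memory_slope=0.0, seed=seed,
    )


def preset_strong_coupling(seed: int = 0, n_subjects: int = 14,
                           n_nodes: int = 50, n_trials_per_run: int = 40,
                           coupling_strength: float = 2.0,
                           n_planted: int = 30) -> SimulationSpec:
    """Single-run preset with strong planted coupling for recovery studies.

    The planted fraction is deliberately large relative to alpha times the
    edge-universe size: consensus over leave-one-trial-out folds removes few
    chance selections (adjacent folds share all but one trial), so the
    achievable consensus precision is roughly
    n_planted / (n_planted + alpha/2 * n_edges).
    """
    pos, neg = random_planted_edges(n_nodes, n_planted, n_planted, seed=seed + 1)
    return SimulationSpec(
        n_subjects=n_subjects, n_nodes=n_nodes, n_sessions=1,
        n_runs_per_session=1, n_trials_per_run=n_trials_per_run,
        planted_positive_edges=pos, planted_negative_edges=neg,
        coupling_strength=coupling_strength, seed=seed,
    )
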