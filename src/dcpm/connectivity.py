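"""Dynamic connectivity: band-limited phase synchrony edge time series.

The pipeline's first stage turns node time series into per-timepoint
phase-synchrony "edge time series": each node signal is band-pass filtered,
its instantaneous phase is extracted from the analytic (Hilbert) signal, and
for every unordered node pair (i, j) the synchrony at sample t is
cos(phi_i(t) - phi_j(t)), i.e. 1 when the two nodes are in phase and -1 when
they are in antiphase.  Trial-level connectomes are then window averages of
the edge time series, shifted forward to account for hemodynamic lag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

logger = logging.getLogger("dcpm")

# Analysis-band and trial-window defaults (seconds / Hz).
DEFAULT_BAND = (0.008, 0.12)
DEFAULT_SHIFT_S = 5.0
DEFAULT_WINDOW_S = 10.0
FILTER_ORDER = 2  # per pass; forward-backward application doubles it


# ---------------------------------------------------------------------------
# Edge indexing: (i, j) with i < j, row-major over the upper triangle.
# All modules share this canonical order.
# ---------------------------------------------------------------------------

def n_edges(n_nodes: int) -> int:
    """Size of the edge universe for ``n_nodes`` (no self pairs)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> np.ndarray:
    """(n_edges, 2) array of node pairs in canonical upper-triangle order."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Canonical edge index of the unordered pair (i, j)."""
    if i == j:
        raise ValueError("self-pairs are not edges")
    if not (0 <= i < n_nodes and 0 <= j < n_nodes):
        raise ValueError(f"node out of range for n_nodes={n_nodes}: ({i}, {j})")
    if i > j:
        i, j = j, i
    # edges with first node < i, plus offset within row i
    return i * n_nodes - i * (i + 1) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NodeTimeSeries:
    """One subject/run matrix of node signals over time.

    values is n_nodes x n_samples; sampling_interval is the repetition time
    in seconds (1 s in the reference study design).
    """

    subject: str
    session: str
    run: str
    values: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (nodes x samples) matrix")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at node {bad[0]}, sample {bad[1]}"
            )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseMatrix:
    """Instantaneous phases per node and sample, radians in (-pi, pi]."""

    phases: np.ndarray
    sampling_interval: float
    low_confidence: np.ndarray = field(default=None)  # boolean sample mask

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.phases.shape[1], dtype=bool)


@dataclass
class EdgeSynchronyTensor:
    """Per-timepoint phase synchrony for all node pairs.

    synchrony is n_edges x n_samples with values in [-1, 1]; rows follow the
    canonical upper-triangle edge order of :func:`edge_pairs`.
    """

    n_nodes: int
    synchrony: np.ndarray
    sampling_interval: float
    subject: str = ""
    session: str = ""
    run: str = ""
    low_confidence: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.synchrony = np.asarray(self.synchrony, dtype=float)
        if self.synchrony.shape[0] != n_edges(self.n_nodes):
            raise ValueError(
                f"expected {n_edges(self.n_nodes)} edge rows for "
                f"{self.n_nodes} nodes, got {self.synchrony.shape[0]}"
            )
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.synchrony.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.synchrony.shape[1]

    @property
    def pairs(self) -> np.ndarray:
        return edge_pairs(self.n_nodes)


@dataclass
class TrialEdgeMatrix:
    """Trial-averaged synchrony: rows = retained trials, columns = edges.

    trial_index holds positional back-pointers into the trial table the
    matrix was built from, so behavior vectors can be realigned after the
    exclusion rules (missing behavior, window past run end) have dropped
    trials.
    """

    values: np.ndarray
    n_nodes: int
    trial_index: np.ndarray
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def behavior(self, construct: str) -> np.ndarray:
        """Aligned behavior vector for ``construct`` (memory / arousal)."""
        return self.trials[construct].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bandpass(
    ts: NodeTimeSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> NodeTimeSeries:
    """Zero-phase Butterworth band-pass of every node signal.

    Forward-backward (filtfilt) application keeps the filter zero-phase so
    downstream instantaneous-phase estimates are not lagged.  Output length
    equals input length.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    b, a = butter(FILTER_ORDER, [low, high], btype="bandpass", fs=1.0 / ts.sampling_interval)
    filtered = filtfilt(b, a, ts.values, axis=1)
    return replace(ts, values=filtered)


def instantaneous_phase(ts: NodeTimeSeries) -> PhaseMatrix:
    """Phase of the analytic signal per node and sample.

    Assumes the input is already band-limited (narrowband), so the analytic
    signal's angle is interpretable as instantaneous phase.  All-zero node
    rows have undefined phase and are rejected, naming the node.  The first
    and last ceil(1/low) seconds are flagged low-confidence (Hilbert edge
    effects); windows overlapping them are retained but logged downstream.
    """
    zero_rows = np.where(~ts.values.any(axis=1))[0]
    if zero_rows.size:
        raise ValueError(
            f"phase undefined for all-zero node(s): {zero_rows.tolist()}"
        )
    phases = np.angle(hilbert(ts.values, axis=1))
    edge_len = int(np.ceil((1.0 / DEFAULT_BAND[0]) / ts.sampling_interval))
    edge_len = min(edge_len, ts.n_samples // 2)
    low_conf = np.zeros(ts.n_samples, dtype=bool)
    if edge_len > 0:
        low_conf[:edge_len] = True
        low_conf[-edge_len:] = True
    return PhaseMatrix(phases=phases, sampling_interval=ts.sampling_interval,
                       low_confidence=low_conf)


def phase_synchrony(
    phases: PhaseMatrix,
    subject: str = "",
    session: str = "",
    run: str = "",
) -> EdgeSynchronyTensor:
    """cos(phi_i - phi_j) for every unordered node pair at every sample.

    Uses cos(a - b) = cos a cos b + sin a sin b so the full tensor is two
    matrix products rather than an explicit pair loop.
    """
    p = phases.phases
    nn = p.shape[0]
    iu, ju = np.triu_indices(nn, k=1)
    c, s = np.cos(p), np.sin(p)
    sync = c[iu] * c[ju] + s[iu] * s[ju]
    np.clip(sync, -1.0, 1.0, out=sync)
    return EdgeSynchronyTensor(
        n_nodes=nn,
        synchrony=sync,
        sampling_interval=phases.sampling_interval,
        subject=subject,
        session=session,
        run=run,
        low_confidence=phases.low_confidence.copy(),
    )


def compute_synchrony(
    ts: NodeTimeSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> EdgeSynchronyTensor:
    """Convenience: bandpass -> Hilbert phase -> cosine phase synchrony."""
    ph = instantaneous_phase(bandpass(ts, low, high))
    return phase_synchrony(ph, subject=ts.subject, session=ts.session, run=ts.run)


def trial_average(
    tensors: EdgeSynchronyTensor | list[EdgeSynchronyTensor],
    trials: pd.DataFrame,
    shift: float = DEFAULT_SHIFT_S,
    window: float = DEFAULT_WINDOW_S,
    construct: str | None = None,
) -> TrialEdgeMatrix:
    """Average each edge's synchrony over a shifted per-trial window.

    For each trial the window is the half-open sample range
    [onset + shift, onset + shift + window), with seconds converted to whole
    samples by rounding toward zero.  The forward shift accounts for the
    hemodynamic delay between the event and its BOLD response.  Trials whose
    window would run past the end of the run are dropped (not truncated),
    and trials with missing behavior for ``construct`` are excluded when a
    construct is given.  Rows pool all supplied subject/run tensors.
    """
    if isinstance(tensors, EdgeSynchronyTensor):
        tensors = [tensors]
    by_key = {(t.subject, t.session, t.run): t for t in tensors}
    dt = tensors[0].sampling_interval
    shift_n = int(shift / dt)
    window_n = int(window / dt)
    if window_n < 1:
        raise ValueError("window shorter than one sample")

    rows: list[np.ndarray] = []
    kept: list[int] = []
    n_dropped_window = 0
    n_dropped_missing = 0
    n_low_conf = 0
    for pos, (idx, tr) in enumerate(trials.iterrows()):
        key = (str(tr["subject"]), str(tr["session"]), str(tr["run"]))
        tensor = by_key.get(key)
        if tensor is None:
            raise KeyError(f"no synchrony tensor for subject/session/run {key}")
        if construct is not None and pd.isna(tr[construct]):
            n_dropped_missing += 1
            continue
        start = int(tr["onset_sample"]) + shift_n
        stop = start + window_n
        if start < 0 or stop > tensor.n_samples:
            n_dropped_window += 1
            logger.warning(
                "trial at row %s dropped: window [%d, %d) outside run of "
                "%d samples", idx, start, stop, tensor.n_samples,
            )
            continue
        if tensor.low_confidence[start:stop].any():
            n_low_conf += 1
        rows.append(tensor.synchrony[:, start:stop].mean(axis=1))
        kept.append(pos)

    if n_dropped_missing:
        logger.info("excluded %d trial(s) with missing %s", n_dropped_missing, construct)
    if n_low_conf:
        logger.info(
            "%d trial window(s) overlap low-confidence filter edges (retained)",
            n_low_conf,
        )
    if not rows:
        raise ValueError("no trials retained after exclusions")
    values = np.vstack(rows)
    kept_arr = np.asarray(kept, dtype=int)
    return TrialEdgeMatrix(
        values=values,
        n_nodes=tensors[0].n_nodes,
        trial_index=kept_arr,
        trials=trials.iloc[kept_arr].reset_index(drop=True),
    )
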