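"""Leave-one-trial-out connectome-based predictive modeling (dCPM core).

Given a trials-by-edges matrix of trial-averaged phase synchrony and a
behavior vector (binary memory outcome or ordinal arousal rating), each
leave-one-trial-out fold

1. correlates every edge with behavior over the training trials and keeps
   edges with two-sided P < alpha, split by correlation sign into positive
   and negative subnetworks;
2. sums synchrony over each subnetwork to two scalar features per trial;
3. fits logistic (memory) or linear (arousal) regression of behavior on the
   two features plus intercept;
4. predicts the held-out trial.

Performance is accuracy (memory, probability threshold 0.5) or Pearson r
(arousal) over the held-out predictions, with significance from permutation
testing (behavior shuffled across trials, the whole procedure rerun).
Consensus predictive networks are the edges selected on every fold.

The fold loop is algebraically flattened: leave-one-out correlation
statistics for all folds come from rank-one downdates of the full-data
sums, subnetwork features for all folds from one matrix product, and the
per-fold regressions from batched normal equations / batched Newton
iterations.  A naive per-fold reference implementation lives in the test
suite and must agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, stdtr

from .connectivity import TrialEdgeMatrix, edge_pairs

logger = logging.getLogger("dcpm")

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
_RIDGE_LINEAR = 1e-10   # relative; only guards rank deficiency
_RIDGE_LOGISTIC = 1e-6  # stabilizes perfect separation
_VAR_TOL = 1e-9

Edge = tuple[int, int]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EdgeSelection:
    """Edges passing the correlation screen, split by sign."""

    positive: frozenset[int]
    negative: frozenset[int]
    alpha: float = DEFAULT_ALPHA
    n_excluded_constant: int = 0

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative selections must be disjoint")


@dataclass
class FoldModel:
    """Fitted fold regression on (positive sum, negative sum) features."""

    construct: str
    coef: np.ndarray           # (intercept, beta_pos, beta_neg)
    selection: EdgeSelection
    feature_mode: str = "two"  # "two" predictors or single "difference"

    def features(self, X: np.ndarray) -> np.ndarray:
        pos = sorted(self.selection.positive)
        neg = sorted(self.selection.negative)
        p = X[:, pos].sum(axis=1) if pos else np.zeros(len(X))
        n = X[:, neg].sum(axis=1) if neg else np.zeros(len(X))
        if self.feature_mode == "difference":
            return np.column_stack([np.ones(len(X)), p - n])
        return np.column_stack([np.ones(len(X)), p, n])

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.features(X) @ self.coef
        if self.construct == "memory":
            return expit(eta)
        return eta


@dataclass
class CPMResult:
    """Cross-validated predictions, performance and permutation evidence."""

    construct: str
    performance: float
    predictions: np.ndarray          # per retained trial; NaN = unpredictable fold
    observed: np.ndarray
    pos_masks: np.ndarray            # (n_folds, n_edges) per-fold selections
    neg_masks: np.ndarray
    alpha: float
    n_nodes: int
    coverage: float = 1.0            # fraction of trials with a prediction
    degenerate: bool = False
    null_distribution: np.ndarray | None = None
    p_value: float | None = None
    condition: tuple[str, str] | None = None

    def fold_selection(self, k: int) -> EdgeSelection:
        return EdgeSelection(
            positive=frozenset(np.flatnonzero(self.pos_masks[k]).tolist()),
            negative=frozenset(np.flatnonzero(self.neg_masks[k]).tolist()),
            alpha=self.alpha,
        )


@dataclass
class PredictiveNetwork:
    """Consensus edge sets: selected on every cross-validation fold."""

    construct: str
    positive_edges: frozenset[Edge]
    negative_edges: frozenset[Edge]
    n_nodes: int
    condition: tuple[str, str] | None = None

    @property
    def positive_indices(self) -> frozenset[int]:
        return frozenset(_pair_to_index(self.positive_edges, self.n_nodes))

    @property
    def negative_indices(self) -> frozenset[int]:
        return frozenset(_pair_to_index(self.negative_edges, self.n_nodes))


def _pair_to_index(pairs, n_nodes: int) -> list[int]:
    from .connectivity import edge_index
    return [edge_index(i, j, n_nodes) for i, j in pairs]


def _index_to_pairs(indices, n_nodes: int) -> frozenset[Edge]:
    pairs = edge_pairs(n_nodes)
    return frozenset(tuple(pairs[k]) for k in indices)


# ---------------------------------------------------------------------------
# Correlation screens
# ---------------------------------------------------------------------------

def _corr_with_pvals(X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r of each column of X with y, two-sided t-test p-values.

    Returns (r, p, valid); columns with (near-)zero variance are invalid
    (r = 0, p = 1).
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc * Xc).sum(axis=0)
    syy = float(yc @ yc)
    sxy = Xc.T @ yc
    denom2 = sxx * syy
    valid = (sxx > _VAR_TOL * n) & (syy > _VAR_TOL * n)
    r = np.zeros_like(sxy)
    np.divide(sxy, np.sqrt(np.where(denom2 > 0, denom2, 1.0)), out=r,
              where=valid)
    np.clip(r, -1.0, 1.0, out=r)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stdtr(df, -np.abs(t))
    p = np.where(valid, p, 1.0)
    return r, p, valid


def _check_y(y: np.ndarray, construct: str) -> None:
    if np.any(~np.isfinite(y)):
        raise ValueError("behavior vector contains missing values; exclude first")
    if len(y) < 3:
        raise ValueError("need at least 3 trials")
    if construct == "memory":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("memory outcomes must be 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("memory vector must contain both classes")
    elif np.ptp(y) == 0:
        raise ValueError("behavior vector is constant")


def select_edges(X: TrialEdgeMatrix | np.ndarray, y: np.ndarray,
                 alpha: float = DEFAULT_ALPHA) -> EdgeSelection:
    """Screen edges by Pearson correlation with behavior at two-sided alpha.

    Positive set: P < alpha and r > 0; negative set: P < alpha and r < 0.
    Binary outcomes use the same Pearson formula (point-biserial).
    Constant edge columns are excluded and counted.
    """
    Xv = X.values if isinstance(X, TrialEdgeMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != len(y):
        raise ValueError("X rows and y must align")
    construct = "memory" if set(np.unique(y)) <= {0.0, 1.0} else "arousal"
    _check_y(y, construct)
    r, p, valid = _corr_with_pvals(Xv, y)
    n_const = int((~valid).sum())
    if n_const:
        logger.info("excluded %d constant edge column(s) from selection", n_const)
    sig = p < alpha
    return EdgeSelection(
        positive=frozenset(np.flatnonzero(sig & (r > 0)).tolist()),
        negative=frozenset(np.flatnonzero(sig & (r < 0)).tolist()),
        alpha=alpha,
        n_excluded_constant=n_const,
    )


def _loo_corr_masks(X: np.ndarray, y: np.ndarray, alpha: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold edge selections for all leave-one-out folds at once.

    Row k gives the selection computed with trial k removed, via rank-one
    downdates of the full-data cross products.  Returns boolean masks
    (n_trials, n_edges) for the positive and negative subnetworks.
    """
    n, _ = X.shape
    m = n - 1
    Sx = X.sum(axis=0)
    Sxx = (X * X).sum(axis=0)
    Sy = float(y.sum())
    Syy = float(y @ y)
    Sxy = X.T @ y

    Sx_k = Sx[None, :] - X
    Sxx_k = Sxx[None, :] - X * X
    Sy_k = (Sy - y)[:, None]
    Syy_k = (Syy - y * y)[:, None]
    Sxy_k = Sxy[None, :] - X * y[:, None]

    if m - 2 < 1:  # too few training trials for a correlation p-value
        z = np.zeros((n, X.shape[1]), dtype=bool)
        return z, z.copy()
    num = m * Sxy_k - Sx_k * Sy_k
    varx = np.maximum(m * Sxx_k - Sx_k * Sx_k, 0.0)
    vary = np.maximum(m * Syy_k - Sy_k * Sy_k, 0.0)
    valid = (varx > _VAR_TOL * m) & (vary > _VAR_TOL * m)
    denom = np.sqrt(varx * vary)
    r = np.zeros_like(num)
    np.divide(num, np.where(denom > 0, denom, 1.0), out=r, where=valid)
    np.clip(r, -1.0, 1.0, out=r)
    df = m - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = np.where(valid, 2.0 * stdtr(df, -np.abs(t)), 1.0)
    sig = p < alpha
    return sig & (r > 0), sig & (r < 0)


# ---------------------------------------------------------------------------
# Fold models
# ---------------------------------------------------------------------------

def fit_fold_model(train_X: np.ndarray, train_y: np.ndarray,
                   selection: EdgeSelection, construct: str,
                   feature_mode: str = "two") -> FoldModel:
    """Fit one fold's regression of behavior on subnetwork sum features.

    Features are the per-trial sums of synchrony over the positive and the
    negative selected edges (or their single difference when
    ``feature_mode='difference'``), plus an intercept.  Memory uses
    logistic regression with a tiny ridge term that keeps perfectly
    separated folds finite; arousal uses ordinary least squares.
    """
    if not selection.positive and not selection.negative:
        raise ValueError("empty selection in both subnetworks: fold unpredictable")
    model = FoldModel(construct=construct, coef=None, selection=selection,
                      feature_mode=feature_mode)
    Z = model.features(np.asarray(train_X, float))
    y = np.asarray(train_y, float)
    if construct == "memory":
        model.coef = _fit_logistic(Z, y)
    else:
        A = Z.T @ Z
        A += _RIDGE_LINEAR * np.trace(A) / len(A) * np.eye(len(A))
        model.coef = np.linalg.solve(A, Z.T @ y)
    return model


def _fit_logistic(Z: np.ndarray, y: np.ndarray, ridge: float = _RIDGE_LOGISTIC,
                  max_iter: int = 50) -> np.ndarray:
    """Ridge-stabilized Newton fit of a logistic regression."""
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        mu = expit(Z @ beta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = Z.T @ (y - mu) - ridge * beta
        H = (Z * w[:, None]).T @ Z + ridge * np.eye(Z.shape[1])
        step = np.linalg.solve(H, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _batched_linear(F: np.ndarray, y: np.ndarray, train_w: np.ndarray
                    ) -> np.ndarray:
    """Weighted least squares for every fold at once.

    F: (n_trials, n_folds, n_feat) per-fold design rows; train_w zeroes the
    held-out trial of each fold.  Returns (n_folds, n_feat) coefficients.
    """
    Fw = F * train_w[:, :, None]
    A = np.einsum("tkf,tkg->kfg", Fw, F)
    b = np.einsum("tkf,t->kf", Fw, y)
    tr = np.einsum("kff->k", A) / A.shape[1]
    A = A + (_RIDGE_LINEAR * np.maximum(tr, 1.0))[:, None, None] * np.eye(A.shape[1])
    return np.linalg.solve(A, b[..., None])[..., 0]


def _batched_logistic(F: np.ndarray, y: np.ndarray, train_w: np.ndarray,
                      ridge: float = _RIDGE_LOGISTIC, max_iter: int = 50
                      ) -> np.ndarray:
    """Newton/IRLS logistic fits for every fold at once."""
    n, K, q = F.shape
    beta = np.zeros((K, q))
    eye = np.eye(q)
    for _ in range(max_iter):
        eta = np.einsum("tkf,kf->tk", F, beta)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12) * train_w
        resid = (y[:, None] - mu) * train_w
        grad = np.einsum("tkf,tk->kf", F, resid) - ridge * beta
        H = np.einsum("tkf,tk,tkg->kfg", F, w, F) + ridge * eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _fold_features(X: np.ndarray, pos_masks: np.ndarray, neg_masks: np.ndarray,
                   feature_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold design rows F (n_trials, n_folds, n_feat) and a mask of
    folds with at least one selected edge."""
    P = X @ pos_masks.T.astype(float)   # (n_trials, n_folds)
    N = X @ neg_masks.T.astype(float)
    ones = np.ones_like(P)
    if feature_mode == "difference":
        F = np.stack([ones, P - N], axis=2)
    else:
        F = np.stack([ones, P, N], axis=2)
    predictable = pos_masks.any(axis=1) | neg_masks.any(axis=1)
    return F, predictable


def _fit_predict_folds(X: np.ndarray, y: np.ndarray, pos_masks: np.ndarray,
                       neg_masks: np.ndarray, construct: str,
                       feature_mode: str) -> np.ndarray:
    """Held-out prediction per fold; NaN where no edges were selected."""
    n = len(y)
    F, predictable = _fold_features(X, pos_masks, neg_masks, feature_mode)
    train_w = 1.0 - np.eye(n)
    if construct == "memory":
        beta = _batched_logistic(F, y, train_w)
    else:
        beta = _batched_linear(F, y, train_w)
    eta = np.einsum("kf,kf->k", F[np.arange(n), np.arange(n), :], beta)
    pred = expit(eta) if construct == "memory" else eta
    pred = np.where(predictable, pred, np.nan)
    return pred


def _performance(pred: np.ndarray, y: np.ndarray, construct: str
                 ) -> tuple[float, bool]:
    """Accuracy (memory) or Pearson r (arousal) over available predictions."""
    ok = np.isfinite(pred)
    degenerate = False
    if ok.sum() < 3:
        degenerate = True
    if construct == "memory":
        if not ok.any():
            return np.nan, True
        perf = float(np.mean((pred[ok] >= 0.5) == (y[ok] >= 0.5)))
    else:
        if ok.sum() < 2 or np.ptp(pred[ok]) == 0 or np.ptp(y[ok]) == 0:
            return np.nan, True
        perf = float(np.corrcoef(pred[ok], y[ok])[0, 1])
        if ok.sum() <= 2:
            degenerate = True
    return perf, degenerate


# ---------------------------------------------------------------------------
# Cross-validation, permutation, consensus
# ---------------------------------------------------------------------------

def loto_cv(X: TrialEdgeMatrix | np.ndarray, y: np.ndarray | None = None,
            construct: str = "arousal", alpha: float = DEFAULT_ALPHA,
            feature_mode: str = "two", n_nodes: int | None = None,
            n_perm: int = 0, seed: int = 0,
            condition: tuple[str, str] | None = None) -> CPMResult:
    """Leave-one-trial-out dCPM: per fold, select edges on the training
    trials, fit the subnetwork-sum regression, predict the held-out trial.

    Memory predictions are thresholded at probability 0.5.  Folds where
    neither subnetwork selects any edge yield no prediction and are excluded
    from the performance statistic (coverage records the fraction kept).
    With ``n_perm > 0`` a permutation test is run and attached.
    """
    if isinstance(X, TrialEdgeMatrix):
        if y is None:
            y = X.behavior(construct)
        if n_nodes is None:
            n_nodes = X.n_nodes
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("y is required when X is a plain array")
    y = np.asarray(y, dtype=float)
    if len(y) >= 3:
        _check_y(y, construct)
    else:
        logger.warning("fewer than 3 trials: cross-validation is degenerate")
    if n_nodes is None:
        n_nodes = round_nodes(Xv.shape[1])  # infer from triangular edge count

    pos_masks, neg_masks = _loo_corr_masks(Xv, y, alpha)
    pred = _fit_predict_folds(Xv, y, pos_masks, neg_masks, construct, feature_mode)
    n_missing = int(np.isnan(pred).sum())
    if n_missing:
        logger.info("%d unpredictable fold(s) excluded from performance", n_missing)
    perf, degenerate = _performance(pred, y, construct)
    result = CPMResult(
        construct=construct, performance=perf, predictions=pred, observed=y,
        pos_masks=pos_masks, neg_masks=neg_masks, alpha=alpha,
        n_nodes=n_nodes, coverage=1.0 - n_missing / len(y),
        degenerate=degenerate, condition=condition,
    )
    if n_perm > 0:
        null, p = permutation_test(Xv, y, construct, alpha, n_perm, seed=seed,
                                   feature_mode=feature_mode)
        result.null_distribution = null
        result.p_value = p
    return result


def round_nodes(n_edges_: int) -> int:
    """Node count whose edge universe has n_edges_ edges; 0 if none does."""
    n = int((1 + np.sqrt(1 + 8 * n_edges_)) / 2)
    if n * (n - 1) // 2 != n_edges_:
        return 0
    return n


def _score(perf: float) -> float:
    """Rankable permutation statistic: undefined performance ranks worst.

    Degenerate-but-defined values (e.g. a two-point correlation) are kept
    as-is so observed and null iterations are treated exchangeably."""
    return perf if np.isfinite(perf) else -np.inf


def permutation_test(X: TrialEdgeMatrix | np.ndarray, y: np.ndarray,
                     construct: str, alpha: float = DEFAULT_ALPHA,
                     n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                     feature_mode: str = "two",
                     subjects: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Null distribution of cross-validated performance under shuffled behavior.

    Each iteration permutes y across all retained trials (or within subject
    when ``subjects`` is given) and reruns the full leave-one-trial-out
    procedure.  p uses the add-one convention (1 + #{null >= observed}) /
    (1 + n_perm), which can never be exactly zero.
    """
    Xv = X.values if isinstance(X, TrialEdgeMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    pos, neg = _loo_corr_masks(Xv, y, alpha)
    obs_pred = _fit_predict_folds(Xv, y, pos, neg, construct, feature_mode)
    observed, _ = _performance(obs_pred, y, construct)

    null = np.empty(n_perm)
    for b in range(n_perm):
        if subjects is None:
            yp = rng.permutation(y)
        else:
            yp = y.copy()
            for s in np.unique(subjects):
                idx = np.flatnonzero(subjects == s)
                yp[idx] = yp[rng.permutation(idx)]
        pos_b, neg_b = _loo_corr_masks(Xv, yp, alpha)
        pred_b = _fit_predict_folds(Xv, yp, pos_b, neg_b, construct, feature_mode)
        perf_b, _ = _performance(pred_b, yp, construct)
        null[b] = perf_b
    scores = np.array([_score(v) for v in null])
    p = (1.0 + np.sum(scores >= _score(observed))) / (1.0 + n_perm)
    return null, float(p)


def consensus_network(result: CPMResult) -> PredictiveNetwork:
    """Edges selected on every leave-one-trial-out fold, per signed subnetwork."""
    if result.pos_masks.shape[0] < 1:
        raise ValueError("need at least one fold")
    pos_idx = np.flatnonzero(result.pos_masks.all(axis=0))
    neg_idx = np.flatnonzero(result.neg_masks.all(axis=0))
    if pos_idx.size == 0 and neg_idx.size == 0:
        logger.warning("consensus network is empty in both subnetworks")
    return PredictiveNetwork(
        construct=result.construct,
        positive_edges=_index_to_pairs(pos_idx, result.n_nodes),
        negative_edges=_index_to_pairs(neg_idx, result.n_nodes),
        n_nodes=result.n_nodes,
        condition=result.condition,
    )


def generalize(X_source: TrialEdgeMatrix | np.ndarray, y_source: np.ndarray,
               X_target: TrialEdgeMatrix | np.ndarray, y_target: np.ndarray,
               construct_source: str, construct_target: str,
               alpha: float = DEFAULT_ALPHA, feature_mode: str = "two",
               pairing: str = "indexed", n_perm: int = 0, seed: int = 0
               ) -> CPMResult:
    """Cross-run / cross-construct generalization of a predictive network.

    Per held-out target trial: edges are selected from the source data
    relating X_source to y_source (with one source trial held out — paired
    to the target fold by index when ``pairing='indexed'``, or selection on
    all source trials when ``pairing='all'``); subnetwork-sum features are
    computed on the target run; a fresh model relates the target training
    trials' features to the target behavior; the held-out target trial is
    predicted.  When source and target are the same data and construct this
    reduces exactly to :func:`loto_cv`.

    Permutations shuffle the target behavior only; source selection is a
    fixed property of the source run.
    """
    Xs = X_source.values if isinstance(X_source, TrialEdgeMatrix) else np.asarray(X_source, float)
    Xt = X_target.values if isinstance(X_target, TrialEdgeMatrix) else np.asarray(X_target, float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target edge manifests do not match")
    n_nodes = round_nodes(Xs.shape[1])
    ys = np.asarray(y_source, dtype=float)
    yt = np.asarray(y_target, dtype=float)
    _check_y(ys, construct_source)
    _check_y(yt, construct_target)

    if pairing == "indexed":
        pos_src, neg_src = _loo_corr_masks(Xs, ys, alpha)
        fold_map = np.arange(len(yt)) % len(ys)
    elif pairing == "all":
        sel = select_edges(Xs, ys, alpha)
        E = Xs.shape[1]
        pos_src = np.zeros((1, E), dtype=bool)
        neg_src = np.zeros((1, E), dtype=bool)
        pos_src[0, sorted(sel.positive)] = True
        neg_src[0, sorted(sel.negative)] = True
        fold_map = np.zeros(len(yt), dtype=int)
    else:
        raise ValueError("pairing must be 'indexed' or 'all'")

    pos_masks = pos_src[fold_map]
    neg_masks = neg_src[fold_map]
    pred = _fit_predict_folds(Xt, yt, pos_masks, neg_masks, construct_target,
                              feature_mode)
    perf, degenerate = _performance(pred, yt, construct_target)
    result = CPMResult(
        construct=construct_target, performance=perf, predictions=pred,
        observed=yt, pos_masks=pos_masks, neg_masks=neg_masks, alpha=alpha,
        n_nodes=n_nodes, coverage=float(np.isfinite(pred).mean()),
        degenerate=degenerate,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(yt)
            pred_b = _fit_predict_folds(Xt, yp, pos_masks, neg_masks,
                                        construct_target, feature_mode)
            perf_b, _ = _performance(pred_b, yp, construct_target)
            null[b] = perf_b
        scores = np.array([_score(v) for v in null])
        result.null_distribution = null
        result.p_value = float(
            (1.0 + np.sum(scores >= _score(perf))) / (1.0 + n_perm))
    return result
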