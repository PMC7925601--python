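"""Lagged ridge-regression encoding models (temporal response functions).

A TRF is a per-channel linear filter from stimulus impulse series to the
neural response, estimated in closed form as ``(S'S + lambda I)^-1 S' r`` on a
lagged design matrix, with leave-one-trial-out cross-validation for the ridge
parameter, permutation-null prediction deltas, and extraction of the
N400-style trough latency from the fitted weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg

from .features import FeatureImpulseSeries

__all__ = [
    "LagWindow",
    "TRFModel",
    "CVResult",
    "PermutationDelta",
    "PeakLatency",
    "build_lagged_design",
    "fit_ridge",
    "cross_validate",
    "permutation_delta",
    "peak_latency",
    "DEFAULT_LAMBDA_GRID",
]

#: Default ridge grid spanning 0.1 ... 1000 (log-spaced).
DEFAULT_LAMBDA_GRID = np.logspace(-1, 3, 9)


@dataclass(frozen=True)
class LagWindow:
    """Stimulus-to-response lag axis, in ms, on the sample grid of ``fs``."""

    lag_min_ms: float
    lag_max_ms: float
    fs: float

    def __post_init__(self) -> None:
        if not self.lag_min_ms < self.lag_max_ms:
            raise ValueError("lag_min_ms must be < lag_max_ms")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def lags_samples(self) -> np.ndarray:
        lo = int(round(self.lag_min_ms * self.fs / 1000.0))
        hi = int(round(self.lag_max_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags_samples * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return self.lags_samples.size


@dataclass
class TRFModel:
    """Fitted TRF: weights are feature x lag x channel; lag axis in ms."""

    weights: np.ndarray
    intercept: np.ndarray
    lam: float
    lag_window: LagWindow
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def flat_weights(self) -> np.ndarray:
        """(n_features * n_lags) x channels, matching the design columns."""
        f, l, c = self.weights.shape
        return self.weights.reshape(f * l, c)

    def predict(self, design: np.ndarray) -> np.ndarray:
        """Predicted response (samples x channels) from a lagged design."""
        return design @ self.flat_weights() + self.intercept


class PeakLatency(NamedTuple):
    latency_ms: float
    at_boundary: bool


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """x delayed by ``lag`` samples (zero-padded; negative = advanced)."""
    out = np.zeros_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
    elif lag < 0:
        out[:lag] = x[-lag:]
    else:
        out[:] = x
    return out


def build_lagged_design(
    features: Sequence[FeatureImpulseSeries | np.ndarray],
    lag_window: LagWindow,
) -> np.ndarray:
    """Design matrix: column (f, l) is feature f delayed by lag l.

    Columns are ordered feature-major (all lags of feature 0, then feature 1,
    ...), lags ascending. ``design @ k`` with ``k`` a kernel sampled on the
    lag grid equals the zero-padded convolution of the feature with ``k``.
    """
    arrays = [
        f.values if isinstance(f, FeatureImpulseSeries) else np.asarray(f, float)
        for f in features
    ]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all features must share trial length")
    lags = lag_window.lags_samples
    if lags.size >= n:
        raise ValueError("lag window exceeds trial length")
    X = np.empty((n, len(arrays) * lags.size))
    for fi, arr in enumerate(arrays):
        for li, lag in enumerate(lags):
            X[:, fi * lags.size + li] = _shift(arr, int(lag))
    return X


class RidgeSingularError(np.linalg.LinAlgError):
    pass


def _solve_ridge(
    G: np.ndarray, b: np.ndarray, lam: float, n_plain: int
) -> np.ndarray:
    """Solve (G + lam * P) w = b with the last column (intercept) unpenalized."""
    A = G.copy()
    idx = np.arange(n_plain)
    A[idx, idx] += lam
    try:
        w = linalg.solve(A, b, assume_a="sym")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
        raise RidgeSingularError(
            "singular ridge system; use lambda > 0"
        ) from exc
    if not np.allclose(A @ w, b, rtol=1e-6, atol=1e-8 * max(1.0, np.abs(b).max())):
        raise RidgeSingularError(
            "ridge system is singular or badly conditioned; use lambda > 0"
        )
    return w


def fit_ridge(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    lag_window: LagWindow | None = None,
    feature_names: Sequence[str] | None = None,
) -> TRFModel:
    """Closed-form ridge fit ``(S'S + lambda I)^-1 S' r`` per channel.

    ``response`` is samples x channels (a 1-D array is treated as one
    channel). An intercept column is appended and left unpenalized.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(design, dtype=float)
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in design or response")
    n, p = X.shape
    Xi = np.column_stack([X, np.ones(n)])
    G = Xi.T @ Xi
    b = Xi.T @ Y
    w = _solve_ridge(G, b, lam, p)
    coef, intercept = w[:p], w[p]
    if lag_window is None:
        lag_window = LagWindow(0.0, max(p - 1, 1), 1000.0)  # lags = samples
    n_lags = lag_window.n_lags
    if p % n_lags != 0:
        raise ValueError("design columns not a multiple of lag count")
    n_feat = p // n_lags
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(n_feat)]
    return TRFModel(
        weights=coef.reshape(n_feat, n_lags, Y.shape[1]),
        intercept=intercept,
        lam=float(lam),
        lag_window=lag_window,
        feature_names=names,
    )


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; constant columns give r = 0 with a warning."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    bad = (na == 0) | (nb == 0)
    if bad.any():
        warnings.warn("constant prediction or response; r set to 0")
    denom = np.where(bad, 1.0, na * nb)
    r = np.einsum("ij,ij->j", a, b) / denom
    return np.where(bad, 0.0, r)


@dataclass
class CVResult:
    """Leave-one-trial-out cross-validation over a ridge grid."""

    lambda_grid: np.ndarray
    accuracies: np.ndarray          # n_lambda x n_folds x n_channels
    selected_lambda: float
    fold_models: list[TRFModel]     # trained at selected lambda, fold = test trial
    lag_window: LagWindow
    feature_names: list[str]

    @property
    def mean_accuracy(self) -> np.ndarray:
        """Per-channel accuracy at the selected lambda, averaged over folds."""
        i = int(np.argmin(np.abs(self.lambda_grid - self.selected_lambda)))
        return self.accuracies[i].mean(axis=0)

    @property
    def n_folds(self) -> int:
        return self.accuracies.shape[1]


def cross_validate(
    stimuli: Sequence[Sequence[FeatureImpulseSeries | np.ndarray]],
    responses: Sequence[np.ndarray],
    lag_window: LagWindow,
    lambda_grid: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> CVResult:
    """Per-trial leave-one-out CV (fourfold when there are 4 trials).

    ``stimuli[t]`` is the feature list of trial ``t``; ``responses[t]`` is
    channels x samples. For each lambda the model is trained on the other
    trials and scored (per-channel Pearson r) on the held-out trial. The
    selected lambda maximizes r averaged across trials and channels; ties go
    to the smallest lambda. One lambda is selected per call (i.e. per subject).
    """
    if len(stimuli) != len(responses):
        raise ValueError("stimuli and responses must align")
    n_trials = len(stimuli)
    if n_trials < 2:
        raise ValueError("cross-validation needs >= 2 trials")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.sort(np.asarray(lambda_grid, float))

    designs = [build_lagged_design(s, lag_window) for s in stimuli]
    Ys = [np.asarray(r, float).T for r in responses]  # samples x channels
    n_ch = Ys[0].shape[1]
    p = designs[0].shape[1]
    Xis = [np.column_stack([X, np.ones(X.shape[0])]) for X in designs]
    Gs = [Xi.T @ Xi for Xi in Xis]
    bs = [Xi.T @ Y for Xi, Y in zip(Xis, Ys)]
    G_all = sum(Gs)
    b_all = sum(bs)

    acc = np.zeros((grid.size, n_trials, n_ch))
    for fold in range(n_trials):
        G = G_all - Gs[fold]
        b = b_all - bs[fold]
        for li, lam in enumerate(grid):
            w = _solve_ridge(G, b, lam, p)
            pred = Xis[fold] @ w
            acc[li, fold] = _pearson_columns(pred, Ys[fold])

    mean_by_lam = acc.mean(axis=(1, 2))
    best = int(np.argmax(mean_by_lam))  # first max -> smallest lambda on ties
    selected = float(grid[best])

    n_lags = lag_window.n_lags
    n_feat = p // n_lags
    if feature_names:
        names = list(feature_names)
    elif all(isinstance(f, FeatureImpulseSeries) for f in stimuli[0]):
        names = [f.name for f in stimuli[0]]
    else:
        names = [f"f{i}" for i in range(n_feat)]
    fold_models = []
    for fold in range(n_trials):
        w = _solve_ridge(G_all - Gs[fold], b_all - bs[fold], selected, p)
        fold_models.append(
            TRFModel(
                weights=w[:p].reshape(n_feat, n_lags, n_ch),
                intercept=w[p],
                lam=selected,
                lag_window=lag_window,
                feature_names=names,
            )
        )
    return CVResult(
        lambda_grid=grid,
        accuracies=acc,
        selected_lambda=selected,
        fold_models=fold_models,
        lag_window=lag_window,
        feature_names=names,
    )


@dataclass
class PermutationDelta:
    """True-minus-null prediction accuracy for one feature."""

    feature_name: str
    true_r: np.ndarray        # per channel, averaged over folds
    null_r: np.ndarray        # n_perm x channels, averaged over folds
    n_perm: int
    seed: int

    @property
    def delta(self) -> np.ndarray:
        return self.true_r - self.null_r.mean(axis=0)


def permutation_delta(
    cv: CVResult,
    stimuli: Sequence[Sequence[FeatureImpulseSeries]],
    responses: Sequence[np.ndarray],
    target_feature: str,
    n_perm: int = 5,
    seed: int = 0,
) -> PermutationDelta:
    """Permutation-null prediction delta for ``target_feature``.

    In each held-out trial the target feature's impulse heights are shuffled
    across its own onset samples (onset positions fixed, other regressors
    untouched) and the fold's trained TRF predicts the response to the
    permuted stimulus. The delta is the per-channel true accuracy minus the
    mean accuracy over the ``n_perm`` null stimuli. Permutation RNG streams
    are derived deterministically from (seed, fold, permutation).
    """
    fi = cv.feature_names.index(target_feature)
    n_trials = len(stimuli)
    n_ch = cv.fold_models[0].n_channels
    true_r = np.zeros((n_trials, n_ch))
    null_r = np.zeros((n_perm, n_trials, n_ch))

    for fold in range(n_trials):
        feats = list(stimuli[fold])
        target = feats[fi]
        if not isinstance(target, FeatureImpulseSeries):
            raise TypeError("permutation requires FeatureImpulseSeries stimuli")
        onsets = target.nonzero_samples()
        if onsets.size < 2:
            raise ValueError(
                f"feature {target_feature!r} has {onsets.size} impulses; "
                "permutation undefined"
            )
        model = cv.fold_models[fold]
        X = build_lagged_design(feats, cv.lag_window)
        Y = np.asarray(responses[fold], float).T
        true_r[fold] = _pearson_columns(model.predict(X), Y)
        heights = target.values[onsets]
        for pi in range(n_perm):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(fold, pi))
            )
            perm_vals = np.zeros_like(target.values)
            perm_vals[onsets] = rng.permutation(heights)
            perm_feats = list(feats)
            perm_feats[fi] = FeatureImpulseSeries(
                target.name, perm_vals, target.fs, target.word_index_map
            )
            Xp = build_lagged_design(perm_feats, cv.lag_window)
            null_r[pi, fold] = _pearson_columns(model.predict(Xp), Y)

    return PermutationDelta(
        feature_name=target_feature,
        true_r=true_r.mean(axis=0),
        null_r=null_r.mean(axis=1),
        n_perm=n_perm,
        seed=seed,
    )


def peak_latency(
    model: TRFModel,
    channel_set: Sequence[int],
    feature: str | int = 0,
    window_ms: tuple[float, float] = (200.0, 600.0),
) -> PeakLatency:
    """Lag (ms) of the most negative weight in the search window.

    Weights are averaged over ``channel_set`` for the named feature; the
    returned latency is the lag of the minimum within ``window_ms`` (ties go
    to the earliest lag). When the minimum sits on the window edge — e.g.
    monotone weights with no interior trough — ``at_boundary`` is True and a
    warning is emitted.
    """
    fi = model.feature_index(feature) if isinstance(feature, str) else feature
    lags_ms = model.lag_window.lags_ms
    lo, hi = window_ms
    if lo < lags_ms[0] or hi > lags_ms[-1]:
        raise ValueError("search window outside the model's lag window")
    sel = (lags_ms >= lo) & (lags_ms <= hi)
    trace = model.weights[fi][:, list(channel_set)].mean(axis=1)
    idx = np.flatnonzero(sel)
    i_min = idx[int(np.argmin(trace[idx]))]
    at_boundary = i_min == idx[0] or i_min == idx[-1]
    if at_boundary:
        warnings.warn("trough at search-window boundary; latency may be clipped")
    return PeakLatency(float(lags_ms[i_min]), bool(at_boundary))
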