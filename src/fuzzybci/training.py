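"""Parameter estimation for the TSK fuzzy neural network.

Antecedents (Gaussian centres and widths) are initialised by fuzzy
c-means clustering of the scaled feature space — one rule per cluster,
which keeps the rule base linear in the cluster count instead of the
``clusters ** inputs`` explosion of grid partitioning.  Widths come from
the distance between neighbouring cluster centres.  Consequent and
mixing parameters start uniform in [-1, 1] and all five parameter groups
are then refined by per-sample gradient descent with momentum and a
bold-driver adaptive learning rate, minimising the squared output error
against one-hot class targets.  Evaluation is by stratified 10-fold
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _kernels
from .errors import (
    ClusterCountError,
    ConfigError,
    RecordingValidationError,
    SingleClassError,
    SmallClassWarning,
    TrainingDivergedError,
)
from .features import FeatureMatrix, scale_features
from .fnn import AntecedentSet, ConsequentSet, FNNModel, MixingWeights, forward


# ---------------------------------------------------------------------------
# Fuzzy c-means


@dataclass
class FCMResult:
    centers: np.ndarray        # (r, m)
    memberships: np.ndarray    # (N, r), rows sum to 1
    iterations: int
    objective: float
    objective_trace: tuple[float, ...] = ()


def fcm_cluster(
    X: np.ndarray,
    r: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> FCMResult:
    """Fuzzy c-means: alternate membership/centre updates until the centres
    move less than ``tol`` or ``max_iter`` is reached.

    Memberships follow the standard update
    u_ij = 1 / sum_l (d_ij / d_il)^(2/(fuzzifier-1)); a sample coincident
    with a centre gets full membership in that cluster.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise RecordingValidationError("FCM input must be N x m")
    n, m = X.shape
    if r < 1:
        raise ClusterCountError("need at least one cluster")
    if n < r:
        raise ClusterCountError(f"fewer samples ({n}) than clusters ({r})")
    if fuzzifier <= 1:
        raise ConfigError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    # seed the centres with r distinct samples: starting from random
    # memberships puts every centre at the grand mean, a degenerate FCM
    # fixed point that high-dimensional data does not escape
    centers = X[rng.choice(n, size=r, replace=False)].copy()
    expo = 1.0 / (fuzzifier - 1.0)
    U = np.full((n, r), 1.0 / r)
    trace: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if iterations == 1:
            new_centers = centers
        else:
            Um = U ** fuzzifier
            new_centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
            U = inv / inv.sum(axis=1, keepdims=True)
        zrows = zero.any(axis=1)
        if zrows.any():
            U[zrows] = 0.0
            first_zero = zero[zrows].argmax(axis=1)
            U[np.flatnonzero(zrows), first_zero] = 1.0
        trace.append(float(((U ** fuzzifier) * d2).sum()))
        shift = (
            np.inf if iterations == 1
            else float(np.abs(new_centers - centers).max())
        )
        centers = new_centers
        if shift < tol:
            break
    return FCMResult(centers, U, iterations, trace[-1], tuple(trace))


def init_antecedents(
    fcm: FCMResult,
    alpha: float = 0.5,
    floor: float = 1e-2,
    X: np.ndarray | None = None,
) -> AntecedentSet:
    """Turn FCM centres into membership-function parameters.

    Centres transfer directly; each rule's width is ``alpha`` times the
    Euclidean distance to its nearest *distinct* other centre (floored),
    shared across inputs.  When the cluster count exceeds the number of
    natural groups FCM merges surplus centres onto the same point;
    measuring against such duplicates would give zero-width (dead) rules,
    so they are skipped.  If every other centre coincides — or with a
    single rule — the widths fall back to the per-dimension data
    standard deviation.
    """
    centers = fcm.centers  # (r, m)
    r, m = centers.shape
    c = centers.T.copy()

    def _std_widths() -> np.ndarray:
        if X is None:
            raise RecordingValidationError(
                "degenerate-centre width init needs the data matrix"
            )
        return np.maximum(np.asarray(X, dtype=np.float64).std(axis=0), floor)

    if r == 1:
        return AntecedentSet(c, _std_widths()[:, None])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    dup_tol = 1e-6 * (1.0 + float(d[np.isfinite(d)].max(initial=0.0)))
    d[d <= dup_tol] = np.inf
    nearest = d.min(axis=1)  # (r,)
    if np.isinf(nearest).all():
        return AntecedentSet(c, np.repeat(_std_widths()[:, None], r, axis=1))
    nearest[np.isinf(nearest)] = np.nanmax(np.where(np.isinf(nearest), np.nan, nearest))
    sigma = np.maximum(alpha * nearest, floor)
    return AntecedentSet(c, np.broadcast_to(sigma, (m, r)).copy())


def init_consequents(
    m: int, r: int, n: int, seed: int | None = None
) -> tuple[ConsequentSet, MixingWeights]:
    """Random initial consequent/mixing parameters, i.i.d. uniform [-1, 1]."""
    if min(m, r, n) < 1:
        raise ConfigError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=(m, r))
    b = rng.uniform(-1.0, 1.0, size=r)
    w = rng.uniform(-1.0, 1.0, size=(r, n))
    return ConsequentSet(a, b), MixingWeights(w)


# ---------------------------------------------------------------------------
# Errors and gradients


def sample_error(u: np.ndarray, u_d: np.ndarray) -> float:
    """Per-sample half squared error E = 1/2 sum_k (u_k^d - u_k)^2."""
    u = np.asarray(u, dtype=np.float64)
    u_d = np.asarray(u_d, dtype=np.float64)
    if u.shape != u_d.shape:
        raise RecordingValidationError("outputs and targets must align")
    return float(0.5 * ((u_d - u) ** 2).sum())


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Root mean squared error over all samples and outputs."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.size == 0:
        raise RecordingValidationError("rmse of an empty prediction set")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


@dataclass
class Gradients:
    mixing: np.ndarray        # dE/dw_jk, (r, n)
    coefficients: np.ndarray  # dE/da_ij, (m, r)
    intercepts: np.ndarray    # dE/db_j, (r,)
    centers: np.ndarray       # dE/dc_ij, (m, r)
    widths: np.ndarray        # dE/dsigma_ij, (m, r)


def gradients(x: np.ndarray, u_d: np.ndarray, model: FNNModel) -> Gradients:
    """Exact partial derivatives of the per-sample error for every
    parameter group, under the product t-norm.

    With e_k = u_k - u_k^d and S = sum_j mu_j:

    - dE/dw_jk = e_k mu_j y_j / S
    - dE/da_ij = (sum_k e_k w_jk) mu_j x_i / S;  dE/db_j likewise without x_i
    - dE/dmu_j = sum_k e_k (w_jk y_j - u_k) / S, chained with
      dmu_j/dc_ij = mu_j 2 (x_i - c_ij) / sigma_ij^2 and
      dmu_j/dsigma_ij = mu_j 2 (x_i - c_ij)^2 / sigma_ij^3.
    """
    if model.tnorm != "product":
        raise ConfigError("gradients are defined for the product t-norm only")
    x = np.asarray(x, dtype=np.float64)
    u_d = np.asarray(u_d, dtype=np.float64)
    c = model.antecedents.centers
    s = model.antecedents.widths
    a = model.consequents.coefficients
    b = model.consequents.intercepts
    w = model.mixing.weights
    z2 = (((x[:, None] - c) / s) ** 2).sum(axis=0)  # (r,) rule exponents
    # rescaled so max mu = 1; u and all gradients depend on mu only
    # through ratios, so this underflow guard is exact
    mu = np.exp(-(z2 - z2.min()))
    y = x @ a + b
    S = mu.sum()
    u = (w.T @ (mu * y)) / S
    e = u - u_d
    g_w = np.outer(mu * y, e) / S
    q = w @ e  # (r,): sum_k e_k w_jk
    g_a = np.outer(x, q * mu / S)
    g_b = q * mu / S
    dmu = (y * q - float(e @ u)) / S  # dE/dmu_j
    diff = x[:, None] - c
    g_c = (dmu * mu) * 2.0 * diff / s ** 2
    g_s = (dmu * mu) * 2.0 * diff ** 2 / s ** 3
    return Gradients(g_w, g_a, g_b, g_c, g_s)


def grid_rule_count(n_inputs: int, n_clusters: int) -> int:
    """Rule count of an exhaustive grid partition: clusters ** inputs.

    For 100 inputs and 2 clusters per input this is 2**100 — the
    combinatorial explosion that motivates clustering-based rule design.
    """
    if n_inputs < 1 or n_clusters < 1:
        raise ConfigError("inputs and clusters must be >= 1")
    return n_clusters ** n_inputs


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainingConfig:
    """Hyper-parameters of the gradient training run.

    Defaults follow the experimental protocol the package reproduces:
    6 rules, 1000 epochs, learning rate 0.05 with momentum 0.9, random
    consequents in [-1, 1], FCM antecedent initialisation with widths at
    half the nearest-centre distance.
    """

    epochs: int = 1000
    learning_rate: float = 0.001
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    #: epochs whose RMSE grows by more than this factor are rolled back
    max_rmse_increase: float = 1.04
    rules: int = 6
    width_scale: float = 0.5
    width_floor: float = 1e-2
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    eval_fraction: float = 0.1
    update_mode: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be > 0")
        if not (0 <= self.momentum < 1):
            raise ConfigError("momentum must lie in [0, 1)")
        if self.rules < 1:
            raise ConfigError("need at least one rule")
        if not (0 <= self.eval_fraction < 1):
            raise ConfigError("eval_fraction must lie in [0, 1)")
        if self.update_mode not in ("sample", "batch"):
            raise ConfigError("update_mode must be 'sample' or 'batch'")


@dataclass
class TrainingHistory:
    """Per-epoch monitoring: training RMSE, held-out evaluation RMSE and
    the learning rate in force during the epoch."""

    train_rmse: np.ndarray
    eval_rmse: np.ndarray
    learning_rate: np.ndarray

    def __len__(self) -> int:
        return self.train_rmse.shape[0]


def _spawn_seeds(seed: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(count)]


def _batch_gradient_step(X, T, c, s, a, b, w, prev, gamma, lam, width_floor):
    """One full-batch update (mean gradient over all samples)."""
    z2 = (((X[:, :, None] - c) / s) ** 2).sum(axis=1)  # (N, r)
    mu = np.exp(-(z2 - z2.min(axis=1, keepdims=True)))  # max mu = 1 per row
    y = X @ a + b  # (N, r)
    S = mu.sum(axis=1, keepdims=True)
    y1 = mu * y
    U = (y1 @ w) / S
    E = U - T  # (N, n)
    n_samples = X.shape[0]
    g_w = (y1 / S).T @ E / n_samples
    q = E @ w.T  # (N, r)
    coef = q * mu / S
    g_a = X.T @ coef / n_samples
    g_b = coef.mean(axis=0)
    dmu = (y * q - (E * U).sum(axis=1, keepdims=True)) / S  # (N, r)
    diff = X[:, :, None] - c
    core = (dmu * mu)[:, None, :]
    g_c = (core * 2.0 * diff / s ** 2).mean(axis=0)
    g_s = (core * 2.0 * diff ** 2 / s ** 3).mean(axis=0)
    for p, g, key in ((w, g_w, "w"), (a, g_a, "a"), (b, g_b, "b"),
                      (c, g_c, "c"), (s, g_s, "s")):
        new = p - gamma * g + lam * (p - prev[key])
        prev[key][...] = p
        p[...] = new
    np.maximum(s, width_floor, out=s)


def fit(
    X: np.ndarray,
    T: np.ndarray,
    cfg: TrainingConfig,
    eval_X: np.ndarray | None = None,
    eval_T: np.ndarray | None = None,
    class_names: Sequence[str] = (),
    feature_names: Sequence[str] = (),
) -> tuple[FNNModel, TrainingHistory]:
    """Fit an FNN to (inputs, target-output) pairs.

    FCM + nearest-centre widths initialise the antecedents; consequents
    and mixing weights start uniform in [-1, 1]; then ``cfg.epochs``
    sweeps of per-sample gradient updates with momentum run in a seeded
    shuffled order.  After each epoch the learning rate is multiplied by
    ``lr_up`` if the epoch's RMSE improved and by ``lr_down`` otherwise
    (bold driver).  Fully deterministic given ``cfg.seed``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    T = np.ascontiguousarray(T, dtype=np.float64)
    if X.ndim != 2 or T.ndim != 2 or X.shape[0] != T.shape[0]:
        raise RecordingValidationError("X and T must be aligned 2-D arrays")
    n_samples, m = X.shape
    n_out = T.shape[1]
    fcm_seed, init_seed, shuffle_seed = _spawn_seeds(cfg.seed, 3)

    fcm = fcm_cluster(
        X, cfg.rules, cfg.fuzzifier, cfg.fcm_tol, cfg.fcm_max_iter, fcm_seed
    )
    ants = init_antecedents(fcm, cfg.width_scale, cfg.width_floor, X)
    cons, mix = init_consequents(m, cfg.rules, n_out, init_seed)

    c = np.ascontiguousarray(ants.centers)
    s = np.ascontiguousarray(ants.widths)
    a = np.ascontiguousarray(cons.coefficients)
    b = np.ascontiguousarray(cons.intercepts)
    w = np.ascontiguousarray(mix.weights)
    pc, ps, pa, pb, pw = (arr.copy() for arr in (c, s, a, b, w))

    have_eval = eval_X is not None and eval_T is not None and len(eval_X) > 0
    if have_eval:
        eval_X = np.ascontiguousarray(eval_X, dtype=np.float64)
        eval_T = np.ascontiguousarray(eval_T, dtype=np.float64)

    hist_train = np.empty(cfg.epochs)
    hist_eval = np.full(cfg.epochs, np.nan)
    hist_lr = np.empty(cfg.epochs)
    gamma = cfg.learning_rate
    rng = np.random.default_rng(shuffle_seed)
    prev_rmse = float(np.sqrt(
        _kernels.forward_sse(X, T, c, s, a, b, w) / (n_samples * n_out)
    ))
    batch_prev = {"w": w.copy(), "a": a.copy(), "b": b.copy(),
                  "c": c.copy(), "s": s.copy()}
    group_pairs = (
        (c, pc), (s, ps), (a, pa), (b, pb), (w, pw),
        (c, batch_prev["c"]), (s, batch_prev["s"]), (a, batch_prev["a"]),
        (b, batch_prev["b"]), (w, batch_prev["w"]),
    )
    last_eval = np.nan
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_samples).astype(np.int64)
        snapshot = tuple(p.copy() for p in (c, s, a, b, w))
        if cfg.update_mode == "sample":
            _kernels.sgd_epoch(
                X, T, order, c, s, a, b, w, pc, ps, pa, pb, pw,
                gamma, cfg.momentum, cfg.width_floor,
            )
        else:
            _batch_gradient_step(X, T, c, s, a, b, w, batch_prev,
                                 gamma, cfg.momentum, cfg.width_floor)
        # post-epoch RMSE of the updated parameters drives the adaptive rate
        sse = _kernels.forward_sse(X, T, c, s, a, b, w)
        train_rmse = float(np.sqrt(sse / (n_samples * n_out)))
        hist_lr[epoch] = gamma
        accepted = (
            np.isfinite(train_rmse)
            and train_rmse <= prev_rmse * cfg.max_rmse_increase
        )
        if accepted:
            # bold driver: grow the rate on improvement, shrink it on a
            # (tolerated) regression
            gamma *= cfg.lr_up if train_rmse < prev_rmse else cfg.lr_down
            prev_rmse = train_rmse
            if have_eval:
                last_eval = float(np.sqrt(
                    _kernels.forward_sse(eval_X, eval_T, c, s, a, b, w)
                    / (eval_X.shape[0] * n_out)
                ))
        else:
            # the epoch regressed too far (or went non-finite): roll the
            # parameters back, zero the momentum and retry smaller — the
            # reset that makes the adaptive rate recover instead of diverge
            for (p, _), snap in zip(group_pairs[:5], snapshot):
                p[...] = snap
            for p, prev_arr in group_pairs:
                prev_arr[...] = p
            gamma *= cfg.lr_down
            if gamma < 1e-15:
                raise TrainingDivergedError(epoch)
        hist_train[epoch] = prev_rmse
        hist_eval[epoch] = last_eval
    model = FNNModel(
        AntecedentSet(c, s),
        ConsequentSet(a, b),
        MixingWeights(w),
        tuple(class_names),
        tuple(feature_names),
    )
    return model, TrainingHistory(hist_train, hist_eval, hist_lr)


def _stratified_eval_split(labels: np.ndarray, fraction: float, seed: int):
    """Indices (train, eval) with per-class proportions preserved; returns
    an empty eval split when the data cannot support one."""
    n = labels.shape[0]
    counts = np.bincount(labels)
    counts = counts[counts > 0]
    n_eval = int(round(n * fraction))
    if fraction <= 0 or n_eval < len(counts) or counts.min() < 2:
        return np.arange(n), np.array([], dtype=np.int64)
    train_idx, eval_idx = train_test_split(
        np.arange(n), test_size=fraction, stratify=labels, random_state=seed
    )
    return np.asarray(train_idx), np.asarray(eval_idx)


def train(
    features: FeatureMatrix, cfg: TrainingConfig
) -> tuple[FNNModel, TrainingHistory]:
    """Train a classifier on an already-scaled, labelled feature matrix.

    Targets are one-hot over the matrix's classes.  A stratified
    ``cfg.eval_fraction`` slice (default 10%) is held out from the
    updates and monitored as the per-epoch evaluation RMSE.
    """
    if features.labels is None:
        raise SingleClassError("training requires labelled features")
    if features.n_samples < cfg.rules:
        raise ClusterCountError(
            f"fewer windows ({features.n_samples}) than rules ({cfg.rules})"
        )
    T = features.one_hot_targets()
    split_seed = _spawn_seeds(cfg.seed + 101, 1)[0]
    tr_idx, ev_idx = _stratified_eval_split(
        features.labels, cfg.eval_fraction, split_seed
    )
    model, history = fit(
        features.values[tr_idx],
        T[tr_idx],
        cfg,
        features.values[ev_idx] if ev_idx.size else None,
        T[ev_idx] if ev_idx.size else None,
        class_names=features.class_names,
        feature_names=features.feature_names,
    )
    return model, history


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Stratified k-fold evaluation summary."""

    fold_train_rmse: list[float]
    fold_eval_rmse: list[float]
    fold_test_rmse: list[float]
    confusion: np.ndarray
    n_correct: int
    n_total: int
    folds: int
    class_names: tuple[str, ...] = ()

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    @property
    def n_incorrect(self) -> int:
        return self.n_total - self.n_correct

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "class_names": list(self.class_names),
            "fold_train_rmse": self.fold_train_rmse,
            "fold_eval_rmse": self.fold_eval_rmse,
            "fold_test_rmse": self.fold_test_rmse,
            "mean_train_rmse": float(np.mean(self.fold_train_rmse)),
            "mean_eval_rmse": float(np.mean(self.fold_eval_rmse)),
            "mean_test_rmse": float(np.mean(self.fold_test_rmse)),
            "confusion": self.confusion.tolist(),
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "n_total": self.n_total,
            "accuracy": self.accuracy,
        }


def cross_validate(
    features: FeatureMatrix,
    cfg: TrainingConfig,
    folds: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the full training recipe.

    Min–max scaling bounds, FCM initialisation and gradient training are
    re-derived inside every fold from its training portion only; each
    window is tested exactly once.  Per-fold RMSEs are reported for the
    training portion, the monitored evaluation slice, and the held-out
    test fold (one-hot targets), together with the pooled confusion
    matrix and accuracy.
    """
    if features.labels is None:
        raise SingleClassError("cross-validation requires labelled features")
    labels = features.labels
    if seed is None:
        seed = cfg.seed
    min_count = int(np.bincount(labels)[np.unique(labels)].min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} windows < {folds} folds; "
            f"using {max(2, min_count)} folds",
            SmallClassWarning,
            stacklevel=2,
        )
        folds = max(2, min_count)
    if features.n_samples < folds:
        raise ClusterCountError("fewer samples than folds")
    n_classes = len(features.class_names)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 31))
    fold_seeds = _spawn_seeds(seed, folds)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    tr_rmse: list[float] = []
    ev_rmse: list[float] = []
    te_rmse: list[float] = []
    n_correct = 0
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(features.values, labels)):
        train_fm = features.subset_rows(tr_idx)
        test_fm = features.subset_rows(te_idx)
        train_scaled = scale_features(train_fm)
        test_scaled = scale_features(train_fm, test_fm)
        fold_cfg = replace(cfg, seed=fold_seeds[fold_i])
        model, history = train(train_scaled, fold_cfg)
        if len(history):
            tr_rmse.append(float(history.train_rmse[-1]))
            ev = history.eval_rmse[-1]
            ev_rmse.append(float(ev) if np.isfinite(ev) else float("nan"))
        else:
            tr_rmse.append(float("nan"))
            ev_rmse.append(float("nan"))
        U = forward(test_scaled.values, model)
        T = test_scaled.one_hot_targets()
        te_rmse.append(rmse(U, T))
        pred = U.argmax(axis=1)
        truth = test_scaled.labels
        np.add.at(confusion, (truth, pred), 1)
        n_correct += int((pred == truth).sum())
    return CVResult(
        tr_rmse, ev_rmse, te_rmse, confusion,
        n_correct, features.n_samples, folds, features.class_names,
    )
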