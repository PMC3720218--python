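"""Predictors for bond dissociation energies.

Three predictors are provided, mirroring the modelling ladder the
descriptor scheme was designed for:

* a **random forest** (bootstrap ensemble of regression trees with
  per-split feature subsampling, 1000 trees and √p candidate variables by
  default) evaluated by out-of-bag (OOB) prediction, with an OOB
  permutation importance (mean increase in MSE when one descriptor is
  permuted among a tree's out-of-bag samples) used for descriptor
  selection;
* an **associative neural-network ensemble (ASNN)**: independently
  trained feed-forward networks (one hidden layer, logistic activation,
  bias units on the input and hidden layers), each fitted by
  Levenberg–Marquardt least squares on a random half of the training set
  with early stopping on the held-out half's RMSD, plus a *memory* of the
  training set.  A query's ensemble-mean prediction is corrected by the
  mean residual of the most similar memory cases, similarity being the
  rank correlation of per-member output vectors — so adding cases to the
  memory improves predictions without retraining any network;
* a **fixed-value baseline**: the training-set mean BDE per
  (element pair, bond order) class.

Inputs and targets of the networks are linearly normalized to
[0.1, 0.9] using training-data bounds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    """RMSD / MAD / MaxError in kcal/mol plus R² (None when the truth has
    zero variance)."""

    rmsd: float
    mad: float
    max_error: float
    r2: float | None
    n: int

    def __str__(self) -> str:
        r2 = "undefined" if self.r2 is None else f"{self.r2:.3f}"
        return (
            f"RMSD {self.rmsd:.2f}  MAD {self.mad:.2f}  "
            f"MaxError {self.max_error:.2f}  R2 {r2}  (n={self.n})"
        )


def evaluate(predictions, truths) -> Metrics:
    """Standard regression metrics; R² = 1 − SS_res / SS_tot."""
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    err = pred - truth
    rmsd = float(np.sqrt(np.mean(err**2)))
    mad = float(np.mean(np.abs(err)))
    max_error = float(np.max(np.abs(err)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    # mathematically guaranteed; assert the contract anyway
    assert rmsd >= mad - 1e-12 and max_error >= rmsd - 1e-12
    assert r2 is None or r2 <= 1.0 + 1e-12
    return Metrics(rmsd, mad, max_error, r2, n=pred.size)


# ---------------------------------------------------------------------------
# Random forest with OOB validation and permutation importance
# ---------------------------------------------------------------------------


@dataclass
class RFConfig:
    n_trees: int = 1000
    max_features: str | int | float = "sqrt"  # candidate variables per split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("tree count must be >= 1")


@dataclass
class RFResult:
    model: BaggingRegressor
    config: RFConfig
    oob_predictions: np.ndarray  # NaN where a sample was never out-of-bag
    oob_metrics: Metrics
    importances: np.ndarray | None

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def _oob_masks(model: BaggingRegressor, n_samples: int):
    for samples in model.estimators_samples_:
        mask = np.ones(n_samples, dtype=bool)
        mask[samples] = False
        yield mask


def train_rf(
    X,
    y,
    config: RFConfig | None = None,
    compute_importance: bool = True,
    importance_max_trees: int = 100,
) -> RFResult:
    """Fit the forest and evaluate it out-of-bag.

    The forest is a bagging ensemble of regression trees that test
    ``max_features`` randomly chosen descriptors at each split; the OOB
    prediction of a sample averages only trees whose bootstrap excluded
    it.  Importance is the mean increase in a tree's OOB MSE after
    permuting one descriptor column (computed over at most
    ``importance_max_trees`` trees to bound cost).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ConfigError("descriptor matrix must be 2-D with at least one column")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ConfigError("missing values are not supported")
    config = config or RFConfig()
    model = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=config.max_features),
        n_estimators=config.n_trees,
        bootstrap=True,
        oob_score=False,
        n_jobs=1,
        random_state=config.seed,
    )
    model.fit(X, y)

    n = X.shape[0]
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    for est, mask in zip(model.estimators_, _oob_masks(model, n)):
        if mask.any():
            oob_sum[mask] += est.predict(X[mask])
            oob_count[mask] += 1
    oob_pred = np.full(n, np.nan)
    seen = oob_count > 0
    oob_pred[seen] = oob_sum[seen] / oob_count[seen]
    oob_metrics = evaluate(oob_pred[seen], y[seen])

    importances = None
    if compute_importance:
        importances = _oob_permutation_importance(
            model, X, y, max_trees=importance_max_trees, seed=config.seed
        )
    return RFResult(model, config, oob_pred, oob_metrics, importances)


def _oob_permutation_importance(
    model: BaggingRegressor, X, y, max_trees: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n, p = X.shape
    increases = np.zeros(p)
    used = 0
    for est, mask in zip(model.estimators_, _oob_masks(model, n)):
        if used >= max_trees or mask.sum() < 2:
            continue
        used += 1
        X_oob = X[mask]
        y_oob = y[mask]
        base = np.mean((est.predict(X_oob) - y_oob) ** 2)
        perm = rng.permutation(X_oob.shape[0])
        for j in range(p):
            column = X_oob[:, j].copy()
            X_oob[:, j] = column[perm]
            increases[j] += np.mean((est.predict(X_oob) - y_oob) ** 2) - base
            X_oob[:, j] = column
    if used == 0:
        return increases
    return increases / used


def select_descriptors(
    importances, k: int, X, corr_threshold: float = 0.95
) -> np.ndarray:
    """Top-``k`` columns by importance, then greedy removal of columns whose
    absolute correlation with an already-retained column exceeds the
    threshold.  Returns retained column indices (importance order)."""
    importances = np.asarray(importances, dtype=float)
    X = np.asarray(X, dtype=float)
    if k > importances.size:
        raise ConfigError("k exceeds the number of descriptors")
    order = np.argsort(-importances, kind="stable")[:k]
    kept: list[int] = []
    for idx in order:
        col = X[:, idx]
        redundant = False
        for other in kept:
            if abs(_safe_corr(col, X[:, other])) > corr_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(int(idx))
    return np.array(kept, dtype=int)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Linear [0.1, 0.9] normalization
# ---------------------------------------------------------------------------


@dataclass
class LinearNormalizer:
    """Per-variable linear map onto [0.1, 0.9] from training-data bounds.
    Constant variables map to the mid-point 0.5."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "LinearNormalizer":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return cls(lo=values.min(axis=0), hi=values.max(axis=0))

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 0.1 + 0.8 * (values - self.lo) / safe
        return np.where(span == 0, 0.5, out)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.hi - self.lo
        return self.lo + (values - 0.1) / 0.8 * span


# ---------------------------------------------------------------------------
# Feed-forward networks trained by Levenberg-Marquardt
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class FeedForwardNet:
    """Fully connected 1-hidden-layer network: logistic hidden units with a
    bias unit on the input and hidden layers, linear output."""

    def __init__(self, n_inputs: int, n_hidden: int = 6, rng=None):
        rng = rng or np.random.default_rng()
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.w1 = rng.uniform(-0.5, 0.5, size=(n_inputs + 1, n_hidden))
        self.w2 = rng.uniform(-0.5, 0.5, size=n_hidden + 1)

    # -- parameter vector -------------------------------------------------

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.w2])

    def set_params(self, theta: np.ndarray) -> None:
        k = self.w1.size
        self.w1 = theta[:k].reshape(self.w1.shape)
        self.w2 = theta[k:].copy()

    # -- forward / jacobian ------------------------------------------------

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        return _sigmoid(Xb @ self.w1), Xb

    def predict(self, X: np.ndarray) -> np.ndarray:
        H, _ = self._hidden(np.asarray(X, dtype=float))
        return H @ self.w2[:-1] + self.w2[-1]

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """d output / d parameters, one row per sample."""
        H, Xb = self._hidden(X)
        d_hidden = H * (1.0 - H) * self.w2[:-1]  # n x h
        # d/dW1[i, j] = x_i * w2_j * sigma'_j
        j_w1 = (Xb[:, :, None] * d_hidden[:, None, :]).reshape(X.shape[0], -1)
        j_w2 = np.hstack([H, np.ones((X.shape[0], 1))])
        return np.hstack([j_w1, j_w2])


def train_lm(
    net: FeedForwardNet,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_iter: int = 150,
    patience: int = 15,
) -> dict:
    """Levenberg-Marquardt least squares with early stopping.

    Each accepted damped Gauss-Newton step is scored by the validation
    RMSD; training stops when the validation RMSD has not improved for
    ``patience`` accepted steps (or the damping underflows the step), and
    the best-on-validation parameters are restored.
    """
    lam = 1e-2
    theta = net.get_params()
    residual = y - net.predict(X)
    sse = float(residual @ residual)
    best_theta = theta.copy()
    best_val = float(np.sqrt(np.mean((y_val - net.predict(X_val)) ** 2)))
    since_best = 0
    iterations = 0
    for _ in range(max_iter):
        J = net.jacobian(X)
        gradient = J.T @ residual
        hessian = J.T @ J
        accepted = False
        for _ in range(30):
            try:
                delta = np.linalg.solve(
                    hessian + lam * np.eye(hessian.shape[0]), gradient
                )
            except np.linalg.LinAlgError:
                lam *= 4.0
                continue
            net.set_params(theta + delta)
            cand_residual = y - net.predict(X)
            cand_sse = float(cand_residual @ cand_residual)
            if np.isfinite(cand_sse) and cand_sse < sse:
                theta = theta + delta
                residual, sse = cand_residual, cand_sse
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 4.0
            if lam > 1e10:
                break
        net.set_params(theta)
        if not accepted:
            break
        iterations += 1
        val_rmsd = float(np.sqrt(np.mean((y_val - net.predict(X_val)) ** 2)))
        if val_rmsd < best_val - 1e-10:
            best_val = val_rmsd
            best_theta = theta.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_params(best_theta)
    return {"iterations": iterations, "val_rmsd": best_val}


# ---------------------------------------------------------------------------
# Ensemble + ASNN memory
# ---------------------------------------------------------------------------


@dataclass
class EnsembleConfig:
    n_members: int = 125
    n_hidden: int = 6
    max_iter: int = 150
    patience: int = 15
    k_neighbors: int = 9
    max_retries: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.n_hidden < 1:
            raise ConfigError("member and hidden-unit counts must be >= 1")


@dataclass
class EnsembleModel:
    """Trained FFNN ensemble plus its training-set memory.

    The memory holds, for every training case, the descriptor vector, the
    label, the per-member outputs (whose rank vector defines similarity to
    a query) and the residual of the ensemble-mean prediction.
    """

    members: list[FeedForwardNet]
    x_norm: LinearNormalizer
    y_norm: LinearNormalizer
    memory_vectors: np.ndarray
    memory_labels: np.ndarray
    memory_outputs: np.ndarray    # n_cases x n_members, kcal/mol
    memory_residuals: np.ndarray  # label - ensemble mean
    memory_ranks: np.ndarray      # centered rank vectors of memory_outputs
    config: EnsembleConfig

    def member_outputs(self, X) -> np.ndarray:
        Xn = self.x_norm.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        outputs = np.column_stack(
            [self.y_norm.inverse(net.predict(Xn)) for net in self.members]
        )
        return outputs

    def predict(self, X) -> np.ndarray:
        """Plain ensemble-mean prediction (no memory correction)."""
        return self.member_outputs(X).mean(axis=1)

    def extend_memory(self, X, y) -> None:
        """Add labelled cases to the memory without retraining members."""
        outputs = self.member_outputs(X)
        residuals = np.asarray(y, dtype=float) - outputs.mean(axis=1)
        self.memory_vectors = np.vstack([self.memory_vectors, np.atleast_2d(X)])
        self.memory_labels = np.concatenate([self.memory_labels, np.asarray(y, float)])
        self.memory_outputs = np.vstack([self.memory_outputs, outputs])
        self.memory_residuals = np.concatenate([self.memory_residuals, residuals])
        self.memory_ranks = _centered_ranks(self.memory_outputs)


def _centered_ranks(matrix: np.ndarray) -> np.ndarray:
    ranks = np.vstack([rankdata(row) for row in matrix])
    return ranks - ranks.mean(axis=1, keepdims=True)


def train_ensemble(X, y, config: EnsembleConfig | None = None) -> EnsembleModel:
    """Train the FFNN ensemble and populate the ASNN memory.

    Every member gets its own random half/half split of the training set
    (reduced training half + validation half for early stopping); inputs
    and the target are normalized to [0.1, 0.9] with bounds from the full
    training set.  Non-convergent members are retrained with a fresh seed,
    a bounded number of times.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ConfigError("X rows must align with y")
    config = config or EnsembleConfig()
    x_norm = LinearNormalizer.fit(X)
    y_norm = LinearNormalizer.fit(y[:, None])
    Xn = x_norm.transform(X)
    yn = y_norm.transform(y[:, None]).ravel()

    n = X.shape[0]
    members: list[FeedForwardNet] = []
    seed_seq = np.random.SeedSequence(config.seed)
    member_seeds = seed_seq.spawn(config.n_members)
    for m, child in enumerate(member_seeds):
        for attempt in range(config.max_retries + 1):
            rng = np.random.default_rng(child if attempt == 0 else child.spawn(1)[0])
            if n >= 4:
                perm = rng.permutation(n)
                half = n // 2
                train_idx, val_idx = perm[:half], perm[half:]
            else:  # too small to hold out a half; validate on the data itself
                train_idx = val_idx = np.arange(n)
            net = FeedForwardNet(X.shape[1], config.n_hidden, rng)
            train_lm(
                net,
                Xn[train_idx],
                yn[train_idx],
                Xn[val_idx],
                yn[val_idx],
                max_iter=config.max_iter,
                patience=config.patience,
            )
            if np.isfinite(net.predict(Xn)).all():
                members.append(net)
                break
            warnings.warn(
                f"member {m} did not converge (attempt {attempt + 1}); retraining",
                stacklevel=2,
            )
        else:
            raise ConfigError(f"member {m} failed to converge after retries")

    model = EnsembleModel(
        members=members,
        x_norm=x_norm,
        y_norm=LinearNormalizer(lo=y_norm.lo.ravel(), hi=y_norm.hi.ravel()),
        memory_vectors=X.copy(),
        memory_labels=y.copy(),
        memory_outputs=np.empty((0, 0)),
        memory_residuals=np.empty(0),
        memory_ranks=np.empty((0, 0)),
        config=config,
    )
    outputs = model.member_outputs(X)
    model.memory_outputs = outputs
    model.memory_residuals = y - outputs.mean(axis=1)
    model.memory_ranks = _centered_ranks(outputs)
    return model


def asnn_predict(model: EnsembleModel, X, k: int | None = None) -> np.ndarray:
    """ASNN prediction: ensemble mean plus the mean residual of the ``k``
    most similar memory cases (rank correlation of member-output vectors).

    Falls back to the plain ensemble mean when the memory is empty.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    outputs = model.member_outputs(X)
    mean_pred = outputs.mean(axis=1)
    n_memory = model.memory_outputs.shape[0]
    if n_memory == 0:
        warnings.warn("empty memory; returning plain ensemble mean", stacklevel=2)
        return mean_pred
    k = model.config.k_neighbors if k is None else k
    if not 1 <= k <= n_memory:
        raise ConfigError(f"k must be in [1, {n_memory}]")
    query_ranks = _centered_ranks(outputs)
    mem = model.memory_ranks
    mem_norms = np.linalg.norm(mem, axis=1)
    corrections = np.empty(X.shape[0])
    for row in range(X.shape[0]):
        q = query_ranks[row]
        qn = np.linalg.norm(q)
        if qn == 0:
            similarity = np.zeros(n_memory)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                similarity = (mem @ q) / (mem_norms * qn)
            similarity = np.nan_to_num(similarity, nan=0.0)
        # rank correlation only orders member outputs, so distinct cases
        # can tie; break ties by raw output distance so that a memory
        # case identical to the query always wins (exact recall)
        distance = np.linalg.norm(
            model.memory_outputs - outputs[row], axis=1
        )
        top = np.lexsort((distance, -similarity))[:k]
        corrections[row] = model.memory_residuals[top].mean()
    return mean_pred + corrections


# ---------------------------------------------------------------------------
# Fixed-value baseline
# ---------------------------------------------------------------------------


@dataclass
class FixedValuePredictor:
    """Training-set mean BDE per (element pair, bond order) class; unseen
    classes fall back to the global mean (flagged)."""

    table: dict[tuple[tuple[str, str], int], float]
    global_mean: float

    def predict(self, records) -> tuple[np.ndarray, np.ndarray]:
        values = np.empty(len(records))
        fallback = np.zeros(len(records), dtype=bool)
        for idx, r in enumerate(records):
            key = (r.element_pair, r.order)
            if key in self.table:
                values[idx] = self.table[key]
            else:
                values[idx] = self.global_mean
                fallback[idx] = True
        if fallback.any():
            warnings.warn(
                f"{int(fallback.sum())} bond(s) of unseen classes predicted "
                "with the global mean",
                stacklevel=2,
            )
        return values, fallback


def baseline_fixed_values(training_records) -> FixedValuePredictor:
    """Fit the fixed-value baseline from labelled training records."""
    labelled = [r for r in training_records if r.bde is not None]
    if not labelled:
        raise ConfigError("empty training set")
    sums: dict[tuple, list[float]] = {}
    for r in labelled:
        sums.setdefault((r.element_pair, r.order), []).append(r.bde)
    table = {key: float(np.mean(vals)) for key, vals in sums.items()}
    return FixedValuePredictor(
        table=table, global_mean=float(np.mean([r.bde for r in labelled]))
    )


# ---------------------------------------------------------------------------
# Leave-one-out helper and persistence
# ---------------------------------------------------------------------------


def loo_metrics(train_fn, X, y) -> Metrics:
    """Leave-one-out cross-validation for small datasets.

    ``train_fn(X, y)`` must return a callable ``predict(X)``; intended for
    the optional full-cross-validation evaluation mode on small corpora.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    predictions = np.empty_like(y)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        predict = train_fn(X[mask], y[mask])
        predictions[i] = float(np.asarray(predict(X[i : i + 1])).ravel()[0])
    return evaluate(predictions, y)


def save_model(model, path) -> None:
    """Serialize a trained model (forest, ensemble, or baseline) with
    joblib; normalization bounds, seeds and memory ride along."""
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
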