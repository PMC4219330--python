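"""Two-stage classifiers: one-vs-rest exposure SVMs and a perceptron stacker.

Stage one trains, for a given feature spec, four binary RBF-kernel SVMs
(one per location class, class vs rest) on class-balanced training sets,
tuning C and gamma by grid search over mean 10-fold cross-validated
accuracy and calibrating membership probabilities (Platt). A protein thus
receives a score vector of four class-membership probabilities per SVM set;
the vectors need not sum to one.

Stage two is a 12 -> H -> 4 multilayer perceptron (default H = 28) with
logistic-sigmoid units throughout, trained by full-batch back-propagation
on squared error against one-hot targets (output 1 for the true class, 0
for the rest). Its inputs are three concatenated score vectors, from SVM
sets trained on the (1 2 3, 4 5 6) and (1, 2 3 4 5 6) 40-component
features and the full-composition 20-component feature. Outputs are raw
sigmoids in [0, 1]^4, deliberately not normalized: the winning output
doubles as the prediction's reliability score.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted

from .curation import CLASS_ORDER, balance_dataset
from .exposure import ExposlocError
from .features import SPEC_A, counts_to_features, validate_spec

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "COARSE_C_GRID",
    "COARSE_GAMMA_GRID",
    "ExposureSVMSet",
    "SigmoidMLP",
    "winner_takes_all",
    "build_stack_input",
    "split_stack_input",
    "ann_forward",
    "train_ann",
    "count_connections",
    "optimize_ann",
    "TrainingDivergenceError",
]

#: C in 2^-5 .. 2^15 and gamma in 2^-15 .. 2^3, multiplicative step 4 —
#: the canonical coarse log-grid for RBF SVM tuning.
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

#: Reduced grids for quick runs (CLI ``--grid coarse``, smoke tests).
COARSE_C_GRID = (2.0 ** -1, 2.0 ** 3, 2.0 ** 7)
COARSE_GAMMA_GRID = (2.0 ** -7, 2.0 ** -3, 2.0 ** 1)


class TrainingDivergenceError(ExposlocError):
    """Perceptron training produced a non-finite loss."""


def _class_order_index(labels) -> np.ndarray:
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return labels


class ExposureSVMSet(ClassifierMixin, BaseEstimator):
    """Four one-vs-rest probabilistic SVMs over one feature spec.

    Fit on the canonical count representation ``X`` of shape (n, 120)
    (see :class:`~exposloc.features.CompositionFeaturizer`) and class
    labels in {N, Y, C, E}. For each class, a balanced positive/negative
    set is drawn, hyperparameters are tuned by grid search on mean
    ``cv``-fold cross-validated accuracy, and the winner is refit with
    Platt-calibrated probability outputs.

    Parameters
    ----------
    spec : feature spec (1-2 range sets) applied to the counts.
    C_grid, gamma_grid : hyperparameter candidates (RBF kernel).
    cv : folds for the tuning cross-validation (default 10).
    tuned_params : optional ``{class: {"C": ..., "gamma": ...}}`` to skip
        the grid search (used when refitting with known parameters).
    random_state : seed controlling balancing and fold shuffling;
        identical inputs and seed give identical models.
    """

    def __init__(self, spec=SPEC_A, C_grid=None, gamma_grid=None, cv=10,
                 tuned_params=None, random_state=None):
        self.spec = spec
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.tuned_params = tuned_params
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(np.asarray(X, dtype=float))
        y = _class_order_index(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        spec = validate_spec(self.spec)
        seed = 0 if self.random_state is None else int(self.random_state)
        F = counts_to_features(X, spec)
        members = {c: list(np.flatnonzero(y == c)) for c in CLASS_ORDER if np.any(y == c)}
        for c, idx in members.items():
            if len(idx) < 2:
                raise ValueError(f"class {c} has fewer than 2 examples")
        self.classifiers_, self.best_params_, self.cv_accuracy_ = {}, {}, {}
        self.balanced_ids_ = {}
        for ci, cls in enumerate(c for c in CLASS_ORDER if c in members):
            balanced = balance_dataset(members, cls, seed=seed + 1000 * ci)
            idx = list(balanced.positives) + [i for i, _ in balanced.negatives]
            Xc = F[idx]
            yc = np.r_[np.ones(len(balanced.positives), dtype=int),
                       np.zeros(len(balanced.negatives), dtype=int)]
            n_min = min(yc.sum(), len(yc) - yc.sum())
            if self.tuned_params is not None and cls in self.tuned_params:
                best = dict(self.tuned_params[cls])
                score = float("nan")
            else:
                if n_min < self.cv:
                    raise ValueError(
                        f"class {cls}: {n_min} examples cannot fill {self.cv} "
                        f"cross-validation folds")
                grid = {
                    "C": list(self.C_grid or DEFAULT_C_GRID),
                    "gamma": list(self.gamma_grid or DEFAULT_GAMMA_GRID),
                }
                search = GridSearchCV(
                    SVC(kernel="rbf"), grid, scoring="accuracy", refit=False,
                    cv=StratifiedKFold(self.cv, shuffle=True, random_state=seed + ci),
                )
                search.fit(Xc, yc)
                best, score = dict(search.best_params_), float(search.best_score_)
            # Platt-style probability calibration of the tuned margin SVM.
            clf = CalibratedClassifierCV(SVC(kernel="rbf", **best),
                                         method="sigmoid", ensemble=False)
            clf.fit(Xc, yc)
            self.classifiers_[cls] = clf
            self.best_params_[cls] = best
            self.cv_accuracy_[cls] = score
            self.balanced_ids_[cls] = idx
        self.classes_ = np.asarray([c for c in CLASS_ORDER if c in members])
        self.spec_ = spec
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-class one-vs-rest membership probabilities, (n, n_classes).

        Columns follow ``classes_`` (fixed N, Y, C, E order); rows do not
        sum to one — each column is an independent binary probability.
        """
        check_is_fitted(self, "classifiers_")
        X = check_array(np.asarray(X, dtype=float))
        F = counts_to_features(X, self.spec_)
        cols = []
        for cls in self.classes_:
            clf = self.classifiers_[cls]
            pos = int(np.flatnonzero(clf.classes_ == 1)[0])
            cols.append(clf.predict_proba(F)[:, pos])
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        """Winner-takes-all class per row (ties to earlier class order)."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def winner_takes_all(
    scores: Union[Mapping[str, float], Sequence],
) -> tuple:
    """Pick the class with the globally best score across one or more score vectors.

    ``scores`` is a single score vector (mapping class -> score, or a
    length-4 sequence in N, Y, C, E order) or a sequence of such vectors.
    Ties break by fixed class order N, Y, C, E first, then by vector order.
    Returns ``(class_label, winning_score)``.
    """
    arr = _as_score_matrix(scores)
    col_best = arr.max(axis=0)
    j = int(np.argmax(col_best))  # first max -> earliest class in fixed order
    return CLASS_ORDER[j], float(col_best[j])


def _as_score_matrix(scores) -> np.ndarray:
    if isinstance(scores, Mapping):
        scores = [scores]
    else:
        scores = list(scores)
        if scores and np.isscalar(scores[0]):
            scores = [scores]
    if not scores:
        raise ValueError("at least one score vector is required")
    rows = []
    for sv in scores:
        if isinstance(sv, Mapping):
            rows.append([float(sv[c]) for c in CLASS_ORDER])
        else:
            sv = list(sv)
            if len(sv) != len(CLASS_ORDER):
                raise ValueError(f"score vector must have {len(CLASS_ORDER)} entries")
            rows.append([float(v) for v in sv])
    return np.asarray(rows)


def build_stack_input(a, b, c) -> np.ndarray:
    """Concatenate three score vectors (sets A, B, C) into a 12-vector.

    Layout: components 0-3 are set A's N, Y, C, E scores, 4-7 set B's,
    8-11 set C's.
    """
    mat = _as_score_matrix([a, b, c])
    out = mat.ravel()
    if np.any(out < 0) or np.any(out > 1):
        raise ValueError("score components must lie in [0, 1]")
    return out


def split_stack_input(x) -> tuple:
    """Inverse of :func:`build_stack_input`."""
    x = np.asarray(x, dtype=float)
    if x.shape != (12,):
        raise ValueError(f"stack input must have shape (12,), got {x.shape}")
    return x[0:4].copy(), x[4:8].copy(), x[8:12].copy()


# ---------------------------------------------------------------------------
# Stage-two perceptron
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SigmoidMLP(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer perceptron with sigmoid hidden *and* output units.

    Trained by full-batch back-propagation (with momentum) on mean squared
    error against one-hot targets: output 1 for the true class, 0 for the
    others. A held-out fraction provides early stopping (best-weights
    restore after ``patience`` epochs without improvement). Outputs are
    independent sigmoids in (0, 1); they are not normalized across classes,
    so the winning output is directly usable as a reliability score.

    Parameters
    ----------
    hidden : hidden-layer width (default 28).
    lr : learning rate for batch gradient descent (default 0.05).
    momentum : classical momentum coefficient (default 0.9).
    max_epochs : epoch cap (default 20000; full-batch epochs on a
        12-dimensional input are microseconds each, and the squared-error
        optimum under weight decay is only reached with a generous budget).
    patience : early-stopping patience in epochs on the validation MSE.
    validation_fraction : held-out share for early stopping; 0 disables it.
    weight_decay : L2 penalty on the weights (not biases). Shrinks output
        magnitudes so that ambiguous score patterns stay below the
        reliability threshold instead of saturating; if the penalized
        optimum degenerates (a trained class never predicted), the decay is
        halved and the fit retried (``weight_decay_`` holds the value
        used).
    input_noise : standard deviation of Gaussian jitter added to the
        training inputs each epoch (a Tikhonov-style smoother).
    random_state : seed for weight initialization, the validation split
        and the jitter.
    """

    def __init__(self, hidden=28, lr=0.05, momentum=0.9, max_epochs=20000,
                 patience=500, validation_fraction=0.1, weight_decay=1e-2,
                 input_noise=0.1, random_state=None):
        self.hidden = hidden
        self.lr = lr
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.weight_decay = weight_decay
        self.input_noise = input_noise
        self.random_state = random_state

    def _forward(self, X):
        H = _sigmoid(X @ self.coefs_[0] + self.intercepts_[0])
        return _sigmoid(H @ self.coefs_[1] + self.intercepts_[1]), H

    def fit(self, X, y):
        X = check_array(np.asarray(X, dtype=float))
        y = _class_order_index(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        self.classes_ = np.asarray(CLASS_ORDER)
        T = np.zeros((X.shape[0], len(CLASS_ORDER)))
        for j, c in enumerate(CLASS_ORDER):
            T[y == c, j] = 1.0
        present = set(np.unique(y))
        # The penalized squared-error optimum can drop a hard class entirely
        # when the penalty outweighs that class's signal (small or noisy
        # inputs). Guard: back the decay off geometrically and refit until
        # every trained class is actually predicted somewhere on the
        # training data — i.e. use the strongest smoothing that still fits
        # all classes.
        decay = float(self.weight_decay)
        for attempt in range(10):
            self._fit_once(X, T, y, decay)
            if decay == 0 or attempt == 9:
                break
            covered = set(self.classes_[np.argmax(self._forward(X)[0], axis=1)])
            if present.issubset(covered):
                break
            decay *= 0.9
        self.weight_decay_ = decay
        self.n_layers_ = 3
        return self

    def _fit_once(self, X, T, y, weight_decay):
        rng = np.random.default_rng(self.random_state)
        d, h, k = X.shape[1], int(self.hidden), len(CLASS_ORDER)
        self.coefs_ = [rng.uniform(-1, 1, (d, h)) / np.sqrt(d),
                       rng.uniform(-1, 1, (h, k)) / np.sqrt(h)]
        self.intercepts_ = [np.zeros(h), np.zeros(k)]

        # Early stopping needs a meaningful held-out set; tiny inputs train on
        # everything for the full epoch budget.
        use_val = (self.validation_fraction > 0
                   and int(X.shape[0] * self.validation_fraction) >= 4)
        if use_val:
            try:
                Xtr, Xval, Ttr, Tval = train_test_split(
                    X, T, test_size=self.validation_fraction, stratify=y,
                    random_state=int(rng.integers(2 ** 31 - 1)))
            except ValueError:  # a class too small to stratify: hold out unstratified
                Xtr, Xval, Ttr, Tval = train_test_split(
                    X, T, test_size=self.validation_fraction,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        else:
            Xtr, Xval, Ttr, Tval = X, None, T, None

        vel = [np.zeros_like(w) for w in self.coefs_ + self.intercepts_]
        best = None
        best_val = np.inf
        stall = 0
        self.loss_curve_ = []
        n = Xtr.shape[0]
        for epoch in range(int(self.max_epochs)):
            if self.input_noise > 0:
                Xin = Xtr + rng.normal(0.0, self.input_noise, Xtr.shape)
            else:
                Xin = Xtr
            O, Hid = self._forward(Xin)
            err = O - Ttr
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
            self.loss_curve_.append(loss)
            d_out = err * O * (1 - O) / n
            g_W2 = Hid.T @ d_out + weight_decay * self.coefs_[1]
            g_b2 = d_out.sum(axis=0)
            d_hid = (d_out @ self.coefs_[1].T) * Hid * (1 - Hid)
            g_W1 = Xin.T @ d_hid + weight_decay * self.coefs_[0]
            g_b1 = d_hid.sum(axis=0)
            params = self.coefs_ + self.intercepts_
            for p, v, g in zip(params, vel, [g_W1, g_W2, g_b1, g_b2]):
                v *= self.momentum
                v -= self.lr * g
                p += v
            if Xval is not None:
                Oval, _ = self._forward(Xval)
                val_loss = float(np.mean((Oval - Tval) ** 2))
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best = ([w.copy() for w in self.coefs_],
                            [b.copy() for b in self.intercepts_], epoch)
                    stall = 0
                else:
                    stall += 1
                    if stall > self.patience:
                        break
        if best is not None:
            self.coefs_, self.intercepts_, self.best_epoch_ = best
        else:
            self.best_epoch_ = len(self.loss_curve_) - 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Raw sigmoid outputs in (0, 1)^4; columns in N, Y, C, E order.

        Deliberately *not* normalized to sum to one (independent per-class
        activations against 0/1 targets).
        """
        check_is_fitted(self, "coefs_")
        X = check_array(np.asarray(X, dtype=float))
        return self._forward(X)[0]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def n_connections_(self) -> int:
        """Number of stored inter-layer weights, biases excluded."""
        check_is_fitted(self, "coefs_")
        return int(sum(w.size for w in self.coefs_))


def ann_forward(model, x) -> np.ndarray:
    """Forward pass sigmoid(W2 @ sigmoid(W1 @ x + b1) + b2) for one input.

    ``model`` is anything exposing ``coefs_``/``intercepts_`` in the
    :class:`SigmoidMLP` layout. Accepts a single input vector or a batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.coefs_[0].shape[0]:
        raise ValueError(
            f"input length {X.shape[1]} != model input size {model.coefs_[0].shape[0]}")
    H = _sigmoid(X @ model.coefs_[0] + model.intercepts_[0])
    O = _sigmoid(H @ model.coefs_[1] + model.intercepts_[1])
    return O[0] if single else O


def train_ann(X, y, hidden=28, seed=None, epochs=20000, lr=0.05, **kwargs) -> SigmoidMLP:
    """Convenience wrapper: fit a :class:`SigmoidMLP` on stack inputs."""
    model = SigmoidMLP(hidden=hidden, max_epochs=epochs, lr=lr,
                       random_state=seed, **kwargs)
    return model.fit(X, y)


def count_connections(layer_sizes: Sequence[int]) -> int:
    """Inter-layer connection count, biases excluded: sum of n_i * n_{i+1}."""
    sizes = [int(s) for s in layer_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two layers")
    return sum(a * b for a, b in zip(sizes, sizes[1:]))


def optimize_ann(
    inputs_by_combo: Mapping[str, np.ndarray],
    y,
    hidden_sizes: Sequence[int] = (28,),
    cv_folds: int = 10,
    seed: Optional[int] = None,
    **mlp_kwargs,
) -> tuple:
    """Sweep (SVM-set combination, hidden width) by mean CV accuracy.

    ``inputs_by_combo`` maps a combination name to its stacked score matrix
    (n, 4 * n_sets). Returns ``(best, sweep)`` where ``best`` is a dict
    with keys ``combo``, ``hidden``, ``accuracy`` and ``sweep`` is a
    DataFrame with one row per (combo, hidden) pair. Ties go to the smaller
    hidden layer, then to combination order.
    """
    if not inputs_by_combo or not list(hidden_sizes):
        raise ValueError("candidate combinations and hidden sizes must be non-empty")
    y = _class_order_index(y)
    rows = []
    seed = 0 if seed is None else int(seed)
    for combo, X in inputs_by_combo.items():
        X = np.asarray(X, dtype=float)
        for hidden in hidden_sizes:
            skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
            accs = []
            for fold, (tr, te) in enumerate(skf.split(X, y)):
                mlp = SigmoidMLP(hidden=hidden, random_state=seed + fold,
                                 **mlp_kwargs)
                mlp.fit(X[tr], y[tr])
                accs.append(float(np.mean(mlp.predict(X[te]) == y[te])))
            rows.append({"combo": combo, "hidden": int(hidden),
                         "accuracy": float(np.mean(accs))})
    sweep = pd.DataFrame(rows)
    order = sweep.sort_values(["accuracy", "hidden"],
                              ascending=[False, True], kind="stable")
    best = order.iloc[0].to_dict()
    best["hidden"] = int(best["hidden"])
    return best, sweep
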