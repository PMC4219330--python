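"""End-to-end orchestration: featurize -> SVM scores -> stack -> final call.

:class:`StackedLocationClassifier` ties the two stages together behind a
single sklearn estimator. Fitting tunes and trains the three one-vs-rest
SVM sets, produces *out-of-fold* stage-one scores for every training
protein (each protein is scored by SVMs that never saw it, avoiding the
optimistic leakage a naive refit-and-score would introduce) and trains the
12-28-4 perceptron on those scores. Prediction runs a profile through
featurization, the three SVM sets, and the perceptron; the winning output
is the call, and a winning score below the reliability threshold (default
0.4) flags the protein as likely belonging to a location outside the four
trained classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted

from .curation import CLASS_ORDER, MIN_LENGTH
from .exposure import AMINO_ACIDS, ExposlocError, ExposureProfile
from .features import DEFAULT_SPECS, CompositionFeaturizer, validate_spec
from .models import ExposureSVMSet, SigmoidMLP

__all__ = [
    "DEFAULT_THRESHOLD",
    "Prediction",
    "StackedLocationClassifier",
    "predict_profile",
    "predict_profiles",
    "save_bundle",
    "load_bundle",
    "NoExposureError",
]

DEFAULT_THRESHOLD = 0.4
BUNDLE_FORMAT_VERSION = 1


class NoExposureError(ExposlocError):
    """A profile has no covered residues, so no features can be computed."""


@dataclass(frozen=True)
class Prediction:
    """Final call for one protein."""

    protein_id: str
    scores: dict          # class -> perceptron output, each in [0, 1]
    predicted_class: str  # argmax of scores (ties to N, Y, C, E order)
    score: float          # the winning output
    reliable: bool        # score >= threshold
    source: str           # "structure" or "predicted" exposure

    def __post_init__(self):
        if (self.scores[self.predicted_class] != self.score
                or self.score != max(self.scores.values())):
            raise ValueError("predicted_class must attain the winning score")


class StackedLocationClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage location classifier (one-vs-rest SVM sets + perceptron).

    ``X`` is the canonical count representation (n, 120) produced by
    :class:`~exposloc.features.CompositionFeaturizer`; ``y`` holds labels
    in {N, Y, C, E}.

    Parameters
    ----------
    specs : the three feature specs feeding stack slots A, B, C.
    hidden : perceptron hidden width (default 28; 12*28 + 28*4 = 448
        connections).
    cv : folds for SVM hyperparameter tuning.
    oof_folds : folds used to generate out-of-fold stage-one scores for
        perceptron training.
    C_grid, gamma_grid : SVM grids (None = package defaults).
    lr, momentum, epochs, patience : perceptron training controls.
    threshold : reliability threshold on the winning output.
    random_state : master seed; all internal seeds derive from it.
    """

    def __init__(self, specs=DEFAULT_SPECS, hidden=28, cv=10, oof_folds=10,
                 C_grid=None, gamma_grid=None, lr=0.05, momentum=0.9,
                 epochs=20000, patience=500, weight_decay=1e-2,
                 input_noise=0.1, threshold=DEFAULT_THRESHOLD,
                 random_state=None):
        self.specs = specs
        self.hidden = hidden
        self.cv = cv
        self.oof_folds = oof_folds
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.lr = lr
        self.momentum = momentum
        self.epochs = epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.input_noise = input_noise
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(np.asarray(X, dtype=float))
        y = np.asarray(y)
        specs = [validate_spec(s) for s in self.specs]
        seed = 0 if self.random_state is None else int(self.random_state)

        self.svm_sets_ = []
        for i, spec in enumerate(specs):
            svm = ExposureSVMSet(spec=spec, C_grid=self.C_grid,
                                 gamma_grid=self.gamma_grid, cv=self.cv,
                                 random_state=seed + i)
            self.svm_sets_.append(svm.fit(X, y))

        # Out-of-fold stage-one scores: refit each SVM set (with the already
        # tuned hyperparameters) on each fold's training part and score the
        # held-out part, so the perceptron never sees leaked scores.
        oof = np.zeros((X.shape[0], 4 * len(specs)))
        skf = StratifiedKFold(self.oof_folds, shuffle=True, random_state=seed + 101)
        for tr, te in skf.split(X, y):
            for i, spec in enumerate(specs):
                svm = ExposureSVMSet(spec=spec, cv=self.cv,
                                     tuned_params=self.svm_sets_[i].best_params_,
                                     random_state=seed + i)
                svm.fit(X[tr], y[tr])
                oof[te, 4 * i:4 * (i + 1)] = svm.predict_proba(X[te])
        self.oof_stack_inputs_ = oof

        self.ann_ = SigmoidMLP(hidden=self.hidden, lr=self.lr,
                               momentum=self.momentum, max_epochs=self.epochs,
                               patience=self.patience,
                               weight_decay=self.weight_decay,
                               input_noise=self.input_noise,
                               random_state=seed + 7)
        self.ann_.fit(oof, y)
        self.classes_ = np.asarray(CLASS_ORDER)
        return self

    def stack_inputs(self, X) -> np.ndarray:
        """Stage-one score matrix (n, 12) from the refit SVM sets."""
        check_is_fitted(self, "svm_sets_")
        return np.hstack([svm.predict_proba(X) for svm in self.svm_sets_])

    def predict_proba(self, X) -> np.ndarray:
        """Perceptron outputs (n, 4), raw sigmoids in N, Y, C, E order."""
        check_is_fitted(self, "ann_")
        return self.ann_.predict_proba(self.stack_inputs(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def wta_predict(self, X) -> np.ndarray:
        """Winner-takes-all baseline over all 12 stage-one scores."""
        scores = self.stack_inputs(X)
        best_per_class = np.stack(
            [scores[:, j::4] for j in range(4)], axis=1).max(axis=2)
        return self.classes_[np.argmax(best_per_class, axis=1)]


# ---------------------------------------------------------------------------
# Profile-level prediction
# ---------------------------------------------------------------------------

def predict_profile(
    profile: ExposureProfile,
    model: StackedLocationClassifier,
    threshold: Optional[float] = None,
    min_length: int = MIN_LENGTH,
) -> Prediction:
    """Run one profile through the fitted two-stage model.

    Profiles shorter than ``min_length`` residues get a warning (the
    training corpus was filtered at that length; inference is not) but are
    still predicted. A profile with zero covered residues raises
    :class:`NoExposureError`.
    """
    if profile.n_covered == 0:
        raise NoExposureError(
            f"{profile.protein_id}: no exposure information (0 covered residues)")
    if len(profile) < min_length:
        warnings.warn(
            f"{profile.protein_id}: sequence has {len(profile)} residues, below "
            f"the {min_length}-residue training filter; prediction may be "
            f"unstable", stacklevel=2)
    if threshold is None:
        threshold = getattr(model, "threshold", DEFAULT_THRESHOLD)
    counts = CompositionFeaturizer().transform([profile])
    out = model.predict_proba(counts)[0]
    j = int(np.argmax(out))
    scores = {c: float(v) for c, v in zip(CLASS_ORDER, out)}
    return Prediction(
        protein_id=profile.protein_id,
        scores=scores,
        predicted_class=CLASS_ORDER[j],
        score=float(out[j]),
        reliable=bool(out[j] >= threshold),
        source=profile.source or "structure",
    )


def predict_profiles(profiles: Iterable[ExposureProfile], model,
                     threshold: Optional[float] = None) -> list:
    """Vector of :class:`Prediction` for many profiles (shared code path)."""
    return [predict_profile(p, model, threshold) for p in profiles]


def predictions_to_rows(predictions: Sequence[Prediction]) -> list:
    """TSV-ready rows: id, four scores, call, winning score, reliable, source."""
    rows = []
    for p in predictions:
        rows.append({
            "protein_id": p.protein_id,
            **{f"score_{c}": p.scores[c] for c in CLASS_ORDER},
            "call": p.predicted_class,
            "score": p.score,
            "reliable": int(p.reliable),
            "source": p.source,
        })
    return rows


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

def save_bundle(model: StackedLocationClassifier, out_dir) -> Path:
    """Serialize a fitted model to ``out_dir`` (JSON manifest + weights).

    The manifest records everything needed to interpret the weights (class
    and amino-acid order, feature specs, seeds, grids, threshold) and is
    byte-stable for identical configurations.
    """
    check_is_fitted(model, "ann_")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "class_order": list(CLASS_ORDER),
        "amino_acid_order": AMINO_ACIDS,
        "specs": [list(list(rs) for rs in validate_spec(s)) for s in model.specs],
        "hidden": int(model.hidden),
        "threshold": float(model.threshold),
        "cv": int(model.cv),
        "oof_folds": int(model.oof_folds),
        "random_state": model.random_state,
        "svm_best_params": [
            {c: {k: float(v) for k, v in p.items()}
             for c, p in svm.best_params_.items()}
            for svm in model.svm_sets_
        ],
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    joblib.dump(model, out_dir / "model.joblib")
    return out_dir


def load_bundle(bundle_dir) -> tuple:
    """Load ``(model, manifest)`` from a bundle directory."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format {manifest.get('format_version')!r}")
    model = joblib.load(bundle_dir / "model.joblib")
    return model, manifest
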