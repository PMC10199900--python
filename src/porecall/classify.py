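"""Per-event classification: encoding, splits, baseline model, metrics.

Each detected event is encoded as a fixed-length, baseline-normalised
waveform vector (1.0 = open pore) plus two scalar features — the
relative blockade ΔI/I0 and log10 of the dwell time.  Two classifiers
consume this encoding: a transparent class-conditional Gaussian(-mixture)
Bayes baseline over the scalar features, and a recurrent sequence model
(:mod:`porecall.lstm`) over the full waveform.  Evaluation reports a
confusion matrix, per-class precision/recall/F1 and the average
identification accuracy (fraction of held-out events called correctly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

from .detect import EventRecord
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "EncodedEvent",
    "encode_event",
    "encode_events",
    "encode_frame",
    "split_dataset",
    "GaussianBayesClassifier",
    "train_bayes_baseline",
    "classify",
    "ClassifierReport",
    "evaluate",
]

DEFAULT_LENGTH = 128
CONTEXT_FRACTION = 0.2  # context included on each side, as a fraction of dwell
CLIP_RANGE = (-0.2, 1.2)


@dataclass
class EncodedEvent:
    waveform_vector: np.ndarray  # length L, baseline-normalised
    scalar_features: tuple[float, float]  # (rel_blockade, log10 dwell_s)
    label: str | None = None


def encode_event(event: EventRecord, L: int = DEFAULT_LENGTH) -> EncodedEvent:
    """Resample an event to ``L`` points of baseline-normalised current.

    The window spans [start − 0.2·Δt, end + 0.2·Δt]; values are divided
    by the local open-pore current (so the encoding is invariant to the
    absolute current level) and clipped to [−0.2, 1.2].
    """
    if event.waveform.size == 0:
        raise ValidationError("event waveform is empty")
    fs = event.sampling_rate
    dwell_n = event.end_index - event.start_index
    ctx = CONTEXT_FRACTION * dwell_n
    t0 = event.start_index - ctx
    t1 = event.end_index + ctx
    pos = np.linspace(t0, t1, L)
    snippet_idx = np.arange(event.waveform_start,
                            event.waveform_start + event.waveform.size)
    vec = np.interp(pos, snippet_idx, event.waveform) / event.I0_local
    vec = np.clip(vec, *CLIP_RANGE)
    rel = event.relative_blockade
    return EncodedEvent(vec, (float(rel), float(np.log10(event.dwell))),
                        label=event.label)


def encode_events(events: list[EventRecord], L: int = DEFAULT_LENGTH) -> list[EncodedEvent]:
    return [encode_event(e, L) for e in events]


def encode_frame(encoded: list[EncodedEvent]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack encoded events into (waveforms [n, L], scalars [n, 2],
    labels [n])."""
    W = np.stack([e.waveform_vector for e in encoded])
    S = np.array([e.scalar_features for e in encoded])
    y = np.array([e.label for e in encoded], dtype=object)
    return W, S, y


def split_dataset(
    events: list,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    labels: np.ndarray | None = None,
    min_per_class: int = 20,
) -> tuple[list, list, list]:
    """Stratified, seeded train/validation/test partition.

    ``events`` may be any sequence with a ``label`` attribute, or pass
    ``labels`` explicitly.  Fractions must sum to 1; per-class sizes are
    rounded so the three parts partition each class exactly.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    if labels is None:
        labels = np.array([e.label for e in events], dtype=object)
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        if idx.size < min_per_class:
            raise InsufficientDataError(
                f"class {cls!r} has {idx.size} events; need >= {min_per_class}"
            )
        idx = rng.permutation(idx)
        n_train = int(round(fractions[0] * idx.size))
        n_val = int(round(fractions[1] * idx.size))
        cuts = [n_train, n_train + n_val]
        for part, sel in zip(parts, np.split(idx, cuts)):
            part.extend(events[i] for i in sel)
    return parts


class GaussianBayesClassifier(BaseEstimator, ClassifierMixin):
    """Class-conditional Gaussian(-mixture) Bayes decision on scalar
    features, with equal class priors.

    Each class density is a full-covariance Gaussian mixture whose
    component count (1 or up to ``max_components``) is chosen by BIC, so
    bimodal blockade populations are modelled without being told.  The
    decision is maximum posterior under equal priors; covariances are
    diagonally regularised, so singular fits cannot occur.

    Fitted attributes: ``classes_``, ``models_``.
    """

    def __init__(self, max_components: int = 2, random_state: int = 0,
                 reg_covar: float = 1e-9):
        self.max_components = max_components
        self.random_state = random_state
        self.reg_covar = reg_covar

    def fit(self, X, y) -> "GaussianBayesClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (events x scalar features)")
        self.classes_ = np.array(sorted(set(y.tolist()), key=str), dtype=object)
        if len(self.classes_) < 2:
            raise ValidationError("need at least 2 classes")
        self.models_ = {}
        for cls in self.classes_:
            Xc = X[y == cls]
            best = None
            for k in range(1, self.max_components + 1):
                if Xc.shape[0] < 10 * k:
                    break
                gm = GaussianMixture(
                    n_components=k, n_init=3, reg_covar=self.reg_covar,
                    random_state=self.random_state,
                ).fit(Xc)
                bic = gm.bic(Xc)
                if best is None or bic < best[0]:
                    best = (bic, gm)
            self.models_[cls] = best[1]
        return self

    def _log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack(
            [self.models_[c].score_samples(X) for c in self.classes_]
        )

    def predict_proba(self, X) -> np.ndarray:
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        ll = self._log_likelihood(X)
        return self.classes_[np.argmax(ll, axis=1)]


def train_bayes_baseline(
    train: list[EncodedEvent], random_state: int = 0
) -> GaussianBayesClassifier:
    """Fit the Bayes baseline on the scalar features of encoded events."""
    _, S, y = encode_frame(train)
    return GaussianBayesClassifier(random_state=random_state).fit(S, y)


def classify(model, events: list[EncodedEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class probabilities for encoded events.

    Dispatches on the model type: the Bayes baseline consumes the scalar
    features, the sequence model the full waveform + scalar encoding.
    Probability rows sum to 1; the label is the argmax with ties broken
    by class order.
    """
    if not events:
        k = len(getattr(model, "classes_", []))
        return np.empty(0, dtype=object), np.zeros((0, k))
    W, S, _ = encode_frame(events)
    if isinstance(model, GaussianBayesClassifier):
        X = S
    else:
        X = np.hstack([W, S])
    proba = model.predict_proba(X)
    labels = model.classes_[np.argmax(proba, axis=1)]
    return labels, proba


@dataclass
class ClassifierReport:
    classes: list[str]
    confusion: np.ndarray  # counts, true x predicted
    per_class: pd.DataFrame  # precision, recall, f1 indexed by class
    average_accuracy: float

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.astype(int).tolist(),
            "per_class": self.per_class.round(6).to_dict(orient="index"),
            "average_accuracy": self.average_accuracy,
        }


def evaluate(predictions, truth, classes: list[str] | None = None) -> ClassifierReport:
    """Confusion matrix, per-class precision/recall/F1 and accuracy.

    ``classes`` fixes the matrix ordering; by default the sorted union
    of the truth labels.  A predicted label absent from the class set is
    an error (the model was trained on a different label set).
    """
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predictions.shape != truth.shape:
        raise ValidationError("predictions and truth must align")
    if classes is None:
        classes = sorted(set(truth.tolist()), key=str)
    index = {c: i for i, c in enumerate(classes)}
    for t in truth:
        if t not in index:
            raise ValidationError(f"truth label {t!r} not in class set {classes}")
    for p in predictions:
        if p not in index:
            raise ValidationError(f"predicted label {p!r} not in class set {classes}")
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predictions):
        confusion[index[t], index[p]] += 1

    tp = np.diag(confusion).astype(float)
    pred_tot = confusion.sum(axis=0).astype(float)
    true_tot = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=list(classes)
    )
    accuracy = float(tp.sum() / confusion.sum()) if confusion.sum() else 0.0
    return ClassifierReport(list(classes), confusion, per_class, accuracy)
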