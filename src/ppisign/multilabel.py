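"""Multi-label classification by label combination over ℓ2-regularized
logistic regression.

Multi-label learning is reduced to multi-class: every distinct label set
observed in training becomes one combined class (the label-combination, or
label-powerset, method), so a single multi-class model covers all label
combinations. The multi-class model is one-vs-rest, each binary problem
minimizing the primal objective

    f(w) = (1/2) wᵀw + C Σ_i log(1 + exp(−y_i wᵀx_i)),

with an unregularized intercept. The regularizer penalizes noise — in
particular the noise carried into training by homolog instances — while
logistic loss keeps fitting linear in the data size, which matters because
pooling target and homolog instances doubles the training set.

Prediction for a protein pair scores the target instance and the homolog
instance separately; each decodes to the label set of its argmax combined
class. The two are fused by comparing raw decision values: the instance
with the larger maximum margin wins (target wins ties — its features are
the proteins' own annotations, the more direct evidence). A null instance
abstains (`None`), and a pair with both instances null is flagged
unpredictable rather than silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .features import FeatureVocabulary, InstancePair, Pair

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "ppisign-model/1"


@dataclass(frozen=True)
class CombinedLabelCodec:
    """Bijection between observed label sets and combined class codes."""

    combos: tuple[frozenset[str], ...]

    @property
    def n_classes(self) -> int:
        return len(self.combos)

    def encode(self, label_set: Iterable[str]) -> int:
        s = frozenset(label_set)
        try:
            return self.combos.index(s)
        except ValueError:
            raise ValueError(
                f"label set {sorted(s)} was never observed in training; "
                f"known combinations: {[sorted(c) for c in self.combos]}"
            ) from None

    def decode(self, code: int) -> frozenset[str]:
        return self.combos[code]

    def combo_strings(self) -> list[str]:
        return [",".join(sorted(c)) for c in self.combos]


def fit_codec(label_sets: Sequence[Iterable[str]]) -> CombinedLabelCodec:
    """Learn the combined-class codebook from training label sets.

    Combinations are ordered by their canonical comma-joined string so the
    coding is deterministic. Every input set must be non-empty.
    """
    if not label_sets:
        raise ValueError("no label sets given")
    distinct = set()
    for s in label_sets:
        fs = frozenset(s)
        if not fs:
            raise ValueError("empty label set in training data")
        distinct.add(fs)
    combos = tuple(sorted(distinct, key=lambda c: ",".join(sorted(c))))
    return CombinedLabelCodec(combos=combos)


@dataclass
class TrainedModel:
    """One-vs-rest weight vectors over the GO-term universe.

    ``W[k]`` and ``b[k]`` score combined class ``k``; ``codec`` maps class
    codes back to label sets; ``vocab`` fixes the feature space and
    ``vocab_fingerprint`` guards against mismatched vocabularies at load
    time.
    """

    W: np.ndarray                       # (n_classes, n_features)
    b: np.ndarray                       # (n_classes,)
    C: float
    tol: float
    codec: CombinedLabelCodec
    vocab: FeatureVocabulary
    vocab_fingerprint: str
    converged: bool
    objectives: tuple[float, ...]       # final primal objective per binary problem
    fit_intercept: bool = True

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]

    @property
    def final_objective(self) -> float:
        return float(sum(self.objectives))


def _primal_objective_grad(wb, X, y, C, fit_intercept):
    d = X.shape[1]
    w = wb[:d]
    bias = wb[d] if fit_intercept else 0.0
    z = y * (X @ w + bias)
    obj = 0.5 * (w @ w) + C * np.sum(np.logaddexp(0.0, -z))
    s = expit(-z)                       # σ(−y f(x))
    ys = y * s
    gw = w - C * (X.T @ ys)
    if fit_intercept:
        return obj, np.concatenate([gw, [-C * np.sum(ys)]])
    return obj, gw


def _newton_polish(wb, X, y, C, fit_intercept, tol, max_steps=50):
    """Damped Newton steps to drive the gradient ∞-norm below *tol*.

    The objective is smooth and strongly convex (the ridge term gives the
    Hessian a unit floor on the weight block), so Newton with step halving
    converges; used to finish off what L-BFGS leaves short of tolerance.
    """
    d = X.shape[1]
    obj, g = _primal_objective_grad(wb, X, y, C, fit_intercept)
    for _ in range(max_steps):
        if np.max(np.abs(g)) <= tol:
            break
        w = wb[:d]
        bias = wb[d] if fit_intercept else 0.0
        z = y * (X @ w + bias)
        s = expit(-z)
        D = C * s * (1.0 - s)           # loss curvature per sample
        if fit_intercept:
            H = np.empty((d + 1, d + 1))
            H[:d, :d] = (X.T * D) @ X + np.eye(d)
            H[:d, d] = X.T @ D
            H[d, :d] = H[:d, d]
            H[d, d] = np.sum(D) + 1e-12
        else:
            H = (X.T * D) @ X + np.eye(d)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            new = wb - t * step
            new_obj, new_g = _primal_objective_grad(new, X, y, C, fit_intercept)
            if new_obj <= obj:
                wb, obj, g = new, new_obj, new_g
                break
            t *= 0.5
        else:
            break
    return wb, obj, g


def _fit_binary(X, y, C, tol, max_iter, fit_intercept):
    """Fit one binary ℓ2-regularized logistic regression problem.

    L-BFGS on the primal, then a Newton polish so that the returned point
    satisfies ‖∇f‖∞ ≤ tol whenever the iteration budget allows.
    """
    d = X.shape[1]
    x0 = np.zeros(d + (1 if fit_intercept else 0))
    res = minimize(
        _primal_objective_grad,
        x0,
        args=(X, y, C, fit_intercept),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-15},
    )
    wb, obj, g = _newton_polish(res.x, X, y, C, fit_intercept, tol)
    grad_inf = float(np.max(np.abs(g)))
    w = wb[:d]
    bias = float(wb[d]) if fit_intercept else 0.0
    return w, bias, float(obj), grad_inf


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    fit_intercept: bool = True,
    codec: CombinedLabelCodec | None = None,
    vocab: FeatureVocabulary | None = None,
) -> TrainedModel:
    """Train the one-vs-rest multi-class model on pooled encoded instances.

    *X* holds the non-null target and homolog vectors (pooled — homolog
    instances are independent training instances), *y* the combined class
    codes. Requires at least two distinct classes and ``C > 0``.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()}); "
            "at least two are required"
        )
    if codec is None:
        codec = CombinedLabelCodec(
            combos=tuple(frozenset({str(c)}) for c in range(int(classes.max()) + 1))
        )
    if vocab is None:
        vocab = FeatureVocabulary(terms=tuple(f"f{i}" for i in range(X.shape[1])))
    n_classes = codec.n_classes
    d = X.shape[1]
    W = np.zeros((n_classes, d))
    b = np.zeros(n_classes)
    objectives = []
    converged = True
    for k in range(n_classes):
        yk = np.where(y == k, 1.0, -1.0)
        if np.all(yk == yk[0]):
            # class absent from this training split: leave a zero scorer,
            # it can never win the argmax against fitted classes
            objectives.append(C * len(yk) * np.log(2.0))
            continue
        w, bias, obj, grad_inf = _fit_binary(X, yk, C, tol, max_iter, fit_intercept)
        W[k] = w
        b[k] = bias
        objectives.append(obj)
        if grad_inf > tol:
            converged = False
            logger.warning(
                "class %d: gradient ∞-norm %.2e > tol %.1e after %d iterations",
                k, grad_inf, tol, max_iter,
            )
    return TrainedModel(
        W=W,
        b=b,
        C=float(C),
        tol=float(tol),
        codec=codec,
        vocab=vocab,
        vocab_fingerprint=vocab.fingerprint(),
        converged=converged,
        objectives=tuple(objectives),
        fit_intercept=fit_intercept,
    )


def pool_instances(
    instances: Sequence[InstancePair], codec: CombinedLabelCodec
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all non-null target and homolog vectors with their class codes."""
    rows, codes = [], []
    for inst in instances:
        code = codec.encode(inst.labels)
        for vec in (inst.target_vec, inst.homolog_vec):
            if vec is not None:
                rows.append(vec)
                codes.append(code)
    if not rows:
        raise ValueError("no non-null instances to train on")
    return np.asarray(rows, dtype=float), np.asarray(codes, dtype=int)


def decision_values(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Per-class raw margins ``W x + b`` for one encoded vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.W.shape[1],):
        raise ValueError(
            f"feature vector length {x.shape} does not match "
            f"model dimensionality {model.W.shape[1]}"
        )
    return model.W @ x + model.b


@dataclass
class PredictionRecord:
    """Decoded label sets and decision values for one protein pair.

    ``target_labels``/``homolog_labels`` are ``None`` when that instance is
    null (an abstention, not a prediction). ``fused_labels`` is the label
    set of the instance with the larger maximum decision value.
    """

    pair: Pair
    target_labels: Optional[frozenset[str]]
    homolog_labels: Optional[frozenset[str]]
    target_decisions: Optional[np.ndarray]
    homolog_decisions: Optional[np.ndarray]
    fused_labels: Optional[frozenset[str]]
    unpredictable: bool = False

    @property
    def target_max_decision(self) -> Optional[float]:
        if self.target_decisions is None:
            return None
        return float(np.max(self.target_decisions))

    @property
    def homolog_max_decision(self) -> Optional[float]:
        if self.homolog_decisions is None:
            return None
        return float(np.max(self.homolog_decisions))


def predict_pair(model: TrainedModel, inst: InstancePair) -> PredictionRecord:
    """Predict label sets for one pair's target and homolog instances and
    fuse them by decision value (ties go to the target instance)."""
    t_labels = h_labels = None
    t_dec = h_dec = None
    if inst.target_vec is not None:
        t_dec = decision_values(model, inst.target_vec)
        t_labels = model.codec.decode(int(np.argmax(t_dec)))
    if inst.homolog_vec is not None:
        h_dec = decision_values(model, inst.homolog_vec)
        h_labels = model.codec.decode(int(np.argmax(h_dec)))
    if t_labels is None and h_labels is None:
        return PredictionRecord(
            pair=inst.pair,
            target_labels=None, homolog_labels=None,
            target_decisions=None, homolog_decisions=None,
            fused_labels=None, unpredictable=True,
        )
    if t_labels is None:
        fused = h_labels
    elif h_labels is None:
        fused = t_labels
    elif float(np.max(h_dec)) > float(np.max(t_dec)):
        fused = h_labels
    else:
        fused = t_labels
    return PredictionRecord(
        pair=inst.pair,
        target_labels=t_labels, homolog_labels=h_labels,
        target_decisions=t_dec, homolog_decisions=h_dec,
        fused_labels=fused,
    )


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a single portable JSON archive."""
    payload = {
        "format": MODEL_FORMAT_VERSION,
        "C": model.C,
        "tol": model.tol,
        "fit_intercept": model.fit_intercept,
        "converged": model.converged,
        "objectives": list(model.objectives),
        "combos": model.codec.combo_strings(),
        "vocabulary": list(model.vocab.terms),
        "vocab_fingerprint": model.vocab_fingerprint,
        "W": model.W.tolist(),
        "b": model.b.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {payload.get('format')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    vocab = FeatureVocabulary(terms=tuple(payload["vocabulary"]))
    if vocab.fingerprint() != payload["vocab_fingerprint"]:
        raise ValueError("vocabulary fingerprint mismatch: corrupt model archive")
    codec = CombinedLabelCodec(
        combos=tuple(
            frozenset(s.split(",")) for s in payload["combos"]
        )
    )
    return TrainedModel(
        W=np.asarray(payload["W"], dtype=float),
        b=np.asarray(payload["b"], dtype=float),
        C=float(payload["C"]),
        tol=float(payload["tol"]),
        codec=codec,
        vocab=vocab,
        vocab_fingerprint=payload["vocab_fingerprint"],
        converged=bool(payload["converged"]),
        objectives=tuple(payload["objectives"]),
        fit_intercept=bool(payload["fit_intercept"]),
    )
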