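"""The readout network: RF responses -> hidden(10) -> class scores.

A small fully connected network decodes the target identity from the
population response vector. Classification is winner-take-all on the output
layer. Training minimises cross-entropy with a full-batch quasi-Newton
optimiser (L-BFGS) on tanh hidden units and a softmax output — a setup whose
solution quality matches scaled-conjugate-gradient backpropagation on
problems of this size. Chance-level calibration uses an empirical null built
by shuffling training labels and testing on correctly labelled data.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

N_HIDDEN = 10
MAX_EPOCHS = 500


@dataclass
class DecoderNet:
    """A trained decoder with its class map.

    ``clf`` is a fitted scikit-learn multilayer perceptron;
    ``classes`` maps output-unit index to symbol name. Ablations mutate
    ``clf.coefs_[0]`` (the input->hidden weight matrix) in place on a copy.
    """

    clf: MLPClassifier
    classes: tuple[str, ...]

    @property
    def n_inputs(self) -> int:
        return self.clf.coefs_[0].shape[0]

    def copy(self) -> "DecoderNet":
        return DecoderNet(copy.deepcopy(self.clf), self.classes)

    def output_activations(self, X: np.ndarray) -> np.ndarray:
        p = self.clf.predict_proba(np.atleast_2d(X))
        k = len(self.classes)
        cls = np.asarray(self.clf.classes_, dtype=int)
        if p.shape[1] == k and np.array_equal(cls, np.arange(k)):
            return p
        # A shuffled training fold can miss a class; absent units score 0.
        out = np.zeros((p.shape[0], k))
        out[:, cls] = p
        return out

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "hidden_activation": self.clf.activation,
            "coefs": [w.tolist() for w in self.clf.coefs_],
            "intercepts": [b.tolist() for b in self.clf.intercepts_],
        }


@dataclass
class PerformanceResult:
    """Iteration-averaged proportion correct for one condition."""

    condition: str
    per_iteration: np.ndarray
    p_value: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)

    @property
    def proportion_correct(self) -> float:
        return float(np.mean(self.per_iteration))

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of the iteration mean."""
        n = self.n_iterations
        if n < 2:
            return float("nan")
        return float(np.std(self.per_iteration, ddof=1) / np.sqrt(n))

    def summary(self) -> dict:
        out = {
            "condition": self.condition,
            "mean": self.proportion_correct,
            "se": self.se,
            "n_iterations": self.n_iterations,
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
        out.update(self.extras)
        return out


def train(
    X: np.ndarray,
    y: np.ndarray,
    classes: tuple[str, ...],
    rng: np.random.Generator,
    n_hidden: int = N_HIDDEN,
    max_epochs: int = MAX_EPOCHS,
) -> DecoderNet:
    """Train the decoder on encoded examples.

    Parameters
    ----------
    X : (n_examples, n_rfs) response matrix.
    y : symbol labels, one per row of X.
    classes : the task's symbol classes, fixing output-unit order.
    rng : seeds the weight initialisation (deterministic per seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with one label per row")
    present = set(np.unique(y))
    if not present <= set(classes):
        raise ValueError(f"labels {present - set(classes)} not in classes {classes}")
    clf = MLPClassifier(
        hidden_layer_sizes=(n_hidden,),
        activation="tanh",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=max_epochs,
        tol=1e-6,
        random_state=int(rng.integers(2**31)),
    )
    # Fit with the full class list even if a shuffled fold misses one.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, _encode_labels(y, classes))
    return DecoderNet(clf, tuple(classes))


def _encode_labels(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[v] for v in y], dtype=int)


def classify(net: DecoderNet, response_vector: np.ndarray) -> str:
    """Winner-take-all readout; ties resolve to the lowest class index."""
    v = np.asarray(response_vector, dtype=float)
    if v.ndim != 1 or v.shape[0] != net.n_inputs:
        raise ValueError(
            f"response vector length {v.shape} does not match net input width {net.n_inputs}"
        )
    scores = net.output_activations(v[None])[0]
    return net.classes[int(np.argmax(scores))]


def classify_batch(net: DecoderNet, X: np.ndarray) -> np.ndarray:
    scores = net.output_activations(X)
    idx = np.argmax(scores, axis=1)
    return np.asarray([net.classes[i] for i in idx])


def evaluate(net: DecoderNet, X: np.ndarray, y: np.ndarray) -> float:
    """Proportion of test examples classified correctly."""
    if len(X) == 0:
        raise ValueError("empty test set")
    pred = classify_batch(net, np.asarray(X, dtype=float))
    return float(np.mean(pred == np.asarray(y)))


def permutation_p_value(null: np.ndarray, observed: float) -> float:
    """Proportion of the chance distribution at or above the observed value.

    Zero means the observed value exceeded every null draw, i.e.
    p < 1/len(null).
    """
    null = np.asarray(null, dtype=float)
    return float(np.mean(null >= observed))
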