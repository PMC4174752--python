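"""Sparse selection: ablating RF units or connections from the decoder.

Three regimes model a readout that samples only part of the population:

- ``drop_units_retrain``: remove whole RFs, then train a fresh network on
  the reduced input layer (a separate readout circuit wired to a sparse
  subset of units).
- ``drop_units_no_retrain``: silence whole RFs in an already-trained network
  (the readout taps the same circuit but only reaches a subset of units).
- ``drop_connections``: silence individual input->hidden weights rather than
  entire units.

Performance as a function of the sampled fraction traces the crowding cost
of sparse selection; the fraction where it first falls to a criterion ratio
of full performance summarises the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import decoder
from .decoder import DecoderNet
from .errors import ThresholdNotReached

MODES = ("drop_units_retrain", "drop_units_no_retrain", "drop_connections")


@dataclass(frozen=True)
class AblationSpec:
    mode: str
    fraction_removed: float

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown ablation mode: {self.mode!r}")
        if not (0.0 <= self.fraction_removed < 1.0):
            raise ValueError(
                f"fraction_removed must be in [0, 1), got {self.fraction_removed}"
            )


@dataclass
class SamplingCurve:
    """Mean performance against fraction of input units/connections sampled."""

    fractions_sampled: np.ndarray  # descending, starts at 1.0
    per_iteration: np.ndarray  # (n_iterations, n_fractions)
    mode: str
    condition: str = ""

    @property
    def mean_performance(self) -> np.ndarray:
        return self.per_iteration.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_iteration.std(axis=0, ddof=1)

    @property
    def n_iterations(self) -> int:
        return self.per_iteration.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fraction_sampled": self.fractions_sampled,
                "mean": self.mean_performance,
                "sd": self.sd,
                "n": self.n_iterations,
            }
        )


DEFAULT_FRACTIONS = np.round(np.arange(1.0, 0.05, -0.1), 10)


def stratified_keep_indices(
    tunings: np.ndarray, n_keep: int, rng: np.random.Generator
) -> np.ndarray:
    """Choose ``n_keep`` unit indices, balanced across tuning classes.

    Splits the kept count as evenly as possible over classes (remainder
    assigned to randomly chosen classes), sampling without replacement
    within each class. Falls back gracefully when n_keep < n_classes.
    """
    classes = np.unique(tunings)
    k = len(classes)
    base, rem = divmod(n_keep, k)
    counts = np.full(k, base, dtype=int)
    extra = rng.choice(k, size=rem, replace=False) if rem else []
    counts[np.asarray(extra, dtype=int)] += 1
    kept = []
    for cls, cnt in zip(classes, counts):
        pool = np.flatnonzero(tunings == cls)
        kept.append(rng.choice(pool, size=min(cnt, len(pool)), replace=False))
    return np.sort(np.concatenate(kept))


def drop_units_no_retrain(
    net: DecoderNet, removed: np.ndarray
) -> DecoderNet:
    """Silence whole input units in a trained net (zero their input weights)."""
    out = net.copy()
    out.clf.coefs_[0][np.asarray(removed, dtype=int), :] = 0.0
    return out


def drop_connections(net: DecoderNet, fraction_removed: float, rng: np.random.Generator) -> DecoderNet:
    """Silence a random fraction of individual input->hidden weights."""
    out = net.copy()
    w = out.clf.coefs_[0]
    n_total = w.size
    n_drop = int(round(fraction_removed * n_total))
    flat = rng.choice(n_total, size=n_drop, replace=False)
    w.ravel()[flat] = 0.0
    return out


def ablate(
    net: DecoderNet,
    spec: AblationSpec,
    rng: np.random.Generator,
    X_train: np.ndarray | None = None,
    y_train: np.ndarray | None = None,
    tunings: np.ndarray | None = None,
) -> tuple[DecoderNet, np.ndarray | None]:
    """Apply an ablation spec; returns (reduced net, kept unit indices).

    For ``drop_units_retrain`` the training data must be supplied: a fresh
    net is trained on the kept input columns, and evaluation must use the
    same column subset (the returned kept indices). For the other modes the
    net is modified in place on a copy and kept indices are None.
    """
    if spec.fraction_removed == 0.0:
        return net, None
    n_units = net.n_inputs
    if spec.mode == "drop_units_retrain":
        if X_train is None or y_train is None:
            raise ValueError("retrain mode needs the encoded training set")
        n_keep = int(round((1.0 - spec.fraction_removed) * n_units))
        n_keep = max(n_keep, 1)
        if tunings is not None:
            kept = stratified_keep_indices(np.asarray(tunings), n_keep, rng)
        else:
            kept = np.sort(rng.choice(n_units, size=n_keep, replace=False))
        reduced = decoder.train(X_train[:, kept], y_train, net.classes, rng)
        return reduced, kept
    if spec.mode == "drop_units_no_retrain":
        n_drop = int(round(spec.fraction_removed * n_units))
        removed = rng.choice(n_units, size=n_drop, replace=False)
        return drop_units_no_retrain(net, removed), None
    # drop_connections
    return drop_connections(net, spec.fraction_removed, rng), None


def threshold_fraction(curve: SamplingCurve, criterion_ratio: float = 0.9) -> float:
    """Fraction sampled where performance first falls to criterion_ratio x full.

    Walks the curve from the full-sampling end and linearly interpolates
    between the two grid points bracketing the first crossing.

    Raises
    ------
    ThresholdNotReached
        If the mean curve never drops below the criterion.
    """
    if not (0.0 < criterion_ratio < 1.0):
        raise ValueError("criterion_ratio must be in (0, 1)")
    fr = np.asarray(curve.fractions_sampled, dtype=float)
    perf = np.asarray(curve.mean_performance, dtype=float)
    order = np.argsort(-fr)  # descending from 1.0
    fr, perf = fr[order], perf[order]
    target = criterion_ratio * perf[0]
    for i in range(1, len(fr)):
        if perf[i] < target:
            if perf[i - 1] == perf[i]:
                return float(fr[i])
            t = (perf[i - 1] - target) / (perf[i - 1] - perf[i])
            return float(fr[i - 1] + t * (fr[i] - fr[i - 1]))
    raise ThresholdNotReached(
        f"curve never falls below {criterion_ratio:.2f} of full performance"
    )
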