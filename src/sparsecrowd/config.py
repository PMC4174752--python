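"""Experiment configurations: per-variant defaults, validation, YAML/JSON IO.

Variants
--------
``peripheral``
    101x101 display, 3 object symbols (circle/triangle/x), 24 RFs of mean
    diameter 50 scaling with slope 0.7, 120 training / 60 test images.
``foveal``
    61x61 display, 45 RFs (5x the peripheral RF density), RF centers biased
    toward the fovea by a cortical-magnification profile; the diameter rule
    keeps the peripheral anchor, so the smaller, more foveal display yields
    smaller RFs.
``feature``
    101x101 display, horizontal/vertical line symbols, 48 RFs of mean
    diameter 20 (a lower, feature-tuned stage).
``tumbling_t``
    Same feature-tuned RF population, but targets/flankers are the letter T
    in 4 cardinal orientations: a 4-way object task read from line detectors.
``zone``
    151x151 display (peripheral display scaled by 150%) with 48 RFs,
    ellipticity 0.5 and 240 training images, used to map the crowding zone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigError
from .glyphs import LINE_SYMBOLS, OBJECT_SYMBOLS, TUMBLING_T_SYMBOLS

VARIANTS = ("peripheral", "foveal", "feature", "tumbling_t", "zone")


@dataclass(frozen=True)
class ExperimentConfig:
    variant: str
    display_size: int
    n_rfs: int
    symbols: tuple[str, ...]
    tuning_symbols: tuple[str, ...]
    mean_diameter: float = 50.0
    scaling_slope: float = 0.7
    diameter_reference_x: float | None = None  # None -> display center
    ellipticity: float = 1.0
    placement: str = "uniform"
    glyph_size: int = 20
    n_train: int = 120
    n_test: int = 60
    n_flankers: int = 2
    n_hidden: int = 10
    n_iterations: int = 1000

    @property
    def n_classes(self) -> int:
        return len(self.symbols)

    @property
    def reference_x(self) -> float:
        if self.diameter_reference_x is not None:
            return self.diameter_reference_x
        return (self.display_size - 1) / 2.0

    def validate(self) -> "ExperimentConfig":
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant: {self.variant!r}")
        if not (0.0 < self.ellipticity <= 1.0):
            raise ConfigError(f"ellipticity outside (0, 1]: {self.ellipticity}")
        if self.n_rfs % len(self.tuning_symbols):
            raise ConfigError(
                f"n_rfs={self.n_rfs} not divisible by "
                f"{len(self.tuning_symbols)} tuning classes"
            )
        if self.n_train % self.n_classes or self.n_test % self.n_classes:
            raise ConfigError("training/test set sizes must be class-balanced")
        if self.display_size < self.glyph_size:
            raise ConfigError("display smaller than glyph")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.placement not in ("uniform", "foveal"):
            raise ConfigError(f"unknown placement: {self.placement!r}")
        return self

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["symbols"] = list(self.symbols)
        d["tuning_symbols"] = list(self.tuning_symbols)
        return d


def default_config(variant: str, **overrides) -> ExperimentConfig:
    """The canonical configuration for a named experiment variant."""
    if variant == "peripheral":
        cfg = ExperimentConfig(
            variant="peripheral",
            display_size=101,
            n_rfs=24,
            symbols=OBJECT_SYMBOLS,
            tuning_symbols=OBJECT_SYMBOLS,
            mean_diameter=50.0,
        )
    elif variant == "foveal":
        cfg = ExperimentConfig(
            variant="foveal",
            display_size=61,
            n_rfs=45,
            symbols=OBJECT_SYMBOLS,
            tuning_symbols=OBJECT_SYMBOLS,
            mean_diameter=50.0,
            diameter_reference_x=50.0,  # keep the peripheral diameter anchor
            placement="foveal",
        )
    elif variant == "feature":
        cfg = ExperimentConfig(
            variant="feature",
            display_size=101,
            n_rfs=48,
            symbols=LINE_SYMBOLS,
            tuning_symbols=LINE_SYMBOLS,
            mean_diameter=20.0,
        )
    elif variant == "tumbling_t":
        cfg = ExperimentConfig(
            variant="tumbling_t",
            display_size=101,
            n_rfs=48,
            symbols=TUMBLING_T_SYMBOLS,
            tuning_symbols=LINE_SYMBOLS,
            mean_diameter=20.0,
        )
    elif variant == "zone":
        cfg = ExperimentConfig(
            variant="zone",
            display_size=151,
            n_rfs=48,
            symbols=OBJECT_SYMBOLS,
            tuning_symbols=OBJECT_SYMBOLS,
            mean_diameter=50.0,
            ellipticity=0.5,
            n_train=240,
            n_iterations=100,
        )
    else:
        raise ConfigError(f"unknown variant: {variant!r}")
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg.validate()


_OVERRIDABLE = {
    f.name for f in dataclasses.fields(ExperimentConfig) if f.name != "variant"
}


def load_config(path) -> ExperimentConfig:
    """Load a YAML/JSON config file; omitted keys take variant defaults.

    The file must name a ``variant``; unknown keys are rejected with the
    offending key named.
    """
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    if "variant" not in data:
        raise ConfigError("config must name a 'variant'")
    variant = data.pop("variant")
    for key in data:
        if key not in _OVERRIDABLE:
            raise ConfigError(f"unknown config key: {key!r}")
    for key in ("symbols", "tuning_symbols"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return default_config(variant, **data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Seed-stream bookkeeping: one global seed expands into named substreams so
# each stage (stimuli, RF placement, weights, ablation, permutation) draws
# from its own reproducible stream.

STAGES = (
    "train_stimuli",
    "test_stimuli",
    "population",
    "weights",
    "ablation",
    "permutation",
)


def stage_rng(seed: int, iteration: int, stage: str) -> np.random.Generator:
    """Deterministic per-(seed, iteration, stage) random generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(iteration), STAGES.index(stage)])
    )
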