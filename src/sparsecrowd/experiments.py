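"""Seeded experiment runners for every simulation in the package.

Every runner is a pure function of (config, seed): stimuli, RF placement,
RF tuning and decoder weights are re-randomised on each iteration from named
substreams of the global seed, so re-runs reproduce results bit-exactly.
Reported means are averages of per-iteration proportion correct, with
Monte-Carlo standard errors available on the result objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoder
from .ablation import (
    DEFAULT_FRACTIONS,
    AblationSpec,
    SamplingCurve,
    ablate,
    threshold_fraction,
)
from .config import ExperimentConfig, stage_rng
from .decoder import DecoderNet, PerformanceResult, evaluate
from .encoding import (
    RFPopulation,
    encode_batch,
    encode_displays,
    encode_set,
    sample_population,
)
from .errors import ConfigError
from .stimuli import (
    LabelledSet,
    paired_flanker_set,
    random_set,
    single_flanker_probe_set,
    zone_probe_positions,
)

FLANKER_OFFSET = 25  # px, center-to-center, for the fixed probe batteries


def build_set(cfg: ExperimentConfig, role: str, rng: np.random.Generator) -> LabelledSet:
    """Generate a class-balanced random training or test set for a variant."""
    if role not in ("training", "test"):
        raise ConfigError(f"role must be 'training' or 'test', got {role!r}")
    n = cfg.n_train if role == "training" else cfg.n_test
    return random_set(
        cfg.symbols,
        n,
        cfg.display_size,
        cfg.n_flankers,
        rng,
        role=role,
        glyph_size=cfg.glyph_size,
        variant=cfg.variant,
    )


def _population(cfg: ExperimentConfig, rng: np.random.Generator, ellipticity=None) -> RFPopulation:
    return sample_population(
        cfg.n_rfs,
        cfg.display_size,
        cfg.tuning_symbols,
        rng,
        mean_diameter=cfg.mean_diameter,
        slope=cfg.scaling_slope,
        reference_x=cfg.reference_x,
        ellipticity=cfg.ellipticity if ellipticity is None else ellipticity,
        placement=cfg.placement,
        glyph_size=cfg.glyph_size,
    )


def _train_iteration(cfg: ExperimentConfig, seed: int, it: int, ellipticity=None):
    """One iteration's fresh stimuli, population and trained decoder."""
    train_set = build_set(cfg, "training", stage_rng(seed, it, "train_stimuli"))
    pop = _population(cfg, stage_rng(seed, it, "population"), ellipticity)
    X, y = encode_set(pop, train_set)
    net = decoder.train(X, y, cfg.symbols, stage_rng(seed, it, "weights"))
    return pop, net, X, y


def _tunings(pop: RFPopulation) -> np.ndarray:
    return np.asarray([pop.tuning_symbols.index(rf.preferred_id) for rf in pop.rfs])


# ---------------------------------------------------------------------------
# Basic accuracy and sampling curves


def run_accuracy(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int,
    fraction_removed: float = 0.0,
    mode: str = "drop_units_retrain",
) -> PerformanceResult:
    """Iteration-averaged test accuracy, optionally with units ablated.

    With ``fraction_removed`` > 0 the chosen ablation regime is applied on
    every iteration before testing.
    """
    per_iter = np.empty(n_iterations)
    for it in range(n_iterations):
        pop, net, X, y = _train_iteration(cfg, seed, it)
        test = build_set(cfg, "test", stage_rng(seed, it, "test_stimuli"))
        Xte, yte = encode_set(pop, test)
        if fraction_removed > 0.0:
            spec = AblationSpec(mode, fraction_removed)
            net2, kept = ablate(
                net, spec, stage_rng(seed, it, "ablation"), X, y, _tunings(pop)
            )
            per_iter[it] = evaluate(net2, Xte if kept is None else Xte[:, kept], yte)
        else:
            per_iter[it] = evaluate(net, Xte, yte)
    label = cfg.variant if fraction_removed == 0 else f"{cfg.variant}:{mode}@{fraction_removed}"
    return PerformanceResult(label, per_iter)


def run_sampling_curve(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int,
    mode: str = "drop_units_retrain",
    fractions_sampled: np.ndarray = DEFAULT_FRACTIONS,
) -> SamplingCurve:
    """Performance vs fraction of input units/connections sampled.

    Stimuli and the RF population are shared across fractions within an
    iteration (a paired design); the removed set is redrawn per fraction.
    """
    fractions = np.asarray(sorted(fractions_sampled, reverse=True), dtype=float)
    if fractions[0] != 1.0:
        raise ValueError("fractions_sampled must include 1.0")
    perf = np.empty((n_iterations, len(fractions)))
    for it in range(n_iterations):
        pop, net, X, y = _train_iteration(cfg, seed, it)
        test = build_set(cfg, "test", stage_rng(seed, it, "test_stimuli"))
        Xte, yte = encode_set(pop, test)
        rng_abl = stage_rng(seed, it, "ablation")
        tn = _tunings(pop)
        for j, f in enumerate(fractions):
            if f == 1.0:
                perf[it, j] = evaluate(net, Xte, yte)
                continue
            net2, kept = ablate(net, AblationSpec(mode, 1.0 - f), rng_abl, X, y, tn)
            perf[it, j] = evaluate(net2, Xte if kept is None else Xte[:, kept], yte)
    return SamplingCurve(fractions, perf, mode, condition=cfg.variant)


def run_permutation_null(
    cfg: ExperimentConfig, seed: int, n_perm: int
) -> np.ndarray:
    """Empirical chance distribution: shuffle training labels, test on truth.

    Each draw trains a fresh decoder on label-shuffled encodings and scores
    it against correctly labelled test images; the resulting accuracies
    center on 1/k.
    """
    null = np.empty(n_perm)
    for it in range(n_perm):
        pop, _, X, y = _train_iteration(cfg, seed, it)
        rng_p = stage_rng(seed, it, "permutation")
        y_shuf = np.array(y)
        rng_p.shuffle(y_shuf)
        net = decoder.train(X, y_shuf, cfg.symbols, stage_rng(seed, it, "weights"))
        test = build_set(cfg, "test", stage_rng(seed, it, "test_stimuli"))
        Xte, yte = encode_set(pop, test)
        null[it] = evaluate(net, Xte, yte)
    return null


@dataclass
class ExperimentSummary:
    """Full + sparse results for one variant (accuracy, curve, crossing)."""

    full: PerformanceResult
    curve: SamplingCurve
    crossing_fraction_sampled: float

    def summary(self) -> dict:
        return {
            "full": self.full.summary(),
            "crossing_fraction_sampled": self.crossing_fraction_sampled,
            "curve": {
                "fractions_sampled": self.curve.fractions_sampled.tolist(),
                "mean": self.curve.mean_performance.tolist(),
                "sd": self.curve.sd.tolist(),
                "mode": self.curve.mode,
                "n_iterations": self.curve.n_iterations,
            },
        }


def run_variant(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int,
    curve_iterations: int | None = None,
    mode: str = "drop_units_retrain",
) -> ExperimentSummary:
    """Full-model accuracy plus the sparse-selection sampling curve."""
    full = run_accuracy(cfg, seed, n_iterations)
    curve = run_sampling_curve(cfg, seed, curve_iterations or n_iterations, mode)
    crossing = threshold_fraction(curve, 0.9)
    return ExperimentSummary(full, curve, crossing)


def run_peripheral(seed: int, n_iterations: int = 200, curve_iterations: int | None = None,
                   cfg: ExperimentConfig | None = None) -> ExperimentSummary:
    from .config import default_config

    return run_variant(cfg or default_config("peripheral"), seed, n_iterations, curve_iterations)


def run_foveal(seed: int, n_iterations: int = 100, curve_iterations: int | None = None,
               cfg: ExperimentConfig | None = None) -> ExperimentSummary:
    from .config import default_config

    return run_variant(cfg or default_config("foveal"), seed, n_iterations, curve_iterations)


# ---------------------------------------------------------------------------
# Paired significance helper


def paired_permutation_test(
    diffs: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 5000,
    alternative: str = "greater",
) -> float:
    """Sign-flip permutation test on paired per-iteration differences."""
    d = np.asarray(diffs, dtype=float)
    obs = d.mean()
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = (signs * d).mean(axis=1)
    if alternative == "greater":
        extreme = null >= obs
    elif alternative == "two-sided":
        extreme = np.abs(null) >= abs(obs)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return float((1 + extreme.sum()) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Inner-outer asymmetry and substitution errors


@dataclass
class FlankerProbeResult:
    """Per-iteration results on the fixed 12-image single-flanker battery."""

    acc_inner: np.ndarray
    acc_outer: np.ndarray
    n_errors: int
    n_flanker_reports: int
    p_inner_gt_outer: float

    @property
    def substitution_rate(self) -> float:
        """Fraction of pooled errors that reported the flanker identity."""
        if self.n_errors == 0:
            return float("nan")
        return self.n_flanker_reports / self.n_errors

    def summary(self) -> dict:
        return {
            "inner_mean": float(self.acc_inner.mean()),
            "outer_mean": float(self.acc_outer.mean()),
            "p_inner_gt_outer": self.p_inner_gt_outer,
            "n_errors": self.n_errors,
            "n_flanker_reports": self.n_flanker_reports,
            "substitution_rate": self.substitution_rate,
            "n_iterations": len(self.acc_inner),
        }


def run_flanker_probe(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int,
    ablation_fraction: float = 0.5,
) -> FlankerProbeResult:
    """Train, ablate post-training, test on the single-flanker battery.

    The battery holds one flanker per image at +/-25 px horizontally from
    the target, never the target's own symbol (12 images for 3 symbols).
    ``ablation_fraction`` of RF units is silenced post-training without
    retraining (0 disables ablation). Inner = flanker on the foveal (left)
    side; outer = eccentric (right) side. Errors are pooled over iterations
    and split by whether the flanker identity was reported.
    """
    probe = single_flanker_probe_set(cfg.symbols, cfg.display_size, FLANKER_OFFSET, cfg.glyph_size)
    displays = [d for d, _ in probe.items]
    targets = np.asarray(probe.labels())
    flankers = np.asarray([d.flankers[0][0] for d, _ in probe.items])
    outer = np.asarray(
        [d.flankers[0][1][1] > d.target_position[1] for d, _ in probe.items]
    )
    acc_in = np.empty(n_iterations)
    acc_out = np.empty(n_iterations)
    n_err = 0
    n_sub = 0
    for it in range(n_iterations):
        pop, net, X, y = _train_iteration(cfg, seed, it)
        if ablation_fraction > 0.0:
            net, _ = ablate(
                net,
                AblationSpec("drop_units_no_retrain", ablation_fraction),
                stage_rng(seed, it, "ablation"),
            )
        Xp = encode_displays(pop, displays)
        pred = decoder.classify_batch(net, Xp)
        correct = pred == targets
        acc_in[it] = correct[~outer].mean()
        acc_out[it] = correct[outer].mean()
        err = ~correct
        n_err += int(err.sum())
        n_sub += int((pred[err] == flankers[err]).sum())
    p = paired_permutation_test(
        acc_in - acc_out, stage_rng(seed, 0, "permutation"), alternative="greater"
    )
    return FlankerProbeResult(acc_in, acc_out, n_err, n_sub, p)


def run_inner_outer(cfg, seed, n_iterations, ablation_fraction=0.5) -> FlankerProbeResult:
    """Inner-outer asymmetry probe (see :func:`run_flanker_probe`)."""
    return run_flanker_probe(cfg, seed, n_iterations, ablation_fraction)


def run_substitution(cfg, seed, n_iterations, ablation_fraction=0.5) -> FlankerProbeResult:
    """Substitution-error probe (see :func:`run_flanker_probe`)."""
    return run_flanker_probe(cfg, seed, n_iterations, ablation_fraction)


# ---------------------------------------------------------------------------
# Radial bias vs RF ellipticity


@dataclass
class RadialBiasResult:
    """Tangential/radial performance ratio per RF ellipticity."""

    ellipticities: np.ndarray
    acc_lr: np.ndarray  # (n_iterations, n_ellipticities), radial flankers
    acc_ab: np.ndarray  # tangential flankers
    p_values: np.ndarray  # departure of the ratio from 1, per ellipticity

    @property
    def ratio(self) -> np.ndarray:
        """mean(AB accuracy) / mean(LR accuracy) per ellipticity (>1 = radial bias)."""
        return self.acc_ab.mean(axis=0) / self.acc_lr.mean(axis=0)

    def summary(self) -> dict:
        return {
            "ellipticities": self.ellipticities.tolist(),
            "ratio": self.ratio.tolist(),
            "p_values": self.p_values.tolist(),
            "acc_lr_mean": self.acc_lr.mean(axis=0).tolist(),
            "acc_ab_mean": self.acc_ab.mean(axis=0).tolist(),
            "n_iterations": self.acc_lr.shape[0],
        }


DEFAULT_ELLIPTICITIES = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5])


def run_radial_bias(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int,
    ellipticities: np.ndarray = DEFAULT_ELLIPTICITIES,
    ablation_fraction: float = 0.5,
) -> RadialBiasResult:
    """Radial-vs-tangential flanker interference as RFs grow elliptical.

    For each ellipticity, the 50%-ablated model is tested on two fixed
    batteries: flankers at +/-25 px left/right of the target (radial axis)
    or above/below (tangential axis). RF centers, stimuli and weights are
    matched across ellipticities within an iteration, so the comparison is
    paired. The bias measure is mean(AB)/mean(LR); its significance per
    ellipticity is a two-sided sign-flip test on per-iteration differences.
    """
    ells = np.asarray(ellipticities, dtype=float)
    lr = paired_flanker_set(cfg.symbols, "lr", cfg.display_size, FLANKER_OFFSET, cfg.glyph_size)
    ab = paired_flanker_set(cfg.symbols, "ab", cfg.display_size, FLANKER_OFFSET, cfg.glyph_size)
    d_lr, y_lr = [d for d, _ in lr.items], np.asarray(lr.labels())
    d_ab, y_ab = [d for d, _ in ab.items], np.asarray(ab.labels())
    acc_lr = np.empty((n_iterations, len(ells)))
    acc_ab = np.empty((n_iterations, len(ells)))
    for it in range(n_iterations):
        for j, e in enumerate(ells):
            pop, net, X, y = _train_iteration(cfg, seed, it, ellipticity=e)
            if ablation_fraction > 0.0:
                net, _ = ablate(
                    net,
                    AblationSpec("drop_units_no_retrain", ablation_fraction),
                    stage_rng(seed, it, "ablation"),
                )
            pred_lr = decoder.classify_batch(net, encode_displays(pop, d_lr))
            pred_ab = decoder.classify_batch(net, encode_displays(pop, d_ab))
            acc_lr[it, j] = np.mean(pred_lr == y_lr)
            acc_ab[it, j] = np.mean(pred_ab == y_ab)
    rng_p = stage_rng(seed, 0, "permutation")
    pvals = np.array(
        [
            paired_permutation_test(acc_ab[:, j] - acc_lr[:, j], rng_p, alternative="two-sided")
            for j in range(len(ells))
        ]
    )
    return RadialBiasResult(ells, acc_lr, acc_ab, pvals)


def largest_significant_ellipticity(result: RadialBiasResult, alpha: float = 0.05) -> float | None:
    """Largest tested ellipticity whose AB/LR ratio departs from 1 at alpha."""
    sig = result.p_values < alpha
    if not sig.any():
        return None
    return float(result.ellipticities[sig].max())


# ---------------------------------------------------------------------------
# Crowding-zone map


@dataclass
class ZoneMap:
    """Mean accuracy as a function of flanker position on a display grid."""

    grid: np.ndarray  # (n_rows, n_cols) mean proportion correct
    row_positions: np.ndarray  # flanker top-left rows
    col_positions: np.ndarray  # flanker top-left cols
    n_iterations: int
    display_size: int
    glyph_size: int
    target_position: tuple[int, int]

    def cell_center_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Flanker-center minus target-center offsets (dy, dx) per grid axis."""
        r0, c0 = self.target_position
        return (self.row_positions - r0).astype(float), (
            self.col_positions - c0
        ).astype(float)

    def far_level(self, min_center_dist: float = 55.0) -> float:
        """Mean accuracy over cells whose flanker is far from the target."""
        dy, dx = self.cell_center_offsets()
        dist = np.hypot(dy[:, None], dx[None, :])
        return float(self.grid[dist >= min_center_dist].mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.grid, index=self.row_positions, columns=self.col_positions
        )


def run_zone_map(
    cfg: ExperimentConfig,
    seed: int,
    n_iterations: int = 100,
    stride: int = 1,
    chunk: int = 256,
    ablation_fraction: float = 0.0,
) -> ZoneMap:
    """Map the crowding zone: accuracy with a flanker at every grid position.

    For each flanker top-left position on the (optionally strided) grid, six
    test images pair each target symbol with each different flanker symbol;
    the cell value is the proportion of those six classified correctly,
    averaged over iterations. Flankers may overlap the central target here
    (cells under the target are naturally impaired).

    The map is probed on the full model by default: with elliptical,
    eccentricity-scaled RFs the interference zone is already elongated and
    asymmetric. ``ablation_fraction`` > 0 instead silences that fraction of
    units post-training before probing, which deepens the zone but also
    depresses the far-field baseline.
    """
    positions = zone_probe_positions(cfg.display_size, stride, cfg.glyph_size)
    rows = np.unique([p[0] for p in positions])
    cols = np.unique([p[1] for p in positions])
    pairs = [
        (t, f) for t in cfg.symbols for f in cfg.symbols if t != f
    ]
    from .stimuli import compose_display

    # Pre-compose the full battery once; it is identical across iterations.
    displays = []
    labels = []
    for (r, c) in positions:
        for t, f in pairs:
            displays.append(
                compose_display(t, [(f, (r, c))], cfg.display_size, cfg.glyph_size)
            )
            labels.append(t)
    labels = np.asarray(labels)
    n_pairs = len(pairs)

    acc = np.zeros(len(positions))
    for it in range(n_iterations):
        pop, net, _, _ = _train_iteration(cfg, seed, it)
        if ablation_fraction > 0.0:
            net, _ = ablate(
                net,
                AblationSpec("drop_units_no_retrain", ablation_fraction),
                stage_rng(seed, it, "ablation"),
            )
        correct = np.empty(len(displays), dtype=bool)
        for lo in range(0, len(displays), chunk):
            sl = slice(lo, min(lo + chunk, len(displays)))
            pred = decoder.classify_batch(net, encode_displays(pop, displays[sl]))
            correct[sl] = pred == labels[sl]
        acc += correct.reshape(len(positions), n_pairs).mean(axis=1)
    acc /= n_iterations
    grid = acc.reshape(len(rows), len(cols))
    from .stimuli import center_position

    return ZoneMap(
        grid,
        rows,
        cols,
        n_iterations,
        cfg.display_size,
        cfg.glyph_size,
        center_position(cfg.display_size, cfg.glyph_size),
    )


# ---------------------------------------------------------------------------
# Feature / object hierarchy


@dataclass
class FeatureObjectResult:
    feature_full: PerformanceResult
    feature_ablated: PerformanceResult
    tumbling_full: PerformanceResult
    tumbling_ablated: PerformanceResult
    fraction_removed: float = 0.75

    def summary(self) -> dict:
        return {
            "fraction_removed": self.fraction_removed,
            "feature_full": self.feature_full.summary(),
            "feature_ablated": self.feature_ablated.summary(),
            "tumbling_full": self.tumbling_full.summary(),
            "tumbling_ablated": self.tumbling_ablated.summary(),
        }


def run_feature_object(
    seed: int,
    n_iterations: int = 100,
    fraction_removed: float = 0.75,
    feature_cfg: ExperimentConfig | None = None,
    tumbling_cfg: ExperimentConfig | None = None,
) -> FeatureObjectResult:
    """The two-stage demonstration: line (2AFC) and tumbling-T (4AFC) tasks.

    Both tasks read the same kind of feature-tuned (horizontal/vertical
    line) RF population; the tumbling-T task can only be solved from the
    relative arrangement of the two strokes. Each task is run full and with
    ``fraction_removed`` of the RF units removed before retraining.
    """
    from .config import default_config

    fc = feature_cfg or default_config("feature")
    tc = tumbling_cfg or default_config("tumbling_t")
    return FeatureObjectResult(
        feature_full=run_accuracy(fc, seed, n_iterations),
        feature_ablated=run_accuracy(fc, seed + 1, n_iterations, fraction_removed),
        tumbling_full=run_accuracy(tc, seed, n_iterations),
        tumbling_ablated=run_accuracy(tc, seed + 1, n_iterations, fraction_removed),
        fraction_removed=fraction_removed,
    )
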