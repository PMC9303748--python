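"""Calibrated parameter-recovery experiments.

Each experiment generates a synthetic condition whose ground truth is
dialed to a target value, runs the full image pipeline on the rendered
fields, and reports the recovered estimate alongside the generating truth.
These back the acceptance checks and the `validate`-style reporting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .indices import fusion_index
from .markers import FieldQuantification, quantify_field
from .stats import validate_counts
from .synthetic import (
    SceneParams,
    calibrate_fusion,
    calibrate_marker_probs,
    field_seed,
    generate_field,
)


@dataclass
class RecoveryResult:
    """Estimate of one condition recovered by the pipeline.

    ``estimate_se`` is the empirical SE over wells (noisy at 3 wells);
    ``sampling_se`` is the analytic SD of the estimator under the
    generating law (binomial marker draws / Bernoulli tube counts), which
    is the appropriate yardstick for an unbiasedness check.
    """

    estimate_mean: float
    estimate_se: float
    per_well: list[float]
    truth_mean: float
    target: float
    sampling_se: float | None = None

    @property
    def within_2se(self) -> bool:
        se = max(self.estimate_se, self.sampling_se or 0.0, 1e-12)
        return abs(self.estimate_mean - self.target) <= 2 * se


def _pooled_wells(
    params_per_field: list[SceneParams], wells: int, fields: int, mode: str
) -> tuple[list[list[FieldQuantification]], list]:
    quants: list[list[FieldQuantification]] = []
    truths = []
    i = 0
    for _ in range(wells):
        row = []
        for _ in range(fields):
            stack, truth = generate_field(params_per_field[i])
            row.append(quantify_field(stack, mode=mode))
            truths.append(truth)
            i += 1
        quants.append(row)
    return quants, truths


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def recover_marker_index(
    target_pct: float,
    *,
    denominator: str,
    seed: int,
    wells: int = 3,
    fields: int = 5,
    n_nuclei: int = 150,
    p_denominator: float = 0.55,
) -> RecoveryResult:
    """Recover a double/denominator marker index (proliferation- or
    differentiation-style) from rendered images with default noise."""
    overrides = calibrate_marker_probs(target_pct, p_denominator, denominator=denominator)
    mode = "pax7-myod" if denominator == "green" else "myog-myod"
    params = [
        SceneParams(n_nuclei=n_nuclei, seed=field_seed(seed, 0, 0, w, f), **overrides)
        for w in range(wells)
        for f in range(fields)
    ]
    quants, truths = _pooled_wells(params, wells, fields, mode)

    per_well = []
    for row in quants:
        num = sum(q.n_double for q in row)
        den = sum((q.n_green if denominator == "green" else q.n_red) for q in row)
        per_well.append(100.0 * num / den)
    t_num = sum(t.n_double for t in truths)
    t_den = sum((t.n_green if denominator == "green" else t.n_red) for t in truths)
    mean, se = _mean_se(per_well)
    p = target_pct / 100.0
    sampling_se = 100.0 * float(np.sqrt(p * (1 - p) / max(t_den, 1)))
    return RecoveryResult(mean, se, per_well, 100.0 * t_num / t_den, target_pct, sampling_se)


def recover_positive_fraction(
    target_pct: float,
    *,
    seed: int,
    wells: int = 3,
    fields: int = 5,
    n_nuclei: int = 150,
) -> RecoveryResult:
    """Recover a single-marker positive fraction (e.g. the Pax7-positive
    percentage of a day-1 population)."""
    p = target_pct / 100.0
    params = [
        SceneParams(
            n_nuclei=n_nuclei, p_green=p, p_red=0.0, p_double=0.0,
            seed=field_seed(seed, 0, 0, w, f),
        )
        for w in range(wells)
        for f in range(fields)
    ]
    quants, truths = _pooled_wells(params, wells, fields, "pax7-myod")
    per_well = [
        100.0 * sum(q.n_green for q in row) / sum(q.n_nuclei for q in row) for row in quants
    ]
    truth = 100.0 * sum(t.n_green for t in truths) / sum(t.n_nuclei for t in truths)
    mean, se = _mean_se(per_well)
    n_total = sum(t.n_nuclei for t in truths)
    sampling_se = 100.0 * float(np.sqrt(p * (1 - p) / max(n_total, 1)))
    return RecoveryResult(mean, se, per_well, truth, target_pct, sampling_se)


def _fractional_count(x: float, rng: np.random.Generator) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def recover_fusion_index(
    target_pct: float,
    *,
    seed: int,
    wells: int = 3,
    fields: int = 5,
    n_nuclei: int = 150,
    nuclei_per_myotube: int = 3,
    shape: tuple[int, int] = (512, 512),
) -> RecoveryResult:
    """Recover the fusion index from MyHC-mode quantification.

    The exact per-field tube count is randomized around the fractional
    calibration so the generating mean equals the target.
    """
    exact_tubes = target_pct / 100.0 * n_nuclei / nuclei_per_myotube
    params = []
    for w in range(wells):
        for f in range(fields):
            fseed = field_seed(seed, 0, 0, w, f)
            n_tubes = _fractional_count(exact_tubes, np.random.default_rng([fseed, 1]))
            overrides = calibrate_fusion(100.0, 1, nuclei_per_myotube)  # geometry only
            overrides["n_myotubes"] = n_tubes
            params.append(SceneParams(n_nuclei=n_nuclei, seed=fseed, shape=shape, **overrides))
    quants, truths = _pooled_wells(params, wells, fields, "myhc")
    per_well = [
        fusion_index(sum(q.n_nuclei_in_myotubes for q in row), sum(q.n_nuclei for q in row))
        for row in quants
    ]
    truth = 100.0 * sum(t.n_in_myotubes for t in truths) / sum(t.n_nuclei for t in truths)
    mean, se = _mean_se(per_well)
    frac = exact_tubes - np.floor(exact_tubes)
    sampling_se = (
        100.0
        * nuclei_per_myotube
        / n_nuclei
        * float(np.sqrt(frac * (1 - frac) / (wells * fields)))
    )
    return RecoveryResult(mean, se, per_well, truth, target_pct, sampling_se)


def recover_myotube_count(
    target_mean: float,
    *,
    seed: int,
    n_fields: int = 15,
    nuclei_per_myotube: int = 2,
    free_nuclei: int = 60,
    shape: tuple[int, int] = (640, 640),
) -> RecoveryResult:
    """Recover the mean myotube count per field.

    Per-field true counts are randomized around the (possibly fractional)
    target mean; reported is the mean automatically detected count.
    """
    detected, truths = [], []
    for f in range(n_fields):
        fseed = field_seed(seed, 0, 0, 0, f)
        n_tubes = _fractional_count(target_mean, np.random.default_rng([fseed, 1]))
        params = SceneParams(
            n_nuclei=n_tubes * nuclei_per_myotube + free_nuclei,
            n_myotubes=n_tubes,
            nuclei_per_myotube_min=nuclei_per_myotube,
            nuclei_per_myotube_max=nuclei_per_myotube,
            myotube_length_px=(60.0, 120.0),
            shape=shape,
            seed=fseed,
        )
        stack, truth = generate_field(params)
        q = quantify_field(stack, mode="myhc")
        detected.append(float(q.n_myotubes))
        truths.append(float(len(truth.myotubes)))
    mean, se = _mean_se(detected)
    return RecoveryResult(mean, se, detected, float(np.mean(truths)), target_mean)


def density_sweep_correlation(
    *,
    seed: int,
    n_fields: int = 16,
    min_nuclei: int = 50,
    max_nuclei: int = 400,
) -> tuple[float, list[int], list[int]]:
    """Pearson r between automated and true nucleus counts over a density
    sweep, mirroring a 16-picture manual-validation experiment."""
    rng = np.random.default_rng(seed)
    densities = rng.integers(min_nuclei, max_nuclei + 1, size=n_fields)
    auto, true = [], []
    for f, n in enumerate(densities):
        params = SceneParams(n_nuclei=int(n), seed=field_seed(seed, 0, 0, 0, f))
        stack, truth = generate_field(params)
        q = quantify_field(stack, mode="pax7-myod")
        auto.append(q.n_nuclei)
        true.append(truth.n_nuclei)
    stats = validate_counts(np.array(true, float), np.array(auto, float))
    return float(stats.pearson_r), auto, true
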