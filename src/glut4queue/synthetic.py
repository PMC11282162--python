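"""Synthetic datasets: sparse 7-replicate samples with optional relative noise.

Synthetic data are true samples of the simulated system at known parameters —
seven independent protocol-suite runs, normalised like the biological data.
Measurement error is emulated by relative noise,

    noisy = value * (1 + eps),

with ``eps ~ Normal(0, level^2)`` (Gaussian) or ``eps ~ Uniform(-level, level)``;
a draw that would make the value negative (non-physical) is re-sampled.  The
re-sampling study repeatedly regenerates the 7-replicate dataset and adds each
noise level to the *same* base dataset, separating sampling variability from
noise effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .distances import AggregationSpec, hierarchical_distance
from .params import NetworkParams, run_seed
from .protocols import SampleTable, default_schedules, normalize_suite, run_protocol_suite

__all__ = [
    "NoiseSpec",
    "SyntheticDataset",
    "generate_synthetic_data",
    "add_relative_noise",
    "resampling_study",
    "NOISE_LEVELS_PERCENT",
]

#: noise levels (percent) used in the robustness studies
NOISE_LEVELS_PERCENT = (0, 1, 2, 3, 4, 5, 7.5, 10, 12.5, 15, 17.5, 20)

_MAX_REDRAWS = 10**6


@dataclass(frozen=True)
class NoiseSpec:
    """Relative-noise model: distribution family and level (0.05 = 5%)."""

    distribution: str = "none"  # gaussian | uniform | none
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.distribution not in ("gaussian", "uniform", "none"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


@dataclass
class SyntheticDataset:
    """A normalised 7-replicate dataset with its generating configuration."""

    table: SampleTable
    params: NetworkParams
    seed: int
    noise: NoiseSpec = NoiseSpec()


def generate_synthetic_data(
    params: NetworkParams,
    n_reps: int = 7,
    seed: int = 0,
    schedules=None,
) -> SyntheticDataset:
    """Create a normalised synthetic dataset of ``n_reps`` true samples."""
    raw = run_protocol_suite(
        params,
        schedules=schedules if schedules is not None else default_schedules(),
        n_runs=n_reps,
        seed=seed,
        role="data",
    )
    return SyntheticDataset(table=normalize_suite(raw), params=params, seed=seed)


def _draw_eps(rng: np.random.Generator, spec: NoiseSpec, size: int) -> np.ndarray:
    if spec.distribution == "gaussian":
        return rng.normal(0.0, spec.level, size)
    return rng.uniform(-spec.level, spec.level, size)


def add_relative_noise(
    table: SampleTable, spec: NoiseSpec, rng: np.random.Generator
) -> SampleTable:
    """Apply relative noise; negative-result draws are rejected and re-drawn."""
    if spec.distribution == "none" or spec.level == 0.0:
        return replace(table, frame=table.frame.copy())
    values = table.frame["value"].to_numpy(dtype=float, copy=True)
    if np.any(values < 0):
        raise ValueError("relative noise requires non-negative values")
    eps = _draw_eps(rng, spec, len(values))
    noisy = values * (1.0 + eps)
    attempts = 0
    while True:
        bad = noisy < 0
        if not bad.any():
            break
        attempts += 1
        if attempts > _MAX_REDRAWS:
            raise RuntimeError("relative-noise re-sampling failed to converge")
        eps_bad = _draw_eps(rng, spec, int(bad.sum()))
        noisy[bad] = values[bad] * (1.0 + eps_bad)
    frame = table.frame.copy()
    frame["value"] = noisy
    meta = dict(table.meta, noise={"distribution": spec.distribution, "level": spec.level})
    return replace(table, frame=frame, meta=meta)


def resampling_study(
    params: NetworkParams,
    n_resamples: int = 1000,
    levels=(0.0, 0.05, 0.10),
    metrics=("ks", "wasserstein1"),
    seed: int = 0,
    noise_distribution: str = "gaussian",
    n_model_runs: int = 100,
    aggregation: AggregationSpec = AggregationSpec("mean"),
    n_reps: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-sampling robustness study at the true parameters.

    For each of ``n_resamples`` fresh ``n_reps``-replicate datasets, noise at
    every level is added to the *same* base dataset and the full hierarchical
    distance against one fixed ``n_model_runs``-replicate model table is
    computed for every metric.

    Returns
    -------
    points:
        Long table ``resample, level, metric, experiment, time, distance``
        of point distances, plus per-(resample, level, metric) combined rows
        stored with ``experiment='combined'`` and ``time=NaN``.
    summary:
        Means and standard deviations over re-samples, grouped by
        (level, metric, experiment, time).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    model_raw = run_protocol_suite(
        params, n_runs=n_model_runs, seed=run_seed(seed, 0, 0), role="model"
    )
    model = normalize_suite(model_raw)

    rows = []
    for i in range(n_resamples):
        base = generate_synthetic_data(params, n_reps=n_reps, seed=run_seed(seed, 1, i))
        noise_rng = np.random.default_rng(run_seed(seed, 2, i))
        for level in levels:
            spec = NoiseSpec("none" if level == 0 else noise_distribution, float(level))
            noisy = add_relative_noise(base.table, spec, noise_rng)
            for metric in metrics:
                hd = hierarchical_distance(noisy, model, metric=metric, aggregation=aggregation)
                for exp_id, dvec in hd.point_distances.items():
                    for t, d in zip(hd.times[exp_id], dvec):
                        rows.append((i, level, metric, exp_id, float(t), float(d)))
                rows.append((i, level, metric, "combined", np.nan, hd.combined))
    points = pd.DataFrame.from_records(
        rows, columns=["resample", "level", "metric", "experiment", "time", "distance"]
    )
    summary = (
        points.groupby(["level", "metric", "experiment", "time"], dropna=False)["distance"]
        .agg(["mean", "std"])
        .reset_index()
    )
    return points, summary
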