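"""Hierarchical ECDF distances between model outputs and data.

Three levels:

1. **point distances** — two-sample distances between the empirical CDFs of
   the data and model values at one measurement time.  Two classes are
   provided: discrete metrics evaluated only at the combined sample points
   (Kolmogorov–Smirnov, Kuiper, Cramér–von Mises, Anderson–Darling) and
   integrated metrics that also account for the spacing between points
   (Wasserstein-1, signed area, squared L2 area);
2. **experiment distances** — a weighted aggregation of the point-distance
   vector across one experiment's time course (mean, L2, max or min);
3. **combined distance** Δ — the weighted L2 combination of the per-experiment
   distances.

All step-function computations are exact: ECDFs change value only at sample
points, so suprema are taken over the distinct values of the combined sample
and areas are accumulated piecewise between consecutive distinct values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import SampleTable

__all__ = [
    "EmpiricalCDF",
    "build_ecdf",
    "ks_distance",
    "wasserstein1_distance",
    "extended_point_distance",
    "point_distance",
    "AggregationSpec",
    "experiment_distance",
    "combined_distance",
    "HierarchicalDistance",
    "hierarchical_distance",
    "POINT_METRICS",
]

#: metric name -> class ("discrete" evaluates at sample points only,
#: "integrated" accumulates area between them)
POINT_METRICS = {
    "ks": "discrete",
    "kuiper": "discrete",
    "cramer_von_mises": "discrete",
    "anderson_darling": "discrete",
    "wasserstein1": "integrated",
    "signed_area": "integrated",
    "squared_area": "integrated",
}


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF of one sample.

    ``P(x) = (1/N) * #{x_n <= x}`` — zero below the smallest sample point,
    one at and above the largest, with a jump of multiplicity/N at each
    distinct value.
    """

    points: np.ndarray  # sorted

    @property
    def n(self) -> int:
        return len(self.points)

    def __call__(self, x) -> np.ndarray | float:
        r = np.searchsorted(self.points, x, side="right") / self.n
        return float(r) if np.isscalar(x) else r


def build_ecdf(values) -> EmpiricalCDF:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    return EmpiricalCDF(points=np.sort(arr))


def _grid(F: EmpiricalCDF, G: EmpiricalCDF):
    """Distinct combined sample points with F and G evaluated there."""
    z = np.union1d(F.points, G.points)
    return z, F(z), G(z)


def ks_distance(F: EmpiricalCDF, G: EmpiricalCDF) -> float:
    """Kolmogorov–Smirnov distance: sup over x of |F(x) - G(x)|, in [0, 1]."""
    _, f, g = _grid(F, G)
    return float(np.max(np.abs(f - g)))


def wasserstein1_distance(F: EmpiricalCDF, G: EmpiricalCDF) -> float:
    """Wasserstein-1 (Earthmover's) distance: the area between the ECDFs."""
    z, f, g = _grid(F, G)
    if len(z) == 1:
        return 0.0
    return float(np.sum(np.abs(f[:-1] - g[:-1]) * np.diff(z)))


def _kuiper(F, G) -> float:
    _, f, g = _grid(F, G)
    d = f - g
    return float(max(d.max(), 0.0) + max((-d).max(), 0.0))


def _cramer_von_mises(F, G) -> float:
    # Anderson's two-sample form: T = (nm/(n+m)^2) * sum over the combined
    # multiset of (F - G)^2
    z = np.sort(np.concatenate([F.points, G.points]))
    d = F(z) - G(z)
    n, m = F.n, G.n
    return float(n * m / (n + m) ** 2 * np.sum(d * d))


def _anderson_darling(F, G) -> float:
    # Pettitt's two-sample form: A2 = (nm/N) * sum_{i<N} (F-G)^2(z_i) /
    # (H(z_i)(1 - H(z_i))), H the combined ECDF over the ordered pooled sample
    z = np.sort(np.concatenate([F.points, G.points]))
    n, m = F.n, G.n
    N = n + m
    zi = z[:-1]
    d = F(zi) - G(zi)
    H = np.searchsorted(z, zi, side="right") / N
    w = H * (1.0 - H)
    mask = w > 0
    return float(n * m / N * np.sum(d[mask] ** 2 / w[mask]))


def _signed_area(F, G) -> float:
    z, f, g = _grid(F, G)
    if len(z) == 1:
        return 0.0
    return float(np.sum((f[:-1] - g[:-1]) * np.diff(z)))


def _squared_area(F, G) -> float:
    z, f, g = _grid(F, G)
    if len(z) == 1:
        return 0.0
    return float(np.sum((f[:-1] - g[:-1]) ** 2 * np.diff(z)))


_EXTENDED = {
    "kuiper": _kuiper,
    "cramer_von_mises": _cramer_von_mises,
    "anderson_darling": _anderson_darling,
    "signed_area": _signed_area,
    "squared_area": _squared_area,
}


def extended_point_distance(F: EmpiricalCDF, G: EmpiricalCDF, metric: str) -> float:
    """Point distances beyond KS/W1; ``signed_area`` is antisymmetric in (F, G)."""
    try:
        fn = _EXTENDED[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose one of {sorted(_EXTENDED)}"
        ) from None
    return fn(F, G)


def point_distance(F: EmpiricalCDF, G: EmpiricalCDF, metric: str) -> float:
    """Dispatch any supported point metric by name."""
    if metric == "ks":
        return ks_distance(F, G)
    if metric == "wasserstein1":
        return wasserstein1_distance(F, G)
    return extended_point_distance(F, G, metric)


@dataclass(frozen=True)
class AggregationSpec:
    """How a point-distance vector is folded into one experiment distance."""

    method: str = "mean"  # mean | l2 | max | min
    weights: np.ndarray | None = None  # per-time, defaults to 1

    def __post_init__(self) -> None:
        if self.method not in ("mean", "l2", "max", "min"):
            raise ValueError(f"unknown aggregation method {self.method!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("aggregation weights must be non-negative")
            object.__setattr__(self, "weights", w)


def experiment_distance(distances, spec: AggregationSpec = AggregationSpec()) -> float:
    """Aggregate one experiment's point distances across its time course."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("point-distance vector is empty")
    if spec.weights is None:
        wd = d
    else:
        if len(spec.weights) != len(d):
            raise ValueError("weights length does not match the time course")
        wd = spec.weights * d
    if spec.method == "mean":
        return float(np.mean(wd))
    if spec.method == "l2":
        return float(np.sqrt(np.sum(wd * wd)))
    if spec.method == "max":
        return float(np.max(wd))
    return float(np.min(wd))


def combined_distance(experiment_distances, experiment_weights=None) -> float:
    """Δ = (Σ_i W_i D_i²)^{1/2} over the E experiments."""
    D = np.asarray(experiment_distances, dtype=float)
    if experiment_weights is None:
        W = np.ones_like(D)
    else:
        W = np.asarray(experiment_weights, dtype=float)
        if W.shape != D.shape:
            raise ValueError("experiment weights must match the number of experiments")
        if np.any(W < 0):
            raise ValueError("experiment weights must be non-negative")
    return float(np.sqrt(np.sum(W * D * D)))


@dataclass
class HierarchicalDistance:
    """Full three-level distance result with all intermediates retained."""

    metric: str
    aggregation: AggregationSpec
    point_distances: dict[str, np.ndarray]  # experiment -> per-time vector
    times: dict[str, np.ndarray]
    experiment_distances: dict[str, float]
    experiment_weights: dict[str, float]
    combined: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "aggregation": {
                "method": self.aggregation.method,
                "weights": None
                if self.aggregation.weights is None
                else list(map(float, self.aggregation.weights)),
            },
            "times": {k: list(map(float, v)) for k, v in self.times.items()},
            "point_distances": {
                k: list(map(float, v)) for k, v in self.point_distances.items()
            },
            "experiment_distances": {
                k: float(v) for k, v in self.experiment_distances.items()
            },
            "experiment_weights": {k: float(v) for k, v in self.experiment_weights.items()},
            "combined": float(self.combined),
            "config": self.config,
        }


def hierarchical_distance(
    data: SampleTable,
    model: SampleTable,
    metric: str = "wasserstein1",
    aggregation: AggregationSpec = AggregationSpec("mean"),
    experiment_weights: dict[str, float] | None = None,
) -> HierarchicalDistance:
    """Compare a data table to a model table across all shared experiments.

    The same point metric and aggregation are applied to every experiment;
    the per-experiment distances are then L2-combined into Δ.  The two tables
    must share experiment ids and measurement times exactly — no silent
    interpolation.
    """
    if metric not in POINT_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose one of {sorted(POINT_METRICS)}")
    experiments = data.experiments
    if experiments != model.experiments:
        raise ValueError(
            f"experiment sets differ: data {experiments} vs model {model.experiments}"
        )

    point: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    D: dict[str, float] = {}
    W = {e: 1.0 for e in experiments}
    if experiment_weights:
        W.update(experiment_weights)

    for exp_id in experiments:
        t_data = data.times(exp_id)
        t_model = model.times(exp_id)
        if not np.array_equal(t_data, t_model):
            raise ValueError(
                f"measurement-time grids differ for {exp_id}: "
                f"{t_data.tolist()} vs {t_model.tolist()}"
            )
        d = np.array(
            [
                point_distance(
                    build_ecdf(data.values_at(exp_id, t)),
                    build_ecdf(model.values_at(exp_id, t)),
                    metric,
                )
                for t in t_data
            ]
        )
        point[exp_id] = d
        times[exp_id] = t_data
        D[exp_id] = experiment_distance(d, aggregation)

    delta = combined_distance([D[e] for e in experiments], [W[e] for e in experiments])
    return HierarchicalDistance(
        metric=metric,
        aggregation=aggregation,
        point_distances=point,
        times=times,
        experiment_distances=D,
        experiment_weights=W,
        combined=delta,
        config={"data_role": data.role, "model_role": model.role},
    )
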