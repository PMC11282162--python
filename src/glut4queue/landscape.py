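"""Distance landscapes over parameter space.

A ``ParameterGrid`` varies a subset of the network parameters (by default the
service rates and the basal activation probability) over evenly spaced points;
``evaluate_landscape`` simulates a fresh model table at every grid point and
computes the full hierarchical distance to a synthetic dataset.  Parameter
distance is measured in grid units: adjacent points along any single dimension
are one unit apart.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import AggregationSpec, hierarchical_distance
from .params import NetworkParams, run_seed
from .protocols import normalize_suite, run_protocol_suite
from .synthetic import SyntheticDataset

__all__ = [
    "GridAxis",
    "ParameterGrid",
    "build_grid",
    "parameter_distance",
    "evaluate_landscape",
    "single_parameter_slices",
    "locate_minimum",
]

DEFAULT_N_POINTS = 21


@dataclass(frozen=True)
class GridAxis:
    name: str
    minimum: float
    maximum: float
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"axis {self.name}: n_points must be >= 2")
        if not self.minimum < self.maximum:
            raise ValueError(f"axis {self.name}: need minimum < maximum")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.n_points)

    @property
    def step(self) -> float:
        return (self.maximum - self.minimum) / (self.n_points - 1)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over varied parameters, the rest fixed."""

    axes: tuple[GridAxis, ...]
    fixed: NetworkParams

    @property
    def varied_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def n_points(self) -> int:
        return int(np.prod([a.n_points for a in self.axes]))

    def points(self):
        """Iterate (index, {name: value}, NetworkParams) over the grid."""
        for k, combo in enumerate(itertools.product(*(a.points for a in self.axes))):
            values = dict(zip(self.varied_names, combo))
            yield k, values, self.fixed.replace(**values)


def build_grid(axes, fixed: NetworkParams) -> ParameterGrid:
    """Validate and assemble a grid; every grid point must be a valid parameter set."""
    axes = tuple(axes)
    if not axes:
        raise ValueError("a grid needs at least one varied parameter")
    names = [a.name for a in axes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate varied parameter names")
    unknown = set(names) - set(fixed.to_dict())
    if unknown:
        raise ValueError(f"unknown parameter names {sorted(unknown)}")
    grid = ParameterGrid(axes=axes, fixed=fixed)
    # reject eagerly, naming the offending corner rather than failing mid-sweep
    for corner in itertools.product(*((a.minimum, a.maximum) for a in axes)):
        values = dict(zip(names, corner))
        try:
            fixed.replace(**values)
        except ValueError as err:
            raise ValueError(f"invalid grid point {values}: {err}") from None
    return grid


def parameter_distance(theta: dict, theta_true: dict, grid: ParameterGrid) -> float:
    """Scaled Euclidean distance in grid units over the varied parameters."""
    total = 0.0
    for axis in grid.axes:
        if axis.step == 0:
            raise ValueError(f"axis {axis.name} has zero step")
        total += ((theta[axis.name] - theta_true[axis.name]) / axis.step) ** 2
    return float(np.sqrt(total))


def evaluate_landscape(
    grid: ParameterGrid,
    data: SyntheticDataset,
    metric: str = "wasserstein1",
    aggregation: AggregationSpec = AggregationSpec("mean"),
    n_model_runs: int = 100,
    seed: int = 0,
    true_values: dict | None = None,
) -> pd.DataFrame:
    """Simulate a fresh model table at every grid point and score it.

    Returns one row per grid point with the varied parameter values, the
    scaled parameter distance to the truth, the per-experiment distances and
    the combined distance.  Simulator failures at a point are recorded in the
    ``error`` column rather than aborting the sweep.
    """
    if not data.table.normalised:
        raise ValueError("synthetic dataset must be normalised")
    truth = {a.name: getattr(data.params, a.name) for a in grid.axes}
    if true_values:
        truth.update(true_values)

    rows = []
    for k, values, params in grid.points():
        row = dict(values)
        row["param_distance"] = parameter_distance(values, truth, grid)
        try:
            raw = run_protocol_suite(params, n_runs=n_model_runs, seed=run_seed(seed, k))
            model = normalize_suite(raw)
            hd = hierarchical_distance(
                data.table, model, metric=metric, aggregation=aggregation
            )
            for exp_id, D in hd.experiment_distances.items():
                row[f"D_{exp_id}"] = D
            row["combined"] = hd.combined
            row["error"] = ""
        except Exception as err:  # degenerate run at this point, keep sweeping
            row["combined"] = np.nan
            row["error"] = str(err)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["varied"] = list(grid.varied_names)
    table.attrs["truth"] = truth
    table.attrs["metric"] = metric
    return table


def single_parameter_slices(
    landscape: pd.DataFrame, true_point: dict, grid: ParameterGrid
) -> dict[str, pd.DataFrame]:
    """Per-parameter slices through the truth.

    For each varied parameter, the rows where every *other* varied parameter
    equals its true value, ordered by the sliced parameter.
    """
    for axis in grid.axes:
        v = true_point[axis.name]
        if not np.any(np.isclose(axis.points, v)):
            raise ValueError(f"true value {v} for {axis.name} is not on the grid")
    slices = {}
    for axis in grid.axes:
        mask = np.ones(len(landscape), dtype=bool)
        for other in grid.axes:
            if other.name != axis.name:
                mask &= np.isclose(landscape[other.name], true_point[other.name])
        slices[axis.name] = landscape[mask].sort_values(axis.name).reset_index(drop=True)
    return slices


def locate_minimum(landscape: pd.DataFrame) -> pd.DataFrame:
    """All rows attaining the minimal combined distance (ties reported, not broken)."""
    if len(landscape) == 0:
        raise ValueError("landscape is empty")
    valid = landscape[np.isfinite(landscape["combined"])]
    if len(valid) == 0:
        raise ValueError("no grid point produced a finite combined distance")
    best = valid["combined"].min()
    return valid[valid["combined"] == best]
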