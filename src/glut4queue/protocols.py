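"""The three in-silico experimental protocols and their normalisation.

Each simulation run executes, in sequence and within the same model instance:

1. 500 time units of basal-phase warm-up (all vesicles start at the endosome);
2. the **basal uptake** experiment — cumulative unique membrane visitors,
   sampled at 12 times over 300 units, visited flags seeded with the vesicles
   currently on the membrane;
3. the **transition** experiment — the fusion sites are switched to their
   insulin state at t = 0 and the plasma-membrane level is sampled at 12 times
   over 60 units (the t = 0 sample is the basal steady-state level, taken at
   the instant of the switch);
4. 500 units from the switch to reach the insulin steady state, then the
   **insulin uptake** experiment, sampled like basal uptake.

Uptake values are normalised to the mean of the insulin-uptake samples at its
final time; transition values to the mean of its own final-time samples (by
which the system is taken to have re-equilibrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import NetworkParams, run_seed
from .simulate import QueueNetworkSimulator

__all__ = [
    "EXPERIMENTS",
    "ExperimentSchedule",
    "SampleTable",
    "default_schedules",
    "run_protocol_suite",
    "normalize_suite",
]

EXPERIMENTS = ("transition", "basal_uptake", "insulin_uptake")

#: duration of each equilibration segment, in simulation time units
WARMUP_DURATION = 500.0


@dataclass(frozen=True)
class ExperimentSchedule:
    """Measurement times of one experiment."""

    experiment_id: str
    measurement_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment_id!r}")
        t = self.measurement_times
        if len(t) == 0 or t[0] != 0:
            raise ValueError("measurement times must start at 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("measurement times must be strictly increasing")


def default_schedules() -> dict[str, ExperimentSchedule]:
    """The measurement schedules of the three experiments (time units)."""
    transition = (0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60)
    uptake = (0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300)
    return {
        "transition": ExperimentSchedule("transition", transition),
        "basal_uptake": ExperimentSchedule("basal_uptake", uptake),
        "insulin_uptake": ExperimentSchedule("insulin_uptake", uptake),
    }


@dataclass
class SampleTable:
    """Long-format measurement table: experiment x time x replicate x value.

    Holds either experimental-role data (sparse, typically 7 replicates) or
    model outputs (typically 100 replicates); the two are distinguished only
    by ``role`` and their replicate counts.
    """

    frame: pd.DataFrame
    role: str = "model"  # "data" | "model"
    normalised: bool = False
    divisors: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    COLUMNS = ("experiment", "time", "replicate", "value")

    def __post_init__(self) -> None:
        if self.role not in ("data", "model"):
            raise ValueError(f"role must be 'data' or 'model', got {self.role!r}")
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample table missing columns {sorted(missing)}")

    @property
    def experiments(self) -> list[str]:
        return sorted(self.frame["experiment"].unique())

    def times(self, experiment: str) -> np.ndarray:
        sub = self.frame[self.frame["experiment"] == experiment]
        return np.sort(sub["time"].unique())

    def values_at(self, experiment: str, time: float) -> np.ndarray:
        sub = self.frame[
            (self.frame["experiment"] == experiment) & (self.frame["time"] == time)
        ]
        return sub["value"].to_numpy()

    def select(self, experiment: str) -> "SampleTable":
        return replace(self, frame=self.frame[self.frame["experiment"] == experiment].copy())

    def replicate_count(self, experiment: str) -> int:
        sub = self.frame[self.frame["experiment"] == experiment]
        counts = sub.groupby("time", sort=True)["replicate"].count()
        return int(counts.iloc[0]) if len(counts) else 0


def _simulate_one_run(
    params: NetworkParams,
    schedules: dict[str, ExperimentSchedule],
    rng: np.random.Generator,
    check_invariants: bool = False,
) -> dict[str, list[float]]:
    # with checking enabled, conservation/capacity invariants are verified
    # after every processed event, not just at the end
    sim = QueueNetworkSimulator(params, rng, check_every_event=check_invariants)
    out: dict[str, list[float]] = {}

    sim.advance(WARMUP_DURATION)
    t0 = WARMUP_DURATION

    sim.reset_visited()
    out["basal_uptake"] = []
    for t in schedules["basal_uptake"].measurement_times:
        sim.advance(t0 + t)
        out["basal_uptake"].append(float(sim.unique_visitors))
    t0 += schedules["basal_uptake"].measurement_times[-1]

    # transition: the t=0 sample is the basal steady-state membrane level,
    # taken before any insulin-phase event can fire
    sim.advance(t0)
    out["transition"] = [float(sim.pm_level)]
    sim.set_phase("insulin")
    for t in schedules["transition"].measurement_times[1:]:
        sim.advance(t0 + t)
        out["transition"].append(float(sim.pm_level))

    sim.advance(t0 + WARMUP_DURATION)
    t0 += WARMUP_DURATION
    sim.reset_visited()
    out["insulin_uptake"] = []
    for t in schedules["insulin_uptake"].measurement_times:
        sim.advance(t0 + t)
        out["insulin_uptake"].append(float(sim.unique_visitors))

    if check_invariants:
        sim.check_state()
    return out


def run_protocol_suite(
    params: NetworkParams,
    schedules: dict[str, ExperimentSchedule] | None = None,
    n_runs: int = 1,
    seed: int | np.random.SeedSequence = 0,
    role: str = "model",
    check_invariants: bool = False,
) -> SampleTable:
    """Simulate ``n_runs`` independent protocol suites.

    Returns the raw (unnormalised) table with one replicate per run for each
    of the three experiments.  Each run draws its own fusion-site activity and
    uses the sub-stream keyed by ``(seed, run)``, so runs are independent and
    individually reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if schedules is None:
        schedules = default_schedules()
    base = seed if isinstance(seed, np.random.SeedSequence) else None

    records = []
    for r in range(n_runs):
        ss = base.spawn(1)[0] if base is not None else run_seed(seed, r)
        rng = np.random.default_rng(ss)
        run = _simulate_one_run(params, schedules, rng, check_invariants=check_invariants)
        for exp_id, values in run.items():
            for t, v in zip(schedules[exp_id].measurement_times, values):
                records.append((exp_id, float(t), r, v))
    frame = pd.DataFrame.from_records(records, columns=SampleTable.COLUMNS)
    meta = {"params": params.to_dict(), "seed": seed if base is None else "spawned", "n_runs": n_runs}
    return SampleTable(frame=frame, role=role, normalised=False, meta=meta)


def normalize_suite(table: SampleTable) -> SampleTable:
    """Normalise a raw protocol-suite table.

    Both uptake experiments are divided by the mean of the insulin-uptake
    samples at its final time point; the transition experiment by the mean of
    its own final-time samples (its steady-state level).  Means pool all
    replicates of the table being normalised.
    """
    if table.normalised:
        raise ValueError("table is already normalised")
    frame = table.frame.copy()

    ins_times = table.times("insulin_uptake")
    trans_times = table.times("transition")
    if len(ins_times) == 0 or len(trans_times) == 0:
        raise ValueError("table must contain insulin_uptake and transition experiments")
    uptake_div = float(np.mean(table.values_at("insulin_uptake", ins_times[-1])))
    trans_div = float(np.mean(table.values_at("transition", trans_times[-1])))
    if uptake_div <= 0 or trans_div <= 0:
        raise ValueError(
            "degenerate run: non-positive normaliser "
            f"(insulin uptake {uptake_div}, transition {trans_div})"
        )

    uptake_mask = frame["experiment"].isin(["basal_uptake", "insulin_uptake"])
    frame.loc[uptake_mask, "value"] /= uptake_div
    frame.loc[frame["experiment"] == "transition", "value"] /= trans_div

    divisors = {"uptake": uptake_div, "transition": trans_div}
    return replace(table, frame=frame, normalised=True, divisors=divisors)
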