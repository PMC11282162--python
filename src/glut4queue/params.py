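"""Model parameters and random-number plumbing for the vesicle-recycling network.

The closed queuing network routes ``n_vesicles`` GLUT4 vesicles cyclically
through four stations: the endosome store (infinite server, rate ``rate_store``),
``n_microtubules`` parallel FIFO microtubule queues of capacity
``microtubule_capacity`` (transit rate ``rate_microtubule``), one single-server
fusion site per microtubule (rate ``rate_fusion``), and the plasma membrane
(infinite server, rate ``rate_membrane``).  Fusion sites are individually
active or inactive; activity is drawn once per model instance, with basal
(no-insulin) activation probability ``p_basal`` and insulin activation
probability ``p_insulin >= p_basal``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "NetworkParams",
    "FusionActivity",
    "DEFAULT_PARAMS",
    "draw_fusion_activity",
    "run_seed",
]

RATE_FIELDS = ("rate_store", "rate_microtubule", "rate_fusion", "rate_membrane")
COUNT_FIELDS = ("n_vesicles", "n_microtubules", "microtubule_capacity")
PROB_FIELDS = ("p_basal", "p_insulin")


@dataclass(frozen=True)
class NetworkParams:
    """The nine parameters of the closed queuing network.

    Rates are events per simulation time unit; counts are vesicle /
    station numbers; probabilities are per-site activation probabilities.
    """

    n_vesicles: int
    n_microtubules: int
    microtubule_capacity: int
    rate_store: float
    rate_microtubule: float
    rate_fusion: float
    rate_membrane: float
    p_basal: float
    p_insulin: float

    def __post_init__(self) -> None:
        for name in COUNT_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        for name in RATE_FIELDS:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (0.0 <= self.p_basal <= self.p_insulin <= 1.0):
            raise ValueError(
                "activation probabilities must satisfy "
                f"0 <= p_basal <= p_insulin <= 1, got p_basal={self.p_basal}, "
                f"p_insulin={self.p_insulin}"
            )

    def replace(self, **changes) -> "NetworkParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


#: Reference parameter set used as the ground truth for synthetic data.
#: Chosen so the simulated curves qualitatively match the immunofluorescence
#: data: a basal surface level well below the insulin level, a transition
#: essentially equilibrated by t = 60, and uptake saturating within t = 300.
DEFAULT_PARAMS = NetworkParams(
    n_vesicles=60,
    n_microtubules=20,
    microtubule_capacity=3,
    rate_store=0.2,
    rate_microtubule=0.5,
    rate_fusion=0.05,
    rate_membrane=0.05,
    p_basal=0.25,
    p_insulin=0.85,
)


@dataclass(frozen=True)
class FusionActivity:
    """Per-site activity in the basal and insulin states.

    One persistent uniform is drawn per fusion site; a site is active in a
    phase iff its uniform is below that phase's activation probability.  With
    ``p_insulin >= p_basal`` the insulin switch can therefore only activate
    sites, never deactivate them — the model hypothesis that insulin recruits
    additional fusion sites.
    """

    site_uniforms: np.ndarray
    basal_active: np.ndarray
    insulin_active: np.ndarray

    def active(self, phase: str) -> np.ndarray:
        if phase == "basal":
            return self.basal_active
        if phase == "insulin":
            return self.insulin_active
        raise ValueError(f"unknown phase {phase!r}; expected 'basal' or 'insulin'")


def draw_fusion_activity(params: NetworkParams, rng: np.random.Generator) -> FusionActivity:
    """Draw the per-site activity state for one model instance."""
    u = rng.random(params.n_microtubules)
    return FusionActivity(
        site_uniforms=u,
        basal_active=u < params.p_basal,
        insulin_active=u < params.p_insulin,
    )


def run_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Derive the sub-stream seed for one run (or nested study index).

    Children are keyed by ``(master_seed, *indices)`` so that adding runs,
    grid points or re-samples never perturbs the random numbers of earlier
    ones.  ``master_seed`` may itself be a sequence of integers (a nested
    study key).
    """
    if isinstance(master_seed, (list, tuple)):
        head = [int(x) for x in master_seed]
    else:
        head = [int(master_seed)]
    return np.random.SeedSequence(head + [int(i) for i in indices])
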