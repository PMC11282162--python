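"""Discrete-event simulation of the closed vesicle-recycling queuing network.

Event semantics
---------------
* Endosome completion (Exp(mu_S) per vesicle, infinite server): the vesicle
  picks one of the M microtubules uniformly.  If that queue already holds L
  vesicles it is blocked and re-enters endosome service with a freshly drawn
  Exp(mu_S) service time; otherwise it joins the tail of the queue and its
  unimpeded transit clock Exp(mu_M) starts.
* Microtubule departure: the head vesicle may move to its associated fusion
  site once (a) its own transit clock has expired or, if it reached the head
  later, the advancement increment Exp(L*mu_M) drawn when its predecessor
  departed has expired — whichever is later — and (b) the fusion site is
  active in the current phase and idle.  Transfer on a freed, active site is
  immediate.  FIFO order is never violated.
* Fusion completion (Exp(mu_F), single server per site): the vesicle is
  deposited on the plasma membrane and its visited flag is set.
* Membrane completion (Exp(mu_P), infinite server): the vesicle returns to
  endosome service.

Simultaneous events are ordered by (time, station priority, insertion order)
with priority membrane > fusion > microtubule > endosome; exponential clocks
make ties measure-zero so this only pins down determinism.
"""

from __future__ import annotations

import hashlib
from collections import deque
from heapq import heappop, heappush

import numpy as np

from .params import FusionActivity, NetworkParams, draw_fusion_activity

__all__ = ["QueueNetworkSimulator", "measure_pm_level", "measure_unique_visitors"]

# station codes for vesicle locations
ENDOSOME, MICROTUBULE, FUSION, MEMBRANE = 0, 1, 2, 3

# event types; the numeric value doubles as the tie-break priority
_EV_MEMBRANE_DONE = 0
_EV_FUSION_DONE = 1
_EV_HEAD_READY = 2
_EV_ENDO_DONE = 3

_EVENT_NAMES = {
    _EV_MEMBRANE_DONE: "membrane_done",
    _EV_FUSION_DONE: "fusion_done",
    _EV_HEAD_READY: "head_ready",
    _EV_ENDO_DONE: "endosome_done",
}


class _ExpBuffer:
    """Block-buffered standard-exponential and uniform draws.

    Scalar numpy draws dominate the event-loop cost; drawing in blocks of 4096
    keeps the loop tight while remaining a pure function of the seed.
    """

    __slots__ = ("_rng", "_block", "_exp", "_ei", "_uni", "_ui")

    def __init__(self, rng: np.random.Generator, block: int = 4096):
        self._rng = rng
        self._block = block
        self._exp = rng.standard_exponential(block)
        self._ei = 0
        self._uni = rng.random(block)
        self._ui = 0

    def exponential(self) -> float:
        i = self._ei
        if i == self._block:
            self._exp = self._rng.standard_exponential(self._block)
            i = 0
        self._ei = i + 1
        return self._exp[i]

    def uniform(self) -> float:
        i = self._ui
        if i == self._block:
            self._uni = self._rng.random(self._block)
            i = 0
        self._ui = i + 1
        return self._uni[i]


class QueueNetworkSimulator:
    """One instance of the closed queuing network.

    Parameters
    ----------
    params:
        Network configuration.
    rng:
        numpy Generator supplying every random draw of this instance.
    activity:
        Fusion-site activity; drawn from ``rng`` if not given.
    phase:
        Initial insulin phase, ``"basal"`` or ``"insulin"``.
    log_events:
        Record an event log (time, event, vesicle, station, queue index);
        useful for debugging and determinism checks.
    """

    def __init__(
        self,
        params: NetworkParams,
        rng: np.random.Generator,
        activity: FusionActivity | None = None,
        phase: str = "basal",
        log_events: bool = False,
        check_every_event: bool = False,
    ):
        self.params = params
        self.rng = rng
        self.activity = activity if activity is not None else draw_fusion_activity(params, rng)
        self._active = self.activity.active(phase)
        self.phase = phase
        self.now = 0.0

        n, m = params.n_vesicles, params.n_microtubules
        self._draws = _ExpBuffer(rng)
        self._mean_store = 1.0 / params.rate_store
        self._mean_transit = 1.0 / params.rate_microtubule
        self._mean_fusion = 1.0 / params.rate_fusion
        self._mean_membrane = 1.0 / params.rate_membrane
        self._mean_increment = 1.0 / (params.microtubule_capacity * params.rate_microtubule)

        self.location = np.full(n, ENDOSOME, dtype=np.int8)
        self.visited = np.zeros(n, dtype=bool)
        self._transit_end = np.zeros(n)
        self._ready = np.full(n, np.inf)
        self._mt_of = np.full(n, -1, dtype=np.int64)
        self.queues: list[deque[int]] = [deque() for _ in range(m)]
        self.site_occupant = np.full(m, -1, dtype=np.int64)
        self._membrane_count = 0

        self._heap: list[tuple[float, int, int, int, int]] = []
        self._seq = 0
        self.event_log: list[tuple] | None = [] if log_events else None
        self._check_every_event = check_every_event

        for v in range(n):
            self._push(self._draws.exponential() * self._mean_store, _EV_ENDO_DONE, v, -1)

    # ------------------------------------------------------------------ events

    def _push(self, time: float, etype: int, vid: int, mt: int) -> None:
        self._seq += 1
        heappush(self._heap, (time, etype, self._seq, vid, mt))

    def _log(self, time: float, etype: int, vid: int, station: int, qidx: int) -> None:
        if self.event_log is not None:
            self.event_log.append((time, _EVENT_NAMES[etype], vid, station, qidx))

    def advance(self, t_end: float) -> None:
        """Process all events up to and including ``t_end``; leave the clock there."""
        if t_end < self.now:
            raise ValueError(f"cannot advance backwards: now={self.now}, t_end={t_end}")
        heap = self._heap
        while heap and heap[0][0] <= t_end:
            time, etype, _seq, vid, mt = heappop(heap)
            if etype == _EV_ENDO_DONE:
                self._on_endosome_done(time, vid)
            elif etype == _EV_HEAD_READY:
                self._on_head_ready(time, vid, mt)
            elif etype == _EV_FUSION_DONE:
                self._on_fusion_done(time, vid, mt)
            else:
                self._on_membrane_done(time, vid)
            if self._check_every_event:
                self.check_state()
        self.now = t_end

    def _on_endosome_done(self, t: float, v: int) -> None:
        m = int(self._draws.uniform() * self.params.n_microtubules)
        q = self.queues[m]
        if len(q) >= self.params.microtubule_capacity:
            # entry blocking: back to endosome service with a fresh draw
            self._log(t, _EV_ENDO_DONE, v, ENDOSOME, m)
            self._push(t + self._draws.exponential() * self._mean_store, _EV_ENDO_DONE, v, -1)
            return
        self._log(t, _EV_ENDO_DONE, v, MICROTUBULE, m)
        q.append(v)
        self.location[v] = MICROTUBULE
        self._mt_of[v] = m
        self._transit_end[v] = t + self._draws.exponential() * self._mean_transit
        if len(q) == 1:
            self._ready[v] = self._transit_end[v]
            self._push(self._ready[v], _EV_HEAD_READY, v, m)
        else:
            self._ready[v] = np.inf

    def _on_head_ready(self, t: float, v: int, m: int) -> None:
        q = self.queues[m]
        if not q or q[0] != v or self.location[v] != MICROTUBULE:
            return  # superseded: the vesicle already transferred at this instant
        self._log(t, _EV_HEAD_READY, v, MICROTUBULE, m)
        if self._active[m] and self.site_occupant[m] < 0:
            self._transfer(t, m)

    def _transfer(self, t: float, m: int) -> None:
        """Move the ready head of microtubule m into its idle, active fusion site."""
        q = self.queues[m]
        v = q.popleft()
        self.location[v] = FUSION
        self._mt_of[v] = m
        self._ready[v] = np.inf
        self.site_occupant[m] = v
        self._push(t + self._draws.exponential() * self._mean_fusion, _EV_FUSION_DONE, v, m)
        if q:
            w = q[0]
            increment = self._draws.exponential() * self._mean_increment
            self._ready[w] = max(self._transit_end[w], t + increment)
            self._push(self._ready[w], _EV_HEAD_READY, w, m)

    def _on_fusion_done(self, t: float, v: int, m: int) -> None:
        self._log(t, _EV_FUSION_DONE, v, MEMBRANE, m)
        self.site_occupant[m] = -1
        self.location[v] = MEMBRANE
        self._mt_of[v] = -1
        self.visited[v] = True
        self._membrane_count += 1
        self._push(t + self._draws.exponential() * self._mean_membrane, _EV_MEMBRANE_DONE, v, -1)
        q = self.queues[m]
        if q and self._active[m] and self._ready[q[0]] <= t:
            self._transfer(t, m)

    def _on_membrane_done(self, t: float, v: int) -> None:
        self._log(t, _EV_MEMBRANE_DONE, v, ENDOSOME, -1)
        self.location[v] = ENDOSOME
        self._membrane_count -= 1
        self._push(t + self._draws.exponential() * self._mean_store, _EV_ENDO_DONE, v, -1)

    # ------------------------------------------------------------------ control

    def set_phase(self, phase: str) -> None:
        """Switch fusion-site activity (the insulin perturbation).

        Newly activated idle sites immediately accept a ready head vesicle.
        """
        old = self._active
        self._active = self.activity.active(phase)
        self.phase = phase
        for m in range(self.params.n_microtubules):
            if self._active[m] and not old[m] and self.site_occupant[m] < 0:
                q = self.queues[m]
                if q and self._ready[q[0]] <= self.now:
                    self._transfer(self.now, m)

    def reset_visited(self) -> None:
        """Start an uptake experiment: tag exactly the vesicles now at the membrane."""
        self.visited[:] = self.location == MEMBRANE

    # -------------------------------------------------------------- observables

    @property
    def pm_level(self) -> int:
        """Plasma-membrane occupancy in vesicle units (the surface GLUT4 level)."""
        return self._membrane_count

    @property
    def unique_visitors(self) -> int:
        """Cumulative number of distinct vesicles that have visited the membrane."""
        return int(self.visited.sum())

    # ------------------------------------------------------------------- checks

    def check_state(self) -> None:
        """Verify conservation and capacity invariants; raise on a simulator bug."""
        p = self.params
        counts = np.bincount(self.location, minlength=4)
        if counts.sum() != p.n_vesicles:
            raise AssertionError("vesicle conservation violated")
        if counts[MEMBRANE] != self._membrane_count:
            raise AssertionError("membrane count out of sync")
        n_queued = 0
        for m, q in enumerate(self.queues):
            if len(q) > p.microtubule_capacity:
                raise AssertionError(f"microtubule {m} over capacity")
            n_queued += len(q)
            for v in q:
                if self.location[v] != MICROTUBULE or self._mt_of[v] != m:
                    raise AssertionError(f"vesicle {v} queue membership inconsistent")
        if n_queued != counts[MICROTUBULE]:
            raise AssertionError("microtubule occupancy out of sync")
        occupied = self.site_occupant[self.site_occupant >= 0]
        if len(occupied) != counts[FUSION]:
            raise AssertionError("fusion occupancy out of sync")
        for v in occupied:
            if self.location[v] != FUSION:
                raise AssertionError(f"vesicle {v} fusion membership inconsistent")

    def event_log_hash(self) -> str:
        """SHA-256 of the event log (requires ``log_events=True``)."""
        if self.event_log is None:
            raise ValueError("simulator was created without log_events=True")
        h = hashlib.sha256()
        for rec in self.event_log:
            h.update(repr(rec).encode())
        return h.hexdigest()


def measure_pm_level(sim: QueueNetworkSimulator) -> int:
    """Plasma-membrane queue length — the model's surface GLUT4 readout."""
    return sim.pm_level


def measure_unique_visitors(sim: QueueNetworkSimulator) -> int:
    """Cumulative unique membrane visitors — the model's uptake readout."""
    return sim.unique_visitors
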