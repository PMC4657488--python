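"""Independent events, day/night classification, effort and encounter rates.

A contact is independent when the animal has left the field of view since
the previous trigger; operationally, consecutive triggers at one camera are
chained into a single event while each gap to the *previous* trigger stays
below a configurable threshold (default 15 minutes). The encounter rate is
the ratio of totals, sum(y)/sum(t), and its variance comes from resampling
camera locations with replacement.
"""

from __future__ import annotations

import logging
import math
from datetime import datetime
from typing import List, Optional, Sequence

import numpy as np

from . import timewin
from .types import CameraTally, Deployment, EncounterRate, EventRecord, HabitatMap, ValidationError

log = logging.getLogger("remcam.events")

DEFAULT_GAP_MIN = 15.0


def collapse_to_independent_events(
    triggers: Sequence[EventRecord],
    gap_min: float = DEFAULT_GAP_MIN,
    per_individual: bool = False,
) -> List[EventRecord]:
    """Merge runs of triggers at one camera into independent events.

    Chained merging: a trigger joins the current event if it follows the
    *previous* trigger by less than ``gap_min`` minutes, so a stationary
    animal re-triggering every few minutes yields one event however long it
    lingers. The merged event keeps the first trigger's timestamp; its count
    is the largest simultaneous count seen in the run (the ``per_individual``
    flag is honoured downstream when events are tallied into y).

    Input must be sorted by (camera_id, timestamp); collapsing is idempotent.
    """
    if gap_min <= 0:
        raise ValidationError(f"gap must be positive, got {gap_min} minutes")
    triggers = list(triggers)
    key = [(t.camera_id, t.timestamp) for t in triggers]
    if key != sorted(key):
        raise ValidationError("triggers must be sorted by (camera_id, timestamp)")
    out: List[EventRecord] = []
    prev: Optional[EventRecord] = None
    current: Optional[EventRecord] = None
    for trig in triggers:
        same_run = (
            prev is not None
            and trig.camera_id == prev.camera_id
            and (trig.timestamp - prev.timestamp).total_seconds() < gap_min * 60.0
        )
        if same_run:
            if trig.count > current.count:
                current = EventRecord(
                    camera_id=current.camera_id,
                    timestamp=current.timestamp,
                    species=current.species,
                    sex=current.sex,
                    count=trig.count,
                )
        else:
            if current is not None:
                out.append(current)
            current = trig
        prev = trig
    if current is not None:
        out.append(current)
    # per_individual has no effect on the event list itself; kept in the
    # signature so callers can record the analyst's choice alongside the gap.
    del per_individual
    return out


def classify_night(timestamp: datetime, window=timewin.NIGHT_WINDOW) -> bool:
    """True iff the clock time falls in the night window [18:00, 06:00)."""
    return timewin.in_window(timestamp, window)


def assign_habitats(
    deployments: Sequence[Deployment], habitat_map: Optional[HabitatMap]
) -> dict:
    """Map camera_id -> habitat label by point-in-polygon of the camera location.

    Cameras outside all polygons are excluded with a warning. Without a map,
    the deployment's own habitat label is used.
    """
    out = {}
    for dep in deployments:
        if habitat_map is None:
            out[dep.camera_id] = dep.habitat
            continue
        label = habitat_map.assign(dep.x, dep.y)
        if label is None:
            log.warning(
                "camera %r at (%.3f, %.3f) falls outside all habitat polygons; excluded",
                dep.camera_id, dep.x, dep.y,
            )
        else:
            out[dep.camera_id] = label
    return out


def _select_deployments(deployments, habitat, habitat_map):
    if habitat is None:
        return list(deployments)
    assigned = assign_habitats(deployments, habitat_map)
    return [d for d in deployments if assigned.get(d.camera_id) == habitat]


def stratum_effort(
    deployments: Sequence[Deployment],
    window="all",
    habitat: Optional[str] = None,
    habitat_map: Optional[HabitatMap] = None,
) -> float:
    """Total effort hours restricted to a habitat and a daily time window.

    The night window contributes 12 h per full camera-day; partial days
    contribute the exact overlap of the active interval with the window.
    """
    chosen = _select_deployments(deployments, habitat, habitat_map)
    return sum(timewin.interval_window_hours(d.start, d.end, window) for d in chosen)


def tally(
    deployments: Sequence[Deployment],
    events: Sequence[EventRecord],
    window="all",
    habitat: Optional[str] = None,
    habitat_map: Optional[HabitatMap] = None,
    per_individual: bool = False,
) -> List[CameraTally]:
    """Per-camera independent-event counts and window effort.

    ``events`` must already be independent (collapsed). Every camera in the
    stratum appears in the output, including zero-event cameras — the
    bootstrap resamples cameras, so zeros carry information.
    """
    chosen = _select_deployments(deployments, habitat, habitat_map)
    ids = {d.camera_id for d in chosen}
    y = {d.camera_id: 0.0 for d in chosen}
    for ev in events:
        if ev.camera_id not in ids:
            continue
        if not timewin.in_window(ev.timestamp, window):
            continue
        y[ev.camera_id] += ev.count if per_individual else 1
    return [
        CameraTally(
            camera_id=d.camera_id,
            y=y[d.camera_id],
            t=timewin.interval_window_hours(d.start, d.end, window),
        )
        for d in chosen
    ]


def encounter_rate(tallies: Sequence[CameraTally]) -> EncounterRate:
    """Ratio-of-totals encounter rate, sum(y) / sum(t), in events per hour."""
    y_total = float(sum(t.y for t in tallies))
    t_total = float(sum(t.t for t in tallies))
    if t_total <= 0:
        raise ValidationError("total effort is zero; encounter rate undefined")
    return EncounterRate(rate=y_total / t_total, y_total=y_total, t_total=t_total)


def bootstrap_rate_variance(
    tallies: Sequence[CameraTally],
    n_boot: int = 10_000,
    seed: int = 0,
) -> EncounterRate:
    """Encounter rate with variance from resampling cameras with replacement.

    Each replicate draws cameras with replacement up to the original count
    and recomputes the ratio-of-totals rate; ``var_boot`` is the variance of
    the replicate rates (replicates whose resampled effort is zero are
    impossible whenever at least one camera has t > 0 in every draw; the
    rare all-zero-effort draws are discarded).
    """
    tallies = list(tallies)
    if len(tallies) < 2:
        raise ValidationError("bootstrap variance needs at least 2 cameras")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    base = encounter_rate(tallies)
    ys = np.array([t.y for t in tallies], dtype=float)
    ts = np.array([t.t for t in tallies], dtype=float)
    rng = np.random.default_rng(seed)
    n = len(tallies)
    idx = rng.integers(0, n, size=(n_boot, n))
    yb = ys[idx].sum(axis=1)
    tb = ts[idx].sum(axis=1)
    ok = tb > 0
    rates = yb[ok] / tb[ok]
    var = float(np.var(rates, ddof=1)) if rates.size > 1 else 0.0
    return EncounterRate(
        rate=base.rate,
        y_total=base.y_total,
        t_total=base.t_total,
        var_boot=var,
        n_boot=int(n_boot),
        seed=int(seed),
    )


def enumerate_rate_variance(tallies: Sequence[CameraTally]) -> float:
    """Exhaustive-resampling variance of the rate over all n^n equally likely
    with-replacement draws. Exponential in the number of cameras; intended as
    an oracle for toy inputs (<= ~6 cameras)."""
    tallies = list(tallies)
    n = len(tallies)
    if n ** n > 10 ** 6:
        raise ValidationError("exhaustive enumeration is only feasible for tiny inputs")
    ys = np.array([t.y for t in tallies], dtype=float)
    ts = np.array([t.t for t in tallies], dtype=float)
    grids = np.meshgrid(*([np.arange(n)] * n), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    yb = ys[idx].sum(axis=1)
    tb = ts[idx].sum(axis=1)
    ok = tb > 0
    rates = yb[ok] / tb[ok]
    return float(np.mean((rates - rates.mean()) ** 2))
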