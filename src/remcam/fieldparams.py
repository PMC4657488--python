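"""Field-parameter estimation: detection zone from approach trials, speed
from continuous follows.

Compass bearings are averaged on the circle (unit-vector means); arithmetic
means fail for sensors straddling north, which the paired-approach protocol
makes a routine case. For speed, the pride is the replication unit: hours
within a follow are autocorrelated, so the group standard error is taken
across pride-level rates, not hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import timewin
from .types import DetectionTrial, DetectionZone, FollowLog, ValidationError

log = logging.getLogger("remcam.fieldparams")


def circular_mean_deg(bearings_deg: Sequence[float]) -> float:
    """Mean direction of compass bearings, in [0, 360)."""
    a = np.radians(np.asarray(bearings_deg, dtype=float))
    mean = math.atan2(np.sin(a).mean(), np.cos(a).mean())
    deg = math.degrees(mean) % 360.0
    return 0.0 if deg == 360.0 else deg  # float wrap: -eps % 360 rounds to 360


def _wrapped_residuals_deg(bearings_deg, mean_deg):
    d = (np.asarray(bearings_deg, dtype=float) - mean_deg + 180.0) % 360.0 - 180.0
    return d


def circular_se_deg(bearings_deg: Sequence[float]) -> float:
    """Standard error of the circular mean: sd of wrapped residuals / sqrt(n).

    Adequate for the tightly clustered bearings produced by detection trials;
    bearings spread over more than a half-circle would need a dispersion-based
    estimator, which the trial protocol never produces.
    """
    b = np.asarray(bearings_deg, dtype=float)
    if b.size < 2:
        return 0.0
    res = _wrapped_residuals_deg(b, circular_mean_deg(b))
    return float(res.std(ddof=1) / math.sqrt(b.size))


def estimate_detection_zone(trial: DetectionTrial) -> DetectionZone:
    """Detection radius and angle (with SEs) from approach-trial measurements.

    r is the mean first-trigger distance (m -> km) with the standard error of
    that mean. theta is the circular difference between the circular means of
    the left- and right-side bearings, resolved into (0, 180] degrees and
    converted to radians; its SE combines the two mean-bearing SEs in
    quadrature. A resolved angle above 180 deg is rejected — the sensor
    cannot see behind its own half-plane.
    """
    dists = np.asarray(trial.radial_distances, dtype=float)
    if dists.size < 2:
        raise ValidationError("need at least 2 radial distances")
    if len(trial.bearing_pairs) < 2:
        raise ValidationError("need at least 2 bearing pairs")
    r_m = float(dists.mean())
    se_r_m = float(dists.std(ddof=1) / math.sqrt(dists.size)) if dists.size > 1 else 0.0

    left = [lb for lb, _ in trial.bearing_pairs]
    right = [rb for _, rb in trial.bearing_pairs]
    mean_l = circular_mean_deg(left)
    mean_r = circular_mean_deg(right)
    # Smallest signed circular difference, then magnitude.
    theta_deg = abs((mean_r - mean_l + 180.0) % 360.0 - 180.0)
    if theta_deg == 0.0:
        raise ValidationError("left and right mean bearings coincide; zero detection angle")
    if theta_deg > 180.0:  # unreachable after wrap resolution, kept as a guard
        raise ValidationError(f"resolved detection angle {theta_deg:.1f} deg exceeds 180 deg")
    se_theta_deg = math.hypot(circular_se_deg(left), circular_se_deg(right))
    return DetectionZone(
        r=r_m / 1000.0,
        se_r=se_r_m / 1000.0,
        theta=math.radians(theta_deg),
        se_theta=math.radians(se_theta_deg),
    )


@dataclass(frozen=True)
class SpeedEstimate:
    """Group mean speed (km/h) across prides, with SE and per-pride rates."""

    v: float
    se_v: float
    n_prides: int
    pride_rates: dict


def _follow_window_rate(follow: FollowLog, window) -> Tuple[float, float]:
    """(km, hours) of one follow inside the daily window, distances pro-rata.

    Segments crossing the 18:00/06:00 boundary are split by time and their
    odometer distance allocated proportionally.
    """
    km = 0.0
    hours = 0.0
    for s, e, dist in follow.segments:
        seg_h = (e - s).total_seconds() / 3600.0
        for a, b, inside in timewin.split_interval_by_window(s, e, window):
            if not inside:
                continue
            frac = ((b - a).total_seconds() / 3600.0) / seg_h
            km += dist * frac
            hours += (b - a).total_seconds() / 3600.0
    return km, hours


def follow_rate(follow: FollowLog, window="all") -> float:
    """Distance-summed hourly rate of one follow over the window (km/h)."""
    km, hours = _follow_window_rate(follow, window)
    if hours <= 0:
        raise ValidationError(f"follow {follow.pride_id!r}: zero hours in window")
    return km / hours


def estimate_speed(
    follows: Sequence[FollowLog],
    window="all",
    group_by: Tuple[str, ...] = ("habitat", "season"),
    min_hours: float = 24.0,
) -> Dict[tuple, SpeedEstimate]:
    """Mean movement speed per (habitat, season) group, pride as the unit.

    Each follow contributes one rate: km moved inside the window divided by
    hours inside the window. Group speed is the unweighted mean across
    prides; its SE is the standard error of that mean. Follows shorter than
    ``min_hours`` total, or with zero window hours, are excluded with a
    warning.
    """
    groups: Dict[tuple, dict] = {}
    for f in follows:
        if f.total_hours < min_hours:
            log.warning("follow %r: only %.1f h total, excluded", f.pride_id, f.total_hours)
            continue
        km, hours = _follow_window_rate(f, window)
        if hours <= 0:
            log.warning("follow %r: zero hours in window, excluded", f.pride_id)
            continue
        key = tuple(getattr(f, g) for g in group_by)
        groups.setdefault(key, {})[f.pride_id] = km / hours
    out = {}
    for key, rates in groups.items():
        vals = np.array(list(rates.values()), dtype=float)
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[key] = SpeedEstimate(v=float(vals.mean()), se_v=se,
                                 n_prides=int(vals.size), pride_rates=dict(rates))
    return out
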