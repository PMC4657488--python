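"""Domain types shared across the package.

All geometry is planar, in kilometres, in a single projected coordinate
system; timestamps are naive local datetimes (camera-stamped clock time).
Angles are stored in radians internally; degrees are accepted at the I/O
boundary and converted once at parse time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

from shapely.geometry.base import BaseGeometry


class RemcamError(Exception):
    """Base class for remcam errors."""


class SchemaError(RemcamError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(RemcamError):
    """A record violates a domain invariant; the message names the row."""


# Detection radii are a few tens of metres; a radius this large in km almost
# certainly means metres were passed where km were expected.
_MAX_PLAUSIBLE_RADIUS_KM = 0.5


@dataclass(frozen=True)
class Deployment:
    """One camera placement with its active interval and habitat label."""

    camera_id: str
    x: float  # km, projected planar
    y: float  # km
    start: datetime
    end: datetime
    habitat: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"deployment {self.camera_id!r}: end {self.end} is not after start {self.start}"
            )

    @property
    def effort_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass(frozen=True)
class EventRecord:
    """One photographic contact (a raw trigger or an independent event)."""

    camera_id: str
    timestamp: datetime
    species: str = "lion"
    sex: str = "female"
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(
                f"event at {self.camera_id!r} {self.timestamp}: count must be >= 1, got {self.count}"
            )


@dataclass(frozen=True)
class DetectionZone:
    """Camera detection sector: radius r (km) and full angle theta (radians)."""

    r: float
    theta: float
    se_r: float = 0.0
    se_theta: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError(f"detection radius must be positive, got {self.r}")
        if self.r >= _MAX_PLAUSIBLE_RADIUS_KM:
            raise ValidationError(
                f"detection radius {self.r} km is implausibly large; "
                "radii are stored in km (metres must be converted: r_m / 1000)"
            )
        if not 0 < self.theta < 2 * math.pi:
            raise ValidationError(
                f"detection angle must be in (0, 2*pi) radians, got {self.theta}"
            )
        if self.se_r < 0 or self.se_theta < 0:
            raise ValidationError("standard errors must be non-negative")


@dataclass(frozen=True)
class REMParams:
    """The field parameters of the REM: speed V (km/h) and the detection zone.

    ``theta`` is the full sector angle in radians and enters the model through
    the profile term ``(2 + theta)``.
    """

    v: float
    r: float
    theta: float
    se_v: float = 0.0
    se_r: float = 0.0
    se_theta: float = 0.0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValidationError(f"speed must be positive, got {self.v}")
        # Delegate radius/angle checks (incl. the metres-vs-km guard).
        DetectionZone(self.r, self.theta, self.se_r, self.se_theta)
        if self.se_v < 0:
            raise ValidationError("se_v must be non-negative")

    @classmethod
    def from_zone(cls, v: float, se_v: float, zone: DetectionZone) -> "REMParams":
        return cls(v=v, r=zone.r, theta=zone.theta, se_v=se_v,
                   se_r=zone.se_r, se_theta=zone.se_theta)

    def replace(self, **kw) -> "REMParams":
        d = dict(v=self.v, r=self.r, theta=self.theta,
                 se_v=self.se_v, se_r=self.se_r, se_theta=self.se_theta)
        d.update(kw)
        return REMParams(**d)


@dataclass(frozen=True)
class PrideRecord:
    """A censused pride: known female count and direct-observation points."""

    pride_id: str
    n_females: int
    observations: tuple  # of (x_km, y_km, datetime)
    season: str = ""

    def __post_init__(self) -> None:
        if self.n_females < 0:
            raise ValidationError(
                f"pride {self.pride_id!r}: n_females must be >= 0, got {self.n_females}"
            )

    @property
    def points(self):
        import numpy as np

        return np.asarray([(p[0], p[1]) for p in self.observations], dtype=float)


class HabitatMap:
    """Named habitat polygons in planar km.

    Point-in-polygon assignment returns the first containing polygon in file
    (insertion) order, so boundary points resolve deterministically.
    """

    def __init__(self, polygons: dict):
        for name, geom in polygons.items():
            if not isinstance(geom, BaseGeometry):
                raise ValidationError(f"habitat {name!r}: not a geometry")
            if not geom.is_valid:
                raise ValidationError(f"habitat {name!r}: invalid geometry (self-intersection?)")
        self.polygons = dict(polygons)

    @property
    def labels(self) -> list:
        return list(self.polygons)

    def area(self, label: str) -> float:
        return self.polygons[label].area

    def assign(self, x: float, y: float) -> Optional[str]:
        from shapely.geometry import Point

        p = Point(x, y)
        for name, geom in self.polygons.items():
            if geom.covers(p):
                return name
        return None


@dataclass(frozen=True)
class CameraTally:
    """Per-camera event count y and effort t (hours) in one analysis window."""

    camera_id: str
    y: float
    t: float

    def __post_init__(self) -> None:
        if self.y < 0 or self.t < 0:
            raise ValidationError(f"camera {self.camera_id!r}: y and t must be >= 0")
        if self.t == 0 and self.y > 0:
            raise ValidationError(f"camera {self.camera_id!r}: events recorded with zero effort")


@dataclass(frozen=True)
class EncounterRate:
    """Ratio-of-totals encounter rate with bootstrap variance."""

    rate: float  # events / hour
    y_total: float
    t_total: float
    var_boot: float = float("nan")
    n_boot: int = 0
    seed: Optional[int] = None

    @property
    def cv(self) -> float:
        if self.rate == 0 or math.isnan(self.var_boot):
            return float("nan")
        return math.sqrt(self.var_boot) / self.rate


@dataclass(frozen=True)
class DensityEstimate:
    """A density estimate (animals/km^2) with its uncertainty and stratum."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_events: int
    effort_hours: float
    stratum: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ValidationError("density estimate must be >= 0")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class REMResult:
    """REM density with delta-method variance decomposition."""

    d: float
    se_d: float
    ci_low: float
    ci_high: float
    cv2_components: dict  # per-parameter CV^2 contributions to CV^2(D)
    rate: EncounterRate
    params: REMParams
    ci_method: str = "lognormal"

    @property
    def cv(self) -> float:
        return self.se_d / self.d if self.d > 0 else float("nan")


@dataclass(frozen=True)
class DetectionTrial:
    """Ex-situ detection-zone trial measurements.

    ``radial_distances`` are first-trigger distances (m) from frontal
    approaches; ``bearing_pairs`` are (left, right) compass bearings in
    degrees from paired perpendicular approaches.
    """

    radial_distances: tuple
    bearing_pairs: tuple

    def __post_init__(self) -> None:
        for d in self.radial_distances:
            if d <= 0:
                raise ValidationError(f"trial distance must be positive, got {d}")
        for lb, rb in self.bearing_pairs:
            if not (0 <= lb < 360 and 0 <= rb < 360):
                raise ValidationError(f"bearings must be in [0, 360), got ({lb}, {rb})")


@dataclass(frozen=True)
class FollowLog:
    """Continuous-follow log: odometer distances over chronological segments."""

    pride_id: str
    habitat: str
    season: str
    segments: tuple  # of (start datetime, end datetime, km)

    def __post_init__(self) -> None:
        prev_end = None
        for s, e, km in self.segments:
            if e <= s:
                raise ValidationError(f"follow {self.pride_id!r}: segment end {e} not after start {s}")
            if km < 0:
                raise ValidationError(f"follow {self.pride_id!r}: negative odometer distance {km}")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"follow {self.pride_id!r}: overlapping segments at {s}")
            prev_end = e

    @property
    def total_hours(self) -> float:
        return sum((e - s).total_seconds() / 3600.0 for s, e, _ in self.segments)


@dataclass(frozen=True)
class UtilizationDistribution:
    """Kernel utilization distribution on a regular grid of cell masses."""

    mass: "object"  # 2D ndarray (nx, ny), sums to 1
    x0: float  # km, lower-left corner of the grid
    y0: float
    cell: float  # km, cell edge
    bandwidth: float  # km

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


@dataclass(frozen=True)
class HomeRange:
    """Isopleth home range: the minimum-area region holding `level` mass."""

    pride_id: str
    level: float
    polygon: BaseGeometry
    area: float  # km^2, cell-count area

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValidationError(f"isopleth level must be in (0, 1), got {self.level}")
        if self.area <= 0:
            raise ValidationError("home-range area must be positive")


@dataclass(frozen=True)
class BufferWidth:
    """Buffer width w (km) = half the mean home-range diameter, with 95% limits."""

    w: float
    w_low: float
    w_high: float
    n: int


@dataclass(frozen=True)
class ReferenceResult:
    """Census-based reference density for one season-habitat stratum."""

    habitat: str
    season: str
    abundance: float  # sum of N_i * p_i
    a: float  # effectively sampled area, km^2
    d_ref: float
    ci_low: float
    ci_high: float
    w: Optional[BufferWidth] = None


def parse_angle(value: float, units: str) -> float:
    """Convert an angle to radians from declared units ('deg' or 'rad')."""
    units = units.lower()
    if units in ("deg", "degree", "degrees"):
        return math.radians(value)
    if units in ("rad", "radian", "radians"):
        return value
    raise ValidationError(f"unknown angle units {units!r}")


def parse_length_km(value: float, units: str) -> float:
    """Convert a length to km from declared units ('m' or 'km')."""
    units = units.lower()
    if units in ("m", "meter", "metre", "meters", "metres"):
        return value / 1000.0
    if units == "km":
        return value
    raise ValidationError(f"unknown length units {units!r}")
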