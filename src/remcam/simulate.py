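"""Movement/detection simulator: every pipeline input from known ground truth.

Animals move independently at a fixed speed across a toroidal arena (the
torus preserves the uniform-density assumption exactly); cameras carry
sector detection zones (radius r, full angle theta about a random heading).
A detection event is emitted when an animal's path crosses from outside to
inside a zone; an animal must leave the zone before it can trigger again,
and an animal resting inside a zone yields a single event however long it
stays. Under these rules the per-camera event rate of straight-line movers
has the closed form

    rho = D * V * r * (2 + theta) / pi,

which is the gas-model contact rate the REM inverts, so simulations double
as parameter-recovery checks for the whole pipeline.

Detection is computed exactly along each linear path segment (disc-interval
clipping plus dense sub-sampling of the sector condition), so for the
straight-line default the event stream does not depend on the time step;
``dt`` only discretises correlated-walk headings.

The placement-bias scenario emulates shade-seeking: during day hours each
animal, with a configurable hazard per day-hour, makes an excursion to the
nearest camera ("tree") — recorded as one contact — and rests there before
resuming its walk. The excursion interrupts, rather than displaces, the
underlying trajectory, so daytime encounter rates are inflated while the
population stays uniformly distributed and night movement remains random —
the mechanism by which non-random placement biases all-events density
estimates upward while leaving night-only estimates unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .events import bootstrap_rate_variance, collapse_to_independent_events, encounter_rate, tally
from .rem import delta_variance, rem_density
from .types import Deployment, DetectionTrial, EventRecord, FollowLog, PrideRecord, REMParams, ValidationError

_DAY_START = 6.0  # clock hours; the day window is [06:00, 18:00)
_DAY_END = 18.0


@dataclass(frozen=True)
class BiasConfig:
    """Daytime camera-attraction scenario.

    ``q`` is the relocation hazard per day-hour; ``rest_h`` is how long the
    animal rests inside the detection zone (truncated at nightfall so night
    movement stays unbiased).
    """

    q: float = 0.1
    rest_h: float = 2.0

    def __post_init__(self) -> None:
        if self.q < 0 or self.rest_h < 0:
            raise ValidationError("bias parameters must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Arena, population, movement and detection geometry for one simulation.

    Defaults are the validation conditions used throughout the package's
    recovery tests: true density 5 animals/km^2 on a 10 x 10 km torus,
    speed 0.2 km/h, a 5 x 5 camera grid with 10 m / 50 degree sectors,
    2000 h of survey.
    """

    arena: Tuple[float, float] = (10.0, 10.0)
    n_animals: int = 500
    speed: float = 0.2  # km/h
    movement: str = "straight"  # or "crw"
    turning_sd: float = 0.5  # rad per sqrt(hour), correlated walk only
    n_cameras: int = 25
    placement: str = "grid"  # or "random"
    detect_r: float = 0.01  # km
    detect_theta: float = math.radians(50.0)  # full sector angle, radians
    duration_h: float = 2000.0
    dt_min: float = 1.0
    bias: Optional[BiasConfig] = None
    start: datetime = datetime(2010, 8, 1, 0, 0)
    shift: Tuple[float, float] = (0.0, 0.0)  # global translation (torus symmetry)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.arena
        if w <= 0 or h <= 0:
            raise ValidationError("arena dimensions must be positive")
        if self.detect_r > min(w, h) / 2.0:
            raise ValidationError(
                f"detection zone (r = {self.detect_r} km) larger than the arena allows"
            )
        if not 0 < self.detect_theta < 2 * math.pi:
            raise ValidationError("detection angle must be in (0, 2*pi)")
        if self.n_animals < 0 or self.n_cameras < 1:
            raise ValidationError("need n_animals >= 0 and n_cameras >= 1")
        if self.speed <= 0 or self.duration_h <= 0 or self.dt_min <= 0:
            raise ValidationError("speed, duration and dt must be positive")
        if self.movement not in ("straight", "crw"):
            raise ValidationError(f"unknown movement model {self.movement!r}")

    @property
    def true_density(self) -> float:
        return self.n_animals / (self.arena[0] * self.arena[1])

    @property
    def analytic_rate(self) -> float:
        """Gas-model events per camera-hour: D * V * r * (2 + theta) / pi."""
        return (
            self.true_density * self.speed * self.detect_r * (2.0 + self.detect_theta) / math.pi
        )


@dataclass
class TruthBundle:
    """Simulated inputs plus the ground truth that produced them."""

    config: SimConfig
    cameras: np.ndarray  # (n_cam, 3): x, y, heading
    deployments: List[Deployment]
    events: List[EventRecord]
    truth: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# path segments
# ---------------------------------------------------------------------------


def _straight_segments_one(x0, y0, heading, speed, t0, dur, w, h):
    """Boundary-split linear segments for one straight stretch on the torus.

    Returns arrays (x0, y0, dx, dy, t0, dur); each sub-segment lies within
    the arena rectangle (up to float epsilon), so camera images only need a
    margin of ~r at the edges.
    """
    vx = speed * math.cos(heading)
    vy = speed * math.sin(heading)
    cuts = [0.0, dur]
    for v, p, size in ((vx, x0, w), (vy, y0, h)):
        if abs(v) < 1e-12:
            continue
        pe = p + v * dur
        klo, khi = sorted((p / size, pe / size))
        ks = np.arange(math.floor(klo) + 1, math.ceil(khi))
        cuts.extend(((k * size - p) / v) for k in ks)
    ts = np.unique(np.clip(np.asarray(cuts, dtype=float), 0.0, dur))
    ta, tb = ts[:-1], ts[1:]
    keep = tb > ta
    ta, tb = ta[keep], tb[keep]
    tm = 0.5 * (ta + tb)
    kx = np.floor((x0 + vx * tm) / w)
    ky = np.floor((y0 + vy * tm) / h)
    return (
        x0 + vx * ta - kx * w,
        y0 + vy * ta - ky * h,
        vx * (tb - ta),
        vy * (tb - ta),
        t0 + ta,
        tb - ta,
    )


class _SegmentStore:
    def __init__(self):
        self.x0, self.y0, self.dx, self.dy, self.t0, self.dur = [], [], [], [], [], []
        self.animal, self.fresh = [], []

    def add(self, arrays, animal, fresh_first=False):
        x0, y0, dx, dy, t0, dur = arrays
        n = len(x0)
        if n == 0:
            return
        self.x0.append(x0)
        self.y0.append(y0)
        self.dx.append(dx)
        self.dy.append(dy)
        self.t0.append(t0)
        self.dur.append(dur)
        self.animal.append(np.full(n, animal, dtype=np.int64))
        f = np.zeros(n, dtype=bool)
        if fresh_first:
            f[0] = True
        self.fresh.append(f)

    def arrays(self):
        if not self.x0:
            z = np.zeros(0)
            return dict(x0=z, y0=z, dx=z, dy=z, t0=z, dur=z,
                        animal=np.zeros(0, dtype=np.int64), fresh=np.zeros(0, dtype=bool))
        return dict(
            x0=np.concatenate(self.x0),
            y0=np.concatenate(self.y0),
            dx=np.concatenate(self.dx),
            dy=np.concatenate(self.dy),
            t0=np.concatenate(self.t0),
            dur=np.concatenate(self.dur),
            animal=np.concatenate(self.animal),
            fresh=np.concatenate(self.fresh),
        )


def _crw_segments(pos, headings, cfg, rng):
    """Per-step segments of a correlated random walk (heading persistence)."""
    w, h = cfg.arena
    dt_h = cfg.dt_min / 60.0
    n_steps = int(math.ceil(cfg.duration_h / dt_h))
    n = cfg.n_animals
    if n_steps * max(n, 1) > 20_000_000:
        raise ValidationError(
            "correlated-walk configuration too large; reduce duration, dt or animals"
        )
    turns = rng.normal(0.0, cfg.turning_sd * math.sqrt(dt_h), size=(n_steps, n))
    phi = headings[None, :] + np.cumsum(turns, axis=0) - turns  # heading during each step
    durs = np.full(n_steps, dt_h)
    durs[-1] = cfg.duration_h - dt_h * (n_steps - 1)
    step_dx = cfg.speed * np.cos(phi) * durs[:, None]
    step_dy = cfg.speed * np.sin(phi) * durs[:, None]
    x = np.concatenate([pos[None, :, 0], pos[None, :, 0] + np.cumsum(step_dx, axis=0)])
    y = np.concatenate([pos[None, :, 1], pos[None, :, 1] + np.cumsum(step_dy, axis=0)])
    t0s = np.concatenate([[0.0], np.cumsum(durs)])[:-1]
    store = _SegmentStore()
    wrap_x = np.floor(x[:-1] / w) * w
    wrap_y = np.floor(y[:-1] / h) * h
    for a in range(n):
        store.add(
            (
                x[:-1, a] - wrap_x[:, a],
                y[:-1, a] - wrap_y[:, a],
                step_dx[:, a],
                step_dy[:, a],
                t0s,
                durs,
            ),
            a,
            fresh_first=True,
        )
    margin = cfg.speed * dt_h
    return store.arrays(), margin


def _advance_day_hours(t: float, e: float, clock0: float) -> float:
    """Absolute sim-hour when ``e`` day-hours have accumulated after ``t``.

    ``clock0`` is the clock hour of simulation start; the day window is
    [06:00, 18:00) each day.
    """
    while True:
        clock = (clock0 + t) % 24.0
        if clock < _DAY_START:
            t += _DAY_START - clock
        elif clock >= _DAY_END:
            t += 24.0 - clock + _DAY_START
        else:
            avail = _DAY_END - clock
            if e <= avail:
                return t + e
            e -= avail
            t += avail


def _day_end_after(t: float, clock0: float) -> float:
    """Sim-hour of the next 18:00 at or after ``t`` (assumes t is in day)."""
    clock = (clock0 + t) % 24.0
    return t + (_DAY_END - clock)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_zone_crossings(
    segments: dict,
    cameras: np.ndarray,
    r: float,
    theta: float,
    arena: Tuple[float, float],
    margin: float = 0.0,
    n_sub: int = 128,
):
    """Outside-to-inside sector crossings along linear path segments.

    ``segments`` holds arrays x0, y0, dx, dy (km), t0, dur (hours), animal
    (int) and fresh (bool: segment starts a path, so starting inside counts
    as an event at t0). Cameras are rows (x, y, heading). Periodic images of
    cameras within ``r + margin`` of the arena edges implement the torus.

    Returns (camera_idx, time_h, animal_idx) arrays sorted by time. Within
    the disc the sector condition is sampled at ``n_sub`` points along the
    clipped chord (resolution ~2 r / n_sub), which resolves wedge-edge
    crossings far below the detection radius.
    """
    w, h = arena
    x0, y0 = segments["x0"], segments["y0"]
    dx, dy = segments["dx"], segments["dy"]
    t0, dur = segments["t0"], segments["dur"]
    animal, fresh = segments["animal"], segments["fresh"]
    cos_half = math.cos(theta / 2.0)
    r2 = r * r
    reach = r + margin + 1e-9

    cand = {k: [] for k in ("seg", "cam", "ax", "ay")}
    for ci in range(cameras.shape[0]):
        cx, cy, _ = cameras[ci]
        for ox in (-w, 0.0, w):
            ix = cx + ox
            if not -reach <= ix <= w + reach:
                continue
            for oy in (-h, 0.0, h):
                iy = cy + oy
                if not -reach <= iy <= h + reach:
                    continue
                ax = x0 - ix
                ay = y0 - iy
                # min distance from the camera to the segment
                dd = dx * dx + dy * dy
                tp = np.clip(-(ax * dx + ay * dy) / np.where(dd > 0, dd, 1.0), 0.0, 1.0)
                mx = ax + tp * dx
                my = ay + tp * dy
                near = mx * mx + my * my <= r2
                if not near.any():
                    continue
                idx = np.nonzero(near)[0]
                cand["seg"].append(idx)
                cand["cam"].append(np.full(idx.size, ci, dtype=np.int64))
                cand["ax"].append(ax[idx])
                cand["ay"].append(ay[idx])

    if not cand["seg"]:
        e = np.zeros(0)
        return e.astype(np.int64), e, e.astype(np.int64)

    seg = np.concatenate(cand["seg"])
    cam = np.concatenate(cand["cam"])
    ax = np.concatenate(cand["ax"])
    ay = np.concatenate(cand["ay"])
    sdx, sdy = dx[seg], dy[seg]
    ux = np.cos(cameras[cam, 2])
    uy = np.sin(cameras[cam, 2])

    def inside(px, py, ux_, uy_):
        rr = px * px + py * py
        return (rr <= r2) & (px * ux_ + py * uy_ >= np.sqrt(rr) * cos_half)

    # interval of the segment inside the detection disc
    dd = sdx * sdx + sdy * sdy
    aa = ax * ax + ay * ay
    b = ax * sdx + ay * sdy
    disc = b * b - dd * (aa - r2)
    moving = dd > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    dd_safe = np.where(moving, dd, 1.0)
    lo = np.clip((-b - sq) / dd_safe, 0.0, 1.0)
    hi = np.clip((-b + sq) / dd_safe, 0.0, 1.0)
    frac = (np.arange(n_sub) + 0.5) / n_sub
    tg = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
    px = ax[:, None] + tg * sdx[:, None]
    py = ay[:, None] + tg * sdy[:, None]
    ins = inside(px, py, ux[:, None], uy[:, None])
    inside0 = inside(ax, ay, ux, uy)
    # stationary segments never transition; their only contribution is the
    # fresh-start case handled below
    ins[~moving] = False
    seq = np.concatenate([inside0[:, None], ins], axis=1)
    ent = ~seq[:, :-1] & seq[:, 1:]
    rows, cols = np.nonzero(ent)
    times = t0[seg[rows]] + tg[rows, cols] * dur[seg[rows]]
    cams = cam[rows]
    anims = animal[seg[rows]]
    # path starts inside a zone: one event at the path's start time
    start_in = inside0 & fresh[seg]
    if start_in.any():
        srows = np.nonzero(start_in)[0]
        times = np.concatenate([times, t0[seg[srows]]])
        cams = np.concatenate([cams, cam[srows]])
        anims = np.concatenate([anims, animal[seg[srows]]])
    order = np.argsort(times, kind="stable")
    return cams[order], times[order], anims[order]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _place_cameras(cfg: SimConfig, rng) -> np.ndarray:
    w, h = cfg.arena
    n = cfg.n_cameras
    if cfg.placement == "grid":
        nx = max(int(round(math.sqrt(n * w / h))), 1)
        ny = max(int(math.ceil(n / nx)), 1)
        xs, ys = [], []
        k = 0
        for j in range(ny):
            for i in range(nx):
                if k >= n:
                    break
                xs.append((i + 0.5) * w / nx)
                ys.append((j + 0.5) * h / ny)
                k += 1
        pos = np.column_stack([xs, ys])
    elif cfg.placement == "random":
        pos = rng.uniform(0, 1, size=(n, 2)) * np.array(cfg.arena)
    else:
        raise ValidationError(f"unknown placement {cfg.placement!r}")
    headings = rng.uniform(0.0, 2 * math.pi, size=n)
    return np.column_stack([pos, headings])


def _torus_nearest_camera(x, y, cameras, arena):
    w, h = arena
    ddx = np.abs(cameras[:, 0] - x)
    ddy = np.abs(cameras[:, 1] - y)
    ddx = np.minimum(ddx, w - ddx)
    ddy = np.minimum(ddy, h - ddy)
    return int(np.argmin(ddx * ddx + ddy * ddy))


def simulate(config: SimConfig) -> TruthBundle:
    """Run the movement/detection simulation and package pipeline inputs.

    With ``config.bias`` unset (or a zero hazard) animals move without any
    attraction to cameras; otherwise the daytime relocation mechanism is
    active. Same seed, same config: byte-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.arena
    sx, sy = cfg.shift
    cameras = _place_cameras(cfg, rng)
    cameras[:, 0] = (cameras[:, 0] + sx) % w
    cameras[:, 1] = (cameras[:, 1] + sy) % h
    pos = rng.uniform(0, 1, size=(cfg.n_animals, 2)) * np.array(cfg.arena)
    pos[:, 0] = (pos[:, 0] + sx) % w
    pos[:, 1] = (pos[:, 1] + sy) % h
    headings = rng.uniform(0.0, 2 * math.pi, size=cfg.n_animals)

    explicit: List[Tuple[int, float]] = []  # (camera_idx, time) from rest arrivals
    biased = cfg.bias is not None and cfg.bias.q > 0

    if cfg.n_animals == 0:
        store = _SegmentStore()
        segs, margin = store.arrays(), 0.0
    elif cfg.movement == "crw":
        if biased:
            raise ValidationError("the bias scenario requires straight-line movement")
        segs, margin = _crw_segments(pos, headings, cfg, rng)
    elif not biased:
        store = _SegmentStore()
        for a in range(cfg.n_animals):
            store.add(
                _straight_segments_one(
                    pos[a, 0], pos[a, 1], headings[a], cfg.speed, 0.0, cfg.duration_h, w, h
                ),
                a,
                fresh_first=True,
            )
        segs, margin = store.arrays(), 0.0
    else:
        clock0 = cfg.start.hour + cfg.start.minute / 60.0 + cfg.start.second / 3600.0
        q, rest_h = cfg.bias.q, cfg.bias.rest_h
        store = _SegmentStore()
        for a in range(cfg.n_animals):
            t = 0.0
            x, y = pos[a]
            heading = headings[a]
            fresh = True
            while t < cfg.duration_h:
                t_reloc = _advance_day_hours(t, rng.exponential(1.0 / q), clock0)
                t_end = min(t_reloc, cfg.duration_h)
                if t_end > t:
                    arrays = _straight_segments_one(
                        x, y, heading, cfg.speed, t, t_end - t, w, h
                    )
                    store.add(arrays, a, fresh_first=fresh)
                    fresh = False
                    x = arrays[0][-1] + arrays[2][-1]
                    y = arrays[1][-1] + arrays[3][-1]
                    x -= math.floor(x / w) * w
                    y -= math.floor(y / h) * h
                if t_reloc >= cfg.duration_h:
                    break
                # Shade excursion: one contact at the nearest camera, then a
                # rest (truncated at nightfall) during which the underlying
                # walk is suspended in place. Treating the excursion as an
                # interruption rather than a displacement keeps the spatial
                # distribution exactly uniform at every instant, so night
                # movement is unbiased by construction.
                ci = _torus_nearest_camera(x, y, cameras, cfg.arena)
                explicit.append((ci, t_reloc))
                t = min(t_reloc + rest_h, _day_end_after(t_reloc, clock0), cfg.duration_h)
                heading = rng.uniform(0.0, 2 * math.pi)
                fresh = False
        segs, margin = store.arrays(), 0.0

    cams_idx, times, anims = detect_zone_crossings(
        segs, cameras, cfg.detect_r, cfg.detect_theta, cfg.arena, margin=margin
    )
    if explicit:
        ec = np.array([c for c, _ in explicit], dtype=np.int64)
        et = np.array([t for _, t in explicit], dtype=float)
        cams_idx = np.concatenate([cams_idx, ec])
        times = np.concatenate([times, et])
        anims = np.concatenate([anims, np.full(ec.size, -1, dtype=np.int64)])
        order = np.argsort(times, kind="stable")
        cams_idx, times, anims = cams_idx[order], times[order], anims[order]

    ids = [f"cam{i:03d}" for i in range(cfg.n_cameras)]
    end = cfg.start + timedelta(hours=cfg.duration_h)
    deployments = [
        Deployment(camera_id=ids[i], x=float(cameras[i, 0]), y=float(cameras[i, 1]),
                   start=cfg.start, end=end, habitat="")
        for i in range(cfg.n_cameras)
    ]
    events = [
        EventRecord(camera_id=ids[int(c)], timestamp=cfg.start + timedelta(hours=float(t)))
        for c, t in zip(cams_idx, times)
    ]
    events.sort(key=lambda e: (e.camera_id, e.timestamp))
    truth = {
        "true_density": cfg.true_density,
        "true_v": cfg.speed,
        "true_r": cfg.detect_r,
        "true_theta": cfg.detect_theta,
        "analytic_rate": cfg.analytic_rate,
        "n_detections": len(events),
        "seed": cfg.seed,
    }
    return TruthBundle(config=cfg, cameras=cameras, deployments=deployments,
                       events=events, truth=truth)


def simulate_bias_scenario(config: SimConfig) -> TruthBundle:
    """Run the daytime camera-attraction scenario (requires ``config.bias``)."""
    if config.bias is None:
        raise ValidationError("simulate_bias_scenario needs a BiasConfig on the SimConfig")
    return simulate(config)


def recover_density(
    bundle: TruthBundle,
    window="all",
    gap_min: float = 15.0,
    n_boot: int = 0,
    seed: int = 0,
    ci: str = "lognormal",
    params: Optional[REMParams] = None,
):
    """Run the estimation pipeline on simulated events using true parameters.

    Collapses triggers to independent events, tallies per camera in the
    window, and applies the REM with the simulator's true V, r, theta (or
    caller-supplied params). With ``n_boot`` > 0, returns the full
    delta-method result; otherwise the point estimate.
    """
    cfg = bundle.config
    if params is None:
        params = REMParams(v=cfg.speed, r=cfg.detect_r, theta=cfg.detect_theta)
    ind = collapse_to_independent_events(bundle.events, gap_min=gap_min)
    tallies = tally(bundle.deployments, ind, window=window)
    if n_boot > 0:
        rate = bootstrap_rate_variance(tallies, n_boot=n_boot, seed=seed)
        return delta_variance(rate, params, ci_method=ci)
    return rem_density(encounter_rate(tallies), params)


# ---------------------------------------------------------------------------
# fixtures for the non-simulated inputs
# ---------------------------------------------------------------------------


def grid_deployments(
    width_km: float,
    height_km: float,
    cell_area_km2: float = 5.0,
    start: datetime = datetime(2010, 8, 1),
    duration_days: float = 90.0,
    habitat: str = "",
) -> List[Deployment]:
    """A survey grid with one camera at the centre of each square cell.

    Cell edge = sqrt(cell_area); a 20 x 42 km area with 5 km^2 cells yields
    cameras at about 2.24 km spacing.
    """
    spacing = math.sqrt(cell_area_km2)
    nx = max(int(round(width_km / spacing)), 1)
    ny = max(int(round(height_km / spacing)), 1)
    end = start + timedelta(days=duration_days)
    deps = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            deps.append(
                Deployment(
                    camera_id=f"cam{k:03d}",
                    x=(i + 0.5) * spacing,
                    y=(j + 0.5) * spacing,
                    start=start,
                    end=end,
                    habitat=habitat,
                )
            )
            k += 1
    return deps


def trials_fixture(
    true_r_m: float = 14.42,
    true_theta_deg: float = 50.12,
    n_radial: int = 10,
    n_pairs: int = 10,
    sd_r_m: float = 0.7,
    sd_bearing_deg: float = 1.5,
    axis_deg: float = 0.0,
    seed: int = 0,
) -> DetectionTrial:
    """Noisy detection-zone trial measurements around a known r and theta.

    With the default sensor axis at 0 degrees (north) the left/right bearings
    straddle the 0/360 wrap, exercising the circular arithmetic.
    """
    rng = np.random.default_rng(seed)
    dists = true_r_m + sd_r_m * rng.standard_normal(n_radial)
    dists = np.maximum(dists, 0.1)
    left = (axis_deg - true_theta_deg / 2.0 + sd_bearing_deg * rng.standard_normal(n_pairs)) % 360
    right = (axis_deg + true_theta_deg / 2.0 + sd_bearing_deg * rng.standard_normal(n_pairs)) % 360
    return DetectionTrial(
        radial_distances=tuple(float(d) for d in dists),
        bearing_pairs=tuple((float(l), float(r)) for l, r in zip(left, right)),
    )


def follows_fixture(
    pride_ids: Sequence[str],
    habitat: str = "grassland",
    season: str = "dry",
    day_speed: float = 0.1,
    night_speed: float = 0.3,
    n_days: int = 4,
    start: datetime = datetime(2010, 8, 1, 6, 0),
    sd: float = 0.0,
    seed: int = 0,
) -> List[FollowLog]:
    """Hourly follow logs with distinct day/night speeds per pride."""
    rng = np.random.default_rng(seed)
    follows = []
    for pid in pride_ids:
        segs = []
        t = start
        for _ in range(24 * n_days):
            e = t + timedelta(hours=1)
            clock = t.hour
            speed = day_speed if _DAY_START <= clock < _DAY_END else night_speed
            km = max(speed + sd * rng.standard_normal(), 0.0)
            segs.append((t, e, float(km)))
            t = e
        follows.append(FollowLog(pride_id=pid, habitat=habitat, season=season,
                                 segments=tuple(segs)))
    return follows


def prides_fixture(
    n_prides: int = 10,
    centers: Optional[np.ndarray] = None,
    arena: Tuple[float, float] = (40.0, 40.0),
    spread_km: float = 3.0,
    n_obs: int = 30,
    n_females_range: Tuple[int, int] = (3, 12),
    season: str = "dry",
    start: datetime = datetime(2010, 8, 1),
    seed: int = 0,
) -> List[PrideRecord]:
    """Pride census records with bivariate-normal observation scatters."""
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = rng.uniform(0.2, 0.8, size=(n_prides, 2)) * np.array(arena)
    centers = np.asarray(centers, dtype=float)
    prides = []
    for i in range(centers.shape[0]):
        pts = centers[i] + spread_km * rng.standard_normal((n_obs, 2))
        nf = int(rng.integers(n_females_range[0], n_females_range[1] + 1))
        obs = tuple(
            (float(x), float(y), start + timedelta(days=float(j)))
            for j, (x, y) in enumerate(pts)
        )
        prides.append(
            PrideRecord(pride_id=f"pride{i:02d}", n_females=nf, observations=obs, season=season)
        )
    return prides
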