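"""Study orchestration: stratified REM and reference estimation with provenance.

A study is a grid of strata — (season, habitat) cells crossed with the
all-hours and night-only time windows. For each stratum the pipeline counts
the data attrition (triggers -> independent events -> window events),
computes the encounter rate with bootstrap variance, applies the REM with
the window-matched speed (night-only estimates pair V_n with night effort),
and, when pride census data are supplied, derives the census reference
density and the percent error of the REM against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import events as ev
from . import reference as ref
from .rem import delta_variance
from .types import (
    Deployment,
    DetectionZone,
    EventRecord,
    HabitatMap,
    PrideRecord,
    REMParams,
    ReferenceResult,
    ValidationError,
)

log = logging.getLogger("remcam.pipeline")


@dataclass(frozen=True)
class StudyParams:
    """Field parameters for a study: one detection zone, speeds per stratum.

    ``speeds`` maps (season, habitat) to {"all": (v, se), "night": (v, se)}
    in km/h.
    """

    zone: DetectionZone
    speeds: Dict[Tuple[str, str], Dict[str, Tuple[float, float]]]

    def rem_params(self, season: str, habitat: str, window: str) -> REMParams:
        key = (season, habitat)
        if key not in self.speeds:
            raise ValidationError(f"no speed estimate for stratum {key}")
        wkey = "night" if window == "night" else "all"
        if wkey not in self.speeds[key]:
            raise ValidationError(f"no {wkey!r} speed for stratum {key}")
        v, se_v = self.speeds[key][wkey]
        return REMParams.from_zone(v=v, se_v=se_v, zone=self.zone)


@dataclass(frozen=True)
class StudyConfig:
    """Strata and analysis knobs for one study run."""

    seasons: Dict[str, Tuple[date, date]]  # label -> inclusive date range
    windows: Tuple[str, ...] = ("all", "night")
    habitats: Optional[Tuple[str, ...]] = None  # default: habitat-map labels
    gap_min: float = 15.0
    per_individual: bool = False
    n_boot: int = 10_000
    seed: int = 0
    ci: str = "lognormal"
    isopleth_level: float = 0.75
    min_obs: int = 5  # observation points required to fit a pride UD

    def __post_init__(self) -> None:
        spans = sorted(self.seasons.values())
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if a1 >= b0:
                raise ValidationError(
                    f"season date ranges overlap: {(a0, a1)} and {(b0, b1)}"
                )


def percent_error(estimate, reference) -> dict:
    """Percent difference of an estimate from a reference density.

    Accepts REMResult/DensityEstimate-like objects (attributes d/estimate,
    ci_low, ci_high) and ReferenceResult/float references. CI endpoints are
    mapped through the same transformation.
    """
    d_ref = reference.d_ref if hasattr(reference, "d_ref") else float(reference)
    if d_ref <= 0:
        raise ValidationError("reference density must be positive for percent error")
    d = estimate.d if hasattr(estimate, "d") else (
        estimate.estimate if hasattr(estimate, "estimate") else float(estimate)
    )
    out = {"value": 100.0 * (d - d_ref) / d_ref}
    if hasattr(estimate, "ci_low"):
        out["ci_low"] = 100.0 * (estimate.ci_low - d_ref) / d_ref
        out["ci_high"] = 100.0 * (estimate.ci_high - d_ref) / d_ref
    return out


def _season_of(ts: datetime, seasons: Dict[str, Tuple[date, date]]) -> Optional[str]:
    d = ts.date()
    for label, (d0, d1) in seasons.items():
        if d0 <= d <= d1:
            return label
    return None


def _clip_deployment(dep: Deployment, d0: date, d1: date) -> Optional[Deployment]:
    start = max(dep.start, datetime.combine(d0, datetime.min.time()))
    end = min(dep.end, datetime.combine(d1, datetime.max.time()))
    if end <= start:
        return None
    return Deployment(camera_id=dep.camera_id, x=dep.x, y=dep.y,
                      start=start, end=end, habitat=dep.habitat)


def _reference_for(
    prides: Sequence[PrideRecord],
    season: str,
    habitat: str,
    habitat_map: HabitatMap,
    deployments: Sequence[Deployment],
    config: StudyConfig,
) -> Optional[ReferenceResult]:
    poly = habitat_map.polygons[habitat]
    contributions = []  # (N_i, p_i)
    areas = []
    for pride in prides:
        if pride.season and pride.season != season:
            continue
        pts = pride.points
        if pts.shape[0] < config.min_obs:
            log.warning("pride %r: only %d observation points, skipped",
                        pride.pride_id, pts.shape[0])
            continue
        ud = ref.fit_ud(pts)
        hr = ref.isopleth(ud, level=config.isopleth_level, pride_id=pride.pride_id)
        p = ref.overlap_proportion(hr, poly)
        if p > 0:
            contributions.append((pride.n_females, p))
            areas.append(hr.area)
    if not contributions:
        return None
    w = ref.buffer_width(areas)
    cam_pts = np.array([[d.x, d.y] for d in deployments])
    if cam_pts.shape[0] < 3:
        return None
    a = ref.effective_area(cam_pts, w.w, poly)
    a_lo = ref.effective_area(cam_pts, w.w_low, poly)
    a_hi = ref.effective_area(cam_pts, w.w_high, poly)
    return ref.reference_density(contributions, a, a_low=a_lo, a_high=a_hi,
                                 habitat=habitat, season=season, w=w)


def run_study(
    deployments: Sequence[Deployment],
    triggers: Sequence[EventRecord],
    habitat_map: Optional[HabitatMap],
    params: StudyParams,
    config: StudyConfig,
    prides: Optional[Sequence[PrideRecord]] = None,
    reference_truth: Optional[float] = None,
) -> dict:
    """Run the full stratified study; returns a JSON-ready report dict.

    ``reference_truth`` supplies a known true density (simulation studies)
    used for percent error when no pride census is given. Strata with zero
    effort are reported as empty rather than raising.
    """
    habitats = (
        list(config.habitats)
        if config.habitats
        else (habitat_map.labels if habitat_map is not None else [""])
    )
    independent = ev.collapse_to_independent_events(
        sorted(triggers, key=lambda e: (e.camera_id, e.timestamp)),
        gap_min=config.gap_min,
    )
    assigned = ev.assign_habitats(deployments, habitat_map)
    report = {
        "provenance": {
            "seed": config.seed,
            "gap_min": config.gap_min,
            "n_boot": config.n_boot,
            "ci": config.ci,
            "per_individual": config.per_individual,
            "n_triggers": len(list(triggers)),
            "n_independent_events": len(independent),
            "windows": list(config.windows),
            "seasons": {k: [str(v[0]), str(v[1])] for k, v in config.seasons.items()},
        },
        "strata": [],
    }
    boot_seed = config.seed
    for season, (d0, d1) in config.seasons.items():
        season_events = [e for e in independent if _season_of(e.timestamp, config.seasons) == season]
        for habitat in habitats:
            deps = [
                d for d in deployments
                if (not habitat or assigned.get(d.camera_id) == habitat)
            ]
            deps = [c for c in (_clip_deployment(d, d0, d1) for d in deps) if c is not None]
            ref_result = None
            if prides is not None and habitat_map is not None and habitat and deps:
                ref_result = _reference_for(prides, season, habitat, habitat_map,
                                            deps, config)
            for window in config.windows:
                entry = {
                    "season": season,
                    "habitat": habitat,
                    "window": window,
                    "n_cameras": len(deps),
                }
                if not deps:
                    entry.update(effort_hours=0.0, n_events=0, empty=True)
                    report["strata"].append(entry)
                    continue
                tallies = ev.tally(
                    deps, season_events, window=window,
                    per_individual=config.per_individual,
                )
                effort = sum(t.t for t in tallies)
                n_events = int(sum(t.y for t in tallies))
                entry.update(effort_hours=effort, n_events=n_events)
                if effort <= 0:
                    entry["empty"] = True
                    report["strata"].append(entry)
                    continue
                rem_params = params.rem_params(season, habitat, window)
                boot_seed += 1
                if len(tallies) >= 2:
                    rate = ev.bootstrap_rate_variance(
                        tallies, n_boot=config.n_boot, seed=boot_seed
                    )
                else:
                    # single camera: resampling variance undefined; report the
                    # point estimate with zero rate variance, flagged below
                    base = ev.encounter_rate(tallies)
                    rate = ev.EncounterRate(
                        rate=base.rate, y_total=base.y_total, t_total=base.t_total,
                        var_boot=0.0, n_boot=0, seed=None,
                    )
                    entry["rate_variance"] = "unavailable (single camera)"
                result = delta_variance(rate, rem_params, ci_method=config.ci)
                entry["rate_per_hour"] = rate.rate
                entry["rate_var_boot"] = rate.var_boot
                entry["v_kmh"] = rem_params.v
                entry["rem"] = {
                    "estimate": result.d,
                    "se": result.se_d,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "cv2_components": result.cv2_components,
                    "ci_method": result.ci_method,
                }
                reference_obj = None
                if ref_result is not None:
                    reference_obj = ref_result
                    entry["reference"] = {
                        "d_ref": ref_result.d_ref,
                        "ci_low": ref_result.ci_low,
                        "ci_high": ref_result.ci_high,
                        "abundance": ref_result.abundance,
                        "effective_area_km2": ref_result.a,
                        "w_km": ref_result.w.w if ref_result.w else None,
                    }
                elif reference_truth is not None:
                    reference_obj = float(reference_truth)
                    entry["reference"] = {"d_ref": reference_obj, "source": "truth"}
                if reference_obj is not None:
                    entry["percent_error"] = percent_error(result, reference_obj)
                report["strata"].append(entry)
    return report


def effort_events_table(report: dict) -> pd.DataFrame:
    """Per-stratum effort and event counts (with speeds), one row per cell."""
    rows = []
    for s in report["strata"]:
        if s["window"] != "all":
            continue
        night = next(
            (
                n for n in report["strata"]
                if n["season"] == s["season"] and n["habitat"] == s["habitat"]
                and n["window"] == "night"
            ),
            None,
        )
        rows.append(
            {
                "season": s["season"],
                "habitat": s["habitat"],
                "effort_days": s.get("effort_hours", 0.0) / 24.0,
                "events_all": s.get("n_events", 0),
                "events_night": night.get("n_events", 0) if night else None,
                "v_all_kmh": s.get("v_kmh"),
                "v_night_kmh": night.get("v_kmh") if night else None,
            }
        )
    return pd.DataFrame(rows)


def density_table(report: dict) -> pd.DataFrame:
    """REM and reference densities with CIs, one row per season-habitat."""
    rows: Dict[Tuple[str, str], dict] = {}
    for s in report["strata"]:
        key = (s["season"], s["habitat"])
        row = rows.setdefault(key, {"season": key[0], "habitat": key[1]})
        if "rem" in s:
            tag = "night" if s["window"] == "night" else "all"
            row[f"rem_{tag}"] = s["rem"]["estimate"]
            row[f"rem_{tag}_ci_low"] = s["rem"]["ci_low"]
            row[f"rem_{tag}_ci_high"] = s["rem"]["ci_high"]
        if "reference" in s and "d_ref" in s["reference"]:
            row["d_ref"] = s["reference"]["d_ref"]
            row["d_ref_ci_low"] = s["reference"].get("ci_low")
            row["d_ref_ci_high"] = s["reference"].get("ci_high")
    return pd.DataFrame(list(rows.values()))


def error_table(report: dict) -> pd.DataFrame:
    """Percent errors of REM estimates against the reference, per stratum."""
    rows = []
    for s in report["strata"]:
        if "percent_error" in s:
            rows.append(
                {
                    "season": s["season"],
                    "habitat": s["habitat"],
                    "window": s["window"],
                    "percent_error": s["percent_error"]["value"],
                    "ci_low": s["percent_error"].get("ci_low"),
                    "ci_high": s["percent_error"].get("ci_high"),
                }
            )
    return pd.DataFrame(rows)


def plot_percent_errors(report: dict, path) -> None:
    """Minimal percent-error bar chart (all vs night per stratum)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = error_table(report)
    if df.empty:
        raise ValidationError("no percent errors in report; was a reference supplied?")
    strata = sorted({(r.season, r.habitat) for r in df.itertuples()})
    x = np.arange(len(strata))
    width = 0.38
    fig, ax = plt.subplots(figsize=(1.8 * len(strata) + 2, 4))
    for off, window, color in ((-width / 2, "all", "0.7"), (width / 2, "night", "0.35")):
        vals = []
        for s in strata:
            sel = df[(df.season == s[0]) & (df.habitat == s[1]) & (df.window == window)]
            vals.append(float(sel.percent_error.iloc[0]) if len(sel) else np.nan)
        ax.bar(x + off, vals, width, label=window, color=color)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(x, [f"{s}-{h}" for s, h in strata])
    ax.set_ylabel("percent error vs reference")
    ax.legend(title="events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
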